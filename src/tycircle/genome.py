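"""Reference genome, Ty annotations and excluded regions.

Coordinates are 0-based half-open everywhere internally; user-facing
reports render 1-based inclusive ``chrN:start-end`` strings (see
:func:`format_locus`).  All per-element analyses operate in *element
orientation*: for a minus-strand element the 5' LTR is the genomically
last interval and sequences are reverse-complemented on extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
FAMILIES = ("Ty1", "Ty2", "Ty3", "Ty3p", "Ty4", "Ty5")
FULL_LENGTH = "full_length"
SOLO_LTR = "solo_ltr"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def format_locus(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as 1-based inclusive ``chr:s-e``."""
    return f"{chrom}:{start + 1}-{end}"


class GenomeError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


class Genome:
    """An ordered set of named chromosome sequences (A, C, G, T, N)."""

    def __init__(self, chroms: Mapping[str, str]):
        if not chroms:
            raise GenomeError("genome contains no sequences")
        self._chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            if name in self._chroms:
                raise GenomeError(f"duplicate chromosome name {name!r}")
            seq = str(seq).upper()
            if not seq:
                raise GenomeError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
            self._chroms[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in self._chroms.items()]
        SeqIO.write(recs, str(path), "fasta")

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def items(self):
        return self._chroms.items()

    def length(self, name: str) -> int:
        return len(self._chroms[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._chroms.values())

    def slice(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic slice; reverse-complemented when ``strand == '-'``."""
        if chrom not in self._chroms:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        n = len(self._chroms[chrom])
        if not (0 <= start < end <= n):
            raise GenomeError(
                f"interval {format_locus(chrom, start, end)} outside chromosome (len {n})"
            )
        s = self._chroms[chrom][start:end]
        return revcomp(s) if strand == "-" else s


@dataclass(frozen=True)
class TyAnnotation:
    """One annotated Ty feature.

    ``ltr5``/``ltr3`` are genomic sub-intervals and denote the
    *transcriptional* 5'/3' LTR: for a minus-strand element ``ltr5`` is
    the genomically last interval.  Present iff ``element_class`` is
    full_length.
    """

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    element_class: str
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_full_length(self) -> bool:
        return self.element_class == FULL_LENGTH

    @property
    def locus(self) -> str:
        return format_locus(self.chrom, self.start, self.end)

    def sequence(self, genome: Genome) -> str:
        """Element sequence in element orientation."""
        return genome.slice(self.chrom, self.start, self.end, self.strand)

    def ltr_local(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(ltr5, ltr3) intervals in element-local oriented coordinates."""
        if self.ltr5 is None or self.ltr3 is None:
            raise AnnotationError(f"{self.element_id}: full_length element missing LTR interval")
        if self.strand == "+":
            l5 = (self.ltr5[0] - self.start, self.ltr5[1] - self.start)
            l3 = (self.ltr3[0] - self.start, self.ltr3[1] - self.start)
        else:
            l5 = (self.end - self.ltr5[1], self.end - self.ltr5[0])
            l3 = (self.end - self.ltr3[1], self.end - self.ltr3[0])
        return l5, l3


_REQUIRED_COLUMNS = ("chrom", "start", "end", "strand", "family", "element_class")
_LTR_COLUMNS = ("ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end")


def _validate_annotation(ann: TyAnnotation, genome: Genome, row: int | None = None) -> None:
    where = f" (row {row})" if row is not None else ""
    if ann.chrom not in genome:
        raise AnnotationError(f"{ann.element_id}: unknown chromosome {ann.chrom!r}{where}")
    if not ann.start < ann.end:
        raise AnnotationError(f"{ann.element_id}: start >= end{where}")
    if ann.end > genome.length(ann.chrom):
        raise AnnotationError(f"{ann.element_id}: end beyond chromosome{where}")
    if ann.strand not in "+-":
        raise AnnotationError(f"{ann.element_id}: bad strand {ann.strand!r}{where}")
    if ann.family not in FAMILIES:
        raise AnnotationError(f"{ann.element_id}: unknown family {ann.family!r}{where}")
    if ann.element_class not in (FULL_LENGTH, SOLO_LTR):
        raise AnnotationError(f"{ann.element_id}: unknown class {ann.element_class!r}{where}")
    if ann.is_full_length:
        if ann.ltr5 is None or ann.ltr3 is None:
            raise AnnotationError(f"{ann.element_id}: full_length without LTR intervals{where}")
        for name, (a, b) in (("ltr5", ann.ltr5), ("ltr3", ann.ltr3)):
            if not (ann.start <= a < b <= ann.end):
                raise AnnotationError(
                    f"{ann.element_id}: {name} interval outside element{where}"
                )
            if b - a < 50:
                raise AnnotationError(f"{ann.element_id}: {name} shorter than 50 bp{where}")
        first, second = sorted([ann.ltr5, ann.ltr3])
        expected5 = first if ann.strand == "+" else second
        if ann.ltr5 != expected5:
            raise AnnotationError(
                f"{ann.element_id}: ltr5/ltr3 order inconsistent with strand{where}"
            )
    elif ann.ltr5 is not None or ann.ltr3 is not None:
        raise AnnotationError(f"{ann.element_id}: solo_ltr must not carry LTR intervals{where}")


def _split_overlaps(anns: list[TyAnnotation], strict: bool) -> list[TyAnnotation]:
    """Split same-family overlapping annotations at the overlap midpoint."""
    out = sorted(anns, key=lambda a: (a.chrom, a.start, a.end))
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        if a.chrom == b.chrom and a.family == b.family and b.start < a.end:
            if strict:
                raise AnnotationError(
                    f"overlapping {a.family} annotations {a.element_id}/{b.element_id}"
                )
            mid = (b.start + a.end) // 2
            log.warning(
                "overlapping %s annotations %s and %s split at midpoint %s:%d",
                a.family, a.element_id, b.element_id, a.chrom, mid,
            )
            for ann, field in ((a, "end"), (b, "start")):
                for name, iv in (("ltr5", ann.ltr5), ("ltr3", ann.ltr3)):
                    if iv is not None:
                        lo, hi = iv
                        new_lo = max(lo, mid) if field == "start" else lo
                        new_hi = min(hi, mid) if field == "end" else hi
                        if (new_lo, new_hi) != (lo, hi):
                            raise AnnotationError(
                                f"overlap split at {mid} would truncate {name} of {ann.element_id}"
                            )
            out[i] = replace(a, end=mid)
            out[i + 1] = replace(b, start=mid)
    return out


def load_annotations(
    table_path: str | Path, genome: Genome, strict: bool = False
) -> list[TyAnnotation]:
    """Load a Table-S3-style tab-separated Ty annotation table.

    Required named columns: chrom, start, end, strand, family,
    element_class; full-length rows additionally carry ltr5_start,
    ltr5_end, ltr3_start, ltr3_end.  An element_id column is optional.
    Same-family overlaps are split at the overlap midpoint with a logged
    warning (an error in strict mode).
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    anns: list[TyAnnotation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            element_id = getattr(row, "element_id", None) or f"{row.family}-{idx - 1}"
            cls = row.element_class
            ltr5 = ltr3 = None
            if cls == FULL_LENGTH:
                vals = [getattr(row, c, None) for c in _LTR_COLUMNS]
                if any(v is None or pd.isna(v) for v in vals):
                    raise AnnotationError("full_length row lacks LTR columns")
                ltr5 = (int(vals[0]), int(vals[1]))
                ltr3 = (int(vals[2]), int(vals[3]))
            ann = TyAnnotation(
                element_id=str(element_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                family=str(row.family),
                element_class=str(cls),
                ltr5=ltr5,
                ltr3=ltr3,
            )
        except AnnotationError:
            raise
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"malformed annotation row {idx}: {exc}") from exc
        _validate_annotation(ann, genome, row=idx)
        anns.append(ann)
    anns = _split_overlaps(anns, strict=strict)
    counts = pd.Series([(a.family, a.element_class) for a in anns]).value_counts()
    for (family, cls), n in counts.items():
        log.info("loaded %d %s %s annotations", n, family, cls)
    return anns


def write_annotations(anns: Sequence[TyAnnotation], path: str | Path) -> None:
    rows = []
    for a in anns:
        rows.append(
            {
                "element_id": a.element_id,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "family": a.family,
                "element_class": a.element_class,
                "ltr5_start": a.ltr5[0] if a.ltr5 else "",
                "ltr5_end": a.ltr5[1] if a.ltr5 else "",
                "ltr3_start": a.ltr3[0] if a.ltr3 else "",
                "ltr3_end": a.ltr3[1] if a.ltr3 else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def extract_ltr_pairs(
    annotations: Iterable[TyAnnotation], genome: Genome, family: str
) -> list[tuple[str, str, str]]:
    """(5' LTR seq, 3' LTR seq, element id) per full-length element, in
    element orientation (minus-strand elements reverse-complemented)."""
    pairs = []
    for ann in annotations:
        if ann.family != family or not ann.is_full_length:
            continue
        if ann.ltr5 is None or ann.ltr3 is None:
            raise AnnotationError(f"{ann.element_id}: full_length element missing an LTR interval")
        ltr5 = genome.slice(ann.chrom, *ann.ltr5, ann.strand)
        ltr3 = genome.slice(ann.chrom, *ann.ltr3, ann.strand)
        pairs.append((ltr5, ltr3, ann.element_id))
    return pairs


class ExclusionSet:
    """Merged, sorted genomic intervals excluded from coverage analyses
    (telomeres, rDNA and similar high-eccDNA regions)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad exclusion interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            merged: list[tuple[int, int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._by_chrom[chrom] = merged

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExclusionSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
        return cls(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))

    def intervals(self, chrom: str | None = None):
        if chrom is not None:
            return list(self._by_chrom.get(chrom, []))
        return [(c, s, e) for c, ivs in sorted(self._by_chrom.items()) for s, e in ivs]

    def __contains__(self, pos: tuple[str, int]) -> bool:
        chrom, p = pos
        return any(s <= p < e for s, e in self._by_chrom.get(chrom, []))

    def mask(self, chrom: str, length: int):
        """Boolean numpy mask, True at excluded positions."""
        import numpy as np

        m = np.zeros(length, dtype=bool)
        for s, e in self._by_chrom.get(chrom, []):
            m[max(0, s) : min(length, e)] = True
        return m

    @property
    def total_length(self) -> int:
        return sum(e - s for ivs in self._by_chrom.values() for s, e in ivs)

    @property
    def n_intervals(self) -> int:
        return sum(len(ivs) for ivs in self._by_chrom.values())


def build_exclusion_set(
    intervals: Iterable[tuple[str, int, int]] | str | Path | None = None,
) -> ExclusionSet:
    """Build an :class:`ExclusionSet` from in-memory intervals or a TSV file."""
    if intervals is None:
        return ExclusionSet()
    if isinstance(intervals, (str, Path)):
        return ExclusionSet.from_tsv(intervals)
    return ExclusionSet(intervals)
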