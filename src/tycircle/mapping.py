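"""Multi-mapping read placement.

The built-in mapper reports *every* genome position where a read (or its
reverse complement) aligns end-to-end with at most ``max_mismatch``
substitutions, truncated deterministically at ``max_hits`` placements.
Completeness is guaranteed by pigeonhole seeding: the read is cut into
``max_mismatch + 1`` disjoint exact-match seeds, so any placement within
the mismatch budget leaves at least one seed intact.  Gapped alignments
enter only through :func:`ingest_sam`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .genome import Genome, revcomp

log = logging.getLogger(__name__)


class Read(NamedTuple):
    """A sequencing read: identifier, sequence, optional quality string."""

    read_id: str
    sequence: str
    quality: str | None = None


class Placement(NamedTuple):
    chrom: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class MapperConfig:
    """Built-in mapper parameters.

    max_mismatch: substitutions tolerated over the full read (default 4,
        ~3% of a 142-nt read).
    max_hits: placement cap per read; all reported coordinates up to the
        cap are kept (default 1000).
    seed_length: exact-seed length override; by default derived per read
        as floor(L / (max_mismatch + 1)), the longest length for which
        the pigeonhole guarantee holds.
    """

    max_mismatch: int = 4
    max_hits: int = 1000
    seed_length: int | None = None

    def __post_init__(self):
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class MultiMapRecord:
    """One read with the complete (capped) set of genome placements."""

    read_id: str
    sequence: str
    quality: str | None = None
    placements: list[Placement] = field(default_factory=list)
    truncated: bool = False
    unmapped_reason: str | None = None

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    @property
    def n_placements(self) -> int:
        return len(self.placements)

    @property
    def mapped(self) -> bool:
        return bool(self.placements)

    @property
    def mean_quality(self) -> float:
        if not self.quality:
            return 0.0
        return float(np.mean([ord(c) - 33 for c in self.quality]))

    def canonical_placement(self) -> Placement:
        return min(self.placements)


class MappingError(ValueError):
    pass


_VALID_READ = re.compile(r"^[ACGTN]+$")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class GenomeMapper:
    """Reusable seed index + verifier over one :class:`Genome`."""

    def __init__(self, genome: Genome, config: MapperConfig | None = None):
        self.genome = genome
        self.config = config or MapperConfig()
        self._names = genome.names
        self._arrays = {name: _encode(genome[name]) for name in self._names}
        self._indexes: dict[int, dict[bytes, list[tuple[str, int]]]] = {}

    def _index(self, k: int) -> dict[bytes, list[tuple[str, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for name in self._names:
                raw = self.genome[name].encode("ascii")
                for pos in range(len(raw) - k + 1):
                    idx.setdefault(raw[pos : pos + k], []).append((name, pos))
            self._indexes[k] = idx
        return idx

    def _seed_length(self, read_len: int) -> int:
        if self.config.seed_length is not None:
            return self.config.seed_length
        return max(1, read_len // (self.config.max_mismatch + 1))

    def map_sequence(self, seq: str) -> tuple[list[Placement], bool]:
        """All placements of ``seq`` (both strands), sorted by
        (chrom, start, strand) and truncated at ``max_hits``.

        Returns (placements, truncated_flag).
        """
        seq = seq.upper()
        if not _VALID_READ.match(seq):
            raise MappingError("read contains characters outside A,C,G,T,N")
        L = len(seq)
        mm = self.config.max_mismatch
        k = self._seed_length(L)
        if L < k:
            return [], False
        idx = self._index(k)
        n_chunks = mm + 1
        queries = {"+": seq, "-": revcomp(seq)}
        candidates: set[tuple[str, int, str]] = set()
        for strand, q in queries.items():
            qb = q.encode("ascii")
            for j in range(n_chunks):
                off = j * k
                if off + k > L:
                    break
                for chrom, pos in idx.get(qb[off : off + k], ()):
                    start = pos - off
                    if 0 <= start <= len(self._arrays[chrom]) - L:
                        candidates.add((chrom, start, strand))
        placements: list[Placement] = []
        qarrs = {s: _encode(q) for s, q in queries.items()}
        for chrom, start, strand in candidates:
            arr = self._arrays[chrom]
            mis = int(np.count_nonzero(arr[start : start + L] != qarrs[strand]))
            if mis <= mm:
                placements.append(Placement(chrom, start, strand, mis))
        placements.sort(key=lambda p: (p.chrom, p.start, p.strand))
        truncated = len(placements) > self.config.max_hits
        if truncated:
            placements = placements[: self.config.max_hits]
        return placements, truncated

    def map_read(self, read: Read) -> MultiMapRecord:
        seq = read.sequence.upper()
        k = self._seed_length(len(seq))
        if len(seq) < k:
            return MultiMapRecord(
                read.read_id, seq, read.quality, unmapped_reason="shorter_than_seed"
            )
        placements, truncated = self.map_sequence(seq)
        if not placements:
            return MultiMapRecord(read.read_id, seq, read.quality, unmapped_reason="no_placement")
        return MultiMapRecord(read.read_id, seq, read.quality, placements, truncated=truncated)

    def map_reads(self, reads: Iterable[Read | tuple]) -> list[MultiMapRecord]:
        records = [self.map_read(Read(*r)) for r in reads]
        n_mapped = sum(r.mapped for r in records)
        log.info("mapped %d/%d reads", n_mapped, len(records))
        return records


def map_reads(
    reads: Iterable[Read | tuple], genome: Genome, config: MapperConfig | None = None
) -> list[MultiMapRecord]:
    """Map an iterable of reads against a genome (convenience wrapper)."""
    return GenomeMapper(genome, config).map_reads(reads)


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq).upper(), qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


_XA_RE = re.compile(r"([^,;]+),([+-])(\d+),([^,;]*),(\d+);")


def ingest_sam(path: str | Path) -> list[MultiMapRecord]:
    """Pool multi-hit SAM/BAM records into one MultiMapRecord per read.

    Placements are collected from primary and secondary alignments and
    from BWA-style XA tags, then deduplicated across encodings.
    """
    by_name: dict[str, MultiMapRecord] = {}
    placements: dict[str, set[Placement]] = {}
    n_skipped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for seg in fh:
            name = seg.query_name
            if seg.is_unmapped:
                if name not in by_name:
                    seq = seg.query_sequence or ""
                    by_name[name] = MultiMapRecord(
                        name, seq, seg.qual, unmapped_reason="unmapped_flag"
                    )
                    placements[name] = set()
                continue
            if not seg.is_secondary and not seg.is_supplementary:
                if seg.query_sequence is None or seg.cigarstring is None:
                    n_skipped += 1
                    continue
                seq = seg.query_sequence
                qual = seg.qual
                if seg.is_reverse:
                    seq = revcomp(seq)
                    qual = qual[::-1] if qual else qual
                rec = by_name.get(name)
                if rec is None or not rec.sequence:
                    by_name[name] = MultiMapRecord(name, seq.upper(), qual)
                    placements.setdefault(name, set())
            else:
                by_name.setdefault(name, MultiMapRecord(name, "", None))
                placements.setdefault(name, set())
            strand = "-" if seg.is_reverse else "+"
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            placements.setdefault(name, set()).add(
                Placement(seg.reference_name, seg.reference_start, strand, int(nm))
            )
            if seg.has_tag("XA"):
                for chrom, s, pos, _cigar, nm in _XA_RE.findall(seg.get_tag("XA")):
                    placements[name].add(Placement(chrom, int(pos) - 1, s, int(nm)))
    if n_skipped:
        log.warning("skipped %d primary records without sequence/CIGAR", n_skipped)
    out = []
    for name, rec in by_name.items():
        pls = sorted(placements.get(name, ()), key=lambda p: (p.chrom, p.start, p.strand))
        if pls and rec.unmapped_reason is None:
            rec.placements = pls
        out.append(rec)
    return out


def remove_duplicates(records: Sequence[MultiMapRecord]) -> list[MultiMapRecord]:
    """Collapse reads sharing an identical canonical placement.

    The canonical placement of a multi-mapper is its lexicographically
    smallest (chrom, start, strand).  Within a duplicate group the read
    with the highest mean base quality is kept (ties broken by input
    order).  Unmapped records pass through unchanged.  Idempotent.
    """
    best: dict[tuple[str, int, str], MultiMapRecord] = {}
    unmapped = []
    total_mapped = 0
    for rec in records:
        if not rec.mapped:
            unmapped.append(rec)
            continue
        total_mapped += 1
        key = rec.canonical_placement()[:3]
        cur = best.get(key)
        if (
            cur is None
            or rec.mean_quality > cur.mean_quality
            or (rec.mean_quality == cur.mean_quality and rec.read_id < cur.read_id)
        ):
            best[key] = rec
    retained = list(best.values())
    log.info("duplicate removal: retained %d of %d mapped reads", len(retained), total_mapped)
    return retained + unmapped


def records_to_tsv(records: Sequence[MultiMapRecord], path: str | Path) -> None:
    """Export placements as a BED-like TSV (one row per placement)."""
    import pandas as pd

    rows = []
    for rec in records:
        if not rec.mapped:
            rows.append(
                {
                    "chrom": ".",
                    "start": -1,
                    "end": -1,
                    "read_id": rec.read_id,
                    "strand": ".",
                    "mismatches": -1,
                    "n_placements": 0,
                    "reason": rec.unmapped_reason or "",
                }
            )
            continue
        for p in rec.placements:
            rows.append(
                {
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.start + rec.read_length,
                    "read_id": rec.read_id,
                    "strand": p.strand,
                    "mismatches": p.mismatches,
                    "n_placements": rec.n_placements,
                    "reason": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
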