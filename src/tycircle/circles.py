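"""eccDNA circle topologies and their expected genome coverage.

Circle models are built from annotated elements: a one-LTR circle spans
midpoint-of-5'-LTR to midpoint-of-3'-LTR (the product of LTR-LTR
recombination within one element), a two-LTR circle is the whole element
joined end-to-start (the NHEJ product of linear extrachromosomal Ty
DNA), and inter-LTR circles join LTRs of different features separated by
10 bp - 30 kb.  Expected coverage extracts every rotation k-mer of a
circle (junction-spanning ones included), maps them like reads and
averages the weighted coverage in element windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage import ProfileConfig, element_profile, weighted_track
from .genome import AnnotationError, Genome, TyAnnotation, revcomp
from .mapping import GenomeMapper, MapperConfig, MultiMapRecord, Read

log = logging.getLogger(__name__)


class CircleScenario(str, Enum):
    ONE_LTR_SAME = "ONE_LTR_SAME"          # LTR-LTR recombination within one element
    TWO_LTR = "TWO_LTR"                    # NHEJ of the linear element, both LTRs
    ONE_LTR_BETWEEN = "ONE_LTR_BETWEEN"    # recombination between LTRs of different features
    AUTOINT_INVERTED = "AUTOINT_INVERTED"  # autointegration, inverted-segment circle
    AUTOINT_TRUNCATED = "AUTOINT_TRUNCATED"  # autointegration, truncated circle
    RECOMB_PARTIAL = "RECOMB_PARTIAL"      # partial element content via inter-LTR recombination


@dataclass(frozen=True)
class CircleModelConfig:
    """kmer_len: read-length analogue used for expected coverage;
    min_sep/max_sep: allowed gap between facing LTR ends for inter-LTR
    circles (10 bp and 30,000 bp)."""

    kmer_len: int = 142
    min_sep: int = 10
    max_sep: int = 30000

    def __post_init__(self):
        if not 0 < self.min_sep < self.max_sep:
            raise ValueError("require 0 < min_sep < max_sep")


def _min_rotation(s: str) -> str:
    # Booth's algorithm; O(n)
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + len(s)]


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation of seq or of its reverse
    complement — the rotation- and strand-invariant identity of a circle."""
    return min(_min_rotation(seq), _min_rotation(revcomp(seq)))


@dataclass
class CircleModel:
    """One simulated eccDNA topology.  Two models are equal iff one's
    sequence is a rotation of the other's (or of its reverse complement)."""

    scenario: CircleScenario
    sequence: str
    source: tuple[str, ...]
    junction_note: str = ""
    _canonical: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("circular sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def canonical(self) -> str:
        if self._canonical is None:
            self._canonical = canonical_rotation(self.sequence)
        return self._canonical

    def __eq__(self, other) -> bool:
        if not isinstance(other, CircleModel):
            return NotImplemented
        return self.scenario == other.scenario and self.canonical() == other.canonical()

    def __hash__(self):
        return hash((self.scenario, self.canonical()))


def ltr_midpoint(interval: tuple[int, int]) -> int:
    """Midpoint offset convention: floor(length / 2) from interval start."""
    start, end = interval
    return start + (end - start) // 2


def one_ltr_circle(element: TyAnnotation, genome: Genome) -> CircleModel:
    """Circle from LTR-LTR recombination within one full-length element:
    genomic slice [midpoint(5' LTR), midpoint(3' LTR)) in element
    orientation, closed into a circle.  For identical equal-length LTRs
    the circle carries the internal sequence plus one full LTR."""
    if element.ltr5 is None or element.ltr3 is None:
        raise AnnotationError(f"{element.element_id}: missing LTR sub-interval")
    m5 = ltr_midpoint(element.ltr5)
    m3 = ltr_midpoint(element.ltr3)
    lo, hi = (m5, m3) if element.strand == "+" else (m3, m5)
    seq = genome.slice(element.chrom, lo, hi, element.strand)
    return CircleModel(
        CircleScenario.ONE_LTR_SAME,
        seq,
        (element.element_id,),
        junction_note="LTR midpoints fused; junction reconstitutes one full LTR",
    )


def two_ltr_circle(element: TyAnnotation, genome: Genome) -> CircleModel:
    """Circle from NHEJ of the whole linear element [start, end): the
    3'-LTR end is joined to the 5'-LTR start."""
    if element.ltr5 is None or element.ltr3 is None:
        raise AnnotationError(f"{element.element_id}: missing LTR sub-interval")
    seq = element.sequence(genome)
    return CircleModel(
        CircleScenario.TWO_LTR,
        seq,
        (element.element_id,),
        junction_note="element 3' end ligated to 5' start (NHEJ)",
    )


def _all_ltr_features(annotations: Iterable[TyAnnotation]):
    """Every LTR interval on the genome: solo LTRs and the LTRs of
    full-length elements, as (chrom, start, end, owner id, label)."""
    feats = []
    for a in annotations:
        if a.is_full_length:
            feats.append((a.chrom, a.ltr5[0], a.ltr5[1], a.element_id, "ltr5"))
            feats.append((a.chrom, a.ltr3[0], a.ltr3[1], a.element_id, "ltr3"))
        else:
            feats.append((a.chrom, a.start, a.end, a.element_id, "solo"))
    return sorted(feats)


def inter_ltr_circles(
    annotations: Sequence[TyAnnotation],
    genome: Genome,
    config: CircleModelConfig | None = None,
) -> list[CircleModel]:
    """One circle per same-chromosome ordered LTR pair whose gap between
    facing ends lies within [min_sep, max_sep]; the extracted sequence
    runs LTR-midpoint to LTR-midpoint on the forward strand."""
    cfg = config or CircleModelConfig()
    feats = _all_ltr_features(annotations)
    models = []
    for i, (chrom_a, sa, ea, id_a, lab_a) in enumerate(feats):
        for chrom_b, sb, eb, id_b, lab_b in feats[i + 1 :]:
            if chrom_b != chrom_a:
                break
            gap = sb - ea
            if gap < cfg.min_sep or gap > cfg.max_sep:
                continue
            lo = sa + (ea - sa) // 2
            hi = sb + (eb - sb) // 2
            seq = genome.slice(chrom_a, lo, hi, "+")
            models.append(
                CircleModel(
                    CircleScenario.ONE_LTR_BETWEEN,
                    seq,
                    (f"{id_a}:{lab_a}", f"{id_b}:{lab_b}"),
                    junction_note=f"midpoint-to-midpoint, gap {gap} bp",
                )
            )
    return models


def circle_kmers(model: CircleModel, kmer_len: int) -> list[str]:
    """All kmer_len-mers of a circle, one per rotation start (exactly L
    for a circle of length L); junction-spanning k-mers included."""
    L = model.length
    if L < kmer_len:
        log.warning("circle of length %d shorter than k=%d, no k-mers", L, kmer_len)
        return []
    doubled = model.sequence + model.sequence
    return [doubled[i : i + kmer_len] for i in range(L)]


def expected_circle_coverage(
    models: Sequence[CircleModel],
    genome: Genome,
    elements: Sequence[TyAnnotation],
    mapper_config: MapperConfig | None = None,
    profile_config: ProfileConfig | None = None,
    kmer_len: int = 142,
) -> dict[CircleScenario, dict[str, np.ndarray]]:
    """Expected element-window coverage profile per circle scenario.

    All rotation k-mers of every model are mapped with the standard
    mapper, weighted 1/n, accumulated into a track and averaged across
    the given full-length elements.
    """
    if not models:
        raise ValueError("no circle models supplied")
    by_scenario: dict[CircleScenario, list[CircleModel]] = {}
    for m in models:
        by_scenario.setdefault(m.scenario, []).append(m)
    mapper = GenomeMapper(genome, mapper_config)
    out = {}
    for scenario, group in by_scenario.items():
        pseudo = []
        for j, model in enumerate(group):
            for i, kmer in enumerate(circle_kmers(model, kmer_len)):
                pseudo.append(Read(f"{scenario.value}:{j}:{i}", kmer))
        records = [r for r in mapper.map_reads(pseudo) if r.mapped]
        track = weighted_track(records, genome)
        out[scenario] = element_profile(track, elements, profile_config)
    return out


def write_circles_fasta(models: Sequence[CircleModel], path: str | Path) -> None:
    """Export models linearized at the canonical rotation."""
    with open(path, "w") as fh:
        for i, m in enumerate(models):
            name = f"{m.scenario.value}|{'+'.join(m.source)}|{i}"
            fh.write(f">{name}\n{m.canonical()}\n")
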