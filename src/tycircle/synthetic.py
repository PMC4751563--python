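"""Synthetic genomes, eccDNA circles and reads with complete ground truth.

The generator states a toy version of the world the pipeline analyses: a
clonal genome carrying full-length LTR retrotransposons whose 5'/3' LTR
pairs have diverged by point mutations (and rare 1-bp indels), plus solo
LTRs; eccDNA circles for each formation scenario; and uniform-start reads
with substitution errors and two-level quality strings.  Everything is
deterministic under a fixed seed, and every read is traceable to a truth
record.

Scenario labels follow the circle-formation taxonomy:
I   two-LTR circle (NHEJ of the linear element)
II  one-LTR circle with hybrid switch exactly at the U3/R border (the
    transpositional circle's *apparent* breakpoint)
III autointegration, inverted-segment circle
IV  autointegration, truncated circle
V   one-LTR circle with hybrid switch at a chosen alignment column
    (intrachromatid LTR-LTR recombination)
VI/VII inter-LTR circles with partial element content
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .breakpoints import GAP, LtrAlignment, LtrRegionModel, align_ltr_pair
from .circles import CircleModel, CircleScenario, ltr_midpoint, one_ltr_circle, two_ltr_circle
from .genome import FULL_LENGTH, SOLO_LTR, Genome, TyAnnotation, revcomp
from .mapping import Read

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_HIGH_Q = "I"  # Q40
_LOW_Q = "#"   # Q2


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the synthetic experiment.

    Geometry defaults approximate a Ty1 element (330-bp LTRs, 5300-bp
    internal sequence); reads default to 142 nt.  ltr_pair_divergence is
    the per-column substitution probability between an element's two
    LTRs; error_rate the per-base sequencing substitution rate.
    """

    n_chromosomes: int = 1
    chrom_length: int = 30000
    n_fullength_elements: int = 2
    n_solo_ltrs: int = 2
    ltr_length: int = 330
    internal_length: int = 5300
    ltr_pair_divergence: float = 0.02
    indel_probability: float = 0.001
    solo_divergence: float = 0.05
    u3_fraction: float = 0.7
    r_fraction: float = 0.1
    read_length: int = 142
    error_rate: float = 0.002
    q_model: float = 0.5
    depth: float = 30.0
    min_flank: int = 600
    family: str = "Ty1"
    seed: int = 0

    def __post_init__(self):
        for name in ("ltr_pair_divergence", "indel_probability", "solo_divergence",
                     "u3_fraction", "r_fraction", "error_rate", "q_model"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.u3_fraction + self.r_fraction >= 1.0:
            raise ValueError("u3_fraction + r_fraction must be < 1")


@dataclass
class ElementTruth:
    element_id: str
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    sub_positions: tuple[int, ...]  # LTR-local positions mutated in the 3' copy
    indels: tuple[str, ...]         # e.g. "ins@17", "del@203"


@dataclass
class CircleTruth:
    circle_id: str
    scenario: str
    element_id: str
    length: int
    switch_column: int = -1      # alignment column (scenarios II/V)
    junction_position: int = -1  # sequence offset of a structural junction (I/III/IV)
    note: str = ""


@dataclass
class SyntheticTruth:
    elements: list[ElementTruth] = field(default_factory=list)
    circles: list[CircleTruth] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def mutate_ltr(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> tuple[str, tuple[int, ...], tuple[str, ...]]:
    """Divergent copy of an LTR: per-column substitutions plus rare 1-bp
    insertions/deletions.  Returns (copy, substituted positions, indels)."""
    out = []
    subs = []
    indels = []
    for i, base in enumerate(seq):
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:
                indels.append(f"del@{i}")
                continue
            ins = chr(rng.choice(BASES))
            out.append(ins)
            out.append(base)
            indels.append(f"ins@{i}")
            continue
        if rng.random() < sub_rate:
            alt = chr(rng.choice(BASES[BASES != ord(base)]))
            out.append(alt)
            subs.append(i)
        else:
            out.append(base)
    return "".join(out), tuple(subs), tuple(indels)


def build_genome(config: SyntheticConfig) -> tuple[Genome, list[TyAnnotation], SyntheticTruth]:
    """Random background genome with implanted full-length elements
    (LTR5 + internal + divergent LTR3) and solo LTRs, evenly spaced with
    at least min_flank bp of background around every feature."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    # features round-robin across chromosomes
    features: list[tuple[str, int]] = []  # (kind, index)
    for i in range(config.n_fullength_elements):
        features.append(("full", i))
    for i in range(config.n_solo_ltrs):
        features.append(("solo", i))
    per_chrom: dict[str, list[tuple[str, int]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    names = list(per_chrom)
    for j, feat in enumerate(features):
        per_chrom[names[j % len(names)]].append(feat)

    # element sequences first (deterministic order), then placement
    full_seqs = []
    for i in range(config.n_fullength_elements):
        ltr5 = _random_dna(rng, config.ltr_length)
        ltr3, subs, indels = mutate_ltr(
            rng, ltr5, config.ltr_pair_divergence, config.indel_probability
        )
        internal = _random_dna(rng, config.internal_length)
        full_seqs.append((ltr5, internal, ltr3, subs, indels))
    solo_seqs = []
    for i in range(config.n_solo_ltrs):
        if full_seqs:
            base = full_seqs[i % len(full_seqs)][0]
            solo, _, _ = mutate_ltr(rng, base, config.solo_divergence, config.indel_probability)
        else:
            solo = _random_dna(rng, config.ltr_length)
        solo_seqs.append(solo)

    chroms: dict[str, str] = {}
    annotations: list[TyAnnotation] = []
    for chrom in names:
        feats = per_chrom[chrom]
        seqs = []
        for kind, i in feats:
            if kind == "full":
                ltr5, internal, ltr3, _, _ = full_seqs[i]
                seqs.append(ltr5 + internal + ltr3)
            else:
                seqs.append(solo_seqs[i])
        total = sum(len(s) for s in seqs)
        gap = (config.chrom_length - total) // (len(feats) + 1) if feats else config.chrom_length
        if feats and gap < config.min_flank:
            raise ValueError(
                f"chromosome {chrom} too short for {len(feats)} features with "
                f">= {config.min_flank} bp flanks; increase chrom_length to "
                f">= {total + (len(feats) + 1) * config.min_flank}"
            )
        parts = []
        pos = 0
        for (kind, i), seq in zip(feats, seqs):
            parts.append(_random_dna(rng, gap))
            pos += gap
            start = pos
            parts.append(seq)
            pos += len(seq)
            if kind == "full":
                ltr5, internal, ltr3, subs, indels = full_seqs[i]
                eid = f"{config.family}-{i + 1}"
                ann = TyAnnotation(
                    element_id=eid,
                    chrom=chrom,
                    start=start,
                    end=pos,
                    strand="+",
                    family=config.family,
                    element_class=FULL_LENGTH,
                    ltr5=(start, start + len(ltr5)),
                    ltr3=(pos - len(ltr3), pos),
                )
                annotations.append(ann)
                truth.elements.append(
                    ElementTruth(eid, chrom, start, pos, ann.ltr5, ann.ltr3, subs, indels)
                )
            else:
                annotations.append(
                    TyAnnotation(
                        element_id=f"{config.family}-solo-{i + 1}",
                        chrom=chrom,
                        start=start,
                        end=pos,
                        strand="+",
                        family=config.family,
                        element_class=SOLO_LTR,
                    )
                )
        tail = config.chrom_length - pos
        parts.append(_random_dna(rng, max(tail, config.min_flank if feats else 0)))
        chroms[chrom] = "".join(parts)
    genome = Genome(chroms)
    log.info(
        "synthetic genome: %d chromosome(s), %d full-length, %d solo LTRs",
        config.n_chromosomes, config.n_fullength_elements, config.n_solo_ltrs,
    )
    return genome, annotations, truth


def _strip(s: str) -> str:
    return s.replace(GAP, "")


def region_model_for(alignment: LtrAlignment, config: SyntheticConfig) -> LtrRegionModel:
    """U3-R-U5 borders as alignment columns from the configured fractions."""
    L = alignment.length
    return LtrRegionModel(
        u3_end_column=int(round(config.u3_fraction * L)),
        r_end_column=int(round((config.u3_fraction + config.r_fraction) * L)),
    )


def _hybrid_ltr_circle(
    element: TyAnnotation,
    genome: Genome,
    alignment: LtrAlignment,
    switch_column: int,
    scenario_note: str,
) -> str:
    """Circle from LTR-LTR recombination at one alignment column: the
    excised circle carries internal sequence flanked by the hybrid LTR
    (3'-LTR prefix up to the switch, 5'-LTR suffix after it)."""
    if not 0 < switch_column < alignment.length:
        raise ValueError(f"switch_column {switch_column} outside alignment (len {alignment.length})")
    l5_local, l3_local = element.ltr_local()
    seq = element.sequence(genome)
    internal = seq[l5_local[1] : l3_local[0]]
    suffix5 = _strip(alignment.gapped5[switch_column:])
    prefix3 = _strip(alignment.gapped3[:switch_column])
    # reading circularly: ... internal | prefix3 >switch> suffix5 | internal ...
    return suffix5 + internal + prefix3


def make_circle(
    scenario: str,
    element: TyAnnotation,
    genome: Genome,
    config: SyntheticConfig,
    rng: np.random.Generator,
    switch_column: int | None = None,
    insertion_offset: int | None = None,
    partner: TyAnnotation | None = None,
    alignment: LtrAlignment | None = None,
    circle_id: str | None = None,
) -> tuple[CircleModel, CircleTruth]:
    """Circle model + truth record for one formation scenario (I-VII)."""
    cid = circle_id or f"circle-{scenario}-{element.element_id}"
    if scenario == "I":
        model = two_ltr_circle(element, genome)
        truth = CircleTruth(
            cid, scenario, element.element_id, model.length,
            junction_position=0, note="element end ligated to start",
        )
        return model, truth
    if scenario in ("II", "V"):
        if alignment is None:
            l5_local, l3_local = element.ltr_local()
            seq = element.sequence(genome)
            alignment = align_ltr_pair(
                seq[l5_local[0] : l5_local[1]], seq[l3_local[0] : l3_local[1]], element.element_id
            )
        if scenario == "II":
            col = region_model_for(alignment, config).u3_end_column
        elif switch_column is not None:
            col = switch_column
        else:
            inf = alignment.informative_columns
            lo = inf[0] + 1 if inf else 1
            hi = inf[-1] if len(inf) > 1 else alignment.length - 1
            choices = [c for c in range(lo, max(hi, lo + 1)) if c not in set(inf)]
            col = int(rng.choice(choices)) if choices else alignment.length // 2
        seq = _hybrid_ltr_circle(element, genome, alignment, col, scenario)
        model = CircleModel(
            CircleScenario.ONE_LTR_SAME, seq, (element.element_id,),
            junction_note=f"hybrid LTR switch at alignment column {col}",
        )
        return model, CircleTruth(cid, scenario, element.element_id, model.length, switch_column=col)
    if scenario in ("III", "IV"):
        seq = element.sequence(genome)
        l5_local, l3_local = element.ltr_local()
        if insertion_offset is None:
            insertion_offset = int(rng.integers(l5_local[1] + 200, l3_local[0] - 200))
        x = insertion_offset
        if scenario == "III":
            circ = seq[:x] + revcomp(seq[x:])
            model = CircleModel(
                CircleScenario.AUTOINT_INVERTED, circ, (element.element_id,),
                junction_note=f"inverted segment from offset {x}",
            )
        else:
            circ = seq[:x]
            model = CircleModel(
                CircleScenario.AUTOINT_TRUNCATED, circ, (element.element_id,),
                junction_note=f"truncated at offset {x}, end joined to start",
            )
        return model, CircleTruth(
            cid, scenario, element.element_id, model.length, junction_position=x
        )
    if scenario in ("VI", "VII"):
        if partner is None:
            raise ValueError(f"scenario {scenario} requires a partner LTR annotation")
        own = element.ltr5 if scenario == "VI" else element.ltr3
        if own is None:
            raise ValueError("element lacks LTR intervals")
        a = (element.chrom, own)
        b = (partner.chrom, (partner.start, partner.end))
        if a[0] != b[0]:
            raise ValueError("partner LTR must share the chromosome")
        (lo_iv, hi_iv) = sorted([a[1], b[1]])
        lo = ltr_midpoint(lo_iv)
        hi = ltr_midpoint(hi_iv)
        seq = genome.slice(element.chrom, lo, hi, "+")
        kind = CircleScenario.ONE_LTR_BETWEEN if scenario == "VI" else CircleScenario.RECOMB_PARTIAL
        model = CircleModel(
            kind, seq, (element.element_id, partner.element_id),
            junction_note="midpoint-to-midpoint between different LTR features",
        )
        return model, CircleTruth(
            cid, scenario, element.element_id, model.length,
            note=f"partner={partner.element_id}",
        )
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class ReadSource:
    name: str
    sequence: str
    circular: bool = False


def simulate_reads(
    sources: Sequence[ReadSource],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[Read], list[dict]]:
    """Uniform-start reads from circles (all rotations, so junction
    reads occur) and/or linear sequences, with Bernoulli substitution
    errors; errored bases receive a low quality with probability q_model.
    Read count per source is round(depth * length / read_length)."""
    reads: list[Read] = []
    truth: list[dict] = []
    L = config.read_length
    for src in sources:
        n_src = len(src.sequence)
        if n_src < L:
            raise ValueError(f"source {src.name} shorter than read length")
        n_reads = int(round(config.depth * n_src / L))
        template = src.sequence + src.sequence if src.circular else src.sequence
        max_start = n_src if src.circular else n_src - L + 1
        starts = rng.integers(0, max_start, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i, (start, flip) in enumerate(zip(starts, strands)):
            seq = template[start : start + L]
            strand = "-" if flip else "+"
            if flip:
                seq = revcomp(seq)
            arr = bytearray(seq.encode("ascii"))
            qual = bytearray((_HIGH_Q * L).encode("ascii"))
            err_mask = rng.random(L) < config.error_rate
            err_positions = np.flatnonzero(err_mask)
            for p in err_positions:
                alt = BASES[BASES != arr[p]]
                arr[p] = int(rng.choice(alt))
                if rng.random() < config.q_model:
                    qual[p] = ord(_LOW_Q)
            rid = f"{src.name}:{i}"
            reads.append(Read(rid, arr.decode("ascii"), qual.decode("ascii")))
            truth.append(
                {
                    "read_id": rid,
                    "source": src.name,
                    "start": int(start),
                    "strand": strand,
                    "n_errors": int(err_positions.size),
                    "error_positions": ";".join(str(int(p)) for p in err_positions),
                }
            )
    return reads, truth


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write elements/circles/reads truth tables as TSV; lossless for the
    fields they carry (tuples serialized as ';'-joined strings)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    el_rows = []
    for e in truth.elements:
        d = asdict(e)
        d["ltr5"] = f"{e.ltr5[0]};{e.ltr5[1]}"
        d["ltr3"] = f"{e.ltr3[0]};{e.ltr3[1]}"
        d["sub_positions"] = ";".join(map(str, e.sub_positions))
        d["indels"] = ";".join(e.indels)
        el_rows.append(d)
    paths["elements"] = outdir / "truth_elements.tsv"
    pd.DataFrame(
        el_rows,
        columns=["element_id", "chrom", "start", "end", "ltr5", "ltr3", "sub_positions", "indels"],
    ).to_csv(paths["elements"], sep="\t", index=False)

    paths["circles"] = outdir / "truth_circles.tsv"
    pd.DataFrame(
        [asdict(c) for c in truth.circles],
        columns=["circle_id", "scenario", "element_id", "length",
                 "switch_column", "junction_position", "note"],
    ).to_csv(paths["circles"], sep="\t", index=False)

    paths["reads"] = outdir / "truth_reads.tsv"
    pd.DataFrame(
        truth.reads,
        columns=["read_id", "source", "start", "strand", "n_errors", "error_positions"],
    ).to_csv(paths["reads"], sep="\t", index=False)
    return paths


def read_truth(outdir: str | Path) -> SyntheticTruth:
    outdir = Path(outdir)
    truth = SyntheticTruth()
    el = pd.read_csv(outdir / "truth_elements.tsv", sep="\t", dtype=str).fillna("")
    for row in el.itertuples(index=False):
        l5 = tuple(int(x) for x in row.ltr5.split(";"))
        l3 = tuple(int(x) for x in row.ltr3.split(";"))
        subs = tuple(int(x) for x in row.sub_positions.split(";")) if row.sub_positions else ()
        indels = tuple(row.indels.split(";")) if row.indels else ()
        truth.elements.append(
            ElementTruth(row.element_id, row.chrom, int(row.start), int(row.end),
                         l5, l3, subs, indels)
        )
    ci = pd.read_csv(outdir / "truth_circles.tsv", sep="\t", dtype=str).fillna("")
    for row in ci.itertuples(index=False):
        truth.circles.append(
            CircleTruth(row.circle_id, row.scenario, row.element_id, int(row.length),
                        int(row.switch_column), int(row.junction_position), row.note)
        )
    rd = pd.read_csv(outdir / "truth_reads.tsv", sep="\t", dtype=str).fillna("")
    truth.reads = [
        {
            "read_id": r.read_id,
            "source": r.source,
            "start": int(r.start),
            "strand": r.strand,
            "n_errors": int(r.n_errors),
            "error_positions": r.error_positions,
        }
        for r in rd.itertuples(index=False)
    ]
    return truth
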