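"""Chimeric-LTR breakpoint inference.

For every full-length element the 5' and 3' LTRs are globally aligned;
every possible recombination product is a chimera taking the downstream
(3') LTR up to a switch point and the upstream (5') LTR after it.
Distinct chimeras are bounded by *informative* alignment columns (where
the two LTRs differ), so a breakpoint is only ever identifiable as an
interval between informative columns, never a point.  Reads that map
end-to-end to a chimera but cannot be placed on the unmanipulated genome
(a relaxed-tolerance stand-in for the original BLAST cross-search)
support the chimera's switch interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import Align

from .genome import Genome, TyAnnotation, revcomp
from .mapping import GenomeMapper, MapperConfig, Read

log = logging.getLogger(__name__)

GAP = "-"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class LtrAlignment:
    """Global pairwise alignment of an element's 5' and 3' LTR."""

    element_id: str
    gapped5: str
    gapped3: str
    score: float

    def __post_init__(self):
        if len(self.gapped5) != len(self.gapped3):
            raise ValueError("gapped rows differ in length")

    @property
    def length(self) -> int:
        return len(self.gapped5)

    @property
    def informative_columns(self) -> list[int]:
        """Columns where the two LTRs differ (gap columns included)."""
        return [i for i, (a, b) in enumerate(zip(self.gapped5, self.gapped3)) if a != b]

    @property
    def ltr5(self) -> str:
        return self.gapped5.replace(GAP, "")

    @property
    def ltr3(self) -> str:
        return self.gapped3.replace(GAP, "")


def align_ltr_pair(ltr5_seq: str, ltr3_seq: str, element_id: str = "") -> LtrAlignment:
    """Global alignment (match +1, mismatch -1, gap open -2, extend -1);
    the first optimal alignment is taken, which is deterministic."""
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("LTR sequences must be non-empty")
    aln = _make_aligner().align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    return LtrAlignment(element_id, str(aln[0]), str(aln[1]), float(aln.score))


class ChimeraEntry(NamedTuple):
    """One distinct chimeric LTR: 3'-LTR prefix + 5'-LTR suffix, switch
    localized to [switch_lo, switch_hi) between informative columns."""

    element_id: str
    name: str
    sequence: str
    switch_lo: int
    switch_hi: int
    col_of_pos: tuple[int, ...]  # alignment column of each sequence position


@dataclass
class ChimeraLibrary:
    element_id: str
    alignment: LtrAlignment
    entries: list[ChimeraEntry] = field(default_factory=list)


def _build_candidate(alignment: LtrAlignment, switch: int) -> tuple[str, tuple[int, ...]]:
    """Chimera for a switch point: downstream (3') LTR columns < switch,
    upstream (5') LTR columns >= switch, gaps stripped."""
    chars = []
    cols = []
    for i in range(alignment.length):
        c = alignment.gapped3[i] if i < switch else alignment.gapped5[i]
        if c != GAP:
            chars.append(c)
            cols.append(i)
    return "".join(chars), tuple(cols)


def enumerate_chimeras(alignment: LtrAlignment) -> ChimeraLibrary:
    """All distinct chimeric LTR sequences of one alignment.

    Candidates are generated for every switch point 1..L-1, gap-stripped,
    deduplicated, and candidates equal to either parent LTR discarded.
    Two switch points between the same pair of consecutive informative
    columns yield the same sequence, so each retained entry carries the
    informative-column interval that generated it; for gapless alignments
    the entry count is max(0, n_informative - 1).
    """
    lib = ChimeraLibrary(alignment.element_id, alignment)
    inf = alignment.informative_columns
    if len(inf) < 2:
        return lib
    parents = {alignment.ltr5, alignment.ltr3}
    by_seq: dict[str, list] = {}
    # representative switch for the group (inf[j-1], inf[j]] is inf[j-1]+1
    for j in range(1, len(inf)):
        seq, cols = _build_candidate(alignment, inf[j - 1] + 1)
        if seq in parents:
            continue
        lo, hi = inf[j - 1], inf[j]
        if seq in by_seq:
            entry = by_seq[seq]
            entry[1] = min(entry[1], lo)
            entry[2] = max(entry[2], hi)
        else:
            by_seq[seq] = [cols, lo, hi]
    for seq, (cols, lo, hi) in by_seq.items():
        name = f"{alignment.element_id}|{lo}-{hi}"
        lib.entries.append(ChimeraEntry(alignment.element_id, name, seq, lo, hi, cols))
    return lib


def build_libraries(
    annotations: Sequence[TyAnnotation], genome: Genome, family: str = "Ty1"
) -> list[ChimeraLibrary]:
    from .genome import extract_ltr_pairs

    libs = []
    for ltr5, ltr3, eid in extract_ltr_pairs(annotations, genome, family):
        libs.append(enumerate_chimeras(align_ltr_pair(ltr5, ltr3, eid)))
    return libs


class SupportRead(NamedTuple):
    read_id: str
    entry_name: str
    start: int
    strand: str
    informative_read_positions: tuple[int, ...]


@dataclass
class BreakpointCall:
    """A recombination breakpoint interval on one element, bounded by
    informative alignment columns and backed by chimera-only reads."""

    element_id: str
    switch_lo: int
    switch_hi: int
    support: list[SupportRead] = field(default_factory=list)
    upstream_of_u3r: bool | None = None

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def supporting_reads(self) -> list[str]:
        return sorted({s.read_id for s in self.support})


@dataclass(frozen=True)
class LtrRegionModel:
    """U3-R-U5 partition of the LTR alignment; the U3/R border is the
    transcription start site, where a transpositional (non-recombination)
    circle shows its apparent breakpoint."""

    u3_end_column: int
    r_end_column: int

    def __post_init__(self):
        if not 0 < self.u3_end_column < self.r_end_column:
            raise ValueError("require 0 < u3_end_column < r_end_column")


def genome_crosscheck(
    reads: Iterable[Read | tuple],
    genome: Genome,
    config: MapperConfig | None = None,
    crosscheck_max_mismatch: int | None = None,
) -> dict[str, bool]:
    """True (pass) per read iff it does NOT map end-to-end to the genome
    within the relaxed tolerance (default max_mismatch + 2, inclusive)."""
    cfg = config or MapperConfig()
    tol = crosscheck_max_mismatch if crosscheck_max_mismatch is not None else cfg.max_mismatch + 2
    mapper = GenomeMapper(genome, MapperConfig(max_mismatch=tol, max_hits=1))
    out = {}
    for raw in reads:
        read = Read(*raw)
        placements, _ = mapper.map_sequence(read.sequence)
        out[read.read_id] = not placements
    return out


def _support_positions(
    entry: ChimeraEntry, informative: frozenset[int], oriented_read: str, start: int
) -> tuple[int, ...] | None:
    """Read-local (oriented) positions of covered informative columns, or
    None when the read does not match at least one informative column on
    each side of the switch interval."""
    seq = entry.sequence
    left_ok = right_ok = False
    read_positions = []
    for off in range(len(oriented_read)):
        col = entry.col_of_pos[start + off]
        if col not in informative:
            continue
        if oriented_read[off] == seq[start + off]:
            if col <= entry.switch_lo:
                left_ok = True
            if col >= entry.switch_hi:
                right_ok = True
        read_positions.append(off)
    if left_ok and right_ok:
        return tuple(read_positions)
    return None


def call_breakpoints(
    reads: Sequence[Read | tuple],
    libraries: Sequence[ChimeraLibrary],
    genome: Genome,
    config: MapperConfig | None = None,
    crosscheck_max_mismatch: int | None = None,
) -> list[BreakpointCall]:
    """Aggregate chimera-supporting reads into breakpoint calls.

    A read supports an entry iff it maps end-to-end to the chimera within
    max_mismatch, has zero genome placements under the cross-check, and
    its matched residues include at least one informative column on each
    side of the switch interval.  Calls are returned sorted by descending
    support.
    """
    cfg = config or MapperConfig()
    entries = {e.name: e for lib in libraries for e in lib.entries}
    if not entries:
        return []
    informative_by_entry: dict[str, frozenset[int]] = {}
    for lib in libraries:
        inf = frozenset(lib.alignment.informative_columns)
        for e in lib.entries:
            informative_by_entry[e.name] = inf
    chimera_genome = Genome({name: e.sequence for name, e in entries.items()})
    chimera_mapper = GenomeMapper(chimera_genome, MapperConfig(cfg.max_mismatch, cfg.max_hits))
    candidates: list[tuple[Read, list]] = []
    for raw in reads:
        read = Read(*raw)
        placements, _ = chimera_mapper.map_sequence(read.sequence)
        if placements:
            # a read supports only its best-matching chimeras; entries one
            # informative column away still match within the mismatch
            # budget but are worse explanations of the read
            best = min(p.mismatches for p in placements)
            candidates.append((read, [p for p in placements if p.mismatches == best]))
    passed = genome_crosscheck(
        [r for r, _ in candidates], genome, cfg, crosscheck_max_mismatch
    )
    calls: dict[tuple[str, int, int], BreakpointCall] = {}
    for read, placements in candidates:
        if not passed.get(read.read_id, False):
            continue
        for p in placements:
            entry = entries[p.chrom]
            oriented = read.sequence if p.strand == "+" else revcomp(read.sequence)
            pos = _support_positions(entry, informative_by_entry[entry.name], oriented, p.start)
            if pos is None:
                continue
            if p.strand == "-":
                L = len(read.sequence)
                pos = tuple(sorted(L - 1 - q for q in pos))
            key = (entry.element_id, entry.switch_lo, entry.switch_hi)
            call = calls.setdefault(
                key, BreakpointCall(entry.element_id, entry.switch_lo, entry.switch_hi)
            )
            call.support.append(
                SupportRead(read.read_id, entry.name, p.start, p.strand, pos)
            )
    out = sorted(calls.values(), key=lambda c: (-c.n_support, c.element_id, c.switch_lo))
    log.info("breakpoint calling: %d calls from %d chimera-hit reads", len(out), len(candidates))
    return out


def quality_filter(
    calls: Sequence[BreakpointCall],
    reads_by_id: Mapping[str, Read],
    min_q: int = 20,
) -> list[BreakpointCall]:
    """Keep a supporting read only if every base it places on an
    informative column has quality >= min_q; drop emptied calls.  Skipped
    with a warning when quality strings are unavailable."""
    out = []
    for call in calls:
        kept = []
        for sup in call.support:
            read = reads_by_id[sup.read_id]
            if read.quality is None:
                log.warning("no quality string for %s; quality filter skipped", sup.read_id)
                kept.append(sup)
                continue
            quals = [ord(read.quality[i]) - 33 for i in sup.informative_read_positions]
            if all(q >= min_q for q in quals):
                kept.append(sup)
        if kept:
            out.append(
                BreakpointCall(
                    call.element_id, call.switch_lo, call.switch_hi, kept, call.upstream_of_u3r
                )
            )
    return out


def annotate_u3r(call: BreakpointCall, region: LtrRegionModel) -> BreakpointCall:
    """Set upstream_of_u3r: True iff the entire switch interval lies
    strictly upstream (lower columns) of the U3/R border; an interval
    straddling the border cannot exclude a transpositional origin."""
    call.upstream_of_u3r = call.switch_hi <= region.u3_end_column
    return call


def calls_to_frame(calls: Sequence[BreakpointCall], annotations=None):
    import pandas as pd

    locus_by_id = {a.element_id: a.locus for a in annotations} if annotations else {}
    rows = [
        {
            "element_id": c.element_id,
            "locus": locus_by_id.get(c.element_id, ""),
            "switch_lo": c.switch_lo,
            "switch_hi": c.switch_hi,
            "n_support": c.n_support,
            "reads": ",".join(c.supporting_reads),
            "upstream_of_u3r": c.upstream_of_u3r,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "element_id",
            "locus",
            "switch_lo",
            "switch_hi",
            "n_support",
            "reads",
            "upstream_of_u3r",
        ],
    )
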