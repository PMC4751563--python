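"""Split-read mosaic detection.

Each read is split into its first and last 50 nt; the parts are mapped
onto the extracted full-length element sequences.  A read is *mosaic*
when no pair of part placements is consistent with a contiguous origin
(same element, same orientation, tail downstream of head within a gap
band), at least one part falls in an LTR and both parts are mapped —
the footprint of circle junctions (end-to-start ligation, inverted
autointegration segments) inside single reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome import Genome, TyAnnotation
from .mapping import GenomeMapper, MapperConfig, Placement, Read

log = logging.getLogger(__name__)

ORDER_REVERSED = "order_reversed"
ORIENTATION_FLIPPED = "orientation_flipped"
CROSS_ELEMENT = "cross_element"


@dataclass(frozen=True)
class MosaicConfig:
    """part_len: length of the head/tail read parts; min_read_len: reads
    shorter than this are skipped; require_ltr_part: keep only reads with
    at least one part placed in an LTR; gap_tolerance: slack added to the
    maximal consistent inter-part gap (set None to disable the gap bound
    and reproduce the looser order/orientation-only rule);
    part_max_mismatch: substitution budget when mapping 50-nt parts."""

    part_len: int = 50
    min_read_len: int = 100
    require_ltr_part: bool = True
    gap_tolerance: int | None = 10
    part_max_mismatch: int = 2

    def __post_init__(self):
        if 2 * self.part_len > self.min_read_len:
            raise ValueError("require 2 * part_len <= min_read_len")


@dataclass
class MosaicCall:
    read_id: str
    element_id: str
    head: Placement
    tail: Placement
    inconsistency_type: str
    scenario_compat: frozenset[str] = frozenset()
    all_pairings: list[tuple[Placement, Placement]] = field(default_factory=list)


def split_read(read: Read, config: MosaicConfig | None = None) -> tuple[str, str] | None:
    """(head, tail) = first and last part_len bases; None for short reads."""
    cfg = config or MosaicConfig()
    if len(read.sequence) < cfg.min_read_len:
        return None
    return read.sequence[: cfg.part_len], read.sequence[-cfg.part_len :]


def _consistent(
    head: Placement, tail: Placement, read_len: int, cfg: MosaicConfig
) -> bool:
    """A head/tail placement pair is consistent with a contiguous read of
    length read_len on the linear element."""
    if head.chrom != tail.chrom or head.strand != tail.strand:
        return False
    # On '+' the tail lies downstream of the head; on '-' (read sampled
    # from the element's reverse strand) the roles mirror.
    d = (tail.start - head.start) if head.strand == "+" else (head.start - tail.start)
    gap = d - cfg.part_len
    if gap < 0:
        return False
    if cfg.gap_tolerance is None:
        return True
    return gap <= read_len - 2 * cfg.part_len + cfg.gap_tolerance


def _pair_type(head: Placement, tail: Placement) -> str:
    if head.chrom != tail.chrom:
        return CROSS_ELEMENT
    if head.strand != tail.strand:
        return ORIENTATION_FLIPPED
    return ORDER_REVERSED


def _in_ltr(placement: Placement, part_len: int, ltr_local) -> bool:
    s, e = placement.start, placement.start + part_len
    return any(s < hi and e > lo for lo, hi in ltr_local)


def classify_scenarios(
    call: MosaicCall,
    element_len: int,
    ltr_local: Sequence[tuple[int, int]],
    read_len: int,
    part_len: int = 50,
) -> frozenset[str]:
    """Map an inconsistent part pair onto the circle-formation scenarios.

    order_reversed across the element end<->start junction -> {I}
    (two-LTR circle ligation).  orientation_flipped -> {III} when both
    parts lie in LTR sequence, else {IV} (autointegration into internal
    sequence).  Anything else (cross-element, interior order reversals)
    -> empty, reported for manual review.
    """
    if call.inconsistency_type == ORIENTATION_FLIPPED:
        both_ltr = _in_ltr(call.head, part_len, ltr_local) and _in_ltr(
            call.tail, part_len, ltr_local
        )
        return frozenset({"III"}) if both_ltr else frozenset({"IV"})
    if call.inconsistency_type == ORDER_REVERSED:
        if call.head.strand == "+":
            near_end, near_start = call.head, call.tail
        else:
            near_end, near_start = call.tail, call.head
        if (
            near_end.start + part_len >= element_len - read_len
            and near_start.start <= read_len
        ):
            return frozenset({"I"})
    return frozenset()


def detect_mosaics(
    reads: Iterable[Read | tuple],
    annotations: Sequence[TyAnnotation],
    genome: Genome,
    config: MosaicConfig | None = None,
    family: str = "Ty1",
) -> list[MosaicCall]:
    """Mosaic calls over the full-length elements of one family.

    Parts are mapped to the extracted element sequences (element
    orientation), not the whole genome.  A read is non-mosaic if ANY
    head/tail pairing is consistent; otherwise every inconsistent pairing
    is recorded and the call carries a representative same-element pair
    when one exists.
    """
    cfg = config or MosaicConfig()
    elements = [a for a in annotations if a.family == family and a.is_full_length]
    if not elements:
        return []
    element_seqs = {el.element_id: el.sequence(genome) for el in elements}
    ltr_local = {el.element_id: list(el.ltr_local()) for el in elements}
    element_lens = {eid: len(s) for eid, s in element_seqs.items()}
    mapper = GenomeMapper(
        Genome(element_seqs), MapperConfig(max_mismatch=cfg.part_max_mismatch, max_hits=1000)
    )
    calls: list[MosaicCall] = []
    n_short = 0
    for raw in reads:
        read = Read(*raw)
        parts = split_read(read, cfg)
        if parts is None:
            n_short += 1
            continue
        head_pl, _ = mapper.map_sequence(parts[0])
        tail_pl, _ = mapper.map_sequence(parts[1])
        if not head_pl or not tail_pl:
            continue
        read_len = len(read.sequence)
        if any(
            _consistent(h, t, read_len, cfg) for h in head_pl for t in tail_pl
        ):
            continue
        pairings = [(h, t) for h in head_pl for t in tail_pl]
        if cfg.require_ltr_part and not any(
            _in_ltr(p, cfg.part_len, ltr_local[p.chrom])
            for p in list(head_pl) + list(tail_pl)
        ):
            continue
        same_el = [(h, t) for h, t in pairings if h.chrom == t.chrom]
        # classify every same-element pairing; a read placing in both LTR
        # copies has spurious pairings alongside the junction-revealing one
        scenarios: set[str] = set()
        representative = None
        for h, t in same_el:
            probe = MosaicCall(read.read_id, h.chrom, h, t, _pair_type(h, t))
            compat = classify_scenarios(
                probe, element_lens[h.chrom], ltr_local[h.chrom], read_len, cfg.part_len
            )
            scenarios |= compat
            if compat and representative is None:
                representative = (h, t)
        head, tail = representative or (same_el or pairings)[0]
        calls.append(
            MosaicCall(
                read_id=read.read_id,
                element_id=head.chrom if same_el else f"{head.chrom}|{tail.chrom}",
                head=head,
                tail=tail,
                inconsistency_type=_pair_type(head, tail),
                scenario_compat=frozenset(scenarios),
                all_pairings=pairings,
            )
        )
    if n_short:
        log.info("skipped %d reads shorter than %d nt", n_short, cfg.min_read_len)
    log.info("mosaic detection: %d calls", len(calls))
    return calls


def calls_to_frame(calls: Sequence[MosaicCall]):
    import pandas as pd

    rows = [
        {
            "read_id": c.read_id,
            "element_id": c.element_id,
            "head_start": c.head.start,
            "head_strand": c.head.strand,
            "tail_start": c.tail.start,
            "tail_strand": c.tail.strand,
            "type": c.inconsistency_type,
            "scenarios": ",".join(sorted(c.scenario_compat)),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "element_id",
            "head_start",
            "head_strand",
            "tail_start",
            "tail_strand",
            "type",
            "scenarios",
        ],
    )
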