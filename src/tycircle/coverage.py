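"""Weighted multi-mapping coverage and Ty-family accounting.

A read with n placements contributes 1/n at every base of each
placement, so the total coverage mass equals the summed length of the
mapped, deduplicated reads — an exact identity used as a pipeline
self-check.  Family intersections count each Ty-mapping read once, in
the cell for the exact set of families its placements touch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ExclusionSet, Genome, TyAnnotation
from .mapping import GenomeMapper, MapperConfig, MultiMapRecord, Read

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileConfig:
    """Windowed element-profile geometry (50-bp windows, 10 flank windows
    spanning 500 bp on each side)."""

    window: int = 50
    flank_windows: int = 10
    flank_span: int = 500

    def __post_init__(self):
        if self.flank_windows * self.window != self.flank_span:
            raise ValueError("flank_windows * window must equal flank_span")


@dataclass(frozen=True)
class LocusCriteria:
    """Criteria for flagging an element as an eccDNA producer locus:
    covered along >= min_covered_fraction of its length and carrying at
    least one uniquely mapping read; elements meeting the coverage bar
    but containing no genome-unique kmer_len-mer are indeterminate."""

    min_covered_fraction: float = 0.995
    kmer_len: int = 142

    def __post_init__(self):
        if not 0 < self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in (0, 1]")


class WeightedCoverageTrack:
    """Per-chromosome arrays of weighted per-base coverage."""

    def __init__(self, genome: Genome):
        self.arrays: dict[str, np.ndarray] = {
            name: np.zeros(genome.length(name)) for name in genome.names
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.arrays[chrom]

    @property
    def mass(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.arrays.items():
                breaks = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def weighted_track(
    records: Sequence[MultiMapRecord], genome: Genome
) -> WeightedCoverageTrack:
    """Accumulate 1/n-weighted coverage from deduplicated mapped reads."""
    track = WeightedCoverageTrack(genome)
    for rec in records:
        if not rec.mapped:
            continue
        w = 1.0 / rec.n_placements
        L = rec.read_length
        for p in rec.placements:
            arr = track.arrays.get(p.chrom)
            if arr is None or p.start < 0 or p.start + L > len(arr):
                raise ValueError(
                    f"placement {p} of read {rec.read_id} outside chromosome"
                )
            arr[p.start : p.start + L] += w
    return track


def _family_lookup(annotations: Iterable[TyAnnotation]):
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append((a.start, a.end, a.family))
    return by_chrom


def read_family_set(
    rec: MultiMapRecord, by_chrom: Mapping[str, list[tuple[int, int, str]]]
) -> frozenset[str]:
    """Families whose annotations any placement overlaps by >= 1 base."""
    fams = set()
    L = rec.read_length
    for p in rec.placements:
        for start, end, family in by_chrom.get(p.chrom, ()):
            if p.start < end and p.start + L > start:
                fams.add(family)
    return frozenset(fams)


def family_venn(
    records: Sequence[MultiMapRecord], annotations: Sequence[TyAnnotation]
) -> pd.DataFrame:
    """Observed Ty-family intersection table.

    Each deduplicated read with at least one placement overlapping an
    annotated Ty feature is counted exactly once, in the cell for the
    exact set of families its placements touch (a read placing 8x in Ty1
    and 2x in Ty2 counts once in the Ty1&Ty2 cell).
    """
    by_chrom = _family_lookup(annotations)
    counts: dict[frozenset[str], int] = {}
    for rec in records:
        if not rec.mapped:
            continue
        fams = read_family_set(rec, by_chrom)
        if fams:
            counts[fams] = counts.get(fams, 0) + 1
    return _venn_frame(counts, annotations)


def _venn_frame(
    counts: Mapping[frozenset[str], float], annotations: Sequence[TyAnnotation]
) -> pd.DataFrame:
    families = sorted({a.family for a in annotations})
    subsets = []
    for r in range(1, len(families) + 1):
        subsets.extend(frozenset(c) for c in combinations(families, r))
    total = sum(counts.values())
    rows = []
    for s in subsets:
        n = counts.get(s, 0)
        rows.append(
            {
                "families": "&".join(sorted(s)),
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
        )
    df = pd.DataFrame(rows).set_index("families")
    return df


def venn_table(observed: pd.DataFrame, expected: pd.DataFrame) -> pd.DataFrame:
    """Join observed and expected family-intersection percentages with the
    log2(observed/expected) ratio used for Venn colouring."""
    df = pd.DataFrame(
        {
            "observed_percent": observed["percent"],
            "expected_percent": expected["percent"],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["log2_ratio"] = np.log2(df["observed_percent"] / df["expected_percent"])
    return df


def feature_kmers(seq: str, kmer_len: int) -> list[str]:
    """All length-k subsequences of a linear feature (N - k + 1 of them)."""
    return [seq[i : i + kmer_len] for i in range(len(seq) - kmer_len + 1)]


def expected_family_coverage(
    annotations: Sequence[TyAnnotation],
    genome: Genome,
    config: MapperConfig | None = None,
    kmer_len: int = 142,
) -> tuple[pd.DataFrame, WeightedCoverageTrack]:
    """Expected family Venn and coverage under a uniform eccDNA model.

    Every annotated Ty feature of length N contributes its N-k+1 k-mers;
    the k-mers are mapped like reads and weighted identically.  Features
    shorter than kmer_len are skipped with a warning.
    """
    mapper = GenomeMapper(genome, config)
    pseudo_reads: list[Read] = []
    for ann in annotations:
        seq = ann.sequence(genome)
        if len(seq) < kmer_len:
            log.warning("feature %s shorter than %d bp, skipped", ann.element_id, kmer_len)
            continue
        for i, kmer in enumerate(feature_kmers(seq, kmer_len)):
            pseudo_reads.append(Read(f"{ann.element_id}#{i}", kmer))
    records = [r for r in mapper.map_reads(pseudo_reads) if r.mapped]
    by_chrom = _family_lookup(annotations)
    counts: dict[frozenset[str], int] = {}
    for rec in records:
        fams = read_family_set(rec, by_chrom)
        if fams:
            counts[fams] = counts.get(fams, 0) + 1
    return _venn_frame(counts, annotations), weighted_track(records, genome)


DEFAULT_BINS = [0.0] + [2.0**e for e in range(-6, 7)] + [np.inf]


def coverage_distribution(
    track: WeightedCoverageTrack,
    feature_sets: Mapping[str, Sequence[tuple[str, int, int]]],
    exclusions: ExclusionSet | None = None,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Fraction of genomic sites per coverage bin, per feature set.

    Excluded positions are removed before binning.  Bins are half-open
    [b_i, b_{i+1}) and must be strictly increasing; the default is
    log2-spaced with a dedicated zero bin.
    """
    bins = list(DEFAULT_BINS if bins is None else bins)
    if any(b1 >= b2 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly increasing")
    exclusions = exclusions or ExclusionSet()
    masks = {c: exclusions.mask(c, len(a)) for c, a in track.arrays.items()}
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(bins, bins[1:])]
    rows = {}
    for name, intervals in feature_sets.items():
        values = []
        for chrom, start, end in intervals:
            arr = track.arrays[chrom][start:end]
            keep = ~masks[chrom][start:end]
            values.append(arr[keep])
        values = np.concatenate(values) if values else np.array([])
        if values.size == 0:
            log.warning("feature set %r is empty after exclusion", name)
            rows[name] = np.zeros(len(labels))
            continue
        hist, _ = np.histogram(values, bins=bins)
        rows[name] = hist / values.size
    return pd.DataFrame(rows, index=labels).T


def _element_windows(arr: np.ndarray, window: int) -> np.ndarray:
    """Mean coverage in windows tiled from position 0; the last partial
    window is averaged over its actual width."""
    n_full, rem = divmod(len(arr), window)
    means = []
    if n_full:
        means.extend(arr[: n_full * window].reshape(n_full, window).mean(axis=1))
    if rem:
        means.append(arr[n_full * window :].mean())
    return np.asarray(means)


def element_profile(
    track: WeightedCoverageTrack,
    elements: Sequence[TyAnnotation],
    config: ProfileConfig | None = None,
) -> dict[str, np.ndarray]:
    """Average windowed coverage profile across full-length elements.

    Flanks are oriented in element orientation (upstream = 5' side);
    internal windows are tiled from the element start.  Elements of
    unequal length are averaged window-wise, ignoring missing trailing
    windows.  Returns dict with 'upstream', 'internal', 'downstream'.
    """
    cfg = config or ProfileConfig()
    up_rows, in_rows, down_rows = [], [], []
    for el in elements:
        if not el.is_full_length:
            continue
        if el.length < cfg.window:
            log.warning("element %s shorter than one window, skipped", el.element_id)
            continue
        arr = track.arrays[el.chrom]
        n = len(arr)
        left = arr[max(0, el.start - cfg.flank_span) : el.start]
        right = arr[el.end : min(n, el.end + cfg.flank_span)]
        if len(left) < cfg.flank_span:
            left = np.concatenate([np.full(cfg.flank_span - len(left), np.nan), left])
        if len(right) < cfg.flank_span:
            right = np.concatenate([right, np.full(cfg.flank_span - len(right), np.nan)])
        body = arr[el.start : el.end]
        if el.strand == "-":
            left, right = right[::-1], left[::-1]
            body = body[::-1]
        up_rows.append(left.reshape(cfg.flank_windows, cfg.window).mean(axis=1))
        down_rows.append(right.reshape(cfg.flank_windows, cfg.window).mean(axis=1))
        in_rows.append(_element_windows(body, cfg.window))
    if not in_rows:
        raise ValueError("no usable full-length elements for profiling")
    max_w = max(len(r) for r in in_rows)
    padded = np.full((len(in_rows), max_w), np.nan)
    for i, r in enumerate(in_rows):
        padded[i, : len(r)] = r
    return {
        "upstream": np.nanmean(np.vstack(up_rows), axis=0),
        "internal": np.nanmean(padded, axis=0),
        "downstream": np.nanmean(np.vstack(down_rows), axis=0),
    }


def profile_to_frame(profile: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for region in ("upstream", "internal", "downstream"):
        for i, v in enumerate(profile[region]):
            rows.append({"region": region, "window": i, "mean_coverage": v})
    return pd.DataFrame(rows)


def element_unique_kmer_count(
    element: TyAnnotation, genome: Genome, kmer_len: int
) -> int:
    """Number of element k-mers occurring exactly once in the genome
    (both strands counted, exact matching)."""
    mapper = GenomeMapper(genome, MapperConfig(max_mismatch=0, max_hits=2))
    seq = element.sequence(genome)
    n_unique = 0
    for i in range(len(seq) - kmer_len + 1):
        placements, _ = mapper.map_sequence(seq[i : i + kmer_len])
        if len(placements) == 1:
            n_unique += 1
    return n_unique


PRODUCER = "producer"
INDETERMINATE = "indeterminate"
NO_EVIDENCE = "no_evidence"


def locus_contribution(
    records: Sequence[MultiMapRecord],
    elements: Sequence[TyAnnotation],
    genome: Genome,
    criteria: LocusCriteria | None = None,
    track: WeightedCoverageTrack | None = None,
) -> pd.DataFrame:
    """Flag each full-length element as producer / indeterminate /
    no_evidence.

    producer: covered along >= min_covered_fraction of its length AND at
    least one read maps uniquely (n_placements == 1 after deduplication)
    within the element.  indeterminate: coverage criterion met but the
    element contains no genome-unique kmer_len-mer, so unique mapping is
    impossible.  Otherwise no_evidence.
    """
    crit = criteria or LocusCriteria()
    if track is None:
        track = weighted_track(records, genome)
    unique_hits: dict[str, list] = {}
    for rec in records:
        if rec.mapped and rec.n_placements == 1:
            unique_hits.setdefault(rec.placements[0].chrom, []).append(
                (rec.placements[0].start, rec.placements[0].start + rec.read_length)
            )
    rows = []
    for el in elements:
        if not el.is_full_length:
            continue
        arr = track.arrays[el.chrom][el.start : el.end]
        covered = float(np.count_nonzero(arr)) / el.length
        has_unique_read = any(
            s < el.end and e > el.start for s, e in unique_hits.get(el.chrom, ())
        )
        if covered >= crit.min_covered_fraction and has_unique_read:
            flag = PRODUCER
            n_unique_kmers = -1
        elif covered >= crit.min_covered_fraction:
            n_unique_kmers = element_unique_kmer_count(el, genome, crit.kmer_len)
            flag = INDETERMINATE if n_unique_kmers == 0 else NO_EVIDENCE
        else:
            flag = NO_EVIDENCE
            n_unique_kmers = -1
        rows.append(
            {
                "element_id": el.element_id,
                "locus": el.locus,
                "family": el.family,
                "covered_fraction": covered,
                "has_unique_read": has_unique_read,
                "n_unique_kmers": n_unique_kmers,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("element_id")
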