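"""Independent brute-force oracles used to validate the implementation."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from tycircle import Genome, revcomp
from tycircle.breakpoints import GAP, LtrAlignment


def brute_force_map(genome: Genome, seq: str, max_mismatch: int):
    """Slide the read (both strands) over every genome position and count
    mismatches — the definitional placement set."""
    out = []
    L = len(seq)
    for chrom in genome.names:
        arr = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = sliding_window_view(arr, L)
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            mism = (windows != qa).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatch)[0]:
                out.append((chrom, int(pos), strand, int(mism[pos])))
    return sorted(out)


def gotoh_score(a: str, b: str, match=1, mismatch=-1, open_=-2, extend=-1) -> float:
    """Affine-gap global alignment score by explicit Gotoh DP (a gap of
    length k scores open + (k-1)*extend)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, X[i][j - 1] + open_, Y[i][j - 1] + extend)
    return max(M[n][m], X[n][m], Y[n][m])


def chimera_sequences_bruteforce(alignment: LtrAlignment) -> set[str]:
    """Generate every switch-point candidate (downstream-LTR prefix +
    upstream-LTR suffix), strip gaps, deduplicate, drop parent-equal
    candidates — the definitional chimera set."""
    parents = {alignment.ltr5, alignment.ltr3}
    out = set()
    for i in range(1, alignment.length):
        cand = (alignment.gapped3[:i] + alignment.gapped5[i:]).replace(GAP, "")
        if cand not in parents:
            out.add(cand)
    return out


def random_ltr_pair(rng: np.random.Generator, length: int, divergence: float, indel_rate: float):
    """An LTR and a divergent copy (substitutions + 1-bp indels)."""
    bases = "ACGT"
    ltr5 = "".join(rng.choice(list(bases), length))
    out = []
    for ch in ltr5:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(bases[rng.integers(4)])  # insertion before
        if rng.random() < divergence:
            out.append(bases[(bases.index(ch) + 1 + int(rng.integers(3))) % 4])
        else:
            out.append(ch)
    ltr3 = "".join(out) or ltr5[:1]
    return ltr5, ltr3
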