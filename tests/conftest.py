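import numpy as np
import pytest

import tycircle as tc
from tycircle import synthetic as syn


def make_divergent_world(internal_len=2000, spacing=8, seed=11, flank=700):
    """Single full-length element whose LTR pair carries one substitution
    every `spacing` columns (~12% divergence) — a highly divergent pair
    like the locus where real breakpoint support was found."""
    rng = np.random.default_rng(seed)
    ltr5 = "".join(rng.choice(list("ACGT"), 330))
    l3 = list(ltr5)
    for c in range(spacing, 330, spacing):
        l3[c] = "ACGT"[("ACGT".index(l3[c]) + 1) % 4]
    ltr3 = "".join(l3)
    internal = "".join(rng.choice(list("ACGT"), internal_len))
    bg1 = "".join(rng.choice(list("ACGT"), flank))
    bg2 = "".join(rng.choice(list("ACGT"), flank))
    genome = tc.Genome({"chr1": bg1 + ltr5 + internal + ltr3 + bg2})
    s = flank
    e = s + 330 + internal_len + 330
    ann = tc.TyAnnotation(
        "Ty1-1", "chr1", s, e, "+", "Ty1", "full_length",
        ltr5=(s, s + 330), ltr3=(e - 330, e),
    )
    alignment = tc.align_ltr_pair(ltr5, ltr3, "Ty1-1")
    return genome, ann, alignment


@pytest.fixture(scope="session")
def divergent_world():
    return make_divergent_world()


@pytest.fixture(scope="session")
def synthetic_world():
    """Small default-divergence world: one full-length element, one solo
    LTR, 2-kb internal sequence."""
    cfg = syn.SyntheticConfig(
        seed=7, chrom_length=16000, n_fullength_elements=1, n_solo_ltrs=1,
        internal_length=2000, depth=20.0,
    )
    genome, annotations, truth = tc.build_genome(cfg)
    return cfg, genome, annotations, truth


@pytest.fixture(scope="session")
def circle_reads_world(synthetic_world):
    """Reads simulated from a two-LTR circle of the synthetic element,
    mapped and deduplicated."""
    cfg, genome, annotations, truth = synthetic_world
    el = next(a for a in annotations if a.is_full_length)
    rng = np.random.default_rng(42)
    model, ctruth = tc.make_circle("I", el, genome, cfg, rng)
    reads, _ = tc.simulate_reads(
        [syn.ReadSource(ctruth.circle_id, model.sequence, circular=True)], cfg, rng
    )
    records = tc.remove_duplicates(tc.map_reads(reads, genome))
    dedup = [r for r in records if r.mapped]
    return genome, annotations, reads, dedup
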