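import numpy as np
import pytest

import tycircle as tc
from tycircle import synthetic as syn
from tycircle.breakpoints import LtrRegionModel, align_ltr_pair, enumerate_chimeras
from tycircle.mapping import MapperConfig, Read

from oracles import chimera_sequences_bruteforce, gotoh_score, random_ltr_pair


def _mut(seq, pos):
    out = list(seq)
    out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestAlignLtrPair:
    def test_identical_sequences_no_informative_columns(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), 330))
        aln = align_ltr_pair(s, s)
        assert aln.length == 330
        assert aln.informative_columns == []

    def test_single_substitution_single_informative_column(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list("ACGT"), 330))
        aln = align_ltr_pair(s, _mut(s, 100))
        assert aln.informative_columns == [100]

    def test_deletion_yields_gap_column_counted_informative(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), 200))
        deleted = s[:80] + s[81:]
        aln = align_ltr_pair(s, deleted)
        assert "-" in aln.gapped3
        assert len(aln.informative_columns) >= 1

    def test_reconstruction_invariant_and_score_matches_gotoh_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            a, b = random_ltr_pair(rng, int(rng.integers(150, 400)), 0.03, 0.01)
            aln = align_ltr_pair(a, b)
            assert aln.ltr5 == a and aln.ltr3 == b
            assert aln.score == gotoh_score(a, b)


class TestEnumerateChimeras:
    def test_identical_ltrs_empty_library(self):
        rng = np.random.default_rng(4)
        s = "".join(rng.choice(list("ACGT"), 330))
        assert enumerate_chimeras(align_ltr_pair(s, s)).entries == []

    def test_single_difference_empty_library(self):
        # with one informative column every candidate equals a parent
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGT"), 330))
        lib = enumerate_chimeras(align_ltr_pair(s, _mut(s, 100)))
        assert lib.entries == []

    def test_two_differences_single_entry_with_interval(self):
        rng = np.random.default_rng(6)
        s = "".join(rng.choice(list("ACGT"), 330))
        lib = enumerate_chimeras(align_ltr_pair(s, _mut(_mut(s, 50), 200)))
        [entry] = lib.entries
        assert (entry.switch_lo, entry.switch_hi) == (50, 200)
        # downstream (3') prefix + upstream (5') suffix
        assert entry.sequence[50] == lib.alignment.gapped3[50]
        assert entry.sequence[200] == lib.alignment.gapped5[200]

    def test_matches_bruteforce_oracle_with_indels(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            a, b = random_ltr_pair(rng, int(rng.integers(200, 400)), 0.04, 0.01)
            aln = align_ltr_pair(a, b)
            lib = enumerate_chimeras(aln)
            assert {e.sequence for e in lib.entries} == chimera_sequences_bruteforce(aln)

    def test_gapless_entry_count_is_informative_minus_one(self):
        rng = np.random.default_rng(8)
        s = "".join(rng.choice(list("ACGT"), 330))
        m = s
        for pos in (30, 90, 151, 260, 300):
            m = _mut(m, pos)
        lib = enumerate_chimeras(align_ltr_pair(s, m))
        assert len(lib.entries) == 5 - 1


@pytest.fixture(scope="module")
def breakpoint_world(divergent_world):
    genome, ann, alignment = divergent_world
    libs = tc.build_libraries([ann], genome)
    cfg = syn.SyntheticConfig(seed=5, depth=60.0)
    return genome, ann, alignment, libs, cfg


class TestCallBreakpoints:
    def test_scenario_v_switch_recovered_in_top_call(self, breakpoint_world):
        genome, ann, alignment, libs, cfg = breakpoint_world
        rng = np.random.default_rng(100)
        model, truth = tc.make_circle(
            "V", ann, genome, cfg, rng, alignment=alignment, switch_column=130
        )
        reads, _ = tc.simulate_reads(
            [syn.ReadSource("c", model.sequence, circular=True)], cfg, rng
        )
        calls = tc.call_breakpoints(reads, libs, genome)
        assert calls, "expected breakpoint support from junction reads"
        top = calls[0]
        assert top.switch_lo <= truth.switch_column < top.switch_hi

    def test_genome_only_reads_give_zero_calls(self, breakpoint_world):
        genome, ann, alignment, libs, cfg = breakpoint_world
        rng = np.random.default_rng(101)
        reads, _ = tc.simulate_reads(
            [syn.ReadSource("g", genome["chr1"], circular=False)], cfg, rng
        )
        assert tc.call_breakpoints(reads, libs, genome) == []

    def test_monotone_in_mismatch_budget(self, breakpoint_world):
        # with the cross-check tolerance held fixed, lowering max_mismatch
        # can only shrink the supporting-read set
        genome, ann, alignment, libs, cfg = breakpoint_world
        rng = np.random.default_rng(102)
        model, _ = tc.make_circle(
            "V", ann, genome, cfg, rng, alignment=alignment, switch_column=130
        )
        reads, _ = tc.simulate_reads(
            [syn.ReadSource("c", model.sequence, circular=True)], cfg, rng
        )
        support = {}
        for mm in (4, 2, 1):
            calls = tc.call_breakpoints(
                reads, libs, genome, MapperConfig(max_mismatch=mm),
                crosscheck_max_mismatch=6,
            )
            support[mm] = {s.read_id for c in calls for s in c.support}
        assert support[1] <= support[2] <= support[4]


class TestGenomeCrosscheck:
    def test_genomic_substring_fails(self, divergent_world):
        genome, ann, _ = divergent_world
        read = genome["chr1"][1000:1142]
        assert tc.genome_crosscheck([("r", read, None)], genome) == {"r": False}

    def test_read_at_exactly_relaxed_tolerance_fails_inclusive(self, divergent_world):
        genome, ann, _ = divergent_world
        read = genome["chr1"][1000:1142]
        for pos in (5, 25, 45, 65, 85, 105):  # exactly max_mismatch+2 = 6
            read = _mut(read, pos)
        assert tc.genome_crosscheck([("r", read, None)], genome) == {"r": False}
        read = _mut(read, 125)  # 7 mismatches: beyond the relaxed tolerance
        assert tc.genome_crosscheck([("r", read, None)], genome) == {"r": True}

    def test_divergent_hybrid_junction_read_passes(self, breakpoint_world):
        genome, ann, alignment, libs, cfg = breakpoint_world
        entry = next(e for e in libs[0].entries if e.switch_lo <= 130 < e.switch_hi)
        read = entry.sequence[60:202]  # >= 7 informative columns on each side
        assert tc.genome_crosscheck([("r", read, None)], genome) == {"r": True}


class TestQualityFilter:
    def _one_call_world(self, breakpoint_world, quality_at_informative):
        genome, ann, alignment, libs, cfg = breakpoint_world
        entry = next(e for e in libs[0].entries if e.switch_lo <= 130 < e.switch_hi)
        seq = entry.sequence[60:202]
        reads = []
        for i, q in enumerate(quality_at_informative):
            qual = ["I"] * 142
            if q is not None:
                # stamp a chosen quality on every informative position
                inf = set(alignment.informative_columns)
                for off in range(142):
                    if entry.col_of_pos[60 + off] in inf:
                        qual[off] = q
            reads.append(Read(f"r{i}", seq, "".join(qual)))
        calls = tc.call_breakpoints(reads, libs, genome)
        return calls, {r.read_id: r for r in reads}

    def test_high_quality_support_unchanged(self, breakpoint_world):
        calls, by_id = self._one_call_world(breakpoint_world, [None, None])
        filtered = tc.quality_filter(calls, by_id, min_q=20)
        assert [c.n_support for c in filtered] == [c.n_support for c in calls]

    def test_low_quality_informative_base_removes_read(self, breakpoint_world):
        calls, by_id = self._one_call_world(breakpoint_world, [None, "#"])
        [call] = calls
        assert call.n_support == 2
        [filtered] = tc.quality_filter(calls, by_id, min_q=20)
        assert filtered.n_support == 1

    def test_all_support_low_quality_drops_call(self, breakpoint_world):
        calls, by_id = self._one_call_world(breakpoint_world, ["#", "#"])
        assert tc.quality_filter(calls, by_id, min_q=20) == []


class TestAnnotateU3r:
    def test_interval_below_border_flagged_upstream(self):
        call = tc.BreakpointCall("e", 100, 150)
        region = LtrRegionModel(u3_end_column=231, r_end_column=264)
        assert tc.annotate_u3r(call, region).upstream_of_u3r is True

    def test_interval_straddling_border_not_upstream(self):
        call = tc.BreakpointCall("e", 224, 232)
        region = LtrRegionModel(u3_end_column=231, r_end_column=264)
        assert tc.annotate_u3r(call, region).upstream_of_u3r is False

    def test_scenario_ii_call_contains_border_and_is_not_upstream(self, breakpoint_world):
        genome, ann, alignment, libs, cfg = breakpoint_world
        rng = np.random.default_rng(103)
        model, truth = tc.make_circle("II", ann, genome, cfg, rng, alignment=alignment)
        region = syn.region_model_for(alignment, cfg)
        assert truth.switch_column == region.u3_end_column
        reads, _ = tc.simulate_reads(
            [syn.ReadSource("c", model.sequence, circular=True)], cfg, rng
        )
        calls = [tc.annotate_u3r(c, region) for c in tc.call_breakpoints(reads, libs, genome)]
        top = calls[0]
        assert top.switch_lo <= region.u3_end_column < top.switch_hi
        assert top.upstream_of_u3r is False
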