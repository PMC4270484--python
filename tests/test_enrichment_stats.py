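"""Permutation association, state-overlap enrichment, odds ratios,
rank-sum comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from orthopeaks import enrichment_stats as es
from orthopeaks.genome_model import GenomeInterval as GI
from orthopeaks.genome_model import StateSegment


class TestPermutationEnrichment:
    def test_saturated_reference_fold_one(self):
        ws = [GI("c", 0, 1000)]
        res = es.permutation_enrichment([GI("c", 0, 100)], ws, ws, n_perm=200, seed=0)
        assert res.fold == 1.0
        assert res.p_greater == 1.0

    def test_mean_matches_exhaustive_enumeration(self):
        """1 kb workspace, one 100 bp segment: expectation over all 901
        placements, versus the permutation mean."""
        ws = [GI("c", 0, 1000)]
        ref = [GI("c", 450, 550)]
        q = [GI("c", 0, 100)]
        overlaps = [
            max(0, min(s + 100, 550) - max(s, 450)) for s in range(0, 901)
        ]
        exact = np.mean(overlaps)
        res = es.permutation_enrichment(q, ref, ws, n_perm=40_000, seed=1)
        se = np.std(overlaps) / math.sqrt(res.n_perm)
        assert res.expected_overlap == pytest.approx(exact, abs=5 * se)

    def test_p_value_floor(self):
        ws = [GI("c", 0, 10_000)]
        res = es.permutation_enrichment(
            [GI("c", 0, 100)], [GI("c", 0, 100)], ws, n_perm=99, seed=2
        )
        assert res.p_greater >= 1 / 100
        assert 0 < res.p_greater <= 1 and 0 < res.p_less <= 1

    def test_workspace_too_small_errors(self):
        with pytest.raises(ValueError, match="workspace"):
            es.permutation_enrichment(
                [GI("c", 0, 100)], [], [GI("c", 0, 50)], n_perm=10, seed=0
            )

    def test_type_one_error_calibrated_under_null(self):
        """Uniformly placed query -> permutation p uniform; rejection rate
        at alpha=0.05 within [0.03, 0.07] over 500 replicates."""
        rng = np.random.default_rng(31)
        ws = [GI("c", 0, 100_000)]
        ref = [GI("c", int(s), int(s) + 500) for s in range(1_000, 95_000, 5_000)]
        n_rej = 0
        n_tests = 500
        for _ in range(n_tests):
            q = [GI("c", int(s), int(s) + 100)
                 for s in rng.integers(0, 99_900, 10)]
            res = es.permutation_enrichment(q, ref, ws, n_perm=200, seed=rng)
            if res.p_greater <= 0.05:
                n_rej += 1
        assert 0.03 <= n_rej / n_tests <= 0.07

    def test_segments_respect_workspace_and_lengths(self):
        rng = np.random.default_rng(4)
        ws = [GI("c", 1000, 3000), GI("c", 10_000, 12_000)]
        q = [GI("c", 1000, 1200), GI("c", 1500, 1800)]
        res = es.permutation_enrichment(q, [GI("c", 0, 500)], ws, n_perm=300, seed=rng)
        assert res.observed_overlap == 0
        assert res.expected_overlap == 0.0  # reference outside workspace


def _tiling_segments(states, bin_=100, chrom="c"):
    return [
        StateSegment(GI(chrom, i * bin_, (i + 1) * bin_), int(s))
        for i, s in enumerate(states)
    ]


class TestStateEnrichment:
    def test_query_inside_one_state(self):
        # state 5 occupies 10% of the workspace; query fully inside it
        states = [5] + [1] * 9
        segs = _tiling_segments(states)
        se = es.state_overlap_enrichment(segs, [GI("c", 0, 100)])
        assert se.folds[5] == pytest.approx(10.0)
        assert se.folds[1] == pytest.approx(0.0)

    def test_uniform_query_folds_near_one(self, rng):
        states = rng.integers(1, 5, 400)
        segs = _tiling_segments(states)
        q = [GI("c", int(s), int(s) + 40) for s in rng.integers(0, 39_000, 600)]
        se = es.state_overlap_enrichment(segs, q)
        for s in range(1, 5):
            assert se.folds[s] == pytest.approx(1.0, abs=0.25)

    def test_matches_per_base_tally(self, rng):
        states = rng.integers(1, 4, 50)
        segs = _tiling_segments(states, bin_=37)
        q = [GI("c", int(s), int(s) + int(w))
             for s, w in zip(rng.integers(0, 1700, 20), rng.integers(1, 120, 20))]
        se = es.state_overlap_enrichment(segs, q)
        # per-base oracle
        state_of = np.zeros(50 * 37, dtype=int)
        for i, s in enumerate(states):
            state_of[i * 37:(i + 1) * 37] = s
        qmask = np.zeros(50 * 37, dtype=bool)
        for iv in q:
            qmask[iv.start:min(iv.end, len(qmask))] = True
        qtot = qmask.sum()
        for s in range(1, 4):
            qfrac = (qmask & (state_of == s)).sum() / qtot
            wfrac = (state_of == s).mean()
            assert se.folds[s] == pytest.approx(qfrac / wfrac)

    def test_fold_invariant_under_coordinate_scaling(self):
        states = [1, 2, 3, 2, 1]
        segs = _tiling_segments(states, bin_=100)
        q = [GI("c", 120, 260)]
        se1 = es.state_overlap_enrichment(segs, q)
        segs10 = _tiling_segments(states, bin_=1000)
        q10 = [GI("c", 1200, 2600)]
        se2 = es.state_overlap_enrichment(segs10, q10)
        for s in (1, 2, 3):
            assert se1.folds[s] == pytest.approx(se2.folds[s])

    def test_query_outside_segmentation_counts_unassigned(self, caplog):
        segs = _tiling_segments([1, 2])
        se = es.state_overlap_enrichment(
            segs, [GI("c", 150, 350)], workspace=[GI("c", 0, 400)]
        )
        assert se.query_fraction[es.UNASSIGNED_STATE] == pytest.approx(0.75)


class TestOddsRatio:
    def test_direct_2x2_arithmetic(self):
        special = {f"s{i}" for i in range(100)}
        rest = {f"r{i}" for i in range(900)}
        occupied = {f"s{i}" for i in range(30)} | {f"r{i}" for i in range(90)}
        lor, p = es.category_gene_odds(special, rest, occupied)
        assert lor == pytest.approx(math.log2((30 / 70) / (90 / 810)))
        assert 0 < p <= 1

    def test_equal_frequencies_zero_log_odds(self):
        special = {f"s{i}" for i in range(10)}
        rest = {f"r{i}" for i in range(100)}
        occupied = {f"s{i}" for i in range(5)} | {f"r{i}" for i in range(50)}
        lor, _ = es.category_gene_odds(special, rest, occupied)
        assert lor == pytest.approx(0.0)

    def test_zero_cell_haldane_correction(self):
        special = {"s1", "s2", "s3", "s4"}
        rest = {f"r{i}" for i in range(8)}
        occupied = {"s1", "s2"} | set()
        lor, _ = es.category_gene_odds(special, rest, occupied)
        # independent 2x2 calculation with +0.5 on every cell
        expected = math.log2(((2 + 0.5) / (2 + 0.5)) / ((0 + 0.5) / (8 + 0.5)))
        assert lor == pytest.approx(expected)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            es.category_gene_odds(set(), {"a"}, set())


class TestRankSum:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert es.rank_sum_compare(x, x) == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_exact_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 11.0, 12.0, 13.0, 14.0]
        # exact two-sided p for complete separation: 2 / C(10,5)
        assert es.rank_sum_compare(x, y) == pytest.approx(2 / 252)

    def test_single_observations(self):
        assert es.rank_sum_compare([1.0], [2.0]) == pytest.approx(1.0)
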