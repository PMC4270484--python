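"""Conservation classification of occupancy sites and rate summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_peak
from orthopeaks import peak_conservation as pc
from orthopeaks import synthetic_data as sd
from orthopeaks.genome_model import GenomeInterval


class TestClassifySourcePeaks:
    def test_empty_destination_all_lost(self, identity_chain):
        src = [make_peak("chrT", 100, 300, summit=200),
               make_peak("chrT", 500, 700, summit=600)]
        cls = pc.classify_source_peaks(src, [], [identity_chain])
        assert cls.labels == ["lost", "lost"]
        assert cls.summary.n_compensatory_sites == 0

    def test_rate_against_brute_force_overlap(self, identity_chain):
        """10 mapped peaks, 4 with overlapping destination peaks -> 0.4."""
        src = [make_peak("chrT", i * 90, i * 90 + 80, summit=i * 90 + 40)
               for i in range(1, 11)]
        dst = [make_peak("chrQ", i * 90 + 20, i * 90 + 60) for i in (1, 3, 5, 7)]
        cls = pc.classify_source_peaks(src, dst, [identity_chain], comp_window=0)
        # brute force: a source peak is conserved iff its lifted summit
        # window [summit-50, summit+51) (identity map) intersects some dst
        expected = [
            any(
                max(p.summit - 50, d.interval.start) < min(p.summit + 51, d.interval.end)
                for d in dst
            )
            for p in src
        ]
        assert [l == "conserved" for l in cls.labels] == expected
        assert cls.summary.rate_conserved == pytest.approx(0.4)

    @pytest.mark.parametrize("gap,expected", [(4999, True), (5001, False)])
    def test_compensatory_window_boundary(self, gap, expected):
        chain = identity_chain_scaled(3)
        src = [make_peak("chrT", 20000, 20200, summit=20100)]
        # lifted window is [20050, 20151); destination peak `gap` bases away
        dst = [make_peak("chrQ", 20151 + gap, 20151 + gap + 100)]
        cls = pc.classify_source_peaks(src, dst, [chain], comp_window=5000)
        assert cls.labels == ["lost"]
        assert (cls.summary.n_lost_with_compensatory == 1) is expected

    def test_unmapped_excluded_from_denominator(self, gapped_chain):
        src = [make_peak("chrT", 0, 250, summit=50),    # maps
               make_peak("chrT", 0, 250, summit=120)]   # inside the dt gap
        dst = [make_peak("chrQ", 0, 120)]
        cls = pc.classify_source_peaks(src, dst, [gapped_chain], flank=0)
        assert cls.labels == ["conserved", "unmapped"]
        assert cls.summary.n_mapped == 1
        assert cls.summary.rate_conserved == 1.0

    def test_planted_rate_recovery_binomial(self, identity_chain):
        """Planted conservation rates fall inside their exact binomial CI."""
        rng = np.random.default_rng(5)
        for p_cons in (0.25, 0.60):
            src, dst = [], []
            n = 800
            n_cons = 0
            for i in range(n):
                s = 1000 + i * 12000
                src.append(make_peak("chrT", s - 100, s + 100, summit=s))
                if rng.random() < p_cons:
                    n_cons += 1
                    dst.append(make_peak("chrQ", s - 30, s + 30))
            big = sd.random_chain(rng)  # unrelated decoy chain on another chrom
            cls = pc.classify_source_peaks(src, dst, [identity_chain_scaled(n)])
            lo, hi = stats.binom.interval(0.95, n, p_cons)
            assert lo <= cls.summary.n_conserved <= hi
            assert cls.summary.n_conserved == n_cons


def identity_chain_scaled(n):
    from orthopeaks.chain_lift import ChainAlignment

    size = 1000 + n * 12000 + 1000
    return ChainAlignment(
        score=1, t_name="chrT", t_size=size, t_strand="+", t_start=0, t_end=size,
        q_name="chrQ", q_size=size, q_strand="+", q_start=0, q_end=size,
        blocks=[(size, 0, 0)], chain_id=1,
    )


class TestClassifyTargetPeaks:
    def test_top_decile_relabeled_exactly(self, rng):
        dst = [
            make_peak("chrQ", i * 1000, i * 1000 + 500, score=float(s))
            for i, s in enumerate(rng.permutation(1000))
        ]
        labels = pc.classify_target_peaks(dst, set(), set(), strong_fraction=0.10)
        strong = {i for i, l in enumerate(labels) if l == "strongly_gained"}
        assert len(strong) == 100
        # independent sort oracle
        expected = set(sorted(range(1000), key=lambda i: -dst[i].score)[:100])
        assert strong == expected

    def test_all_conserved_no_gained(self):
        dst = [make_peak("chrQ", 0, 100), make_peak("chrQ", 200, 300)]
        labels = pc.classify_target_peaks(dst, {0, 1}, set())
        assert labels == ["conserved", "conserved"]

    def test_partition_is_disjoint(self, rng):
        dst = [make_peak("chrQ", i * 500, i * 500 + 300, score=float(rng.integers(100)))
               for i in range(50)]
        labels = pc.classify_target_peaks(dst, {0, 1, 2}, {3, 4})
        assert labels[:5] == ["conserved"] * 3 + ["compensatory"] * 2
        assert set(labels[5:]) <= {"gained", "strongly_gained"}


class TestRankFilter:
    def test_ceiling_rule(self):
        peaks = [make_peak("c", i * 10, i * 10 + 5, score=float(i)) for i in range(7)]
        kept = pc.rank_filter_peaks(peaks, 0.5)
        assert len(kept) == 4  # ceil(3.5)
        assert {p.score for p in kept} == {3.0, 4.0, 5.0, 6.0}

    def test_identity_at_full_fraction(self):
        peaks = [make_peak("c", 0, 5), make_peak("c", 10, 15)]
        assert pc.rank_filter_peaks(peaks, 1.0) == peaks

    def test_monotone_sensitivity_when_score_tracks_conservation(self, identity_chain):
        """Keeping stronger peaks never lowers the conserved rate when
        score correlates with planted conservation (the top-25% effect)."""
        rng = np.random.default_rng(9)
        src, dst = [], []
        for i in range(400):
            s = 500 + i * 2000
            conserved = rng.random() < 0.3
            score = float(rng.lognormal(1.0 + (1.0 if conserved else 0.0), 0.3))
            src.append(make_peak("chrT", s - 100, s + 100, summit=s, score=score))
            if conserved:
                dst.append(make_peak("chrQ", s - 30, s + 30))
        chain = identity_chain_scaled(400)
        rates = []
        for frac in (1.0, 0.5, 0.25):
            cls = pc.classify_source_peaks(
                pc.rank_filter_peaks(src, frac), dst, [chain]
            )
            rates.append(cls.summary.rate_conserved)
        assert rates[0] <= rates[1] <= rates[2]


class TestGeneCategories:
    def test_priority_and_window(self):
        from orthopeaks.genome_model import GeneRecord

        genes = [
            GeneRecord("g1", None, GenomeInterval("c", 50_000, 60_000, "+"), 50_000, 59_999, "+"),
            GeneRecord("g2", None, GenomeInterval("c", 200_000, 210_000, "+"), 200_000, 209_999, "+"),
        ]
        cats = pc.assign_gene_categories(
            genes,
            {
                "conserved": [GenomeInterval("c", 45_000, 45_100)],
                "gained": [GenomeInterval("c", 55_000, 55_100)],
                "lost": [GenomeInterval("c", 215_000, 215_100)],
            },
            window=10_000,
        )
        assert cats == {"g1": "conserved", "g2": "lost"}
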