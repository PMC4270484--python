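"""Tag pileup, normalization, promoter matrices and metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from orthopeaks import signal_quant as sq
from orthopeaks.genome_model import GeneRecord, GenomeInterval

SIZES = {"chr1": 10_000}


def tag(start, end, strand="+", chrom="chr1"):
    return GenomeInterval(chrom, start, end, strand)


def gene(gid, tss, tes, strand="+", chrom="chr1", pad=0):
    lo, hi = min(tss, tes), max(tss, tes) + 1
    return GeneRecord(gid, None, GenomeInterval(chrom, lo, hi, strand), tss, tes, strand)


class TestPileup:
    def test_single_plus_tag_covers_fragment(self):
        track = sq.extend_and_pileup([tag(1000, 1036)], SIZES, 200, bin_width=1)
        v = track.values("chr1")
        assert v[999] == 0 and v[1000] == 1 and v[1199] == 1 and v[1200] == 0

    def test_minus_tag_extends_5prime(self):
        track = sq.extend_and_pileup([tag(1000, 1036, "-")], SIZES, 200, bin_width=1)
        v = track.values("chr1")
        assert v[835] == 0 and v[836] == 1 and v[1035] == 1 and v[1036] == 0

    def test_zero_tags_zero_track(self):
        track = sq.extend_and_pileup([], SIZES, 200)
        assert track.values("chr1").sum() == 0

    def test_overlapping_tags_match_per_base_oracle(self, rng):
        tags = [
            tag(int(s), int(s) + 36, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(300, 9000, 60)
        ]
        track = sq.extend_and_pileup(tags, SIZES, 200, bin_width=1)
        oracle = np.zeros(10_000)
        for t in tags:
            s = t.start if t.strand == "+" else t.end - 200
            oracle[max(0, s): t.start + 200 if t.strand == "+" else t.end] += 1
        np.testing.assert_array_equal(track.values("chr1"), oracle)

    def test_total_mass_is_tags_times_fragment(self, rng):
        tags = [tag(int(s), int(s) + 36) for s in rng.integers(300, 9000, 40)]
        track = sq.extend_and_pileup(tags, SIZES, 200, bin_width=25)
        assert track.total_mass() == pytest.approx(40 * 200)

    def test_frame_pileup_matches_object_pileup(self, rng):
        starts = rng.integers(300, 9000, 50)
        strands = np.where(rng.random(50) < 0.5, "+", "-")
        tags = [tag(int(s), int(s) + 36, st) for s, st in zip(starts, strands)]
        df = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 36, "strand": strands}
        )
        a = sq.extend_and_pileup(tags, SIZES, 200, bin_width=25)
        b = sq.pileup_tag_frame(df, SIZES, 200, bin_width=25)
        np.testing.assert_allclose(a.values("chr1"), b.values("chr1"))


class TestNormalizeSubtract:
    def test_self_subtraction_zero(self, rng):
        tags = [tag(int(s), int(s) + 36) for s in rng.integers(0, 9000, 30)]
        t = sq.extend_and_pileup(tags, SIZES, 200)
        out = sq.normalize_subtract(t, t, 30, 30)
        assert out.values("chr1").sum() == 0

    def test_rpm_scaling(self):
        t = sq.extend_and_pileup([tag(0, 36)], SIZES, 200, bin_width=1)
        out = sq.normalize_subtract(t, sq.extend_and_pileup([], SIZES, 200, 1), 10, 1)
        # 1 read of a 10-read library -> 1e5 RPM over the fragment
        assert out.values("chr1")[100] == pytest.approx(1e5)

    def test_floor_at_zero(self):
        treat = sq.extend_and_pileup([tag(0, 36)], SIZES, 200, bin_width=1)
        ctrl = sq.extend_and_pileup([tag(0, 36), tag(0, 36)], SIZES, 200, bin_width=1)
        out = sq.normalize_subtract(treat, ctrl, 10, 10)
        assert (out.values("chr1") >= 0).all()
        assert out.values("chr1")[100] == 0.0


class TestPromoterMatrix:
    def test_constant_signal_gives_log2_of_1_plus_c(self):
        track = sq.SignalTrack(bin_width=25, chrom_sizes=SIZES)
        track.values("chr1")[:] = 3.0
        genes = [gene("g1", 5000, 8000), gene("g2", 7000, 4000, "-")]
        pm = sq.promoter_matrix({"m": track}, genes, 2000, 2000)
        np.testing.assert_allclose(pm["m"], np.log2(4.0))

    def test_minus_strand_window_is_reflected(self, rng):
        track = sq.SignalTrack(bin_width=1, chrom_sizes=SIZES)
        track.values("chr1")[:] = rng.random(10_000)
        plus = gene("gp", 5000, 8000, "+")
        minus = gene("gm", 5000, 3000, "-")
        pm = sq.promoter_matrix({"m": track}, [plus, minus], 1000, 500)
        v = track.values("chr1")
        expected_plus = np.log2(1 + v[4000:5500].mean())
        expected_minus = np.log2(1 + v[5001 - 500: 5001 + 1000].mean())
        assert pm.loc["gp", "m"] == pytest.approx(expected_plus)
        assert pm.loc["gm", "m"] == pytest.approx(expected_minus)

    def test_zero_track_gives_zero(self):
        track = sq.SignalTrack(bin_width=25, chrom_sizes=SIZES)
        pm = sq.promoter_matrix({"m": track}, [gene("g1", 5000, 8000)])
        assert pm.loc["g1", "m"] == 0.0

    def test_bin_width_one_is_oracle_for_bin_25(self, rng):
        """Promoter means at 25 bp bins stay within an edge-bin's worth of
        the exact per-base computation."""
        starts = rng.integers(300, 9000, 200)
        tags = [tag(int(s), int(s) + 36) for s in starts]
        genes = [gene("g1", 4987, 8000), gene("g2", 6013, 3000, "-")]
        exact = sq.promoter_matrix(
            {"m": sq.extend_and_pileup(tags, SIZES, 200, 1)}, genes, 2000, 2000
        )
        binned = sq.promoter_matrix(
            {"m": sq.extend_and_pileup(tags, SIZES, 200, 25)}, genes, 2000, 2000
        )
        assert np.abs(exact["m"] - binned["m"]).max() < 0.05


class TestMetagene:
    def _uniform_track(self, value):
        track = sq.SignalTrack(bin_width=25, chrom_sizes=SIZES)
        track.values("chr1")[:] = value
        return track

    def test_flat_signal_flat_profile(self):
        genes = [gene("g1", 3000, 6000), gene("g2", 7500, 6000, "-")]
        prof = sq.metagene_profile(self._uniform_track(2.0), genes, 2000, 100)
        np.testing.assert_allclose(prof, 2.0)

    def test_profile_length(self):
        genes = [gene("g1", 3000, 6000)]
        prof = sq.metagene_profile(self._uniform_track(1.0), genes, 2000, 100)
        assert len(prof) == 2 * (2000 // 25) + 100

    def test_step_at_tss_lands_on_flank_body_boundary(self):
        track = sq.SignalTrack(bin_width=1, chrom_sizes=SIZES)
        track.values("chr1")[3000:] = 1.0  # step exactly at the TSS
        prof = sq.metagene_profile(track, [gene("g1", 3000, 6000)], 2000, 100)
        fb = 2000
        assert prof[:fb].sum() == 0
        np.testing.assert_allclose(prof[fb:], 1.0)

    def test_no_eligible_genes_errors(self):
        with pytest.raises(ValueError, match="body length"):
            sq.metagene_profile(self._uniform_track(1.0), [gene("g", 10, 50)], 2000, 100)


class TestPromoterClassAndCorrelation:
    def test_threshold_classification(self):
        pm = pd.DataFrame(
            {
                "H3K4me3": np.log2(1 + np.array([2.0, 2.0, 0.0, 0.0])),
                "H3K27me3": np.log2(1 + np.array([0.0, 1.0, 1.0, 0.0])),
            },
            index=["a", "b", "c", "d"],
        )
        labels = sq.promoter_mark_class(pm)
        assert list(labels) == ["active", "bivalent", "repressed", "neither"]

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="H3K27me3"):
            sq.promoter_mark_class(pd.DataFrame({"H3K4me3": [1.0, 2.0, 3.0]}))

    def test_correlation_identities(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 7.0], index=list("abcde"))
        assert sq.matrix_correlation(a, a) == pytest.approx(1.0)
        assert sq.matrix_correlation(a, -a) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        x = pd.Series([1.0, 2.0, 4.0, 5.0, 8.0], index=list("abcde"))
        y = pd.Series([2.0, 1.0, 5.0, 4.0, 9.0], index=list("abcde"))
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert sq.matrix_correlation(x, y) == pytest.approx(float(expected))

    def test_zero_variance_reported_missing(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(sq.matrix_correlation(a, b))
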