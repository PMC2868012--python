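"""Anchor-aligned profiles, quantile summaries, region-expression correlation."""

import numpy as np
import pytest

from chiptile.datamodel import (
    AlignedProfileMatrix,
    Feature,
    FeatureSet,
    ProbeAnnotation,
    ProfileGrid,
    RegionSpec,
    ValidationError,
)
from chiptile.profiles import (
    align_profiles,
    default_regions,
    expression_groups,
    mean_profile,
    outlier_profiles,
    quantile_profiles,
    region_expression_correlation,
    region_mean_occupancy,
)


def dense_annotation(chrom="chr1", n=400, spacing=10, L=25):
    entries = {chrom: [(i, i * spacing, "+") for i in range(n)]}
    return ProbeAnnotation(entries=entries, probe_length=L)


def single_feature(strand, start=1000, end=2000, chrom="chr1", fid="g1"):
    return FeatureSet(features=[Feature(fid, chrom, start, end, strand)])


class TestAlignProfiles:
    def test_linear_ramp_bin_means(self):
        """Signal equal to relative position gives closed-form bin means:
        probes every 10 bp, bins of 50 bp hold rel positions {b0, b0+10, ...,
        b0+40}, whose mean is the bin center offset by the sampling grid."""
        anno = dense_annotation()
        feats = single_feature("+", start=1000)
        signal = np.zeros(400)
        idx, starts = anno.chrom_arrays("chr1")
        signal[idx] = starts - 1000  # value = relative position
        m = align_profiles(anno, signal, feats, "TSS", 500, 500, 50)
        expected = np.arange(-500, 500, 50) + np.mean([0, 10, 20, 30, 40])
        np.testing.assert_allclose(m.matrix[0], expected)

    def test_minus_strand_profile_is_mirrored(self):
        """A pattern attached to a minus-strand feature at the mirrored locus
        reproduces the plus-strand row reversed."""
        anno = dense_annotation(n=401)
        rng = np.random.default_rng(0)
        signal = rng.normal(size=401)
        plus = single_feature("+", start=2000, end=3000)
        m_plus = align_profiles(anno, signal, plus, "TSS", 500, 500, 50)
        # mirror: probes at position p get the signal of position 4000-p
        idx, starts = anno.chrom_arrays("chr1")
        mirrored = np.empty_like(signal)
        pos_to_val = dict(zip(starts.tolist(), signal[idx].tolist()))
        for i, p in zip(idx, starts):
            mirrored[i] = pos_to_val.get(4000 - int(p), np.nan)
        minus = single_feature("-", start=1000, end=2001)  # TSS at 2000
        m_minus = align_profiles(anno, mirrored, minus, "TSS", 500, 500, 50)
        np.testing.assert_allclose(
            m_minus.matrix[0], m_plus.matrix[0], equal_nan=True
        )

    def test_window_without_probes_is_all_nan_and_counted(self):
        anno = dense_annotation(n=10)  # probes only cover [0, 100)
        feats = single_feature("+", start=50_000, end=51_000)
        m = align_profiles(anno, np.ones(10), feats, "TSS", 100, 100, 50)
        assert np.isnan(m.matrix[0]).all()
        assert m.n_empty_rows == 1

    def test_bin_size_must_divide_window(self):
        with pytest.raises(ValidationError):
            ProfileGrid(upstream=100, downstream=100, bin_size=33)

    def test_strand_mirror_invariance_full_dataset(self):
        """Flipping all strands and point-mirroring probe starts and feature
        anchors about a constant leaves every profile row unchanged (probe
        membership is by the start's relative coordinate)."""
        C = 5000
        anno = dense_annotation(n=398)
        rng = np.random.default_rng(5)
        signal = rng.normal(size=398)
        feats = FeatureSet(
            features=[
                Feature("a", "chr1", 1000, 2000, "+"),
                Feature("b", "chr1", 2500, 3200, "-"),
            ]
        )
        m1 = align_profiles(anno, signal, feats, "TSS", 300, 300, 50)
        idx, starts = anno.chrom_arrays("chr1")
        new_starts = C - starts
        order = np.argsort(new_starts)
        anno2 = ProbeAnnotation(
            entries={
                "chr1": [(int(idx[i]), int(new_starts[i]), "+") for i in order]
            },
            probe_length=25,
        )
        # + feature [s, e) with TSS at s mirrors to a - feature whose TSS
        # (rightmost base) sits at C-s, i.e. interval [C-e+1, C-s+1)
        feats2 = FeatureSet(
            features=[
                Feature("a", "chr1", C - 2000 + 1, C - 1000 + 1, "-"),
                Feature("b", "chr1", C - 3200 + 1, C - 2500 + 1, "+"),
            ]
        )
        m2 = align_profiles(anno2, signal, feats2, "TSS", 300, 300, 50)
        np.testing.assert_allclose(m1.matrix, m2.matrix, equal_nan=True)


class TestMeanAndQuantiles:
    def _matrix(self, rows):
        rows = np.asarray(rows, dtype=float)
        grid = ProfileGrid(0, rows.shape[1] * 10, 10)
        return AlignedProfileMatrix(
            matrix=rows,
            grid=grid,
            anchor="TSS",
            feature_ids=[f"f{i}" for i in range(rows.shape[0])],
        )

    def test_mean_profile_identical_rows(self):
        m = self._matrix([[1.0, 2.0, 3.0]] * 4)
        means, n = mean_profile(m)
        np.testing.assert_allclose(means, [1, 2, 3])
        assert n.tolist() == [4, 4, 4]

    def test_mean_profile_ignores_missing(self):
        m = self._matrix([[1.0, np.nan], [3.0, np.nan]])
        means, n = mean_profile(m)
        assert means[0] == 2.0 and np.isnan(means[1])
        assert n.tolist() == [2, 0]

    def test_median_of_1_to_9(self):
        col = np.arange(1.0, 10.0)
        m = self._matrix(col[:, None])
        qp = quantile_profiles(m, levels=[0.5])
        assert qp.matrix[0, 0] == 5.0

    def test_quantiles_non_decreasing_across_levels(self):
        rng = np.random.default_rng(4)
        m = self._matrix(rng.normal(size=(30, 6)))
        qp = quantile_profiles(m)
        assert np.all(np.diff(qp.matrix, axis=1) >= -1e-12)

    def test_matches_per_column_quantile_oracle(self):
        rng = np.random.default_rng(8)
        levels = [0.1, 0.25, 0.5, 0.75, 0.9]
        for _ in range(100):
            rows = rng.normal(size=(rng.integers(5, 40), rng.integers(2, 8)))
            if rng.random() < 0.3:
                rows[rng.random(rows.shape) < 0.2] = np.nan
            m = self._matrix(rows)
            qp = quantile_profiles(m, levels=levels)
            for b in range(rows.shape[1]):
                col = rows[:, b]
                col = col[~np.isnan(col)]
                if col.size:
                    np.testing.assert_allclose(
                        qp.matrix[b], np.quantile(col, levels)
                    )
                else:
                    assert np.isnan(qp.matrix[b]).all()

    def test_single_level_equals_median_oracle(self):
        rng = np.random.default_rng(14)
        rows = rng.normal(size=(25, 5))
        m = self._matrix(rows)
        qp = quantile_profiles(m, levels=[0.5])
        np.testing.assert_allclose(qp.matrix[:, 0], np.median(rows, axis=0))
        np.testing.assert_allclose(qp.median_line, np.median(rows, axis=0))

    def test_mean_median_divergence_under_spike_mixture(self):
        """A 5% subpopulation with a 10-fold TSS binding spike drags the mean
        profile far above the median profile — the phenomenon the quantile
        profile exposes. On the log-enrichment scale unbound genes sit near 0
        and a 10-fold increase contributes log2(10) at the TSS bin."""
        rng = np.random.default_rng(2025)
        n_feat, n_bins = 400, 20
        base = rng.normal(0.0, 0.1, size=(n_feat, n_bins))
        tss_bin = 5
        spiked = rng.random(n_feat) < 0.05
        base[spiked, tss_bin] += np.log2(10)
        m = self._matrix(base)
        means, _ = mean_profile(m)
        qp = quantile_profiles(m, levels=[0.5])
        median = qp.matrix[:, 0]
        assert means[tss_bin] > 2 * abs(median[tss_bin])
        assert means[tss_bin] - median[tss_bin] > 0.1
        others = [b for b in range(n_bins) if b != tss_bin]
        assert np.all(np.abs(means[others] - median[others]) < 0.05)

    def test_outlier_rows_flagged(self):
        rng = np.random.default_rng(33)
        rows = rng.normal(size=(60, 10))
        rows[0] = 50.0  # constantly above the 0.95 band
        rows[1] = np.nan  # all-missing: counted, never flagged
        m = self._matrix(rows)
        flagged, n_missing = outlier_profiles(m)
        assert 0 in flagged
        assert 1 not in flagged
        assert n_missing == 1
        # the per-bin median row of a tight dataset is never flagged
        tight = np.tile(np.arange(10.0), (21, 1)) + rng.normal(
            0, 0.1, size=(21, 10)
        )
        m2 = self._matrix(tight)
        flagged2, _ = outlier_profiles(m2)
        med_row = int(np.argsort(tight[:, 0])[10])
        assert med_row not in flagged2


class TestRegions:
    def test_region_mean_plus_strand(self):
        anno = ProbeAnnotation(
            entries={"chr1": [(0, 1010, "+"), (1, 1050, "+"), (2, 3000, "+")]},
            probe_length=25,
        )
        feats = single_feature("+", start=1000, end=2000)
        region = RegionSpec("r", "TSS", 0, "TSS", 100)
        vals, counters = region_mean_occupancy(
            anno, np.array([1.0, 3.0, 99.0]), feats, region
        )
        assert vals[0] == 2.0

    def test_minus_strand_orientation_invariance(self):
        # mirrored locus: minus-strand TSS at 1999; same offsets catch
        # mirrored probes
        anno_plus = ProbeAnnotation(
            entries={"chr1": [(0, 1010, "+"), (1, 1050, "+")]}, probe_length=25
        )
        plus = single_feature("+", start=1000, end=2000)
        region = RegionSpec("r", "TSS", 0, "TSS", 100)
        v_plus, _ = region_mean_occupancy(
            anno_plus, np.array([1.0, 3.0]), plus, region
        )
        anno_minus = ProbeAnnotation(
            entries={"chr1": [(0, 2949, "+"), (1, 2989, "+")]}, probe_length=25
        )
        minus = single_feature("-", start=2000, end=3000)  # TSS at 2999
        v_minus, _ = region_mean_occupancy(
            anno_minus, np.array([3.0, 1.0]), minus, region
        )
        assert v_plus[0] == v_minus[0]

    def test_degenerate_region_skipped_and_counted(self):
        feats = single_feature("+", start=0, end=300)
        region = RegionSpec("mid", "TSS", 500, "TTS", -500)
        anno = dense_annotation(n=50)
        vals, counters = region_mean_occupancy(anno, np.ones(50), feats, region)
        assert np.isnan(vals[0])
        assert counters["degenerate"] == 1

    def test_correlation_identities(self):
        rng = np.random.default_rng(6)
        occ = rng.normal(size=(1, 50))
        ro = type("RO", (), {})()
        from chiptile.profiles import RegionOccupancy

        ids = [f"g{i}" for i in range(50)]
        ro = RegionOccupancy(region_ids=["r1"], feature_ids=ids, matrix=occ)
        expr_same = {g: float(v) for g, v in zip(ids, occ[0])}
        out = region_expression_correlation(ro, expr_same)
        assert out["r1"]["r"] == pytest.approx(1.0)
        expr_neg = {g: float(-v) for g, v in zip(ids, occ[0])}
        out = region_expression_correlation(ro, expr_neg)
        assert out["r1"]["r"] == pytest.approx(-1.0)

    def test_signal_region_attains_maximal_r_close_to_analytic(self):
        """Expression built from one region's occupancy: that region wins the
        correlation ranking and matches the closed-form r."""
        rng = np.random.default_rng(123)
        n = 2000
        ids = [f"g{i}" for i in range(n)]
        from chiptile.profiles import RegionOccupancy

        occ = rng.normal(0, 1.0, size=(5, n))
        beta, noise_sd = 2.0, 0.5
        expr_vals = beta * occ[3] + rng.normal(0, noise_sd, size=n)
        expr = {g: float(v) for g, v in zip(ids, expr_vals)}
        ro = RegionOccupancy(
            region_ids=[f"r{k}" for k in range(5)], feature_ids=ids, matrix=occ
        )
        out = region_expression_correlation(ro, expr)
        rs = {k: out[k]["r"] for k in ro.region_ids}
        assert max(rs, key=lambda k: rs[k]) == "r3"
        sigma = occ[3].std()
        analytic = beta * sigma / np.sqrt(beta**2 * sigma**2 + noise_sd**2)
        assert rs["r3"] == pytest.approx(analytic, abs=0.05)

    def test_too_few_pairs_rejected(self):
        from chiptile.profiles import RegionOccupancy

        ro = RegionOccupancy(
            region_ids=["r"], feature_ids=["a", "b", "c"],
            matrix=np.array([[1.0, np.nan, 2.0]]),
        )
        with pytest.raises(ValidationError):
            region_expression_correlation(ro, {"a": 1.0, "c": 2.0})

    def test_default_region_set_resolves_for_long_genes(self):
        feat = Feature("g", "chr1", 0, 3000, "+")
        for spec in default_regions():
            assert spec.resolve(feat) is not None

    def test_expression_groups_percentile_cutoffs(self):
        expr = {f"g{i}": float(i) for i in range(100)}
        low, high = expression_groups(expr, 0.2, 0.1)
        assert len(low) in (20, 21) and len(high) in (10, 11)
        assert all(expr[g] <= 20 for g in low)
        assert all(expr[g] >= 89 for g in high)
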