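import numpy as np
import pytest

import spineprint as sp
from spineprint.reliability import ICCMap


def brute_force_icc(x1, x2):
    """One-way random-effects ANOVA per edge, written out longhand."""
    ns = x1.shape[0]
    k = 2
    out = np.empty(x1.shape[1])
    for e in range(x1.shape[1]):
        vals = np.stack([x1[:, e], x2[:, e]], axis=1)  # Ns x 2
        subj_means = vals.mean(axis=1)
        grand = vals.mean()
        ss_between = k * np.sum((subj_means - grand) ** 2)
        ss_within = np.sum((vals - subj_means[:, None]) ** 2)
        msr = ss_between / (ns - 1)
        msw = ss_within / (ns * (k - 1))
        denom = msr + (k - 1) * msw
        out[e] = (msr - msw) / denom if denom > 0 else np.nan
    return out


class TestEdgeICC:
    def test_identical_runs_distinct_subjects_icc_one(self, rng):
        v = rng.standard_normal((5, 21))
        icc = sp.edge_icc(v, v.copy())
        vals = icc.edge_values()
        assert np.allclose(vals, 1.0)

    def test_all_equal_values_undefined(self):
        v = np.full((4, 10), 0.3)
        icc = sp.edge_icc(v, v.copy())
        assert np.all(np.isnan(icc.edge_values()))

    def test_matches_bruteforce_anova(self, rng):
        x1 = rng.standard_normal((6, 15))
        x2 = x1 + 0.5 * rng.standard_normal((6, 15))
        icc = sp.edge_icc(x1, x2)
        assert np.allclose(icc.edge_values(), brute_force_icc(x1, x2), atol=1e-10)

    def test_matches_pingouin_reference(self, rng):
        """Independent library check of the one-way random ICC at one edge."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x1 = rng.standard_normal(8)
        x2 = x1 + 0.3 * rng.standard_normal(8)
        df = pd.DataFrame(
            {
                "subject": list(range(8)) * 2,
                "run": [1] * 8 + [2] * 8,
                "value": np.concatenate([x1, x2]),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="run", ratings="value"
        )
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        ours = sp.edge_icc(x1[:, None].repeat(3, 1), x2[:, None].repeat(3, 1))
        assert ours.edge_values()[0] == pytest.approx(icc1, abs=1e-10)

    def test_symmetric_in_runs_and_map_shape(self, rng):
        x1 = rng.standard_normal((7, 45))  # 45 edges -> 10-region map
        x2 = rng.standard_normal((7, 45))
        a = sp.edge_icc(x1, x2)
        b = sp.edge_icc(x2, x1)
        assert np.allclose(a.edge_values(), b.edge_values(), equal_nan=True)
        assert a.values.shape == (10, 10)
        assert np.all(np.isnan(np.diag(a.values)))
        assert np.allclose(a.values, a.values.T, equal_nan=True)

    def test_invariant_under_common_affine_transform(self, rng):
        x1 = rng.standard_normal((6, 10))
        x2 = rng.standard_normal((6, 10))
        a = sp.edge_icc(x1, x2).edge_values()
        b = sp.edge_icc(3.5 * x1 - 2.0, 3.5 * x2 - 2.0).edge_values()
        assert np.allclose(a, b, atol=1e-10)


class TestThresholdPercentile:
    def test_retained_count_against_exhaustive_sort(self, rng):
        # 100 distinct edge values -> a 15-region map has 105 edges; use 100
        vals = rng.permutation(100).astype(float)
        edges = np.concatenate([vals, np.full(5, np.nan)])
        from spineprint.connectivity import devectorize

        m = devectorize(edges, 15)
        np.fill_diagonal(m, np.nan)
        thr, filt = sp.threshold_percentile(ICCMap(m), q=0.95)
        assert thr == pytest.approx(np.quantile(vals, 0.95))
        retained = np.sum(filt.edge_values() >= thr) // 1
        sorted_vals = np.sort(vals)
        expected = np.sum(sorted_vals >= thr)
        assert retained == expected
        assert expected in (5, 6)

    def test_zero_quantile_keeps_everything(self, rng):
        x1 = rng.standard_normal((5, 10))
        x2 = x1 + 0.2 * rng.standard_normal((5, 10))
        icc = sp.edge_icc(x1, x2)
        thr, filt = sp.threshold_percentile(icc, q=0.0)
        assert np.allclose(filt.edge_values(), icc.edge_values(), equal_nan=True)

    def test_constant_map_threshold_is_constant(self):
        from spineprint.connectivity import devectorize

        m = devectorize(np.full(6, 0.4), 4)
        np.fill_diagonal(m, np.nan)
        thr, filt = sp.threshold_percentile(ICCMap(m), q=0.95)
        assert thr == pytest.approx(0.4)
        assert np.all(filt.edge_values() == pytest.approx(0.4))

    def test_all_nan_rejected(self):
        m = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            sp.threshold_percentile(ICCMap(m), q=0.95)


class TestNodalStrength:
    def test_single_edge(self):
        m = np.zeros((5, 5))
        m[1, 3] = m[3, 1] = 0.6
        np.fill_diagonal(m, np.nan)
        s = sp.nodal_strength(ICCMap(m), mode="sum")
        assert np.allclose(s, [0, 0.6, 0, 0.6, 0])

    def test_constant_map_closed_form(self):
        n, c = 6, 0.3
        m = np.full((n, n), c)
        np.fill_diagonal(m, np.nan)
        assert np.allclose(sp.nodal_strength(ICCMap(m), "sum"), (n - 1) * c)
        assert np.allclose(sp.nodal_strength(ICCMap(m), "mean"), c)

    def test_matches_bruteforce_row_sums(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        m = (a + a.T) / 2
        np.fill_diagonal(m, np.nan)
        s = sp.nodal_strength(ICCMap(m), "sum")
        expected = [np.nansum(m[i]) for i in range(8)]
        assert np.allclose(s, expected)


class TestAverageWithinLevelBlocks:
    def _map_for(self, levels, block_values):
        """Build a spinal ICC map whose within-level blocks are as given."""
        scheme = sp.build_spinal_scheme(levels)
        n = scheme.n_regions
        m = np.zeros((n, n))
        for lv, block in enumerate(block_values):
            sl = slice(14 * lv, 14 * (lv + 1))
            m[sl, sl] = block
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        return ICCMap(m, scheme=scheme)

    def test_identical_blocks_pass_through(self, rng):
        b = rng.uniform(0, 1, (14, 14))
        b = (b + b.T) / 2
        icc = self._map_for(["C4", "C5", "C6"], [b, b, b])
        avg = sp.average_within_level_blocks([icc])
        off = ~np.eye(14, dtype=bool)
        assert np.allclose(avg.values[off], b[off])

    def test_two_datasets_average(self, rng):
        b1 = (lambda a: (a + a.T) / 2)(rng.uniform(0, 1, (14, 14)))
        b2 = (lambda a: (a + a.T) / 2)(rng.uniform(0, 1, (14, 14)))
        m1 = self._map_for(["C4"], [b1])
        m2 = self._map_for(["C4"], [b2])
        avg = sp.average_within_level_blocks([m1, m2])
        off = ~np.eye(14, dtype=bool)
        assert np.allclose(avg.values[off], ((b1 + b2) / 2)[off])

    def test_nan_cells_average_remaining_levels(self, rng):
        b = (lambda a: (a + a.T) / 2)(rng.uniform(0, 1, (14, 14)))
        b_nan = b.copy()
        b_nan[0, 1] = b_nan[1, 0] = np.nan
        icc = self._map_for(["C4", "C5"], [b_nan, b])
        avg = sp.average_within_level_blocks([icc])
        assert avg.values[0, 1] == pytest.approx(b[0, 1])
        assert avg.values[0, 2] == pytest.approx(b[0, 2])

    def test_non_spinal_scheme_rejected(self, rng):
        m = np.zeros((119, 119))
        np.fill_diagonal(m, np.nan)
        icc = ICCMap(m, scheme=sp.default_brain_scheme())
        with pytest.raises(ValueError, match="spinal"):
            sp.average_within_level_blocks([icc])


class TestICCAnalysisEstimator:
    def test_fit_attributes(self, small_cohort_vectors):
        v1, v2 = small_cohort_vectors
        est = sp.ICCAnalysis(quantile=0.95, strength_mode="sum").fit(v1, v2)
        n = est.icc_map_.n_regions
        assert est.nodal_strength_.shape == (n,)
        finite = est.icc_map_.edge_values()
        finite = finite[np.isfinite(finite)]
        assert est.threshold_ == pytest.approx(np.quantile(finite, 0.95))
        # thresholding keeps only the top edges
        kept = est.filtered_map_.edge_values()
        kept = kept[np.isfinite(kept)]
        assert np.all((kept == 0) | (kept >= est.threshold_))

    def test_mean_icc_grows_with_subject_effect(self):
        """Coarse monotonicity: stronger fingerprints give more reliable edges."""
        means = []
        for alpha in (0.0, 0.4, 0.8):
            spec = sp.CohortSpec(
                n_subjects=8, n_regions=20, n_timepoints=150,
                alpha=alpha, gamma=0.1, noise_sd=0.3, seed=21,
            )
            cohort = sp.generate_cohort(spec)
            v1 = np.vstack(
                [sp.vectorize_upper(sp.compute_fc(ts)).values
                 for ts in cohort.run_matrix(0)]
            )
            v2 = np.vstack(
                [sp.vectorize_upper(sp.compute_fc(ts)).values
                 for ts in cohort.run_matrix(1)]
            )
            means.append(np.nanmean(sp.edge_icc(v1, v2).values))
        assert means[0] < means[1] < means[2]
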