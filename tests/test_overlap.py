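import warnings

import numpy as np
import pytest

from earlyframe.overlap import (OverlapResult, TfceParams, pattern_overlap,
                                permutation_glm_tfce, sweep_and_rank,
                                tfce_transform, threshold_sweep)


class TestTfceTransform:
    def test_zero_map(self, closed_mesh):
        out = tfce_transform(np.zeros(closed_mesh.n_vertices), closed_mesh,
                             include=np.ones(closed_mesh.n_vertices, bool))
        assert np.all(out == 0)

    def test_single_vertex_spike_closed_form(self, closed_mesh):
        n = closed_mesh.n_vertices
        inc = np.ones(n, bool)
        h0 = 3.0
        stat = np.zeros(n)
        stat[10] = h0
        params = TfceParams(height_exponent=2.0, extent_exponent=1.0, n_steps=100)
        out = tfce_transform(stat, closed_mesh, params, inc)
        a = closed_mesh.vertex_areas[10]
        dh = h0 / 100
        heights = np.arange(dh, h0 + dh / 2, dh)
        expected = np.sum(a * heights ** 2 * dh)
        assert out[10] == pytest.approx(expected, rel=1e-9)
        assert np.all(out[np.arange(n) != 10] == 0)

    def test_step_refinement_stable_on_smooth_map(self, closed_mesh):
        # smooth bump: halving dh changes TFCE by < 1 %
        z = closed_mesh.vertices[:, 2]
        stat = np.maximum(0.0, z / z.max()) ** 2 * 4.0
        inc = np.ones(closed_mesh.n_vertices, bool)
        coarse = tfce_transform(stat, closed_mesh, TfceParams(n_steps=100), inc)
        fine = tfce_transform(stat, closed_mesh, TfceParams(n_steps=200), inc)
        assert np.max(np.abs(fine - coarse)) / coarse.max() < 0.01

    def test_monotone_in_stat_map(self, closed_mesh):
        rng = np.random.default_rng(0)
        inc = np.ones(closed_mesh.n_vertices, bool)
        stat = np.abs(rng.normal(size=closed_mesh.n_vertices))
        params = TfceParams(n_steps=50)
        dh = stat.max() / 50
        lo = tfce_transform(stat, closed_mesh, params, inc, dh=dh)
        hi = tfce_transform(stat + 0.5, closed_mesh, params, inc, dh=dh)
        assert np.all(hi >= lo - 1e-9)

    def test_nonfinite_treated_as_zero(self, closed_mesh):
        stat = np.full(closed_mesh.n_vertices, np.nan)
        out = tfce_transform(stat, closed_mesh,
                             include=np.ones(closed_mesh.n_vertices, bool))
        assert np.all(out == 0)


class TestPermutationGlm:
    def _mesh_include(self, mesh):
        return np.ones(mesh.n_vertices, bool)

    def test_strong_effect_recovers_vulnerable_patch(self, mesh3):
        rng = np.random.default_rng(1)
        vuln = mesh3.patches["vulnerable"]
        inc = mesh3.included
        n = 24
        group = np.repeat([1.0, 0.0], n // 2)
        y = rng.normal(0, 0.05, size=(n, mesh3.n_vertices))
        y[group == 1] += 5.0 * vuln  # enormous effect, almost no noise
        res = permutation_glm_tfce(y, group, None, mesh3, 200,
                                   TfceParams(n_steps=25), rng, inc)
        sig = res.p_fwe < 0.05
        core = vuln & inc
        assert sig[core].mean() > 0.95
        assert sig[~vuln & inc].mean() < 0.05

    def test_constant_response_flagged_not_significant(self, closed_mesh):
        rng = np.random.default_rng(2)
        n = 12
        y = rng.normal(size=(n, closed_mesh.n_vertices))
        y[:, 5] = 3.0
        with pytest.warns(UserWarning, match="constant-response"):
            res = permutation_glm_tfce(y, rng.normal(size=n), None, closed_mesh,
                                       50, TfceParams(n_steps=10), rng,
                                       self._mesh_include(closed_mesh))
        assert not res.valid[5]
        assert np.isnan(res.p_fwe[5])

    def test_rank_deficient_design_named(self, closed_mesh):
        rng = np.random.default_rng(3)
        n = 10
        y = rng.normal(size=(n, closed_mesh.n_vertices))
        x = np.ones(n)  # collinear with the intercept
        with pytest.raises(ValueError, match="collinear"):
            permutation_glm_tfce(y, x, None, closed_mesh, 10,
                                 TfceParams(n_steps=5), rng,
                                 self._mesh_include(closed_mesh))

    def test_fwe_p_range(self, closed_mesh):
        rng = np.random.default_rng(4)
        n, p_count = 12, 99
        y = rng.normal(size=(n, closed_mesh.n_vertices))
        res = permutation_glm_tfce(y, rng.normal(size=n), None, closed_mesh,
                                   p_count, TfceParams(n_steps=10), rng,
                                   self._mesh_include(closed_mesh))
        valid = np.isfinite(res.p_fwe)
        assert np.all(res.p_fwe[valid] >= 1.0 / (p_count + 1) - 1e-12)
        assert np.all(res.p_fwe[valid] <= 1.0)

    def test_nuisance_regression_freedman_lane(self, closed_mesh):
        # effect fully explained by the nuisance covariate -> not significant
        rng = np.random.default_rng(5)
        n = 20
        z = rng.normal(size=n)
        x = z + 0.01 * rng.normal(size=n)  # interest almost equals nuisance
        y = np.outer(z, np.ones(closed_mesh.n_vertices))
        y += rng.normal(0, 0.5, size=y.shape)
        res = permutation_glm_tfce(y, x, z[:, None], closed_mesh, 100,
                                   TfceParams(n_steps=10), rng,
                                   self._mesh_include(closed_mesh))
        assert np.nanmin(res.p_fwe) > 0.05


class TestPatternOverlap:
    def test_identical_patterns(self):
        p = np.array([0.01, 0.2, 0.01, 0.8])
        res = pattern_overlap(p, p.copy(), 0.05)
        assert res.balanced_accuracy == 1.0

    def test_complement_patterns(self):
        p_true = np.array([0.01, 0.01, 0.5, 0.5])
        p_pred = np.array([0.5, 0.5, 0.01, 0.01])
        res = pattern_overlap(p_true, p_pred, 0.05)
        assert res.balanced_accuracy == 0.0

    def test_confusion_arithmetic(self):
        res = OverlapResult(0.05, tp=30, fn=10, tn=50, fp=10)
        assert res.sensitivity == pytest.approx(0.75)
        assert res.specificity == pytest.approx(5 / 6)
        assert res.balanced_accuracy == pytest.approx((0.75 + 5 / 6) / 2)

    def test_label_symmetry_of_bacc(self):
        a = OverlapResult(0.05, tp=30, fn=10, tn=50, fp=5)
        b = OverlapResult(0.05, tp=50, fn=5, tn=30, fp=10)  # TP<->TN, FN<->FP
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)

    def test_empty_true_pattern_flagged(self):
        p_true = np.full(10, 0.9)
        p_pred = np.full(10, 0.01)
        with pytest.warns(UserWarning, match="degenerate"):
            res = pattern_overlap(p_true, p_pred, 0.05)
        assert not res.valid
        assert np.isnan(res.balanced_accuracy)

    def test_counts_partition_included_vertices(self):
        rng = np.random.default_rng(6)
        p1, p2 = rng.uniform(size=100), rng.uniform(size=100)
        include = rng.random(100) > 0.3
        res = pattern_overlap(p1, p2, 0.5, include)
        assert res.tp + res.fp + res.tn + res.fn == include.sum()


class TestThresholdSweep:
    def test_91_thresholds_with_exact_endpoints(self):
        t = threshold_sweep()
        assert len(t) == 91
        assert t[0] == 0.05
        assert t[-1] == 0.001
        assert np.all(np.diff(t) < 0)

    def test_even_spacing(self):
        t = threshold_sweep()
        np.testing.assert_allclose(np.diff(t), np.diff(t)[0], rtol=1e-9)


class TestSweepAndRank:
    def test_dominating_region_gets_top_rank(self):
        rng = np.random.default_rng(7)
        v = 200
        p_true = rng.uniform(size=v) * 0.2
        good = p_true.copy()                      # perfect agreement
        bad = np.roll(p_true, v // 2)             # scrambled agreement
        table, ranking = sweep_and_rank(
            {"good": (p_true, good), "bad": (p_true, bad)},
            thresholds=np.linspace(0.05, 0.01, 10))
        assert ranking.mean_ranks["good"] == pytest.approx(2.0)

    def test_identical_regions_single_group(self):
        rng = np.random.default_rng(8)
        p_true = rng.uniform(size=100) * 0.2
        p_pred = rng.uniform(size=100) * 0.2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, ranking = sweep_and_rank(
                {"a": (p_true, p_pred), "b": (p_true, p_pred)},
                thresholds=np.linspace(0.05, 0.01, 10))
        assert len(ranking.groups) == 1
        assert ranking.p_value == 1.0

    def test_needs_two_regions(self):
        with pytest.raises(ValueError, match="2 reference regions"):
            sweep_and_rank({"only": (np.ones(5), np.ones(5))})
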