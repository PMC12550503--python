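"""GP imputation against a closed-form dense oracle, the window-estimate
arithmetic, the merge rule, and imputation-quality properties."""

from __future__ import annotations

import numpy as np
import pytest

from sepsiswatch.ctwh import WindowConfig
from sepsiswatch.ehr import Episode, Observation
from sepsiswatch.mgp import (
    CTWH_MERGE,
    MGP,
    OUT_OF_SPAN,
    MgpConfig,
    MgpHyperparameters,
    ctwh_estimate,
    fit_mgp,
    impute_episode,
    impute_grid,
    merge_estimates,
)
from sepsiswatch.panel import FeaturePanel, VariableSpec


def _panel_1var():
    return FeaturePanel([VariableSpec("HR", "bpm", 50, 220, 0, 350)])


def _episode(times, values, variable="HR", reference=48.0, eid="e0"):
    return Episode(
        eid, 2.0, "male", 12.0, "control", anchor_time_h=reference,
        observations=[Observation(t, variable, v) for t, v in zip(times, values)],
    )


def _hypers_1var(ell=2.0, signal=1.0, noise=1e-2, mean=0.0, scale=1.0, span_var="HR"):
    return MgpHyperparameters(
        variables=[span_var],
        means=np.array([mean]), scales=np.array([scale]), medians=np.array([mean]),
        length_scales_h=np.array([ell]), shared_length_scale_h=ell,
        task_corr=np.eye(1), coupling_var=0.0, indep_var=signal, noise_var=noise,
    )


def _oracle_gp(t_train, y_train, t_query, ell, signal, noise, kind="exponential"):
    """Textbook dense GP regression, written independently."""

    def k(a, b):
        d = np.abs(a[:, None] - b[None, :])
        return signal * (np.exp(-d / ell) if kind == "exponential" else np.exp(-0.5 * (d / ell) ** 2))

    ktt = k(t_train, t_train) + noise * np.eye(len(t_train))
    kst = k(t_query, t_train)
    kss = k(t_query, t_query)
    inv = np.linalg.inv(ktt)
    mean = kst @ inv @ y_train
    cov = kss - kst @ inv @ kst.T
    return mean, np.sqrt(np.clip(np.diag(cov), 0, None))


WINDOWS_1 = WindowConfig(entries={"HR": (4.0, 1, 100.0)})


class TestFitMgp:
    def test_single_observation_interpolated(self):
        ep = _episode([40.0], [130.0])
        hp = _hypers_1var(noise=1e-8, mean=120.0, scale=10.0)
        cfg = MgpConfig(jitter=1e-10, noise_floor=1e-9)
        post = fit_mgp(ep, _panel_1var(), WINDOWS_1, cfg, hp, cutoff_h=48.0)
        mean, _ = post.predict(np.array([40.0]), "HR")
        assert mean[0] == pytest.approx(130.0, abs=1e-4)

    @pytest.mark.parametrize("kind", ["exponential", "squared_exponential"])
    def test_matches_closed_form_oracle(self, kind):
        t_train = np.array([40.0, 43.0, 46.0])
        y_train = np.array([0.5, -0.3, 1.2])
        ell, signal, noise = 2.0, 1.0, 0.01
        ep = _episode(t_train, y_train)
        hp = _hypers_1var(ell=ell, signal=signal, noise=noise)
        cfg = MgpConfig(kernel=kind, jitter=1e-12, noise_floor=0.0)
        post = fit_mgp(ep, _panel_1var(), WINDOWS_1, cfg, hp, cutoff_h=48.0)
        t_query = np.array([39.0, 41.5, 44.0, 45.5, 47.0])
        got_mean, got_sd = post.predict(t_query, "HR")
        exp_mean, exp_sd = _oracle_gp(t_train, y_train, t_query, ell, signal, noise, kind)
        np.testing.assert_allclose(got_mean, exp_mean, atol=1e-8)
        np.testing.assert_allclose(got_sd, exp_sd, atol=1e-6)

    def test_reversion_to_prior_far_from_data(self):
        ep = _episode([10.0], [5.0])
        windows = WindowConfig(entries={"HR": (4.0, 1, 1000.0)})
        hp = _hypers_1var(ell=2.0, mean=120.0, scale=10.0)
        post = fit_mgp(ep, _panel_1var(), windows, MgpConfig(), hp, cutoff_h=48.0)
        mean, sd = post.predict(np.array([47.0]), "HR")
        assert mean[0] == pytest.approx(120.0, abs=0.5)
        assert sd[0] == pytest.approx(10.0, abs=0.5)  # prior sd = scale * sqrt(signal)

    def test_only_prespan_observations_excluded(self):
        # span 4 h: the observation at t=10 is outside [44, 48]
        windows = WindowConfig(entries={"HR": (4.0, 1, 4.0)})
        ep = _episode([10.0, 46.0], [200.0, 130.0])
        hp = _hypers_1var(mean=120.0, scale=10.0)
        post = fit_mgp(ep, _panel_1var(), windows, MgpConfig(), hp, cutoff_h=48.0)
        assert len(post.t_train) == 1 and post.t_train[0] == 46.0

    def test_zero_observations_fallback_flag(self):
        ep = _episode([], [])
        hp = _hypers_1var()
        post = fit_mgp(ep, _panel_1var(), WINDOWS_1, MgpConfig(), hp, cutoff_h=48.0)
        assert post.fallback

    def test_rank_one_coupling_tracks_other_variable(self):
        """Two perfectly correlated tasks, one observed: the unobserved
        variable's posterior tracks the observed one."""
        panel = FeaturePanel(
            [VariableSpec("A", "u", -10, 10, -100, 100),
             VariableSpec("B", "u", -10, 10, -100, 100)]
        )
        windows = WindowConfig(entries={"A": (4.0, 1, 100.0), "B": (4.0, 1, 100.0)})
        hp = MgpHyperparameters(
            variables=["A", "B"],
            means=np.zeros(2), scales=np.ones(2), medians=np.zeros(2),
            length_scales_h=np.array([2.0, 2.0]), shared_length_scale_h=2.0,
            task_corr=np.ones((2, 2)), coupling_var=0.99, indep_var=0.01,
            noise_var=1e-4,
        )
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(36, 48, 15))
        y = np.sin(t / 2.0)
        ep = Episode(
            "e0", 2.0, "male", 12.0, "control", anchor_time_h=48.0,
            observations=[Observation(float(tt), "A", float(vv)) for tt, vv in zip(t, y)],
        )
        post = fit_mgp(ep, panel, windows, MgpConfig(), hp, cutoff_h=48.0)
        q = np.linspace(38, 47, 20)
        mean_a, _ = post.predict(q, "A")
        mean_b, _ = post.predict(q, "B")
        assert np.corrcoef(mean_a, mean_b)[0, 1] > 0.95


class TestImputeGrid:
    def test_values_at_observation_times(self):
        t = np.array([37.0, 40.0, 44.0, 47.0])
        y = np.array([115.0, 125.0, 122.0, 135.0])
        ep = _episode(t, y)
        hp = _hypers_1var(ell=3.0, noise=1e-6, mean=120.0, scale=10.0)
        post = fit_mgp(ep, _panel_1var(), WINDOWS_1, MgpConfig(jitter=1e-10), hp, cutoff_h=48.0)
        mean, _ = post.predict(t, "HR")
        np.testing.assert_allclose(mean, y, atol=0.05)

    def test_grid_beyond_cutoff_rejected(self):
        ep = _episode([40.0], [120.0])
        post = fit_mgp(ep, _panel_1var(), WINDOWS_1, MgpConfig(), _hypers_1var(), cutoff_h=48.0)
        with pytest.raises(ValueError, match="cutoff"):
            impute_grid(post, np.array([47.0, 49.0]), WINDOWS_1)

    def test_sd_nonnegative_and_shrinks_with_information(self):
        t = np.array([38.0, 42.0, 46.0])
        y = np.array([0.1, -0.2, 0.4])
        ep1 = _episode(t, y)
        ep2 = _episode(np.append(t, 44.0), np.append(y, 0.1))
        hp = _hypers_1var(ell=3.0)
        cfg = MgpConfig()
        g1 = impute_grid(fit_mgp(ep1, _panel_1var(), WINDOWS_1, cfg, hp, 48.0),
                         np.arange(36.0, 49.0), WINDOWS_1)
        g2 = impute_grid(fit_mgp(ep2, _panel_1var(), WINDOWS_1, cfg, hp, 48.0),
                         np.arange(36.0, 49.0), WINDOWS_1)
        assert np.all(g1.sd >= 0)
        assert np.all(g2.sd <= g1.sd + 1e-6)

    def test_out_of_span_flagged_with_median(self):
        windows = WindowConfig(entries={"HR": (2.0, 1, 2.0)})
        ep = _episode([47.5], [130.0])
        hp = _hypers_1var(mean=120.0, scale=10.0)
        grid = impute_grid(
            fit_mgp(ep, _panel_1var(), windows, MgpConfig(), hp, 48.0),
            np.arange(36.0, 49.0), windows,
        )
        flags = grid.source[0]
        # grid runs 36..48; span 2 h back from the 48 h cutoff -> cells
        # strictly before t=46 are out of span
        assert all(f == OUT_OF_SPAN for f in flags[:10])
        assert all(f != OUT_OF_SPAN for f in flags[10:])
        assert grid.values[0, 0] == pytest.approx(120.0)


class TestCtwhEstimate:
    def _ep(self):
        # windows of width 4 ending at 48: T0=[44,48): mean 8; T1=[40,44): mean 4
        return _episode([41.0, 43.0, 45.0, 47.0], [3.0, 5.0, 7.0, 9.0])

    def test_constant_windows_invariant(self):
        ep = _episode([41.0, 45.0], [5.0, 5.0])
        windows = WindowConfig(entries={"HR": (4.0, 2, 8.0)}, correlations={"HR": [0.3]})
        value, weight = ctwh_estimate(ep, "HR", windows, 48.0)
        assert value == pytest.approx(5.0)
        assert weight == 1.0

    def test_weighted_mean_arithmetic(self):
        windows = WindowConfig(entries={"HR": (4.0, 2, 8.0)}, correlations={"HR": [0.5]})
        value, weight = ctwh_estimate(self._ep(), "HR", windows, 48.0)
        # (1.0·8 + 0.5·4) / 1.5 = 6.666…
        assert value == pytest.approx((1.0 * 8 + 0.5 * 4) / 1.5)
        assert weight == 1.0

    def test_spec_example_weights(self):
        """Window means {4, 8} with correlations {1.0, 0.5} → 5.333…"""
        ep = _episode([45.0, 41.0], [4.0, 8.0])
        windows = WindowConfig(entries={"HR": (4.0, 2, 8.0)}, correlations={"HR": [0.5]})
        value, _ = ctwh_estimate(ep, "HR", windows, 48.0)
        assert value == pytest.approx((1.0 * 4 + 0.5 * 8) / 1.5)

    def test_all_windows_empty(self):
        ep = _episode([10.0], [5.0])
        windows = WindowConfig(entries={"HR": (2.0, 2, 4.0)})
        value, weight = ctwh_estimate(ep, "HR", windows, 48.0)
        assert weight == 0.0 and np.isnan(value)


class TestMergeEstimates:
    def test_endpoints(self):
        cfg0 = MgpConfig(merge_weight_mode="fixed", fixed_weight=0.0)
        cfg1 = MgpConfig(merge_weight_mode="fixed", fixed_weight=1.0)
        assert merge_estimates(4.0, 8.0, 1.0, cfg0)[0] == 4.0
        assert merge_estimates(4.0, 8.0, 1.0, cfg1)[0] == 8.0

    def test_quarter_weight(self):
        cfg = MgpConfig(merge_weight_mode="fixed", fixed_weight=0.25)
        value, flag = merge_estimates(4.0, 8.0, 1.0, cfg)
        assert value == pytest.approx(5.0)
        assert flag == CTWH_MERGE

    def test_correlation_mode_scales_with_window_weight(self):
        cfg = MgpConfig(merge_weight_mode="correlation", fixed_weight=0.5)
        # λ = 0.5 (window weight) × 0.5 = 0.25
        assert merge_estimates(4.0, 8.0, 0.5, cfg)[0] == pytest.approx(5.0)

    def test_fallback_to_defined_source(self):
        cfg = MgpConfig()
        assert merge_estimates(float("nan"), 8.0, 1.0, cfg) == (8.0, CTWH_MERGE)
        assert merge_estimates(4.0, float("nan"), 0.0, cfg) == (4.0, MGP)

    def test_both_undefined(self):
        cfg = MgpConfig()
        with pytest.raises(ValueError):
            merge_estimates(float("nan"), float("nan"), 0.0, cfg)
        value, flag = merge_estimates(float("nan"), float("nan"), 0.0, cfg, fallback_value=7.0)
        assert value == 7.0 and flag == OUT_OF_SPAN


class TestImputationQuality:
    def test_posterior_consistent_at_observations(self, small_cohort, panel, windows, hypers, mgp_cfg):
        """Posterior predictive within 2 noise-sd of ≥95% of conditioning
        observations."""
        hits = total = 0
        for ep in small_cohort[:15]:
            post = fit_mgp(ep, panel, windows, mgp_cfg, hypers)
            if post.fallback:
                continue
            for code in ("HR", "LAC", "SBP"):
                t, v = ep.times_values(code)
                span = windows.span_h(code)
                m = (t <= post.cutoff_h) & (t >= post.cutoff_h - span)
                if not m.any():
                    continue
                mean, _ = post.predict(t[m], code)
                j = hypers.index(code)
                tol = 2.0 * hypers.scales[j] * np.sqrt(hypers.noise_var) + 1e-6
                # total predictive tolerance: noise + residual posterior sd
                _, sd = post.predict(t[m], code)
                hits += int(np.sum(np.abs(mean - v[m]) <= 2 * np.sqrt(sd**2 + (tol / 2) ** 2)))
                total += int(m.sum())
        assert total > 50
        assert hits / total >= 0.95

    def test_rmse_beats_mean_imputation(self, small_cohort, panel, windows, hypers, mgp_cfg):
        """Dual-step imputation error on held-out masked observations is
        no worse than population-mean imputation (20% masking)."""
        rng = np.random.default_rng(0)
        err_mgp, err_mean = [], []
        for ep in small_cohort[:25]:
            t_all = [(i, o) for i, o in enumerate(ep.observations)
                     if ep.reference_time_h - 12 <= o.time_h <= ep.reference_time_h]
            if len(t_all) < 10:
                continue
            mask_idx = rng.choice(len(t_all), size=max(1, len(t_all) // 5), replace=False)
            held = [t_all[i][1] for i in mask_idx]
            drop = {t_all[i][0] for i in mask_idx}
            from dataclasses import replace

            thinned = replace(
                ep, observations=[o for i, o in enumerate(ep.observations) if i not in drop]
            )
            post = fit_mgp(thinned, panel, windows, mgp_cfg, hypers)
            for o in held:
                if o.variable not in windows:
                    continue
                j = hypers.index(o.variable)
                mean, _ = post.predict(np.array([o.time_h]), o.variable)
                c_val, c_w = ctwh_estimate(thinned, o.variable, windows, o.time_h)
                merged, _ = merge_estimates(mean[0], c_val, c_w, mgp_cfg,
                                            fallback_value=hypers.medians[j])
                scale = hypers.scales[j]
                err_mgp.append(((merged - o.value) / scale) ** 2)
                err_mean.append(((hypers.means[j] - o.value) / scale) ** 2)
        assert len(err_mgp) > 100
        assert np.sqrt(np.mean(err_mgp)) <= np.sqrt(np.mean(err_mean))

    def test_grid_finite_and_flags_partition(self, small_cohort, panel, windows, hypers, mgp_cfg):
        grid = impute_episode(small_cohort[2], panel, windows, mgp_cfg, hypers)
        assert np.all(np.isfinite(grid.values))
        assert np.all(grid.sd >= 0)
        valid = {OBSERVED_ALL for OBSERVED_ALL in ("observed", "mgp", "ctwh_merge", "out_of_span")}
        assert set(grid.source.ravel().tolist()) <= valid
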