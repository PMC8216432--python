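"""Tests for the marginal likelihood, the NLMM fitter and group contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import thermacclim as ta
from thermacclim.inference import (
    FitConfig,
    TrajectoryDataset,
    VarianceComponents,
    adjusted_r2,
    compact_letter_display,
    compare_groups,
    fit_nlmm,
    initialize,
    marginal_loglik,
    marginal_loglik_ghq,
    predict,
)


def _params(data, preset):
    return {g: preset.params for g in data.groups}


class TestMarginalLoglik:
    def test_no_random_effect_reduces_to_plain_regression(self, tcore_p1, small_tcore_data):
        """With sigma_r2 = 0 the marginal likelihood is the iid Gaussian one."""
        data = small_tcore_data
        var = VarianceComponents(0.0, tcore_p1.variance.sigma_e2)
        ll = marginal_loglik(_params(data, tcore_p1), var, data)
        from thermacclim.model import evaluate

        resid = data.frame["value"].to_numpy() - evaluate(
            tcore_p1.params, data.frame["day"].to_numpy()
        )
        expected = norm.logpdf(resid, scale=np.sqrt(var.sigma_e2)).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_closed_form_matches_adaptive_quadrature(self, tcore_p1, adfi_p1):
        for preset, seed in ((tcore_p1, 3), (adfi_p1, 4)):
            data = ta.simulate_trajectories(preset, n_animals=5, seed=seed)
            p = _params(data, preset)
            ll = marginal_loglik(p, preset.variance, data)
            ll_ghq = marginal_loglik_ghq(p, preset.variance, data, n_nodes=31)
            assert ll == pytest.approx(ll_ghq, abs=1e-6)

    def test_quadrature_default_nine_nodes_agrees(self, tcore_p1, small_tcore_data):
        p = _params(small_tcore_data, tcore_p1)
        ll = marginal_loglik(p, tcore_p1.variance, small_tcore_data)
        ll9 = marginal_loglik_ghq(p, tcore_p1.variance, small_tcore_data, n_nodes=9)
        assert ll == pytest.approx(ll9, abs=1e-6)

    def test_translation_invariance(self, tcore_p1, small_tcore_data):
        """Shifting all observations and y0 by c leaves the likelihood fixed."""
        data = small_tcore_data
        c = 2.34
        shifted = TrajectoryDataset(
            data.frame.assign(value=data.frame["value"] + c), variable=data.variable
        )
        p0 = _params(data, tcore_p1)
        p1 = {g: q.replace(y0=q.y0 + c) for g, q in p0.items()}
        ll0 = marginal_loglik(p0, tcore_p1.variance, data)
        ll1 = marginal_loglik(p1, tcore_p1.variance, shifted)
        assert ll0 == pytest.approx(ll1, abs=1e-8)

    def test_degenerate_residual_variance_rejected(self, tcore_p1, small_tcore_data):
        with pytest.raises(ValueError):
            marginal_loglik(
                _params(small_tcore_data, tcore_p1),
                VarianceComponents(0.1, 0.0),
                small_tcore_data,
            )


class TestInitialize:
    def test_recovers_thresholds_from_noiseless_sharp_data(self, noiseless_sharp_data):
        data, params = noiseless_sharp_data
        init = initialize(data)
        assert init.td1 == pytest.approx(params.td1, abs=0.25)
        assert init.td2 == pytest.approx(params.td2, abs=0.25)

    def test_constant_data_gives_flat_fit(self):
        days = np.arange(-1.0, 11.0)
        frame = pd.DataFrame(
            {
                "animal_id": "a0",
                "group": "g",
                "day": np.tile(days, 2),
                "value": 7.0,
            }
        )
        init = initialize(TrajectoryDataset(frame, variable="Tcore_C"))
        assert init.y0 == pytest.approx(7.0, abs=1e-8)
        assert init.v1 == pytest.approx(0.0, abs=1e-8)
        assert init.v2 == pytest.approx(0.0, abs=1e-8)

    def test_noisy_tcore_initial_td1_within_one_day(self, tcore_p1):
        data = ta.simulate_trajectories(tcore_p1, n_animals=18, seed=11)
        init = initialize(data)
        assert abs(init.td1 - 1.46) < 1.0

    def test_too_few_distinct_days_rejected(self):
        frame = pd.DataFrame(
            {
                "animal_id": ["a"] * 4,
                "group": "g",
                "day": [0.0, 1.0, 2.0, 3.0],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError):
            initialize(TrajectoryDataset(frame, variable="Tcore_C"))


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "sse,ctss,n,p,expected",
        [
            (0.0, 450.0, 216, 12, 1.0),
            (450.0 * 203 / 215, 450.0, 216, 12, 0.0),
            (36.0, 450.0, 216, 12, 0.9152709359605911),  # hand arithmetic
        ],
    )
    def test_values(self, sse, ctss, n, p, expected):
        assert adjusted_r2(sse, ctss, n, p) == pytest.approx(expected, abs=1e-12)

    def test_unit_rescaling_invariance(self):
        c2 = 3.7**2
        assert adjusted_r2(36.0, 450.0, 216, 12) == pytest.approx(
            adjusted_r2(36.0 * c2, 450.0 * c2, 216, 12)
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 2.0, 13, 12)
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 0.0, 216, 12)
        with pytest.raises(ValueError):
            adjusted_r2(-1.0, 2.0, 216, 12)


class TestFitNlmm:
    def test_recovers_exact_model_from_noiseless_data(self, noiseless_sharp_data):
        data, params = noiseless_sharp_data
        # data come from the sharp limit, so fit in the same (near-sharp)
        # model class; r = 0.25 would add irreducible kink-smoothing error
        fit = fit_nlmm(data, FitConfig(r1=1e-4, r2=1e-4, n_multistart=2))
        p = fit.params_by_group["g"]
        for name in ("y0", "v1", "v2", "td1", "td2"):
            assert getattr(p, name) == pytest.approx(getattr(params, name), abs=1e-3), name
        assert fit.monotone

    def test_zero_between_animal_signal_gives_small_sigma_r2(self, tcore_p1):
        preset = ta.Preset(
            label="novar",
            variable="Tcore",
            group=tcore_p1.group,
            period="P1",
            params=tcore_p1.params,
            variance=VarianceComponents(0.0, tcore_p1.variance.sigma_e2),
            se=tcore_p1.se,
            adj_r2=np.nan,
            n_animals=18,
        )
        data = ta.simulate_trajectories(preset, n_animals=18, seed=5)
        fit = fit_nlmm(data, FitConfig(n_multistart=2))
        assert fit.variance.sigma_r2 < 0.05 * fit.variance.sigma_e2

    def test_single_fit_matches_table_scale(self, tcore_p1):
        data = ta.simulate_trajectories(tcore_p1, n_animals=18, seed=1)
        fit = fit_nlmm(data)
        p = fit.params_by_group[tcore_p1.group]
        assert p.y0 == pytest.approx(39.3, abs=3 * 0.05 * np.sqrt(2))
        assert p.td1 == pytest.approx(1.46, abs=3 * 0.13 * np.sqrt(2))
        assert fit.converged and fit.se_by_group is not None
        assert fit.se_by_group[tcore_p1.group]["td1"] < 0.5

    def test_merged_groups_reproduce_pooled_loglik(self, tcore_p1):
        """A joint fit with equal group parameters equals the pooled fit."""
        data = ta.simulate_trajectories(tcore_p1, n_animals=8, seed=9)
        frame = data.frame.copy()
        frame.loc[frame.index[: len(frame) // 2], "group"] = "A"
        frame.loc[frame.index[len(frame) // 2 :], "group"] = "B"
        split = TrajectoryDataset(frame, variable=data.variable)
        shared = {"A": tcore_p1.params, "B": tcore_p1.params}
        pooled = {tcore_p1.group: tcore_p1.params}
        ll_split = marginal_loglik(shared, tcore_p1.variance, split)
        ll_pooled = marginal_loglik(pooled, tcore_p1.variance, data)
        assert ll_split == pytest.approx(ll_pooled, abs=1e-9)

    def test_profiling_r_picks_best_loglik(self, tcore_p1):
        data = ta.simulate_trajectories(tcore_p1, n_animals=6, seed=21)
        fixed = [
            fit_nlmm(data, FitConfig(r1=r, r2=r, n_multistart=1)) for r in (0.1, 0.5)
        ]
        profiled = fit_nlmm(
            data, FitConfig(r_profile=(0.1, 0.5), n_multistart=1)
        )
        assert profiled.loglik == pytest.approx(max(f.loglik for f in fixed), abs=1e-6)


@pytest.fixture(scope="module")
def fitted(tcore_p1):
    data = ta.simulate_trajectories(tcore_p1, n_animals=8, seed=13)
    return fit_nlmm(data, FitConfig(n_multistart=2)), data


class TestPredict:
    def test_marginal_at_day0_is_y0(self, fitted):
        fit, _ = fitted
        curve = predict(fit, [0.0], mode="marginal")
        g = fit.groups[0]
        # smooth-model offset from y0 at d=0 is the (small) softplus tail
        from thermacclim.model import evaluate

        assert curve["value"].iloc[0] == pytest.approx(
            evaluate(fit.params_by_group[g], 0.0)
        )

    def test_conditional_equals_marginal_when_no_random_effect(self, fitted):
        fit, _ = fitted
        fit_no_b = ta.FitResult(**{**fit.__dict__})
        fit_no_b.blups = {a: 0.0 for a in fit.blups}
        days = [0.0, 5.0]
        marg = predict(fit, days, mode="marginal")
        cond = predict(fit_no_b, days, mode="conditional")
        for _, row in cond.iterrows():
            m = marg[(marg["group"] == row["group"]) & (marg["day"] == row["day"])]
            assert row["value"] == pytest.approx(m["value"].iloc[0])

    def test_blups_are_shrunken_animal_means(self, fitted):
        """b_i = sr2 * sum(e_ij) / (n_i*sr2 + se2) for marginal residuals e."""
        fit, data = fitted
        from thermacclim.model import evaluate

        g = fit.groups[0]
        sr2, se2 = fit.variance.sigma_r2, fit.variance.sigma_e2
        for animal, sub in data.frame.groupby("animal_id"):
            e = sub["value"].to_numpy() - evaluate(
                fit.params_by_group[g], sub["day"].to_numpy()
            )
            expected = sr2 * e.sum() / (len(e) * sr2 + se2)
            assert fit.blups[animal] == pytest.approx(expected, abs=1e-10)

    def test_extrapolation_warns(self, fitted):
        fit, _ = fitted
        with pytest.warns(UserWarning):
            predict(fit, [12.0], mode="marginal")


def _two_group_data(preset_a, preset_b, seed):
    da = ta.simulate_trajectories(preset_a, n_animals=9, seed=seed, animal_prefix="a")
    db = ta.simulate_trajectories(preset_b, n_animals=9, seed=seed + 50000, animal_prefix="b")
    frame = pd.concat(
        [da.frame.assign(group="G1"), db.frame.assign(group="G2")], ignore_index=True
    )
    return TrajectoryDataset(frame, variable=da.variable)


class TestCompareGroups:
    CFG = FitConfig(n_multistart=2, seed=0)

    def test_identical_parameter_vectors_give_zero_wald(self, tcore_p1):
        data = ta.simulate_trajectories(tcore_p1, n_animals=8, seed=17)
        frame = pd.concat(
            [data.frame.assign(group="G1"),
             data.frame.assign(group="G2", animal_id=data.frame["animal_id"] + "x")],
            ignore_index=True,
        )
        dup = TrajectoryDataset(frame, variable=data.variable)
        fit, table, letters = compare_groups(dup, self.CFG)
        # identical data in both groups -> identical estimates -> z ~= 0
        # (up to independent-optimization noise in the two coordinate blocks)
        assert np.allclose(table["z"].abs(), 0.0, atol=1e-2)
        assert (table["p_value"] > 0.99).all()
        assert all(len(set(v.values())) == 1 for v in letters.values())

    def test_null_type_one_error_rate(self):
        """Two groups from the same preset: ~alpha of the Wald tests reject."""
        preset = ta.preset_from_table3("ADFI/P3/TTH")
        n_sig = 0
        all_ns = 0
        reps = 25
        for k in range(reps):
            fit, table, _ = compare_groups(_two_group_data(preset, preset, 100 + k), self.CFG)
            nsig = int((table["p_value"] < 0.05).sum())
            n_sig += nsig
            all_ns += int(nsig == 0)
        # 13 = 99.9% binomial(125, 0.05) bound; all-ns expected ~0.95^5
        assert n_sig <= 13
        assert all_ns >= int(0.70 * reps)

    def test_detects_recovery_slope_difference(self):
        """v2 = 11.50 vs 5.99 (first vs repeated challenge) is detected in
        the majority of replicates at n=9 per group."""
        pa = ta.preset_from_table3("ADFI/P3/TTH")
        pb = ta.preset_from_table3("ADFI/P3/HHH")
        detected = 0
        reps = 25
        for k in range(reps):
            fit, table, _ = compare_groups(_two_group_data(pa, pb, 300 + k), self.CFG)
            row = table[table["parameter"] == "v2"].iloc[0]
            detected += int(row["p_value"] < 0.05)
        assert detected >= 13

    def test_single_group_rejected(self, small_tcore_data):
        with pytest.raises(ValueError):
            compare_groups(small_tcore_data, self.CFG)


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        out = compact_letter_display(["a", "b", "c"], set())
        assert set(out.values()) == {"a"}

    def test_chain_structure(self):
        # x < y < z with only (x, z) significant: y shares with both
        out = compact_letter_display(["x", "y", "z"], {frozenset(("x", "z"))})
        assert set(out["x"]) & set(out["y"])
        assert set(out["y"]) & set(out["z"])
        assert not set(out["x"]) & set(out["z"])

    def test_all_pairs_distinct(self):
        sig = {frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))}
        out = compact_letter_display(["a", "b", "c"], sig)
        assert len({out["a"], out["b"], out["c"]}) == 3
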