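"""Adaptively enriched RDA, adaptive-index projection and genomic offset."""

import numpy as np
import pandas as pd
import pytest

from adaptscape.landscape import adaptive_index, fit_aerda, genomic_offset
from adaptscape.ordination import fit_rda
from adaptscape.preprocess import standardize, standardize_like
from adaptscape.simulate import default_config, make_future_env, make_scenario

from conftest import env_from_frame


@pytest.fixture(scope="module")
def fitted_landscape():
    """A small standardized environment, per-site response, and aeRDA fit."""
    rng = np.random.default_rng(0)
    S = 30
    df = pd.DataFrame(
        {
            "temp": np.linspace(0, 3, S) + rng.normal(0, 0.1, S),
            "flow": rng.normal(size=S),
        },
        index=[f"s{i}" for i in range(S)],
    )
    env = standardize(env_from_frame(df))
    Z = env.values.to_numpy()
    Y = np.column_stack(
        [Z[:, 0] * b + rng.normal(0, 0.3, S) for b in (1.0, -0.8, 0.5, 0.9, -1.2)]
    )
    fit = fit_rda(Y, env.values)
    return env, Y, fit


class TestFitAerda:
    def test_all_loci_equals_full_fit(self, fitted_landscape):
        env, Y, full = fitted_landscape
        ae = fit_aerda(Y, np.ones(Y.shape[1], dtype=bool), env.values)
        assert ae.r2 == pytest.approx(full.r2, rel=1e-12)
        np.testing.assert_allclose(ae.eigenvalues, full.eigenvalues, rtol=1e-10)

    def test_single_locus_single_axis(self, fitted_landscape):
        env, Y, _ = fitted_landscape
        mask = np.zeros(Y.shape[1], dtype=bool)
        mask[0] = True
        ae = fit_aerda(Y, mask, env.values)
        assert ae.n_axes == 1

    def test_zero_outliers_rejected(self, fitted_landscape):
        env, Y, _ = fitted_landscape
        with pytest.raises(ValueError, match="relax"):
            fit_aerda(Y, np.zeros(Y.shape[1], dtype=bool), env.values)

    def test_causal_variable_tops_axis_one_on_simulations(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            S = 40
            df = pd.DataFrame(
                {
                    "causal": np.linspace(0, 2, S) + rng.normal(0, 0.2, S),
                    "bystander": rng.normal(size=S),
                    "other": rng.normal(size=S),
                },
                index=[f"s{i}" for i in range(S)],
            )
            env = standardize(env_from_frame(df))
            Z = env.values.to_numpy()
            Y = np.column_stack(
                [Z[:, 0] * rng.choice([-1, 1]) + rng.normal(0, 0.5, S) for _ in range(12)]
            )
            ae = fit_aerda(Y, np.ones(12, dtype=bool), env.values)
            wins += ae.variable_scores["RDA1"].abs().idxmax() == "causal"
        assert wins >= 8


class TestAdaptiveIndex:
    def test_single_predictor_definition(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"t": rng.normal(size=20)}, index=[f"s{i}" for i in range(20)])
        env = standardize(env_from_frame(df))
        z = env.values["t"].to_numpy()
        Y = np.column_stack([z, -z]) + rng.normal(0, 0.1, (20, 2))
        fit = fit_rda(Y, env.values)
        ai = adaptive_index(fit, env, axes=(1,))
        score = fit.variable_scores.loc["t", "RDA1"]
        np.testing.assert_allclose(ai["AI1"], score * z, rtol=1e-10)

    def test_mean_environment_maps_to_zero(self, fitted_landscape):
        env, _, fit = fitted_landscape
        mean_row = env.copy()
        mean_row.values = env.values.iloc[:1] * 0.0
        ai = adaptive_index(fit, mean_row)
        np.testing.assert_allclose(ai.to_numpy(), 0.0, atol=1e-12)

    def test_projection_consistent_with_site_scores(self, fitted_landscape):
        env, _, fit = fitted_landscape
        ai = adaptive_index(fit, env, axes=(1,))
        r = np.corrcoef(ai["AI1"], fit.site_scores[:, 0])[0, 1]
        assert abs(r) >= 0.8

    def test_missing_model_variable_rejected(self, fitted_landscape):
        env, _, fit = fitted_landscape
        with pytest.raises(ValueError, match="flow"):
            adaptive_index(fit, env.select(["temp"]))


class TestGenomicOffset:
    def test_future_equals_current_offset_zero(self, fitted_landscape):
        env, _, fit = fitted_landscape
        fut = env.copy()
        fut.scenario_tag = "same"
        grid = genomic_offset(fit, env, fut)
        np.testing.assert_allclose(grid["offset"], 0.0, atol=1e-12)

    def test_offset_linear_in_single_variable_shift(self, fitted_landscape):
        env, _, fit = fitted_landscape
        fut1, fut2 = env.copy(), env.copy()
        fut1.values = env.values.copy()
        fut2.values = env.values.copy()
        fut1.values["temp"] += 0.5
        fut2.values["temp"] += 1.0
        fut1.scenario_tag, fut2.scenario_tag = "d1", "d2"
        o1 = genomic_offset(fit, env, fut1)["offset"]
        o2 = genomic_offset(fit, env, fut2)["offset"]
        np.testing.assert_allclose(o2, 2 * o1, rtol=1e-8)

    def test_non_model_variable_ignored(self, fitted_landscape):
        env, _, fit = fitted_landscape
        rng = np.random.default_rng(2)
        fut = env.copy()
        fut.values = env.values.copy()
        fut.values["temp"] += 1.0
        base = genomic_offset(fit, env, fut)["offset"]
        aug_env = env.copy()
        aug_env.values = env.values.assign(unused=rng.normal(size=len(env.values)))
        aug_env.var_meta["unused"] = env.var_meta["temp"]
        aug_fut = fut.copy()
        aug_fut.values = fut.values.assign(unused=rng.normal(size=len(env.values)))
        aug_fut.var_meta["unused"] = env.var_meta["temp"]
        scrambled = genomic_offset(fit, aug_env, aug_fut)["offset"]
        np.testing.assert_allclose(scrambled, base, rtol=1e-12)

    def test_larger_uniform_shift_means_larger_mean_offset(self):
        cfg = default_config(seed=3, m_env=0.0)
        bundle = make_scenario(cfg)
        env = standardize(bundle.env_current)
        rng = np.random.default_rng(3)
        Z = env.values[["temperature", "precipitation"]]
        Y = np.column_stack(
            [Z.to_numpy() @ rng.normal(size=2) + rng.normal(0, 0.4, len(Z)) for _ in range(10)]
        )
        fit = fit_rda(Y, env.values[["temperature", "precipitation", "turbidity"]])
        small_cfg = default_config(seed=3, m_env=0.0, future_shift={"temperature": 0.5})
        big_cfg = default_config(seed=3, m_env=0.0, future_shift={"temperature": 1.5})
        fut_small = standardize_like(make_future_env(bundle.env_current, small_cfg), env)
        fut_big = standardize_like(make_future_env(bundle.env_current, big_cfg), env)
        o_small = genomic_offset(fit, env, fut_small)["offset"].mean()
        o_big = genomic_offset(fit, env, fut_big)["offset"].mean()
        assert o_big > o_small

    def test_eigenvalue_weights_accepted(self, fitted_landscape):
        env, _, fit = fitted_landscape
        fut = env.copy()
        fut.values = env.values.copy()
        fut.values["temp"] += 1.0
        k = min(2, fit.n_axes)
        w = fit.proportion_explained()[:k]
        grid = genomic_offset(fit, env, fut, axes=tuple(range(1, k + 1)), weights=w)
        assert (grid["offset"] >= 0).all()
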