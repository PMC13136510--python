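"""MAF filtering, kNN imputation, correlation pruning, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adaptscape.datatypes import GenotypeMatrix
from adaptscape.preprocess import (
    knn_impute_env,
    knn_impute_genotypes,
    maf_filter,
    prune_correlated,
    standardize,
    standardize_like,
)
from adaptscape.simulate import default_config, make_scenario

from conftest import env_from_frame


def matrix_from(dosages, prefix="l"):
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    ids = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(
        dosages, [f"{prefix}{j}" for j in range(L)], ids, {i: "s1" for i in ids}
    )


class TestMafFilter:
    def test_single_alt_allele_among_100_removed(self):
        col = np.zeros((100, 1))
        col[0, 0] = 1  # f = 0.005 < 0.01
        G = matrix_from(np.hstack([col, np.tile([[0], [2]], (50, 1))]))
        out = maf_filter(G, 0.01)
        assert out.locus_ids == ["l1"]

    def test_balanced_loci_kept(self):
        G = matrix_from(np.tile([[0, 2], [2, 0]], (10, 1)))
        assert maf_filter(G, 0.01).n_loci == 2

    def test_brute_force_frequency_tally(self):
        rng = np.random.default_rng(42)
        freqs = np.concatenate([rng.uniform(0.05, 0.5, 7), [0.002, 0.004, 0.006]])
        dosages = rng.binomial(2, freqs, size=(400, 10)).astype(float)
        G = matrix_from(dosages)
        # independent tally: per-locus allele counting
        expected_keep = []
        for j in range(10):
            f = dosages[:, j].sum() / (2 * 400)
            if min(f, 1 - f) >= 0.01:
                expected_keep.append(G.locus_ids[j])
        out = maf_filter(G, 0.01)
        assert out.locus_ids == expected_keep
        assert len(expected_keep) <= 7

    def test_boundary_equality_retained(self):
        # f exactly 0.01 with 100 diploids: 2 ALT alleles
        col = np.zeros((100, 1))
        col[0, 0] = 2
        out = maf_filter(matrix_from(col), 0.01)
        assert out.n_loci == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        G = matrix_from(rng.binomial(2, rng.uniform(0, 0.3, 20), size=(50, 20)).astype(float))
        once = maf_filter(G, 0.05)
        twice = maf_filter(once, 0.05)
        assert once.locus_ids == twice.locus_ids


class TestGenotypeImputation:
    def test_unanimous_column(self):
        dosages = np.full((8, 3), 2.0)
        dosages[0, 1] = np.nan
        out = knn_impute_genotypes(matrix_from(dosages), k=3)
        assert out.dosages[0, 1] == 2.0

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        G = matrix_from(rng.integers(0, 3, size=(10, 6)).astype(float))
        out = knn_impute_genotypes(G)
        np.testing.assert_array_equal(out.dosages, G.dosages)

    def test_observed_entries_never_altered(self, demo_bundle):
        G = demo_bundle.genotypes
        obs = ~G.missing_mask
        out = knn_impute_genotypes(G)
        np.testing.assert_array_equal(out.dosages[obs], G.dosages[obs])
        assert not np.isnan(out.dosages).any()

    def test_beats_column_mean_baseline_on_planted_mask(self):
        cfg = default_config(seed=5, m_geno=0.0)
        bundle = make_scenario(cfg)
        truth = bundle.genotypes.dosages.copy()
        rng = np.random.default_rng(99)
        mask = rng.random(truth.shape) < 0.05
        masked = truth.copy()
        masked[mask] = np.nan
        G = GenotypeMatrix(
            masked, bundle.genotypes.locus_ids, bundle.genotypes.individual_ids,
            bundle.genotypes.site_of,
        )
        imputed = knn_impute_genotypes(G)
        knn_acc = np.mean(imputed.dosages[mask] == truth[mask])
        col_mean = np.clip(np.floor(np.nanmean(masked, axis=0) + 0.5), 0, 2)
        baseline = np.broadcast_to(col_mean, truth.shape)
        base_acc = np.mean(baseline[mask] == truth[mask])
        assert knn_acc > base_acc


class TestEnvImputation:
    def test_identical_sites_share_value(self):
        df = pd.DataFrame(
            {"a": [1.0, 1.0, 1.0, 1.0], "b": [5.0, 5.0, np.nan, 5.0]},
            index=list("wxyz"),
        )
        out = knn_impute_env(env_from_frame(df), k=2)
        assert out.values.loc["y", "b"] == 5.0

    def test_no_missing_identity(self, tiny_env):
        out = knn_impute_env(tiny_env)
        pd.testing.assert_frame_equal(out.values, tiny_env.values)

    def test_smooth_gradient_recovery(self):
        rng = np.random.default_rng(7)
        g = np.linspace(0, 1, 50)
        df = pd.DataFrame(
            {"u": 3 * g + rng.normal(0, 0.1, 50), "v": -2 * g + rng.normal(0, 0.1, 50)},
            index=[f"s{i}" for i in range(50)],
        )
        truth = df.copy()
        mask = rng.random(df.shape) < 0.15
        mask[mask.all(axis=1)] = [True, False]
        df = df.mask(mask)
        out = knn_impute_env(env_from_frame(df), k=5)
        for j, col in enumerate(df.columns):
            sel = mask[:, j]
            if sel.any():
                err = np.abs(out.values[col].to_numpy()[sel] - truth[col].to_numpy()[sel])
                assert err.mean() < truth[col].std()

    def test_all_missing_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="all sites"):
            knn_impute_env(env_from_frame(df))


class TestPruneCorrelated:
    def test_hand_checked_triplet(self):
        # |r(x,y)| = 0.986 > 0.7; |r(x,z)| = 0.3, |r(y,z)| = 0.247 below
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, 5], "y": [1, 2, 3, 4, 6], "z": [5, 1, 4, 2, 3]},
            dtype=float, index=[f"s{i}" for i in range(5)],
        )
        pruned, report = prune_correlated(env_from_frame(df), 0.7)
        kept = set(pruned.variables)
        assert "z" in kept
        assert len({"x", "y"} & kept) == 1
        assert len(report) == 1 and report.iloc[0]["reason"] == "correlation"

    def test_single_variable_unchanged(self, tiny_env):
        single = tiny_env.select(["temp"])
        pruned, report = prune_correlated(single)
        assert pruned.variables == ["temp"] and report.empty

    def test_identical_columns_one_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]},
                          index=[f"s{i}" for i in range(4)])
        pruned, report = prune_correlated(env_from_frame(df))
        assert len(pruned.variables) == 1
        assert report.iloc[0]["r"] == pytest.approx(1.0)

    def test_keep_list_protects(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.1, 2, 3, 4.2]},
                          index=[f"s{i}" for i in range(4)])
        pruned, _ = prune_correlated(env_from_frame(df), keep_list=["a"])
        assert "a" in pruned.variables

    def test_stable_under_second_application(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        df = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(0, 0.2, 30),
                "c": rng.normal(size=30),
                "d": base * -1 + rng.normal(0, 0.1, 30),
            },
            index=[f"s{i}" for i in range(30)],
        )
        once, _ = prune_correlated(env_from_frame(df))
        twice, report = prune_correlated(once)
        assert twice.variables == once.variables and report.empty


class TestStandardize:
    def test_sample_sd_convention(self, tiny_env):
        out = standardize(tiny_env)
        np.testing.assert_allclose(out.values["temp"], [-1.0, 0.0, 1.0])
        assert out.var_meta["temp"].mean == pytest.approx(2.0)
        assert out.var_meta["temp"].sd == pytest.approx(1.0)

    def test_idempotent_values(self, tiny_env):
        once = standardize(tiny_env)
        twice = standardize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12)

    def test_binary_left_alone(self):
        df = pd.DataFrame({"p": [0.0, 1.0, 1.0]}, index=["s1", "s2", "s3"])
        out = standardize(env_from_frame(df, binary=("p",)))
        np.testing.assert_array_equal(out.values["p"], [0, 1, 1])

    def test_zero_sd_rejected(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]}, index=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="flat"):
            standardize(env_from_frame(df))

    @given(delta=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_future_shift_is_linear_in_standard_units(self, delta):
        df = pd.DataFrame({"t": [10.0, 12.0, 15.0, 11.0]}, index=[f"s{i}" for i in range(4)])
        current = standardize(env_from_frame(df))
        future_raw = env_from_frame(df + delta)
        future = standardize_like(future_raw, current)
        sd = current.var_meta["t"].sd
        np.testing.assert_allclose(
            future.values["t"] - current.values["t"], delta / sd, atol=1e-9
        )
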