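"""RDA engine against a brute-force least-squares + eigendecomposition oracle,
plus the printed-table adjusted-R^2 arithmetic."""

import numpy as np
import pandas as pd
import pytest

from adaptscape.ordination import (
    adjusted_r2,
    ezekiel_adjusted_r2,
    fit_rda,
    permutation_anova,
)


def rda_oracle(Y, X, Z=None):
    """Independent brute-force reference: explicit projections + eig of the
    fitted crossproduct."""
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    Yc = Y - Y.mean(0)
    Zd = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    P_z = Zd @ np.linalg.pinv(Zd)
    Yr = Yc - P_z @ Yc
    Xr = np.asarray(X, float) - P_z @ np.asarray(X, float)
    P_x = Xr @ np.linalg.pinv(Xr)
    F = P_x @ Yr
    total = np.sum(Yc**2) / (n - 1)
    constrained = np.trace(F.T @ F) / (n - 1)
    residual = np.sum((Yr - F) ** 2) / (n - 1)
    evals, evecs = np.linalg.eigh(F.T @ F / (n - 1))
    order = np.argsort(evals)[::-1]
    return {
        "total": total,
        "constrained": constrained,
        "residual": residual,
        "r2": constrained / total,
        "eigenvalues": evals[order],
        "eigenvectors": evecs[:, order],
    }


def subspace_distance(A, B):
    """1 - smallest principal-angle cosine between equal-rank column spaces."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return 1.0 - s.min()


class TestFitRda:
    def test_perfectly_predicted_single_locus(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        fit = fit_rda(x[:, None].copy(), x[:, None])
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.n_axes == 1

    def test_orthogonal_predictor_gives_zero_r2(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        y -= y.mean()
        x -= x.mean()
        x -= y * (x @ y) / (y @ y)  # exact orthogonality
        fit = fit_rda(y[:, None], x[:, None])
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("with_z", [False, True])
    def test_matches_brute_force_oracle(self, with_z):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(15, 40))
            L = int(rng.integers(3, 12))
            q = int(rng.integers(1, 4))
            Y = rng.normal(size=(n, L))
            X = rng.normal(size=(n, q))
            Z = rng.normal(size=(n, 2)) if with_z else None
            fit = fit_rda(Y, X, Z)
            ref = rda_oracle(Y, X, Z)
            assert fit.constrained_inertia == pytest.approx(ref["constrained"], rel=1e-8)
            assert fit.residual_inertia == pytest.approx(ref["residual"], rel=1e-8)
            assert fit.r2 == pytest.approx(ref["r2"], rel=1e-8)
            k = fit.n_axes
            np.testing.assert_allclose(
                fit.eigenvalues, ref["eigenvalues"][:k], rtol=1e-8, atol=1e-12
            )
            assert subspace_distance(
                fit.locus_loadings, ref["eigenvectors"][:, :k]
            ) < 1e-8

    def test_inertia_decomposition_and_eigenvalue_sum(self):
        rng = np.random.default_rng(2)
        fit = fit_rda(rng.normal(size=(30, 10)), rng.normal(size=(30, 3)), rng.normal(size=(30, 2)))
        decomposed = fit.conditioned_inertia + fit.constrained_inertia + fit.residual_inertia
        assert decomposed == pytest.approx(fit.total_inertia, rel=1e-8)
        assert fit.eigenvalues.sum() == pytest.approx(fit.constrained_inertia, rel=1e-8)
        assert np.all(np.diff(fit.eigenvalues) <= 1e-12)

    def test_empty_z_equals_zero_matrix_z_and_constant_z(self):
        rng = np.random.default_rng(3)
        Y, X = rng.normal(size=(25, 6)), rng.normal(size=(25, 2))
        base = fit_rda(Y, X)
        zeroz = fit_rda(Y, X, np.zeros((25, 1)))
        constz = fit_rda(Y, X, np.full((25, 1), 3.5))
        for other in (zeroz, constz):
            assert other.r2 == pytest.approx(base.r2, rel=1e-10)
            assert other.constrained_inertia == pytest.approx(base.constrained_inertia, rel=1e-10)

    def test_r2_invariant_to_invertible_recombination(self):
        rng = np.random.default_rng(4)
        Y, X = rng.normal(size=(30, 8)), rng.normal(size=(30, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        assert fit_rda(Y, X @ A).r2 == pytest.approx(fit_rda(Y, X).r2, rel=1e-9)

    def test_rank_deficient_predictors_dropped(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        Xdup = pd.DataFrame(
            np.column_stack([X, X[:, 0] + X[:, 1]]), columns=["a", "b", "c"]
        )
        fit = fit_rda(rng.normal(size=(20, 5)), Xdup)
        assert fit.q == 2

    def test_too_few_individuals_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="n > q"):
            fit_rda(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))

    def test_sign_convention(self):
        rng = np.random.default_rng(8)
        fit = fit_rda(rng.normal(size=(30, 10)), rng.normal(size=(30, 3)))
        for a in range(fit.n_axes):
            col = fit.locus_loadings[:, a]
            assert col[np.argmax(np.abs(col))] > 0


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "n,q,r2,expected",
        [(2229, 10, 0.0694, 0.0652), (2251, 55, 0.1179, 0.0958)],
    )
    def test_full_model_rows(self, n, q, r2, expected):
        assert ezekiel_adjusted_r2(r2, n, q) == pytest.approx(expected, abs=5e-5)

    def test_zero_r2_adjusts_nonpositive(self):
        assert ezekiel_adjusted_r2(0.0, 100, 5) <= 0.0

    def test_semipartial_difference_construction(self):
        rng = np.random.default_rng(9)
        Y, X, Z = rng.normal(size=(50, 6)), rng.normal(size=(50, 2)), rng.normal(size=(50, 2))
        fit = fit_rda(Y, X, Z)
        joint = fit_rda(Y, np.column_stack([X, Z]))
        cond = fit_rda(Y, Z)
        expected = ezekiel_adjusted_r2(joint.r2, 50, 4) - ezekiel_adjusted_r2(cond.r2, 50, 2)
        assert adjusted_r2(fit) == pytest.approx(expected, rel=1e-8)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            ezekiel_adjusted_r2(0.5, 10, 9)


class TestPermutationAnova:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        Y = np.column_stack([x, 2 * x])
        p, _ = permutation_anova(Y, x[:, None], n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(11)
        Y, X = rng.normal(size=(25, 4)), rng.normal(size=(25, 2))
        p1, f1 = permutation_anova(Y, X, n_perm=199, seed=42)
        p2, f2 = permutation_anova(Y, X, n_perm=199, seed=42)
        assert p1 == p2 and f1 == f2

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            Y = rng.normal(size=(20, 3))
            X = rng.normal(size=(20, 2))
            p, _ = permutation_anova(Y, X, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09
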