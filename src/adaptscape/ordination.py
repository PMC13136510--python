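"""Constrained ordination: redundancy analysis (RDA) and partial RDA.

RDA regresses a column-centered multivariate response Y (individuals x loci)
on predictors X, then eigen-decomposes the fitted values; partial RDA first
removes conditioning covariates Z from both Y and X by ordinary least
squares.  Inertia is defined on the variance scale (sum of column variances,
denominator n-1); only ratios of inertias are ever reported, so the
denominator convention cancels.

The decomposition satisfies

    total = conditioned + constrained + residual

with ``R^2 = constrained / total``.  Adjusted R^2 follows Ezekiel's formula,
with the semipartial (difference) construction for partial models.
Permutation significance permutes rows of the Z-residualized response
(reduced-model permutation) and compares pseudo-F statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

log = logging.getLogger(__name__)

__all__ = ["RdaFit", "fit_rda", "adjusted_r2", "ezekiel_adjusted_r2", "permutation_anova"]

_RANK_TOL = 1e-9


@dataclass
class RdaFit:
    """A fitted (partial) redundancy analysis.

    ``locus_loadings`` are the unit-norm right singular vectors of the fitted
    value matrix; ``site_scores`` the corresponding linear-combination scores
    (U * S); ``variable_scores`` the Pearson correlation of each residualized
    predictor with each site-score axis (biplot-style).  The sign convention
    makes the largest-magnitude element of each loading column positive.
    """

    eigenvalues: np.ndarray          # per constrained axis, variance scale
    locus_loadings: np.ndarray       # loci x axes, unit columns
    site_scores: np.ndarray          # individuals x axes
    variable_scores: pd.DataFrame    # predictors x axes
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    conditioned_inertia: float
    r2: float
    adj_r2: float
    n: int
    q: int                           # effective predictor rank
    c: int                           # effective conditioning rank
    predictor_names: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def proportion_explained(self) -> np.ndarray:
        """Share of constrained inertia per axis."""
        return self.eigenvalues / self.eigenvalues.sum()

    def to_dir(self, path: str | Path) -> None:
        """Serialize to a directory of CSVs plus a JSON summary."""
        import json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        axes = [f"RDA{a + 1}" for a in range(self.n_axes)]
        pd.DataFrame({"axis": axes, "eigenvalue": self.eigenvalues}).to_csv(
            path / "eigenvalues.csv", index=False
        )
        pd.DataFrame(self.locus_loadings, columns=axes, index=self.locus_ids or None).to_csv(
            path / "locus_loadings.csv"
        )
        pd.DataFrame(self.site_scores, columns=axes).to_csv(path / "site_scores.csv", index=False)
        self.variable_scores.to_csv(path / "variable_scores.csv")
        summary = {
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "residual_inertia": self.residual_inertia,
            "conditioned_inertia": self.conditioned_inertia,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "q": self.q,
            "c": self.c,
        }
        (path / "summary.json").write_text(json.dumps(summary, indent=2))


def _as_matrix(M, n: int) -> np.ndarray:
    if M is None:
        return np.empty((n, 0))
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != n:
        raise ValueError("row count mismatch between response and covariates")
    return M


def _inertia(M: np.ndarray) -> float:
    """Sum of column variances of a centered matrix (denominator n-1)."""
    return float(np.sum(M * M) / (M.shape[0] - 1))


def _residualize(M: np.ndarray, Z1: np.ndarray) -> np.ndarray:
    """Residuals of M on [intercept, Z] via least squares."""
    coef, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    return M - Z1 @ coef


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > _RANK_TOL * diag[0]))
    return np.sort(piv[:rank])


def fit_rda(
    Y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    Z: np.ndarray | pd.DataFrame | None = None,
    locus_ids: list[str] | None = None,
) -> RdaFit:
    """Fit an RDA (Z empty) or partial RDA (Z conditioning covariates).

    Y is column-centered internally.  Redundant predictor columns (after
    residualization on Z) are dropped with a warning; the effective ranks
    are reported as ``q`` and ``c``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (individuals x loci)")
    n = Y.shape[0]
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = _as_matrix(X, n)
    Z = _as_matrix(Z, n)
    if x_names is None:
        x_names = [f"x{j + 1}" for j in range(X.shape[1])]

    Yc = Y - Y.mean(axis=0)
    total = _inertia(Yc)

    Z1 = np.column_stack([np.ones(n), Z])
    z_keep = _independent_columns(Z1)
    Z1 = Z1[:, z_keep]
    c = Z1.shape[1] - 1  # effective conditioning rank beyond the intercept
    Yres = _residualize(Yc, Z1)
    Xres = _residualize(X, Z1)
    conditioned = total - _inertia(Yres)

    keep = _independent_columns(Xres)
    if len(keep) < Xres.shape[1]:
        dropped = [x_names[j] for j in range(Xres.shape[1]) if j not in keep]
        log.warning("dropping rank-deficient predictors: %s", dropped)
    Xres = Xres[:, keep]
    x_names = [x_names[j] for j in keep]
    q = Xres.shape[1]
    if q == 0:
        raise ValueError("no linearly independent predictors remain")
    if n <= q + c + 1:
        raise ValueError(f"need n > q + c + 1 (n={n}, q={q}, c={c})")

    B = np.linalg.pinv(Xres.T @ Xres) @ (Xres.T @ Yres)
    Yhat = Xres @ B
    constrained = _inertia(Yhat)
    residual = _inertia(Yres - Yhat)

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    max_axes = min(q, n - 1, Y.shape[1])
    nz = eigenvalues > max(eigenvalues[0], 1e-30) * 1e-12 if eigenvalues.size else np.array([], bool)
    n_axes = min(int(nz.sum()), max_axes)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    eigenvalues = eigenvalues[:n_axes]

    loadings = Vt.T  # loci x axes, unit columns
    # sign convention: largest-magnitude element of each loading column positive
    for a in range(n_axes):
        jmax = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[jmax, a] < 0:
            loadings[:, a] *= -1.0
            U[:, a] *= -1.0
    site_scores = U * s

    axes = [f"RDA{a + 1}" for a in range(n_axes)]
    var_scores = np.zeros((q, n_axes))
    for j in range(q):
        xj = Xres[:, j]
        for a in range(n_axes):
            sa = site_scores[:, a]
            if xj.std() > 0 and sa.std() > 0:
                var_scores[j, a] = float(np.corrcoef(xj, sa)[0, 1])
    variable_scores = pd.DataFrame(var_scores, index=x_names, columns=axes)

    r2 = constrained / total if total > 0 else 0.0
    fit = RdaFit(
        eigenvalues=eigenvalues,
        locus_loadings=loadings,
        site_scores=site_scores,
        variable_scores=variable_scores,
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
        conditioned_inertia=conditioned,
        r2=r2,
        adj_r2=np.nan,
        n=n,
        q=q,
        c=c,
        predictor_names=x_names,
        locus_ids=list(locus_ids) if locus_ids is not None else [],
    )
    fit.adj_r2 = adjusted_r2(fit)
    return fit


def ezekiel_adjusted_r2(r2: float, n: int, q_total: int) -> float:
    """Ezekiel's adjustment: ``1 - (1 - R^2) (n - 1) / (n - 1 - q_total)``."""
    denom = n - 1 - q_total
    if denom <= 0:
        raise ValueError(f"adjusted R^2 undefined: n - 1 - q_total = {denom} <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / denom


def adjusted_r2(fit: RdaFit) -> float:
    """Adjusted R^2 of a fit; semipartial (difference) form for partial models.

    For an unconditioned model this is Ezekiel's formula with all predictors.
    For a partial model, adj(X|Z) = adjEzekiel(R^2 of X and Z jointly)
    - adjEzekiel(R^2 of Z alone), evaluated from the fit's inertia
    decomposition.
    """
    if fit.c == 0:
        return ezekiel_adjusted_r2(fit.r2, fit.n, fit.q)
    r2_joint = (fit.conditioned_inertia + fit.constrained_inertia) / fit.total_inertia
    r2_cond = fit.conditioned_inertia / fit.total_inertia
    return ezekiel_adjusted_r2(r2_joint, fit.n, fit.q + fit.c) - ezekiel_adjusted_r2(
        r2_cond, fit.n, fit.c
    )


def permutation_anova(
    Y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    Z: np.ndarray | pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, float]:
    """Permutation test of the constrained fraction; returns ``(p, F)``.

    ``F = (constrained/q) / (residual/(n - q - c - 1))``.  The null
    distribution permutes rows of the Z-residualized response and re-projects
    onto the residualized predictor space;
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    X = _as_matrix(X, n)
    Z = _as_matrix(Z, n)
    Yc = Y - Y.mean(axis=0)
    Z1 = np.column_stack([np.ones(n), Z])
    Z1 = Z1[:, _independent_columns(Z1)]
    c = Z1.shape[1] - 1
    Yres = _residualize(Yc, Z1)
    Xres = _residualize(X, Z1)
    Xres = Xres[:, _independent_columns(Xres)]
    q = Xres.shape[1]
    if n <= q + c + 1:
        raise ValueError(f"need n > q + c + 1 (n={n}, q={q}, c={c})")
    # orthonormal basis of the predictor space: constrained SS = ||Q^T Y||^2
    Q, _ = np.linalg.qr(Xres)
    df_resid = n - q - c - 1

    def f_stat(M: np.ndarray) -> float:
        total_ss = float(np.sum(M * M))
        fitted_ss = float(np.sum((Q.T @ M) ** 2))
        resid_ss = max(total_ss - fitted_ss, 0.0)
        if resid_ss <= 1e-12 * max(total_ss, 1.0):  # numerically perfect fit
            return np.inf
        return (fitted_ss / q) / (resid_ss / df_resid)

    f_obs = f_stat(Yres)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(Yres[perm]) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return p, f_obs
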