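"""Locus outlier detection from ordination loadings.

Each locus is scored by its squared Mahalanobis distance D^2 over the first
K axis loadings, computed against the location and scatter of all loci.
The distances are rescaled by the genomic inflation factor
``lambda = median(D^2) / median(chi^2_K)`` and converted to upper-tail
chi^2_K p-values, so a well-calibrated null yields uniform p.  Multiple
testing is handled by Bonferroni (family-wise) or Benjamini-Hochberg (FDR)
thresholds.  The same scan drives both the conservative neutral-locus
selection (high FDR on PCA loadings) and the genotype-environment outlier
detection (Bonferroni on RDA loadings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["OutlierReport", "mahalanobis_scan", "classify_outliers", "neutral_structure"]

_P_FLOOR = 1e-300


@dataclass
class OutlierReport:
    """Per-locus D^2, p-value and outlier flag, plus scan metadata."""

    locus_ids: list[str]
    d2: np.ndarray
    p_values: np.ndarray
    inflation_factor: float
    k_axes: int
    alpha: float | None = None
    threshold_type: str | None = None
    flags: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return len(self.p_values)

    @property
    def outlier_ids(self) -> list[str]:
        if self.flags is None:
            raise ValueError("run classify_outliers first")
        return [lid for lid, f in zip(self.locus_ids, self.flags) if f]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"locus_id": self.locus_ids, "d2": self.d2, "p_value": self.p_values}
        )
        if self.flags is not None:
            df["outlier"] = self.flags
        return df

    def to_csv(self, path: str | Path) -> None:
        import json

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        header = {
            "inflation_factor": self.inflation_factor,
            "k_axes": self.k_axes,
            "alpha": self.alpha,
            "threshold_type": self.threshold_type,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    def manhattan_frame(self) -> pd.DataFrame:
        """Locus order vs -log10 p, ready for a Manhattan-style plot."""
        return pd.DataFrame(
            {
                "order": np.arange(self.n_loci),
                "locus_id": self.locus_ids,
                "neglog10_p": -np.log10(np.maximum(self.p_values, _P_FLOOR)),
            }
        )


def mahalanobis_scan(
    loadings: np.ndarray,
    locus_ids: list[str] | None = None,
    robust: bool = False,
) -> OutlierReport:
    """Score loci by squared Mahalanobis distance over K axis loadings.

    ``robust=True`` uses minimum-covariance-determinant location/scatter
    (resistant to the outliers being sought); the default uses classical
    moments.  D^2 is divided by the genomic inflation factor before the
    chi^2_K upper-tail transform.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim == 1:
        loadings = loadings[:, None]
    L, K = loadings.shape
    if K < 1 or L <= K + 1:
        raise ValueError("need more loci than axes + 1")
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(loadings)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center = loadings.mean(axis=0)
        cov = np.cov(loadings, rowvar=False).reshape(K, K)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular loading covariance; try fewer axes"
        ) from exc
    delta = loadings - center
    d2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    lam = float(np.median(d2) / stats.chi2.median(K))
    if not lam > 0:
        raise ValueError("non-positive inflation factor (degenerate loadings)")
    p = stats.chi2.sf(d2 / lam, df=K)
    p = np.maximum(p, _P_FLOOR)
    if locus_ids is None:
        locus_ids = [f"locus{j}" for j in range(L)]
    return OutlierReport(
        locus_ids=list(locus_ids), d2=d2, p_values=p, inflation_factor=lam, k_axes=K
    )


def classify_outliers(
    report: OutlierReport,
    alpha: float = 0.01,
    threshold_type: str = "bonferroni",
) -> OutlierReport:
    """Flag outliers at level ``alpha`` by Bonferroni or BH step-up."""
    p = report.p_values
    L = report.n_loci
    if threshold_type == "bonferroni":
        flags = p < alpha / L
    elif threshold_type == "bh_fdr":
        from statsmodels.stats.multitest import multipletests

        flags, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    else:
        raise ValueError("threshold_type must be 'bonferroni' or 'bh_fdr'")
    return replace(
        report, alpha=alpha, threshold_type=threshold_type, flags=np.asarray(flags)
    )


def _standardize_columns(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; returns the matrix and a mask of non-constant columns."""
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(Y, dtype=float)
    Z[:, ok] = (Y[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def neutral_structure(
    dosages: np.ndarray,
    locus_ids: list[str] | None = None,
    fdr: float = 0.40,
    k_scan: int = 2,
    n_pcs: int = 2,
    robust: bool = False,
) -> tuple[np.ndarray, np.ndarray, OutlierReport]:
    """Select conservatively neutral loci and return neutral-PCA scores.

    PCA is run on the column-standardized dosage matrix; per-locus loadings
    on the first ``k_scan`` components are scanned for structural outliers
    at a deliberately permissive FDR (default 40%), and the PCA is refit on
    the surviving (neutral) loci.  Returns ``(neutral_mask, pc_scores,
    report)`` where ``pc_scores`` has ``n_pcs`` zero-mean columns.

    A high FDR errs toward discarding loci: anything resembling a structural
    outlier is kept out of the neutral set used for conditioning.
    """
    Y = np.asarray(dosages, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("dosage matrix must be imputed before the neutral scan")
    n, L = Y.shape
    if locus_ids is None:
        locus_ids = [f"locus{j}" for j in range(L)]
    Z, variable = _standardize_columns(Y)
    if variable.sum() <= k_scan + 1:
        raise ValueError("too few variable loci for the structure scan")
    U, s, Vt = np.linalg.svd(Z[:, variable], full_matrices=False)
    loadings = Vt[:k_scan].T
    scan_ids = [locus_ids[j] for j in np.flatnonzero(variable)]
    report = mahalanobis_scan(loadings, locus_ids=scan_ids, robust=robust)
    report = classify_outliers(report, alpha=fdr, threshold_type="bh_fdr")
    neutral = np.zeros(L, dtype=bool)
    neutral[np.flatnonzero(variable)] = ~report.flags
    # constant loci carry no structural signal; count them as neutral
    neutral[~variable] = True
    n_neutral_variable = int((neutral & variable).sum())
    if n_neutral_variable < 10 * n_pcs:
        raise ValueError(
            f"neutral set too small ({n_neutral_variable} loci) for {n_pcs} PCs"
        )
    Zn = Z[:, neutral & variable]
    Un, sn, _ = np.linalg.svd(Zn, full_matrices=False)
    scores = Un[:, :n_pcs] * sn[:n_pcs]
    log.info(
        "neutral scan: %d of %d loci flagged, %d neutral",
        int(report.flags.sum()), L, int(neutral.sum()),
    )
    return neutral, scores, report
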