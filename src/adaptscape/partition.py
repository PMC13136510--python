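"""Variance partitioning across predictor categories via partial RDA.

The full model regresses genotypes on every predictor jointly; each
category's *pure* effect is the constrained inertia of a partial RDA with
that category as predictors and all remaining predictors as conditioning
covariates.  The confounded fraction is the full-model variance minus the
sum of pure effects (floored at zero), the standard partitioning identity.
Percent-explainable columns divide by the full-model variance, percent-total
columns by total inertia.

Because categories with many variables mechanically explain more, a
subsampling analysis re-estimates each large category's pure adjusted R^2
from random draws of a fixed number of its variables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ordination import adjusted_r2, fit_rda, permutation_anova

log = logging.getLogger(__name__)

__all__ = ["partition", "subsample_categories", "percent_explainable"]


def percent_explainable(variance: float, full_variance: float) -> float:
    """Share (in percent) of the full model's explainable variance."""
    return 100.0 * variance / full_variance


def _check_categories(predictors: pd.DataFrame, categories: dict[str, list[str]]) -> None:
    seen: set[str] = set()
    for name, cols in categories.items():
        if not cols:
            raise ValueError(f"category {name!r} has no predictors")
        overlap = seen & set(cols)
        if overlap:
            raise ValueError(f"categories overlap on {sorted(overlap)}")
        unknown = [c for c in cols if c not in predictors.columns]
        if unknown:
            raise ValueError(f"category {name!r} names unknown predictors {unknown}")
        seen |= set(cols)
    uncovered = [c for c in predictors.columns if c not in seen]
    if uncovered:
        raise ValueError(f"predictors not covered by any category: {uncovered}")


def partition(
    Y: np.ndarray,
    predictors: pd.DataFrame,
    categories: dict[str, list[str]],
    seed: int = 0,
    n_perm: int = 99,
) -> pd.DataFrame:
    """Partition genetic variance across disjoint predictor categories.

    Returns a table with one row per model (full, each category pure,
    confounded, total unexplained, total inertia) and columns R^2,
    adjusted R^2, variance (inertia units), permutation p, percent
    explainable and percent total.  One seed derives a separate permutation
    substream per row.
    """
    _check_categories(predictors, categories)
    root = np.random.SeedSequence(seed)
    substreams = root.spawn(1 + len(categories))

    full = fit_rda(Y, predictors)
    total = full.total_inertia
    full_var = full.constrained_inertia
    p_full, _ = permutation_anova(Y, predictors, n_perm=n_perm, seed=substreams[0])
    rows = [
        {
            "model": "full",
            "r2": full.r2,
            "adj_r2": full.adj_r2,
            "variance": full_var,
            "p_value": p_full,
            "percent_explainable": 100.0,
            "percent_total": 100.0 * full_var / total,
        }
    ]
    pure_sum = 0.0
    for stream, (name, cols) in zip(substreams[1:], categories.items()):
        rest = [c for c in predictors.columns if c not in cols]
        fit = fit_rda(Y, predictors[cols], predictors[rest] if rest else None)
        p_cat, _ = permutation_anova(
            Y, predictors[cols], predictors[rest] if rest else None,
            n_perm=n_perm, seed=stream,
        )
        pure = fit.constrained_inertia
        pure_sum += pure
        rows.append(
            {
                "model": f"{name} only",
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
                "variance": pure,
                "p_value": p_cat,
                "percent_explainable": percent_explainable(pure, full_var),
                "percent_total": 100.0 * pure / total,
            }
        )
    confounded = full_var - pure_sum
    if confounded < 0:
        log.warning("negative confounded variance %.4f floored at 0", confounded)
        confounded = 0.0
    unexplained = total - full_var
    rows.append(
        {
            "model": "confounded",
            "r2": np.nan,
            "adj_r2": np.nan,
            "variance": confounded,
            "p_value": np.nan,
            "percent_explainable": percent_explainable(confounded, full_var),
            "percent_total": 100.0 * confounded / total,
        }
    )
    rows.append(
        {
            "model": "total unexplained",
            "r2": np.nan,
            "adj_r2": np.nan,
            "variance": unexplained,
            "p_value": np.nan,
            "percent_explainable": np.nan,
            "percent_total": 100.0 * unexplained / total,
        }
    )
    rows.append(
        {
            "model": "total inertia",
            "r2": np.nan,
            "adj_r2": np.nan,
            "variance": total,
            "p_value": np.nan,
            "percent_explainable": np.nan,
            "percent_total": 100.0,
        }
    )
    return pd.DataFrame(rows).set_index("model")


def subsample_categories(
    Y: np.ndarray,
    predictors: pd.DataFrame,
    categories: dict[str, list[str]],
    n_vars: int = 4,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure-effect adjusted R^2 from random ``n_vars``-variable draws.

    Categories with more than ``n_vars`` predictors are resampled ``n_iter``
    times (uniform, without replacement); smaller categories pass through
    with their unsubsampled pure adjusted R^2 for comparison.  Returns a
    long table (category, iteration, adj_r2, subsampled).
    """
    _check_categories(predictors, categories)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for name, cols in categories.items():
        rest_all = [c for c in predictors.columns if c not in cols]
        if len(cols) <= n_vars:
            fit = fit_rda(Y, predictors[cols], predictors[rest_all] if rest_all else None)
            records.append(
                {"category": name, "iteration": 0, "r2": fit.r2,
                 "adj_r2": adjusted_r2(fit), "subsampled": False}
            )
            continue
        for it in range(n_iter):
            draw = sorted(rng.choice(len(cols), size=n_vars, replace=False))
            sub = [cols[j] for j in draw]
            fit = fit_rda(Y, predictors[sub], predictors[rest_all] if rest_all else None)
            records.append(
                {"category": name, "iteration": it, "r2": fit.r2,
                 "adj_r2": adjusted_r2(fit), "subsampled": True}
            )
    return pd.DataFrame(records)
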