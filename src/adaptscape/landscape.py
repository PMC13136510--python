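"""Adaptively-enriched RDA, adaptive-index projection, and genomic offset.

After outlier loci are identified, the ordination is refit on those loci
alone (the adaptively enriched model).  The adaptive index of a location on
axis ``a`` is the projection of its standardized environment onto that
axis's variable scores:

    AI_a(x) = sum_j score(j, a) * z_j(x)

over the fitted predictors (conditioning covariates are excluded — they
have no future-scenario values).  Genomic offset is the Euclidean distance
between a location's adaptive index under current versus future conditions,
optionally weighted per axis; it proxies the magnitude of adaptive change a
population would need under the projected environment.  Because variable
scores are correlations (a per-model scaling), offsets are comparable within
one fitted model, not across models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import EnvTable
from .ordination import RdaFit, fit_rda

log = logging.getLogger(__name__)

__all__ = ["fit_aerda", "adaptive_index", "genomic_offset"]


def fit_aerda(
    Y: np.ndarray,
    outlier_mask: np.ndarray,
    X: pd.DataFrame,
    Z: pd.DataFrame | np.ndarray | None = None,
    locus_ids: list[str] | None = None,
) -> RdaFit:
    """Refit the (partial) RDA restricted to outlier loci."""
    outlier_mask = np.asarray(outlier_mask)
    if outlier_mask.dtype == bool:
        idx = np.flatnonzero(outlier_mask)
    else:
        idx = outlier_mask
    if idx.size == 0:
        raise ValueError("no outlier loci; relax alpha or the threshold type")
    sub_ids = [locus_ids[j] for j in idx] if locus_ids is not None else None
    return fit_rda(np.asarray(Y, float)[:, idx], X, Z, locus_ids=sub_ids)


def adaptive_index(
    fit: RdaFit,
    env: EnvTable,
    axes: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Per-location adaptive index on the requested (1-based) axes.

    ``env`` must be standardized with the *current* scenario's parameters
    and contain every fitted predictor; extra columns are ignored.
    """
    if not env.standardized:
        raise ValueError("environment table must be standardized first")
    missing = [v for v in fit.predictor_names if v not in env.values.columns]
    if missing:
        raise ValueError(f"environment table lacks model variables: {missing}")
    axes = tuple(a for a in axes if a <= fit.n_axes)
    if not axes:
        raise ValueError("no requested axis exists in the fit")
    Zv = env.values[fit.predictor_names].to_numpy(dtype=float)
    cols = {}
    for a in axes:
        scores = fit.variable_scores.iloc[:, a - 1].to_numpy()
        cols[f"AI{a}"] = Zv @ scores
    return pd.DataFrame(cols, index=env.values.index)


def genomic_offset(
    fit: RdaFit,
    env_current: EnvTable,
    env_future: EnvTable,
    axes: tuple[int, ...] = (1, 2),
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Euclidean distance between current and future adaptive index.

    Both tables must be standardized with the current scenario's parameters
    and cover the same locations.  ``weights=None`` weights axes equally;
    pass ``fit.proportion_explained()`` restricted to the axes for
    eigenvalue-proportion weighting.
    """
    if list(env_current.values.index) != list(env_future.values.index):
        raise ValueError("current and future tables must cover the same locations")
    ai_cur = adaptive_index(fit, env_current, axes)
    ai_fut = adaptive_index(fit, env_future, axes)
    used_axes = [int(c[2:]) for c in ai_cur.columns]
    if weights is None:
        w = np.ones(len(used_axes))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(used_axes),):
            raise ValueError(f"need one weight per axis ({len(used_axes)})")
    delta = ai_fut.to_numpy() - ai_cur.to_numpy()
    offset = np.sqrt(np.sum(w * delta**2, axis=1))
    out = pd.DataFrame(index=ai_cur.index)
    for c in ai_cur.columns:
        out[f"{c}_current"] = ai_cur[c]
        out[f"{c}_{env_future.scenario_tag}"] = ai_fut[c]
    out["offset"] = offset
    out.attrs["axis_weights"] = w.tolist()
    out.attrs["scenario"] = env_future.scenario_tag
    return out
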