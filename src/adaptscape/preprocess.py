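"""Data reduction ahead of ordination: MAF filtering, kNN imputation of
genotypes and environment, correlation pruning, and centering/scaling.

The genotype imputer follows the LD-kNN idea: for each missing call, find the
loci most correlated with the target locus, measure individual-to-individual
distance on those loci only, and average the dosages of the nearest
neighbours with inverse-distance weights.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .datatypes import EnvTable, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "maf_filter",
    "allele_frequencies",
    "knn_impute_genotypes",
    "knn_impute_env",
    "prune_correlated",
    "standardize",
    "standardize_like",
]


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus ALT-allele frequency over non-missing genotypes (NaN if none)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(G.dosages, axis=0) / 2.0


def maf_filter(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop loci with minor allele frequency strictly below ``threshold``.

    MAF is ``min(f, 1-f)`` with ``f`` the mean dosage / 2 over non-missing
    entries.  Loci exactly at the threshold are retained.  Loci with all
    entries missing are removed with a warning.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    f = allele_frequencies(G)
    all_missing = np.isnan(f)
    if all_missing.any():
        log.warning("removing %d loci with no observed genotypes", all_missing.sum())
    maf = np.minimum(f, 1.0 - f)
    keep = ~all_missing & (maf >= threshold)
    n_removed = G.n_loci - int(keep.sum())
    log.info("MAF filter (< %g): removed %d of %d loci", threshold, n_removed, G.n_loci)
    return G.select_loci(keep)


def _pairwise_complete_corr(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between columns over pairwise-complete rows.

    Returns ``(r, n_pairs)``.  Computed with indicator-matrix products so the
    cost is a handful of BLAS calls instead of an L x L Python loop; the
    values are identical to naive pairwise-complete Pearson.
    """
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    X0sq = X0 * X0
    n = M.T @ M
    sx = X0.T @ M       # sum of x_a over rows where b observed
    sxx = X0sq.T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = np.sqrt(varx * varx.T)
        r = cov / denom
    r[~np.isfinite(r)] = 0.0
    return r, n


def knn_impute_genotypes(
    G: GenotypeMatrix, k: int = 5, m_ld_loci: int = 30
) -> GenotypeMatrix:
    """Impute missing dosages from the k nearest individuals at LD loci.

    For each locus with missing calls: take the ``m_ld_loci`` loci with the
    highest ``|r|`` to it (pairwise-complete Pearson); the distance between
    two individuals is the mean squared dosage difference over those loci
    where both are observed; each missing call is the 1/d-weighted mean
    dosage of the ``k`` nearest individuals observed at the locus, rounded to
    the nearest integer in {0,1,2}.  Ties in distance break on the lower
    individual index.  Falls back to the rounded locus mean when fewer than
    ``k`` usable neighbours exist.
    """
    if G.n_individuals < k + 1:
        raise ValueError(f"need at least k+1={k + 1} individuals")
    X = G.dosages.copy()
    miss = np.isnan(X)
    if not miss.any():
        return G
    if miss.all(axis=0).any():
        raise ValueError("cannot impute loci with no observed genotypes")
    r, _ = _pairwise_complete_corr(X)
    np.fill_diagonal(r, 0.0)
    col_mean = np.nanmean(X, axis=0)
    n_fallback = 0
    out = X.copy()
    for l in np.flatnonzero(miss.any(axis=0)):
        m = min(m_ld_loci, G.n_loci - 1)
        ld_idx = np.argsort(-np.abs(r[l]), kind="stable")[:m]
        sub = X[:, ld_idx]  # n x m, NaN allowed
        rows = np.flatnonzero(miss[:, l])
        observed_at_l = ~miss[:, l]
        # mean squared difference over jointly observed LD loci
        diff = sub[rows, None, :] - sub[None, :, :]
        with np.errstate(invalid="ignore"):
            d = np.nanmean(diff * diff, axis=2)  # |rows| x n
        for ri, i in enumerate(rows):
            di = d[ri].copy()
            di[i] = np.nan
            candidates = np.flatnonzero(observed_at_l & np.isfinite(di))
            if candidates.size < k:
                out[i, l] = np.clip(np.floor(col_mean[l] + 0.5), 0, 2)
                n_fallback += 1
                continue
            order = candidates[np.argsort(di[candidates], kind="stable")]
            nearest = order[:k]
            w = 1.0 / np.maximum(di[nearest], 1e-12)
            val = float(np.sum(w * X[nearest, l]) / np.sum(w))
            out[i, l] = np.clip(np.floor(val + 0.5), 0, 2)
    if n_fallback:
        log.info("locus-mean fallback used for %d missing calls", n_fallback)
    return GenotypeMatrix(out, list(G.locus_ids), list(G.individual_ids), dict(G.site_of))


def knn_impute_env(E: EnvTable, k: int = 10) -> EnvTable:
    """Impute missing environment cells from the k nearest sites.

    Site-to-site distance is the mean squared difference over jointly
    observed variables, computed on internally standardized values so that
    variables on different scales contribute comparably.  Continuous cells
    get a Gaussian-kernel weighted mean (weight = exp(-d)); binary cells a
    weighted majority vote.
    """
    V = E.values.to_numpy(dtype=float)
    miss = np.isnan(V)
    if not miss.any():
        return E
    if miss.all(axis=1).any():
        raise ValueError("a site with no observed variables cannot be imputed")
    if miss.all(axis=0).any():
        bad = [E.variables[j] for j in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"variables missing at all sites: {bad}")
    mu = np.nanmean(V, axis=0)
    sd = np.nanstd(V, axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    Z = (V - mu) / sd
    out = V.copy()
    is_binary = np.array([E.var_meta[v].type == "binary" for v in E.variables])
    diff = Z[:, None, :] - Z[None, :, :]
    with np.errstate(invalid="ignore"):
        D = np.nanmean(diff * diff, axis=2)
    for s, j in zip(*np.nonzero(miss)):
        d = D[s].copy()
        d[s] = np.nan
        candidates = np.flatnonzero(~miss[:, j] & np.isfinite(d))
        if candidates.size == 0:
            raise ValueError(f"no donor site for variable {E.variables[j]!r}")
        order = candidates[np.argsort(d[candidates], kind="stable")][:k]
        w = np.exp(-d[order])
        if is_binary[j]:
            out[s, j] = 1.0 if np.sum(w * V[order, j]) / np.sum(w) >= 0.5 else 0.0
        else:
            out[s, j] = np.sum(w * V[order, j]) / np.sum(w)
    result = E.copy()
    result.values = pd.DataFrame(out, index=E.values.index, columns=E.values.columns)
    return result


def prune_correlated(
    E: EnvTable,
    r_threshold: float = 0.7,
    keep_list: list[str] | None = None,
) -> tuple[EnvTable, pd.DataFrame]:
    """Greedily drop variables until no pair has ``|r| > r_threshold``.

    While an offending pair remains, the member with the larger mean
    absolute correlation to all remaining variables is dropped, never a
    ``keep_list`` member (if both members are protected, the pair is logged
    and tolerated).  Zero-variance variables are dropped first.  Returns the
    pruned table and a report of dropped variables with the partner that
    triggered each drop.
    """
    keep_list = list(keep_list or [])
    dropped: list[dict[str, object]] = []
    cols = list(E.variables)
    V = E.values
    for v in list(cols):
        if V[v].std(ddof=1) == 0 or np.isnan(V[v].std(ddof=1)):
            if v in keep_list:
                log.warning("zero-variance variable %r protected by keep_list", v)
                continue
            log.warning("dropping zero-variance variable %r", v)
            dropped.append({"variable": v, "partner": "", "r": np.nan, "reason": "zero_variance"})
            cols.remove(v)
    protected_pairs: list[tuple[str, str]] = []
    while True:
        if len(cols) < 2:
            break
        corr = V[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        for a, b in protected_pairs:
            if a in cols and b in cols:
                absr[cols.index(a), cols.index(b)] = 0.0
                absr[cols.index(b), cols.index(a)] = 0.0
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_threshold:
            break
        a, b = cols[i], cols[j]
        if a in keep_list and b in keep_list:
            log.warning("correlated pair (%s, %s) both protected; retaining both", a, b)
            protected_pairs.append((a, b))
            continue
        if a in keep_list:
            victim, partner = b, a
        elif b in keep_list:
            victim, partner = a, b
        else:
            mean_i = absr[i].sum() / (len(cols) - 1)
            mean_j = absr[j].sum() / (len(cols) - 1)
            if mean_i >= mean_j:
                victim, partner = a, b
            else:
                victim, partner = b, a
        dropped.append(
            {"variable": victim, "partner": partner, "r": float(corr[i, j]), "reason": "correlation"}
        )
        cols.remove(victim)
    report = pd.DataFrame(dropped, columns=["variable", "partner", "r", "reason"])
    return E.select(cols), report


def standardize(E: EnvTable) -> EnvTable:
    """Center and scale continuous variables; record mean/sd in the metadata.

    Binary variables are left on their native 0/1 scale.  The recorded
    parameters are what :func:`standardize_like` applies to future-scenario
    tables, so indices computed from different scenarios share a scale.
    """
    out = E.copy()
    for v in E.variables:
        meta = out.var_meta[v]
        if meta.type != "continuous":
            out.var_meta[v] = replace(meta, mean=0.0, sd=1.0)
            continue
        x = out.values[v].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if not sd > 0:
            raise ValueError(f"variable {v!r} has zero standard deviation")
        out.values[v] = (x - mu) / sd
        out.var_meta[v] = replace(meta, mean=mu, sd=sd)
    out.standardized = True
    return out


def standardize_like(E: EnvTable, reference: EnvTable) -> EnvTable:
    """Standardize ``E`` (e.g. a future scenario) with ``reference``'s parameters."""
    if not reference.standardized:
        raise ValueError("reference table is not standardized")
    out = E.copy()
    for v in out.variables:
        if v not in reference.var_meta:
            raise ValueError(f"variable {v!r} absent from reference metadata")
        ref = reference.var_meta[v]
        if ref.type != "continuous":
            out.var_meta[v] = replace(out.var_meta[v], mean=0.0, sd=1.0)
            continue
        if ref.mean is None or ref.sd is None:
            raise ValueError(f"reference parameters missing for {v!r}")
        x = out.values[v].to_numpy(dtype=float)
        out.values[v] = (x - ref.mean) / ref.sd
        out.var_meta[v] = replace(out.var_meta[v], mean=ref.mean, sd=ref.sd)
    out.standardized = True
    return out
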