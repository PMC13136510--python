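"""Per-group diversity (Ho, He, Fis) and pairwise Fst summaries.

Expected heterozygosity uses the small-sample correction
``He = 2n/(2n-1) * (1 - p^2 - q^2)`` with ``n`` genotyped diploids, and group
summaries are ratio-of-averages across loci (mean of per-locus numerators
over mean of per-locus denominators), the convention of the classical
gene-diversity estimator family.

Two pairwise-Fst variants are provided.  The default, ``"hudson"``, is the
ratio-of-averages estimator ``1 - mean_l(Hw) / mean_l(Hb)`` with ``Hw`` the
average corrected within-group diversity and ``Hb = p1*q2 + p2*q1`` the
between-group heterozygosity; its expectation under a two-population
drift model with divergence parameter F is F itself, which is what the
simulation-recovery tests check.  ``"nei_gst"`` uses the pooled-frequency
total diversity ``Ht = 1 - pbar^2 - qbar^2`` instead, which for two
populations estimates F/(2-F) rather than F.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["per_pop_diversity", "pairwise_fst", "group_frequencies"]


def _groups(G: GenotypeMatrix, grouping: dict[str, str] | None) -> np.ndarray:
    """Group label per individual: waterway (via grouping map) or site id."""
    sites = G.sites
    if grouping is None:
        return sites
    return np.asarray([grouping[s] for s in sites])


def group_frequencies(
    G: GenotypeMatrix, grouping: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(group, locus) ALT frequency and genotyped-diploid count."""
    labels = _groups(G, grouping)
    freqs, counts = {}, {}
    for g in np.unique(labels):
        block = G.dosages[labels == g]
        n = (~np.isnan(block)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(block, axis=0) / (2.0 * n)
        freqs[g], counts[g] = p, n
    f = pd.DataFrame(freqs, index=G.locus_ids).T
    c = pd.DataFrame(counts, index=G.locus_ids).T
    return f, c


def _corrected_he(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Small-sample corrected gene diversity 2n/(2n-1) * 2p(1-p)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)


def per_pop_diversity(
    G: GenotypeMatrix, grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Ho, He (corrected) and Fis per group, each a mean over loci.

    Fis is the ratio-of-averages ``1 - mean(Ho)/mean(He)``; it is reported
    missing (with a warning) for groups monomorphic at every locus.
    """
    labels = _groups(G, grouping)
    rows = []
    for g in np.unique(labels):
        block = G.dosages[labels == g]
        observed = ~np.isnan(block)
        n = observed.sum(axis=0)
        usable = n >= 1
        with np.errstate(invalid="ignore"):
            p = np.nansum(block, axis=0) / (2.0 * n)
            ho = np.nansum(block == 1.0, axis=0) / n
        he = _corrected_he(p, n)
        mean_ho = float(np.mean(ho[usable]))
        mean_he = float(np.mean(he[usable]))
        if mean_he > 0:
            fis = 1.0 - mean_ho / mean_he
        else:
            log.warning("group %r monomorphic at all loci; Fis undefined", g)
            fis = np.nan
        rows.append({"group": g, "n": int(block.shape[0]), "Ho": mean_ho, "He": mean_he, "Fis": fis})
    return pd.DataFrame(rows).set_index("group")


def pairwise_fst(
    G: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    variant: str = "hudson",
) -> pd.DataFrame:
    """Square matrix of pairwise Fst between groups (ratio of averages).

    Loci monomorphic in both groups of a pair, or genotyped in fewer than
    two diploids in either group, are excluded from that pair's means.
    Negative estimates are reported as computed.
    """
    if variant not in ("hudson", "nei_gst"):
        raise ValueError("variant must be 'hudson' or 'nei_gst'")
    freqs, counts = group_frequencies(G, grouping)
    groups = list(freqs.index)
    fst = pd.DataFrame(np.zeros((len(groups), len(groups))), index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        p1, p2 = freqs.loc[a].to_numpy(), freqs.loc[b].to_numpy()
        n1, n2 = counts.loc[a].to_numpy(), counts.loc[b].to_numpy()
        ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
        poly = ok & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
        if not poly.any():
            log.warning("no shared polymorphic loci for pair (%s, %s)", a, b)
            fst.loc[a, b] = fst.loc[b, a] = np.nan
            continue
        hs = 0.5 * (_corrected_he(p1[poly], n1[poly]) + _corrected_he(p2[poly], n2[poly]))
        if variant == "hudson":
            ht = p1[poly] * (1 - p2[poly]) + p2[poly] * (1 - p1[poly])
        else:
            pbar = 0.5 * (p1[poly] + p2[poly])
            ht = 1.0 - pbar**2 - (1.0 - pbar) ** 2
        value = 1.0 - np.mean(hs) / np.mean(ht)
        if value < 0:
            log.info("negative Fst estimate %.4f for pair (%s, %s)", value, a, b)
        fst.loc[a, b] = fst.loc[b, a] = value
    return fst
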