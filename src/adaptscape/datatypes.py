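"""Core containers for the genotype-environment association pipeline.

Three tables travel through the pipeline: a ``GenotypeMatrix`` of allele
dosages (individuals x loci), a ``SiteTable`` locating sampling sites, and an
``EnvTable`` of per-site predictor variables with category/type metadata.
Dosage is the count of ALT alleles (0/1/2); orientation only flips ordination
loading signs and cancels in every reported statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "SiteTable", "VarMeta", "EnvTable"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with an explicit missing mask.

    Parameters
    ----------
    dosages
        Float array, shape ``(n_individuals, n_loci)``; non-missing entries in
        {0, 1, 2}, missing entries NaN.
    locus_ids
        Unique locus identifiers, one per column (``chrom:pos`` or arbitrary).
    individual_ids
        Unique individual identifiers, one per row.
    site_of
        Mapping individual id -> site id; every individual maps to one site.
    """

    dosages: np.ndarray
    locus_ids: list[str]
    individual_ids: list[str]
    site_of: dict[str, str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.locus_ids = list(self.locus_ids)
        self.individual_ids = list(self.individual_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        n, L = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match columns")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        missing = [i for i in self.individual_ids if i not in self.site_of]
        if missing:
            raise ValueError(f"individuals without a site assignment: {missing[:5]}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the genotype is missing."""
        return np.isnan(self.dosages)

    @property
    def sites(self) -> np.ndarray:
        """Site id per individual, aligned with rows."""
        return np.asarray([self.site_of[i] for i in self.individual_ids])

    def select_loci(self, index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given locus columns."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            locus_ids=[self.locus_ids[j] for j in index],
            individual_ids=list(self.individual_ids),
            site_of=dict(self.site_of),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.locus_ids
        )


@dataclass
class SiteTable:
    """Sampling sites: id, waterway membership and geographic coordinates."""

    table: pd.DataFrame  # columns: site_id, waterway_id, longitude, latitude

    REQUIRED = ("site_id", "waterway_id", "longitude", "latitude")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"site table missing column {col!r}")
        if self.table["site_id"].duplicated().any():
            dupes = self.table.loc[self.table["site_id"].duplicated(), "site_id"]
            raise ValueError(f"duplicated site ids: {list(dupes)[:5]}")
        self.table = self.table.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"])

    def waterway_of(self) -> dict[str, str]:
        return dict(zip(self.table["site_id"], self.table["waterway_id"]))

    def validate_against(self, G: GenotypeMatrix) -> None:
        known = set(self.site_ids)
        used = set(G.site_of.values())
        orphan = used - known
        if orphan:
            raise ValueError(f"sites referenced by genotypes but absent: {sorted(orphan)[:5]}")


@dataclass
class VarMeta:
    """Per-variable metadata: category label, type, standardization parameters."""

    category: str
    type: str  # "continuous" or "binary"
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.type not in ("continuous", "binary"):
            raise ValueError(f"variable type must be continuous|binary, got {self.type!r}")


@dataclass
class EnvTable:
    """Sites x predictor-variables table with per-variable metadata.

    ``values`` is indexed by site_id; ``var_meta`` must cover every column.
    ``scenario_tag`` distinguishes current from future-projection tables.
    Standardization parameters (mean, sd) are recorded in ``var_meta`` when
    :func:`adaptscape.preprocess.standardize` is applied; future scenarios are
    standardized with the *current* scenario's parameters so the adaptive
    index is comparable across scenarios.
    """

    values: pd.DataFrame
    var_meta: dict[str, VarMeta]
    scenario_tag: str = "current"
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated site ids in environment table")
        missing_meta = [c for c in self.values.columns if c not in self.var_meta]
        if missing_meta:
            raise ValueError(f"variables without metadata: {missing_meta}")
        for name, meta in self.var_meta.items():
            if meta.type == "continuous" and self.standardized and meta.sd is not None:
                if not meta.sd > 0:
                    raise ValueError(f"recorded sd must be > 0 for {name!r}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def continuous_variables(self) -> list[str]:
        return [v for v in self.variables if self.var_meta[v].type == "continuous"]

    def binary_variables(self) -> list[str]:
        return [v for v in self.variables if self.var_meta[v].type == "binary"]

    def categories(self) -> dict[str, list[str]]:
        """Group variable names by their category label."""
        out: dict[str, list[str]] = {}
        for v in self.variables:
            out.setdefault(self.var_meta[v].category, []).append(v)
        return out

    def select(self, variables: list[str]) -> "EnvTable":
        unknown = [v for v in variables if v not in self.values.columns]
        if unknown:
            raise ValueError(f"unknown variables: {unknown}")
        return EnvTable(
            values=self.values[variables].copy(),
            var_meta={v: replace(self.var_meta[v]) for v in variables},
            scenario_tag=self.scenario_tag,
            standardized=self.standardized,
        )

    def copy(self) -> "EnvTable":
        return EnvTable(
            values=self.values.copy(),
            var_meta={v: replace(m) for v, m in self.var_meta.items()},
            scenario_tag=self.scenario_tag,
            standardized=self.standardized,
        )

    def per_individual(self, G: GenotypeMatrix) -> pd.DataFrame:
        """Expand site-level rows to one row per individual of ``G``."""
        sites = G.sites
        missing = sorted(set(sites) - set(self.values.index))
        if missing:
            raise ValueError(f"individuals from sites absent in env table: {missing[:5]}")
        return self.values.loc[sites].set_axis(G.individual_ids, axis=0)
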