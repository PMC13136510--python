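"""Readers and writers for genotype, environment and site tables.

Genotypes come in as VCF (biallelic SNPs, GT field; via cyvcf2) or as a plain
dosage TSV (individuals x loci, entries 0/1/2/NA).  Environment and site
tables are CSV.  All readers accept gzip-compressed files.  Writers exist so
every format round-trips losslessly, which the test suite exercises.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import EnvTable, GenotypeMatrix, SiteTable, VarMeta

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_env_table",
    "write_env_table",
    "read_site_table",
    "write_site_table",
    "read_individual_map",
    "write_individual_map",
]


def read_vcf(
    path: str | Path,
    site_of: dict[str, str] | None = None,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a :class:`GenotypeMatrix`.

    Dosage is the count of ALT alleles per diploid GT call; ``./.`` becomes
    missing.  Multiallelic records are skipped with a logged count when
    ``skip_multiallelic`` is true, otherwise they raise.  Locus ids are
    ``ID`` if present, else ``chrom:pos``.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise ValueError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS}"
            )
        lid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        col = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = float(sum(alleles))
        locus_ids.append(lid)
        columns.append(col)
    vcf.close()
    if n_multi:
        log.info("skipped %d multiallelic records in %s", n_multi, path)
    if not columns:
        raise ValueError(f"no usable biallelic records in {path!r}")
    if len(set(locus_ids)) != len(locus_ids):
        seen: set[str] = set()
        dupes = [lid for lid in locus_ids if lid in seen or seen.add(lid)]
        raise ValueError(f"duplicated locus ids in VCF: {dupes[:5]}")
    dosages = np.column_stack(columns)
    if site_of is None:
        site_of = {s: "unassigned" for s in samples}
    return GenotypeMatrix(dosages, locus_ids, samples, site_of)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages back out as a minimal VCF 4.2 file (GT only).

    Dosage 0/1/2 becomes ``0/0``, ``0/1``, ``1/1``; missing becomes ``./.``.
    Locus ids of the form ``chrom:pos`` are split back into CHROM/POS, any
    other id is placed on a synthetic contig with consecutive positions.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        for j, lid in enumerate(G.locus_ids):
            if ":" in lid and lid.rsplit(":", 1)[1].isdigit():
                chrom, pos = lid.rsplit(":", 1)
            else:
                chrom, pos = "ctg1", str(j + 1)
            calls = [
                gt_map.get(G.dosages[i, j], "./.") for i in range(G.n_individuals)
            ]
            fh.write(
                f"{chrom}\t{pos}\t{lid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV: header row of locus ids, first column individual id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError("no individuals in dosage table")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw in ("NA", "", "nan"):
                values[i, j] = np.nan
                continue
            try:
                v = float(raw)
            except ValueError:
                v = -1.0
            if v not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"invalid dosage {raw!r} at row {df.index[i]!r}, column {col!r}"
                )
            values[i, j] = v
    site_of = {s: "unassigned" for s in df.index}
    return GenotypeMatrix(values, list(df.columns), list(df.index), site_of)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = G.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t")


def read_env_table(
    path: str | Path,
    meta_path: str | Path,
    scenario_tag: str = "current",
) -> EnvTable:
    """Read a sites x variables CSV plus a metadata CSV (variable, category, type)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()]
        raise ValueError(f"duplicated site rows: {list(dupes)[:5]}")
    meta_df = pd.read_csv(meta_path)
    for col in ("variable", "category", "type"):
        if col not in meta_df.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    meta: dict[str, VarMeta] = {}
    for _, row in meta_df.iterrows():
        meta[row["variable"]] = VarMeta(
            category=row["category"],
            type=row["type"],
            mean=row["mean"] if "mean" in meta_df.columns and pd.notna(row.get("mean")) else None,
            sd=row["sd"] if "sd" in meta_df.columns and pd.notna(row.get("sd")) else None,
        )
    uncovered = [c for c in df.columns if c not in meta]
    if uncovered:
        raise ValueError(f"variables absent from metadata: {uncovered}")
    meta = {v: m for v, m in meta.items() if v in df.columns}
    return EnvTable(values=df, var_meta=meta, scenario_tag=scenario_tag)


def write_env_table(E: EnvTable, path: str | Path, meta_path: str | Path) -> None:
    out = E.values.copy()
    out.index.name = "site_id"
    out.to_csv(path)
    rows = [
        {
            "variable": v,
            "category": m.category,
            "type": m.type,
            "mean": m.mean,
            "sd": m.sd,
        }
        for v, m in E.var_meta.items()
    ]
    pd.DataFrame(rows).to_csv(meta_path, index=False)


def read_site_table(path: str | Path) -> SiteTable:
    return SiteTable(pd.read_csv(path))


def write_site_table(S: SiteTable, path: str | Path) -> None:
    S.table.to_csv(path, index=False)


def read_individual_map(path: str | Path) -> dict[str, str]:
    """Read the individual -> site assignment CSV (individual_id, site_id)."""
    df = pd.read_csv(path)
    for col in ("individual_id", "site_id"):
        if col not in df.columns:
            raise ValueError(f"individual map missing column {col!r}")
    return dict(zip(df["individual_id"].astype(str), df["site_id"].astype(str)))


def write_individual_map(site_of: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": list(site_of), "site_id": [site_of[k] for k in site_of]}
    ).to_csv(path, index=False)
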