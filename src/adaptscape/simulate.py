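"""Synthetic genotype-environment datasets with the structure the pipeline assumes.

Sites lie on a one-dimensional gradient (coordinate ``g in [0, 1]``) grouped
into contiguous regions, mimicking hierarchically structured waterways.
Neutral allele frequencies drift hierarchically under the Balding-Nichols
model: a locus's ancestral frequency ``p0 ~ U(0.05, 0.95)`` begets region
frequencies ``Beta(p0 (1-F_region)/F_region, (1-p0)(1-F_region)/F_region)``,
which beget site frequencies with intensity ``F_site``.  Adaptive loci add a
logistic-scale shift ``beta * z(site)`` tracking a causal environmental
variable, producing the monotone genotype-environment clines that
association methods assume.  Genotypes are binomial draws of two alleles per
individual; genotype and environment cells go missing completely at random.

Environment variables come in five flavours: linear gradients (with noise),
a variable constructed to a target correlation with a partner (to exercise
|r| > 0.7 pruning), barrier-like step variables, spatially clumped binary
presence variables, and pure noise.  A future scenario shifts configured
variables by a constant in raw units.

All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EnvTable, GenotypeMatrix, SiteTable, VarMeta
from . import io as gio

__all__ = ["SimConfig", "EnvVarSpec", "simulate_env", "simulate_genotypes",
           "make_future_env", "make_scenario", "ScenarioBundle", "default_config"]


@dataclass
class EnvVarSpec:
    """One environment variable: name, generator kind and its parameters."""

    name: str
    kind: str  # gradient | correlated | step | binary | noise
    category: str = "hydroclimatic"
    slope: float = 1.0        # gradient strength (gradient kind)
    noise: float = 0.3        # sd of additive noise (gradient/noise kinds)
    partner: str | None = None    # correlated kind
    r_target: float = 0.9         # correlated kind

    def __post_init__(self) -> None:
        if self.kind not in ("gradient", "correlated", "step", "binary", "noise"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "correlated" and self.partner is None:
            raise ValueError(f"correlated variable {self.name!r} needs a partner")

    @property
    def type(self) -> str:
        return "binary" if self.kind in ("step", "binary") else "continuous"


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic scenario."""

    s_sites: int = 40
    r_regions: int = 4
    n_per_site: int = 20
    l_neutral: int = 980
    l_adaptive: int = 20
    f_region: float = 0.10
    f_site: float = 0.05
    env: list[EnvVarSpec] = dc_field(default_factory=list)
    causal_variable: str = "temperature"
    beta: float = 1.5
    m_geno: float = 0.02
    m_env: float = 0.05
    future_shift: dict[str, float] = dc_field(default_factory=dict)
    future_tag: str = "future"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in (self.f_region, self.f_site):
            if not 0.0 < f < 1.0:
                raise ValueError("drift intensities must lie in (0, 1)")
        for m in (self.m_geno, self.m_env):
            if not 0.0 <= m < 1.0:
                raise ValueError("missing rates must lie in [0, 1)")
        if not self.env:
            self.env = _default_env_spec()
        names = [v.name for v in self.env]
        if len(set(names)) != len(names):
            raise ValueError("duplicate environment variable names")
        if self.causal_variable not in names:
            raise ValueError(f"causal variable {self.causal_variable!r} not in env spec")
        unknown = [v for v in self.future_shift if v not in names]
        if unknown:
            raise ValueError(f"future shift for unknown variables: {unknown}")
        if not self.future_shift:
            self.future_shift = {self.causal_variable: 1.0}

    @property
    def n_loci(self) -> int:
        return self.l_neutral + self.l_adaptive


def _default_env_spec() -> list[EnvVarSpec]:
    return [
        EnvVarSpec("temperature", "gradient", "hydroclimatic", slope=2.0, noise=0.3),
        EnvVarSpec("temp_proxy", "correlated", "hydroclimatic", partner="temperature", r_target=0.9),
        EnvVarSpec("precipitation", "gradient", "hydroclimatic", slope=-1.0, noise=0.6),
        EnvVarSpec("barrier", "step", "fragmentation"),
        EnvVarSpec("non_native", "binary", "species"),
        EnvVarSpec("turbidity", "noise", "land_cover", noise=1.0),
    ]


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The demo scenario: 40 sites x 20 diploids, 1000 loci, 20 adaptive."""
    return SimConfig(seed=seed, **overrides)


def _rngs(cfg: SimConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(cfg.seed)
    keys = ("env", "geno", "missing", "future")
    return {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}


def _site_frame(cfg: SimConfig) -> pd.DataFrame:
    if cfg.s_sites < 3:
        raise ValueError("need at least 3 sites")
    g = np.linspace(0.0, 1.0, cfg.s_sites)
    # Ancestral-lineage membership is hierarchical but not collinear with the
    # environmental gradient (colonization and stocking history scramble
    # lineages along a shoreline), so sites are dealt to regions by a
    # seed-determined permutation rather than contiguous blocks.
    balanced = np.arange(cfg.s_sites) % cfg.r_regions
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E61]))
    region = rng.permutation(balanced)
    return pd.DataFrame(
        {
            "site_id": [f"s{i:03d}" for i in range(cfg.s_sites)],
            "waterway_id": [f"w{r}" for r in region],
            "longitude": -92.0 + 4.0 * g,  # east-west transect
            "latitude": np.full(cfg.s_sites, 47.0),
            "g": g,
            "region": region,
        }
    )


def simulate_env(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[EnvTable, SiteTable]:
    """Generate the current-scenario environment table and the site table."""
    rng = rng if rng is not None else _rngs(cfg)["env"]
    sites = _site_frame(cfg)
    g = sites["g"].to_numpy()
    S = cfg.s_sites
    values: dict[str, np.ndarray] = {}
    for spec in cfg.env:
        if spec.kind == "gradient":
            values[spec.name] = spec.slope * g + rng.normal(0.0, spec.noise, S)
        elif spec.kind == "noise":
            values[spec.name] = rng.normal(0.0, spec.noise, S)
        elif spec.kind == "step":
            cut = rng.integers(S // 4, 3 * S // 4)
            values[spec.name] = (np.arange(S) >= cut).astype(float)
        elif spec.kind == "binary":
            latent = np.convolve(rng.normal(size=S + 6), np.ones(7) / 7.0, mode="valid")
            values[spec.name] = (latent > np.median(latent)).astype(float)
        elif spec.kind == "correlated":
            base = values[spec.partner]
            z = (base - base.mean()) / base.std(ddof=1)
            eps = rng.normal(size=S)
            eps = (eps - eps.mean()) / eps.std(ddof=1)
            # orthogonalize the noise so the realized correlation is tight
            eps -= z * np.dot(eps, z) / np.dot(z, z)
            eps /= eps.std(ddof=1)
            values[spec.name] = spec.r_target * z + np.sqrt(1.0 - spec.r_target**2) * eps
    table = pd.DataFrame(values, index=sites["site_id"].to_numpy())
    table.index.name = "site_id"
    meta = {s.name: VarMeta(category=s.category, type=s.type) for s in cfg.env}
    env = EnvTable(values=table, var_meta=meta, scenario_tag="current")
    if cfg.m_env > 0:
        mask = rng.random(table.shape) < cfg.m_env
        # never blank binary cells or an entire row/column
        for j, spec in enumerate(cfg.env):
            if spec.type == "binary":
                mask[:, j] = False
        for i in range(mask.shape[0]):
            if mask[i].all():
                mask[i, 0] = False
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[0, j] = False
        env.values = env.values.mask(mask)
    site_table = SiteTable(sites[["site_id", "waterway_id", "longitude", "latitude"]].copy())
    return env, site_table


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float, size: int) -> np.ndarray:
    """Draw ``size`` daughter frequencies per entry of ``p`` under drift F."""
    p = np.clip(p, 1e-4, 1.0 - 1e-4)  # Beta draws can underflow to exactly 0/1
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(np.broadcast_to(a, (size,) + p.shape), np.broadcast_to(b, (size,) + p.shape))


def simulate_genotypes(
    cfg: SimConfig, env: EnvTable, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw genotypes under hierarchical drift plus environmental selection.

    Returns the genotype matrix and a truth table marking adaptive loci,
    their causal variable and effect size.
    """
    rngs = _rngs(cfg)
    rng = rng if rng is not None else rngs["geno"]
    rng_miss = rngs["missing"]
    sites = _site_frame(cfg)
    region = sites["region"].to_numpy()
    L, S = cfg.n_loci, cfg.s_sites

    p0 = rng.uniform(0.05, 0.95, L)
    p_region = _balding_nichols(rng, p0, cfg.f_region, cfg.r_regions)  # R x L
    p_site = np.empty((S, L))
    for s in range(S):
        p_site[s] = _balding_nichols(rng, p_region[region[s]], cfg.f_site, 1)[0]

    p_site = np.clip(p_site, 1e-4, 1.0 - 1e-4)  # guard logit against Beta underflow

    adaptive = np.zeros(L, dtype=bool)
    adaptive[rng.choice(L, size=cfg.l_adaptive, replace=False)] = True
    betas = np.zeros(L)
    betas[adaptive] = cfg.beta * rng.choice([-1.0, 1.0], size=cfg.l_adaptive)
    causal = env.values[cfg.causal_variable].to_numpy(dtype=float)
    causal = np.where(np.isnan(causal), np.nanmean(causal), causal)
    z = (causal - causal.mean()) / causal.std(ddof=1)
    logit = np.log(p_site / (1.0 - p_site)) + z[:, None] * betas[None, :]
    p_sel = 1.0 / (1.0 + np.exp(-logit))
    n_clip = int(np.sum((p_sel < 0.001) | (p_sel > 0.999)))
    if n_clip:
        import logging

        logging.getLogger(__name__).info("clipped %d selected site frequencies", n_clip)
    p_sel = np.clip(p_sel, 0.001, 0.999)

    n = cfg.n_per_site * S
    dosages = np.empty((n, L))
    site_ids = sites["site_id"].to_numpy()
    individual_ids = []
    site_of = {}
    for s in range(S):
        rows = slice(s * cfg.n_per_site, (s + 1) * cfg.n_per_site)
        dosages[rows] = rng.binomial(2, p_sel[s], size=(cfg.n_per_site, L)).astype(float)
        for i in range(cfg.n_per_site):
            iid = f"ind{s * cfg.n_per_site + i:05d}"
            individual_ids.append(iid)
            site_of[iid] = site_ids[s]
    if cfg.m_geno > 0:
        mask = rng_miss.random(dosages.shape) < cfg.m_geno
        # keep every locus observed somewhere
        dead = mask.all(axis=0)
        mask[0, dead] = False
        dosages[mask] = np.nan
    locus_ids = [f"chr{1 + j % 8}:{1000 + j}" for j in range(L)]
    G = GenotypeMatrix(dosages, locus_ids, individual_ids, site_of)
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "adaptive": adaptive,
            "causal_variable": np.where(adaptive, cfg.causal_variable, ""),
            "beta": betas,
        }
    )
    return G, truth


def make_future_env(env: EnvTable, cfg: SimConfig, noise_sd: float = 0.0) -> EnvTable:
    """Shift configured variables by their delta (raw units); retag the table."""
    out = env.copy()
    rng = _rngs(cfg)["future"]
    for var, delta in cfg.future_shift.items():
        if var not in out.values.columns:
            raise ValueError(f"future shift names unknown variable {var!r}")
        shift = delta
        if noise_sd > 0:
            shift = delta + rng.normal(0.0, noise_sd, len(out.values))
        out.values[var] = out.values[var] + shift
    out.scenario_tag = cfg.future_tag
    return out


@dataclass
class ScenarioBundle:
    """Everything one synthetic study produces, in memory."""

    genotypes: GenotypeMatrix
    env_current: EnvTable
    env_future: EnvTable
    site_table: SiteTable
    truth: pd.DataFrame
    config: SimConfig


def make_scenario(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    genotype_format: str = "tsv",
) -> ScenarioBundle:
    """Compose environment, genotypes and future scenario; optionally write files.

    When ``out_dir`` is given, writes genotypes (TSV or VCF), current and
    future environment CSVs, the variable metadata CSV, the site table and
    the individual->site map, plus the truth table.  Deterministic under the
    config seed.
    """
    if genotype_format not in ("tsv", "vcf"):
        raise ValueError("genotype_format must be 'tsv' or 'vcf'")
    env, site_table = simulate_env(cfg)
    G, truth = simulate_genotypes(cfg, env)
    future = make_future_env(env, cfg)
    bundle = ScenarioBundle(G, env, future, site_table, truth, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if genotype_format == "tsv":
            gio.write_dosage_tsv(G, out / "genotypes.tsv")
        else:
            gio.write_vcf(G, out / "genotypes.vcf")
        gio.write_env_table(env, out / "env_current.csv", out / "env_meta.csv")
        future_copy = future.copy()
        gio.write_env_table(future_copy, out / "env_future.csv", out / "env_meta_future.csv")
        gio.write_site_table(site_table, out / "sites.csv")
        gio.write_individual_map(G.site_of, out / "individuals.csv")
        truth.to_csv(out / "truth.csv", index=False)
    return bundle
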