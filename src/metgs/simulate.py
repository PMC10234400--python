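"""Synthetic multi-environment trial generator.

Emulates a two-population clonal breeding trial: genotypes carry additive
marker effects (optionally partly population-specific), plots follow a
randomized complete block design nested in location x harvest-year
environments, and genotype-by-environment interaction is the sum of a
low-rank bilinear term (the structure an AMMI analysis estimates) and a
regression-on-environment term (the structure Finlay-Wilkinson regression
estimates). Stability is genetically controlled by default: the FW slope
deviations and the bilinear genotype scores are linear in the marker dosages
(with their own independent marker effects), so stability indices are
themselves predictable from genomic data — the premise the prediction stages
test. The generating values are returned in a :class:`TruthRecord` so every
downstream estimator can be validated against its matched generating process.

Default dimensions mirror a two-location, four-harvest robusta coffee trial:
populations of 103 and 118 clones, 3 blocks, and 56k biallelic SNPs.
Desk-scale analyses override ``n_markers`` and population sizes.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = ["SimulationConfig", "TruthRecord", "simulate_markers", "simulate_phenotypes"]

PHENOTYPE_COLUMNS = ["genotype", "population", "location", "year", "block", "trait", "value"]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic trial.

    ``h2_target`` is the plot-level narrow-sense ratio
    ``var(g) / (var(g) + sigma2_e)`` used to solve the residual variance from
    the realized genetic variance; ``residual_sd`` overrides that solution
    when given (0 yields noiseless plots). ``fw_slope_sd`` is the SD of the
    Finlay-Wilkinson slope deviations b_i; ``gxe_sd`` the per-cell SD of the
    rank-``gxe_rank`` bilinear interaction; ``prop_specific_effects`` the
    fraction of loci whose effects carry population-specific components.
    With ``genetic_stability`` (default) the FW slopes and bilinear genotype
    scores are built from the markers, so stability is heritable; turning it
    off draws them independently of the genome.
    """

    n_genotypes_per_pop: int | tuple[int, ...] = (103, 118)
    n_pops: int = 2
    n_markers: int = 56000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_locations: int = 2
    n_years: int = 4
    n_blocks: int = 3
    h2_target: float = 0.2
    gxe_rank: int = 2
    gxe_sd: float = 0.7
    fw_slope_sd: float = 0.3
    prop_specific_effects: float = 0.5
    effect_prior: str = "normal"
    pi_zero: float = 0.99
    genetic_stability: bool = True
    env_sd: float = 1.0
    block_sd: float = 0.25
    mu: float = 20.0
    missing_rate: float = 0.0
    residual_sd: float | None = None
    trait: str = "YIELD"
    years: tuple[int, ...] | None = None
    locations: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        for name in ("n_markers", "n_locations", "n_years", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lower < upper <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if not 0.0 <= self.pi_zero <= 1.0:
            raise ValueError("pi_zero must lie in [0, 1]")
        if not 0.0 <= self.prop_specific_effects <= 1.0:
            raise ValueError("prop_specific_effects must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.effect_prior not in ("normal", "spike_slab"):
            raise ValueError("effect_prior must be 'normal' or 'spike_slab'")
        if self.gxe_rank < 0:
            raise ValueError("gxe_rank must be >= 0")
        if self.years is not None and len(self.years) != self.n_years:
            raise ValueError("years must list n_years labels")
        if self.locations is not None and len(self.locations) != self.n_locations:
            raise ValueError("locations must list n_locations labels")

    @property
    def pop_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_genotypes_per_pop, int):
            sizes = (self.n_genotypes_per_pop,) * self.n_pops
        else:
            sizes = tuple(self.n_genotypes_per_pop)[: self.n_pops]
            if len(sizes) < self.n_pops:
                sizes = sizes + (sizes[-1],) * (self.n_pops - len(sizes))
        if any(s < 1 for s in sizes):
            raise ValueError("population sizes must be >= 1")
        return sizes

    @property
    def year_labels(self) -> tuple[int, ...]:
        return self.years if self.years is not None else tuple(range(2007, 2007 + self.n_years))

    @property
    def location_labels(self) -> tuple[str, ...]:
        if self.locations is not None:
            return tuple(self.locations)
        if self.n_locations == 2:
            return ("FEM", "FES")
        return tuple(f"L{i + 1}" for i in range(self.n_locations))


@dataclasses.dataclass
class TruthRecord:
    """Generating values kept for recovery tests.

    ``beta_common`` (b0) plus ``beta_specific[p]`` (b_p) compose the
    population effect vectors ``beta_pop[p] = b0 + b_p`` exactly. The bilinear
    interaction is ``gamma @ diag(lam) @ delta.T`` with double-centered,
    column-orthonormal scores.
    """

    mu: float
    beta_common: np.ndarray
    beta_specific: dict[str, np.ndarray]
    beta_pop: dict[str, np.ndarray]
    genetic_values: pd.Series
    env_effects: pd.Series
    fw_slopes: pd.Series
    bilinear_lam: np.ndarray
    bilinear_gamma: pd.DataFrame
    bilinear_delta: pd.DataFrame
    block_effects: pd.Series
    sigma_e: float
    col_means: np.ndarray

    def interaction_matrix(self) -> pd.DataFrame:
        """Bilinear G-by-E cell values (genotypes x environments)."""
        mat = self.bilinear_gamma.to_numpy() @ np.diag(self.bilinear_lam) @ self.bilinear_delta.to_numpy().T
        return pd.DataFrame(mat, index=self.bilinear_gamma.index, columns=self.bilinear_delta.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu,
            "sigma_e": self.sigma_e,
            "beta_common": self.beta_common.tolist(),
            "beta_specific": {k: v.tolist() for k, v in self.beta_specific.items()},
            "genetic_values": self.genetic_values.to_dict(),
            "env_effects": self.env_effects.to_dict(),
            "fw_slopes": self.fw_slopes.to_dict(),
            "bilinear_lam": self.bilinear_lam.tolist(),
            "block_effects": {f"{k[0]}|{k[1]}": v for k, v in self.block_effects.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------- #
def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Draw SNP dosages under Hardy-Weinberg sampling.

    Allele frequencies are drawn once per locus from ``maf_range`` and shared
    across populations (related breeding populations from a common base);
    missing calls are introduced completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_markers)
    sizes = config.pop_sizes
    n_total = sum(sizes)
    dosages = rng.binomial(2, freqs, size=(n_total, config.n_markers)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    genotype_ids: list[str] = []
    populations: list[str] = []
    for p, size in enumerate(sizes, start=1):
        width = max(3, len(str(size)))
        for i in range(size):
            genotype_ids.append(f"pop{p}_g{i + 1:0{width}d}")
            populations.append(f"pop{p}")
    locus_ids = [f"snp{j + 1:05d}" for j in range(config.n_markers)]
    return MarkerMatrix(dosages, genotype_ids, locus_ids, np.array(populations, dtype=object))


def _orthonormalize(raw: np.ndarray) -> np.ndarray:
    """Zero column means + orthonormal columns (QR with deterministic signs)."""
    raw = raw - raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q *= np.sign(np.diag(r))
    # columns of q stay mean-zero: centering is preserved by QR on centered input
    return q


def _orthonormal_centered(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Random n x rank matrix with zero column means and orthonormal columns."""
    if rank > n - 1:
        raise ValueError(f"bilinear rank {rank} needs at least {rank + 1} levels, got {n}")
    return _orthonormalize(rng.standard_normal((n, rank)))


def simulate_phenotypes(
    markers: MarkerMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate plot-level records for every genotype x environment x block.

    The plot model is
    ``Y = mu + g_i + (1 + b_i) h_j + block_k|j + bilinear_ij + e``,
    i.e. additive genetics from the markers, environment main effects,
    blocks nested in environments, FW-type and bilinear interaction, and
    i.i.d. residuals whose variance is solved from the realized genetic
    variance to hit ``h2_target`` (unless ``residual_sd`` overrides it).
    """
    sizes = config.pop_sizes
    if markers.n_genotypes != sum(sizes):
        raise ValueError(
            f"markers carry {markers.n_genotypes} genotypes but config specifies {sum(sizes)}"
        )
    if config.residual_sd is None and config.h2_target == 0.0:
        raise ValueError("h2_target=0 requires an explicit residual_sd (cannot solve residual variance)")
    if config.residual_sd is not None and config.residual_sd == 0.0 and config.h2_target == 0.0:
        raise ValueError("h2_target=0 with zero residual variance is contradictory")

    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    n_total, p = markers.dosages.shape

    # mean-imputed, column-centered dosages define the additive values
    X = markers.dosages.copy()
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    Xc = X - col_means

    pop_levels = markers.pop_levels
    b0 = rng.standard_normal(p)
    if config.effect_prior == "spike_slab":
        b0[rng.random(p) < config.pi_zero] = 0.0
    specific_mask = rng.random(p) < config.prop_specific_effects
    beta_specific = {}
    for lab in pop_levels:
        b_p = np.zeros(p)
        if specific_mask.any():
            b_p[specific_mask] = rng.standard_normal(int(specific_mask.sum()))
            if config.effect_prior == "spike_slab":
                b_p[rng.random(p) < config.pi_zero] = 0.0
        beta_specific[lab] = b_p
    beta_pop = {lab: b0 + beta_specific[lab] for lab in pop_levels}

    pop_arr = np.array([str(q) for q in markers.populations], dtype=object)
    g = np.empty(n_total)
    for lab in pop_levels:
        rows = pop_arr == lab
        g[rows] = Xc[rows] @ beta_pop[lab]
    sd_g = g.std()
    if sd_g > 0:
        scale = 1.0 / sd_g  # genetic SD = 1 trait unit
        g *= scale
        b0 *= scale
        for lab in pop_levels:
            beta_specific[lab] *= scale
        # recompose so beta_pop = b0 + b_p holds exactly after rescaling
        beta_pop = {lab: b0 + beta_specific[lab] for lab in pop_levels}

    env_ids = [f"{loc}:{yr}" for loc in config.location_labels for yr in config.year_labels]
    n_env = len(env_ids)
    h = rng.normal(0.0, config.env_sd, size=n_env)
    h -= h.mean()
    if config.genetic_stability:
        # slope deviations are an independent marker-determined trait
        fw = Xc @ rng.standard_normal(p)
    else:
        fw = rng.normal(size=n_total)
    fw -= fw.mean()
    sd_fw = fw.std()
    fw = fw * (config.fw_slope_sd / sd_fw) if sd_fw > 0 else np.zeros(n_total)

    rank = config.gxe_rank
    if rank > 0:
        if config.genetic_stability:
            gamma = _orthonormalize(Xc @ rng.standard_normal((p, rank)))
        else:
            gamma = _orthonormal_centered(rng, n_total, rank)
        delta = _orthonormal_centered(rng, n_env, rank)
        weights = 0.7 ** np.arange(rank)
        lam2 = weights / weights.sum() * config.gxe_sd**2 * n_total * n_env
        lam = np.sqrt(lam2)
    else:
        gamma = np.zeros((n_total, 0))
        delta = np.zeros((n_env, 0))
        lam = np.zeros(0)
    bilinear = gamma @ np.diag(lam) @ delta.T

    if config.residual_sd is not None:
        sigma_e = float(config.residual_sd)
    elif config.h2_target == 1.0:
        sigma_e = 0.0
    else:
        var_g = float(np.var(g))
        sigma_e = float(np.sqrt(var_g * (1.0 - config.h2_target) / config.h2_target))

    blocks = [f"b{k + 1}" for k in range(config.n_blocks)]
    block_eff = rng.normal(0.0, config.block_sd, size=(n_env, config.n_blocks))

    n_rows = n_total * n_env * config.n_blocks
    noise = rng.normal(0.0, sigma_e, size=n_rows) if sigma_e > 0 else np.zeros(n_rows)

    records: dict[str, list] = {c: [] for c in PHENOTYPE_COLUMNS}
    values = np.empty(n_rows)
    row = 0
    for j, env in enumerate(env_ids):
        loc, yr = env.split(":")
        cell = config.mu + g + h[j] + fw * h[j] + bilinear[:, j]
        for k, blk in enumerate(blocks):
            vals = cell + block_eff[j, k] + noise[row : row + n_total]
            values[row : row + n_total] = vals
            records["genotype"].extend(markers.genotype_ids)
            records["population"].extend(pop_arr.tolist())
            records["location"].extend([loc] * n_total)
            records["year"].extend([int(yr)] * n_total)
            records["block"].extend([blk] * n_total)
            records["trait"].extend([config.trait] * n_total)
            row += n_total
    records["value"] = values.tolist()
    pheno = pd.DataFrame(records)

    block_index = pd.MultiIndex.from_product([env_ids, blocks], names=["environment", "block"])
    truth = TruthRecord(
        mu=config.mu,
        beta_common=b0,
        beta_specific=beta_specific,
        beta_pop=beta_pop,
        genetic_values=pd.Series(g, index=markers.genotype_ids, name="g"),
        env_effects=pd.Series(h, index=env_ids, name="h"),
        fw_slopes=pd.Series(fw, index=markers.genotype_ids, name="b"),
        bilinear_lam=lam,
        bilinear_gamma=pd.DataFrame(gamma, index=markers.genotype_ids),
        bilinear_delta=pd.DataFrame(delta, index=env_ids),
        block_effects=pd.Series(block_eff.ravel(), index=block_index, name="block_effect"),
        sigma_e=sigma_e,
        col_means=col_means,
    )
    return pheno, truth


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    """Write long-format plot records as tab-separated text."""
    pheno.to_csv(path, sep="\t", index=False, float_format="%.10g")


def study_config(**overrides) -> SimulationConfig:
    """The default study conditions, with keyword overrides for desk-scale runs."""
    return dataclasses.replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()
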