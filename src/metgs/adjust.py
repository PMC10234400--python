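"""Fixed-effects adjustment of multi-environment trial plot data.

Provides empirical BLUEs (adjusted genotype means, "lsMEANS") from ordinary
least squares under sum-to-zero identification, for a single harvest year
(genotype + block) or across year x location environments (genotype +
environment + block-within-environment + genotype-by-environment), plus
variance components and entry-mean heritability for the random-effects
counterpart of the same design.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger("metgs.adjust")

__all__ = [
    "AdjustedMeans",
    "VarianceComponents",
    "validate_phenotypes",
    "fit_single_year",
    "fit_multi_year",
    "estimate_h2",
]

REQUIRED_COLUMNS = ("genotype", "location", "year", "block", "trait", "value")


def validate_phenotypes(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format plot table: required columns, finite values,
    no duplicate (genotype, environment, block, trait) keys."""
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            raise ValueError(f"phenotype table is missing required column '{col}'")
    values = pd.to_numeric(data["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        rows = data.index[bad].tolist()[:5]
        raise ValueError(f"non-finite or non-numeric phenotype values at rows {rows}")
    keys = data[["genotype", "location", "year", "block", "trait"]]
    dup = keys.duplicated()
    if dup.any():
        first = keys[dup].iloc[0].to_dict()
        raise ValueError(f"duplicate plot key: {first}")
    out = data.copy()
    out["value"] = values.astype(float)
    if "population" not in out.columns:
        out["population"] = "pop1"
    out["environment"] = out["location"].astype(str) + ":" + out["year"].astype(str)
    return out


@dataclasses.dataclass
class AdjustedMeans:
    """Genotype eBLUEs for one trait under one scenario.

    ``eblues`` is indexed by genotype and reported as mu_hat + G_hat_i
    (marginal over blocks and environments under sum-to-zero coding).
    """

    trait: str
    scenario: str
    eblues: pd.Series
    mu: float
    residual_variance: float
    df_model: int
    df_residual: int
    excluded: list[str] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": self.eblues.index,
                "scenario": self.scenario,
                "trait": self.trait,
                "eblue": self.eblues.to_numpy(),
            }
        )


@dataclasses.dataclass
class VarianceComponents:
    """Plot-model variance components and entry-mean heritability."""

    sigma2_G: float
    sigma2_E: float
    sigma2_GE: float
    sigma2_e: float
    H2: float
    sigma2_block: float = 0.0
    method: str = "anova"
    n_env: int = 0
    n_blocks: int = 0
    n_iter: int = 0
    converged: bool = True
    floored: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------- #
# sum-to-zero design helpers
# ---------------------------------------------------------------------- #
def _sum_code(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero contrast columns for a factor; returns (n, L-1) matrix
    and the level order (last level coded -1 in every column)."""
    levels = sorted(pd.unique(labels))
    n_lev = len(levels)
    idx = pd.Categorical(labels, categories=levels).codes
    cols = np.zeros((len(labels), max(n_lev - 1, 0)))
    for j in range(n_lev - 1):
        cols[idx == j, j] = 1.0
        cols[idx == n_lev - 1, j] = -1.0
    return cols, [str(lv) for lv in levels]


def _effects_from_sum_code(coefs: np.ndarray) -> np.ndarray:
    """Full effect vector (length L) from L-1 sum-coded coefficients."""
    return np.concatenate([coefs, [-coefs.sum()]]) if coefs.size else np.zeros(1)


def _subset(data: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = data[data["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait '{trait}'")
    return sub


def _check_connected(sub: pd.DataFrame) -> None:
    """Genotype-environment incidence must form one connected component."""
    genos = sorted(sub["genotype"].unique())
    envs = sorted(sub["environment"].unique())
    parent: dict[str, str] = {f"g:{g}": f"g:{g}" for g in genos}
    parent.update({f"e:{e}": f"e:{e}" for e in envs})

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g, e in sub[["genotype", "environment"]].drop_duplicates().itertuples(index=False):
        rg, re = find(f"g:{g}"), find(f"e:{e}")
        if rg != re:
            parent[rg] = re
    roots = {find(f"g:{g}") for g in genos}
    if len(roots) > 1:
        by_root: dict[str, list[str]] = {}
        for g in genos:
            by_root.setdefault(find(f"g:{g}"), []).append(str(g))
        smallest = min(by_root.values(), key=len)
        raise ValueError(
            f"disconnected trial design: genotypes {smallest[:10]} share no "
            "environment with the rest of the data"
        )


# ---------------------------------------------------------------------- #
def fit_single_year(
    data: pd.DataFrame,
    trait: str,
    year: int | str,
    location: str | None = None,
    scenario: str = "I",
) -> AdjustedMeans:
    """OLS eBLUEs for one environment: Y = mu + G_i + B_k + e."""
    data = validate_phenotypes(data)
    sub = _subset(data, trait)
    sub = sub[sub["year"].astype(str) == str(year)]
    if location is not None:
        sub = sub[sub["location"] == location]
    if sub.empty:
        raise ValueError(f"no records for trait '{trait}' in year {year}")
    if sub["environment"].nunique() > 1:
        raise ValueError(
            "fit_single_year expects one environment; pass `location` to select one"
        )
    all_genos = sorted(data.loc[data["trait"] == trait, "genotype"].unique())
    present = set(sub["genotype"])
    excluded = [g for g in all_genos if g not in present]
    if excluded:
        logger.info("fit_single_year(%s, %s): %d genotypes absent, excluded", trait, year, len(excluded))
    if sub["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")

    y = sub["value"].to_numpy()
    Xg, geno_levels = _sum_code(sub["genotype"])
    Xb, _ = _sum_code(sub["block"])
    X = np.column_stack([np.ones(len(sub)), Xg, Xb])
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    mu = coefs[0]
    g_eff = _effects_from_sum_code(coefs[1 : Xg.shape[1] + 1])
    resid = y - X @ coefs
    df_resid = max(len(y) - rank, 0)
    s2 = float(resid @ resid / df_resid) if df_resid > 0 else 0.0
    eblues = pd.Series(mu + g_eff, index=geno_levels, name="eblue")
    return AdjustedMeans(trait, scenario, eblues, float(mu), s2, int(rank), int(df_resid), excluded)


def fit_multi_year(
    data: pd.DataFrame,
    trait: str,
    years: Iterable[int | str],
    location: str | None = None,
    scenario: str = "custom",
) -> AdjustedMeans:
    """OLS eBLUEs across environments:
    Y = mu + G_i + E_j + B_k|E_j + GE_ij + e.

    Genotype eBLUEs are the main-effect estimates (G-by-E absorbed into the
    interaction term); with balanced complete data they equal the genotype
    raw means. Missing plots are handled by least squares on observed cells
    (minimum-norm / generalized-inverse solution when rank-deficient).
    """
    data = validate_phenotypes(data)
    years = {str(y) for y in years}
    sub = _subset(data, trait)
    sub = sub[sub["year"].astype(str).isin(years)]
    if location is not None:
        sub = sub[sub["location"] == location]
    if sub.empty:
        raise ValueError(f"no records for trait '{trait}' in years {sorted(years)}")
    if sub["environment"].nunique() < 2:
        raise ValueError("fit_multi_year requires >= 2 environments; use fit_single_year")
    _check_connected(sub)
    all_genos = sorted(data.loc[data["trait"] == trait, "genotype"].unique())
    present = set(sub["genotype"])
    excluded = [g for g in all_genos if g not in present]
    if excluded:
        logger.info("fit_multi_year(%s): %d genotypes absent, excluded", trait, len(excluded))

    y = sub["value"].to_numpy()
    n = len(y)
    Xg, geno_levels = _sum_code(sub["genotype"])
    Xe, _ = _sum_code(sub["environment"])
    # blocks nested in environment: sum-coded block columns per environment
    blk_cols = []
    for env in sorted(sub["environment"].unique()):
        rows = (sub["environment"] == env).to_numpy()
        codes, _ = _sum_code(sub.loc[rows, "block"])
        full = np.zeros((n, codes.shape[1]))
        full[rows] = codes
        blk_cols.append(full)
    Xb = np.column_stack(blk_cols) if blk_cols else np.zeros((n, 0))
    # genotype x environment interaction (sum coding x sum coding)
    Xge = (Xg[:, :, None] * Xe[:, None, :]).reshape(n, -1)
    X = np.column_stack([np.ones(n), Xg, Xe, Xb, Xge])
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    mu = coefs[0]
    g_eff = _effects_from_sum_code(coefs[1 : Xg.shape[1] + 1])
    resid = y - X @ coefs
    df_resid = max(n - rank, 0)
    s2 = float(resid @ resid / df_resid) if df_resid > 0 else 0.0
    eblues = pd.Series(mu + g_eff, index=geno_levels, name="eblue")
    return AdjustedMeans(trait, scenario, eblues, float(mu), s2, int(rank), int(df_resid), excluded)


# ---------------------------------------------------------------------- #
# variance components
# ---------------------------------------------------------------------- #
def _is_balanced(sub: pd.DataFrame) -> bool:
    counts = sub.groupby(["genotype", "environment", "block"], observed=True).size()
    g = sub["genotype"].nunique()
    e = sub["environment"].nunique()
    b = sub.groupby("environment", observed=True)["block"].nunique()
    if b.nunique() != 1:
        return False
    return len(counts) == g * e * int(b.iloc[0]) and (counts == 1).all()


def _anova_components(sub: pd.DataFrame) -> tuple[dict, int, int]:
    """Expected-mean-squares solution for the balanced complete design
    (equals REML inside the parameter space for balanced data)."""
    g = sub["genotype"].nunique()
    e = sub["environment"].nunique()
    b = int(sub.groupby("environment", observed=True)["block"].nunique().iloc[0])
    y = sub["value"]
    grand = y.mean()
    tot_ss = ((y - grand) ** 2).sum()
    gm = sub.groupby("genotype", observed=True)["value"].mean()
    em = sub.groupby("environment", observed=True)["value"].mean()
    bm = sub.groupby(["environment", "block"], observed=True)["value"].mean()
    cm = sub.groupby(["genotype", "environment"], observed=True)["value"].mean()
    ss_g = e * b * ((gm - grand) ** 2).sum()
    ss_e = g * b * ((em - grand) ** 2).sum()
    ss_b = g * ((bm - bm.groupby("environment", observed=True).transform("mean")) ** 2).sum()
    ss_ge = b * (
        (cm - gm.reindex(cm.index.get_level_values(0)).to_numpy()
         - em.reindex(cm.index.get_level_values(1)).to_numpy() + grand) ** 2
    ).sum()
    ss_err = tot_ss - ss_g - ss_e - ss_b - ss_ge
    df_g, df_e_env, df_b = g - 1, e - 1, e * (b - 1)
    df_ge = (g - 1) * (e - 1)
    df_err = e * (g - 1) * (b - 1)
    ms = {
        "G": ss_g / df_g,
        "E": ss_e / df_e_env if df_e_env else 0.0,
        "B": ss_b / df_b if df_b else 0.0,
        "GE": ss_ge / df_ge,
        "err": ss_err / df_err if df_err else 0.0,
    }
    comp = {
        "sigma2_e": ms["err"],
        "sigma2_GE": (ms["GE"] - ms["err"]) / b,
        "sigma2_G": (ms["G"] - ms["GE"]) / (e * b),
        "sigma2_block": (ms["B"] - ms["err"]) / g if df_b else 0.0,
    }
    comp["sigma2_E"] = (
        (ms["E"] - b * comp["sigma2_GE"] - g * comp["sigma2_block"] - comp["sigma2_e"]) / (g * b)
        if df_e_env
        else 0.0
    )
    return comp, e, b


def _em_reml(
    y: np.ndarray,
    z_blocks: Sequence[np.ndarray],
    names: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[np.ndarray, float, int, bool, list[float], list[str]]:
    """EM-REML for y = 1*mu + sum_i Z_i u_i + e with u_i ~ N(0, s2_i I).

    Returns (s2 per random term, s2_e, n_iter, converged, reml loglik trace,
    floored terms). Dense mixed-model-equations implementation intended for
    modest problem sizes.
    """
    n = len(y)
    X = np.ones((n, 1))
    Z = np.column_stack(z_blocks)
    q_sizes = [zb.shape[1] for zb in z_blocks]
    q = sum(q_sizes)
    W = np.column_stack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    offsets = np.cumsum([1] + q_sizes)  # column offsets of each u_i inside [b; u]

    s2 = np.full(len(z_blocks), np.var(y) / (len(z_blocks) + 1) + 1e-8)
    s2e = np.var(y) / (len(z_blocks) + 1) + 1e-8
    floor = 1e-12
    loglik_trace: list[float] = []
    floored: set[str] = set()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = WtW.copy()
        for i, zb in enumerate(z_blocks):
            sl = slice(offsets[i], offsets[i] + q_sizes[i])
            A[sl, sl] += np.eye(q_sizes[i]) * (s2e / s2[i])
        c, low = cho_factor(A, lower=True)
        sol = cho_solve((c, low), Wty)
        Ainv = cho_solve((c, low), np.eye(A.shape[0]))
        # REML log-likelihood (up to constant):
        # -2l = (n - q - p) log s2e + sum_i q_i log s2_i + log|A| + y'Py, with
        # log|A| from the Cholesky factor, p = 1 fixed effect, and
        # y'Py = (y'y - sol'W'y)/s2e.
        logdetA = 2.0 * np.log(np.diag(c)).sum()
        ypy = (yty - float(sol @ Wty)) / s2e
        loglik = -0.5 * ((n - q - 1) * np.log(s2e) + sum(
            qs * np.log(si) for qs, si in zip(q_sizes, s2)
        ) + logdetA + ypy)
        loglik_trace.append(loglik)

        s2_new = np.empty_like(s2)
        for i in range(len(z_blocks)):
            sl = slice(offsets[i], offsets[i] + q_sizes[i])
            u_i = sol[sl]
            tr = np.trace(Ainv[sl, sl])
            s2_new[i] = (float(u_i @ u_i) + s2e * tr) / q_sizes[i]
        s2e_new = (yty - float(sol @ Wty)) / (n - X.shape[1])
        for i, nm in enumerate(names):
            if s2_new[i] < floor:
                s2_new[i] = floor
                floored.add(nm)
        s2e_new = max(s2e_new, floor)
        # change relative to the total variance: a component decaying
        # geometrically to its zero boundary must not stall convergence
        total = s2e_new + float(s2_new.sum())
        rel = max(
            float(np.max(np.abs(s2_new - s2))), abs(s2e_new - s2e)
        ) / max(total, 1e-10)
        s2, s2e = s2_new, s2e_new
        if rel < tol:
            converged = True
            break
    return s2, s2e, it, converged, loglik_trace, sorted(floored)


def estimate_h2(
    data: pd.DataFrame,
    trait: str,
    location: str | None = None,
    method: str = "auto",
    tol: float = 1e-8,
    max_iter: int = 5000,
    return_trace: bool = False,
):
    """Variance components and entry-mean heritability
    H2 = s2_G / (s2_G + s2_GE/n_env + s2_e/(n_env*n_blocks)).

    Random terms: genotype, environment, block-within-environment, G-by-E;
    balanced complete designs use the exact closed-form (ANOVA/EMS) solution,
    which coincides with REML at balance; unbalanced data are fit by EM-REML
    on the mixed-model equations. Negative solutions are floored at zero and
    flagged in ``floored``.
    """
    data = validate_phenotypes(data)
    sub = _subset(data, trait)
    if location is not None:
        sub = sub[sub["location"] == location]
    if sub["environment"].nunique() < 2:
        raise ValueError("estimate_h2 requires >= 2 environments")
    if sub.groupby("environment", observed=True)["block"].nunique().min() < 2:
        raise ValueError("estimate_h2 requires >= 2 blocks per environment")
    n_env = sub["environment"].nunique()
    n_blk = int(round(sub.groupby("environment", observed=True)["block"].nunique().mean()))

    balanced = _is_balanced(sub)
    if method == "anova" or (method == "auto" and balanced):
        comp, n_env, n_blk = _anova_components(sub)
        floored = [k for k, v in comp.items() if v < 0]
        comp = {k: max(v, 0.0) for k, v in comp.items()}
        vc = VarianceComponents(
            sigma2_G=comp["sigma2_G"],
            sigma2_E=comp["sigma2_E"],
            sigma2_GE=comp["sigma2_GE"],
            sigma2_e=comp["sigma2_e"],
            sigma2_block=comp["sigma2_block"],
            H2=0.0,
            method="anova",
            n_env=n_env,
            n_blocks=n_blk,
            floored=floored,
        )
        trace: list[float] = []
    else:
        y = sub["value"].to_numpy()
        zg, _ = _one_hot(sub["genotype"])
        ze, _ = _one_hot(sub["environment"])
        zb, _ = _one_hot(sub["environment"].astype(str) + "|" + sub["block"].astype(str))
        zge, _ = _one_hot(sub["genotype"].astype(str) + "|" + sub["environment"].astype(str))
        s2, s2e, it, conv, trace, floored = _em_reml(
            y, [zg, ze, zb, zge], ["G", "E", "B", "GE"], tol=tol, max_iter=max_iter
        )
        vc = VarianceComponents(
            sigma2_G=float(s2[0]),
            sigma2_E=float(s2[1]),
            sigma2_block=float(s2[2]),
            sigma2_GE=float(s2[3]),
            sigma2_e=float(s2e),
            H2=0.0,
            method="em_reml",
            n_env=n_env,
            n_blocks=n_blk,
            n_iter=it,
            converged=conv,
            floored=floored,
        )
    denom = vc.sigma2_G + vc.sigma2_GE / n_env + vc.sigma2_e / (n_env * n_blk)
    vc.H2 = float(vc.sigma2_G / denom) if denom > 0 else 0.0
    vc.H2 = min(max(vc.H2, 0.0), 1.0)
    if return_trace:
        return vc, trace
    return vc


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(labels))
    idx = pd.Categorical(labels, categories=levels).codes
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z, [str(lv) for lv in levels]
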