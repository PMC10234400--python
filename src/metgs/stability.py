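"""Environmental-stability indices from a genotype x environment table.

Two complementary lenses on genotype-by-environment interaction:

* AMMI — additive main effects plus an SVD of the double-centered
  interaction residual; per-genotype indices are SPC (summed absolute
  weighted PC scores) and ASV (weighted Euclidean length of the first two
  interaction PC scores; lower = more stable).
* Finlay-Wilkinson — two-step regression of each genotype's adjusted means
  on the environment effects; the stability index is the deviation of the
  fitted slope from 1 (|b| near 0 = stable).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("metgs.stability")

__all__ = [
    "TwoWayTable",
    "AMMIResult",
    "FWResult",
    "prepare_two_way",
    "ammi_decompose",
    "select_n_components",
    "ammi_stability",
    "fw_fit",
    "stability_table",
]


@dataclasses.dataclass
class TwoWayTable:
    """Complete genotype x environment matrix of adjusted means."""

    values: np.ndarray
    genotype_ids: list[str]
    env_ids: list[str]
    n_reps: int = 1
    error_ms: float | None = None  # pooled plot-error mean square (per plot)
    error_df: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids), len(self.env_ids)):
            raise ValueError("values shape must match genotype and environment ids")
        if np.isnan(self.values).any():
            raise ValueError("two-way table must be complete; use prepare_two_way")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_envs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.env_ids)


def prepare_two_way(
    means_by_env: Mapping[str, "object"] | pd.DataFrame,
    policy: str = "drop",
    em_rank: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
    min_dims: tuple[int, int] = (3, 3),
    n_reps: int = 1,
    error_ms: float | None = None,
    error_df: int | None = None,
) -> tuple[TwoWayTable, dict]:
    """Assemble a complete genotype x environment table of adjusted means.

    ``means_by_env`` maps environment id -> AdjustedMeans (or a genotype-
    indexed Series), or is a long DataFrame with columns
    (genotype, environment, value). Incomplete genotypes are either dropped
    (``policy='drop'``) or EM-imputed (``policy='em'``): missing cells are
    iteratively filled with the additive prediction mu + g + e plus, when
    ``em_rank`` > 0, the leading ``em_rank`` SVD components of the residual.

    Returns the table plus a report of dropped genotypes / imputed cells.
    """
    if isinstance(means_by_env, pd.DataFrame):
        wide = means_by_env.pivot(index="genotype", columns="environment", values="value")
    else:
        series = {}
        for env, m in means_by_env.items():
            series[env] = m.eblues if hasattr(m, "eblues") else pd.Series(m)
        wide = pd.DataFrame(series)
    wide = wide.sort_index()
    report: dict = {"dropped_genotypes": [], "imputed_cells": []}
    mat = wide.to_numpy(dtype=float)
    miss = np.isnan(mat)
    if miss.any():
        if policy == "drop":
            keep = ~miss.any(axis=1)
            for g, row in zip(wide.index[~keep], miss[~keep]):
                envs = [wide.columns[j] for j in np.flatnonzero(row)]
                report["dropped_genotypes"].append(str(g))
                logger.info("prepare_two_way: dropped %s (missing in %s)", g, envs)
            wide = wide.loc[keep]
            mat = wide.to_numpy(dtype=float)
        elif policy == "em":
            report["imputed_cells"] = [
                (str(wide.index[i]), str(wide.columns[j])) for i, j in zip(*np.nonzero(miss))
            ]
            obs = ~miss
            fill = np.nanmean(mat)
            work = np.where(miss, fill, mat)
            for _ in range(max_iter):
                mu = work.mean()
                g = work.mean(axis=1) - mu
                e = work.mean(axis=0) - mu
                pred = mu + g[:, None] + e[None, :]
                if em_rank > 0:
                    resid = work - pred
                    u, s, vt = np.linalg.svd(resid, full_matrices=False)
                    pred = pred + (u[:, :em_rank] * s[:em_rank]) @ vt[:em_rank]
                new = np.where(obs, mat, pred)
                if np.max(np.abs(new - work)) < tol:
                    work = new
                    break
                work = new
            mat = work
        else:
            raise ValueError(f"unknown completion policy '{policy}'")
    if mat.shape[0] < min_dims[0] or mat.shape[1] < min_dims[1]:
        raise ValueError(
            f"two-way table is {mat.shape[0]}x{mat.shape[1]} after completion; "
            f"AMMI requires at least {min_dims[0]} genotypes and {min_dims[1]} environments"
        )
    table = TwoWayTable(
        mat,
        [str(g) for g in wide.index],
        [str(c) for c in wide.columns],
        n_reps=n_reps,
        error_ms=error_ms,
        error_df=error_df,
    )
    return table, report


# ---------------------------------------------------------------------- #
@dataclasses.dataclass
class AMMIResult:
    """AMMI decomposition: Y_ij = mu + g_i + e_j + sum_n lam_n gamma_in delta_jn."""

    mu: float
    g: pd.Series
    e: pd.Series
    lam: np.ndarray
    gamma: pd.DataFrame  # genotype scores (columns = components)
    delta: pd.DataFrame  # environment scores
    var_fraction: np.ndarray
    interaction_ss: float
    n_reps: int = 1
    error_ms: float | None = None
    error_df: int | None = None

    @property
    def n_components(self) -> int:
        return len(self.lam)

    def genotype_scores(self) -> pd.DataFrame:
        """IPCA scores lam^0.5 * gamma (one column per component)."""
        return self.gamma * np.sqrt(self.lam)

    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        k = self.n_components if n_components is None else n_components
        mat = (
            self.mu
            + self.g.to_numpy()[:, None]
            + self.e.to_numpy()[None, :]
            + self.gamma.to_numpy()[:, :k] @ np.diag(self.lam[:k]) @ self.delta.to_numpy()[:, :k].T
        )
        return pd.DataFrame(mat, index=self.g.index, columns=self.e.index)


def ammi_decompose(table: TwoWayTable) -> AMMIResult:
    """Fit the AMMI model by double-centering and SVD.

    Sign convention: each genotype-score column's largest-magnitude element
    is made positive (environment scores follow), so output is deterministic
    across linear-algebra backends. A constant table yields all singular
    values 0 with zero scores (documented convention, no exception).
    """
    if table.n_genotypes < 3 or table.n_envs < 3:
        raise ValueError("AMMI requires at least a 3x3 table")
    Y = table.values
    mu = Y.mean()
    g = Y.mean(axis=1) - mu
    e = Y.mean(axis=0) - mu
    Z = Y - mu - g[:, None] - e[None, :]
    k = min(table.n_genotypes - 1, table.n_envs - 1)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    scale = max(np.abs(Y).max(), 1.0)
    for n in range(k):
        if s[n] <= 1e-12 * scale:
            s[n] = 0.0
            u[:, n] = 0.0
            vt[n] = 0.0
        else:
            imax = np.argmax(np.abs(u[:, n]))
            if u[imax, n] < 0:
                u[:, n] *= -1
                vt[n] *= -1
    ss = float((Z**2).sum())
    var_frac = (s**2) / ss if ss > 0 else np.zeros(k)
    return AMMIResult(
        mu=float(mu),
        g=pd.Series(g, index=table.genotype_ids, name="g"),
        e=pd.Series(e, index=table.env_ids, name="e"),
        lam=s,
        gamma=pd.DataFrame(u, index=table.genotype_ids),
        delta=pd.DataFrame(vt.T, index=table.env_ids),
        var_fraction=var_frac,
        interaction_ss=ss,
        n_reps=table.n_reps,
        error_ms=table.error_ms,
        error_df=table.error_df,
    )


def select_n_components(
    result: AMMIResult,
    alpha: float = 0.05,
    error_ms: float | None = None,
    error_df: int | None = None,
    cap: int | None = 2,
    method: str = "fr",
) -> int:
    """Number of interaction components retained by F-testing.

    ``method='fr'`` (default) uses the sequential residual F-test: after
    fitting N components the leftover interaction SS is compared against the
    plot-error mean square; N grows while the leftover is significant. This
    test holds its size under a pure-noise interaction. ``method='gollob'``
    tests each component's mean square lam_n^2 / (g + e - 1 - 2n) directly
    (classical, but liberal for leading components). ``error_ms`` is the
    plot-level residual mean square and is divided by the table's replicate
    count; when omitted, values attached to the decomposition are used, or
    (for Gollob) the pooled trailing components serve as the denominator.
    The result is capped (default 2 components) to keep SPC/ASV comparable
    across traits; components with non-positive degrees of freedom are
    untestable and excluded.
    """
    gsz, esz = len(result.g), len(result.e)
    lam2 = result.lam**2
    k = len(lam2)
    if error_ms is None:
        error_ms, error_df = result.error_ms, result.error_df
    cell_ms = error_ms / max(result.n_reps, 1) if error_ms is not None else None

    df_n = np.array([gsz + esz - 1 - 2 * (n + 1) for n in range(k)], dtype=float)
    testable = df_n > 0
    n_sel = 0
    if method == "fr":
        if cell_ms is None or error_df is None:
            raise ValueError("method 'fr' requires error_ms and error_df")
        total_df = (gsz - 1) * (esz - 1)
        for n in range(0, k):
            ss_left = lam2[n:].sum()
            df_left = total_df - df_n[:n].sum()
            if df_left <= 0 or ss_left <= 0:
                break
            f = (ss_left / df_left) / cell_ms
            pval = stats.f.sf(f, df_left, error_df)
            if pval < alpha:
                if not testable[n]:
                    break
                n_sel = n + 1
            else:
                break
    elif method == "gollob":
        for n in range(k):
            if not testable[n]:
                break
            ms_n = lam2[n] / df_n[n]
            if cell_ms is not None and error_df is not None:
                f = ms_n / cell_ms
                pval = stats.f.sf(f, df_n[n], error_df)
            else:
                ss_rest = lam2[n + 1 :].sum()
                df_rest = df_n[n + 1 :][testable[n + 1 :]].sum()
                if df_rest <= 0 or ss_rest <= 0:
                    break
                f = ms_n / (ss_rest / df_rest)
                pval = stats.f.sf(f, df_n[n], df_rest)
            if pval < alpha:
                n_sel = n + 1
            else:
                break
    else:
        raise ValueError(f"unknown method '{method}'")
    if cap is not None:
        n_sel = min(n_sel, cap)
    return int(n_sel)


def ammi_stability(result: AMMIResult, n_components: int = 2) -> pd.DataFrame:
    """Per-genotype SPC and ASV.

    SPC_i = sum_{n<=N} |lam_n^0.5 gamma_in| — absolute values keep the index
    sign-free so lower always means more stable. ASV uses the first two IPCA
    scores s_in = lam_n^0.5 gamma_in weighted by the component SS ratio:
    ASV_i = sqrt((SS1/SS2 * s_i1)^2 + s_i2^2). When the second component is
    null the ASV degenerates to |s_i1| and the ``asv_degenerate`` flag is set.
    """
    if n_components < 1:
        raise ValueError("SPC requires at least 1 retained component")
    scores = result.genotype_scores().to_numpy()
    n_avail = scores.shape[1]
    N = min(n_components, n_avail)
    spc = np.abs(scores[:, :N]).sum(axis=1)
    degenerate = False
    if n_avail >= 2 and result.lam[1] > 0:
        weight = (result.lam[0] ** 2) / (result.lam[1] ** 2)
        asv = np.sqrt((weight * scores[:, 0]) ** 2 + scores[:, 1] ** 2)
    else:
        degenerate = True
        logger.warning("second AMMI component is null; ASV degenerates to |IPCA1 score|")
        asv = np.abs(scores[:, 0]) if n_avail >= 1 else np.zeros(len(result.g))
    out = pd.DataFrame(
        {"SPC": spc, "ASV": asv}, index=result.g.index
    )
    out.attrs["asv_degenerate"] = degenerate
    out.attrs["n_components"] = N
    return out


# ---------------------------------------------------------------------- #
@dataclasses.dataclass
class FWResult:
    """Finlay-Wilkinson two-step regression estimates."""

    intercepts: pd.Series       # per-genotype mean level g_i
    slope_dev: pd.Series        # b_i = fitted slope - 1
    env_effects: pd.Series      # h_j (mean 0)
    residual_var: pd.Series     # per-genotype residual variance (df = E - 2)
    non_responsive: pd.Series   # flat response flag (fitted slope ~ 0)

    @property
    def abs_slope_dev(self) -> pd.Series:
        return self.slope_dev.abs().rename("fw_abs_slope")


def fw_fit(table: TwoWayTable, flat_tol: float = 1e-8) -> FWResult:
    """Two-step Finlay-Wilkinson regression on a complete table.

    Step 1 estimates environment effects h_j as environment means minus the
    grand mean; step 2 regresses each genotype's row on h_j by OLS. The
    reported coefficient is the slope deviation b_i = slope - 1; on a
    complete table the genotype-mean of b_i is exactly 0 because the average
    row regression reproduces the environment means. Genotypes with a near-
    zero fitted slope (constant response) are flagged non-responsive.
    """
    if table.n_envs < 2:
        raise ValueError("Finlay-Wilkinson regression requires >= 2 environments")
    Y = table.values
    mu = Y.mean()
    h = Y.mean(axis=0) - mu
    ssh = float(h @ h)
    if ssh <= 0 or np.unique(np.round(h, 12)).size < 2:
        raise ValueError("environment effects have zero variance; FW slopes inestimable")
    row_means = Y.mean(axis=1)
    slopes = (Y - row_means[:, None]) @ h / ssh
    resid = Y - row_means[:, None] - np.outer(slopes, h)
    df = table.n_envs - 2
    rvar = (resid**2).sum(axis=1) / df if df > 0 else np.zeros(len(slopes))
    idx = table.genotype_ids
    return FWResult(
        intercepts=pd.Series(row_means, index=idx, name="fw_intercept"),
        slope_dev=pd.Series(slopes - 1.0, index=idx, name="fw_slope_dev"),
        env_effects=pd.Series(h, index=table.env_ids, name="h"),
        residual_var=pd.Series(rvar, index=idx, name="fw_resid_var"),
        non_responsive=pd.Series(np.abs(slopes) < flat_tol, index=idx, name="non_responsive"),
    )


def stability_table(
    ammi: pd.DataFrame, fw: FWResult, trait: str = "trait"
) -> pd.DataFrame:
    """Combined per-genotype stability report with ranks (1 = most stable)."""
    out = pd.DataFrame(
        {
            "trait": trait,
            "SPC": ammi["SPC"],
            "ASV": ammi["ASV"],
            "fw_slope_dev": fw.slope_dev,
            "fw_abs_slope": fw.abs_slope_dev,
        }
    )
    out["rank_ASV"] = out["ASV"].rank(method="first").astype(int)
    out["rank_FW"] = out["fw_abs_slope"].rank(method="first").astype(int)
    out.index.name = "genotype"
    return out
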