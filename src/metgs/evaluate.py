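"""Validation designs: year-increment forecasting, k-fold cross-validation
of traits and stability indices, performance-stability correlation, and
performance x stability co-selection.

Predictive ability is always the Pearson correlation between observed
adjusted means (eBLUEs, or stability indices) and predicted GEBVs in the
held-out data.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import adjust
from .markers import MarkerMatrix
from .predict import GenomicModelConfig, fit_genomic, predict_gebv

logger = logging.getLogger("metgs.evaluate")

__all__ = [
    "ScenarioSpec",
    "default_scenarios",
    "PredictionReport",
    "SelectionOverlap",
    "run_year_increment",
    "run_cv",
    "correlate_performance_stability",
    "select_overlap",
]


# Breeder-declared selection direction per trait: 'higher' for yield, vigor
# and post-harvest weights/sieve fractions; 'lower' for disease severity and
# maturation/uniformity scores where small values are favorable.
DEFAULT_TRAIT_DIRECTIONS: dict[str, str] = {
    "YIELD": "higher",
    "VIGOR": "higher",
    "GSCE": "higher",
    "GSIZ": "higher",
    "CHERRY_g": "higher",
    "GREEN_g": "higher",
    "M10": "higher",
    "M11": "higher",
    "M12": "higher",
    "M13": "higher",
    "M15": "higher",
    "M17": "higher",
    "RES": "lower",
    "CHE:GREE": "lower",
    "FL": "lower",
    "UNIF": "lower",
    "PRT": "lower",
    "RUST": "lower",
    "LMINER": "lower",
    "CERC": "lower",
}


@dataclasses.dataclass
class ScenarioSpec:
    """Training/validation year composition for forecast scenarios."""

    label: str
    train_years: tuple[int, ...]
    validation_years: tuple[int, ...] = (2014, 2015)
    location: str | None = None

    def __post_init__(self) -> None:
        if not self.train_years:
            raise ValueError(f"scenario {self.label}: empty training years")
        overlap = set(self.train_years) & set(self.validation_years)
        if overlap:
            raise ValueError(f"scenario {self.label}: years {sorted(overlap)} in both sets")


def default_scenarios(location: str = "FEM") -> list[ScenarioSpec]:
    """Scenarios I-VI: cumulative 2007..2012 harvests predicting 2014-2015."""
    labels = ["I", "II", "III", "IV", "V", "VI"]
    return [
        ScenarioSpec(lab, tuple(range(2007, 2008 + i)), (2014, 2015), location)
        for i, lab in enumerate(labels)
    ]


@dataclasses.dataclass
class PredictionReport:
    """Per-scenario/fold predictive abilities plus bookkeeping for replay."""

    results: pd.DataFrame
    n_fits: int = 0
    fold_assignments: dict = dataclasses.field(default_factory=dict)
    seeds: list[int] = dataclasses.field(default_factory=list)

    def summary(self, by: Sequence[str] = ("population",)) -> pd.DataFrame:
        return (
            self.results.groupby(list(by), observed=True)["predictive_ability"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


# ---------------------------------------------------------------------- #
def run_year_increment(
    data: pd.DataFrame,
    markers: MarkerMatrix,
    scenarios: Sequence[ScenarioSpec],
    config: GenomicModelConfig,
    trait: str = "YIELD",
) -> PredictionReport:
    """Train marker effects on each scenario's training-year eBLUEs and
    correlate predicted GEBVs with validation-year eBLUEs (per population)."""
    data = adjust.validate_phenotypes(data)
    rows = []
    n_fits = 0
    val0 = scenarios[0].validation_years
    loc0 = scenarios[0].location
    val_blue = _adjust_years(data, trait, val0, loc0, scenario="validation")
    for spec in scenarios:
        missing = set(str(y) for y in spec.validation_years) - set(
            data["year"].astype(str).unique()
        )
        if missing:
            raise ValueError(f"validation years {sorted(missing)} absent from the data")
        if spec.validation_years != val0 or spec.location != loc0:
            val_blue = _adjust_years(
                data, trait, spec.validation_years, spec.location, scenario="validation"
            )
        train_blue = _adjust_years(data, trait, spec.train_years, spec.location, spec.label)
        fits = fit_genomic(train_blue.eblues, markers, config)
        n_fits += 1
        gebv = predict_gebv(fits, markers)
        pop_of = dict(zip(markers.genotype_ids, (str(p) for p in markers.populations)))
        obs = val_blue.eblues
        for pop in sorted(set(pop_of.values())):
            genos = [g for g in obs.index if pop_of.get(g) == pop and g in gebv.index]
            if len(genos) < 3:
                continue
            r = float(stats.pearsonr(obs.reindex(genos), gebv.reindex(genos))[0])
            rows.append(
                {
                    "scenario": spec.label,
                    "trait": trait,
                    "population": pop,
                    "n_train_years": len(spec.train_years),
                    "predictive_ability": r,
                    "n": len(genos),
                }
            )
    return PredictionReport(pd.DataFrame(rows), n_fits=n_fits, seeds=[config.seed])


def _adjust_years(data, trait, years, location, scenario):
    years = tuple(years)
    if len(years) == 1:
        return adjust.fit_single_year(data, trait, years[0], location=location, scenario=scenario)
    return adjust.fit_multi_year(data, trait, years, location=location, scenario=scenario)


# ---------------------------------------------------------------------- #
def _stratified_folds(
    genotypes: Sequence[str], populations: Mapping[str, str], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Population-stratified fold labels; invariant to genotype input order."""
    assignment: dict[str, int] = {}
    by_pop: dict[str, list[str]] = {}
    for g in sorted(genotypes):
        by_pop.setdefault(populations.get(g, "pop1"), []).append(g)
    for pop in sorted(by_pop):
        members = by_pop[pop]
        perm = rng.permutation(len(members))
        for slot, idx in enumerate(perm):
            assignment[members[idx]] = slot % k
    return assignment


def run_cv(
    y: pd.Series,
    markers: MarkerMatrix,
    config: GenomicModelConfig,
    k: int = 10,
    reps: int = 5,
    seed: int | None = None,
) -> PredictionReport:
    """k-fold cross-validation with ``reps`` repetitions.

    Folds are stratified by population and re-drawn per repetition from the
    repetition seed, so reports regenerate exactly from config + seed. One
    model fit is logged per fold per repetition (k * reps total); predictive
    ability is the per-population Pearson correlation pooled over each
    repetition's held-out predictions, with observations and predictions
    centered within fold first (pooling uncentered folds is biased downward
    under a null signal because every fold's predictions track its training
    mean).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = y.dropna()
    y.index = y.index.astype(str)
    genos = [g for g in markers.genotype_ids if g in set(y.index)]
    if k > len(genos):
        raise ValueError(f"k={k} folds exceed {len(genos)} genotypes")
    mk = markers.subset(genotypes=genos)
    pop_of = dict(zip(mk.genotype_ids, (str(p) for p in mk.populations)))
    base_seed = config.seed if seed is None else seed
    rows = []
    n_fits = 0
    fold_assignments: dict[int, dict[str, int]] = {}
    rep_seeds = []
    for rep in range(reps):
        rep_seed = (base_seed + 1000003 * (rep + 1)) % (2**31)
        rep_seeds.append(rep_seed)
        rng = np.random.default_rng(rep_seed)
        folds = _stratified_folds(genos, pop_of, k, rng)
        fold_assignments[rep] = folds
        preds = pd.Series(index=pd.Index(genos, dtype=object), dtype=float)
        for fold in range(k):
            test = [g for g in genos if folds[g] == fold]
            train = [g for g in genos if folds[g] != fold]
            if not test:
                continue
            fit_cfg = dataclasses.replace(config, seed=(rep_seed + fold) % (2**31))
            fits = fit_genomic(y.reindex(train), mk.subset(genotypes=train), fit_cfg)
            n_fits += 1
            preds.loc[test] = predict_gebv(fits, mk.subset(genotypes=test)).to_numpy()
        fold_lab = pd.Series({g: folds[g] for g in genos})
        for pop in sorted(set(pop_of.values())) + ["all"]:
            members = [g for g in genos if pop == "all" or pop_of[g] == pop]
            r = _fold_centered_pearson(
                y.reindex(members), preds.reindex(members), fold_lab.reindex(members)
            )
            rows.append(
                {"rep": rep, "population": pop, "predictive_ability": r, "n": len(members)}
            )
    return PredictionReport(
        pd.DataFrame(rows), n_fits=n_fits, fold_assignments=fold_assignments, seeds=rep_seeds
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def _fold_centered_pearson(obs: pd.Series, pred: pd.Series, fold: pd.Series) -> float:
    oc = obs - obs.groupby(fold).transform("mean")
    pc = pred - pred.groupby(fold).transform("mean")
    return _safe_pearson(oc.to_numpy(), pc.to_numpy())


# ---------------------------------------------------------------------- #
def correlate_performance_stability(
    performance: pd.Series,
    stability: pd.DataFrame,
    metrics: Sequence[str] = ("ASV", "fw_slope_dev"),
    trait: str = "trait",
) -> pd.DataFrame:
    """Pearson correlation (with two-sided p and significance stars) between
    genotype performance eBLUEs and each stability metric column."""
    performance = performance.dropna()
    common = performance.index.intersection(stability.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genotypes shared between performance and stability")
    rows = []
    for metric in metrics:
        x = performance.reindex(common).to_numpy(dtype=float)
        z = stability.loc[common, metric].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(z) == 0:
            rows.append({"trait": trait, "metric": metric, "r": np.nan, "p": np.nan, "stars": ""})
            continue
        r, p = stats.pearsonr(x, z)
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        rows.append({"trait": trait, "metric": metric, "r": float(r), "p": float(p), "stars": stars})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
@dataclasses.dataclass
class SelectionOverlap:
    """Top-set co-selection: best performers vs most stable genotypes."""

    performance_set: list[str]
    asv_set: list[str]
    fw_set: list[str]
    counts: dict[str, int]

    @staticmethod
    def _top(values: pd.Series, frac: float, ascending: bool) -> list[str]:
        n = max(int(np.floor(len(values) * frac)), 1)
        # deterministic tie-break: sort on value, then genotype id
        df = pd.DataFrame({"v": values.to_numpy(), "g": values.index.astype(str)})
        df = df.sort_values(["v", "g"], ascending=[ascending, True], kind="mergesort")
        return df["g"].head(n).tolist()


def select_overlap(
    performance: pd.Series,
    stability: pd.DataFrame,
    direction: str,
    perf_frac: float = 0.10,
    stab_frac: float = 0.20,
) -> SelectionOverlap:
    """Intersect the best-``perf_frac`` performers with the top-``stab_frac``
    stable genotypes under AMMI (lowest ASV) and FW (|slope deviation| ~ 0).

    ``direction`` must be declared per trait: 'higher' (yield, vigor) or
    'lower' (disease severity, maturation scores); there is no silent
    default. Set sizes follow floor(n * frac) with a minimum of 1; ties break
    on genotype id.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be declared as 'higher' or 'lower' for the trait")
    common = performance.index.intersection(stability.index)
    perf = performance.reindex(common)
    perf_set = SelectionOverlap._top(perf, perf_frac, ascending=(direction == "lower"))
    asv_set = SelectionOverlap._top(stability.loc[common, "ASV"], stab_frac, ascending=True)
    fw_set = SelectionOverlap._top(
        stability.loc[common, "fw_slope_dev"].abs(), stab_frac, ascending=True
    )
    sp, sa, sf = set(perf_set), set(asv_set), set(fw_set)
    counts = {
        "performance": len(sp),
        "asv": len(sa),
        "fw": len(sf),
        "performance_asv": len(sp & sa),
        "performance_fw": len(sp & sf),
        "asv_fw": len(sa & sf),
        "triple": len(sp & sa & sf),
    }
    return SelectionOverlap(perf_set, asv_set, fw_set, counts)
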