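"""File formats, run configuration, and pipeline orchestration.

Formats: long-format phenotype TSV/CSV (genotype, population, location, year,
block, trait, value — extra columns pass through), marker dosage TSV or
minimal VCF, tab-separated result tables, and a JSON run manifest recording
the config hash, seeds, stage timings and output checksums so every output
is regenerable from the manifest alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import adjust, evaluate, predict, simulate, stability
from .markers import MarkerMatrix, read_dosage_tsv, read_vcf, write_dosage_tsv

logger = logging.getLogger("metgs.io")

__all__ = ["read_phenotypes", "read_markers", "RunConfig", "load_run_config", "run_pipeline"]


def read_phenotypes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format phenotype table (TSV or CSV).

    ``column_map`` renames file columns onto the required schema, e.g.
    ``{"clone": "genotype"}``. Missing required columns and non-numeric
    values raise with the offending name / line; extra columns are kept as
    passthrough metadata.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        with open(path) as fh:
            header = fh.readline()
        if "\t" in header:
            sep = "\t"
        elif "," in header:
            sep = ","
    df = pd.read_csv(path, sep=sep, dtype={"genotype": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in adjust.REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric value at line {line}")
    out = adjust.validate_phenotypes(df)
    logger.info("read %d plot records, %d genotypes, %d environments from %s",
                len(out), out["genotype"].nunique(), out["environment"].nunique(), path)
    return out


def read_markers(
    path: str | Path,
    fmt: str = "auto",
    populations: Mapping[str, str] | None = None,
) -> MarkerMatrix:
    """Read marker dosages from VCF or dosage TSV (``fmt='auto'`` sniffs the
    extension/header)."""
    path = Path(path)
    if fmt == "auto":
        if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
            fmt = "vcf"
        else:
            with open(path, "rb") as fh:
                fmt = "vcf" if fh.read(2) == b"##" else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path, populations=populations)
    if fmt == "dosage_tsv":
        mk = read_dosage_tsv(path)
        if populations:
            pops = np.array(
                [str(populations.get(g, p)) for g, p in zip(mk.genotype_ids, mk.populations)],
                dtype=object,
            )
            mk = MarkerMatrix(mk.dosages, mk.genotype_ids, mk.locus_ids, pops, mk.biallelic)
        return mk
    raise ValueError(f"unknown marker format '{fmt}'")


# ---------------------------------------------------------------------- #
@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline settings (see the YAML example in the README)."""

    output_dir: str = "metgs_output"
    phenotypes_path: str | None = None
    markers_path: str | None = None
    stages: tuple[str, ...] = ("simulate", "adjust", "stability", "predict", "evaluate")
    simulation: simulate.SimulationConfig = dataclasses.field(
        default_factory=simulate.SimulationConfig
    )
    genomic: predict.GenomicModelConfig = dataclasses.field(
        default_factory=predict.GenomicModelConfig
    )
    trait_directions: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(evaluate.DEFAULT_TRAIT_DIRECTIONS)
    )
    perf_frac: float = 0.10
    stab_frac: float = 0.20
    cv_folds: int = 10
    cv_reps: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = simulate.SimulationConfig(**raw.pop("simulation", {})) if "simulation" in raw else None
    gen = predict.GenomicModelConfig(**raw.pop("genomic", {})) if "genomic" in raw else None
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.simulation = sim
    if gen is not None:
        cfg.genomic = gen
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order
    simulate -> adjust -> stability -> predict -> evaluate.

    Any stage failure marks the output directory with ``failed/<stage>`` and
    re-raises; on success a ``manifest.json`` records config hash, seeds,
    timings and output checksums. Returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("metgs").setLevel(config.log_level.upper())
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            _STAGES[stage](config, state, out)
            manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s: done (%.2fs)", stage, time.perf_counter() - t0)
    except Exception as exc:
        marker = out / "failed"
        marker.mkdir(exist_ok=True)
        (marker / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    markers = simulate.simulate_markers(sim)
    pheno, truth = simulate.simulate_phenotypes(markers, sim)
    state["markers_raw"] = markers
    state["phenotypes"] = adjust.validate_phenotypes(pheno)
    state["truth"] = truth
    state["traits"] = [sim.trait]
    simulate.write_phenotypes(pheno, out / "phenotypes.tsv")
    write_dosage_tsv(markers, out / "markers.tsv")
    truth.to_json(out / "truth.json")


def _stage_load(config: RunConfig, state: dict) -> None:
    if "phenotypes" not in state:
        if not config.phenotypes_path:
            raise ValueError("no phenotypes: enable the simulate stage or set phenotypes_path")
        state["phenotypes"] = read_phenotypes(config.phenotypes_path)
        state["traits"] = sorted(state["phenotypes"]["trait"].unique())
    if "markers_raw" not in state and config.markers_path:
        state["markers_raw"] = read_markers(config.markers_path)


def _stage_adjust(config: RunConfig, state: dict, out: Path) -> None:
    _stage_load(config, state)
    pheno = state["phenotypes"]
    frames, vc_all = [], {}
    per_env: dict[str, dict[str, dict[str, adjust.AdjustedMeans]]] = {}
    overall: dict[str, dict[str, adjust.AdjustedMeans]] = {}
    for pop, sub in pheno.groupby("population", observed=True):
        for trait in state["traits"]:
            years = sorted(sub["year"].unique())
            am = adjust.fit_multi_year(sub, trait, years, scenario="all-environments")
            overall.setdefault(str(pop), {})[trait] = am
            frames.append(am.to_frame().assign(population=pop))
            env_means: dict[str, adjust.AdjustedMeans] = {}
            for env, esub in sub.groupby("environment", observed=True):
                loc, yr = str(env).split(":")
                env_means[str(env)] = adjust.fit_single_year(
                    esub, trait, yr, location=loc, scenario=str(env)
                )
            per_env.setdefault(str(pop), {})[trait] = env_means
            vc = adjust.estimate_h2(sub, trait)
            vc_all[f"{pop}:{trait}"] = vc.to_dict()
    state["eblues"] = overall
    state["eblues_per_env"] = per_env
    pd.concat(frames).to_csv(out / "eblues.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "variance_components.json").write_text(json.dumps(vc_all, indent=1))
    state["variance_components"] = vc_all


def _stage_stability(config: RunConfig, state: dict, out: Path) -> None:
    if "eblues_per_env" not in state:
        _stage_adjust(config, state, out)
    tables = []
    coords = []
    state["stability"] = {}
    for pop, by_trait in state["eblues_per_env"].items():
        for trait, env_means in by_trait.items():
            table, report = stability.prepare_two_way(env_means)
            ammi = stability.ammi_decompose(table)
            idx = stability.ammi_stability(ammi, n_components=2)
            fw = stability.fw_fit(table)
            stab = stability.stability_table(idx, fw, trait=trait)
            stab.insert(0, "population", pop)
            state["stability"].setdefault(pop, {})[trait] = stab
            tables.append(stab.reset_index())
            sc = ammi.genotype_scores()
            ec = ammi.delta * np.sqrt(ammi.lam)
            for kind, frame in (("genotype", sc), ("environment", ec)):
                coords.append(
                    pd.DataFrame(
                        {
                            "population": pop,
                            "trait": trait,
                            "id": frame.index,
                            "kind": kind,
                            "pc1": frame.iloc[:, 0],
                            "pc2": frame.iloc[:, 1] if frame.shape[1] > 1 else 0.0,
                        }
                    )
                )
    pd.concat(tables).to_csv(out / "stability.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(coords).to_csv(out / "ammi_biplot.tsv", sep="\t", index=False, float_format="%.6g")


def _stage_predict(config: RunConfig, state: dict, out: Path) -> None:
    if "stability" not in state:
        _stage_stability(config, state, out)
    if "markers_raw" not in state:
        raise ValueError("predict stage needs markers: simulate them or set markers_path")
    markers, qc_report = predict.qc_filter(state["markers_raw"])
    state["markers"] = markers
    (out / "qc_report.json").write_text(json.dumps(dataclasses.asdict(qc_report), indent=1))
    rows = []
    gcfg = dataclasses.replace(config.genomic, seed=config.seed)
    for pop, by_trait in state["eblues"].items():
        sub = markers.subset(
            genotypes=[g for g, p in zip(markers.genotype_ids, markers.populations) if str(p) == pop]
        )
        for trait, am in by_trait.items():
            rep = evaluate.run_cv(am.eblues, sub, gcfg, k=config.cv_folds, reps=config.cv_reps)
            rows.append(rep.results.assign(population=pop, trait=trait, target="eblue"))
            stab = state["stability"][pop][trait]
            for metric in ("fw_slope_dev", "ASV"):
                rep = evaluate.run_cv(stab[metric], sub, gcfg, k=config.cv_folds, reps=config.cv_reps)
                rows.append(rep.results.assign(population=pop, trait=trait, target=metric))
    res = pd.concat(rows)
    res.to_csv(out / "predictive_ability.tsv", sep="\t", index=False, float_format="%.4f")
    state["predictive_ability"] = res


def _stage_evaluate(config: RunConfig, state: dict, out: Path) -> None:
    if "stability" not in state:
        _stage_stability(config, state, out)
    corr_rows, overlap = [], {}
    for pop, by_trait in state["eblues"].items():
        for trait, am in by_trait.items():
            stab = state["stability"][pop][trait]
            corr = evaluate.correlate_performance_stability(am.eblues, stab, trait=trait)
            corr_rows.append(corr.assign(population=pop))
            if trait not in config.trait_directions:
                raise ValueError(f"no selection direction declared for trait '{trait}'")
            direction = config.trait_directions[trait]
            sel = evaluate.select_overlap(
                am.eblues, stab, direction, config.perf_frac, config.stab_frac
            )
            overlap[f"{pop}:{trait}"] = {
                "counts": sel.counts,
                "performance_set": sel.performance_set,
                "asv_set": sel.asv_set,
                "fw_set": sel.fw_set,
            }
    pd.concat(corr_rows).to_csv(
        out / "performance_stability_correlation.tsv", sep="\t", index=False, float_format="%.4f"
    )
    (out / "selection_overlap.json").write_text(json.dumps(overlap, indent=1))
    state["overlap"] = overlap


_STAGES = {
    "simulate": _stage_simulate,
    "adjust": _stage_adjust,
    "stability": _stage_stability,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}
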