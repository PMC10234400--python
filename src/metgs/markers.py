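"""SNP dosage container with VCF and dosage-TSV round trips.

The in-memory representation is a genotype-by-locus matrix of alternate-allele
dosages (0/1/2), stored as float64 with NaN marking missing calls so that
quality control (missingness, MAF) can be computed before imputation.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MarkerMatrix", "read_dosage_tsv", "write_dosage_tsv", "read_vcf", "write_vcf"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclasses.dataclass
class MarkerMatrix:
    """Genotype x locus dosage matrix with per-locus metadata.

    Parameters
    ----------
    dosages
        ``(n_genotypes, n_loci)`` float array with entries in {0, 1, 2} or NaN
        for missing calls.
    genotype_ids, locus_ids
        Row and column labels (opaque strings).
    populations
        Per-genotype population label; single-population data may use one label.
    biallelic
        Per-locus flag; loci read from multi-allelic VCF records are flagged
        False and removed by :func:`metgs.predict.qc_filter`.
    """

    dosages: np.ndarray
    genotype_ids: list[str]
    locus_ids: list[str]
    populations: np.ndarray
    biallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D genotype x locus array")
        n, p = self.dosages.shape
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.locus_ids = [str(m) for m in self.locus_ids]
        if len(self.genotype_ids) != n:
            raise ValueError(f"{len(self.genotype_ids)} genotype ids for {n} rows")
        if len(self.locus_ids) != p:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {p} columns")
        self.populations = np.asarray(self.populations, dtype=object)
        if self.populations.shape != (n,):
            raise ValueError("populations must give one label per genotype")
        if self.biallelic is None:
            self.biallelic = np.ones(p, dtype=bool)
        else:
            self.biallelic = np.asarray(self.biallelic, dtype=bool)
            if self.biallelic.shape != (p,):
                raise ValueError("biallelic must give one flag per locus")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            # allow imputed (fractional) dosages only within [0, 2]
            if observed.min() < 0 or observed.max() > 2:
                raise ValueError("dosages must lie in [0, 2]")

    # ------------------------------------------------------------------ #
    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missingness(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency among observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    @property
    def pop_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.populations:
            seen.setdefault(str(lab), None)
        return list(seen)

    # ------------------------------------------------------------------ #
    def subset(
        self,
        genotypes: Sequence[str] | None = None,
        loci: Sequence[str] | np.ndarray | None = None,
    ) -> "MarkerMatrix":
        """Return a new matrix restricted to the given genotype ids and/or loci.

        ``loci`` may be a sequence of locus ids or a boolean mask.
        """
        rows = np.arange(self.n_genotypes)
        if genotypes is not None:
            index = {g: i for i, g in enumerate(self.genotype_ids)}
            missing = [g for g in genotypes if g not in index]
            if missing:
                raise KeyError(f"unknown genotype ids: {missing[:5]}")
            rows = np.array([index[g] for g in genotypes])
        cols = np.arange(self.n_loci)
        if loci is not None:
            loci_arr = np.asarray(loci)
            if loci_arr.dtype == bool:
                cols = np.flatnonzero(loci_arr)
            else:
                index = {m: i for i, m in enumerate(self.locus_ids)}
                cols = np.array([index[str(m)] for m in loci_arr])
        return MarkerMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            genotype_ids=[self.genotype_ids[i] for i in rows],
            locus_ids=[self.locus_ids[j] for j in cols],
            populations=self.populations[rows],
            biallelic=self.biallelic[cols],
        )

    def split_populations(self) -> dict[str, "MarkerMatrix"]:
        return {
            lab: self.subset(
                genotypes=[g for g, p in zip(self.genotype_ids, self.populations) if str(p) == lab]
            )
            for lab in self.pop_levels
        }


# ---------------------------------------------------------------------- #
# dosage TSV
# ---------------------------------------------------------------------- #
def write_dosage_tsv(markers: MarkerMatrix, path: str | Path) -> None:
    """Write a tab-separated dosage matrix: genotype, population, then one
    column per locus id. Missing calls are written as ``NA``."""
    df = pd.DataFrame(markers.dosages, columns=markers.locus_ids)
    df.insert(0, "population", [str(p) for p in markers.populations])
    df.insert(0, "genotype", markers.genotype_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    if "genotype" not in df.columns:
        raise ValueError(f"{path}: dosage TSV requires a 'genotype' column")
    genotype_ids = df["genotype"].tolist()
    if "population" in df.columns:
        populations = df["population"].astype(str).to_numpy(dtype=object)
        value_cols = [c for c in df.columns if c not in ("genotype", "population")]
    else:
        populations = np.array(["pop1"] * len(df), dtype=object)
        value_cols = [c for c in df.columns if c != "genotype"]
    if not value_cols:
        raise ValueError(f"{path}: no locus columns found")
    dosages = df[value_cols].to_numpy(dtype=float)
    return MarkerMatrix(dosages, genotype_ids, list(value_cols), populations)


# ---------------------------------------------------------------------- #
# VCF (VCFv4.2, GT-only; phasing ignored)
# ---------------------------------------------------------------------- #
def write_vcf(markers: MarkerMatrix, path: str | Path) -> None:
    """Write dosages as a minimal biallelic-SNP VCFv4.2 (GT field only).

    Fractional (imputed) dosages cannot be represented and raise an error.
    """
    observed = markers.dosages[~np.isnan(markers.dosages)]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise ValueError("VCF output requires integer dosages; write dosage TSV instead")
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(markers.genotype_ids),
    ]
    for j, locus in enumerate(markers.locus_ids):
        calls = []
        for i in range(markers.n_genotypes):
            d = markers.dosages[i, j]
            calls.append("./." if np.isnan(d) else _GT_STRINGS[int(d)])
        lines.append(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, populations: Mapping[str, str] | None = None) -> MarkerMatrix:
    """Read GT dosages from a VCF; alternate-allele counts become dosages.

    Multi-allelic records are retained with missing dosages and flagged
    non-biallelic so that downstream QC removes them. ``populations`` maps
    sample id -> population label (default: a single ``pop1`` label).
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    biallelic: list[bool] = []
    for idx, variant in enumerate(vcf):
        locus_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        if len(variant.ALT) != 1 or not variant.is_snp:
            biallelic.append(False)
            dosage_cols.append(np.full(len(samples), np.nan))
            continue
        biallelic.append(True)
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                col[i] = float(sum(1 for a in alleles if a > 0))
        dosage_cols.append(col)
    if not locus_ids:
        raise ValueError(f"{path}: VCF contains no variant records")
    pops = np.array(
        [str(populations.get(s, "pop1")) if populations else "pop1" for s in samples],
        dtype=object,
    )
    return MarkerMatrix(
        dosages=np.column_stack(dosage_cols),
        genotype_ids=samples,
        locus_ids=locus_ids,
        populations=pops,
        biallelic=np.array(biallelic, dtype=bool),
    )
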