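"""Marker QC and Bayesian whole-genome regression samplers."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from metgs import (
    GenomicModelConfig,
    MarkerMatrix,
    build_pop_design,
    fit_genomic,
    gibbs_bayesb,
    gibbs_brr,
    predict_gebv,
    qc_filter,
)


# ---------------------------------------------------------------------- #
# QC
# ---------------------------------------------------------------------- #
def _matrix(dosages, biallelic=None, pops=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return MarkerMatrix(
        dosages,
        [f"g{i}" for i in range(n)],
        [f"m{j}" for j in range(p)],
        np.array(pops if pops is not None else ["pop1"] * n, dtype=object),
        biallelic,
    )


def test_qc_hand_enumerated_toy():
    nan = np.nan
    # 10 genotypes x 6 loci:
    # m0 ok; m1 60% missing; m2 non-biallelic; m3 MAF=0.009-ish (0/200);
    # m4 MAF exactly boundary-ish; m5 ok with one missing call
    dos = np.zeros((10, 6))
    dos[:, 0] = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
    dos[:6, 1] = nan
    dos[6:, 1] = [0, 1, 1, 2]
    dos[:, 2] = 1
    dos[:, 3] = 0           # MAF 0 -> removed
    dos[:, 4] = [1] + [0] * 9   # freq 0.05 -> retained
    dos[:, 5] = [0, 1, 2, 1, 0, 1, 2, 1, 0, nan]
    bial = np.array([True, True, False, True, True, True])
    mk, report = qc_filter(_matrix(dos, bial))
    assert mk.locus_ids == ["m0", "m4", "m5"]
    assert report.n_removed_missing == 1
    assert report.n_removed_nonbiallelic == 1
    assert report.n_removed_maf == 1
    assert report.n_imputed_calls == 1
    # mean imputation preserves allele frequency
    assert mk.dosages[9, 2] == pytest.approx(np.nanmean(dos[:, 5]))
    assert not np.isnan(mk.dosages).any()


def test_qc_maf_boundary():
    n = 1000
    rng = np.random.default_rng(1)
    base = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    low = np.zeros((n, 1)); low[:9, 0] = 2   # freq 0.009
    keep = np.zeros((n, 1)); keep[:11, 0] = 2  # freq 0.011
    mk, report = qc_filter(_matrix(np.hstack([base, low, keep])))
    assert mk.locus_ids == ["m0", "m2"]


def test_qc_all_removed_errors():
    with pytest.raises(ValueError, match="every locus"):
        qc_filter(_matrix(np.zeros((5, 3))))


# ---------------------------------------------------------------------- #
# BRR
# ---------------------------------------------------------------------- #
def test_brr_fixed_variance_matches_ridge_oracle():
    rng = np.random.default_rng(5)
    n, p = 50, 20
    X = rng.normal(size=(n, p))
    y = 1.5 + X @ rng.normal(scale=0.3, size=p) + rng.normal(scale=0.5, size=n)
    s2b, s2e = 0.1, 0.25
    cfg = GenomicModelConfig(
        n_iter=30000, burn_in=5000, thin=5, update_variances=False,
        sigma2_beta=s2b, sigma2_e=s2e, seed=7,
    )
    fit = gibbs_brr(y, X, cfg)
    Xc = X - X.mean(axis=0)
    ridge = np.linalg.solve(Xc.T @ Xc + (s2e / s2b) * np.eye(p), Xc.T @ (y - y.mean()))
    assert np.abs(fit.beta - ridge).max() < 0.02


def test_brr_bit_reproducible_and_gebv_identity():
    rng = np.random.default_rng(2)
    X = rng.binomial(2, 0.4, size=(40, 30)).astype(float)
    y = rng.normal(size=40)
    cfg = GenomicModelConfig(n_iter=800, burn_in=200, seed=5)
    f1 = gibbs_brr(y, X, cfg)
    f2 = gibbs_brr(y, X, cfg)
    assert np.array_equal(f1.beta, f2.beta)
    assert np.array_equal(f1.sigma2_e_samples, f2.sigma2_e_samples)
    # GEBV = mu + Xc beta reproducible from stored effects
    recon = f1.mu["pop1"] + (X - f1.col_means) @ f1.beta
    np.testing.assert_allclose(f1.gebv.to_numpy(), recon, atol=1e-10)


def test_brr_constant_y_shrinks_effects_to_zero():
    rng = np.random.default_rng(3)
    X = rng.binomial(2, 0.5, size=(30, 10)).astype(float)
    fit = gibbs_brr(np.full(30, 3.2), X, GenomicModelConfig(n_iter=2000, burn_in=500, seed=1))
    assert np.abs(fit.beta).max() < 1e-4
    assert fit.mu["pop1"] == pytest.approx(3.2, abs=1e-4)


def test_brr_shrinkage_monotone_in_variance_ratio():
    rng = np.random.default_rng(4)
    n, p = 60, 15
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    norms = []
    for ratio in (0.1, 1.0, 10.0, 100.0):
        cfg = GenomicModelConfig(
            n_iter=6000, burn_in=1000, update_variances=False,
            sigma2_beta=1.0 / ratio, sigma2_e=1.0, seed=8,
        )
        norms.append(np.abs(gibbs_brr(y, X, cfg).beta).sum())
    assert norms == sorted(norms, reverse=True)


def test_non_finite_phenotypes_rejected():
    X = np.zeros((5, 3))
    with pytest.raises(ValueError, match="non-finite"):
        gibbs_brr(np.array([1.0, np.nan, 2.0, 3.0, 4.0]), X)


# ---------------------------------------------------------------------- #
# BayesB
# ---------------------------------------------------------------------- #
def test_bayesb_collapses_to_brr_when_pi_zero():
    rng = np.random.default_rng(11)
    n, p = 120, 60
    X = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(float)
    y = 5 + (X - X.mean(0)) @ rng.normal(scale=0.3, size=p) + rng.normal(size=n)
    fb = gibbs_bayesb(
        y, X, GenomicModelConfig(model="BayesB", n_iter=6000, burn_in=1000,
                                 pi_zero_fixed=0.0, seed=3)
    )
    fr = gibbs_brr(y, X, GenomicModelConfig(n_iter=6000, burn_in=1000, seed=3))
    assert (fb.inclusion_prob == 1.0).all()
    assert np.corrcoef(fb.beta, fr.beta)[0, 1] > 0.99


def test_bayesb_null_data_inclusion_matches_prior():
    rng = np.random.default_rng(21)
    X = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(150, 200)).astype(float)
    y = rng.normal(size=150)
    fit = gibbs_bayesb(
        y, X, GenomicModelConfig(model="BayesB", n_iter=4000, burn_in=1000, seed=9)
    )
    assert fit.inclusion_prob.mean() == pytest.approx(fit.pi_in_samples.mean(), abs=0.05)


def test_bayesb_degenerate_pi_rejected():
    with pytest.raises(ValueError, match="no markers"):
        GenomicModelConfig(model="BayesB", pi_zero_fixed=1.0)


# ---------------------------------------------------------------------- #
# population designs
# ---------------------------------------------------------------------- #
def _two_pops(rng, n1=3, n2=2, p=4):
    X1 = _matrix(rng.binomial(2, 0.5, size=(n1, p)).astype(float), pops=["A"] * n1)
    X2 = MarkerMatrix(
        rng.binomial(2, 0.5, size=(n2, p)).astype(float),
        [f"h{i}" for i in range(n2)],
        [f"m{j}" for j in range(p)],
        np.array(["B"] * n2, dtype=object),
    )
    return X1, X2


def test_mp_design_zero_blocks(rng):
    X1, X2 = _two_pops(rng)
    design = build_pop_design(X1, X2, "MP")
    assert design.X.shape == (5, 12)
    # foreign population's specific-effect block is exactly zero
    assert (design.X[3:, 4:8] == 0).all()   # pop B rows, pop A specific block
    assert (design.X[:3, 8:] == 0).all()    # pop A rows, pop B specific block
    assert list(design.groups) == [0] * 4 + [1] * 4 + [2] * 4


def test_swapping_populations_permutes_specific_blocks(rng):
    X1, X2 = _two_pops(rng)
    d12 = build_pop_design(X1, X2, "MP")
    d21 = build_pop_design(X2, X1, "MP")
    n1, n2, p = 3, 2, 4
    np.testing.assert_allclose(d12.X[:n1, p : 2 * p], d21.X[n2:, 2 * p :])
    np.testing.assert_allclose(d12.X[n1:, 2 * p :], d21.X[:n2, p : 2 * p])
    # AP design is the same rows, just reordered
    a12 = build_pop_design(X1, X2, "AP")
    a21 = build_pop_design(X2, X1, "AP")
    np.testing.assert_allclose(a12.X, np.vstack([a21.X[n2:], a21.X[:n2]]))


def test_locus_mismatch_between_populations_errors(rng):
    X1, X2 = _two_pops(rng)
    X2 = MarkerMatrix(
        X2.dosages, X2.genotype_ids, ["m0", "m1", "m2", "zz"], X2.populations
    )
    with pytest.raises(ValueError, match="zz"):
        build_pop_design(X1, X2, "MP")


def test_mp_beta_composition_and_population_resolved_prediction(rng):
    # 2-locus toy: prediction for population 1 must use b0 + b1 only
    X1, X2 = _two_pops(rng, n1=6, n2=6, p=2)
    y = pd.Series(
        rng.normal(size=12), index=list(X1.genotype_ids) + list(X2.genotype_ids)
    )
    stacked = MarkerMatrix(
        np.vstack([X1.dosages, X2.dosages]),
        list(X1.genotype_ids) + list(X2.genotype_ids),
        X1.locus_ids,
        np.array(["A"] * 6 + ["B"] * 6, dtype=object),
    )
    cfg = GenomicModelConfig(pop_mode="MP", n_iter=600, burn_in=200, seed=2)
    fit = fit_genomic(y, stacked, cfg)
    np.testing.assert_array_equal(fit.beta_for_pop("A"), fit.beta_common + fit.beta_specific("A"))
    pred = predict_gebv(fit, stacked.subset(genotypes=X1.genotype_ids))
    x0 = X1.dosages[0]
    by_hand = (
        fit.mu["A"]
        + (x0 - fit.col_means) @ fit.beta_common
        + (x0 - fit.spec_col_means["A"]) @ fit.beta_specific("A")
    )
    assert pred.iloc[0] == pytest.approx(by_hand, abs=1e-10)
    with pytest.raises(ValueError, match="unknown population"):
        bad = MarkerMatrix(X1.dosages, X1.genotype_ids, X1.locus_ids,
                           np.array(["C"] * 6, dtype=object))
        predict_gebv(fit, bad)


def test_predict_in_sample_identity_and_intercept_only(rng):
    # symmetric +-1 coding keeps column means at zero, so an all-zero row
    # scores exactly the posterior-mean intercept
    X = np.vstack([np.eye(6), -np.eye(6)])
    y = rng.normal(size=12)
    mk = _matrix(X + 1.0)  # dosages in {0,1,2}
    fit = gibbs_brr(pd.Series(y, index=mk.genotype_ids), mk,
                    GenomicModelConfig(n_iter=800, burn_in=200, seed=3))
    pred = predict_gebv(fit, mk)
    np.testing.assert_allclose(pred.to_numpy(), fit.gebv.to_numpy(), atol=1e-12)
    center = _matrix(np.full((1, 6), 1.0))  # row at the column means
    assert predict_gebv(fit, center).iloc[0] == pytest.approx(fit.mu["pop1"], abs=1e-12)


def test_sp_prediction_requires_known_population(rng):
    X1, X2 = _two_pops(rng, n1=8, n2=8, p=5)
    stacked = MarkerMatrix(
        np.vstack([X1.dosages, X2.dosages]),
        list(X1.genotype_ids) + list(X2.genotype_ids),
        X1.locus_ids,
        np.array(["A"] * 8 + ["B"] * 8, dtype=object),
    )
    y = pd.Series(rng.normal(size=16), index=stacked.genotype_ids)
    fits = fit_genomic(y, stacked, GenomicModelConfig(n_iter=400, burn_in=100, seed=1))
    assert set(fits) == {"A", "B"}
    unknown = MarkerMatrix(X1.dosages, X1.genotype_ids, X1.locus_ids,
                           np.array(["Z"] * 8, dtype=object))
    with pytest.raises(ValueError, match="Z"):
        predict_gebv(fits, unknown)


def test_missing_dosages_rejected_before_sampling(rng):
    dos = rng.binomial(2, 0.5, size=(10, 4)).astype(float)
    dos[0, 0] = np.nan
    with pytest.raises(ValueError, match="qc_filter"):
        gibbs_brr(rng.normal(size=10), _matrix(dos))
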