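"""AMMI and Finlay-Wilkinson stability: decomposition identities and indices."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgs.stability import (
    AMMIResult,
    TwoWayTable,
    ammi_decompose,
    ammi_stability,
    fw_fit,
    prepare_two_way,
    select_n_components,
    stability_table,
)
from tests.conftest import make_two_way


# ---------------------------------------------------------------------- #
# prepare_two_way
# ---------------------------------------------------------------------- #
def test_prepare_complete_is_identity(rng):
    tab = make_two_way(rng)
    long = tab.to_frame().stack().rename("value").reset_index()
    long.columns = ["genotype", "environment", "value"]
    out, report = prepare_two_way(long)
    np.testing.assert_array_equal(out.values, tab.values)
    assert not report["dropped_genotypes"] and not report["imputed_cells"]


def test_em_imputation_recovers_additive_fill(rng):
    g, e = 8, 5
    gi = rng.normal(0, 1, g)
    ej = rng.normal(0, 1, e)
    vals = 5.0 + gi[:, None] + ej[None, :]  # purely additive, rank-0 interaction
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(g)], columns=[f"e{j}" for j in range(e)])
    long = df.stack().rename("value").reset_index()
    long.columns = ["genotype", "environment", "value"]
    removed = long.drop(index=[7])
    expected = long.loc[7, "value"]
    out, report = prepare_two_way(removed, policy="em", em_rank=0)
    gname, ename = long.loc[7, "genotype"], long.loc[7, "environment"]
    assert (gname, ename) in report["imputed_cells"]
    i, j = out.genotype_ids.index(gname), out.env_ids.index(ename)
    assert out.values[i, j] == pytest.approx(expected, abs=1e-6)


def test_drop_policy_removes_sparse_genotype_with_report(rng):
    tab = make_two_way(rng, g=8, e=8)
    long = tab.to_frame().stack().rename("value").reset_index()
    long.columns = ["genotype", "environment", "value"]
    # keep genotype g01 in a single environment only
    keep = ~((long["genotype"] == "g01") & (long["environment"] != "e01"))
    out, report = prepare_two_way(long[keep], policy="drop")
    assert "g01" not in out.genotype_ids
    assert report["dropped_genotypes"] == ["g01"]


def test_too_small_after_completion_errors(rng):
    long = pd.DataFrame(
        {"genotype": ["a", "a", "b", "b"], "environment": ["x", "y", "x", "y"], "value": [1, 2, 3, 4.0]}
    )
    with pytest.raises(ValueError, match="at least"):
        prepare_two_way(long)


# ---------------------------------------------------------------------- #
# AMMI
# ---------------------------------------------------------------------- #
def test_rank_one_interaction_recovered_exactly(rng):
    g, e = 10, 6
    u = rng.normal(0, 1, g); u -= u.mean()
    v = rng.normal(0, 1, e); v -= v.mean()
    inter = np.outer(u, v)
    vals = 20.0 + rng.normal(0, 1, g)[:, None] + rng.normal(0, 1, e)[None, :] + inter
    tab = TwoWayTable(vals, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)])
    res = ammi_decompose(tab)
    assert res.lam[0] == pytest.approx(np.linalg.norm(u) * np.linalg.norm(v), rel=1e-10)
    assert res.lam[1] == pytest.approx(0.0, abs=1e-8)
    gamma1 = res.gamma.to_numpy()[:, 0]
    cosang = abs(gamma1 @ u) / np.linalg.norm(u)
    assert cosang == pytest.approx(1.0, abs=1e-10)


def test_additive_table_has_zero_singular_values(rng):
    g, e = 6, 5
    vals = 3.0 + rng.normal(0, 1, g)[:, None] + rng.normal(0, 1, e)[None, :]
    tab = TwoWayTable(vals, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)])
    res = ammi_decompose(tab)
    assert np.abs(res.lam).max() < 1e-8


def test_constant_table_convention_no_exception():
    tab = TwoWayTable(np.full((4, 4), 7.0), list("abcd"), list("wxyz"))
    res = ammi_decompose(tab)
    assert (res.lam == 0).all()
    assert (res.gamma.to_numpy() == 0).all()


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ss_partition_and_reconstruction_identities(seed):
    r = np.random.default_rng(seed)
    tab = make_two_way(r, g=10, e=6)
    res = ammi_decompose(tab)
    Y = tab.values
    Z = Y - Y.mean() - (Y.mean(1) - Y.mean())[:, None] - (Y.mean(0) - Y.mean())[None, :]
    ss = (Z**2).sum()
    assert res.lam @ res.lam == pytest.approx(ss, rel=1e-8)
    recon = res.reconstruct().to_numpy()
    assert np.abs(recon - Y).max() < 1e-8 * max(1.0, np.abs(Y).max())
    # singular values ordered, score matrices orthonormal
    assert (np.diff(res.lam) <= 1e-12).all()
    gam = res.gamma.to_numpy()
    np.testing.assert_allclose(gam.T @ gam, np.eye(gam.shape[1]), atol=1e-8)


def test_component_selection_rank1_signal_and_noise():
    g, e, b, sigma = 10, 6, 3, 1.0
    err_df = e * (g - 1) * (b - 1)
    # strong rank-1 signal -> exactly one component retained
    r = np.random.default_rng(100)
    u = r.normal(0, 1, g); u -= u.mean(); u /= np.linalg.norm(u)
    v = r.normal(0, 1, e); v -= v.mean(); v /= np.linalg.norm(v)
    cells = 10 + r.normal(0, 1, g)[:, None] + r.normal(0, 1, e)[None, :] \
        + 5.0 * np.outer(u, v) + r.normal(0, sigma / np.sqrt(b), (g, e))
    tab = TwoWayTable(cells, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)],
                      n_reps=b, error_ms=sigma**2, error_df=err_df)
    assert select_n_components(ammi_decompose(tab), alpha=0.05, cap=None) == 1

    # pure-noise interaction: N = 0 in >= 90% of simulations
    zeros = 0
    n_sim = 200
    for s in range(n_sim):
        r = np.random.default_rng(10_000 + s)
        cells = 10 + r.normal(0, 1, g)[:, None] + r.normal(0, 1, e)[None, :] \
            + r.normal(0, sigma / np.sqrt(b), (g, e))
        tab = TwoWayTable(cells, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)],
                          n_reps=b, error_ms=sigma**2, error_df=err_df)
        zeros += select_n_components(ammi_decompose(tab), alpha=0.05, cap=None) == 0
    assert zeros >= 0.9 * n_sim

    # default cap keeps at most two components
    r = np.random.default_rng(55)
    tab = make_two_way(r, g=12, e=8, interaction_scale=4.0)
    tab.n_reps, tab.error_ms, tab.error_df = 3, 0.01, 100
    res = ammi_decompose(tab)
    assert select_n_components(res, alpha=0.05) <= 2
    assert select_n_components(res, alpha=0.05) == min(
        select_n_components(res, alpha=0.05, cap=None), 2
    )


def _toy_result(scores, lam):
    """AMMIResult with prescribed IPCA scores: gamma_in = s_in / sqrt(lam_n)."""
    scores = np.asarray(scores, dtype=float)
    g, k = scores.shape
    gamma = scores / np.sqrt(lam)
    idx = [f"g{i}" for i in range(g)]
    return AMMIResult(
        mu=0.0,
        g=pd.Series(np.zeros(g), index=idx),
        e=pd.Series(np.zeros(3), index=list("xyz")),
        lam=np.asarray(lam, dtype=float),
        gamma=pd.DataFrame(gamma, index=idx),
        delta=pd.DataFrame(np.zeros((3, k)), index=list("xyz")),
        var_fraction=np.ones(k) / k,
        interaction_ss=float((np.asarray(lam) ** 2).sum()),
    )


def test_asv_pythagorean_toy():
    # equal component SS -> weight 1; scores (3,4) -> ASV 5
    res = _toy_result([[3.0, 4.0], [0.0, 0.0]], lam=[2.0, 2.0])
    out = ammi_stability(res, 2)
    assert out.loc["g0", "ASV"] == pytest.approx(5.0, abs=1e-12)
    assert out.loc["g1", "ASV"] == 0.0  # null-interaction genotype: maximally stable
    assert out.loc["g0", "SPC"] == pytest.approx(7.0)


def test_asv_degenerate_second_component_flagged():
    res = _toy_result([[3.0, 0.0], [1.0, 0.0]], lam=[2.0, 0.0])
    out = ammi_stability(res, 1)
    assert out.attrs["asv_degenerate"]
    assert out.loc["g0", "ASV"] == pytest.approx(3.0)


def test_asv_ranking_matches_independent_svd_oracle(rng):
    tab = make_two_way(rng, g=10, e=4, interaction_scale=1.5)
    res = ammi_decompose(tab)
    out = ammi_stability(res, 2)
    # independent recomputation from numpy SVD of the double-centered table
    Y = tab.values
    Z = Y - Y.mean() - (Y.mean(1) - Y.mean())[:, None] - (Y.mean(0) - Y.mean())[None, :]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    s1, s2 = u[:, 0] * np.sqrt(s[0]), u[:, 1] * np.sqrt(s[1])
    asv = np.sqrt(((s[0] ** 2 / s[1] ** 2) * s1) ** 2 + s2**2)
    assert list(np.argsort(out["ASV"].to_numpy())) == list(np.argsort(asv))
    np.testing.assert_allclose(np.sort(out["ASV"]), np.sort(asv), rtol=1e-8)


def test_asv_scale_equivariance_and_env_permutation_invariance(rng):
    # IPCA scores are lam^0.5 * gamma, so rescaling the table by c scales
    # every index by sqrt(c): rankings (the quantity that drives selection)
    # are unchanged
    tab = make_two_way(rng, g=8, e=5)
    base = ammi_stability(ammi_decompose(tab), 2)
    c = 3.7
    scaled = TwoWayTable(tab.values * c, tab.genotype_ids, tab.env_ids)
    out = ammi_stability(ammi_decompose(scaled), 2)
    np.testing.assert_allclose(out["ASV"], base["ASV"] * np.sqrt(c), rtol=1e-8)
    np.testing.assert_allclose(out["SPC"], base["SPC"] * np.sqrt(c), rtol=1e-8)
    assert list(out["ASV"].rank()) == list(base["ASV"].rank())

    perm = rng.permutation(tab.n_envs)
    permuted = TwoWayTable(
        tab.values[:, perm], tab.genotype_ids, [tab.env_ids[j] for j in perm]
    )
    pout = ammi_stability(ammi_decompose(permuted), 2)
    np.testing.assert_allclose(pout["ASV"], base["ASV"], rtol=1e-8)
    pfw = fw_fit(permuted)
    bfw = fw_fit(tab)
    np.testing.assert_allclose(pfw.slope_dev, bfw.slope_dev, rtol=1e-8)


# ---------------------------------------------------------------------- #
# Finlay-Wilkinson
# ---------------------------------------------------------------------- #
def test_fw_recovers_generating_slopes_exactly(rng):
    g, e = 12, 6
    gi = rng.normal(0, 1, g)
    h = rng.normal(0, 1.5, e); h -= h.mean()
    b = rng.normal(0, 0.4, g); b -= b.mean()  # identifiable FW slopes sum to g
    vals = 8.0 + gi[:, None] + np.outer(1.0 + b, h)
    tab = TwoWayTable(vals, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)])
    fw = fw_fit(tab)
    np.testing.assert_allclose(fw.slope_dev.to_numpy(), b - 0.0, atol=1e-9)
    np.testing.assert_allclose(fw.env_effects.to_numpy(), h, atol=1e-9)


def test_fw_mean_slope_deviation_zero_on_complete_table(rng):
    tab = make_two_way(rng, g=20, e=8, interaction_scale=2.0)
    fw = fw_fit(tab)
    assert abs(fw.slope_dev.mean()) < 1e-10
    assert abs(fw.env_effects.mean()) < 1e-10


def test_fw_flat_response_flagged_non_responsive(rng):
    g, e = 5, 4
    h = np.array([-2.0, -1.0, 1.0, 2.0])
    vals = 4.0 + np.arange(g)[:, None] + np.outer(np.ones(g), h)
    vals[2] = 6.0  # constant response across environments
    tab = TwoWayTable(vals, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)])
    fw = fw_fit(tab)
    assert fw.slope_dev.iloc[2] == pytest.approx(-1.0, abs=1e-10)
    assert fw.non_responsive.iloc[2]
    assert not fw.non_responsive.drop(fw.non_responsive.index[2]).any()


def test_fw_errors_without_environment_variance():
    tab = TwoWayTable(np.tile([[1.0], [2.0], [3.0]], (1, 3)), list("abc"), list("xyz"))
    with pytest.raises(ValueError, match="zero variance"):
        fw_fit(tab)


def test_fw_slopes_track_first_pc_scores_when_delta_proportional_to_h(rng):
    # bilinear-only interaction whose environment scores are proportional to
    # the environment effects: the FW slope deviations then recover the
    # first-PC genotype scores up to scale
    g, e = 15, 6
    gi = rng.normal(0, 1, g)
    h = rng.normal(0, 1.5, e); h -= h.mean()
    gamma1 = rng.normal(0, 1, g); gamma1 -= gamma1.mean(); gamma1 /= np.linalg.norm(gamma1)
    delta1 = h / np.linalg.norm(h)
    lam = 4.0
    vals = 12.0 + gi[:, None] + h[None, :] + lam * np.outer(gamma1, delta1)
    tab = TwoWayTable(vals, [f"g{i}" for i in range(g)], [f"e{j}" for j in range(e)])
    fw = fw_fit(tab)
    res = ammi_decompose(tab)
    score1 = res.gamma.to_numpy()[:, 0]
    r = np.corrcoef(fw.slope_dev.to_numpy(), score1)[0, 1]
    assert abs(r) > 0.999


def test_stability_table_combines_indices(rng):
    tab = make_two_way(rng)
    res = ammi_decompose(tab)
    out = stability_table(ammi_stability(res, 2), fw_fit(tab), trait="YIELD")
    assert set(out.columns) >= {"SPC", "ASV", "fw_slope_dev", "fw_abs_slope", "rank_ASV", "rank_FW"}
    assert sorted(out["rank_ASV"]) == list(range(1, len(out) + 1))
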