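import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from doceeg.layout import make_layout
from doceeg.stats import (
    art_anova,
    cluster_perm,
    compare_proportions,
    hedges_g,
    lattice_adjacency,
    mann_whitney_z,
    pair_adjacency,
    rank_effect_r,
    spatiotemporal_adjacency,
    welch_t,
    wilcoxon_signed_rank,
)

CHAIN3 = np.array(
    [[False, True, False], [True, False, True], [False, True, False]]
)


def brute_force_cluster_p(a, b):
    """Exhaustive oracle: all C(8,4) relabelings, scipy Welch t first step."""

    def clusters(ga, gb):
        t, p = sst.ttest_ind(ga, gb, equal_var=False)
        supra = p < 0.05
        out = []
        for sign in (1, -1):
            act = supra & ((t > 0) if sign > 0 else (t < 0))
            i = 0
            while i < len(t):
                if act[i]:
                    j = i
                    while j + 1 < len(t) and act[j + 1]:
                        j += 1
                    mem = list(range(i, j + 1))
                    out.append((mem, t[mem].sum()))
                    i = j + 1
                else:
                    i += 1
        return out

    pooled = np.vstack([a, b])
    obs = clusters(a, b)
    nulls = []
    for idx in itertools.combinations(range(8), 4):
        sel = np.zeros(8, bool)
        sel[list(idx)] = True
        nulls.append(
            max((abs(m) for _, m in clusters(pooled[sel], pooled[~sel])), default=0.0)
        )
    nulls = np.array(nulls)
    return {
        tuple(mem): (mass, (nulls >= abs(mass) - 1e-9).sum() / len(nulls))
        for mem, mass in obs
    }


@pytest.mark.parametrize("seed", [0, 1, 5])
def test_exact_enumeration_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.9, 1.0, (4, 3))
    b = rng.normal(0.0, 1.0, (4, 3))
    res = cluster_perm(a, b, CHAIN3, "welch_t", exact=True)
    oracle = brute_force_cluster_p(a, b)
    assert len(res.clusters) == len(oracle)
    for c in res.clusters:
        mass, p = oracle[tuple(c.members.tolist())]
        assert np.isclose(c.mass, mass)
        assert c.p_value == p


def test_planted_contiguous_effect_recovered():
    rng = np.random.default_rng(2)
    layout = make_layout(20, "ring", "k-nearest", k=2)
    a = rng.normal(0, 1, (10, 20))
    b = rng.normal(0, 1, (10, 20))
    a[:, 2:12] += 2.5  # broad effect on 10 contiguous ring channels
    res = cluster_perm(a, b, layout.adjacency, "welch_t", n_perm=500, seed=0)
    sig = res.significant()
    assert sig
    members = set(sig[0].members.tolist())
    assert len(members & set(range(2, 12))) >= 8


def test_cluster_mass_equals_member_stat_sum():
    rng = np.random.default_rng(3)
    a = rng.normal(0.8, 1, (8, 6))
    b = rng.normal(0, 1, (8, 6))
    adj = make_layout(6, "ring", "k-nearest", k=2).adjacency
    res = cluster_perm(a, b, adj, "welch_t", n_perm=200, seed=1)
    for c in res.clusters:
        assert np.isclose(c.mass, res.stat[c.members].sum(), atol=1e-9)
        assert 0 < c.p_value <= 1


def test_paired_mode_detects_within_subject_shift():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, (12, 6))
    post = base + rng.normal(0, 0.3, (12, 6))
    post[:, :3] += 1.0
    adj = make_layout(6, "ring", "k-nearest", k=2).adjacency
    res = cluster_perm(post, base, adj, "dependent_t", paired=True, n_perm=500, seed=2)
    assert res.min_p < 0.05
    assert set(res.significant()[0].members.tolist()) <= {0, 1, 2, 3, 4, 5}


def test_monotone_in_planted_amplitude():
    adj = make_layout(8, "ring", "k-nearest", k=2).adjacency
    rng = np.random.default_rng(5)
    base_a = rng.normal(0, 1, (10, 8))
    base_b = rng.normal(0, 1, (10, 8))
    pvals = []
    for amp in [0.5, 1.0, 1.5, 2.0, 2.5]:
        a = base_a.copy()
        a[:, 2:6] += amp
        res = cluster_perm(a, base_b, adj, "welch_t", n_perm=300, seed=9)
        pvals.append(res.min_p)
    assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(pvals, pvals[1:]))


def test_mismatched_adjacency_rejected():
    with pytest.raises(ValueError):
        cluster_perm(np.zeros((3, 4)), np.zeros((3, 4)), CHAIN3, "welch_t")


def test_first_step_stats_match_scipy():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, (9, 5))
    b = rng.normal(0.5, 2, (7, 5))
    t, p = welch_t(a, b)
    t_ref, p_ref = sst.ttest_ind(a, b, equal_var=False)
    assert np.allclose(t, t_ref) and np.allclose(p, p_ref)
    z, _ = mann_whitney_z(a, b)
    for col in range(5):
        u_ref = sst.mannwhitneyu(a[:, col], b[:, col], method="asymptotic")
        # same U -> same |z| (scipy reports p from the same normal approx)
        z_ref = sst.norm.isf(u_ref.pvalue / 2)
        assert np.isclose(abs(z[col]), z_ref, atol=0.06)


# --- pair adjacency --------------------------------------------------------


def test_pair_adjacency_ring4_hand_enumeration():
    layout = make_layout(4, "ring", "k-nearest", k=2)
    pairs, adj = pair_adjacency(layout)
    assert pairs == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    idx = {p: i for i, p in enumerate(pairs)}
    dense = adj.toarray()
    assert np.array_equal(dense, dense.T)
    assert not np.any(np.diag(dense))
    # (0,1) and (1,2): share electrode 1; 0 and 2 are not ring-neighbors
    assert not dense[idx[(0, 1)], idx[(1, 2)]]
    # (0,1) and (0,3): share 0; 1 and 3 are not neighbors
    assert not dense[idx[(0, 1)], idx[(0, 3)]]
    # (0,1) and (1,3)... no wait: (0,1) and (0,2) share 0; 1~2 neighbors
    assert dense[idx[(0, 1)], idx[(0, 2)]]
    # disjoint (0,1) and (2,3): 0~3 and 1~2 -> neighbors
    assert dense[idx[(0, 1)], idx[(2, 3)]]


def test_spatiotemporal_and_lattice_adjacency_shapes():
    layout = make_layout(5, "ring", "k-nearest", k=2)
    st_adj = spatiotemporal_adjacency(layout, 7)
    assert st_adj.shape == (35, 35)
    # channel 0 at t=3 touches t=2, t=4 and both ring neighbors at t=3
    row = st_adj[3].toarray().ravel()
    assert row[2] and row[4]
    assert row[1 * 7 + 3] and row[4 * 7 + 3]
    lat = lattice_adjacency((4, 5))
    assert lat.shape == (20, 20)
    assert lat.sum() == 2 * (3 * 5 + 4 * 4)


# --- effect sizes ----------------------------------------------------------


def test_hedges_g_hand_computed_value():
    a = np.array([0.0, 0.0, 1.0, 1.0])
    b = np.array([1.0, 1.0, 2.0, 2.0])
    # pooled sd = sqrt(1/3), J = 1 - 3/23
    expected = (1 - 3 / 23) * (-1.0) / np.sqrt(1 / 3)
    es = hedges_g(a, b, n_boot=0)
    assert np.isclose(es.value, expected)
    assert np.isclose(hedges_g(b, a, n_boot=0).value, -expected)


def test_hedges_g_bootstrap_ci_brackets_value():
    rng = np.random.default_rng(0)
    a = rng.normal(1.0, 1, 30)
    b = rng.normal(0.0, 1, 30)
    es = hedges_g(a, b, n_boot=500, seed=1)
    assert es.ci_low < es.value < es.ci_high


def test_hedges_g_zero_pooled_sd_undefined():
    with pytest.raises(ValueError):
        hedges_g(np.ones(4), np.ones(4), n_boot=0)


def test_rank_effect_r_arithmetic():
    assert rank_effect_r(3.0, 36).value == pytest.approx(0.5)
    assert rank_effect_r(0.0, 10).value == 0.0


def test_wilcoxon_exact_small_sample_matches_enumeration():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([0.2, 1.1, 2.5, 2.9, 4.4, 4.8])
    z, p = wilcoxon_signed_rank(x, y)
    # exact null: all 2^6 sign patterns of the |d| ranks
    d = x - y
    ranks = sst.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=6):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_exact = min(1.0, 2 * min((ws >= w_obs).mean(), (ws <= w_obs).mean()))
    assert p == pytest.approx(p_exact)
    assert z > 0  # x systematically exceeds y


# --- ART ANOVA -------------------------------------------------------------


def test_art_anova_pure_interaction_design():
    rng = np.random.default_rng(7)
    rows = []
    for g, group in enumerate(["R-", "R+"]):
        for s in range(20):
            sid = f"{group}{s}"
            for w, session in enumerate(["pre", "post"]):
                val = (1.0 if (g + w) % 2 == 0 else -1.0) + rng.normal(0, 0.7)
                rows.append(
                    {"subject": sid, "group": group, "session": session, "value": val}
                )
    res = art_anova(pd.DataFrame(rows))
    assert res["interaction"]["p"] < 0.05
    assert res["between"]["p"] > 0.05
    assert res["within"]["p"] > 0.05
    assert res["interaction"]["df1"] == 1 and res["interaction"]["df2"] == 38


def test_art_anova_constant_data_no_effect():
    rows = [
        {"subject": f"{g}{s}", "group": g, "session": w, "value": 1.0}
        for g in "AB"
        for s in range(4)
        for w in ["pre", "post"]
    ]
    res = art_anova(pd.DataFrame(rows))
    for eff in res.values():
        assert not (eff["p"] < 0.05)


def test_art_anova_requires_full_design():
    rows = [
        {"subject": f"A{s}", "group": "A", "session": "pre", "value": 1.0}
        for s in range(4)
    ]
    with pytest.raises(ValueError):
        art_anova(pd.DataFrame(rows))


# --- proportions -----------------------------------------------------------


def test_equal_proportions_chi2_floored_at_zero():
    chi2, df, p = compare_proportions(5, 10, 5, 10)
    assert chi2 == 0.0 and df == 1 and p == 1.0


def test_proportion_test_validates_input():
    with pytest.raises(ValueError):
        compare_proportions(5, 4, 1, 10)
    with pytest.raises(ValueError):
        compare_proportions(0, 10, 0, 10)
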