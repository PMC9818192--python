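"""Cohort statistics: BH against the step-up definition, exact Mann-Whitney
against pairwise-comparison enumeration, KL divergence, the level transform,
Ward-D2 clustering, PCA, PD-like detection and target filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy import stats as sps

from mirnaeditome.core import EditingMatrix
from mirnaeditome.stats import (
    age_correlation,
    bh_adjust,
    cluster_samples,
    consistent_targets,
    differential_editing,
    exact_mannwhitney,
    find_pd_like,
    kl_type_divergence,
    pca_samples,
    transform_levels,
)


def _brute_force_bh(p):
    """Step-up definition: sort ascending, adjusted_(i) = min_{j>=i} m*p_(j)/j,
    capped at 1, returned in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_bh_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.2]), [0.2])
    assert np.allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])
    assert bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        bh_adjust([1.5])


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_bh_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, size=rng.integers(1, 40))
    assert np.max(np.abs(bh_adjust(p) - _brute_force_bh(p))) < 1e-12


def _oracle_mw(x, y):
    """Independent enumeration using pairwise comparisons for U."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx_a):
        a = [pooled[i] for i in idx_a]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx_a)]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in a for yi in b)

    mu = n1 * len(y) / 2.0
    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    assignments = list(combinations(range(len(pooled)), n1))
    hits = sum(abs(u_of(a) - mu) >= dev - 1e-12 for a in assignments)
    return u_obs, hits / len(assignments)


def test_exact_mannwhitney_examples():
    u, p = exact_mannwhitney([1, 2, 3], [4, 5, 6])
    assert u == 0 and p == pytest.approx(0.1)
    u, p = exact_mannwhitney([1, 1, 1], [1, 1, 1])
    assert p == 1.0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 6), st.integers(1, 6))
def test_exact_mannwhitney_matches_enumeration(seed, n1, n2):
    rng = np.random.default_rng(seed)
    # integer values induce ties regularly
    x = rng.integers(0, 6, size=n1).astype(float)
    y = rng.integers(0, 6, size=n2).astype(float)
    u, p = exact_mannwhitney(x, y)
    u_ref, p_ref = _oracle_mw(x, y)
    assert u == pytest.approx(u_ref)
    assert p == pytest.approx(p_ref)


def _matrix(levels, groups, ages=None):
    samples = [f"s{i}" for i in range(levels.shape[1])]
    meta = pd.DataFrame(
        {
            "group": groups,
            "age": ages if ages is not None else [70.0] * len(samples),
        },
        index=samples,
    )
    lv = pd.DataFrame(
        levels, index=[f"site{i}" for i in range(levels.shape[0])], columns=samples
    )
    return EditingMatrix(lv, meta)


def test_differential_editing_direction_and_symmetry():
    levels = np.array([[0.1, 0.12, 0.11, 0.3, 0.32, 0.31]])
    m = _matrix(levels, ["a"] * 3 + ["b"] * 3)
    res_ab = differential_editing(m, "a", "b")
    res_ba = differential_editing(m, "b", "a")
    assert res_ab.direction.iloc[0] == "decreased"
    assert res_ba.direction.iloc[0] == "increased"
    assert res_ab.raw_p.iloc[0] == pytest.approx(res_ba.raw_p.iloc[0])
    assert 0 <= res_ab.U.iloc[0] <= 9
    with pytest.raises(ValueError):
        differential_editing(m, "a", "missing")


def test_differential_asymptotic_branch_matches_scipy():
    rng = np.random.default_rng(4)
    levels = rng.uniform(0, 1, size=(3, 24))
    m = _matrix(levels, ["a"] * 12 + ["b"] * 12)
    res = differential_editing(m, "a", "b")
    for i in range(3):
        ref = sps.mannwhitneyu(
            levels[i, :12], levels[i, 12:], alternative="two-sided", method="asymptotic"
        )
        assert res.raw_p.iloc[i] == pytest.approx(float(ref.pvalue))


def test_age_correlation_perfect_monotone_and_oracle():
    ages = [60.0, 70.0, 80.0, 90.0]
    increasing = np.array([[0.1, 0.2, 0.3, 0.4]])
    m = _matrix(increasing, ["g"] * 4, ages)
    res = age_correlation(m, "g", method="spearman")
    assert res.rho.iloc[0] == pytest.approx(1.0)
    # rank-correlation oracle: ages [60,70,80,90], levels [0.1,0.2,0.15,0.3]
    m2 = _matrix(np.array([[0.1, 0.2, 0.15, 0.3]]), ["g"] * 4, ages)
    res2 = age_correlation(m2, "g", method="spearman")
    assert res2.rho.iloc[0] == pytest.approx(0.8)  # pearson of ranks [1,3,2,4]
    # constant level: undefined rho reported with p = 1
    m3 = _matrix(np.array([[0.2, 0.2, 0.2, 0.2]]), ["g"] * 4, ages)
    res3 = age_correlation(m3, "g")
    assert np.isnan(res3.rho.iloc[0]) and res3.raw_p.iloc[0] == 1.0
    with pytest.raises(ValueError, match=">= 3"):
        age_correlation(_matrix(np.ones((1, 2)) * 0.1, ["g", "g"], [60, 70]), "g")
    with pytest.raises(ValueError, match="method"):
        age_correlation(m, "g", method="kendall")


def test_age_correlation_pearson_variant():
    ages = [60.0, 65.0, 75.0, 88.0]
    y = np.array([[0.1, 0.12, 0.2, 0.28]])
    m = _matrix(y, ["g"] * 4, ages)
    res = age_correlation(m, "g", method="pearson")
    assert res.rho.iloc[0] == pytest.approx(np.corrcoef(ages, y[0])[0, 1])


def test_kl_divergence_values_and_properties():
    assert kl_type_divergence({"a": 3, "b": 7}, {"a": 3, "b": 7}) == pytest.approx(0.0)
    # hand evaluation on already-normalized inputs with pseudocount 0
    expected = 0.5 * np.log2(2.0) + 0.5 * np.log2(2.0 / 3.0)
    got = kl_type_divergence({"a": 0.5, "b": 0.5}, {"a": 0.25, "b": 0.75}, pseudocount=0.0)
    assert got == pytest.approx(expected)
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = {t: int(c) for t, c in zip("abcd", rng.integers(0, 50, 4))}
        q = {t: int(c) for t, c in zip("abcd", rng.integers(0, 50, 4))}
        assert kl_type_divergence(p, q) >= 0.0
    with pytest.raises(ValueError):
        kl_type_divergence({}, {})
    with pytest.raises(ValueError):
        kl_type_divergence({"a": 1}, {"b": 1})


def test_transform_levels_endpoints_and_monotonicity():
    m = _matrix(np.array([[0.0, 0.5, 1.0]]), ["g"] * 3)
    t = transform_levels(m).levels.to_numpy()[0]
    assert t[0] == 0.0
    assert t[2] == pytest.approx(np.log2(101.0))
    assert t[0] < t[1] < t[2]


def _two_group_levels(rng, n_sites=50, n_a=10, n_b=10, shift=0.3, sd=0.02):
    # the group effect must change profile *shape* (random sign per site);
    # a uniform offset is invisible to correlation distance
    base = rng.uniform(0.15, 0.55, size=n_sites)
    signed = shift * rng.choice([-1.0, 1.0], size=n_sites)
    a = base[:, None] + rng.normal(0, sd, size=(n_sites, n_a))
    b = (base + signed)[:, None] + rng.normal(0, sd, size=(n_sites, n_b))
    return np.clip(np.concatenate([a, b], axis=1), 0, 1)


def test_cluster_recovers_groups_and_is_order_invariant():
    rng = np.random.default_rng(12)
    levels = _two_group_levels(rng)
    m = transform_levels(_matrix(levels, ["a"] * 10 + ["b"] * 10))
    res = cluster_samples(m, k=2)
    labels = res.labels
    ga = {labels[f"s{i}"] for i in range(10)}
    gb = {labels[f"s{i}"] for i in range(10, 20)}
    assert len(ga) == 1 and len(gb) == 1 and ga != gb
    # permuting the sample columns leaves the flat clustering unchanged
    perm = list(rng.permutation(m.samples))
    m_perm = EditingMatrix(m.levels[perm], m.metadata.loc[perm])
    res_perm = cluster_samples(m_perm, k=2)
    assert res_perm.labels.sort_index().equals(labels.sort_index())
    assert res.to_newick().endswith(";")


def test_cluster_duplicates_merge_first_and_zero_variance_errors():
    rng = np.random.default_rng(5)
    profile = rng.uniform(0, 1, size=8)
    levels = np.column_stack([profile, profile, rng.uniform(0, 1, size=8)])
    m = _matrix(levels, ["g"] * 3)
    res = cluster_samples(m, k=2)
    assert res.labels["s0"] == res.labels["s1"] != res.labels["s2"]
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)
    levels[:, 2] = 0.4  # constant sample
    with pytest.raises(ValueError, match="s2"):
        cluster_samples(_matrix(levels, ["g"] * 3))


def test_pca_properties():
    rng = np.random.default_rng(9)
    levels = _two_group_levels(rng)
    m = transform_levels(_matrix(levels, ["a"] * 10 + ["b"] * 10))
    res = pca_samples(m)
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
    pc1 = res.scores["PC1"]
    a, b = pc1.iloc[:10], pc1.iloc[10:]
    pooled_sd = np.sqrt((a.var() + b.var()) / 2)
    assert abs(a.mean() - b.mean()) > 3 * pooled_sd
    # duplicated samples get identical scores
    dup = np.column_stack([levels[:, 0], levels[:, 0], levels[:, 5]])
    res2 = pca_samples(_matrix(dup, ["g"] * 3))
    assert np.allclose(res2.scores.iloc[0], res2.scores.iloc[1], atol=1e-9)
    with pytest.raises(ValueError):
        pca_samples(_matrix(np.full((3, 4), 0.2), ["g"] * 4))


def test_find_pd_like():
    labels = pd.Series({"c1": 1, "c2": 1, "c3": 1, "n1": 2, "n2": 2, "n3": 1})
    groups = {"c1": "case", "c2": "case", "c3": "case", "n1": "ctl", "n2": "ctl", "n3": "ctl"}
    assert find_pd_like(labels, groups, "case", "ctl") == ["n3"]
    clean = pd.Series({"c1": 1, "c2": 1, "n1": 2, "n2": 2})
    assert find_pd_like(clean, groups, "case", "ctl") == []
    with pytest.raises(ValueError, match="no samples labeled"):
        find_pd_like(labels, groups, "nope", "ctl")
    tie = pd.Series({"c1": 1, "c2": 2, "n1": 1})
    with pytest.raises(ValueError, match="tie"):
        find_pd_like(tie, groups, "case", "ctl")


def test_consistent_targets_rules():
    table = {"G1": "down", "G2": "up", "G3": "unchanged"}
    assert consistent_targets("up", table) == ["G1"]
    assert consistent_targets("down", table) == ["G2"]
    assert consistent_targets("up", {}) == []
    with pytest.raises(ValueError):
        consistent_targets("sideways", table)
    with pytest.raises(ValueError):
        consistent_targets("up", {"G": "wat"})
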