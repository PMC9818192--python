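"""Cohort-level statistics over an editing matrix.

Age correlation (rank-based by default, with the t-approximation p-value),
two-sided Mann-Whitney differential editing (exact by enumeration for small
groups), Benjamini-Hochberg correction, Kullback-Leibler divergence of
editing-type compositions, the log2(100*level + 1) transform, correlation-
distance Ward-D2 clustering, centered PCA, detection of control samples that
cluster with cases, and direction-consistent target filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import EditingMatrix


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Age correlation


def _rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p from the t-approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    if np.isnan(rho) or n < 3:
        return 1.0
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def age_correlation(
    matrix: EditingMatrix, group: str, method: str = "spearman", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-site correlation between editing level and age within one group.

    ``method`` is "spearman" (rank-based, the default) or "pearson". Sites
    with a constant level across the group get an undefined rho and p = 1.
    BH correction is applied across sites within the group.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method}")
    samples = [
        s for s in matrix.group_samples(group) if pd.notna(matrix.metadata.loc[s, "age"])
    ]
    if len(samples) < 3:
        raise ValueError(f"need >= 3 aged samples in group {group}")
    ages = matrix.metadata.loc[samples, "age"].to_numpy(dtype=float)
    rows = []
    for site in matrix.sites:
        y = matrix.levels.loc[site, samples].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(ages) == 0:
            rho, p = np.nan, 1.0
        elif method == "spearman":
            rho = _rank_correlation(ages, y)
            p = _correlation_pvalue(rho, len(samples))
        else:
            rho = float(np.corrcoef(ages, y)[0, 1])
            p = _correlation_pvalue(rho, len(samples))
        rows.append({"site": site, "rho": rho, "raw_p": p, "n": len(samples)})
    df = pd.DataFrame(rows)
    df["corrected_p"] = bh_adjust(df["raw_p"].to_numpy())
    df["significant"] = df["corrected_p"] < alpha
    df["method"] = method
    return df


# ---------------------------------------------------------------------------
# Differential editing


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x (midrank tie handling)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def exact_mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration of group assignments.

    p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) over all C(n1+n2, n1)
    re-assignments of the pooled values; ties enter through midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
        total += 1
    return float(u_obs), hits / total


def differential_editing(
    matrix: EditingMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per site between two groups.

    Exact enumeration when both groups have <= ``exact_max_n`` samples, else
    the normal approximation with tie and continuity corrections. Direction
    is the sign of mean(group_a) - mean(group_b) ("increased" means higher in
    group_a). BH correction across sites.
    """
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    if not sa or not sb:
        raise ValueError("both groups must be non-empty")
    rows = []
    for site in matrix.sites:
        x = matrix.levels.loc[site, sa].to_numpy(dtype=float)
        y = matrix.levels.loc[site, sb].to_numpy(dtype=float)
        if len(x) <= exact_max_n and len(y) <= exact_max_n:
            u, p = exact_mannwhitney(x, y)
        else:
            res = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            u, p = float(res.statistic), float(res.pvalue)
        diff = x.mean() - y.mean()
        direction = "increased" if diff > 0 else ("decreased" if diff < 0 else "unchanged")
        rows.append(
            {
                "site": site,
                "n_a": len(x),
                "n_b": len(y),
                "U": u,
                "raw_p": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    df["corrected_p"] = bh_adjust(df["raw_p"].to_numpy())
    df["significant"] = df["corrected_p"] < alpha
    return df


# ---------------------------------------------------------------------------
# Type-composition divergence


def kl_type_divergence(
    counts_p: Mapping[str, float],
    counts_q: Mapping[str, float],
    pseudocount: float = 0.5,
    base: float = 2.0,
) -> float:
    """D(P || Q) over editing-type compositions, in bits by default.

    Both count vectors are smoothed with ``pseudocount`` per type and
    normalized. The type universes must coincide and every smoothed count
    must be positive.
    """
    types = sorted(counts_p)
    if not types:
        raise ValueError("empty type universe")
    if sorted(counts_q) != types:
        raise ValueError("type universes differ")
    p = np.array([counts_p[t] for t in types], dtype=float) + pseudocount
    q = np.array([counts_q[t] for t in types], dtype=float) + pseudocount
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("counts plus pseudocount must be positive")
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)) / np.log(base))


# ---------------------------------------------------------------------------
# Transform / clustering / PCA


def transform_levels(matrix: EditingMatrix) -> EditingMatrix:
    """Variance-stabilizing display transform: level -> log2(100*level + 1)."""
    return EditingMatrix(np.log2(100.0 * matrix.levels + 1.0), matrix.metadata.copy())


@dataclass
class ClusterResult:
    linkage: np.ndarray
    sample_order: list[str]  # canonical (sorted) order used for the linkage
    labels: pd.Series  # sample -> flat cluster id (1..k)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.sample_order[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def cluster_samples(matrix: EditingMatrix, k: int = 2) -> ClusterResult:
    """Ward-D2 hierarchical clustering of samples.

    Distance is 1 - Pearson correlation between sample level profiles.
    Samples are ordered canonically (sorted ids) before linkage so the flat
    clustering is invariant to input order.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    order = sorted(matrix.samples)
    X = matrix.levels[order].to_numpy(dtype=float)
    sds = X.std(axis=0)
    scale = max(1.0, float(np.abs(X).max()))
    for sid, sd in zip(order, sds):
        if sd <= 1e-12 * scale:
            raise ValueError(f"sample {sid} has zero variance; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(Z, order, pd.Series(flat, index=order))


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # sites x components


def pca_samples(matrix: EditingMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of samples over site columns: centered (not scaled), via SVD.

    Component signs are fixed so each component's largest-magnitude loading
    is positive; explained-variance fractions sum to 1.
    """
    if len(matrix.samples) < 2 or len(matrix.sites) < 2:
        raise ValueError("need >= 2 samples and >= 2 sites")
    X = matrix.levels.T.to_numpy(dtype=float)  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("all-constant matrix: PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or len(S)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for j in range(len(S)):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    var = S**2
    total_var = (X**2).sum()
    ratio = var / total_var
    cols = [f"PC{j + 1}" for j in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=cols),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(Vt.T, index=matrix.sites, columns=cols),
    )


def find_pd_like(
    labels: pd.Series,
    groups: Mapping[str, str],
    case_label: str,
    control_label: str,
) -> list[str]:
    """Control samples that fall in the case-majority flat cluster.

    ``labels`` maps sample -> cluster id (from cluster_samples at k=2). Raises
    on a tie for the case-majority cluster or when no case samples exist.
    """
    case_samples = [s for s in labels.index if groups.get(s) == case_label]
    if not case_samples:
        raise ValueError(f"no samples labeled {case_label}: no case-majority cluster")
    counts = labels.loc[case_samples].value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        raise ValueError("tie in case majority; use a different k or resolve manually")
    majority = counts.index[0]
    return sorted(
        s
        for s in labels.index
        if groups.get(s) == control_label and labels[s] == majority
    )


def consistent_targets(
    mirna_direction: str, target_table: Mapping[str, str]
) -> list[str]:
    """Keep targets whose expression moves opposite to the edited miRNA.

    An up-regulated (in cases) edited miRNA keeps targets that are down in
    cases, and vice versa; unchanged targets are dropped.
    """
    if mirna_direction not in ("up", "down"):
        raise ValueError(f"unknown miRNA direction: {mirna_direction}")
    wanted = "down" if mirna_direction == "up" else "up"
    out = []
    for gene, direction in target_table.items():
        if direction not in ("up", "down", "unchanged"):
            raise ValueError(f"unknown direction token {direction!r} for {gene}")
        if direction == wanted:
            out.append(gene)
    return sorted(out)
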