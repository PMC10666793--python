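"""Turnover-environment statistics: Euclidean environmental distances,
seeded Spearman Mantel tests, turnover-vs-alpha correlations, and the
ANOVA + compact-letter-display comparison used for stage contrasts.

The Mantel test correlates the off-diagonal entries of two distance
matrices with Spearman's rank correlation and assesses it by jointly
permuting the rows/columns of the second matrix; the p-value is
``(1 + #{r_perm >= r_obs}) / (permutations + 1)`` (one-sided "greater"
by default, the convention of vegan-style ecological software).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io import ParameterError

__all__ = [
    "env_distance",
    "MantelResult",
    "mantel",
    "turnover_alpha_correlation",
    "AnovaLetters",
    "anova_letters",
]


def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (sample sd); constant columns are dropped
    with a warning."""
    df = df.astype(float)
    sds = df.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=3)
        df = df.drop(columns=constant)
        sds = sds.drop(constant)
    return (df - df.mean()) / sds


def env_distance(env_block: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance over Z-scored environmental columns."""
    if len(env_block) < 2:
        raise ParameterError("need at least 2 samples for a distance matrix")
    z = zscore_columns(env_block)
    if z.shape[1] == 0:
        raise ParameterError("no non-constant environmental columns")
    return DistanceMatrix(squareform(pdist(z.to_numpy())), ids=[str(i) for i in env_block.index])


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Spearman Mantel test between two distance matrices.

    Rows/columns of ``d2`` are permuted jointly.  Since a joint
    relabeling only permutes the condensed entries, ranks are computed
    once and the permutation loop reduces to index shuffling.
    """
    if list(d1.ids) != list(d2.ids):
        raise ParameterError("distance matrices must share ids and order")
    n = d1.shape[0]
    if n < 4:
        raise ParameterError("Mantel test needs at least 4 samples")
    if alternative not in ("greater", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")

    v1 = squareform(d1.data, checks=False)
    v2 = squareform(d2.data, checks=False)
    r1 = stats.rankdata(v1)
    r2 = stats.rankdata(v2)
    r_obs = _pearson(r1, r2)

    if permutations <= 0:
        return MantelResult(float(r_obs), float("nan"), 0)

    rng = np.random.default_rng(seed)
    # square matrix of d2's condensed ranks, for joint-relabeling lookup
    R2 = squareform(r2, checks=False)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r2p = squareform(R2[np.ix_(perm, perm)], checks=False)
        r_perm = _pearson(r1, r2p)
        if alternative == "greater":
            hits += r_perm >= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p = (1 + hits) / (permutations + 1)
    return MantelResult(float(r_obs), float(p), permutations)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def turnover_alpha_correlation(turnover_ratios, alpha_values):
    """Spearman correlation of turnover ratio with alpha diversity.

    Pairs where either value is NaN (e.g. undefined turnover ratio) are
    dropped first; needs at least 5 complete pairs.
    """
    t = np.asarray(turnover_ratios, dtype=float)
    a = np.asarray(alpha_values, dtype=float)
    if t.shape != a.shape:
        raise ParameterError("paired vectors differ in length")
    keep = np.isfinite(t) & np.isfinite(a)
    if keep.sum() < 5:
        raise ParameterError("fewer than 5 complete pairs")
    rho, p = stats.spearmanr(t[keep], a[keep])
    return float(rho), float(p)


def screen_env_variables(
    target_dm: DistanceMatrix,
    env_block: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-variable Mantel screening against one target distance matrix.

    Each environmental column is turned into its own single-variable
    Euclidean distance matrix (after Z-scoring) and Mantel-tested
    against ``target_dm``; returns a table ranked by |r|.
    """
    rows = []
    for col in env_block.columns:
        sub = env_block[[col]]
        if sub[col].std(ddof=1) == 0 or sub[col].isna().any():
            continue
        res = mantel(target_dm, env_distance(sub), permutations=permutations,
                     seed=seed)
        rows.append({"variable": col, "r": res.r, "p": res.p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ParameterError("no usable environmental columns")
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class AnovaLetters:
    f_statistic: float
    p_value: float
    group_means: dict
    letters: dict  # group -> letter string, 'a' on the largest mean


def anova_letters(values, group_labels, alpha: float = 0.05) -> AnovaLetters:
    """One-way ANOVA with Tukey-HSD compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``;
    letters are assigned in order of decreasing group mean ('a' first).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) < 3:
        raise ParameterError("need at least 3 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ParameterError("every group needs at least 2 observations")
    f_stat, p_val = stats.f_oneway(*samples)

    means = {g: float(np.mean(s)) for g, s in zip(groups, samples)}
    order = sorted(groups, key=lambda g: -means[g])

    if all(np.allclose(s, s[0]) for s in samples) and len({s[0] for s in samples}) == 1:
        nonsig = {(g, h) for g in groups for h in groups}
    else:
        hsd = stats.tukey_hsd(*samples)
        nonsig = set()
        for i, g in enumerate(groups):
            for j, h in enumerate(groups):
                if i != j and hsd.pvalue[i, j] >= alpha:
                    nonsig.add((g, h))

    letters = _compact_letters(order, nonsig)
    return AnovaLetters(float(f_stat), float(p_val), means, letters)


def _compact_letters(order, nonsig) -> dict:
    """Maximal cliques of the not-significantly-different graph, lettered
    by their highest-ranked member; reconstructs the pairwise
    significance pattern exactly."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(order)
    g.add_edges_from((a, b) for (a, b) in nonsig if a != b)
    cliques = list(nx.find_cliques(g))
    rank = {grp: i for i, grp in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[m] for m in c))
    letters = {grp: "" for grp in order}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for member in sorted(clique, key=lambda m: rank[m]):
            letters[member] += letter
    return letters
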