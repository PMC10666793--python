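"""Alpha and beta diversity, and the Sorensen turnover/nestedness partition.

Alpha indices: Shannon H' (natural log), observed richness, Pielou
evenness J = H'/ln(S_obs), and Faith's phylogenetic diversity (PD,
rooted: the path to the root is included by default).  Beta metrics:
Bray-Curtis, weighted UniFrac (raw by default, normalised by flag), and
the presence-based Sorensen dissimilarity partitioned into its turnover
(Simpson, beta_sim) and nestedness (beta_nes) components::

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_nes = beta_sor - beta_sim

with a = shared species, b and c = species unique to either sample.
beta_sim / beta_sor is the turnover ratio: the fraction of dissimilarity
attributable to species replacement rather than richness difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.beta import weighted_unifrac as _skbio_weighted_unifrac
from skbio.stats.distance import DistanceMatrix

from .io import FeatureTable, ParameterError, SampleFrame, check_tree_covers

__all__ = [
    "shannon",
    "richness",
    "pielou",
    "faith_pd",
    "bray_curtis",
    "weighted_unifrac",
    "BetaPartition",
    "sorensen_partition",
    "alpha_table",
    "beta_matrix",
    "pairwise_beta",
]


def _clean(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ParameterError("abundance vector must be 1-D")
    if (x < 0).any():
        raise ParameterError("abundances must be non-negative")
    if x.sum() <= 0:
        raise ParameterError("abundance vector sums to zero")
    return x


def shannon(abundances) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (natural log)."""
    x = _clean(abundances)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def richness(abundances) -> int:
    """Observed richness: number of taxa with abundance > 0."""
    x = _clean(abundances)
    return int((x > 0).sum())


def pielou(abundances) -> float:
    """Pielou evenness J = H'/ln(S_obs); NaN when only one taxon is present."""
    x = _clean(abundances)
    s = richness(x)
    if s < 2:
        return float("nan")
    return shannon(x) / np.log(s)


def faith_pd(abundances, taxon_ids, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's PD: total branch length of the minimal subtree spanning
    the observed taxa.

    With ``include_root`` (the common default of mainstream
    implementations) the path from the crown group to the root counts;
    without it only the crown subtree is summed.
    """
    x = _clean(abundances)
    if len(x) != len(taxon_ids):
        raise ParameterError("abundances and taxon_ids differ in length")
    observed = [t for t, v in zip(taxon_ids, x) if v > 0]
    check_tree_covers(tree, observed)
    if include_root:
        return float(_skbio_faith_pd(x, taxon_ids, tree, validate=False))
    obs = set(observed)
    n_obs = len(obs)
    total = 0.0
    counts = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            counts[id(node)] = 1 if node.name in obs else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
        below = counts[id(node)]
        if 0 < below < n_obs:
            total += node.length or 0.0
    return float(total)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    xv, yv = _clean(x), _clean(y)
    if len(xv) != len(yv):
        raise ParameterError("vectors differ in length")
    return float(braycurtis(xv, yv))


def weighted_unifrac(x, y, taxon_ids, tree: TreeNode, normalized: bool = False) -> float:
    """Weighted UniFrac between two abundance vectors.

    Raw form (default): sum over edges of b_e * |P_e(x) - P_e(y)| where
    P_e is the fraction of a sample's abundance descending from edge e.
    The normalised form divides by sum b_e * (P_e(x) + P_e(y)) and lies
    in [0, 1].
    """
    xv, yv = _clean(x), _clean(y)
    if len(xv) != len(yv) or len(xv) != len(taxon_ids):
        raise ParameterError("vectors and taxon_ids differ in length")
    present = [t for t, u, v in zip(taxon_ids, xv, yv) if u > 0 or v > 0]
    check_tree_covers(tree, present)
    return float(
        _skbio_weighted_unifrac(xv, yv, taxon_ids, tree, normalized=normalized,
                                validate=False)
    )


@dataclass(frozen=True)
class BetaPartition:
    """Sorensen partition for one sample pair."""

    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_nes: float
    turnover_ratio: float  # NaN when beta_sor == 0


def sorensen_partition(presence_x, presence_y) -> BetaPartition:
    """Partition Sorensen dissimilarity into turnover and nestedness."""
    px = np.asarray(presence_x, dtype=bool)
    py = np.asarray(presence_y, dtype=bool)
    if px.shape != py.shape:
        raise ParameterError("presence vectors differ in length")
    if not px.any() or not py.any():
        raise ParameterError("each sample must contain at least one taxon")
    a = int((px & py).sum())
    b = int((px & ~py).sum())
    c = int((~px & py).sum())
    beta_sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    beta_nes = beta_sor - beta_sim
    ratio = beta_sim / beta_sor if beta_sor > 0 else float("nan")
    return BetaPartition(a, b, c, beta_sor, beta_sim, beta_nes, ratio)


def alpha_table(table: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity: H', richness, Pielou J, and (given a
    tree) Faith PD."""
    rows = {}
    taxa = table.taxon_ids
    for sid, vec in zip(table.sample_ids, table.counts):
        row = {
            "shannon": shannon(vec),
            "richness": richness(vec),
            "pielou": pielou(vec),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(vec, taxa, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def beta_matrix(
    table: FeatureTable,
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """All-pairs dissimilarity matrix for one metric."""
    X = table.counts
    n = len(X)
    ids = [str(s) for s in table.sample_ids]
    out = np.zeros((n, n))
    if metric == "bray_curtis":
        from scipy.spatial.distance import pdist, squareform

        out = squareform(pdist(X, metric="braycurtis"))
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ParameterError("weighted_unifrac needs a tree")
        taxa = table.taxon_ids
        check_tree_covers(tree, [t for t, tot in zip(taxa, X.sum(0)) if tot > 0])
        for i in range(n):
            for j in range(i + 1, n):
                d = _skbio_weighted_unifrac(
                    X[i], X[j], taxa, tree, normalized=normalized, validate=False
                )
                out[i, j] = out[j, i] = d
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    return DistanceMatrix(out, ids=ids)


def _pairs_for_scale(meta: SampleFrame, scale: str):
    """Yield (sample_i, sample_j, stage, distance_km) for one scale.

    Local pairs are the parallel replicates sharing site (hence local
    area) and stage; continental pairs share stage but sit at different
    sites.
    """
    df = meta.data
    if scale == "local":
        for (site, stage), cell in df.groupby(["site", "stage"], observed=True):
            ids = cell.index.tolist()
            if len(ids) < 2:
                warnings.warn(
                    f"stage {stage} at {site} has <2 samples; skipped at local scale",
                    stacklevel=3,
                )
                continue
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    d = abs(cell["x_km"].iloc[i] - cell["x_km"].iloc[j])
                    yield ids[i], ids[j], stage, float(d)
    elif scale == "continental":
        for stage, cell in df.groupby("stage", observed=True):
            ids = cell.index.tolist()
            sites = cell["site"].tolist()
            xs = cell["x_km"].tolist()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if sites[i] == sites[j]:
                        continue
                    yield ids[i], ids[j], stage, float(abs(xs[i] - xs[j]))
    else:
        raise ParameterError(f"unknown scale {scale!r}")


def pairwise_beta(
    table: FeatureTable,
    meta: SampleFrame,
    metric: str = "bray_curtis",
    scale: str = "local",
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> pd.DataFrame:
    """Long-format pairwise beta diversity at one spatial scale.

    One row per qualifying pair with columns ``sample_i, sample_j,
    stage, scale, distance_km`` plus either ``value`` (abundance
    metrics) or the partition columns ``beta_sor, beta_sim, beta_nes,
    turnover_ratio``.
    """
    meta = meta.aligned_to(table)
    data = table.data
    if metric in ("bray_curtis", "weighted_unifrac"):
        dm = beta_matrix(table, metric=metric, tree=tree, normalized=normalized)
        lookup = {s: i for i, s in enumerate(dm.ids)}
    elif metric != "sorensen_partition":
        raise ParameterError(f"unknown metric {metric!r}")

    records = []
    for si, sj, stage, dist in _pairs_for_scale(meta, scale):
        rec = {
            "sample_i": si,
            "sample_j": sj,
            "stage": stage,
            "scale": scale,
            "distance_km": dist,
        }
        if metric == "sorensen_partition":
            part = sorensen_partition(
                data.loc[si].to_numpy() > 0, data.loc[sj].to_numpy() > 0
            )
            rec.update(
                beta_sor=part.beta_sor,
                beta_sim=part.beta_sim,
                beta_nes=part.beta_nes,
                turnover_ratio=part.turnover_ratio,
            )
        else:
            rec["value"] = dm.data[lookup[str(si)], lookup[str(sj)]]
        records.append(rec)
    return pd.DataFrame(records)
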