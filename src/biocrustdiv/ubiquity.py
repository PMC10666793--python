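"""Ubiquitous taxa, cumulative-abundance phylogeny filtering, and the
edge-length abundance distribution (ELAD).

Ubiquitous taxa are species present (abundance > 0) in strictly more
than a given fraction of samples (default 85%) within a scope — a
single successional stage or the whole metacommunity.  The ELAD relates
each edge of a community's (pruned) phylogeny to the abundance (or tip
count) descending from it; its cumulative ranked curve has an elbow
whose position summarises how branch length is distributed over rare vs
abundant lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import FeatureTable, ParameterError, SampleFrame, check_tree_covers, to_proportions

__all__ = [
    "UbiquitousSet",
    "ubiquitous_taxa",
    "alpha_vs_ubiquitous",
    "cumulative_abundance_filter",
    "EladCurve",
    "elad",
]


@dataclass(frozen=True)
class UbiquitousSet:
    taxa: tuple
    scope: str
    threshold: float
    #: per-sample summed relative abundance of the set (index = sample ids)
    abundance: pd.Series


def ubiquitous_taxa(
    table: FeatureTable,
    meta: SampleFrame | None = None,
    threshold: float = 0.85,
    scope: str = "metacommunity",
) -> UbiquitousSet:
    """Taxa occupying strictly more than ``threshold`` of the scope's
    samples, with their per-sample summed relative abundance.

    ``scope`` is ``"metacommunity"`` or one of the stage labels (then
    ``meta`` is required to select the stage's samples).
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    if scope == "metacommunity":
        sub = table
    else:
        if meta is None:
            raise ParameterError("stage-scoped selection needs metadata")
        meta = meta.aligned_to(table)
        ids = meta.data.index[meta.data["stage"] == scope].tolist()
        if not ids:
            raise ParameterError(f"no samples in scope {scope!r}")
        sub = table.filter_samples(ids)
    presence = sub.data.to_numpy() > 0
    occupancy = presence.mean(axis=0)
    members = [t for t, occ in zip(sub.taxon_ids, occupancy) if occ > threshold]
    props = to_proportions(sub)
    abundance = props.data[members].sum(axis=1) if members else pd.Series(
        0.0, index=sub.sample_ids
    )
    return UbiquitousSet(tuple(members), scope, threshold, abundance)


def alpha_vs_ubiquitous(ubiq: UbiquitousSet, alpha_values: pd.Series) -> dict:
    """Relationship of an alpha-diversity index with the per-sample
    ubiquitous-taxa abundance.

    Reports the Spearman correlation plus a saturating (piecewise-linear,
    one-breakpoint) fit whose breakpoint estimates where alpha stops
    responding to ubiquitous-taxa abundance.
    """
    x = ubiq.abundance
    y = alpha_values.reindex(x.index)
    keep = x.notna() & y.notna()
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    if len(x) < 5:
        raise ParameterError("fewer than 5 complete pairs")
    rho, p = stats.spearmanr(x, y)
    bp, sse = _best_breakpoint(x, y)
    return {"rho": float(rho), "p": float(p), "breakpoint": bp, "sse": sse}


def _best_breakpoint(x: np.ndarray, y: np.ndarray):
    """Grid search for the elbow of a continuous piecewise-linear fit
    y = a + b*min(x, c) (slope 0 after the breakpoint c)."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    lo, hi = np.quantile(xs, [0.1, 0.9])
    best = (float("nan"), float("inf"))
    for c in np.linspace(lo, hi, 81):
        design = np.column_stack([np.ones_like(xs), np.minimum(xs, c)])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        sse = float(((design @ coef - ys) ** 2).sum())
        if sse < best[1]:
            best = (float(c), sse)
    return best


def cumulative_abundance_filter(table: FeatureTable, fraction: float = 0.85) -> list:
    """Most-abundant taxa jointly covering at least ``fraction`` of total
    relative abundance.

    Taxa are ranked by total relative abundance (descending, ties broken
    by taxon id) and the smallest prefix whose cumulative share reaches
    ``fraction`` is retained.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    props = to_proportions(table)
    totals = props.data.sum(axis=0)
    totals = totals / totals.sum()
    ranked = totals.sort_values(ascending=False, kind="mergesort")
    # stable sort on descending value; break exact ties by taxon id
    ranked = ranked.iloc[
        np.lexsort((ranked.index.astype(str), -ranked.to_numpy()))
    ]
    cum = ranked.cumsum()
    # smallest prefix with cumulative share >= fraction
    k = int(np.searchsorted(cum.to_numpy(), fraction - 1e-12) + 1)
    k = min(k, len(ranked))
    return ranked.index[:k].tolist()


@dataclass(frozen=True)
class EladCurve:
    """Edge-length abundance distribution of one community phylogeny."""

    #: per-edge records: descendant abundance A_e and branch length b_e
    edges: pd.DataFrame
    #: log2-spaced abundance bins -> total branch length
    binned: pd.DataFrame
    #: cumulative branch length over edges ranked by ascending A_e
    cumulative: pd.DataFrame
    mode: str
    #: abundance rank fraction of the cumulative curve's elbow
    #: (max distance-to-chord point)
    elbow: float

    @property
    def total_length(self) -> float:
        return float(self.edges["length"].sum())


def elad(tree: TreeNode, community_abundances: pd.Series, mode: str = "abundance") -> EladCurve:
    """Edge-length abundance distribution for one community.

    Tips absent from the community (abundance 0 or missing) are pruned
    first, so the curve describes the community's own phylogeny.  In
    ``abundance`` mode A_e is the summed relative abundance below the
    edge; in ``tip_count`` mode it is the number of descendant tips.
    """
    if mode not in ("abundance", "tip_count"):
        raise ParameterError(f"unknown mode {mode!r}")
    present = community_abundances[community_abundances > 0]
    if present.empty:
        raise ParameterError("community has no taxa present")
    check_tree_covers(tree, present.index)
    pruned = tree.shear(list(present.index.astype(str)))
    props = present / present.sum()

    records = []
    acc: dict[int, float] = {}
    for node in pruned.postorder(include_self=False):
        if node.is_tip():
            acc[id(node)] = float(props[node.name]) if mode == "abundance" else 1.0
        else:
            acc[id(node)] = sum(acc[id(c)] for c in node.children)
        records.append({"abundance": acc[id(node)], "length": float(node.length or 0.0)})
    edges = pd.DataFrame(records)

    binned = _log2_bins(edges)
    ranked = edges.sort_values("abundance", kind="mergesort").reset_index(drop=True)
    ranked["cum_length"] = ranked["length"].cumsum()
    elbow = _elbow_rank_fraction(ranked["cum_length"].to_numpy())
    cumulative = ranked[["abundance", "cum_length"]]
    return EladCurve(edges, binned, cumulative, mode, elbow)


def _log2_bins(edges: pd.DataFrame) -> pd.DataFrame:
    a = edges["abundance"].to_numpy()
    lo = np.floor(np.log2(a.min()))
    hi = np.ceil(np.log2(a.max()))
    if hi <= lo:
        hi = lo + 1
    bounds = 2.0 ** np.arange(lo, hi + 1)
    idx = np.clip(np.searchsorted(bounds, a, side="left"), 1, len(bounds) - 1)
    out = pd.DataFrame({
        "bin_low": bounds[idx - 1],
        "bin_high": bounds[idx],
        "length": edges["length"].to_numpy(),
    })
    return (
        out.groupby(["bin_low", "bin_high"], as_index=False)["length"].sum()
    )


def _elbow_rank_fraction(cum_length: np.ndarray) -> float:
    """Elbow of the cumulative curve: the point with maximum perpendicular
    distance to the chord joining its endpoints, as a rank fraction."""
    n = len(cum_length)
    if n < 3:
        return float("nan")
    x = np.linspace(0.0, 1.0, n)
    y = cum_length / cum_length[-1]
    chord = y[0] + (y[-1] - y[0]) * x
    return float(x[int(np.argmax(np.abs(y - chord)))])
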