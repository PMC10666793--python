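"""Balanced-biogeography analysis: ANOSIM over randomized sample
combinations under two grouping schemes, regression of community
difference against geographic distance, and the intersection distance
where successional convergence and distance decay balance.

For each pair of sites possessing all three successional stages, the
same samples are grouped two ways: *among_stages* (three stage groups,
each pooling both sites) and *between_sites* (two site groups, each
pooling all stages).  Community difference is ANOSIM's R computed on
many random sample subsets ("combinational comparisons"); regressing R
on inter-site distance gives one falling line (stage separation fades
with distance as within-stage scatter grows) and one rising line
(site separation grows by distance decay).  Their crossing distance d*
marks where distance decay overtakes successional convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .diversity import beta_matrix
from .io import FeatureTable, ParameterError, SampleFrame, STAGES

__all__ = [
    "AnosimResult",
    "anosim",
    "enumerate_site_pairs",
    "combination_anosim",
    "RegressionLine",
    "distance_regression",
    "IntersectionResult",
    "intersection_distance",
]

SCHEMES = ("among_stages", "between_sites")


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    n_samples: int


def anosim(
    d: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean rank of between-group distances - mean rank of
    within-group distances) / (M/2), with M = n(n-1)/2 pairwise
    distances ranked with midrank ties.  R is 1 when every
    between-group distance exceeds every within-group distance and has
    null expectation 0.  The p-value comes from permuting group labels:
    p = (1 + #{R_perm >= R_obs}) / (permutations + 1).
    """
    labels = np.asarray(groups)
    n = d.shape[0]
    if len(labels) != n:
        raise ParameterError("grouping length does not match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ParameterError("need >=2 groups with >=2 members each")

    from scipy.spatial.distance import squareform

    ranks = stats.rankdata(squareform(d.data, checks=False))
    iu, ju = np.triu_indices(n, k=1)
    r_obs = _anosim_r(ranks, labels[iu] == labels[ju])
    if permutations <= 0:
        return AnosimResult(float(r_obs), float("nan"), 0, n)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        hits += _anosim_r(ranks, perm[iu] == perm[ju]) >= r_obs
    p = (1 + hits) / (permutations + 1)
    return AnosimResult(float(r_obs), float(p), permutations, n)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    n_within = int(within.sum())
    if n_within == 0 or n_within == m:
        raise ParameterError("degenerate grouping: no within- or between-group pairs")
    sum_within = ranks[within].sum()
    mean_within = sum_within / n_within
    mean_between = (ranks.sum() - sum_within) / (m - n_within)
    return (mean_between - mean_within) / (m / 2.0)


def enumerate_site_pairs(meta: SampleFrame, min_per_cell: int = 2) -> pd.DataFrame:
    """All pairs of sites that both possess every successional stage
    with at least ``min_per_cell`` samples, with their distances."""
    df = meta.data
    ok_sites = []
    for site, sub in df.groupby("site", observed=True):
        counts = sub.groupby("stage", observed=True).size()
        if all(counts.get(s, 0) >= min_per_cell for s in STAGES):
            ok_sites.append((site, float(sub["x_km"].iloc[0])))
    rows = []
    for i in range(len(ok_sites)):
        for j in range(i + 1, len(ok_sites)):
            (a, xa), (b, xb) = ok_sites[i], ok_sites[j]
            rows.append({"site_a": a, "site_b": b, "distance_km": abs(xa - xb)})
    return pd.DataFrame(rows)


def combination_anosim(
    source,
    meta: SampleFrame,
    site_pair: tuple,
    scheme: str = "both",
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    n_combinations: int = 100,
    subset_sizes: tuple = (4, 6, 8, 10, 12),
    permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Randomized combinational ANOSIM comparisons for one site pair.

    ``source`` is either a :class:`FeatureTable` (distances are computed
    with ``metric``) or a precomputed :class:`DistanceMatrix`.  For each
    of ``n_combinations`` draws a per-group subset size is drawn
    uniformly from ``subset_sizes`` (capped by group availability, never
    below 2), that many samples are drawn without replacement from every
    group, and ANOSIM is run on the subset.  Results carry the site-pair
    distance for the downstream regression.
    """
    if isinstance(source, FeatureTable):
        meta_aligned = meta.aligned_to(source)
        dm = beta_matrix(source, metric=metric, tree=tree)
    elif isinstance(source, DistanceMatrix):
        meta_aligned = meta
        dm = source
    else:
        raise ParameterError("source must be a FeatureTable or DistanceMatrix")
    schemes = SCHEMES if scheme == "both" else (scheme,)
    for s in schemes:
        if s not in SCHEMES:
            raise ParameterError(f"unknown scheme {s!r}")

    df = meta_aligned.data
    site_a, site_b = site_pair
    pool = df[df["site"].isin([site_a, site_b])]
    if pool.empty:
        raise ParameterError(f"no samples for site pair {site_pair}")
    distance = float(
        abs(pool.loc[pool["site"] == site_a, "x_km"].iloc[0]
            - pool.loc[pool["site"] == site_b, "x_km"].iloc[0])
    )
    id_pos = {sid: i for i, sid in enumerate(dm.ids)}

    rng = np.random.default_rng(seed)
    sizes = np.asarray(subset_sizes, dtype=int)
    if (sizes < 2).any():
        raise ParameterError("subset sizes must be >= 2")
    records = []
    for sch in schemes:
        key = "stage" if sch == "among_stages" else "site"
        group_ids = {
            g: sub.index.tolist() for g, sub in pool.groupby(key, observed=True)
        }
        smallest = min(len(v) for v in group_ids.values())
        if smallest < 2:
            short = [g for g, v in group_ids.items() if len(v) < 2]
            raise ParameterError(
                f"cells too small for scheme {sch!r} at {site_pair}: {short}"
            )
        for _ in range(n_combinations):
            k = int(min(rng.choice(sizes), smallest))
            chosen, labels = [], []
            for g, ids in group_ids.items():
                take = rng.choice(len(ids), size=k, replace=False)
                chosen.extend(ids[t] for t in take)
                labels.extend([g] * k)
            idx = [id_pos[str(s)] for s in chosen]
            sub_dm = DistanceMatrix(
                dm.data[np.ix_(idx, idx)], ids=[str(s) for s in chosen]
            )
            res = anosim(
                sub_dm, labels, permutations=permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            records.append({
                "scheme": sch,
                "site_a": site_a,
                "site_b": site_b,
                "distance_km": distance,
                "subset_size": k,
                "R": res.R,
                "p": res.p,
                "metric": metric,
            })
    return pd.DataFrame(records)


@dataclass(frozen=True)
class RegressionLine:
    scheme: str
    slope: float       # per km
    intercept: float
    r_squared: float   # fit of the line itself
    slope_p: float     # two-sided t-test of slope = 0
    n: int
    statistic: str


def distance_regression(results: pd.DataFrame, statistic: str = "R") -> dict:
    """Ordinary least squares of community difference on distance, one
    line per grouping scheme.

    ``statistic`` selects the response: ANOSIM's R (default — negative
    values survive) or its square.
    """
    if statistic not in ("R", "R_squared"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    lines = {}
    for scheme, sub in results.groupby("scheme"):
        x = sub["distance_km"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ParameterError(f"scheme {scheme!r} has <2 distinct distances")
        y = sub["R"].to_numpy(dtype=float)
        if statistic == "R_squared":
            y = y**2
        fit = stats.linregress(x, y)
        lines[scheme] = RegressionLine(
            scheme=scheme,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            slope_p=float(fit.pvalue),
            n=len(x),
            statistic=statistic,
        )
    return lines


@dataclass(frozen=True)
class IntersectionResult:
    d_km: float          # NaN when the configuration is not the balanced one
    valid: bool
    ci_low: float
    ci_high: float
    slope_among: float
    slope_between: float


def intersection_distance(
    line_among: RegressionLine,
    line_between: RegressionLine,
    results: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> IntersectionResult:
    """Crossing distance of the two scheme lines.

    d* = (intercept_among - intercept_between) / (slope_between -
    slope_among).  A crossing is only reported (``valid``) in the
    balanced configuration — among-stages slope significantly negative
    and between-sites slope significantly positive at ``alpha``.  A
    bootstrap interval over combination records is attached when the
    per-combination results are supplied.
    """
    ds = line_between.slope - line_among.slope
    if ds == 0:
        raise ParameterError("parallel lines have no intersection")
    d_star = (line_among.intercept - line_between.intercept) / ds
    valid = (
        line_among.slope < 0
        and line_between.slope > 0
        and line_among.slope_p < alpha
        and line_between.slope_p < alpha
    )

    ci_low = ci_high = float("nan")
    if valid and results is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        groups = {s: sub.reset_index(drop=True) for s, sub in results.groupby("scheme")}
        for _ in range(n_boot):
            resampled = []
            for s, sub in groups.items():
                take = rng.integers(0, len(sub), len(sub))
                resampled.append(sub.iloc[take])
            try:
                lines = distance_regression(
                    pd.concat(resampled, ignore_index=True),
                    statistic=line_among.statistic,
                )
                denom = lines["between_sites"].slope - lines["among_stages"].slope
                if denom != 0:
                    draws.append(
                        (lines["among_stages"].intercept
                         - lines["between_sites"].intercept) / denom
                    )
            except ParameterError:
                continue
        if draws:
            ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    return IntersectionResult(
        d_km=float(d_star) if valid else float("nan"),
        valid=bool(valid),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        slope_among=line_among.slope,
        slope_between=line_between.slope,
    )
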