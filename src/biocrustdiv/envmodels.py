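"""Environmental regulation of diversity.

Two complementary model families:

* **All-subset regression** — after greedy multicollinearity screening,
  every predictor subset (up to ``max_size``) is fitted by ordinary
  least squares; the subset with the highest goodness of fit (R^2) wins
  and GoF ties are broken by the lower AIC (Gaussian log-likelihood,
  constant included).
* **PLS path modelling** — latent variables (climatic, edaphic, biotic,
  integrated alpha, taxonomic beta, phylogenetic beta) measured by
  blocks of pairwise-distance indicators, estimated by Lohmoeller's
  alternating algorithm (mode A outer weights, centroid inner scheme).
  Indicators with |loading| < 0.7 are pruned iteratively and the GoF
  index sqrt(mean communality x mean R^2) summarises the final model.

Pairwise-distance observations are not independent, so PLS-PM paths are
reported without p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .io import ParameterError
from .turnover import zscore_columns

__all__ = [
    "filter_multicollinearity",
    "SubsetModel",
    "all_subset_regression",
    "residual_normality_check",
    "block_distances",
    "PLSPathModel",
    "PLSPathResults",
    "prune_paths",
]


def filter_multicollinearity(
    X: pd.DataFrame,
    r_threshold: float = 0.8,
    method: str = "pairwise",
    vif_threshold: float = 10.0,
) -> list:
    """Remove collinear predictors; returns the retained column names.

    ``method="pairwise"`` (default): while any pair has |Pearson r| >=
    ``r_threshold``, the member of the worst pair with the larger mean
    absolute correlation to the remaining predictors is dropped (column
    order breaks ties).  ``method="vif"``: iteratively drop the
    predictor with the largest variance inflation factor while it
    exceeds ``vif_threshold``.
    """
    if X.shape[1] < 2:
        return X.columns.tolist()
    if method == "vif":
        return _filter_vif(X, vif_threshold)
    if method != "pairwise":
        raise ParameterError(f"unknown method {method!r}")
    cols = list(X.columns)
    corr = X[cols].corr().abs()
    while len(cols) > 1:
        sub = corr.loc[cols, cols].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < r_threshold:
            break
        mean_i = sub[i].mean()
        mean_j = sub[j].mean()
        # prefer dropping the more globally collinear one; on a tie the
        # later column goes, keeping the earlier by declaration order
        drop = cols[j] if mean_j >= mean_i else cols[i]
        cols.remove(drop)
    return cols


def _filter_vif(X: pd.DataFrame, threshold: float) -> list:
    cols = list(X.columns)
    while len(cols) > 1:
        Z = ((X[cols] - X[cols].mean()) / X[cols].std(ddof=1)).to_numpy()
        vifs = []
        for k in range(len(cols)):
            others = np.delete(Z, k, axis=1)
            beta, *_ = np.linalg.lstsq(others, Z[:, k], rcond=None)
            rss = float(((Z[:, k] - others @ beta) ** 2).sum())
            tss = float((Z[:, k] ** 2).sum())
            r2 = 0.0 if tss == 0 else 1 - rss / tss
            vifs.append(1.0 / max(1 - r2, 1e-12))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        cols.pop(worst)
    return cols


@dataclass(frozen=True)
class SubsetModel:
    predictors: tuple
    coefficients: pd.Series  # includes "intercept"
    gof: float               # R^2
    adj_r2: float
    aic: float
    n: int


def _ols_stats(y: np.ndarray, X: np.ndarray):
    """OLS via normal equations; returns (beta, rss) or None if singular."""
    design = np.column_stack([np.ones(len(y)), X])
    gram = design.T @ design
    if np.linalg.cond(gram) > 1e12:
        return None
    beta = np.linalg.solve(gram, design.T @ y)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    # k counts the regression coefficients (incl. intercept) plus sigma^2
    sigma2 = max(rss / n, 1e-300)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    return float(2 * (n_coef + 1) - 2 * llf)


def all_subset_regression(
    y, X: pd.DataFrame, max_size: int | None = None, gof_tol: float = 1e-9
) -> SubsetModel:
    """Exhaustive best-subset OLS selection.

    Every non-empty predictor subset of size <= ``max_size`` is fitted;
    the highest-R^2 subset is selected, and subsets whose R^2 ties
    within ``gof_tol`` are separated by the lower AIC.
    """
    yv = np.asarray(y, dtype=float)
    cols = list(X.columns)
    p = len(cols)
    if max_size is None:
        max_size = p
    max_size = min(max_size, p)
    n = len(yv)
    if n <= max_size + 1:
        raise ParameterError("need n > max_size + 1 observations")
    Xv = X.to_numpy(dtype=float)
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise ParameterError("response is constant")

    best = None
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(range(p), size):
            fit = _ols_stats(yv, Xv[:, combo])
            if fit is None:
                warnings.warn(
                    f"singular design for subset {tuple(cols[i] for i in combo)}; skipped",
                    stacklevel=2,
                )
                continue
            beta, rss = fit
            r2 = 1.0 - rss / tss
            aic = _gaussian_aic(rss, n, len(combo) + 1)
            cand = (combo, beta, r2, aic)
            if best is None:
                best = cand
            else:
                _, _, br2, baic = best
                if r2 > br2 + gof_tol or (abs(r2 - br2) <= gof_tol and aic < baic):
                    best = cand
    if best is None:
        raise ParameterError("no non-singular subset found")
    combo, beta, r2, aic = best
    names = tuple(cols[i] for i in combo)
    k = len(combo)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    coef = pd.Series(beta, index=["intercept", *names])
    return SubsetModel(names, coef, float(r2), float(adj), float(aic), n)


def residual_normality_check(residuals, alpha: float = 0.05) -> dict:
    """Skewness/kurtosis diagnostic for OLS residuals (reported as a
    flag, never used as a gate)."""
    r = np.asarray(residuals, dtype=float)
    skew_stat, skew_p = stats.skewtest(r)
    kurt_stat, kurt_p = stats.kurtosistest(r)
    return {
        "skewness": float(stats.skew(r)),
        "kurtosis": float(stats.kurtosis(r)),
        "skew_p": float(skew_p),
        "kurtosis_p": float(kurt_p),
        "acceptable": bool(skew_p >= alpha and kurt_p >= alpha),
    }


def _pair_index(ids) -> list:
    return [f"{a}|{b}" for a, b in itertools.combinations(ids, 2)]


def block_distances(
    frame=None,
    alpha: pd.DataFrame | None = None,
    beta_tax: pd.DataFrame | None = None,
    beta_phylo: pd.DataFrame | None = None,
    per_variable: bool = False,
    sample_ids=None,
) -> dict:
    """Indicator blocks for the path model: aligned lower-triangle
    pairwise-distance vectors.

    Environmental blocks and the integrated-alpha block (PD, richness,
    Pielou) are Z-scored then Euclidean; taxonomic/phylogenetic beta
    indicators are Bray-Curtis / weighted-UniFrac pair values supplied
    as square DataFrames.  With ``per_variable`` each raw variable
    contributes its own single-column distance indicator; otherwise one
    block-level distance per block.
    """
    blocks: dict[str, pd.DataFrame] = {}
    ids = None

    def _euclid_block(df: pd.DataFrame, name: str):
        z = zscore_columns(df)
        if per_variable:
            return pd.DataFrame(
                {c: pdist(z[[c]].to_numpy()) for c in z.columns},
                index=_pair_index(df.index),
            )
        return pd.DataFrame(
            {name: pdist(z.to_numpy())}, index=_pair_index(df.index)
        )

    if frame is not None:
        for name in frame.blocks:
            df = frame.env_block(name)
            blocks[name] = _euclid_block(df, name)
            ids = list(df.index)
    if alpha is not None:
        cols = [c for c in ("faith_pd", "richness", "pielou") if c in alpha.columns]
        if len(cols) < 2:
            raise ParameterError("integrated alpha needs PD, richness and Pielou")
        blocks["alpha"] = _euclid_block(alpha[cols], "alpha")
        ids = ids or list(alpha.index)
    for name, dm in (("beta_tax", beta_tax), ("beta_phylo", beta_phylo)):
        if dm is None:
            continue
        order = sample_ids or ids or list(dm.index)
        sq = dm.loc[order, order].to_numpy()
        blocks[name] = pd.DataFrame(
            {name: sq[np.triu_indices(len(order), k=1)]}, index=_pair_index(order)
        )
    if not blocks:
        raise ParameterError("no blocks supplied")
    ref = None
    for b in blocks.values():
        if ref is None:
            ref = list(b.index)
        elif list(b.index) != ref:
            raise ParameterError("blocks are not aligned on the same pair ordering")
    return blocks


#: canonical causal order for the biodiversity path model: environment
#: blocks are exogenous, beta diversity mediates, integrated alpha is
#: the final response.
DEFAULT_PATH_ORDER = ("climatic", "edaphic", "biotic", "beta_tax", "beta_phylo", "alpha")


def default_path_matrix(latents=DEFAULT_PATH_ORDER) -> pd.DataFrame:
    """Lower-triangular full path matrix: every latent receives a path
    from every latent preceding it in the causal order."""
    n = len(latents)
    m = np.tril(np.ones((n, n), dtype=int), k=-1)
    return pd.DataFrame(m, index=latents, columns=latents)


class PLSPathModel:
    """Partial-least-squares path model over indicator blocks.

    Parameters
    ----------
    blocks : dict of str -> DataFrame
        Indicator block per latent variable; rows aligned across blocks.
    path_matrix : DataFrame
        Square 0/1 matrix; ``path_matrix.loc[j, i] == 1`` means latent
        ``i`` -> latent ``j``.  Must be lower-triangular under its own
        ordering (acyclic).
    """

    def __init__(self, blocks: dict, path_matrix: pd.DataFrame | None = None):
        if not blocks:
            raise ParameterError("at least one block required")
        if path_matrix is None:
            path_matrix = default_path_matrix(tuple(blocks))
        latents = list(path_matrix.index)
        if list(path_matrix.columns) != latents:
            raise ParameterError("path matrix rows and columns must match")
        missing = [l for l in latents if l not in blocks]
        if missing:
            raise ParameterError(f"blocks missing for latents: {missing}")
        pm = path_matrix.to_numpy()
        if np.any(np.triu(pm) != 0):
            raise ParameterError("path matrix must be lower-triangular (acyclic)")
        self.latents = latents
        self.path_matrix = path_matrix.astype(int)
        self.blocks = {l: blocks[l].astype(float) for l in latents}
        lengths = {len(b) for b in self.blocks.values()}
        if len(lengths) != 1:
            raise ParameterError("blocks differ in number of observations")
        for name, b in self.blocks.items():
            if b.shape[1] == 0:
                raise ParameterError(f"block {name!r} has no indicators")

    def fit(self, tol: float = 1e-6, max_iter: int = 300) -> "PLSPathResults":
        """Lohmoeller alternating estimation (mode A, centroid scheme).

        The sign of each latent is fixed to correlate positively with
        its first indicator, making results deterministic.
        """
        Z = {l: zscore_columns(b).to_numpy() for l, b in self.blocks.items()}
        for name, z in Z.items():
            if z.shape[1] == 0:
                raise ParameterError(f"block {name!r} lost all indicators (constant)")
        n = len(next(iter(Z.values())))
        adj = self.path_matrix.to_numpy()
        neighbors = ((adj + adj.T) > 0)
        weights = {l: np.ones(Z[l].shape[1]) for l in self.latents}

        def scores(w):
            Y = np.column_stack([
                _standardize(Z[l] @ w[l]) for l in self.latents
            ])
            return Y

        def align(Y, w):
            # each latent positively correlated with its first indicator
            for k, l in enumerate(self.latents):
                if np.corrcoef(Z[l][:, 0], Y[:, k])[0, 1] < 0:
                    Y[:, k] *= -1
                    w[l] = -w[l]
            return Y, w

        Y, weights = align(scores(weights), weights)
        converged = len(self.latents) == 1  # nothing to iterate on
        for _ in range(max_iter):
            if converged:
                break
            C = np.atleast_2d(np.corrcoef(Y, rowvar=False))
            inner = np.where(neighbors, np.sign(C), 0.0)
            np.fill_diagonal(inner, 0.0)
            new_weights = {}
            for k, l in enumerate(self.latents):
                zk = _standardize(Y @ inner[k])
                new_weights[l] = Z[l].T @ zk / n  # mode A: cov(indicator, proxy)
            Y_new, new_weights = align(scores(new_weights), new_weights)
            delta = float(np.max(np.abs(Y_new - Y)))
            weights, Y = new_weights, Y_new
            if delta < tol:
                converged = True
        if not converged:
            raise ParameterError(
                f"PLS-PM failed to converge in {max_iter} iterations (delta={delta:.2e})"
            )

        loadings = {
            l: pd.Series(
                [np.corrcoef(Z[l][:, j], Y[:, k])[0, 1] for j in range(Z[l].shape[1])],
                index=self.blocks[l].columns,
            )
            for k, l in enumerate(self.latents)
        }
        paths = pd.DataFrame(
            0.0, index=self.latents, columns=self.latents
        )
        r2 = {}
        for k, l in enumerate(self.latents):
            preds = [m for m, flag in zip(self.latents, adj[k]) if flag]
            if not preds:
                continue
            idx = [self.latents.index(m) for m in preds]
            Xp = Y[:, idx]
            beta, *_ = np.linalg.lstsq(Xp, Y[:, k], rcond=None)
            paths.loc[l, preds] = beta
            fitted = Xp @ beta
            r2[l] = float(1.0 - ((Y[:, k] - fitted) ** 2).sum()
                          / ((Y[:, k] - Y[:, k].mean()) ** 2).sum())
        communality = {
            l: float((loadings[l] ** 2).mean()) for l in self.latents
        }
        gof = float(np.sqrt(np.mean(list(communality.values()))
                            * np.mean(list(r2.values())))) if r2 else float("nan")
        return PLSPathResults(
            model=self,
            scores=pd.DataFrame(Y, columns=self.latents,
                                index=next(iter(self.blocks.values())).index),
            outer_loadings=loadings,
            path_coefficients=paths,
            r_squared=r2,
            communality=communality,
            gof=gof,
        )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


@dataclass
class PLSPathResults:
    """Fitted path model: loadings, inner paths, per-equation R^2 and
    the GoF index sqrt(mean communality x mean R^2)."""

    model: PLSPathModel
    scores: pd.DataFrame
    outer_loadings: dict
    path_coefficients: pd.DataFrame
    r_squared: dict
    communality: dict
    gof: float
    pruning_log: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["PLS path model", "=" * 46]
        lines.append(f"GoF index: {self.gof:.4f}")
        lines.append("")
        lines.append("Outer loadings")
        for l, s in self.outer_loadings.items():
            for ind, v in s.items():
                lines.append(f"  {l:<12} {ind:<24} {v:+.4f}")
        lines.append("")
        lines.append("Inner paths (column -> row)   coef")
        pm = self.model.path_matrix
        for j in pm.index:
            for i in pm.columns:
                if pm.loc[j, i]:
                    lines.append(
                        f"  {i:<12} -> {j:<12} {self.path_coefficients.loc[j, i]:+.4f}"
                    )
        lines.append("")
        for l, v in self.r_squared.items():
            lines.append(f"  R^2[{l}] = {v:.4f}")
        if self.pruning_log:
            lines.append("")
            lines.append("Pruned indicators: " + ", ".join(
                f"{b}:{i}" for b, i in self.pruning_log))
        return "\n".join(lines)


def prune_paths(results: PLSPathResults, loading_threshold: float = 0.7,
                tol: float = 1e-6, max_iter: int = 300) -> PLSPathResults:
    """Iteratively drop indicators with |loading| below the threshold
    and refit; a block that empties takes its latent variable and paths
    with it.  Stops at a fixpoint where every surviving indicator loads
    at or above the threshold."""
    model = results.model
    blocks = {l: b.copy() for l, b in model.blocks.items()}
    pm = model.path_matrix.copy()
    log = list(results.pruning_log)
    current = results
    while True:
        weak = []
        for l, s in current.outer_loadings.items():
            for ind, v in s.items():
                if abs(v) < loading_threshold:
                    weak.append((l, ind, abs(v)))
        if not weak:
            current.pruning_log = log
            return current
        # drop the single weakest indicator, then refit
        l, ind, _ = min(weak, key=lambda t: t[2])
        blocks[l] = blocks[l].drop(columns=[ind])
        log.append((l, ind))
        if blocks[l].shape[1] == 0:
            del blocks[l]
            pm = pm.drop(index=l, columns=l)
            if pm.empty or not pm.to_numpy().any():
                raise ParameterError(
                    "pruning emptied the model: no structural paths remain"
                )
        current = PLSPathModel(blocks, pm).fit(tol=tol, max_iter=max_iter)
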