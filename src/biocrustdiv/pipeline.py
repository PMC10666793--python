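"""End-to-end orchestration: simulate or load the data, then run every
analysis stage and write TSV outputs plus a JSON summary.

Stage order: io/synthesis -> alpha/beta diversity -> Sorensen partition
-> turnover/Mantel -> ubiquitous taxa & ELAD -> biogeography
(combination ANOSIM, regression, intersection) -> environmental models
(all-subset regression, PLS path model).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

from . import biogeography as bg
from . import diversity as dv
from . import envmodels as em
from . import turnover as tv
from . import ubiquity as ub
from .io import (
    FeatureTable,
    ParameterError,
    SampleFrame,
    STAGES,
    read_feature_table,
    read_metadata,
    read_tree,
    write_feature_table,
    write_metadata,
    write_tree,
)
from .simulate import SimParams, simulate_metacommunity

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULT_THRESHOLDS = {
    "occupancy": 0.85,
    "cumulative": 0.85,
    "loading": 0.7,
    "permutations": 999,
    "combinations": 100,
}


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    Either ``synthetic`` maps domain name -> SimParams, or ``inputs``
    maps domain name -> dict of paths (table / metadata / block_map /
    tree / optional orientation).
    """

    outdir: str = "biocrustdiv_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    metrics: tuple = ("bray_curtis", "weighted_unifrac")

    def __post_init__(self):
        if not self.synthetic and not self.inputs:
            raise ParameterError("config needs a synthetic block or input paths")
        if self.synthetic and self.inputs:
            raise ParameterError("give either synthetic parameters or input paths")
        t = dict(DEFAULT_THRESHOLDS)
        t.update(self.thresholds)
        for key in ("occupancy", "cumulative", "loading"):
            if not 0 < t[key] <= 1:
                raise ParameterError(f"threshold {key} must be in (0, 1]")
        self.thresholds = t


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    synthetic = {}
    for name, params in (raw.get("synthetic") or {}).items():
        synthetic[name] = SimParams(**params)
    return PipelineConfig(
        outdir=raw.get("outdir", "biocrustdiv_out"),
        seed=int(raw["seed"]),
        synthetic=synthetic,
        inputs=raw.get("inputs") or {},
        thresholds=raw.get("thresholds") or {},
        metrics=tuple(raw.get("metrics", ("bray_curtis", "weighted_unifrac"))),
    )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "seed": config.seed,
            "synthetic": {k: vars(v) for k, v in config.synthetic.items()},
            "inputs": config.inputs,
            "thresholds": config.thresholds,
            "metrics": list(config.metrics),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_domain(name: str, config: PipelineConfig):
    if config.synthetic:
        params = config.synthetic[name]
        return simulate_metacommunity(params)
    paths = config.inputs[name]
    table = read_feature_table(paths["table"], orientation=paths.get("orientation", "samples"))
    meta = read_metadata(paths["metadata"], block_map=paths.get("block_map"))
    tree = read_tree(paths["tree"]) if paths.get("tree") else None
    return table, meta.aligned_to(table), tree


def _round(obj, nd=6):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), nd)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every domain; returns the JSON-ready summary.

    Outputs land under ``config.outdir``: per-stage TSVs, the inputs
    (when simulated), ``summary.json`` and ``run_log.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    domains = list(config.synthetic or config.inputs)
    thr = config.thresholds
    summary: dict = {"domains": {}}
    stage_name = "init"
    try:
        for di, name in enumerate(domains):
            dseed = config.seed * 1000 + di
            stage_name = f"load:{name}"
            table, meta, tree = _load_domain(name, config)
            ddir = out / name
            ddir.mkdir(exist_ok=True)
            if config.synthetic:
                write_feature_table(table, ddir / "feature_table.tsv")
                write_metadata(meta, ddir / "metadata.tsv", ddir / "block_map.yaml")
                if tree is not None:
                    write_tree(tree, ddir / "tree.nwk")
            summary["domains"][name] = _run_domain(
                name, table, meta, tree, ddir, thr, config.metrics, dseed
            )
            stage_name = f"done:{name}"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    summary = _round(summary)
    log = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "thresholds": thr,
        "domains": domains,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return summary


def _run_domain(name, table, meta, tree, ddir, thr, metrics, seed):
    res: dict = {}
    stages_present = [s for s in STAGES if (meta.data["stage"] == s).any()]

    # ---- alpha diversity -------------------------------------------------
    alpha = dv.alpha_table(table, tree)
    alpha.to_csv(ddir / "alpha.tsv", sep="\t", index_label="sample_id")
    stage_of = meta.data["stage"]
    res["alpha"] = {
        s: {c: float(alpha.loc[stage_of == s, c].mean()) for c in alpha.columns}
        for s in stages_present
    }
    if len(stages_present) == 3:
        letters = tv.anova_letters(alpha["shannon"].to_numpy(), stage_of.to_numpy())
        res["alpha_anova"] = {
            "F": letters.f_statistic,
            "p": letters.p_value,
            "letters": {str(k): v for k, v in letters.letters.items()},
        }

    # ---- beta diversity and the Sorensen partition ----------------------
    beta_frames = []
    res["beta"] = {}
    for metric in metrics:
        for scale in ("local", "continental"):
            pb = dv.pairwise_beta(table, meta, metric=metric, scale=scale, tree=tree)
            pb.insert(0, "metric", metric)
            beta_frames.append(pb)
            res["beta"].setdefault(metric, {})[scale] = {
                str(s): float(g["value"].mean())
                for s, g in pb.groupby("stage", observed=True)
            }
    part_frames = {}
    res["turnover_ratio"] = {}
    for scale in ("local", "continental"):
        part = dv.pairwise_beta(table, meta, metric="sorensen_partition", scale=scale)
        part.insert(0, "metric", "sorensen_partition")
        part_frames[scale] = part
        res["turnover_ratio"][scale] = {
            str(s): float(g["turnover_ratio"].mean())
            for s, g in part.groupby("stage", observed=True)
        }
    pd.concat(beta_frames + list(part_frames.values()), ignore_index=True).to_csv(
        ddir / "beta_pairs.tsv", sep="\t", index=False
    )

    # ---- turnover ratio vs alpha, and Mantel against environments -------
    part_c = part_frames["continental"]
    mean_alpha_pair = 0.5 * (
        alpha.loc[part_c["sample_i"], "shannon"].to_numpy()
        + alpha.loc[part_c["sample_j"], "shannon"].to_numpy()
    )
    rho, p = tv.turnover_alpha_correlation(
        part_c["turnover_ratio"].to_numpy(), mean_alpha_pair
    )
    res["turnover_vs_alpha"] = {"rho": rho, "p": p}

    mantel_rows = []
    for s in stages_present:
        ids = meta.data.index[stage_of == s].tolist()
        ratio_dm = _turnover_matrix(table, ids)
        for block in meta.blocks:
            env_dm = tv.env_distance(meta.env_block(block).loc[ids])
            mres = tv.mantel(
                ratio_dm, env_dm, permutations=thr["permutations"], seed=seed + 7
            )
            mantel_rows.append(
                {"stage": s, "block": block, "r": mres.r, "p": mres.p}
            )
    mantel_df = pd.DataFrame(mantel_rows)
    mantel_df.to_csv(ddir / "mantel_turnover_env.tsv", sep="\t", index=False)
    res["mantel_turnover_env"] = mantel_rows

    # ---- ubiquitous taxa and the ELAD ------------------------------------
    res["ubiquitous"] = {}
    for scope in [*stages_present, "metacommunity"]:
        uset = ub.ubiquitous_taxa(table, meta, threshold=thr["occupancy"], scope=scope)
        entry = {
            "n_taxa": len(uset.taxa),
            "mean_abundance": float(uset.abundance.mean()),
        }
        if len(uset.taxa) >= 1:
            try:
                rel = ub.alpha_vs_ubiquitous(uset, alpha["shannon"])
                entry["alpha_rho"] = rel["rho"]
                entry["alpha_breakpoint"] = rel["breakpoint"]
            except ParameterError:
                pass
        res["ubiquitous"][scope] = entry

    retained = ub.cumulative_abundance_filter(table, fraction=thr["cumulative"])
    res["phylogeny_filter"] = {
        "n_retained": len(retained),
        "n_total": len(table.taxon_ids),
    }
    if tree is not None:
        elad_rows = []
        from .io import to_proportions

        props = to_proportions(table)
        for s in stages_present:
            ids = meta.data.index[stage_of == s]
            mean_abund = props.data.loc[ids, retained].mean(axis=0)
            if (mean_abund > 0).sum() < 3:
                continue
            curve = ub.elad(tree, mean_abund)
            elad_rows.append(
                {
                    "stage": s,
                    "elbow": curve.elbow,
                    "total_branch_length": curve.total_length,
                    "n_edges": len(curve.edges),
                }
            )
        pd.DataFrame(elad_rows).to_csv(ddir / "elad.tsv", sep="\t", index=False)
        res["elad"] = elad_rows

    # ---- biogeography -----------------------------------------------------
    res["biogeography"] = {}
    site_pairs = bg.enumerate_site_pairs(meta)
    if len(site_pairs) >= 2:
        for mi, metric in enumerate(metrics):
            dm = dv.beta_matrix(table, metric=metric, tree=tree)
            combos = []
            for pi, row in site_pairs.iterrows():
                combos.append(
                    bg.combination_anosim(
                        dm,
                        meta,
                        (row["site_a"], row["site_b"]),
                        metric=metric,
                        n_combinations=thr["combinations"],
                        seed=seed * 10_000 + mi * 100 + pi,
                    )
                )
            combo_df = pd.concat(combos, ignore_index=True)
            combo_df.to_csv(ddir / f"combination_anosim_{metric}.tsv", sep="\t", index=False)
            lines = bg.distance_regression(combo_df)
            inter = bg.intersection_distance(
                lines["among_stages"],
                lines["between_sites"],
                results=combo_df,
                n_boot=200,
                seed=seed + 11,
            )
            res["biogeography"][metric] = {
                "slope_among": lines["among_stages"].slope,
                "slope_between": lines["between_sites"].slope,
                "intersection_km": inter.d_km,
                "valid": inter.valid,
                "ci_low": inter.ci_low,
                "ci_high": inter.ci_high,
            }

    # ---- environmental models --------------------------------------------
    res["env_models"] = _env_models(table, meta, tree, alpha, ddir, thr, metrics, stages_present)
    return res


def _turnover_matrix(table: FeatureTable, ids) -> DistanceMatrix:
    """Pairwise turnover-ratio matrix for one set of samples (NaN-free:
    identical pairs get ratio 0)."""
    presence = table.data.loc[ids].to_numpy() > 0
    n = len(ids)
    vals = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            part = dv.sorensen_partition(presence[i], presence[j])
            vals[k] = 0.0 if np.isnan(part.turnover_ratio) else part.turnover_ratio
            k += 1
    return DistanceMatrix(squareform(vals), ids=[str(i) for i in ids])


def _env_models(table, meta, tree, alpha, ddir, thr, metrics, stages_present):
    out: dict = {"all_subset": {}, "plspm": {}}
    stage_of = meta.data["stage"]
    subset_rows = []
    for s in stages_present:
        ids = meta.data.index[stage_of == s].tolist()
        out["all_subset"][str(s)] = {}
        for block in meta.blocks:
            X = meta.env_block(block).loc[ids]
            kept = em.filter_multicollinearity(X)
            y = alpha.loc[ids, "shannon"]
            try:
                model = em.all_subset_regression(
                    y, X[kept], max_size=min(4, len(kept))
                )
            except ParameterError as exc:
                out["all_subset"][str(s)][block] = {"error": str(exc)}
                continue
            out["all_subset"][str(s)][block] = {
                "gof": model.gof,
                "aic": model.aic,
                "predictors": list(model.predictors),
            }
            subset_rows.append(
                {"stage": s, "block": block, "gof": model.gof, "aic": model.aic,
                 "predictors": ";".join(model.predictors)}
            )
        # PLS path model over pairwise distances within the stage
        try:
            sub_table = table.filter_samples(ids)
            beta_tax = _beta_square(sub_table, "bray_curtis", tree)
            beta_phylo = (
                _beta_square(sub_table, "weighted_unifrac", tree)
                if "weighted_unifrac" in metrics and tree is not None
                else None
            )
            blocks = em.block_distances(
                frame=_subframe(meta, ids),
                alpha=alpha.loc[ids],
                beta_tax=beta_tax,
                beta_phylo=beta_phylo,
                per_variable=True,
                sample_ids=ids,
            )
            order = [l for l in em.DEFAULT_PATH_ORDER if l in blocks]
            fitted = em.PLSPathModel(blocks, em.default_path_matrix(order)).fit()
            pruned = em.prune_paths(fitted, loading_threshold=thr["loading"])
            out["plspm"][str(s)] = {
                "gof": pruned.gof,
                "r_squared": pruned.r_squared,
                "n_pruned": len(pruned.pruning_log),
                "paths": {
                    f"{i}->{j}": float(pruned.path_coefficients.loc[j, i])
                    for j in pruned.path_coefficients.index
                    for i in pruned.path_coefficients.columns
                    if pruned.model.path_matrix.loc[j, i]
                },
            }
            (ddir / f"plspm_{s}.txt").write_text(pruned.summary())
        except ParameterError as exc:
            out["plspm"][str(s)] = {"error": str(exc)}
    if subset_rows:
        pd.DataFrame(subset_rows).to_csv(
            ddir / "all_subset_models.tsv", sep="\t", index=False
        )
    return out


def _beta_square(table, metric, tree) -> pd.DataFrame:
    dm = dv.beta_matrix(table, metric=metric, tree=tree)
    return pd.DataFrame(dm.data, index=table.sample_ids, columns=table.sample_ids)


def _subframe(meta: SampleFrame, ids) -> SampleFrame:
    return SampleFrame(meta.data.loc[ids], blocks=meta.blocks)
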