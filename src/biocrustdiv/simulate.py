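"""Synthetic biocrust metacommunity generator.

Emulates the sampling design the analysis assumes: successional stages
(A = cyanobacterial, C = cyanobacteria-lichen, M = moss) nested in sites
along a dryland transect, four parallel replicates per site x stage,
stage-driven convergence, distance-driven decay, and environmental
covariates correlated with stage and with location.

Data-generating model
---------------------
Each of ``pool_size`` species gets a lognormal base abundance, a home
location uniform on the transect, and a niche position on the
successional axis (stages coded 0, 1, 2).  The expected relative
abundance of species *i* in a sample at transect position *x* and stage
*s* is::

    mu_i  propto  base_i
                  * exp(-(x - home_i)^2 / (2 * lam_s^2))             # range kernel
                  * exp(-kappa * (trait_i - s)^2 / (2 * sigma_s^2))  # stage niche
                  * eps_i                                            # replicate noise

``kappa`` (the ``convergence`` parameter) is the strength of
stage-driven niche selection.  It scales the stage-affinity exponent —
at ``kappa = 0`` succession imposes no compositional structure at all —
and it drives successional convergence: ``lam_s = decay_range_km *
(1 + kappa * s)`` widens species ranges with stage so late-stage
communities are more alike across distant sites, while replicate-level
lognormal noise shrinks as ``1/(1 + kappa * s)`` so within-site (local)
dissimilarity falls with stage as well.  The stage-affinity breadth
``sigma_s`` broadens with stage under the ``bacteria_like`` profile
(generalist turnover, alpha diversity rises A -> M) and narrows under
``eukaryote_like`` (specialist turnover, alpha falls).  Reads are drawn
multinomially at a fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import FeatureTable, ParameterError, SampleFrame, STAGES

__all__ = [
    "SimParams",
    "simulate_tree",
    "simulate_metacommunity",
    "expected_patterns",
    "planted_combination_results",
]

_STAGE_CODE = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the metacommunity simulator.

    Defaults describe a transect of 4 local areas (two sites each) across
    3,000 km with four parallel replicates per site and stage.
    """

    n_sites: int = 8
    transect_length_km: float = 3000.0
    replicates_per_stage: int = 4
    pool_size: int = 300
    reads_per_sample: int = 2000
    convergence: float = 1.0          # kappa >= 0
    decay_range_km: float = 600.0     # lambda; np.inf disables distance decay
    domain_profile: str = "bacteria_like"
    env_noise_sd: float = 0.5
    replicate_noise_sd: float = 0.6
    niche_breadth: float = 0.5        # sigma_0, stage-affinity units
    niche_broadening: float = 1.5     # per-stage relative change of sigma_s
    area_halfwidth_km: float = 25.0   # site offset from its local-area centre
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2 or self.n_sites % 2:
            raise ParameterError("n_sites must be an even integer >= 2")
        if self.pool_size < 3:
            raise ParameterError("pool_size must be >= 3")
        if self.replicates_per_stage < 1 or self.reads_per_sample < 1:
            raise ParameterError("replicates and read depth must be positive")
        if self.convergence < 0 or self.decay_range_km <= 0:
            raise ParameterError("convergence must be >= 0 and decay_range_km > 0")
        if self.env_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.domain_profile not in ("bacteria_like", "eukaryote_like"):
            raise ParameterError(f"unknown domain_profile {self.domain_profile!r}")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def simulate_tree(pool_size: int, seed: int) -> TreeNode:
    """Random rooted binary tree with ``pool_size`` tips.

    Built by successive random joins; branch lengths are iid
    exponential(1).  Deterministic for a fixed seed.
    """
    if pool_size < 2:
        raise ParameterError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"sp{i:04d}", length=float(rng.exponential(1.0)))
             for i in range(pool_size)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _stage_sigma(params: SimParams, stage_code: int) -> float:
    g = params.niche_broadening
    if params.domain_profile == "bacteria_like":
        return params.niche_breadth * (1.0 + g * stage_code)
    return params.niche_breadth * (1.0 + g * (2 - stage_code))


def _site_positions(params: SimParams) -> np.ndarray:
    """Sites paired into local areas; area centres spread over the transect."""
    n_areas = params.n_sites // 2
    centres = (np.arange(n_areas) + 0.5) * params.transect_length_km / n_areas
    offs = params.area_halfwidth_km
    return np.repeat(centres, 2) + np.tile([-offs, offs], n_areas)


def simulate_metacommunity(params: SimParams):
    """Draw one metacommunity.

    Returns
    -------
    (FeatureTable, SampleFrame, TreeNode)
        Counts table (row sums equal ``reads_per_sample`` exactly),
        metadata with environmental blocks, and the species phylogeny.
    """
    rng = np.random.default_rng(params.seed)
    S = params.pool_size
    L = params.transect_length_km

    base = rng.lognormal(mean=0.0, sigma=1.0, size=S)
    home = rng.uniform(0.0, L, size=S)
    trait = rng.uniform(-0.5, 2.5, size=S)
    taxa = [f"sp{i:04d}" for i in range(S)]

    sites = _site_positions(params)
    site_effect = rng.normal(0.0, 1.0, size=(params.n_sites, 4))

    rows, meta_rows, index = [], [], []
    for site in range(params.n_sites):
        x = sites[site]
        for stage in STAGES:
            s = _STAGE_CODE[stage]
            lam = params.decay_range_km * (1.0 + params.convergence * s)
            if np.isinf(lam):
                kernel = np.ones(S)
            else:
                kernel = np.exp(-0.5 * ((x - home) / lam) ** 2)
            sigma = _stage_sigma(params, s)
            affinity = np.exp(-0.5 * params.convergence * ((trait - s) / sigma) ** 2)
            expected = base * kernel * affinity
            rep_sd = params.replicate_noise_sd / (1.0 + params.convergence * s)
            for rep in range(params.replicates_per_stage):
                noise = rng.lognormal(0.0, rep_sd, size=S) if rep_sd > 0 else 1.0
                mu = expected * noise
                total = mu.sum()
                if total <= 0:
                    raise ParameterError(
                        "expected composition vanished; decay_range_km too small "
                        "for the transect"
                    )
                counts = rng.multinomial(params.reads_per_sample, mu / total)
                rows.append(counts)
                index.append(f"s{site:02d}{stage}{rep}")
                meta_rows.append(
                    _metadata_row(params, rng, site, x, stage, s, site_effect[site])
                )

    table = FeatureTable(
        pd.DataFrame(np.asarray(rows), index=index, columns=taxa), mode="counts"
    )
    meta = pd.DataFrame(meta_rows, index=index)
    blocks = {
        "climatic": ["mat_c", "map_mm", "sunshine_h", "windspeed_ms"],
        "edaphic": ["ph", "total_n", "organic_c", "crust_thickness_mm"],
        "biotic": ["chlorophyll_a", "eps", "fv_fm"],
    }
    frame = SampleFrame(meta, blocks=blocks)
    tree = simulate_tree(S, seed=params.seed + 1)
    return table, frame, tree


def _metadata_row(params, rng, site, x, stage, s, site_eff):
    """Climatic columns follow smooth monotone functions of position;
    edaphic columns carry site + stage effects; biotic columns stage
    effects only — each plus iid noise."""
    e = params.env_noise_sd
    u = x / params.transect_length_km
    return {
        "site": f"site{site:02d}",
        "local_area": f"area{site // 2}",
        "stage": stage,
        "x_km": x,
        # climatic: monotone in transect position
        "mat_c": 12.0 - 8.0 * u + rng.normal(0, e),
        "map_mm": 120.0 + 260.0 * u**2 + rng.normal(0, 40 * e),
        "sunshine_h": 2600.0 + 900.0 / (1.0 + np.exp(-6 * (u - 0.5))) + rng.normal(0, 60 * e),
        "windspeed_ms": 2.0 + 2.5 * np.sqrt(u) + rng.normal(0, e),
        # edaphic: site + stage structure
        "ph": 8.5 - 0.3 * s + 0.2 * site_eff[0] + rng.normal(0, 0.1 * e),
        "total_n": 0.2 + 0.15 * s + 0.05 * site_eff[1] + rng.normal(0, 0.05 * e),
        "organic_c": 2.0 + 1.5 * s + 0.4 * site_eff[2] + rng.normal(0, 0.3 * e),
        "crust_thickness_mm": 2.0 + 3.0 * s + 0.5 * site_eff[3] + rng.normal(0, 0.5 * e),
        # biotic: stage structure
        "chlorophyll_a": 1.0 + 1.2 * s + rng.normal(0, 0.3 * e),
        "eps": 3.0 - 0.8 * s + rng.normal(0, 0.4 * e),
        "fv_fm": 0.35 + 0.1 * s + rng.normal(0, 0.05 * e),
    }


def expected_patterns(params: SimParams) -> dict:
    """Qualitative trend signs implied by the parameters.

    Keys: ``alpha_vs_stage``, ``beta_vs_stage`` (within-stage dissimilarity
    A -> M), ``among_stage_anosim_vs_distance``,
    ``between_site_anosim_vs_distance``; values in {"+", "-", "flat"}.
    """
    if params.convergence == 0:
        alpha = "flat"  # no stage-driven selection, no alpha trend either
    else:
        alpha = "+" if params.domain_profile == "bacteria_like" else "-"
    beta = "-" if params.convergence > 0 else "flat"
    finite = np.isfinite(params.decay_range_km)
    among = "-" if (params.convergence > 0 and finite) else "flat"
    between = "+" if finite else "flat"
    return {
        "alpha_vs_stage": alpha,
        "beta_vs_stage": beta,
        "among_stage_anosim_vs_distance": among,
        "between_site_anosim_vs_distance": between,
    }


def planted_combination_results(
    crossing_km: float,
    seed: int,
    n_site_pairs: int = 10,
    n_combinations: int = 100,
    max_distance_km: float = 3000.0,
    noise_sd: float = 0.05,
    slope_per_km: float = 1.5e-4,
    midpoint_r: float = 0.45,
) -> pd.DataFrame:
    """Combination-comparison records with a known crossing distance.

    Draws per-combination ANOSIM-R-like values around two opposite linear
    group-mean trends — among-stage separation falling with distance,
    between-site separation rising — constructed to cross exactly at
    ``crossing_km``.  Used to validate the regression + intersection
    machinery against a planted truth.
    """
    rng = np.random.default_rng(seed)
    dists = rng.uniform(0.05 * max_distance_km, 0.95 * max_distance_km, n_site_pairs)
    recs = []
    for d in dists:
        among = midpoint_r - slope_per_km * (d - crossing_km)
        between = midpoint_r + slope_per_km * (d - crossing_km)
        for scheme, mean_r in (("among_stages", among), ("between_sites", between)):
            draws = np.clip(rng.normal(mean_r, noise_sd, n_combinations), -1.0, 1.0)
            for r in draws:
                recs.append({"scheme": scheme, "distance_km": d, "R": float(r)})
    return pd.DataFrame(recs)
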