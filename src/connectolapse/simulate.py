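"""Synthetic longitudinal connectome cohorts with planted structure.

The generator emulates a two-group longitudinal diffusion-connectome study:
a parcellation of cortical regions organized into planted modules (plus a
small striatal seed set), a noiseless base network whose edge weights follow
the subtype hierarchy intramodular > intrahemispheric > interhemispheric >
cortico-striatal, and per-subject-per-visit observations in which the
disease group's connection strengths decline at rates that increase with the
connection's topological path length:

    control:  W_ij(t) = B_ij * exp(covariates + u_i + v_i t + eps)
    disease:  W_ij(t) = B_ij * exp(-lambda L*_ij - (kappa0 + kappa1 L*_ij) t
                                   + covariates + u_i + v_i t + eps)

with eps ~ N(0, noise_sd^2) i.i.d. per edge/visit, and u_i, v_i per-subject
random intercepts/slopes shared across edges.  Noise and degeneration act
multiplicatively on the log scale so weights stay positive and per-subject
least-squares slopes of log-linear decline are well defined.  The "true"
path length L* is computed once on the noiseless base network, making it
independent of sampling noise.  A ground-truth ledger records the planted
partition, base network, path lengths and per-edge disease rates
r_ij = -(kappa0 + kappa1 L*_ij).

A standardized cognitive composite is coupled to baseline interhemispheric
strength, emulating the observed association between callosal connectivity
and global cognition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from connectolapse.io import (
    CohortRecord,
    ConnectomeObservation,
    LongDataset,
    Region,
    RegionAtlas,
)
from connectolapse.subtypes import SubtypeLabel, classify_pair
from connectolapse.topology import shortest_paths, to_length_matrix

__all__ = ["SimulationConfig", "GroundTruth", "generate_atlas", "generate_base_network", "generate_cohort"]

SITES = ("London", "Paris", "Leiden", "Vancouver")

_DEFAULT_BASE_WEIGHTS = {
    "intramodular": 20.0,
    "intrahemispheric": 6.0,
    "interhemispheric": 3.0,
    "cortico_striatal": 1.0,
}
# SIFT2-style connectomes are deliberately unthresholded, so every analysed
# pair carries a (possibly weak) weight; the subtype hierarchy lives in the
# weights, not in differential sparsity.
_DEFAULT_DENSITY = {
    "intramodular": 1.0,
    "intrahemispheric": 1.0,
    "interhemispheric": 1.0,
    "cortico_striatal": 1.0,
}
_DEFAULT_COVARIATES = {"age": -0.002, "sex_F": 0.02, "site": (0.0, 0.03, -0.03, 0.01)}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target study's shape: 85 controls / 82 disease-group
    subjects, 3 annual visits, 70 cortical regions in 3 planted modules per
    hemisphere plus 4 striatal regions, and log-scale degeneration whose rate
    grows with topological path length.
    """

    n_controls: int = 85
    n_preHD: int = 82
    n_visits: int = 3
    modules_per_hemisphere: int = 3
    cortical_per_module: int | None = None  # overrides n_cortical when set
    n_cortical: int = 70
    n_striatal: int = 4
    base_weights: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_WEIGHTS))
    edge_density: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITY))
    noise_sd: float = 0.1  # log-scale multiplicative edge noise per visit
    subject_intercept_sd: float = 0.05  # per-subject log-scale offset
    subject_slope_sd: float = 0.02  # per-subject log-scale slope
    baseline_deficit: float = 0.15  # lambda: cross-sectional deficit per unit path length
    rate_intercept: float = 0.02  # kappa0: per-year log decline, all lengths
    rate_slope: float = 0.08  # kappa1: additional per-year decline per unit path length
    covariate_effects: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    missing_visit_prob: float = 0.0
    cognition_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_per_module is not None:
            self.n_cortical = self.cortical_per_module * 2 * self.modules_per_hemisphere
        if min(self.n_controls, self.n_preHD, self.n_visits, self.modules_per_hemisphere) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_cortical < 2 * self.modules_per_hemisphere:
            raise ValueError("need at least one cortical region per module")
        if self.noise_sd < 0 or self.subject_intercept_sd < 0 or self.subject_slope_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0.0 <= self.missing_visit_prob <= 1.0:
            raise ValueError("missing_visit_prob must lie in [0, 1]")
        for key in ("intramodular", "intrahemispheric", "interhemispheric", "cortico_striatal"):
            if self.base_weights.get(key, 0) <= 0:
                raise ValueError(f"base weight for {key} must be positive")
            if not 0.0 <= self.edge_density.get(key, 1.0) <= 1.0:
                raise ValueError(f"edge density for {key} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    true_partition: dict[int, int]  # cortical region -> planted module
    base_network: np.ndarray  # noiseless B
    path_lengths: np.ndarray  # L* on B (inf off-network)
    rates: np.ndarray  # per-edge disease log-rate r_ij = -(k0 + k1 L*_ij); 0 off-network
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_partition": {str(k): v for k, v in self.true_partition.items()},
            "base_network": self.base_network.tolist(),
            "path_lengths": np.where(np.isfinite(self.path_lengths), self.path_lengths, None).tolist(),
            "rates": self.rates.tolist(),
            "config": {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in asdict(self.config).items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def generate_atlas(config: SimulationConfig) -> RegionAtlas:
    """Planted-module parcellation: cortical regions split as evenly as
    possible over ``2 * modules_per_hemisphere`` modules, striatal regions
    split across hemispheres."""
    regions: list[Region] = []
    rid = 0
    per_hemi = [config.n_cortical // 2, config.n_cortical - config.n_cortical // 2]
    for hemi, n_h in zip(("L", "R"), per_hemi):
        mph = config.modules_per_hemisphere
        sizes = [n_h // mph + (1 if k < n_h % mph else 0) for k in range(mph)]
        for m, size in enumerate(sizes, start=1):
            for k in range(size):
                regions.append(Region(rid, f"ctx_{hemi}_m{m}_{k:02d}", hemi, "cortical"))
                rid += 1
    striatal_names = ("caudate", "putamen", "accumbens", "pallidum")
    for s in range(config.n_striatal):
        hemi = "L" if s % 2 == 0 else "R"
        base = striatal_names[(s // 2) % len(striatal_names)]
        suffix = "" if s < 2 * len(striatal_names) else f"_{s}"
        regions.append(Region(rid, f"{base}_{hemi}{suffix}", hemi, "striatal"))
        rid += 1
    return RegionAtlas(tuple(regions))


def planted_partition(config: SimulationConfig, atlas: RegionAtlas) -> dict[int, int]:
    """Cortical region -> planted module id (L modules 1..m, R modules m+1..2m)."""
    part: dict[int, int] = {}
    for r in atlas.regions:
        if r.tissue_class != "cortical":
            continue
        hemi, module = r.name.split("_")[1], int(r.name.split("_")[2][1:])
        offset = 0 if hemi == "L" else config.modules_per_hemisphere
        part[r.region_id] = module + offset
    return part


def generate_base_network(
    config: SimulationConfig, atlas: RegionAtlas, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Noiseless-in-expectation base network B with planted subtype hierarchy.

    Each analysed pair gets an edge with its subtype's density; edge weights
    are the subtype base weight under multiplicative log-normal jitter
    (exactly the base weight when noise_sd = 0).  A spanning backbone is
    added if sampling leaves the graph disconnected, so path lengths are
    finite.  Striatal-striatal pairs carry no edges (excluded by design).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    part = planted_partition(config, atlas)
    n = atlas.n
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            label = classify_pair(i, j, atlas, part)
            if label is SubtypeLabel.EXCLUDED:
                continue
            key = label.value
            if rng.random() < config.edge_density[key]:
                w = config.base_weights[key] * np.exp(rng.normal(0.0, config.noise_sd))
                B[i, j] = B[j, i] = w
    _connect_components(B, atlas, part, config, rng)
    L_star = shortest_paths(to_length_matrix(B))
    rates = np.where(B > 0, -(config.rate_intercept + config.rate_slope * L_star), 0.0)
    truth = GroundTruth(
        true_partition=part,
        base_network=B,
        path_lengths=L_star,
        rates=rates,
        config=config,
    )
    return B, truth


def _connect_components(
    B: np.ndarray,
    atlas: RegionAtlas,
    part: Mapping[int, int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Bridge disconnected components in place with subtype-typical edges."""
    G = nx.from_numpy_array(B)
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    if len(components) == 1:
        return
    core = sorted(components[0])
    for comp in components[1:]:
        a = int(rng.choice(sorted(comp)))
        b = int(rng.choice(core))
        # striatal-striatal bridges are not allowed; reroute to a cortical node
        if not atlas.is_cortical(a) and not atlas.is_cortical(b):
            cortical_core = [c for c in core if atlas.is_cortical(c)]
            b = int(rng.choice(cortical_core))
        key = classify_pair(a, b, atlas, part).value
        B[a, b] = B[b, a] = config.base_weights[key]


def generate_cohort(config: SimulationConfig) -> tuple[LongDataset, GroundTruth]:
    """Full synthetic longitudinal cohort plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    atlas = generate_atlas(config)
    B, truth = generate_base_network(config, atlas, rng)
    on_edge = B > 0
    logB = np.where(on_edge, np.log(np.where(on_edge, B, 1.0)), 0.0)
    L_star = np.where(on_edge, truth.path_lengths, 0.0)

    cov = config.covariate_effects
    site_eff = dict(zip(SITES, cov.get("site", (0.0,) * len(SITES))))

    cohort: list[CohortRecord] = []
    observations: list[ConnectomeObservation] = []
    specs = [("control", f"C{k:03d}") for k in range(config.n_controls)] + [
        ("preHD", f"P{k:03d}") for k in range(config.n_preHD)
    ]
    prehd_interhemi: dict[str, float] = {}
    inter_mask = _interhemispheric_mask(atlas, truth.true_partition)

    for group, sid in specs:
        age = float(np.clip(rng.normal(46.0, 8.0), 25.0, 65.0))
        sex = "F" if rng.random() < 0.5 else "M"
        site = SITES[int(rng.integers(len(SITES)))]
        education = int(rng.integers(1, 6))
        cag = int(rng.integers(40, 48)) if group == "preHD" else None
        u_i = rng.normal(0.0, config.subject_intercept_sd)
        v_i = rng.normal(0.0, config.subject_slope_sd)
        cov_term = cov.get("age", 0.0) * (age - 46.0) + cov.get("sex_F", 0.0) * (sex == "F") + site_eff[site]

        visits = [1] + [
            v for v in range(2, config.n_visits + 1) if rng.random() >= config.missing_visit_prob
        ]
        for visit in visits:
            t = float(visit - 1)
            logW = logB + cov_term + u_i + v_i * t
            if group == "preHD":
                logW = logW - config.baseline_deficit * L_star - (
                    config.rate_intercept + config.rate_slope * L_star
                ) * t
            eps = rng.normal(0.0, config.noise_sd, size=B.shape)
            eps = (eps + eps.T) / np.sqrt(2.0)  # keep symmetric, same marginal SD
            W = np.where(on_edge, np.exp(logW + eps), 0.0)
            np.fill_diagonal(W, 0.0)
            obs = ConnectomeObservation(subject_id=sid, visit=visit, W=W)
            observations.append(obs)
            if group == "preHD" and visit == 1:
                prehd_interhemi[sid] = float(obs.W[inter_mask].sum())
        cohort.append(
            CohortRecord(
                subject_id=sid, group=group, age=age, sex=sex, site=site,
                education=education, cag=cag, cognition=None,
            )
        )

    _attach_cognition(cohort, prehd_interhemi, config, rng)
    return LongDataset(atlas=atlas, observations=observations, cohort=cohort), truth


def _interhemispheric_mask(atlas: RegionAtlas, part: Mapping[int, int]) -> np.ndarray:
    mask = np.zeros((atlas.n, atlas.n), dtype=bool)
    for i in range(atlas.n):
        for j in range(i + 1, atlas.n):
            if classify_pair(i, j, atlas, part) is SubtypeLabel.INTERHEMISPHERIC:
                mask[i, j] = True
    return mask


def _attach_cognition(
    cohort: list[CohortRecord],
    prehd_interhemi: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Standardized cognitive composite coupled to baseline interhemispheric strength."""
    if not prehd_interhemi:
        return
    sids = list(prehd_interhemi)
    x = np.array([prehd_interhemi[s] for s in sids])
    z = (x - x.mean()) / x.std(ddof=1) if x.std(ddof=1) > 0 else np.zeros_like(x)
    rho = config.cognition_coupling
    noise_sd = float(np.sqrt(max(0.0, 1.0 - rho**2)))
    cog = rho * z + rng.normal(0.0, noise_sd, size=len(sids))
    values = dict(zip(sids, cog))
    for idx, rec in enumerate(cohort):
        if rec.subject_id in values:
            cohort[idx] = CohortRecord(
                subject_id=rec.subject_id, group=rec.group, age=rec.age, sex=rec.sex,
                site=rec.site, education=rec.education, cag=rec.cag,
                cognition=float(values[rec.subject_id]),
            )
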