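"""Synthetic multi-site, multi-state cohort generator with ground truth.

The generator emulates the statistical regime the downstream analysis
assumes, at desk scale:

* Four brain states whose FC shares a dominant stable individual
  component; state-specific modulation is much smaller than differences
  between individuals.
* Behavioral measures grouped into domains, each driven by a
  domain-shared latent factor that loads on a planted set of "core"
  edges, plus a measure-specific factor loading on measure-specific
  edges. The within-domain feature-overlap parameter sets the fraction
  of a measure's planted edges that come from the shared domain core;
  domain cores are mutually disjoint.
* A motion confound (mean FD) that shifts all edges additively and leaks
  into every behavioral measure, reproducing the confounding that
  train-fold nuisance regression must remove.
* Balanced site assignment with additive site offsets on behavior, so a
  within-site permutation differs measurably from a global shuffle.

All FC construction happens in Fisher-z space (signals add there, then
``tanh``), keeping correlations in (-1, 1) by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import FCMatrix, n_edges
from .containers import BehaviorTable, ConnectomeSet

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_timeseries_run",
]

DEFAULT_STATES = ("rest", "MID", "SST", "N-back")
DEFAULT_MEASURES = {"cognition": 16, "personality": 9, "mental_health": 11}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    The full-scale defaults mirror the study design (419 regions in 18
    network groups, measures 16/9/11 across three domains); the test
    scale (60 regions / 6 networks / 400 participants / 10 sites) keeps
    full nested cross-validation in the minutes range.
    """

    n_participants: int = 400
    n_regions: int = 60
    n_networks: int = 6
    n_sites: int = 10
    states: tuple = DEFAULT_STATES
    measures_per_domain: dict = field(
        default_factory=lambda: dict(DEFAULT_MEASURES)
    )
    #: fraction of all edges planted as each domain's shared core
    edge_signal_density: float = 0.05
    #: fraction of a measure's planted edges drawn from the domain core
    within_domain_feature_overlap: float = 0.8
    #: sd of the per-(participant, state, edge) z-space state modulation
    state_modulation_sd: float = 0.05
    #: sd of the stable per-(participant, edge) z-space measurement noise
    noise_sd: float = 0.1
    #: target correlation between mean FD and each behavioral measure
    motion_behavior_corr: float = 0.2
    seed: int = 0
    # --- secondary knobs (documented defaults, rarely moved) ---
    #: sd of the stable individual edge profile (z space)
    individual_sd: float = 0.25
    #: sd of per-edge baseline connectivity around its mean (z space)
    baseline_sd: float = 0.2
    baseline_mean: float = 0.15
    #: core-edge effect size sd (z-space units per latent-factor sd)
    edge_beta_sd: float = 0.15
    #: behavior loading on its latent signal
    behavior_loading: float = 1.0
    #: sd of behavioral measurement noise
    behavior_noise_sd: float = 0.75
    #: sd of additive site offsets on behavior
    site_offset_sd: float = 0.25
    #: uniform z-space edge shift per sd of mean FD
    motion_fc_strength: float = 0.05
    #: optional per-domain, per-state signal multipliers
    #: (domain -> sequence of len(states)); None = 1 everywhere
    state_signal_profile: dict | None = None
    #: number of pure-noise measures appended in domain "noise"
    n_noise_measures: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_regions", "n_networks", "n_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if not self.states:
            raise ValueError("state list must be nonempty")
        for frac in ("edge_signal_density", "within_domain_feature_overlap"):
            if not 0.0 <= getattr(self, frac) <= 1.0:
                raise ValueError(f"{frac} must be in [0, 1]")
        if not -1.0 < self.motion_behavior_corr < 1.0:
            raise ValueError("motion_behavior_corr must be in (-1, 1)")
        for name in ("state_modulation_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 1 for v in self.measures_per_domain.values()):
            raise ValueError("each domain needs at least one measure")

    @property
    def domains(self) -> list:
        return list(self.measures_per_domain)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort.

    ``planted_edges``/``edge_betas`` describe the domain-shared cores;
    ``measure_edges``/``measure_betas`` the measure-specific remainders.
    ``latent_factors`` holds the domain factors (participants x domains).
    """

    planted_edges: dict
    edge_betas: dict
    confound_beta: float
    latent_factors: pd.DataFrame
    measure_edges: dict = field(default_factory=dict)
    measure_betas: dict = field(default_factory=dict)
    loadings: dict = field(default_factory=dict)
    site_offsets: dict = field(default_factory=dict)

    def all_domain_edges(self, domain: str) -> np.ndarray:
        """Union of the domain core and its measures' specific edges."""
        parts = [np.asarray(self.planted_edges[domain], dtype=int)]
        for m, dom_edges in self.measure_edges.items():
            if self.loadings.get(m, {}).get("domain") == domain:
                parts.append(np.asarray(dom_edges, dtype=int))
        return np.unique(np.concatenate(parts))

    def to_json(self, path) -> None:
        payload = {
            "planted_edges": {d: np.asarray(v).tolist() for d, v in self.planted_edges.items()},
            "edge_betas": {d: np.asarray(v).tolist() for d, v in self.edge_betas.items()},
            "confound_beta": self.confound_beta,
            "latent_factors": self.latent_factors.to_dict(orient="index"),
            "measure_edges": {m: np.asarray(v).tolist() for m, v in self.measure_edges.items()},
            "measure_betas": {m: np.asarray(v).tolist() for m, v in self.measure_betas.items()},
            "loadings": self.loadings,
            "site_offsets": self.site_offsets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _plant_edges(cfg: CohortConfig, rng: np.random.Generator):
    """Draw disjoint domain cores and measure-specific edge sets."""
    E = cfg.n_edges
    core_size = int(round(cfg.edge_signal_density * E))
    if cfg.edge_signal_density > 0 and core_size == 0:
        raise ValueError(
            f"edge_signal_density={cfg.edge_signal_density} plants 0 edges at E={E}"
        )
    w = cfg.within_domain_feature_overlap
    spec_size = 0 if w >= 1.0 else (
        core_size if w == 0.0 else int(round(core_size * (1 - w) / w))
    )
    n_specific = sum(cfg.measures_per_domain.values())
    need = core_size * len(cfg.domains) + spec_size * n_specific
    if need > E:
        raise ValueError(
            f"planted-edge demand {need} exceeds {E} edges; lower the density"
        )
    pool = rng.permutation(E)
    pos = 0
    cores, specifics = {}, {}
    for d in cfg.domains:
        cores[d] = np.sort(pool[pos : pos + core_size])
        pos += core_size
        for k in range(cfg.measures_per_domain[d]):
            specifics[f"{d}_{k+1:02d}"] = np.sort(pool[pos : pos + spec_size])
            pos += spec_size
    return cores, specifics, core_size, spec_size


def generate_cohort(config: CohortConfig):
    """Generate one cohort.

    Returns
    -------
    (ConnectomeSet, BehaviorTable, meta DataFrame, SyntheticTruth)
        ``meta`` has one row per participant: participant, site, mean_fd,
        mean_dvars, age, sex, race_bin, income_bin.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, E = cfg.n_participants, cfg.n_edges
    states = list(cfg.states)
    n_states = len(states)
    domains = cfg.domains

    participants = [f"sub-{i:04d}" for i in range(n)]
    # balanced site assignment
    sites = np.array([f"site{(i % cfg.n_sites):02d}" for i in range(n)])
    rng.shuffle(sites)

    # motion: mean FD lognormal around 0.15 mm; DVARS correlated with FD
    mean_fd = np.exp(rng.normal(np.log(0.15), 0.4, size=n))
    fdz = (mean_fd - mean_fd.mean()) / mean_fd.std()
    mean_dvars = 25.0 + 30.0 * mean_fd + rng.normal(0, 2.0, size=n)

    cores, specifics, core_size, spec_size = _plant_edges(cfg, rng)
    core_betas = {d: rng.normal(0, cfg.edge_beta_sd, size=core_size) for d in domains}
    spec_betas = {
        m: rng.normal(0, cfg.edge_beta_sd, size=spec_size) for m in specifics
    }

    L = rng.standard_normal((n, len(domains)))  # domain latent factors
    eta = {m: rng.standard_normal(n) for m in specifics}  # measure factors

    profile = cfg.state_signal_profile or {}
    state_scale = {
        d: np.asarray(profile.get(d, np.ones(n_states)), dtype=float)
        for d in domains
    }
    for d, sc in state_scale.items():
        if sc.shape != (n_states,):
            raise ValueError(f"state_signal_profile[{d!r}] must have {n_states} entries")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=E)
    indiv = rng.normal(0, cfg.individual_sd, size=(n, E))
    stable_noise = rng.normal(0, cfg.noise_sd, size=(n, E))

    # shared z-space signal (state-independent part)
    z_base = baseline + indiv + stable_noise + cfg.motion_fc_strength * fdz[:, None]
    signal = np.zeros((n, E))  # unit-scale signal, modulated per state below
    per_state_signal = np.zeros((n_states, n, E))
    for di, d in enumerate(domains):
        dom_sig = np.zeros((n, E))
        dom_sig[:, cores[d]] += np.outer(L[:, di], core_betas[d])
        for k in range(cfg.measures_per_domain[d]):
            m = f"{d}_{k+1:02d}"
            if spec_size:
                dom_sig[:, specifics[m]] += np.outer(eta[m], spec_betas[m])
        for si in range(n_states):
            per_state_signal[si] += state_scale[d][si] * dom_sig

    edges = np.empty((n, n_states, E))
    for si in range(n_states):
        z = z_base + per_state_signal[si]
        if cfg.state_modulation_sd > 0:
            z = z + rng.normal(0, cfg.state_modulation_sd, size=(n, E))
        edges[:, si, :] = np.tanh(z)

    connectomes = ConnectomeSet(
        participants=participants, states=states, edges=edges, n_regions=cfg.n_regions
    )

    # behavior
    w = cfg.within_domain_feature_overlap
    a_shared, a_spec = np.sqrt(w), np.sqrt(1.0 - w)
    var_other = (
        cfg.behavior_loading**2 + cfg.site_offset_sd**2 + cfg.behavior_noise_sd**2
    )
    c = cfg.motion_behavior_corr
    confound_beta = c * np.sqrt(var_other / (1 - c**2)) if c != 0 else 0.0

    site_names = sorted(set(sites))
    site_off = {s: rng.normal(0, cfg.site_offset_sd) for s in site_names}
    site_vec = np.array([site_off[s] for s in sites])

    cols, domain_map, loadings = {}, {}, {}
    for di, d in enumerate(domains):
        for k in range(cfg.measures_per_domain[d]):
            m = f"{d}_{k+1:02d}"
            g = a_shared * L[:, di] + a_spec * eta[m]
            y = (
                cfg.behavior_loading * g
                + confound_beta * fdz
                + site_vec
                + rng.normal(0, cfg.behavior_noise_sd, size=n)
            )
            cols[m] = y
            domain_map[m] = d
            loadings[m] = {"domain": d, "loading": cfg.behavior_loading}
    for k in range(cfg.n_noise_measures):
        m = f"noise_{k+1:02d}"
        cols[m] = rng.standard_normal(n)
        domain_map[m] = "noise"
        loadings[m] = {"domain": "noise", "loading": 0.0}

    behavior = BehaviorTable(
        values=pd.DataFrame(cols, index=pd.Index(participants, name="participant")),
        domains=domain_map,
    )

    meta = pd.DataFrame(
        {
            "participant": participants,
            "site": sites,
            "mean_fd": mean_fd,
            "mean_dvars": mean_dvars,
            "age": rng.uniform(108, 131, size=n).round(1),
            "sex": rng.choice(["F", "M"], size=n),
            "race_bin": rng.choice(
                ["r1", "r2", "r3", "r4", "r5"], size=n, p=[0.5, 0.2, 0.15, 0.1, 0.05]
            ),
            "income_bin": rng.choice(
                ["i1", "i2", "i3", "i4"], size=n, p=[0.25, 0.3, 0.3, 0.15]
            ),
        }
    )

    truth = SyntheticTruth(
        planted_edges={d: cores[d] for d in domains},
        edge_betas={d: core_betas[d] for d in domains},
        confound_beta=float(confound_beta),
        latent_factors=pd.DataFrame(
            L, index=pd.Index(participants, name="participant"), columns=domains
        ),
        measure_edges=specifics,
        measure_betas=spec_betas,
        loadings=loadings,
        site_offsets=site_off,
    )
    return connectomes, behavior, meta, truth


def _nearest_psd_correlation(c: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_timeseries_run(
    n_frames: int,
    fc_target: FCMatrix | np.ndarray,
    fd_spikes=(),
    seed: int = 0,
    tr_seconds: float = 0.8,
):
    """Draw a time-series run whose empirical correlation converges to
    ``fc_target``, with an FD trace exceeding 0.3 mm exactly at
    ``fd_spikes``.

    Returns an :class:`~connpredict.connectome.ROITimeSeriesRun`.
    """
    from .connectome import ROITimeSeriesRun  # local import avoids cycle at import time

    target = fc_target.values if isinstance(fc_target, FCMatrix) else np.asarray(fc_target)
    r = target.shape[0]
    if n_frames < r + 1:
        import warnings

        warnings.warn(
            f"n_frames={n_frames} < n_regions+1={r+1}: empirical FC is rank deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    cov = _nearest_psd_correlation(target)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(r))
    signals = rng.standard_normal((n_frames, r)) @ chol.T

    fd = rng.uniform(0.05, 0.25, size=n_frames)
    dvars = rng.uniform(15.0, 40.0, size=n_frames)
    spikes = np.asarray(sorted(set(int(i) for i in fd_spikes)), dtype=int)
    if spikes.size and (spikes.min() < 0 or spikes.max() >= n_frames):
        raise ValueError("fd spike index out of range")
    fd[spikes] = 0.35 + rng.exponential(0.3, size=spikes.size)
    return ROITimeSeriesRun(signals=signals, fd=fd, dvars=dvars)
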