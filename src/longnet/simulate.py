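"""Synthetic longitudinal connectome cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes — a cohort of older adults, each observed at a few occasions, with
nonnegative weighted functional networks organized into seven planted
resting-state communities whose membership reconfigures between occasions
— while storing every generative event, so the temporal metrics can be
validated against hand-countable truth.

Per subject, the first layer's community structure is exactly the seven
predefined networks.  Between consecutive layers each node is flagged to
switch community with a subject-specific probability (increasing with
simulated age when ``age_effect > 0``), and flagged nodes move either as
cohesive subgroups (a random subset of same-community movers relocates to
one common target) or as disjoint lone movers, in a configurable
proportion.  Layer weights are two-valued block matrices (within- vs.
between-community mean, Fisher-z scale) plus Gaussian noise clipped at
zero.  Cognitive T-scores decline linearly in time with subject-specific
slopes that steepen with age, plus a retest bump at follow-ups.

What this emulates — and what it does not: weights are drawn directly on
the Fisher-z scale (an optional latent-factor mode produces ROI time
series instead, exercising the correlation step); there is no hemodynamic
signal model, no head-motion artifact structure, and noise is i.i.d.
Gaussian, so passing tests demonstrate correctness of the pipeline's
computations, not realism of BOLD data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.optimize import brentq

from .connectome import (
    DEFAULT_NETWORKS,
    ConnectivityLayer,
    MultilayerNetwork,
    ROITimeSeries,
)
from .modularity import MultilayerPartition

#: Yeo-7 block sizes for the 200-region Schaefer parcellation, in the
#: order FPCN, DMN, DAN, SVAN, LIMB, SM, VIS.
SCHAEFER200_YEO7_SIZES = (30, 45, 23, 22, 12, 37, 31)

#: Target age distribution at baseline: mean 69.8 years on [64, 83].
AGE_RANGE = (64.0, 83.0)
AGE_MEAN = 69.8
_AGE_SCALE = 4.0


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults.

    Defaults mirror the study design the pipeline targets: 150 subjects,
    200 regions in 7 networks, 4 occasions.  Edge-weight means are on the
    Fisher-z scale (within-network connectivity well above between-network
    connectivity); ``base_switch_prob`` sets the per-node, per-transition
    community switching rate at the mean age and ``age_effect`` its
    per-year increment; ``cohesive_fraction`` is the share of switching
    events executed as subgroup moves rather than lone moves.  Cognitive
    scores are T-scored (intercept 50) and decline by ``cognitive_slope_mean``
    points/year on average, steeper with age by ``slope_age_effect``.
    """

    n_subjects: int = 150
    n_nodes: int = 200
    n_layers: int = 4
    network_sizes: tuple[int, ...] | None = None
    mu_within: float = 0.5
    mu_between: float = 0.1
    noise_sd: float = 0.1
    base_switch_prob: float = 0.2
    age_effect: float = 0.004
    cohesive_fraction: float = 0.75
    cognitive_intercept: float = 50.0
    cognitive_slope_mean: float = -0.5
    slope_age_effect: float = -0.05
    slope_sd: float = 1.0
    retest_bump: float = 1.8
    cognitive_noise_sd: float = 1.0
    occasion_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            self.network_sizes = _default_sizes(self.n_nodes)
        if sum(self.network_sizes) != self.n_nodes:
            raise ValueError(
                f"network sizes {self.network_sizes} sum to {sum(self.network_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if any(s < 1 for s in self.network_sizes):
            raise ValueError("every network needs at least one node")
        if not (0 <= self.base_switch_prob <= 1):
            raise ValueError("base_switch_prob must be in [0, 1]")
        if not (0 <= self.cohesive_fraction <= 1):
            raise ValueError("cohesive_fraction must be in [0, 1]")
        if not (self.mu_within > self.mu_between >= 0):
            raise ValueError("need mu_within > mu_between >= 0")
        if len(self.occasion_times) < self.n_layers:
            raise ValueError("occasion_times must cover every layer")


def _default_sizes(n_nodes: int) -> tuple[int, ...]:
    """Seven block sizes: the Schaefer-200 split, or proportional to it."""
    if n_nodes == 200:
        return SCHAEFER200_YEO7_SIZES
    frac = np.array(SCHAEFER200_YEO7_SIZES) / 200.0
    sizes = np.maximum(1, np.floor(frac * n_nodes).astype(int))
    # distribute the remainder to the largest networks first
    for i in np.argsort(-frac):
        if sizes.sum() == n_nodes:
            break
        sizes[i] += 1
    while sizes.sum() > n_nodes:
        sizes[np.argmax(sizes)] -= 1
    return tuple(int(s) for s in sizes)


@dataclass
class SubjectRecord:
    """One simulated subject: network, ground-truth partition, covariates."""

    subject_id: str
    network: MultilayerNetwork
    truth: MultilayerPartition
    age: float
    gender: int
    education: int
    fd: float
    switch_prob: float


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its generative ground truth."""

    subjects: list[SubjectRecord]
    covariates: pd.DataFrame  # subject, age, gender, education, fd
    cognition: pd.DataFrame  # subject, occasion, time, speed_T, memory_T
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _truncnorm_loc() -> float:
    """Location of a scale-4 normal whose [64, 83] truncation has mean 69.8."""

    def truncated_mean(loc: float) -> float:
        a = (AGE_RANGE[0] - loc) / _AGE_SCALE
        b = (AGE_RANGE[1] - loc) / _AGE_SCALE
        return _sps.truncnorm.mean(a, b, loc=loc, scale=_AGE_SCALE) - AGE_MEAN

    return brentq(truncated_mean, 60.0, 80.0, xtol=1e-10)


_AGE_LOC = None  # solved lazily, then cached


def sample_ages(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Baseline ages: truncated normal on [64, 83] years with mean 69.8."""
    global _AGE_LOC
    if n < 1:
        raise ValueError("n must be >= 1")
    if _AGE_LOC is None:
        _AGE_LOC = _truncnorm_loc()
    rng = np.random.default_rng(seed)
    a = (AGE_RANGE[0] - _AGE_LOC) / _AGE_SCALE
    b = (AGE_RANGE[1] - _AGE_LOC) / _AGE_SCALE
    return _sps.truncnorm.rvs(
        a, b, loc=_AGE_LOC, scale=_AGE_SCALE, size=n, random_state=rng
    )


def planted_partition(network_sizes: tuple[int, ...]) -> np.ndarray:
    """Layer-1 truth: node i belongs to its predefined network's block."""
    return np.repeat(np.arange(len(network_sizes)), network_sizes)


def evolve_partition(
    previous: np.ndarray,
    switch_prob: float,
    cohesive_fraction: float,
    rng: np.random.Generator,
    n_communities: int | None = None,
) -> np.ndarray:
    """One step of community reconfiguration.

    Each node is independently flagged to switch with ``switch_prob``.
    Flagged nodes sharing a community (a random subgroup of that
    community) are executed as one cohesive move to a common target with
    probability ``cohesive_fraction``, and as disjoint lone moves
    otherwise; lone movers pick independent random targets, and a
    community contributing a single flagged node always moves it alone.
    Targets are always existing community ids different from the source.
    """
    prev = np.asarray(previous)
    k = n_communities if n_communities is not None else int(prev.max()) + 1
    if k < 2:
        return prev.copy()
    nxt = prev.copy()
    flagged = np.flatnonzero(rng.random(prev.shape[0]) < switch_prob)
    if flagged.size == 0:
        return nxt

    def lone_move(node: int) -> None:
        options = [c for c in range(k) if c != prev[node]]
        nxt[node] = options[rng.integers(len(options))]

    for c in np.unique(prev[flagged]):
        members = flagged[prev[flagged] == c]
        cohesive = members.size >= 2 and rng.random() < cohesive_fraction
        if cohesive:
            options = [cc for cc in range(k) if cc != c]
            target = options[rng.integers(len(options))]
            nxt[members] = target
        else:
            for node in members:
                lone_move(int(node))
    return nxt


def layer_from_partition(
    partition_layer: np.ndarray,
    mu_within: float,
    mu_between: float,
    noise_sd: float,
    rng: np.random.Generator,
    node_labels: list[str] | None = None,
) -> ConnectivityLayer:
    """Two-valued block matrix plus clipped Gaussian noise.

    weight(i, j) = max(0, mu_block + N(0, noise_sd)) where mu_block is
    ``mu_within`` for same-community pairs and ``mu_between`` otherwise;
    symmetric with zero diagonal.
    """
    if not mu_within > mu_between:
        raise ValueError("mu_within must exceed mu_between")
    g = np.asarray(partition_layer)
    n = g.shape[0]
    mu = np.where(g[:, None] == g[None, :], mu_within, mu_between)
    iu = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    noise = rng.normal(0.0, noise_sd, size=iu[0].size) if noise_sd > 0 else 0.0
    w[iu] = np.maximum(0.0, mu[iu] + noise)
    w = w + w.T
    if node_labels is None:
        node_labels = [f"n{i:03d}" for i in range(n)]
    return ConnectivityLayer(w, node_labels)


def simulate_time_series(
    partition_layer: np.ndarray,
    n_timepoints: int,
    within_corr: float,
    rng: np.random.Generator,
    node_labels: list[str] | None = None,
    occasion: int = 0,
) -> ROITimeSeries:
    """Latent block-factor signals whose correlations carry the block structure.

    Node i's signal is sqrt(rho) * f_c(i) + sqrt(1 - rho) * eps_i with one
    latent factor per community, so same-community pairs correlate at
    about ``within_corr`` and cross-community pairs at about zero.
    """
    if not (0 < within_corr < 1):
        raise ValueError("within_corr must be in (0, 1)")
    g = np.asarray(partition_layer)
    n = g.shape[0]
    k = int(g.max()) + 1
    factors = rng.normal(size=(n_timepoints, k))
    eps = rng.normal(size=(n_timepoints, n))
    values = np.sqrt(within_corr) * factors[:, g] + np.sqrt(1 - within_corr) * eps
    if node_labels is None:
        node_labels = [f"n{i:03d}" for i in range(n)]
    return ROITimeSeries(values, node_labels, occasion=occasion)


def _network_map(sizes: tuple[int, ...], node_labels: list[str]) -> dict[str, str]:
    names = DEFAULT_NETWORKS[: len(sizes)]
    blocks = np.repeat(np.arange(len(sizes)), sizes)
    return {lbl: names[b] for lbl, b in zip(node_labels, blocks)}


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort with retained ground truth.

    Subject-level randomness flows through one seed sequence derived from
    ``config.seed``, so the cohort is bit-reproducible and any single
    subject can be regenerated in isolation.
    """
    root = np.random.SeedSequence(config.seed)
    cov_ss, *subject_ss = root.spawn(config.n_subjects + 1)
    cov_rng = np.random.default_rng(cov_ss)

    ages = sample_ages(config.n_subjects, cov_rng)
    genders = cov_rng.integers(0, 2, size=config.n_subjects)
    education = cov_rng.integers(1, 4, size=config.n_subjects)
    fd = cov_rng.lognormal(mean=np.log(0.2), sigma=0.3, size=config.n_subjects)
    mean_age = ages.mean()

    node_labels = [f"n{i:03d}" for i in range(config.n_nodes)]
    net_map = _network_map(config.network_sizes, node_labels)
    base = planted_partition(config.network_sizes)
    k = len(config.network_sizes)

    subjects = []
    cog_rows = []
    for s in range(config.n_subjects):
        sid = f"sub{s:03d}"
        rng = np.random.default_rng(subject_ss[s])
        p_switch = float(
            np.clip(config.base_switch_prob + config.age_effect * (ages[s] - mean_age), 0, 1)
        )
        layers_g = [base.copy()]
        for _ in range(config.n_layers - 1):
            layers_g.append(
                evolve_partition(
                    layers_g[-1], p_switch, config.cohesive_fraction, rng, n_communities=k
                )
            )
        layers = [
            layer_from_partition(
                g, config.mu_within, config.mu_between, config.noise_sd, rng, node_labels
            )
            for g in layers_g
        ]
        network = MultilayerNetwork(layers, list(node_labels), dict(net_map))
        truth = MultilayerPartition(np.stack(layers_g, axis=1))

        slope = {
            d: config.cognitive_slope_mean
            + config.slope_age_effect * (ages[s] - mean_age)
            + rng.normal(0.0, config.slope_sd)
            for d in ("speed", "memory")
        }
        for occ in range(config.n_layers):
            t = config.occasion_times[occ]
            row = {"subject": sid, "occasion": occ, "time": t}
            for d in ("speed", "memory"):
                row[f"{d}_T"] = (
                    config.cognitive_intercept
                    + slope[d] * t
                    + config.retest_bump * (occ > 0)
                    + rng.normal(0.0, config.cognitive_noise_sd)
                )
            cog_rows.append(row)

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                network=network,
                truth=truth,
                age=float(ages[s]),
                gender=int(genders[s]),
                education=int(education[s]),
                fd=float(fd[s]),
                switch_prob=p_switch,
            )
        )

    covariates = pd.DataFrame(
        {
            "subject": [rec.subject_id for rec in subjects],
            "age": [rec.age for rec in subjects],
            "gender": [rec.gender for rec in subjects],
            "education": [rec.education for rec in subjects],
            "fd": [rec.fd for rec in subjects],
        }
    )
    cognition = pd.DataFrame(cog_rows)
    return SyntheticCohort(subjects, covariates, cognition, config)


def small_test_config(**overrides) -> SimulationConfig:
    """A reduced-scale config for fast exercises: 56 nodes, equal blocks."""
    defaults = dict(
        n_subjects=30,
        n_nodes=56,
        network_sizes=(8,) * 7,
        n_layers=4,
        noise_sd=0.05,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with only the seed replaced."""
    return replace(config, seed=seed)
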