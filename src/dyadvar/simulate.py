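"""Synthetic dyad cohorts with known lag-1 dynamics.

The study data this package targets (30 mother-infant dyads, two coded
5-minute play sessions per month over months 3-12, 26 behavior codes)
are not public, so every stage of the pipeline is exercised against
synthetic cohorts whose ground truth is known exactly. Each dyad's
monthly 26-vector follows a stationary VAR(1),

    x(t) = c + A x(t-1) + eta,   eta ~ N(0, Sigma),

with group-specific coupling matrix A, a burn-in so the recorded window
starts at stationarity, and dyads i.i.d. within group. Two emission
regimes map latents to observations: ``gaussian_latent`` keeps the raw
draws (the linear model is exactly correct, enabling exact parameter
recovery) and ``poisson_counts`` produces realistic non-negative counts
through a log-link (the linear VAR is then only an approximation, as it
is for real coded behavior).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import MonthlyPanel
from .vocabulary import ALL_CODES, GROUPS

BURN_IN = 50  # steps discarded before the recorded window


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def default_coupling(variables: Sequence[str] = ALL_CODES) -> dict[str, np.ndarray]:
    """Default per-group lag-1 coupling matrices.

    Every code carries mild persistence (0.3 on the diagonal). Two
    mother-to-infant / infant-to-mother channels are coupled with
    opposite signs in the two groups — positive for boys, negative for
    girls — emulating the qualitative pattern that infant motor
    milestones draw increased maternal engagement in one group and
    decreased engagement in the other.
    """
    m = len(variables)
    base = 0.3 * np.eye(m)
    couplings = [
        ("Crawl", "Points to Object"),          # infant response <- maternal impulse
        ("Rocks/Jiggles", "Stand Independently"),  # maternal response <- infant impulse
    ]
    a_boy, a_girl = base.copy(), base.copy()
    for resp, imp in couplings:
        if resp in variables and imp in variables:
            i, j = variables.index(resp), variables.index(imp)
            a_boy[i, j] = 0.4
            a_girl[i, j] = -0.4
    return {"boy": a_boy, "girl": a_girl}


@dataclasses.dataclass
class GeneratorConfig:
    """Configuration of a synthetic dyad cohort.

    Defaults mirror the emulated study design: 15 dyads per group, months
    3-12, two 300-second sessions per month (20 sessions per infant
    aggregating to 10 monthly rows), and all 26 behavior codes.
    """

    n_dyads_per_group: int = 15
    months: Sequence[int] = tuple(range(3, 13))
    sessions_per_month: int = 2
    session_length: float = 300.0
    variables: Sequence[str] = ALL_CODES
    coupling_by_group: Mapping[str, np.ndarray] | None = None
    intercept_by_group: Mapping[str, np.ndarray] | None = None
    innovation_cov: np.ndarray | None = None
    emission: str = "gaussian_latent"
    duration_scale: float = 30.0   # seconds per softplus unit
    count_loc: float = 1.0         # log-link intercept for Poisson counts
    count_slope: float = 0.5       # log-link slope on the latent
    seed: int = 0

    def __post_init__(self):
        self.variables = list(self.variables)
        m = len(self.variables)
        if self.n_dyads_per_group < 1:
            raise ConfigurationError("n_dyads_per_group must be >= 1")
        if self.emission not in {"gaussian_latent", "poisson_counts"}:
            raise ConfigurationError(f"unknown emission {self.emission!r}")
        if self.coupling_by_group is None:
            self.coupling_by_group = default_coupling(self.variables)
        self.coupling_by_group = {
            g: np.asarray(a, dtype=float) for g, a in self.coupling_by_group.items()
        }
        for g, a in self.coupling_by_group.items():
            if a.shape != (m, m):
                raise ConfigurationError(f"group {g!r}: A has shape {a.shape}, expected {(m, m)}")
            rho = np.max(np.abs(np.linalg.eigvals(a)))
            if rho >= 1.0:
                raise ConfigurationError(
                    f"group {g!r}: coupling matrix is unstable (spectral radius {rho:.3f} >= 1)"
                )
        if self.intercept_by_group is None:
            self.intercept_by_group = {g: np.zeros(m) for g in self.coupling_by_group}
        self.intercept_by_group = {
            g: np.asarray(c, dtype=float) for g, c in self.intercept_by_group.items()
        }
        if self.innovation_cov is None:
            self.innovation_cov = np.eye(m)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        if self.innovation_cov.shape != (m, m):
            raise ConfigurationError("innovation_cov has the wrong shape")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ConfigurationError("innovation_cov must be symmetric")
        try:
            np.linalg.cholesky(self.innovation_cov)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("innovation_cov must be positive-definite") from exc

    @property
    def group_labels(self) -> list[str]:
        return [g for g in GROUPS if g in self.coupling_by_group] or sorted(self.coupling_by_group)


@dataclasses.dataclass
class DyadGroundTruth:
    """Planted parameters and their closed-form orthogonalized IRF."""

    group: str
    coupling: np.ndarray     # A
    intercept: np.ndarray    # c
    innovation_cov: np.ndarray
    irf: np.ndarray          # (horizon+1, m, m); irf[h, i, j] = response i to impulse j

    def __post_init__(self):
        # Impact response is the Cholesky column; stable A makes it decay.
        assert np.allclose(self.irf[0], np.linalg.cholesky(self.innovation_cov))


def _simulate_latents(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent monthly draws, shape (n_dyads_total, n_months, m).

    Dyads are ordered group-by-group in ``config.group_labels`` order.
    All dyads of a group are advanced jointly (vectorized over dyads).
    """
    m = len(config.variables)
    n_t = len(config.months)
    chol = np.linalg.cholesky(config.innovation_cov)
    blocks = []
    for g in config.group_labels:
        a = config.coupling_by_group[g]
        c = config.intercept_by_group[g]
        n = config.n_dyads_per_group
        x = np.zeros((n, m))
        out = np.empty((n, n_t, m))
        for t in range(BURN_IN + n_t):
            eta = rng.standard_normal((n, m)) @ chol.T
            x = c + x @ a.T + eta
            if t >= BURN_IN:
                out[:, t - BURN_IN, :] = x
        blocks.append(out)
    return np.concatenate(blocks, axis=0)


def _cohort_metadata(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    dyads, groups = [], []
    for g in config.group_labels:
        for i in range(config.n_dyads_per_group):
            dyads.append(f"{g}{i + 1:02d}")
            groups.append(g)
    return dyads, groups


def generate_cohort(
    config: GeneratorConfig, return_events: bool = False
) -> MonthlyPanel | tuple[MonthlyPanel, pd.DataFrame]:
    """Draw a synthetic cohort panel (optionally with a session event log).

    The same seed always yields a bit-identical cohort. With
    ``return_events=True`` the panel is aggregated from the returned
    session-level log, so log and panel are exactly consistent.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    latents = _simulate_latents(config, rng)
    dyads, groups = _cohort_metadata(config)

    if config.emission == "gaussian_latent":
        values, encoding = latents, "duration_seconds"
    else:
        rate = np.exp(config.count_loc + config.count_slope * latents)
        values = rng.poisson(rate).astype(float)
        encoding = "occurrence_count"

    panel = MonthlyPanel(
        dyad_ids=dyads,
        groups=groups,
        months=np.asarray(config.months, dtype=int),
        variables=list(config.variables),
        values=values,
        encoding=encoding,
    )
    if not return_events:
        return panel
    if config.emission != "poisson_counts":
        raise ConfigurationError(
            "session-level logs need a non-negative emission; use "
            "emission='poisson_counts' or generate_events()"
        )
    events = events_from_monthly(
        monthly_counts=values, monthly_durations=None, config=config, rng=rng
    )
    return panel, events


def generate_events(config: GeneratorConfig) -> pd.DataFrame:
    """Session-level event log carrying BOTH encodings from shared latents.

    Monthly occurrence counts are Poisson with a log-link on the latent;
    monthly durations are softplus-scaled latents in seconds. Both are
    split across the month's sessions, so aggregating the log by month
    recovers the monthly totals exactly. This is the input the full
    four-model study pipeline consumes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    latents = _simulate_latents(config, rng)
    counts = rng.poisson(np.exp(config.count_loc + config.count_slope * latents)).astype(float)
    durations = config.duration_scale * _softplus(latents)
    return events_from_monthly(counts, durations, config, rng)


def events_from_monthly(
    monthly_counts: np.ndarray | None,
    monthly_durations: np.ndarray | None,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Split monthly totals into per-session event rows.

    Counts are split multinomially across sessions; durations are split
    equally. Column sums by month reproduce the inputs exactly.
    """
    dyads, groups = _cohort_metadata(config)
    n_d = len(dyads)
    n_t = len(config.months)
    m = len(config.variables)
    s = config.sessions_per_month
    ref = monthly_counts if monthly_counts is not None else monthly_durations
    if monthly_counts is None:
        monthly_counts = np.zeros_like(ref)
    if monthly_durations is None:
        monthly_durations = np.maximum(ref, 0.0)

    # per-session counts: multinomial split with equal session probabilities
    session_counts = rng.multinomial(
        monthly_counts.astype(int).ravel(), np.full(s, 1.0 / s)
    ).reshape(n_d, n_t, m, s)
    session_durations = np.repeat(monthly_durations[..., None] / s, s, axis=-1)

    rows = {
        "dyad_id": np.repeat(dyads, n_t * m * s),
        "group": np.repeat(groups, n_t * m * s),
        "month": np.tile(np.repeat(np.asarray(config.months, int), m * s), n_d),
        "session": np.tile(np.arange(1, s + 1), n_d * n_t * m),
        "code": np.tile(np.repeat(config.variables, s), n_d * n_t),
        "duration_s": session_durations.ravel(),
        "occurrences": session_counts.astype(float).ravel(),
    }
    return pd.DataFrame(rows)


def ground_truth_irf(config: GeneratorConfig, horizon: int = 10) -> dict[str, DyadGroundTruth]:
    """Closed-form orthogonalized IRFs of the planted dynamics, per group.

    Theta_0 = chol(Sigma); Theta_h = A Theta_{h-1}. These are the curves
    estimated IRFs converge to as cohorts grow.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    chol = np.linalg.cholesky(config.innovation_cov)
    out = {}
    for g in config.group_labels:
        a = config.coupling_by_group[g]
        theta = np.empty((horizon + 1, *chol.shape))
        theta[0] = chol
        for h in range(1, horizon + 1):
            theta[h] = a @ theta[h - 1]
        out[g] = DyadGroundTruth(
            group=g,
            coupling=a,
            intercept=config.intercept_by_group[g],
            innovation_cov=config.innovation_cov,
            irf=theta,
        )
    return out
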