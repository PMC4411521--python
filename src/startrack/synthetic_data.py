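"""Synthetic star-track performance generator.

Emulates the two study designs so every downstream analysis runs
without external data: a validity study (default 20 subjects x 4
conditions in randomized crossover order) and a retest study (default
11 subjects x 2 identical sessions).

Model
-----
Completion times are lognormal with a subject effect, a condition
effect and a trial residual::

    time_ij = exp(log(base_median_time_s) + u_i + beta_c + eps_ij)
    u_i   ~ Normal(0, subject_sd_log_time)
    eps_ij ~ Normal(0, residual_sd_log_time)

Error counts are overdispersed counts whose mean carries the same
condition effect (interventions slow subjects down *and* make them
sloppier) and a subject rate effect v_i ~ Normal(0, subject_sd_log_rate)::

    errors_ij ~ CountDist(mean = base_error_rate * exp(v_i + beta_c))

with variance mean * (1 + error_dispersion) (negative binomial;
dispersion 0 degenerates to Poisson).  The count is realized through a
Gaussian-copula quantile so that a subject's error realization — not
just their underlying rate — is a stable trait: across the two retest
sessions both the latent subject effects (u, v) and the count-copula
latent correlate at ``retest_stability``, which makes the
perfect-stability limit exact (stability 1 with zero time residual
reproduces session one verbatim).  Within a subject, u and v correlate
at ``skill_correlation``: dexterous subjects are both fast and accurate,
which is what gives a composite speed+accuracy score its test-retest
reliability.

beta_baseline = 0; ``effect_fatigue``, ``effect_stress`` and
``effect_combined`` are log-scale multipliers applied to both channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.stats import nbinom, norm, poisson

from .randomization import CrossoverSchedule
from .trial_model import (
    RETEST_CONDITIONS,
    VALIDITY_CONDITIONS,
    EventLog,
    TrialRecord,
)

__all__ = [
    "SimulationConfig",
    "simulate_validity_study",
    "simulate_retest_study",
    "simulate_event_log",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic performance model.

    Defaults are calibrated so the synthetic studies reproduce the
    geometry the analyses are designed for: baseline-versus-intervention
    differences in mean integrated measure of roughly 0.4-0.6 and a
    test-retest correlation near 0.9.
    """

    n_subjects: int = 20
    #: median completion time of a rested subject, seconds
    base_median_time_s: float = 180.0
    #: expected border contacts per attempt at baseline
    base_error_rate: float = 12.0
    #: between-subject SD of log completion time
    subject_sd_log_time: float = 0.25
    #: between-subject SD of log error rate
    subject_sd_log_rate: float = 0.35
    #: within-subject (trial-to-trial) SD of log completion time
    residual_sd_log_time: float = 0.10
    #: count variance is mean * (1 + dispersion); 0 = Poisson
    error_dispersion: float = 0.15
    #: log-scale shifts applied to both time and error rate
    effect_fatigue: float = 0.18
    effect_stress: float = 0.18
    effect_combined: float = 0.25
    #: cross-session correlation of all subject-level latents, in [0, 1]
    retest_stability: float = 0.9
    #: within-subject correlation of the time and error-rate effects
    skill_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("base_median_time_s",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "base_error_rate",
            "subject_sd_log_time",
            "subject_sd_log_rate",
            "residual_sd_log_time",
            "error_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.retest_stability <= 1.0:
            raise ValueError("retest_stability must be in [0, 1]")
        if not -1.0 <= self.skill_correlation <= 1.0:
            raise ValueError("skill_correlation must be in [-1, 1]")

    @property
    def condition_effects(self) -> dict[str, float]:
        return {
            "baseline": 0.0,
            "fatigue": self.effect_fatigue,
            "stress": self.effect_stress,
            "fatigue_stress": self.effect_combined,
        }

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        """Load a config from a TOML file whose keys mirror the field names."""
        import tomllib

        data = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation keys in {path}: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


def _corr_sqrt(corr: np.ndarray) -> np.ndarray:
    """Symmetric square root of a correlation matrix (tolerates rank loss)."""
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _count_from_quantile(mean: np.ndarray, dispersion: float, z: np.ndarray) -> np.ndarray:
    """Count draw via the Gaussian copula: the quantile of the count
    distribution at Phi(z).  Variance is mean * (1 + dispersion)."""
    mean = np.asarray(mean, dtype=float)
    q = norm.cdf(z)
    out = np.zeros_like(mean)
    pos = mean > 0
    if dispersion > 0:
        r = mean[pos] / dispersion
        p = 1.0 / (1.0 + dispersion)
        out[pos] = nbinom.ppf(q[pos], r, p)
    else:
        out[pos] = poisson.ppf(q[pos], mean[pos])
    return out.astype(int)


def _subject_latents(
    rng: np.random.Generator, n: int, n_sessions: int, stability: float, skill: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (u, v, w) latents of shape (n, n_sessions).

    u scales to the log-time effect, v to the log-rate effect, w is the
    count-copula latent.  Within a session corr(u, v) = skill; across
    sessions every latent correlates at ``stability``; w is independent
    of (u, v).
    """
    if n_sessions == 1:
        z = rng.standard_normal((n, 2))
        u = z[:, :1]
        v = skill * z[:, :1] + math.sqrt(max(0.0, 1 - skill**2)) * z[:, 1:2]
        w = rng.standard_normal((n, 1))
        return u, v, w
    rho, c = stability, skill
    corr_uv = np.array(
        [
            [1, rho, c, rho * c],
            [rho, 1, rho * c, c],
            [c, rho * c, 1, rho],
            [rho * c, c, rho, 1],
        ]
    )
    z = rng.standard_normal((n, 4)) @ _corr_sqrt(corr_uv).T
    u, v = z[:, :2], z[:, 2:]
    corr_w = np.array([[1, rho], [rho, 1]])
    w = rng.standard_normal((n, 2)) @ _corr_sqrt(corr_w).T
    return u, v, w


def simulate_validity_study(
    config: SimulationConfig, schedule: CrossoverSchedule
) -> list[TrialRecord]:
    """Simulate the four-arm crossover: one trial per subject per condition.

    Trials are emitted in each subject's scheduled session order, so the
    output is exactly the pile of result files an examiner would collect.
    """
    if schedule.n_subjects != config.n_subjects:
        raise ValueError(
            f"schedule has {schedule.n_subjects} subjects, config expects "
            f"{config.n_subjects}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_subjects
    u, v, w_unused = _subject_latents(
        rng, n, 1, config.retest_stability, config.skill_correlation
    )
    u = config.subject_sd_log_time * u[:, 0]
    v = config.subject_sd_log_rate * v[:, 0]
    effects = config.condition_effects
    trials: list[TrialRecord] = []
    for i, (subject, order) in enumerate(schedule.orders.items()):
        for cond in order:
            beta = effects[cond]
            eps = config.residual_sd_log_time * rng.standard_normal()
            t = math.exp(math.log(config.base_median_time_s) + u[i] + beta + eps)
            mean = config.base_error_rate * math.exp(v[i] + beta)
            e = _count_from_quantile(
                np.array([mean]), config.error_dispersion, rng.standard_normal(1)
            )[0]
            trials.append(
                TrialRecord(
                    subject_id=subject,
                    phase="validity",
                    condition=cond,
                    completion_time_s=t,
                    error_count=int(e),
                )
            )
    return trials


def simulate_retest_study(config: SimulationConfig) -> list[TrialRecord]:
    """Simulate two identical sessions per subject, two days apart.

    No condition effects apply; all subject-level latents correlate
    across the sessions at ``retest_stability``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_subjects
    u, v, w = _subject_latents(
        rng, n, 2, config.retest_stability, config.skill_correlation
    )
    u = config.subject_sd_log_time * u
    v = config.subject_sd_log_rate * v
    width = max(2, len(str(n)))
    subjects = [f"R{i:0{width}d}" for i in range(1, n + 1)]
    trials: list[TrialRecord] = []
    for day_idx, cond in enumerate(RETEST_CONDITIONS):
        eps = config.residual_sd_log_time * rng.standard_normal(n)
        times = np.exp(np.log(config.base_median_time_s) + u[:, day_idx] + eps)
        means = config.base_error_rate * np.exp(v[:, day_idx])
        errs = _count_from_quantile(means, config.error_dispersion, w[:, day_idx])
        for i, subject in enumerate(subjects):
            trials.append(
                TrialRecord(
                    subject_id=subject,
                    phase="retest",
                    condition=cond,
                    completion_time_s=float(times[i]),
                    error_count=int(errs[i]),
                )
            )
    # interleave as the sessions happened: subject-major, day within subject
    trials.sort(key=lambda t: (t.subject_id, t.condition))
    return trials


def simulate_event_log(trial: TrialRecord, seed: int) -> EventLog:
    """Invent a raw event log consistent with a trial.

    Error contacts are scattered uniformly over the attempt;
    ``summarize_event_log`` recovers the trial's (time, errors) exactly.
    """
    rng = np.random.default_rng(seed)
    duration = trial.completion_time_s
    times = np.sort(rng.uniform(0.0, duration, size=trial.error_count))
    # keep ms-rounded error times strictly inside the attempt
    times = np.clip(np.round(times, 3), 0.0, duration)
    return EventLog(
        subject_id=trial.subject_id,
        condition=trial.condition,
        rounds=10,
        start_s=0.0,
        error_times_s=tuple(float(t) for t in times),
        end_s=duration,
    )
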