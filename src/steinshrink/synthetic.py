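"""Synthetic multi-participant cohorts with the hierarchical structure the
shrinkage analysis assumes.

Each generator draws a per-participant true parameter from a
between-participant Gaussian, then emits within-participant time series
around it:

* stepping trials with linear foot-placement responses ``dS = J dP`` plus
  residual noise, pelvis-state deviations drawn from a stationary Gaussian;
* metabolic trials with an exponential on-transient (or a constant, for
  resting) sampled at irregular breath times from a gamma renewal process,
  with additive Gaussian noise; metabolic power is split into VO2/VCO2 by a
  fixed respiratory exchange ratio so the Brockway conversion round-trips.

Generator-truth parameter values are returned alongside the trials so tests
and sweeps can compare against both the full-trial proxy truth and the real
underlying value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import BROCKWAY_CO2, BROCKWAY_O2, MetabolicTrial, SteppingTrial

__all__ = [
    "PopulationSpec",
    "StepGenSpec",
    "MetabGenSpec",
    "gen_stepping",
    "gen_metabolic",
    "default_stepping_population",
    "default_step_spec",
    "default_walking_population",
    "default_walking_spec",
    "default_resting_population",
    "default_resting_spec",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant distribution of the true parameter.

    ``k`` participants with true values drawn i.i.d. from
    Normal(between_mean, between_sd^2); ``seed`` fixes the whole cohort.
    """

    k: int
    between_mean: float
    between_sd: float
    seed: int = 0

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("need k >= 4 participants")
        if self.between_sd < 0:
            raise ValueError("between_sd must be non-negative")


@dataclass(frozen=True)
class StepGenSpec:
    """Stepping-trial generator settings.

    ``J_true_base`` is the 2x3 Jacobian shared by the cohort except for the
    ``varied_entry`` (row, col), which is drawn per participant from the
    population spec.  Pelvis-state deviations are Normal(0, state_cov);
    foot-position deviations get additive residual noise of sd
    ``residual_sd`` (m).  Absolute coordinates are reconstructed around
    ``mean_state`` / ``mean_foot`` offsets.
    """

    n_steps: int = 100
    J_true_base: tuple = (
        (0.05, 0.25, 0.0),
        (0.0, 0.0, 0.30),
    )
    varied_entry: tuple = (0, 1)
    state_cov: tuple = (
        (1.0e-4, 0.0, 0.0),
        (0.0, 2.5e-3, 0.0),
        (0.0, 0.0, 2.5e-3),
    )
    residual_sd: float = 0.01
    mean_state: tuple = (0.0, 0.0, 1.30)
    mean_foot: tuple = (0.0, 0.72)

    def __post_init__(self):
        if self.n_steps < 7:
            raise ValueError("n_steps must be at least 7")
        cov = np.asarray(self.state_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("state_cov must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("state_cov must be positive semidefinite")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass(frozen=True)
class MetabGenSpec:
    """Metabolic-trial generator settings.

    The per-participant steady state ``a0`` comes from the population spec;
    transient amplitude and time constant are drawn per participant from
    their own Gaussians (tau redrawn until positive).  Breath times follow a
    gamma renewal process with the stated mean interval and coefficient of
    variation.  ``rer`` is the (constant) respiratory exchange ratio used to
    split metabolic power into VO2/VCO2 by inverting the Brockway equation.
    """

    a1_mean: float = -2.0
    a1_sd: float = 0.3
    tau_mean: float = 30.0
    tau_sd: float = 5.0
    duration_s: float = 390.0
    breath_interval_mean_s: float = 2.2
    breath_interval_cv: float = 0.2
    noise_sd: float = 0.3
    rer: float = 0.85

    def __post_init__(self):
        if self.rer <= 0:
            raise ValueError("respiratory exchange ratio must be positive")
        if self.breath_interval_mean_s <= 0 or self.breath_interval_cv <= 0:
            raise ValueError("breath intervals must be positive")
        if self.tau_mean <= 0:
            raise ValueError("tau_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_stepping_population(seed: int = 0) -> PopulationSpec:
    """k=8 cohort of foot-placement gains around 0.25 with sd 0.08."""
    return PopulationSpec(k=8, between_mean=0.25, between_sd=0.08, seed=seed)


def default_step_spec() -> StepGenSpec:
    return StepGenSpec()


def default_walking_population(seed: int = 0) -> PopulationSpec:
    """k=11 cohort of walking steady states around 4.5 W/kg with sd 0.4."""
    return PopulationSpec(k=11, between_mean=4.5, between_sd=0.4, seed=seed)


def default_walking_spec() -> MetabGenSpec:
    return MetabGenSpec()


def default_resting_population(seed: int = 0) -> PopulationSpec:
    """k=27 cohort of resting rates around 1.2 W/kg with sd 0.15."""
    return PopulationSpec(k=27, between_mean=1.2, between_sd=0.15, seed=seed)


def default_resting_spec() -> MetabGenSpec:
    return MetabGenSpec(noise_sd=0.25)


def _participant_ids(k: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(k)]


def gen_stepping(
    pop: PopulationSpec, spec: StepGenSpec | None = None
) -> tuple[list[SteppingTrial], np.ndarray]:
    """Simulate stepping trials; returns (trials, generator-truth gains)."""
    spec = default_step_spec() if spec is None else spec
    rng = np.random.default_rng(pop.seed)
    gains = pop.between_mean + pop.between_sd * rng.standard_normal(pop.k)
    cov = np.asarray(spec.state_cov, dtype=float)
    mean_state = np.asarray(spec.mean_state, dtype=float)
    mean_foot = np.asarray(spec.mean_foot, dtype=float)
    trials = []
    for pid, gain in zip(_participant_ids(pop.k), gains):
        J = np.asarray(spec.J_true_base, dtype=float).copy()
        J[spec.varied_entry] = gain
        dP = rng.multivariate_normal(np.zeros(3), cov, size=spec.n_steps, method="svd")
        dS = dP @ J.T + spec.residual_sd * rng.standard_normal((spec.n_steps, 2))
        P = mean_state + dP
        S = mean_foot + dS
        trials.append(
            SteppingTrial(
                participant_id=pid,
                x_pelvis=P[:, 0],
                xdot_pelvis=P[:, 1],
                ydot_pelvis=P[:, 2],
                x_foot=S[:, 0],
                y_foot=S[:, 1],
            )
        )
    return trials, gains


def _breath_times(rng, mean, cv, duration):
    # gamma renewal: shape = 1/cv^2, scale = mean * cv^2
    shape = 1.0 / cv**2
    scale = mean * cv**2
    # draw in blocks until the trial duration is covered
    times = []
    t = 0.0
    while t < duration:
        block = rng.gamma(shape, scale, size=64)
        for dt in block:
            t += dt
            if t >= duration:
                break
            times.append(t)
    return np.asarray(times)


def gen_metabolic(
    pop: PopulationSpec,
    spec: MetabGenSpec | None = None,
    resting: bool = False,
) -> tuple[list[MetabolicTrial], np.ndarray]:
    """Simulate breath-by-breath trials; returns (trials, generator-truth a0).

    For walking (``resting=False``) the noiseless power is
    ``a0 + a1 exp(-t/tau)``; for resting it is the constant ``a0``.  Noisy
    power is clipped at zero before splitting into gas fluxes so that the
    non-negativity invariant of :class:`MetabolicTrial` holds.
    """
    spec = default_walking_spec() if spec is None else spec
    rng = np.random.default_rng(pop.seed)
    a0s = pop.between_mean + pop.between_sd * rng.standard_normal(pop.k)
    denom = BROCKWAY_O2 + BROCKWAY_CO2 * spec.rer
    trials = []
    for pid, a0 in zip(_participant_ids(pop.k), a0s):
        t = _breath_times(
            rng, spec.breath_interval_mean_s, spec.breath_interval_cv, spec.duration_s
        )
        if resting:
            e = np.full(t.size, a0)
        else:
            a1 = spec.a1_mean + spec.a1_sd * rng.standard_normal()
            tau = -1.0
            while tau <= 0:
                tau = spec.tau_mean + spec.tau_sd * rng.standard_normal()
            e = a0 + a1 * np.exp(-t / tau)
        e = e + spec.noise_sd * rng.standard_normal(t.size)
        e = np.maximum(e, 0.0)
        vo2 = e / denom
        vco2 = spec.rer * vo2
        trials.append(MetabolicTrial(participant_id=pid, t=t, vo2=vo2, vco2=vco2))
    return trials, a0s
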