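"""Per-participant maximum-likelihood estimators for the three study problems.

Three estimation problems feed the shrinkage stage, each producing one scalar
per participant together with a squared standard error:

* **Foot-placement control** — ordinary least squares of next-stance-foot
  position deviations on midstance pelvis-state deviations (a 2x3 Jacobian
  ``dS = J dP``); the scalar of interest is the sideways-foot response to
  sideways pelvis velocity, J[0, 1].
* **Walking metabolic rate** — metabolic power from breath-by-breath gas
  exchange via the Brockway equation, with the steady state taken as the
  asymptote ``a0`` of an exponential transient ``E = a0 + a1 exp(-t/tau)``;
  its standard error comes from a case-resampling bootstrap.
* **Resting metabolic rate** — a plain mean of metabolic power over the
  first n breaths, with a single standard error pooled across participants
  (center each participant's series, pool the deviations cohort-wide,
  bootstrap the standard error of a mean of n draws from the pool).

Truncation is always "the first n samples" of a trial, mimicking stopping
the recording early.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)

__all__ = [
    "SteppingTrial",
    "JacobianEstimate",
    "MetabolicTrial",
    "ExponentialFit",
    "RestingEstimate",
    "fit_jacobian",
    "extract_gain",
    "brockway",
    "fit_steady_state",
    "resting_mean",
    "BROCKWAY_O2",
    "BROCKWAY_CO2",
    "MIN_STEPS",
    "MIN_METAB_POINTS",
]

#: Brockway coefficients converting mL s^-1 kg^-1 gas fluxes to W/kg.
BROCKWAY_O2 = 16.58
BROCKWAY_CO2 = 4.51

#: minimum steps for the 2x3 deviation-form regression (3 slopes + centering)
MIN_STEPS = 7
#: minimum breaths for the 3-parameter exponential fit
MIN_METAB_POINTS = 5


@dataclass(frozen=True)
class SteppingTrial:
    """One participant's per-step midstance pelvis states and foot placements.

    Arrays are step-ordered and share one length: sideways pelvis position
    ``x_pelvis`` (m), sideways/forward pelvis velocity ``xdot_pelvis`` /
    ``ydot_pelvis`` (m/s) at midstance, and the next stance-foot position
    ``x_foot`` / ``y_foot`` (m).
    """

    participant_id: str
    x_pelvis: np.ndarray
    xdot_pelvis: np.ndarray
    ydot_pelvis: np.ndarray
    x_foot: np.ndarray
    y_foot: np.ndarray

    def __post_init__(self):
        arrays = {}
        for name in ("x_pelvis", "xdot_pelvis", "ydot_pelvis", "x_foot", "y_foot"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite value in {name}")
            arrays[name] = a
        n = {a.size for a in arrays.values()}
        if len(n) != 1:
            raise ValueError("per-step arrays must share one length")
        if n.pop() < MIN_STEPS:
            raise ValueError(
                f"trial {self.participant_id!r} has fewer than {MIN_STEPS} steps"
            )
        for name, a in arrays.items():
            a.setflags(write=False)
            object.__setattr__(self, name, a)

    @property
    def n_steps(self) -> int:
        return self.x_pelvis.size

    def pelvis_state(self) -> np.ndarray:
        """(n, 3) midstance pelvis state P = (X, Xdot, Ydot)."""
        return np.column_stack([self.x_pelvis, self.xdot_pelvis, self.ydot_pelvis])

    def foot_position(self) -> np.ndarray:
        """(n, 2) next stance foot position S = (X_foot, Y_foot)."""
        return np.column_stack([self.x_foot, self.y_foot])


@dataclass(frozen=True)
class JacobianEstimate:
    """Fitted 2x3 foot-placement Jacobian with per-coefficient variances.

    Row order is (X_foot, Y_foot); column order (X_pelvis, Xdot_pelvis,
    Ydot_pelvis).  The shrunk scalar, the sideways-foot gain on sideways
    pelvis velocity, sits at ``J[0, 1]``.
    """

    J: np.ndarray
    coef_variances: np.ndarray
    n_steps_used: int


@dataclass(frozen=True)
class MetabolicTrial:
    """One participant's breath-by-breath gas-exchange series.

    ``t`` (s) strictly increasing; ``vo2`` and ``vco2`` are mass-normalized
    gas fluxes in mL s^-1 kg^-1, both non-negative.
    """

    participant_id: str
    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        vco2 = np.asarray(self.vco2, dtype=float)
        if not (t.size == vo2.size == vco2.size):
            raise ValueError("t, vo2, vco2 must share one length")
        for name, a in (("t", t), ("vo2", vo2), ("vco2", vco2)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite value in {name}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"trial {self.participant_id!r}: breath times must be "
                "strictly increasing"
            )
        if np.any(vo2 < 0) or np.any(vco2 < 0):
            raise ValueError("gas fluxes must be non-negative")
        for name, a in (("t", t), ("vo2", vo2), ("vco2", vco2)):
            a.setflags(write=False)
            object.__setattr__(self, name, a)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def edot(self) -> np.ndarray:
        """Metabolic power series (W/kg) via the Brockway equation."""
        return brockway(self.vo2, self.vco2)


@dataclass(frozen=True)
class ExponentialFit:
    """Exponential steady-state fit ``E(t) = a0 + a1 exp(-t/tau)``.

    ``a0`` is the steady-state metabolic rate (W/kg), ``a1`` the transient
    amplitude (negative for an on-transient rising to steady state), ``tau``
    the time constant (s, > 0).  ``se_a0`` is the bootstrap standard error
    of ``a0`` (0 when no bootstrap was requested).
    """

    a0: float
    a1: float
    tau: float
    se_a0: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class RestingEstimate:
    """Per-participant resting metabolic mean with the pooled bootstrap SE."""

    participant_id: str
    mean_edot: float
    se: float
    n_points: int


def brockway(vo2, vco2):
    """Metabolic power (W/kg) from gas fluxes (mL s^-1 kg^-1).

    ``Edot = 16.58 * VO2 + 4.51 * VCO2``, elementwise over arrays.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas fluxes must be non-negative")
    out = BROCKWAY_O2 * vo2 + BROCKWAY_CO2 * vco2
    return float(out) if out.ndim == 0 else out


def fit_jacobian(trial: SteppingTrial, n_steps: int | None = None) -> JacobianEstimate:
    """OLS fit of the foot-placement Jacobian on the first ``n_steps`` steps.

    Outputs and predictors are centered on their means over the truncated
    window and regressed without an intercept (deviation form).  Coefficient
    variances use the homoskedastic OLS formula with residual degrees of
    freedom ``n - 4`` (three slopes plus the implicit mean).
    """
    n = trial.n_steps if n_steps is None else int(n_steps)
    if n < MIN_STEPS:
        raise ValueError(f"need at least {MIN_STEPS} steps, got {n}")
    if n > trial.n_steps:
        raise ValueError(
            f"requested {n} steps but trial {trial.participant_id!r} "
            f"has only {trial.n_steps}"
        )
    P = trial.pelvis_state()[:n]
    S = trial.foot_position()[:n]
    dP = P - P.mean(axis=0)
    dS = S - S.mean(axis=0)
    coef, _, rank, _ = np.linalg.lstsq(dP, dS, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient predictor matrix (collinear pelvis states)")
    J = coef.T  # rows: outputs, cols: predictors
    resid = dS - dP @ coef
    dof = n - 4
    sigma2 = (resid**2).sum(axis=0) / dof  # per output row
    xtx_inv_diag = np.diag(np.linalg.inv(dP.T @ dP))
    coef_var = np.outer(sigma2, xtx_inv_diag)  # 2x3
    return JacobianEstimate(J=J, coef_variances=coef_var, n_steps_used=n)


def extract_gain(jac: JacobianEstimate) -> tuple[float, float]:
    """The shrunk scalar: sideways-foot gain on sideways pelvis velocity.

    Returns the (X_foot, Xdot_pelvis) Jacobian entry and its coefficient
    variance.
    """
    return float(jac.J[0, 1]), float(jac.coef_variances[0, 1])


def _exp_model(params, t):
    a0, a1, tau = params
    return a0 + a1 * np.exp(-t / tau)


def _fit_exponential_once(t, e, tau0, tau_max):
    a0_init = float(e[-max(1, e.size // 3) :].mean())
    a1_init = float(e[0] - a0_init)
    x0 = np.array([a0_init, a1_init, tau0])

    def resid(params):
        return _exp_model(params, t) - e

    res = least_squares(
        resid,
        x0,
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, tau_max]),
        method="trf",
        max_nfev=2000,
    )
    return res


def _fit_exponential(t, e, rng=None, max_restarts=5):
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("degenerate time span")
    tau_max = 10.0 * span
    tau0 = span / 3.0
    rng = np.random.default_rng(0) if rng is None else rng
    for _ in range(max_restarts + 1):
        res = _fit_exponential_once(t, e, tau0, tau_max)
        if res.success:
            return res
        tau0 = span / 3.0 * float(rng.uniform(0.2, 3.0))  # jittered restart
    return None


def fit_steady_state(
    trial: MetabolicTrial,
    n_points: int,
    bootstrap_reps: int = 1000,
    seed=None,
) -> ExponentialFit:
    """Nonlinear LS fit of ``E = a0 + a1 exp(-t/tau)`` to the first n breaths.

    The steady-state standard error ``se_a0`` comes from a case-resampling
    bootstrap: resample breath indices with replacement, refit, and take the
    spread of ``a0`` over ``bootstrap_reps`` replicates.  The spread is
    measured by the normal-consistent median absolute deviation rather than
    the plain standard deviation: a small fraction of resampled sets lose
    the early transient, push tau to its bound, and extrapolate an absurd
    asymptote, and those few refits would otherwise dominate the SE.  The
    ``converged`` flag is honest: a fit that fails after restarts is
    returned with ``converged=False`` so the caller can exclude the
    participant.

    ``seed`` may be an int, a :class:`numpy.random.Generator`, or None.
    """
    n_points = int(n_points)
    if n_points < MIN_METAB_POINTS:
        raise ValueError(
            f"need at least {MIN_METAB_POINTS} points for a 3-parameter fit, "
            f"got {n_points}"
        )
    if n_points > trial.n_samples:
        raise ValueError(
            f"requested {n_points} points but trial {trial.participant_id!r} "
            f"has only {trial.n_samples}"
        )
    t = trial.t[:n_points]
    e = trial.edot[:n_points]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    res = _fit_exponential(t, e, rng=rng)
    if res is None:
        logger.warning(
            "exponential fit failed to converge for participant %r at n=%d",
            trial.participant_id,
            n_points,
        )
        return ExponentialFit(
            a0=float("nan"), a1=float("nan"), tau=float("nan"),
            se_a0=float("nan"), converged=False, n_points=n_points,
        )
    a0, a1, tau = (float(v) for v in res.x)

    se_a0 = 0.0
    if bootstrap_reps > 0:
        boot_a0 = []
        for _ in range(bootstrap_reps):
            idx = np.sort(rng.integers(0, n_points, n_points))
            tb, eb = t[idx], e[idx]
            if tb[-1] == tb[0]:
                continue  # all-duplicate draw: no time span to fit
            rb = _fit_exponential(tb, eb, rng=rng, max_restarts=2)
            if rb is not None:
                boot_a0.append(rb.x[0])
        if len(boot_a0) >= 2:
            se_a0 = float(median_abs_deviation(boot_a0, scale="normal"))
    return ExponentialFit(
        a0=a0, a1=a1, tau=tau, se_a0=se_a0, converged=True, n_points=n_points
    )


def resting_mean(
    trials,
    n_points: int,
    bootstrap_reps: int = 1000,
    seed=None,
) -> list[RestingEstimate]:
    """Per-participant resting means with one cohort-pooled bootstrap SE.

    Each participant's estimate is the mean metabolic power over the first
    ``n_points`` breaths.  The shared standard error is obtained by centering
    each participant's truncated series, pooling the deviations over all
    participants, and bootstrapping the standard error of a mean of
    ``n_points`` draws from the pool.
    """
    n_points = int(n_points)
    if n_points < 1:
        raise ValueError("n_points must be positive")
    means, devs = [], []
    for trial in trials:
        if trial.n_samples < n_points:
            raise ValueError(
                f"trial {trial.participant_id!r} has {trial.n_samples} "
                f"points, fewer than n_points = {n_points}"
            )
        e = trial.edot[:n_points]
        m = float(e.mean())
        means.append(m)
        devs.append(e - m)
    if not devs:
        raise ValueError("empty pool: no trials supplied")
    pool = np.concatenate(devs)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if bootstrap_reps > 0 and np.ptp(pool) > 0:
        draws = rng.choice(pool, size=(bootstrap_reps, n_points), replace=True)
        se = float(np.std(draws.mean(axis=1), ddof=1))
    else:
        se = 0.0
    return [
        RestingEstimate(
            participant_id=trial.participant_id,
            mean_edot=m,
            se=se,
            n_points=n_points,
        )
        for trial, m in zip(trials, means)
    ]
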