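import numpy as np
import pytest

from steinshrink.estimators import BROCKWAY_O2, MetabolicTrial, SteppingTrial


@pytest.fixture
def small_estimates():
    """The hand-checked 4-participant set: y = 0..3, unit variances."""
    from steinshrink.shrinkage import EstimateSet

    return EstimateSet(["a", "b", "c", "d"], [0.0, 1.0, 2.0, 3.0], [1.0] * 4)


def make_stepping_trial(J, n_steps=100, residual_sd=0.0, seed=0, pid="P01"):
    """Stepping trial generated exactly from the linear foot-placement model."""
    rng = np.random.default_rng(seed)
    J = np.asarray(J, dtype=float)
    dP = rng.multivariate_normal(
        np.zeros(3), np.diag([1e-4, 2.5e-3, 2.5e-3]), size=n_steps
    )
    dS = dP @ J.T + residual_sd * rng.standard_normal((n_steps, 2))
    P = dP + np.array([0.0, 0.0, 1.3])
    S = dS + np.array([0.0, 0.72])
    return SteppingTrial(
        participant_id=pid,
        x_pelvis=P[:, 0],
        xdot_pelvis=P[:, 1],
        ydot_pelvis=P[:, 2],
        x_foot=S[:, 0],
        y_foot=S[:, 1],
    )


def make_metabolic_trial(edot, t=None, pid="P01"):
    """Metabolic trial whose Brockway power equals ``edot`` exactly (VCO2=0)."""
    edot = np.asarray(edot, dtype=float)
    if t is None:
        t = np.arange(edot.size, dtype=float) * 2.0
    return MetabolicTrial(
        participant_id=pid, t=t, vo2=edot / BROCKWAY_O2, vco2=np.zeros(edot.size)
    )
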