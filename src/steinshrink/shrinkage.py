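"""James-Stein shrinkage of per-participant estimates toward their grand mean.

Given maximum-likelihood estimates ``y_i`` (one per participant, i = 1..k)
with per-participant error variances, the James-Stein estimator (JSE) moves
each estimate toward the grand mean ``ybar`` by a shrinkage factor ``c``::

    z_i = ybar + c * (y_i - ybar)
    c   = 1 - mean(var_i) * (k - 3) / sum((y_i - ybar)**2)

With ``c`` computed this way the JSEs have, on average, lower summed squared
error (SSE) from the unknown true values than the MLEs whenever k >= 4.
When unequal per-participant variances are supplied, their plain mean is
used as the pooled error-variance heuristic.  The positive-part variant
clips a negative ``c`` to zero (never shrink *past* the grand mean); it
dominates the unclipped estimator and is the default here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EstimateSet",
    "ShrinkageResult",
    "RiskComparison",
    "shrinkage_factor",
    "apply_shrinkage",
    "risk_comparison",
    "MIN_PARTICIPANTS",
]

#: smallest cohort for which the shrinkage factor is defined with k - 3 > 0
MIN_PARTICIPANTS = 4


@dataclass(frozen=True)
class EstimateSet:
    """Per-participant estimates with their squared standard errors.

    Parameters
    ----------
    participant_ids
        Opaque labels, one per participant.
    estimates
        The per-participant MLEs ``y_i`` (units of the estimated quantity).
    variances
        Squared standard errors of each ``y_i`` (same units squared);
        all must be non-negative.
    """

    participant_ids: tuple = field()
    estimates: np.ndarray = field()
    variances: np.ndarray = field()

    def __init__(self, participant_ids, estimates, variances):
        ids = tuple(participant_ids)
        y = np.asarray(estimates, dtype=float)
        v = np.asarray(variances, dtype=float)
        if y.ndim != 1 or v.ndim != 1:
            raise ValueError("estimates and variances must be 1-D sequences")
        if not (len(ids) == y.size == v.size):
            raise ValueError(
                f"length mismatch: {len(ids)} ids, {y.size} estimates, "
                f"{v.size} variances"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
            raise ValueError("estimates and variances must be finite")
        if np.any(v < 0):
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "participant_ids", ids)
        object.__setattr__(self, "estimates", y)
        object.__setattr__(self, "variances", v)
        self.estimates.setflags(write=False)
        self.variances.setflags(write=False)

    @property
    def k(self) -> int:
        """Number of participants."""
        return len(self.participant_ids)

    @property
    def grand_mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def mean_variance(self) -> float:
        """Pooled error variance: the plain mean of the supplied variances."""
        return float(self.variances.mean())


@dataclass(frozen=True)
class ShrinkageResult:
    """Outcome of applying James-Stein shrinkage to an :class:`EstimateSet`."""

    grand_mean: float
    c_raw: float
    c: float
    shrunk_estimates: np.ndarray
    used_positive_part: bool


@dataclass(frozen=True)
class RiskComparison:
    """Squared-error comparison of MLEs and JSEs against true values."""

    sse_mle: float
    sse_jse: float
    pct_reduction: float
    per_participant_sq_errors_mle: np.ndarray
    per_participant_sq_errors_jse: np.ndarray
    paired_t_p: float


def _check_shrinkable(est: EstimateSet) -> float:
    if est.k < MIN_PARTICIPANTS:
        raise ValueError(
            f"insufficient participants for shrinkage: k = {est.k} < "
            f"{MIN_PARTICIPANTS} (the shrinkage factor needs k - 3 > 0)"
        )
    ss = float(np.sum((est.estimates - est.grand_mean) ** 2))
    if ss <= 0.0:
        raise ValueError(
            "degenerate spread: all estimates identical, shrinkage factor "
            "undefined (division by zero)"
        )
    return ss


def shrinkage_factor(est: EstimateSet) -> float:
    """Raw James-Stein shrinkage factor ``c`` (may be negative, never > 1).

    ``c = 1 - mean(var) * (k - 3) / sum((y_i - ybar)^2)``.

    Raises
    ------
    ValueError
        If ``k < 4`` or the estimates have zero spread.
    """
    ss = _check_shrinkable(est)
    return 1.0 - est.mean_variance * (est.k - 3) / ss


def apply_shrinkage(est: EstimateSet, positive_part: bool = True) -> ShrinkageResult:
    """Shrink each estimate toward the grand mean: ``z_i = ybar + c (y_i - ybar)``.

    With ``positive_part`` (the default), a negative raw shrinkage factor is
    replaced by zero so that estimates are never moved beyond the grand mean;
    ``used_positive_part`` records whether clipping actually occurred.
    """
    c_raw = shrinkage_factor(est)
    clipped = positive_part and c_raw < 0.0
    c = 0.0 if clipped else c_raw
    ybar = est.grand_mean
    z = ybar + c * (est.estimates - ybar)
    return ShrinkageResult(
        grand_mean=ybar,
        c_raw=c_raw,
        c=c,
        shrunk_estimates=z,
        used_positive_part=clipped,
    )


def risk_comparison(truth, est: EstimateSet, shr: ShrinkageResult) -> RiskComparison:
    """Compare summed squared errors of MLEs and JSEs against true values.

    ``SSE_MLE = sum((x_i - y_i)^2)`` and likewise for the shrunk estimates.
    The percent reduction is ``100 * (SSE_MLE - SSE_JSE) / SSE_MLE`` (defined
    as 0 when both errors vanish).  A two-sided paired t test on the k pairs
    of per-participant squared errors yields ``paired_t_p``.
    """
    x = np.asarray(truth, dtype=float)
    if x.shape != est.estimates.shape:
        raise ValueError(
            f"truth has length {x.size}, expected k = {est.k}"
        )
    sq_mle = (x - est.estimates) ** 2
    sq_jse = (x - shr.shrunk_estimates) ** 2
    sse_mle = float(sq_mle.sum())
    sse_jse = float(sq_jse.sum())
    if sse_mle > 0.0:
        pct = 100.0 * (sse_mle - sse_jse) / sse_mle
    else:
        pct = 0.0
    diffs = sq_mle - sq_jse
    if np.all(diffs == 0.0):
        p = 1.0  # identical errors: no evidence of any difference
    elif np.ptp(diffs) == 0.0:
        p = 0.0  # constant nonzero difference: zero variance, certain shift
    else:
        p = float(stats.ttest_rel(sq_mle, sq_jse).pvalue)
    return RiskComparison(
        sse_mle=sse_mle,
        sse_jse=sse_jse,
        pct_reduction=pct,
        per_participant_sq_errors_mle=sq_mle,
        per_participant_sq_errors_jse=sq_jse,
        paired_t_p=p,
    )
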