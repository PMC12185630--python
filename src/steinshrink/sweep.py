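"""Truncation sweep: how much does shrinkage help at each trial length?

The experiment mirrors the core protocol of the analysis: take each
participant's full trial as the proxy "truth" (100 steps or 54/40 breaths),
recompute every participant's MLE from progressively shorter prefixes, apply
James-Stein shrinkage across participants at each prefix length, and compare
summed squared errors of MLEs and JSEs against the truth.  The decay of
SSE_JSE with prefix length is summarized by an exponential
``SSE = a1 * exp(-b1 * n)`` fitted by linear regression on log(SSE).

On synthetic cohorts the generator's true parameters are also available, so
the sweep reports both comparisons: against the full-trial proxy truth (the
only option for real data, and the source of the known negative-reduction
artifact when the prefix approaches the full length) and against the
generator truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import extract_gain, fit_jacobian, fit_steady_state, resting_mean
from .shrinkage import EstimateSet, apply_shrinkage, risk_comparison

logger = logging.getLogger(__name__)

__all__ = [
    "PROBLEMS",
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "fit_sse_decay",
    "shrinkage_trend",
    "plot_sweep",
]

PROBLEMS = ("foot_placement", "walking_metabolic", "resting_metabolic")

#: full-trial lengths used as proxy truth, per problem
DEFAULT_TRUTH_N = {
    "foot_placement": 100,
    "walking_metabolic": 54,
    "resting_metabolic": 40,
}

#: truncation grids, per problem
DEFAULT_GRIDS = {
    "foot_placement": (15, 25, 35, 50, 70, 90),
    "walking_metabolic": (15, 21, 27, 33, 39, 45, 51),
    "resting_metabolic": (10, 15, 20, 25, 30, 35),
}


@dataclass(frozen=True)
class SweepConfig:
    """Settings for one truncation sweep.

    ``truth_n`` is the full-trial length defining the proxy truth; ``grid``
    the strictly increasing prefix lengths (all below ``truth_n``) at which
    MLEs and JSEs are compared.
    """

    problem: str
    truth_n: int
    grid: tuple
    bootstrap_reps: int = 1000
    seed: int = 0
    positive_part: bool = True

    def __post_init__(self):
        if self.problem not in PROBLEMS:
            raise ValueError(f"unknown problem {self.problem!r}; one of {PROBLEMS}")
        grid = tuple(int(n) for n in self.grid)
        if len(grid) == 0:
            raise ValueError("empty truncation grid")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        if grid[-1] >= self.truth_n:
            raise ValueError("all grid values must be below truth_n")
        object.__setattr__(self, "grid", grid)

    @classmethod
    def default(cls, problem: str, **overrides) -> "SweepConfig":
        kwargs = dict(
            problem=problem,
            truth_n=DEFAULT_TRUTH_N[problem],
            grid=DEFAULT_GRIDS[problem],
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class SweepResult:
    """Per-truncation-length shrinkage outcomes plus the SSE decay fit.

    ``table`` has one row per grid value with columns ``n, c_raw, c,
    sse_mle, sse_jse, pct_reduction, paired_t_p`` (and ``*_true`` variants
    when generator truth was supplied).  ``decay_fit`` is (a1, b1) of
    ``SSE_JSE ~ a1 * exp(-b1 * n)`` against proxy truth, or None if any
    SSE was non-positive.
    """

    config: SweepConfig
    table: pd.DataFrame
    truth: np.ndarray
    participant_ids: tuple
    excluded_ids: tuple = field(default=())
    decay_fit: tuple | None = None


def _stepping_estimates(trials, n):
    out = [extract_gain(fit_jacobian(tr, n)) for tr in trials]
    est, var = zip(*out)
    return np.asarray(est), np.asarray(var), [True] * len(trials)


def _walking_estimates(trials, n, bootstrap_reps, seeds):
    est, var, ok = [], [], []
    for tr, s in zip(trials, seeds):
        fit = fit_steady_state(tr, n, bootstrap_reps=bootstrap_reps, seed=s)
        est.append(fit.a0)
        var.append(fit.se_a0**2)
        ok.append(fit.converged)
    return np.asarray(est), np.asarray(var), ok


def _resting_estimates(trials, n, bootstrap_reps, seed):
    ests = resting_mean(trials, n, bootstrap_reps=bootstrap_reps, seed=seed)
    return (
        np.asarray([e.mean_edot for e in ests]),
        np.asarray([e.se**2 for e in ests]),
        [True] * len(trials),
    )


def run_sweep(trials, cfg: SweepConfig, true_values=None) -> SweepResult:
    """Run the full truncation sweep for one cohort of trials.

    Participants whose metabolic fit fails to converge at any length are
    excluded from the whole sweep (k stays constant across the grid); an
    error is raised if fewer than 4 participants remain or if any trial is
    shorter than ``truth_n``.  The sweep is deterministic given
    ``cfg.seed``.
    """
    trials = list(trials)
    for tr in trials:
        length = tr.n_steps if hasattr(tr, "n_steps") else tr.n_samples
        if length < cfg.truth_n:
            raise ValueError(
                f"participant {tr.participant_id!r} has only {length} "
                f"samples, fewer than truth_n = {cfg.truth_n}"
            )
    if true_values is not None:
        true_values = np.asarray(true_values, dtype=float)
        if true_values.size != len(trials):
            raise ValueError("true_values must have one entry per trial")

    lengths = [cfg.truth_n, *cfg.grid]
    ss = np.random.SeedSequence(cfg.seed)
    # one independent substream per (length, participant) for the bootstraps
    children = ss.spawn(len(lengths) * max(len(trials), 1) + len(lengths))

    per_length = {}
    converged = np.ones(len(trials), dtype=bool)
    for j, n in enumerate(lengths):
        if cfg.problem == "foot_placement":
            est, var, ok = _stepping_estimates(trials, n)
        elif cfg.problem == "walking_metabolic":
            seeds = children[j * len(trials) : (j + 1) * len(trials)]
            est, var, ok = _walking_estimates(trials, n, cfg.bootstrap_reps, seeds)
        else:
            seed = children[len(lengths) * len(trials) + j]
            est, var, ok = _resting_estimates(trials, n, cfg.bootstrap_reps, seed)
        per_length[n] = (est, var)
        converged &= np.asarray(ok)

    keep = np.flatnonzero(converged)
    excluded = tuple(
        trials[i].participant_id for i in np.flatnonzero(~converged)
    )
    for pid in excluded:
        logger.warning("excluding participant %r: non-converged fit", pid)
    if keep.size < 4:
        raise ValueError(
            f"insufficient participants for shrinkage after exclusions: "
            f"k = {keep.size} < 4"
        )
    ids = tuple(trials[i].participant_id for i in keep)
    truth = per_length[cfg.truth_n][0][keep]
    if true_values is not None:
        true_values = true_values[keep]

    rows = []
    for n in cfg.grid:
        est, var = (a[keep] for a in per_length[n])
        est_set = EstimateSet(ids, est, var)
        shr = apply_shrinkage(est_set, positive_part=cfg.positive_part)
        if shr.used_positive_part:
            logger.warning("shrinkage factor clipped to 0 at n = %d", n)
        cmp_proxy = risk_comparison(truth, est_set, shr)
        row = {
            "n": n,
            "c_raw": shr.c_raw,
            "c": shr.c,
            "sse_mle": cmp_proxy.sse_mle,
            "sse_jse": cmp_proxy.sse_jse,
            "pct_reduction": cmp_proxy.pct_reduction,
            "paired_t_p": cmp_proxy.paired_t_p,
        }
        if true_values is not None:
            cmp_true = risk_comparison(true_values, est_set, shr)
            row.update(
                sse_mle_true=cmp_true.sse_mle,
                sse_jse_true=cmp_true.sse_jse,
                pct_reduction_true=cmp_true.pct_reduction,
                paired_t_p_true=cmp_true.paired_t_p,
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    decay = None
    if len(cfg.grid) >= 3 and np.all(table["sse_jse"].to_numpy() > 0):
        decay = fit_sse_decay(table["n"].to_numpy(), table["sse_jse"].to_numpy())
    return SweepResult(
        config=cfg,
        table=table,
        truth=truth,
        participant_ids=ids,
        excluded_ids=excluded,
        decay_fit=decay,
    )


def fit_sse_decay(grid, sse_values) -> tuple[float, float]:
    """Fit ``SSE ~ a1 * exp(-b1 * n)`` by OLS on the log-transformed SSE.

    Returns (a1, b1) where a1 = exp(intercept) and b1 = -slope.
    """
    n = np.asarray(grid, dtype=float)
    sse = np.asarray(sse_values, dtype=float)
    if n.size < 3:
        raise ValueError("need at least 3 grid points for the decay fit")
    if np.any(sse <= 0):
        raise ValueError("non-positive SSE: log-linear decay fit undefined")
    slope, intercept = np.polyfit(n, np.log(sse), 1)
    return float(np.exp(intercept)), float(-slope)


def shrinkage_trend(result: SweepResult) -> dict:
    """Concordance of the shrinkage factor with truncation length.

    Reports the Spearman rank correlation of c against n, whether c is
    non-decreasing across the grid, and any adjacent decreases.  A constant
    c (e.g. pinned at 1) has no defined rank trend and is reported as
    ``"no trend"``.
    """
    n = result.table["n"].to_numpy()
    c = result.table["c"].to_numpy()
    violations = [
        (int(n[i]), int(n[i + 1]))
        for i in range(len(n) - 1)
        if c[i + 1] < c[i]
    ]
    if np.ptp(c) == 0.0:
        return {
            "trend": "no trend",
            "concordance": float("nan"),
            "nondecreasing": True,
            "violations": [],
        }
    rho = float(stats.spearmanr(n, c).statistic)
    trend = "increasing" if rho > 0 else ("decreasing" if rho < 0 else "flat")
    return {
        "trend": trend,
        "concordance": rho,
        "nondecreasing": len(violations) == 0,
        "violations": violations,
    }


def plot_sweep(result: SweepResult, out_dir) -> list:
    """Write the three sweep panels (SSE, percent reduction, c vs n) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = result.table
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t["n"], t["sse_mle"], "o-", label="MLE")
    ax.plot(t["n"], t["sse_jse"], "s-", color="crimson", label="JSE")
    if result.decay_fit is not None:
        a1, b1 = result.decay_fit
        xs = np.linspace(t["n"].min(), t["n"].max(), 100)
        ax.plot(xs, a1 * np.exp(-b1 * xs), "--", color="pink",
                label="JSE fit a1*exp(-b1*n)")
    ax.set_xlabel("truncation length n")
    ax.set_ylabel("summed squared error")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "sse_vs_n.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.plot(t["n"], t["pct_reduction"], "o-", label="vs full-trial truth")
    if "pct_reduction_true" in t:
        ax.plot(t["n"], t["pct_reduction_true"], "s--", label="vs generator truth")
        ax.legend()
    ax.set_xlabel("truncation length n")
    ax.set_ylabel("% SSE reduction by JSE")
    fig.tight_layout()
    p = out_dir / "pct_reduction_vs_n.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t["n"], t["c"], "o-")
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("truncation length n")
    ax.set_ylabel("shrinkage factor c")
    ax.set_ylim(min(0.0, t["c"].min()) - 0.05, 1.05)
    fig.tight_layout()
    p = out_dir / "shrinkage_factor_vs_n.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
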