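"""Model evaluation: IPCW time-dependent concordance, percentile bootstrap,
Welch's t-test for model comparison, Brier score, calibration curves.

The time-dependent concordance C^td at horizon tau scores every comparable
pair (i, j) — t_i < t_j, t_i <= tau, d_i = 1 — as concordant when the model
ranks patient i at higher risk; ties in risk count one half.  Censoring bias
is removed by inverse-probability-of-censoring weights: each pair carries
weight G(t_i)^-2, with G the Kaplan-Meier estimator of the censoring
survival function on the evaluation set (the truncated estimator of Uno et
al.; G is floored to bound the weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CensoringSurvival",
    "censoring_survival",
    "ctd_index",
    "bootstrap_ci",
    "welch_t",
    "brier_score",
    "calibration_curve",
    "evaluable_labels",
    "EvaluationReport",
    "evaluate_predictions",
]

G_FLOOR = 0.05


@dataclass(frozen=True)
class CensoringSurvival:
    """Right-continuous step function G(t): Kaplan-Meier of the censoring
    distribution (censorings treated as events and vice versa).  G(0) = 1."""

    times: np.ndarray    # distinct censoring times, increasing
    values: np.ndarray   # G just after each time

    def __call__(self, t, left_limit: bool = False) -> np.ndarray:
        """G(t) (or the left limit G(t-)); vectorized over t."""
        t_arr = np.asarray(t, dtype=float)
        side = "left" if left_limit else "right"
        idx = np.searchsorted(self.times, t_arr, side=side)
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx]
        return out if t_arr.ndim else float(out)


def censoring_survival(times, events) -> CensoringSurvival:
    """Product-limit estimator of P(censoring time > t).

    Standard convention for tied times: events precede censorings, so the
    at-risk set for a censoring at t excludes subjects whose event occurred
    at t is not reduced — deaths at t remain at risk for the censoring KM.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    uniq = np.unique(t)
    n = len(t)
    g = 1.0
    out_t, out_v = [], []
    for u in uniq:
        at_risk = np.sum(t >= u)
        n_censored = np.sum((t == u) & (d == 0))
        if n_censored > 0:
            g *= 1.0 - n_censored / at_risk
            out_t.append(u)
            out_v.append(g)
    return CensoringSurvival(times=np.asarray(out_t), values=np.asarray(out_v))


def ctd_index(risk_scores, times, events, tau: float,
              censoring: CensoringSurvival | None = None) -> float:
    """IPCW time-dependent concordance at horizon ``tau``.

    Comparable pairs: t_i < t_j with t_i <= tau and d_i = 1; pair weight
    G(t_i)^-2 evaluated as the left limit and floored at 0.05; ties in risk
    count 1/2.  Raises when no comparable pair exists.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(d)):
        raise ValueError("risk/time/event lengths differ")
    if censoring is None:
        censoring = censoring_survival(t, d)
    g = np.maximum(censoring(t, left_limit=True), G_FLOOR)
    w = 1.0 / g ** 2
    # pair (i, j): i ranges over horizon-limited events, j over later times;
    # blocked over i to keep memory linear in block size
    is_case = (d == 1) & (t <= tau)
    case_idx = np.flatnonzero(is_case)
    num = 0.0
    den = 0.0
    block = 256
    for lo in range(0, len(case_idx), block):
        i = case_idx[lo:lo + block]
        comparable = t[i][:, None] < t[None, :]
        concordant = r[i][:, None] > r[None, :]
        tied = r[i][:, None] == r[None, :]
        weights = comparable * w[i][:, None]
        num += float(np.sum(weights * (concordant + 0.5 * tied)))
        den += float(np.sum(weights))
    if den == 0.0:
        raise ValueError(f"no comparable pairs at tau={tau}")
    return float(num / den)


def bootstrap_ci(metric: Callable[[np.ndarray], float], data: np.ndarray,
                 trials: int = 500, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float, np.ndarray]:
    """Percentile bootstrap of ``metric`` over index-resamples of ``data``.

    Resamples with replacement to the original size; returns the empirical
    (2.5th, 97.5th) percentiles and the full vector of per-trial values.
    Trials where the metric fails (e.g., a resample with no comparable pairs)
    are recorded as NaN and excluded from the percentiles.
    """
    n = len(data)
    if n == 0:
        raise ValueError("empty evaluation set")
    rng = np.random.default_rng(seed)
    values = np.empty(trials)
    for b in range(trials):
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = metric(data[idx])
        except Exception:
            values[b] = np.nan
    ok = values[np.isfinite(values)]
    if len(ok) == 0:
        raise ValueError("metric failed in every bootstrap trial")
    alpha = (1.0 - level) / 2.0
    lower = float(np.percentile(ok, 100 * alpha))
    upper = float(np.percentile(ok, 100 * (1 - alpha)))
    return lower, upper, values


def welch_t(sample_a, sample_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided) with Welch-Satterthwaite
    degrees of freedom; both-degenerate equal-mean samples give (0, 1)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need size >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.inf) * np.sign(np.mean(a) - np.mean(b)), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def evaluable_labels(times, events, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Binary outcome at ``horizon`` for calibration/Brier.

    Evaluable subjects: event by the horizon (y = 1) or follow-up beyond it
    (y = 0); subjects censored before the horizon are excluded.  Returns
    (evaluable mask, y for evaluable subjects).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    event_by = (d == 1) & (t <= horizon)
    beyond = t > horizon
    mask = event_by | beyond
    return mask, event_by[mask].astype(float)


def brier_score(predicted, outcomes) -> float:
    """Mean squared difference between predicted probability and the 0/1
    outcome; 0 is a perfect score."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) == 0:
        raise ValueError("empty evaluable set")
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration_curve(predicted, outcomes, bins: int = 10) -> dict:
    """Equal-width probability bins on [0, 1]: per-bin count, mean predicted
    probability, and observed event fraction (NaN for empty bins)."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    with np.errstate(invalid="ignore"):
        mean_pred = np.where(counts > 0,
                             np.bincount(idx, weights=p, minlength=bins)
                             / np.maximum(counts, 1), np.nan)
        observed = np.where(counts > 0,
                            np.bincount(idx, weights=y, minlength=bins)
                            / np.maximum(counts, 1), np.nan)
    return {
        "bin_edges": edges,
        "count": counts,
        "mean_predicted": mean_pred,
        "observed_fraction": observed,
    }


@dataclass
class EvaluationReport:
    """Per-horizon discrimination plus 12-month calibration summary."""

    horizons: list[float]
    ctd: dict[float, float] = field(default_factory=dict)
    ctd_ci: dict[float, tuple[float, float]] = field(default_factory=dict)
    bootstrap_values: dict[float, np.ndarray] = field(default_factory=dict)
    brier: float | None = None
    calibration: dict | None = None
    n_evaluable: int | None = None
    n_excluded_censored: int | None = None

    def to_dict(self) -> dict:
        out = {
            "horizons": self.horizons,
            "ctd": {str(int(h)): self.ctd[h] for h in self.horizons if h in self.ctd},
            "ctd_ci": {str(int(h)): list(self.ctd_ci[h])
                       for h in self.horizons if h in self.ctd_ci},
            "brier_365": self.brier,
            "n_evaluable": self.n_evaluable,
            "n_excluded_censored": self.n_excluded_censored,
        }
        if self.calibration is not None:
            out["calibration"] = {
                k: np.asarray(v).tolist() for k, v in self.calibration.items()
            }
        return out


def evaluate_predictions(risk_matrix: np.ndarray, times, events,
                         horizons: Sequence[float], seed: int = 0,
                         bootstrap_trials: int = 500,
                         calibration_horizon: float | None = None,
                         calibration_bins: int = 10) -> EvaluationReport:
    """Full evaluation of a (n x len(horizons)) risk matrix against observed
    (time, event) outcomes: C^td with percentile bootstrap CI per horizon,
    plus Brier score and a calibration table at the final horizon."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    horizons = [float(h) for h in horizons]
    if risk_matrix.shape != (len(t), len(horizons)):
        raise ValueError(
            f"risk matrix {risk_matrix.shape} does not match "
            f"{len(t)} patients x {len(horizons)} horizons"
        )
    report = EvaluationReport(horizons=horizons)
    stacked = np.column_stack([risk_matrix, t, d])
    for k, tau in enumerate(horizons):
        report.ctd[tau] = ctd_index(risk_matrix[:, k], t, d, tau)

        def metric(rows, _k=k, _tau=tau):
            return ctd_index(rows[:, _k], rows[:, -2], rows[:, -1].astype(int), _tau)

        lo, hi, values = bootstrap_ci(metric, stacked, trials=bootstrap_trials,
                                      seed=seed + k)
        report.ctd_ci[tau] = (lo, hi)
        report.bootstrap_values[tau] = values
    cal_tau = horizons[-1] if calibration_horizon is None else float(calibration_horizon)
    cal_col = horizons.index(cal_tau) if cal_tau in horizons else len(horizons) - 1
    mask, y = evaluable_labels(t, d, cal_tau)
    if mask.sum() > 0:
        p = risk_matrix[mask, cal_col]
        report.brier = brier_score(p, y)
        report.calibration = calibration_curve(p, y, bins=calibration_bins)
        report.n_evaluable = int(mask.sum())
        report.n_excluded_censored = int(len(t) - mask.sum())
    return report
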