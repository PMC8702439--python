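"""Subjective time perception: line-scale normalization and power-law fits.

Participants judge durations by setting a length on a 28.5 cm line; lengths
are converted to subjective days T by anchoring on the mean length produced
for the one-week duration (7 cm-equivalents per week).  Per participant and
delay condition, the power law T = alpha * t**beta is fitted by ordinary
least squares on the log-log scale, the natural estimator under
multiplicative (Weber-like) judgment noise.  alpha captures the overall
degree of time contraction; beta the diminishing sensitivity to time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AnchoringError, FitError, ValidationError

log = logging.getLogger(__name__)

LINE_MAX_CM = 28.5
WEEK_DURATION = 7.0

#: Durations contributing to each condition's perception fit: the delays
#: appearing in that condition's titration battery (SS and LL sides).
CONDITION_DURATIONS: dict[str, frozenset[float]] = {
    "immediate": frozenset({7.0, 15.0, 30.0, 80.0, 140.0}),
    "non_immediate": frozenset({15.0, 22.0, 30.0, 45.0, 95.0, 155.0}),
}


@dataclass(frozen=True)
class PerceptionFit:
    """Power-law parameters for one participant x condition."""

    participant_id: str
    condition: str
    alpha: float
    beta: float
    rss_log: float  # residual sum of squares on the log scale
    n_points: int


def normalize_to_days(
    judgments: pd.DataFrame, week_anchor_policy: str = "cohort_mean"
) -> pd.DataFrame:
    """Convert line lengths to subjective days: T = 7 * length / L_week.

    ``L_week`` is the mean one-week line length across the cohort
    (``cohort_mean``) or within each participant (``individual``).
    """
    required = {"participant_id", "duration_days", "line_length_cm"}
    missing = required - set(judgments.columns)
    if missing:
        raise ValidationError(f"judgments table missing columns: {sorted(missing)}")
    week = judgments[judgments["duration_days"] == WEEK_DURATION]
    if week.empty:
        raise AnchoringError("no one-week judgment available for anchoring")
    out = judgments.copy()
    if week_anchor_policy == "cohort_mean":
        anchor = float(week["line_length_cm"].mean())
        if anchor <= 0:
            raise ValidationError("one-week anchor length must be positive")
        out["subjective_days"] = WEEK_DURATION * out["line_length_cm"] / anchor
    elif week_anchor_policy == "individual":
        anchors = week.groupby("participant_id")["line_length_cm"].mean()
        missing_p = set(out["participant_id"]) - set(anchors.index)
        if missing_p:
            raise AnchoringError(
                f"participants without a one-week judgment: {sorted(missing_p)}"
            )
        if (anchors <= 0).any():
            raise ValidationError("one-week anchor length must be positive")
        out["subjective_days"] = (
            WEEK_DURATION
            * out["line_length_cm"]
            / out["participant_id"].map(anchors).to_numpy()
        )
    else:
        raise ValidationError(f"unknown anchoring policy {week_anchor_policy!r}")
    return out


def fit_power_law(
    points,
    condition_durations=None,
    participant_id: str = "anon",
    condition: str = "all",
    method: str = "loglog_ols",
) -> PerceptionFit:
    """Fit T = alpha * t**beta to (duration, subjective days) points.

    The default estimator is OLS on log T = log alpha + beta log t; points
    with T <= 0 are dropped with a logged warning.  ``method='nls'`` uses
    nonlinear least squares on the original scale instead.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be (duration, subjective_days) pairs")
    t, T = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise ValidationError("durations must be positive")
    if condition_durations is not None:
        keep = np.isin(t, list(condition_durations))
        t, T = t[keep], T[keep]
    pos = T > 0
    if not np.all(pos):
        log.warning(
            "dropping %d zero/negative subjective-time points for %s/%s",
            int((~pos).sum()),
            participant_id,
            condition,
        )
        t, T = t[pos], T[pos]
    if t.size < 3:
        raise FitError("need at least 3 usable points for a 2-parameter fit")
    if np.unique(t).size < 2:
        raise FitError("degenerate design: all durations identical")
    x, y = np.log(t), np.log(T)
    beta, log_alpha = np.polyfit(x, y, 1)
    if method == "nls":
        popt, _ = curve_fit(
            lambda tt, a, b: a * tt**b, t, T, p0=[float(np.exp(log_alpha)), beta]
        )
        alpha, beta = float(popt[0]), float(popt[1])
        rss = float(np.sum((np.log(alpha) + beta * x - y) ** 2))
    elif method == "loglog_ols":
        alpha = float(np.exp(log_alpha))
        rss = float(np.sum((log_alpha + beta * x - y) ** 2))
    else:
        raise ValidationError(f"unknown fit method {method!r}")
    return PerceptionFit(
        participant_id=participant_id,
        condition=condition,
        alpha=alpha,
        beta=float(beta),
        rss_log=rss,
        n_points=int(t.size),
    )


def fit_cohort_perception(
    judgments: pd.DataFrame,
    week_anchor_policy: str = "cohort_mean",
    method: str = "loglog_ols",
) -> pd.DataFrame:
    """Per-participant, per-condition power-law fits from raw line judgments.

    Returns a long table (participant_id, condition, alpha, beta, rss_log,
    n_points) ready for the group-level ANOVAs and the subjective-time refit.
    """
    normalized = normalize_to_days(judgments, week_anchor_policy)
    rows = []
    for pid, sub in normalized.groupby("participant_id", sort=True):
        for cond, durations in CONDITION_DURATIONS.items():
            pts = sub[sub["duration_days"].isin(durations)][
                ["duration_days", "subjective_days"]
            ].to_numpy()
            fit = fit_power_law(
                pts, durations, participant_id=str(pid), condition=cond, method=method
            )
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "alpha": fit.alpha,
                    "beta": fit.beta,
                    "rss_log": fit.rss_log,
                    "n_points": fit.n_points,
                }
            )
    return pd.DataFrame(rows)
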