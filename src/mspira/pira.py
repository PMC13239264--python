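"""Detection of progression independent of relapse activity (PIRA).

PIRA is operationalized as confirmed EDSS worsening, with a roving
(re-settable) baseline, in a cohort that is relapse-free during follow-up:

* the baseline EDSS is the score closest in time to therapy start within
  (-1 year, +1 month], ignoring scores within 30 days of a relapse;
* worsening requires an increase from the current baseline of at least
  1.5 points if the baseline is 0, 1.0 if 1-5.5, and 0.5 if 6-9.5;
* a worsening event must occur between +1 month and +6 years and be
  confirmed by a score at least 12 months later, with every score in the
  confirmation interval remaining at or above the worsening threshold level
  (scores recorded after 6 years may still confirm);
* after a confirmed (>= 3 months) EDSS improvement the baseline is reset
  ("roving baseline") and the worsening threshold is recomputed from the
  new, lower baseline.

The improvement magnitude needed for re-baselining is not fixed by the
worsening criteria; here any decrease of >= 0.5 (one grid step) below the
current baseline counts as an improvement candidate, confirmed by a score
>= 3 months later with all interim scores strictly below the current
baseline, and the new baseline is the minimum score over the confirmation
interval. This mirrors the structure of worsening confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import DAYS_PER_MONTH, DAYS_PER_YEAR, FOLLOWUP_DAYS

__all__ = [
    "EDSS_GRID",
    "PIRAParams",
    "BaselineAssessment",
    "PIRAResult",
    "worsening_threshold",
    "clean_scores",
    "select_baseline_score",
    "confirm_worsening",
    "detect_pira",
    "detect_cohort",
]

#: admissible EDSS values: 0 plus the half-point grid from 1.0 to 9.5
EDSS_GRID = (0.0,) + tuple(1.0 + 0.5 * k for k in range(18))

_GRID_SET = frozenset(EDSS_GRID)


def _on_grid(value: float) -> bool:
    return float(value) in _GRID_SET


@dataclass(frozen=True)
class PIRAParams:
    """Windows and thresholds of the PIRA definition (all times in days)."""

    baseline_window: tuple[float, float] = (-DAYS_PER_YEAR, DAYS_PER_MONTH)
    relapse_exclusion_window: float = 30.0
    event_window: tuple[float, float] = (DAYS_PER_MONTH, FOLLOWUP_DAYS)
    confirmation_min: float = DAYS_PER_YEAR
    improvement_confirmation_min: float = 3 * DAYS_PER_MONTH
    improvement_step: float = 0.5

    def __post_init__(self) -> None:
        if self.confirmation_min <= 0:
            raise ValueError("confirmation_min must be positive")
        if self.improvement_confirmation_min <= 0:
            raise ValueError("improvement_confirmation_min must be positive")


@dataclass(frozen=True)
class BaselineAssessment:
    edss: float
    t: float
    provenance: str  # "initial" | "rebaselined"


@dataclass
class PIRAResult:
    pira: bool
    event_t: float | None = None
    confirmed_at_t: float | None = None
    baseline_history: list[BaselineAssessment] = field(default_factory=list)
    censor_reason: str | None = None  # "no_event" | "no_followup_scores"

    @property
    def n_rebaselines(self) -> int:
        return sum(1 for b in self.baseline_history if b.provenance == "rebaselined")


def worsening_threshold(baseline_edss: float) -> float:
    """Required EDSS increase for worsening, given the current baseline.

    0 -> 1.5; 1.0-5.5 -> 1.0; 6.0-9.5 -> 0.5.
    """
    b = float(baseline_edss)
    if not _on_grid(b):
        raise ValueError(f"EDSS value {baseline_edss!r} is not on the EDSS grid")
    if b == 0.0:
        return 1.5
    if b <= 5.5:
        return 1.0
    return 0.5


def clean_scores(
    times: np.ndarray,
    scores: np.ndarray,
    relapse_times: np.ndarray,
    window: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop every score within `window` days of any relapse (|dt| <= window)."""
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    relapse_times = np.asarray(relapse_times, dtype=float)
    if relapse_times.size == 0 or times.size == 0:
        return times, scores
    dist = np.abs(times[:, None] - relapse_times[None, :]).min(axis=1)
    keep = dist > window
    return times[keep], scores[keep]


def select_baseline_score(
    times: np.ndarray,
    scores: np.ndarray,
    params: PIRAParams | None = None,
) -> BaselineAssessment | None:
    """Baseline = cleaned score closest in time to therapy start.

    Eligible scores lie in (lo, hi] (default (-1 y, +1 mo]); ties in |t| are
    broken in favour of the pre-start score, which reflects the pre-treatment
    state.
    """
    params = params or PIRAParams()
    lo, hi = params.baseline_window
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    mask = (times > lo) & (times <= hi)
    if not mask.any():
        return None
    cand_t = times[mask]
    cand_e = scores[mask]
    # sort key: |t| then t (ascending) => tie at equal |t| picks negative t
    order = np.lexsort((cand_t, np.abs(cand_t)))
    i = order[0]
    return BaselineAssessment(edss=float(cand_e[i]), t=float(cand_t[i]), provenance="initial")


def confirm_worsening(
    candidate_t: float,
    threshold_level: float,
    later_times: np.ndarray,
    later_scores: np.ndarray,
    params: PIRAParams | None = None,
) -> tuple[bool, float | None]:
    """Confirm a candidate worsening event.

    Confirmed iff some later score at t >= candidate_t + confirmation_min is
    >= threshold_level and every score in (candidate_t, t] stays at or above
    threshold_level. Returns (confirmed, earliest confirming time).
    """
    params = params or PIRAParams()
    for t, e in zip(later_times, later_scores):
        if e < threshold_level:
            return False, None
        if t >= candidate_t + params.confirmation_min:
            return True, float(t)
    return False, None


def _confirm_improvement(
    idx: int,
    times: np.ndarray,
    scores: np.ndarray,
    current_baseline: float,
    params: PIRAParams,
) -> float | None:
    """If the score at `idx` starts a confirmed improvement, return the new
    baseline (minimum score over the confirmation interval), else None."""
    t0 = times[idx]
    for j in range(idx + 1, len(times)):
        if scores[j] >= current_baseline:
            return None
        if times[j] >= t0 + params.improvement_confirmation_min:
            return float(np.min(scores[idx : j + 1]))
    return None


def detect_pira(
    times: np.ndarray,
    scores: np.ndarray,
    baseline: BaselineAssessment,
    params: PIRAParams | None = None,
) -> PIRAResult:
    """Chronological roving-baseline scan for the earliest confirmed event.

    `times`/`scores` are the full cleaned trajectory (may include the
    baseline score and scores beyond the 6-year event window; the latter can
    still confirm). At each post-baseline score, improvement re-baselining is
    evaluated before worsening, so an improved-then-worsened trajectory is
    judged from the improved level.
    """
    params = params or PIRAParams()
    if baseline is None:
        raise ValueError("detect_pira requires a baseline assessment")
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    post = times > baseline.t
    t = times[post]
    e = scores[post]
    history = [baseline]
    current = baseline.edss
    lo, hi = params.event_window

    if t.size == 0:
        return PIRAResult(False, baseline_history=history, censor_reason="no_followup_scores")

    for i in range(len(t)):
        if e[i] <= current - params.improvement_step:
            new_base = _confirm_improvement(i, t, e, current, params)
            if new_base is not None:
                history.append(BaselineAssessment(new_base, float(t[i]), "rebaselined"))
                current = new_base
            continue  # a score below baseline cannot be a worsening event
        if lo < t[i] <= hi:
            level = current + worsening_threshold(current)
            if e[i] >= level:
                ok, conf_t = confirm_worsening(t[i], level, t[i + 1 :], e[i + 1 :], params)
                if ok:
                    return PIRAResult(
                        True,
                        event_t=float(t[i]),
                        confirmed_at_t=conf_t,
                        baseline_history=history,
                    )
    return PIRAResult(False, baseline_history=history, censor_reason="no_event")


def detect_cohort(
    edss: pd.DataFrame,
    relapses: pd.DataFrame,
    patient_ids,
    params: PIRAParams | None = None,
) -> pd.DataFrame:
    """Run cleaning, baseline selection, and detection per patient.

    Returns one row per requested patient with columns ``pira``, ``event_t``,
    ``confirmed_at_t``, ``n_rebaselines``, ``censor_reason``. Patients without
    a valid baseline get ``pira=False`` and ``censor_reason='no_baseline'``
    (upstream inclusion criteria normally remove them).
    """
    params = params or PIRAParams()
    edss_by = {pid: g for pid, g in edss.groupby("patient_id")}
    rel_by = {pid: g["t"].to_numpy(float) for pid, g in relapses.groupby("patient_id")}
    rows = []
    for pid in patient_ids:
        g = edss_by.get(pid)
        if g is None:
            rows.append((pid, False, np.nan, np.nan, 0, "no_baseline"))
            continue
        t, e = clean_scores(
            g["t"].to_numpy(float),
            g["edss"].to_numpy(float),
            rel_by.get(pid, np.empty(0)),
            params.relapse_exclusion_window,
        )
        base = select_baseline_score(t, e, params)
        if base is None:
            rows.append((pid, False, np.nan, np.nan, 0, "no_baseline"))
            continue
        res = detect_pira(t, e, base, params)
        rows.append(
            (
                pid,
                res.pira,
                res.event_t if res.event_t is not None else np.nan,
                res.confirmed_at_t if res.confirmed_at_t is not None else np.nan,
                res.n_rebaselines,
                res.censor_reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "pira", "event_t", "confirmed_at_t", "n_rebaselines", "censor_reason"],
    )
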