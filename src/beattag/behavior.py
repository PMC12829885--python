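"""Rhythm-reproduction scoring: proportional error, correctness, learning slopes.

Participants hear a rhythm and tap it back; reproduced intervals are the
differences between consecutive tap times (the absolute time of the first
tap carries no information — the response window has no external anchor).
A rhythm of n intervals therefore requires n+1 taps: the final tap
demarcates the end of the last interval, mirroring the appended closing
tone in the stimulus. Trials with too many or too few taps cannot be
aligned interval-by-interval and are excluded from error averaging
(and scored incorrect).

Scores:

- proportional error — mean over intervals of |reproduced - target| /
  target; 0 is perfect.
- correctness — every interval within +/-15% of its target (20% for the
  first, more lenient training block).
- learning slope — ordinary least-squares slope of the four session-mean
  errors over chronologically ordered sessions; negative slopes mean
  improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReproductionTrial",
    "EXCLUDED",
    "proportional_error",
    "is_correct",
    "learning_slope",
    "read_tap_log",
    "score_trials",
    "session_condition_means",
    "simulate_tap_log",
]

#: sentinel for trials removed from error averaging (tap-count mismatch)
EXCLUDED = None


@dataclass
class ReproductionTrial:
    """One reproduction attempt: target interonset intervals and tap times (ms)."""

    target_intervals_ms: tuple[float, ...]
    tap_times_ms: tuple[float, ...]
    session: int = 1
    block: int = 1
    condition: str = "strong"
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.target_intervals_ms = tuple(float(x) for x in self.target_intervals_ms)
        self.tap_times_ms = tuple(float(x) for x in self.tap_times_ms)
        if any(t2 <= t1 for t1, t2 in zip(self.tap_times_ms, self.tap_times_ms[1:])):
            raise ValueError("tap times must be strictly increasing")
        if any(d <= 0 for d in self.target_intervals_ms):
            raise ValueError("target intervals must be positive")

    @property
    def reproduced_intervals_ms(self) -> tuple[float, ...]:
        return tuple(np.diff(self.tap_times_ms))

    @property
    def tap_count_ok(self) -> bool:
        """n intervals need exactly n+1 taps for one-to-one alignment."""
        return len(self.tap_times_ms) == len(self.target_intervals_ms) + 1


def proportional_error(trial: ReproductionTrial) -> float | None:
    """Mean of |reproduced - target| / target over the rhythm's intervals.

    Returns :data:`EXCLUDED` (None) when the tap count does not match —
    it is then unclear which tap corresponds to which interval.
    """
    if not trial.tap_count_ok:
        return EXCLUDED
    rep = np.asarray(trial.reproduced_intervals_ms)
    tgt = np.asarray(trial.target_intervals_ms)
    return float(np.mean(np.abs(rep - tgt) / tgt))


def is_correct(trial: ReproductionTrial, tolerance: float = 0.15) -> bool:
    """True iff every reproduced interval is within ``tolerance`` of its target.

    A 500-ms interval is accurately demarcated, at the default 15%
    tolerance, by taps separated by 425-575 ms. Tap-count mismatches are
    incorrect.
    """
    if not trial.tap_count_ok:
        return False
    rep = np.asarray(trial.reproduced_intervals_ms)
    tgt = np.asarray(trial.target_intervals_ms)
    return bool(np.all(np.abs(rep - tgt) <= tolerance * tgt))


def learning_slope(session_errors: Sequence[float]) -> float:
    """OLS slope of mean error across the four chronologically ordered sessions.

    Refuses incomplete profiles: a participant missing a session mean has
    no defined learning rate.
    """
    errors = np.asarray(session_errors, dtype=np.float64)
    if errors.size != 4:
        raise ValueError(f"expected 4 session means, got {errors.size}")
    if np.any(np.isnan(errors)):
        gaps = [i + 1 for i in np.flatnonzero(np.isnan(errors))]
        raise ValueError(f"missing session mean(s) for session(s) {gaps}")
    sessions = np.arange(1.0, 5.0)
    slope, _ = np.polyfit(sessions, errors, 1)
    return float(slope)


def read_tap_log(path: str | Path, targets_ms: dict[str, Sequence[float]]) -> list[ReproductionTrial]:
    """Read a delimited tap log into trials.

    Expected columns: trial_id, session, block, condition, rhythm_id,
    tap_time_ms (one row per tap). ``targets_ms`` maps rhythm_id to the
    rhythm's target interonset intervals.
    """
    rows = pd.read_csv(path)
    trials = []
    for (trial_id, session, block, condition, rhythm_id), grp in rows.groupby(
        ["trial_id", "session", "block", "condition", "rhythm_id"], sort=False
    ):
        trials.append(
            ReproductionTrial(
                target_intervals_ms=tuple(targets_ms[str(rhythm_id)]),
                tap_times_ms=tuple(np.sort(grp["tap_time_ms"].to_numpy())),
                session=int(session),
                block=int(block),
                condition=str(condition),
                trial_id=str(trial_id),
            )
        )
    return trials


def score_trials(trials: Iterable[ReproductionTrial]) -> pd.DataFrame:
    """Per-trial scores: proportional error (NaN when excluded) and correctness.

    The first block of session 1 uses the more lenient 20% correctness
    window; all other blocks use 15%.
    """
    records = []
    for t in trials:
        tol = 0.20 if (t.session == 1 and t.block == 1) else 0.15
        err = proportional_error(t)
        records.append(
            {
                "trial_id": t.trial_id,
                "session": t.session,
                "block": t.block,
                "condition": t.condition,
                "n_target_intervals": len(t.target_intervals_ms),
                "n_taps": len(t.tap_times_ms),
                "excluded": err is EXCLUDED,
                "proportional_error": np.nan if err is EXCLUDED else err,
                "tolerance": tol,
                "correct": is_correct(t, tolerance=tol),
            }
        )
    return pd.DataFrame.from_records(records)


def session_condition_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean proportional error per session x condition (excluded trials dropped)."""
    valid = scores[~scores["excluded"]]
    out = (
        valid.groupby(["session", "condition"], sort=True)["proportional_error"]
        .mean()
        .reset_index()
    )
    return out


def simulate_tap_log(
    rhythm_targets_ms: dict[str, Sequence[float]],
    n_sessions: int = 4,
    trials_per_block: int = 12,
    initial_noise_sd: float = 0.20,
    noise_decay: float = 0.75,
    miss_tap_prob: float = 0.02,
    rng: np.random.Generator | None = None,
) -> list[ReproductionTrial]:
    """Synthetic tap data with Gaussian timing noise shrinking across sessions.

    Each reproduced interval is the target scaled by ``1 + eps`` with
    ``eps ~ N(0, sd_s)`` and ``sd_s = initial_noise_sd * noise_decay**(s-1)``
    — a learner whose timing variability decays geometrically over the four
    training sessions. Occasionally a tap is dropped (tap-count exclusion).
    """
    rng = np.random.default_rng() if rng is None else rng
    ids = sorted(rhythm_targets_ms)
    trials = []
    for session in range(1, n_sessions + 1):
        sd = initial_noise_sd * noise_decay ** (session - 1)
        for block in (1, 2):
            for k in range(trials_per_block):
                rid = ids[rng.integers(len(ids))]
                targets = np.asarray(rhythm_targets_ms[rid], dtype=float)
                eps = rng.normal(0.0, sd, size=targets.size)
                intervals = np.maximum(targets * (1 + eps), 1.0)
                taps = np.concatenate([[0.0], np.cumsum(intervals)])
                if rng.random() < miss_tap_prob:
                    taps = taps[:-1]
                condition = rid.split(":", 1)[0] if ":" in rid else "strong"
                trials.append(
                    ReproductionTrial(
                        target_intervals_ms=tuple(targets),
                        tap_times_ms=tuple(taps),
                        session=session,
                        block=block,
                        condition=condition,
                        trial_id=f"s{session}b{block}t{k}",
                    )
                )
    return trials
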