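"""Adaptive digit-triplet speech-in-noise staircase simulation.

A virtual listener answers triplets with probability given by a logistic
psychometric function whose 50% point is the listener's true
speech-reception threshold (SRT).  The staircase is 1-down/1-up with a
fixed step: the signal-to-noise ratio drops by one step after a correct
answer and rises by one step after an incorrect one, so the procedure
converges on the 50% intelligibility level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from audiotwin.cohort import TwinCohort

logger = logging.getLogger(__name__)


@dataclass
class ListenerProfile:
    """Psychometric description of one virtual listener."""

    srt_true: float
    slope: float = 1.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")


@dataclass
class StaircaseTrace:
    """Record of one adaptive run and the resulting SRT estimate."""

    levels: np.ndarray
    correct: np.ndarray
    step: float
    n_trials: int
    snr_estimate: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        if len(self.levels) != self.n_trials or len(self.correct) != self.n_trials:
            raise ValueError("levels/correct length must equal n_trials")
        diffs = np.abs(np.diff(self.levels))
        if diffs.size and not np.allclose(diffs, self.step):
            raise ValueError("consecutive levels must differ by exactly one step")


def psychometric(snr: float, listener: ListenerProfile) -> float:
    """Probability of a correct triplet at ``snr`` dB.

    ``p = lapse/2 + (1 - lapse) / (1 + exp(-slope * (snr - srt_true)))`` —
    strictly increasing in SNR, equal to 0.5 at the true SRT.
    """
    snr = float(snr)
    if not math.isfinite(snr):
        raise ValueError("snr must be finite")
    lam = listener.lapse_rate
    z = -listener.slope * (snr - listener.srt_true)
    if z > 700.0:  # avoid overflow at extreme slopes/levels
        core = 0.0
    elif z < -700.0:
        core = 1.0
    else:
        core = 1.0 / (1.0 + math.exp(z))
    return lam / 2.0 + (1.0 - lam) * core


def run_staircase(
    listener: ListenerProfile,
    start_snr: float,
    step: float = 2.0,
    n_trials: int = 24,
    burn_in: int = 4,
    seed: int | np.random.Generator = 0,
) -> StaircaseTrace:
    """Run one 1-down/1-up staircase and estimate the SRT.

    The estimate is the mean of the levels presented after ``burn_in``
    trials together with the virtual next level implied by the final
    response.
    """
    if n_trials < 8:
        raise ValueError("n_trials must be >= 8")
    if not step > 0:
        raise ValueError("step must be > 0")
    if not 0 <= burn_in < n_trials:
        raise ValueError("burn_in must be in [0, n_trials)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = np.empty(n_trials, dtype=float)
    correct = np.empty(n_trials, dtype=bool)
    level = float(start_snr)
    for i in range(n_trials):
        levels[i] = level
        p = psychometric(level, listener)
        ok = rng.uniform() < p
        correct[i] = ok
        level = level - step if ok else level + step
    used = np.append(levels[burn_in:], level)  # include the virtual next level
    return StaircaseTrace(
        levels=levels,
        correct=correct,
        step=step,
        n_trials=n_trials,
        snr_estimate=float(used.mean()),
    )


def administer_to_cohort(
    cohort: TwinCohort,
    step: float = 2.0,
    n_trials: int = 24,
    burn_in: int = 4,
    slope: float = 1.0,
    lapse_rate: float = 0.0,
    start_offset: float = 10.0,
    start_jitter: float = 2.0,
    seed: int = 0,
    return_traces: bool = False,
) -> TwinCohort | tuple[TwinCohort, dict[str, StaircaseTrace]]:
    """Run an independent staircase per subject and fill the snr column.

    Each subject's starting level is ``srt_true + start_offset`` plus uniform
    jitter of ``±start_jitter`` dB, mimicking the self-adapted starting
    intensity of the deployed test.  Subjects without a stored true SRT keep
    a missing SNR and are counted in the log.
    """
    rng = np.random.default_rng(seed)
    if len(cohort.records) == 0:
        logger.warning("administer_to_cohort: empty cohort")
        return (cohort, {}) if return_traces else cohort
    traces: dict[str, StaircaseTrace] = {}
    new_records = []
    missing = 0
    for rec in cohort.records:
        truth = rec.latent_truth or {}
        srt_true = truth.get("srt_true")
        new = rec
        if srt_true is None:
            missing += 1
        else:
            start = srt_true + start_offset + rng.uniform(-start_jitter, start_jitter)
            trace = run_staircase(
                ListenerProfile(srt_true=srt_true, slope=slope, lapse_rate=lapse_rate),
                start_snr=start,
                step=step,
                n_trials=n_trials,
                burn_in=burn_in,
                seed=rng,
            )
            traces[rec.subject_id] = trace
            new = type(rec)(
                subject_id=rec.subject_id,
                pair_id=rec.pair_id,
                zygosity=rec.zygosity,
                age=rec.age,
                sex=rec.sex,
                thresholds_left=rec.thresholds_left,
                thresholds_right=rec.thresholds_right,
                snr=trace.snr_estimate,
                latent_truth=rec.latent_truth,
            )
        new_records.append(new)
    if missing:
        logger.warning("administer_to_cohort: %d subjects lacked a true SRT", missing)
    out = TwinCohort(
        records=new_records,
        freqs=cohort.freqs,
        config=cohort.config,
        provenance=cohort.provenance + "; staircase snr",
    )
    return (out, traces) if return_traces else out


def traces_to_frames(
    traces: dict[str, StaircaseTrace],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (subject_id, trial, level_db, correct) and per-subject summary."""
    tidy_rows = []
    summary_rows = []
    for sid, tr in traces.items():
        for i in range(tr.n_trials):
            tidy_rows.append(
                {
                    "subject_id": sid,
                    "trial": i + 1,
                    "level_db": tr.levels[i],
                    "correct": bool(tr.correct[i]),
                }
            )
        summary_rows.append({"subject_id": sid, "snr_estimate": tr.snr_estimate})
    tidy = pd.DataFrame(tidy_rows, columns=["subject_id", "trial", "level_db", "correct"])
    summary = pd.DataFrame(summary_rows, columns=["subject_id", "snr_estimate"])
    return tidy, summary
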