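"""Beat-interval regularity metrics.

A spontaneously beating monolayer yields a well-level series of beat
times. Irregularity is quantified the way the cardiac MEA literature
does: cycle lengths (CL, the interval between successive beats), their
coefficient of variation (COV = 100 x SD/mean, on the beat period),
Poincare pairs (CL_k vs CL_{k+1}; a regular rhythm collapses onto a
single point on the identity line), and a rule-based ectopic-beat
classifier that flags premature depolarisations tightly coupled to the
preceding beat (short coupling interval relative to the running median
cycle length).

COV deliberately includes intervals created by ectopic beats: the metric
summarises total rhythm irregularity, ectopy included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientCoverageError, InvalidArgumentError

__all__ = ["BeatSeries", "RhythmSummary", "cycle_lengths", "cov_percent",
           "poincare_pairs", "classify_ectopic", "rhythm_summary"]


@dataclass
class BeatSeries:
    """Well-level beat times (s) with regular/ectopic classes."""

    well_id: str
    beat_times: np.ndarray
    beat_classes: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, float)
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("beat times must be strictly increasing")
        if len(self.beat_classes) != len(t):
            raise InvalidArgumentError("beat_classes must align 1:1 with beat_times")


@dataclass
class RhythmSummary:
    well_id: str
    mean_cl_s: float
    sd_cl_s: float
    cov_pct: float
    n_beats: int
    n_ectopic: int
    poincare: np.ndarray  # (n_cl - 1, 2) of (CL_k, CL_{k+1})


def cycle_lengths(beat_times: np.ndarray) -> np.ndarray:
    """Successive differences of the beat-time series (s)."""
    t = np.asarray(beat_times, float)
    if t.size < 2:
        raise InsufficientCoverageError("need >= 2 beats for cycle lengths")
    cl = np.diff(t)
    if np.any(cl <= 0):
        raise InvalidArgumentError("beat times must be strictly increasing")
    return cl


def cov_percent(cls_: np.ndarray) -> float:
    """Coefficient of variation of cycle lengths, percent (sample SD)."""
    cl = np.asarray(cls_, float)
    if cl.size < 3:
        raise InsufficientCoverageError("need >= 3 cycle lengths for COV")
    return float(100.0 * np.std(cl, ddof=1) / np.mean(cl))


def poincare_pairs(cls_: np.ndarray) -> np.ndarray:
    """Consecutive (CL_k, CL_{k+1}) pairs for a Poincare plot."""
    cl = np.asarray(cls_, float)
    if cl.size < 2:
        raise InsufficientCoverageError("need >= 2 cycle lengths for Poincare pairs")
    return np.column_stack([cl[:-1], cl[1:]])


def classify_ectopic(beat_times: np.ndarray,
                     coupling_threshold_ratio: float = 0.6,
                     median_window: int = 9) -> np.ndarray:
    """Flag premature (ectopic) beats by coupling interval.

    A beat is ectopic when the interval that precedes it is shorter than
    ``coupling_threshold_ratio`` times the running median of recent cycle
    lengths (trailing window of up to ``median_window`` intervals). The
    first beat, having no preceding interval, is always regular.
    """
    t = np.asarray(beat_times, float)
    if t.size < 4:
        raise InsufficientCoverageError("need >= 4 beats to classify ectopy")
    if not 0.0 < coupling_threshold_ratio < 1.0:
        raise InvalidArgumentError("coupling_threshold_ratio must be in (0, 1)")
    cl = np.diff(t)
    classes = np.array(["regular"] * t.size, dtype=object)
    for k in range(1, t.size):
        prev = cl[max(0, k - 1 - median_window):k - 1]  # intervals before this one
        if prev.size == 0:
            continue
        if cl[k - 1] < coupling_threshold_ratio * float(np.median(prev)):
            classes[k] = "ectopic"
    return classes


def rhythm_summary(series: BeatSeries) -> RhythmSummary:
    """Well-level rhythm statistics (COV includes ectopy-driven intervals)."""
    cl = cycle_lengths(series.beat_times)
    return RhythmSummary(
        well_id=series.well_id,
        mean_cl_s=float(np.mean(cl)),
        sd_cl_s=float(np.std(cl, ddof=1)) if cl.size > 1 else 0.0,
        cov_pct=cov_percent(cl) if cl.size >= 3 else float("nan"),
        n_beats=int(series.beat_times.size),
        n_ectopic=int(np.sum(series.beat_classes == "ectopic")),
        poincare=poincare_pairs(cl) if cl.size >= 2 else np.empty((0, 2)),
    )
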