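"""Per-beat, per-electrode field-potential feature extraction.

The landmarks follow the standard cardiac MEA definitions:

* spike time ``t_spike`` — the instant of maximum downward slope of the
  negative depolarisation spike (sample of the most negative first
  derivative within the detected spike);
* depolarisation slope — that most negative derivative, in V/s (signed);
* ``t_twave`` — the peak of the positive repolarising T-wave;
* FPD — ``(t_twave - t_spike) * 1000`` in ms, the field-potential
  duration (surrogate of action-potential duration / QT interval);
* FPD_c — FPD rate-corrected with the Fridericia cube-root formula,
  ``FPD / CL^(1/3)``, using the well-level cycle length (s) preceding the
  beat.

Spike detection is amplitude-thresholded (multiple of the trace's median
absolute deviation, with a refractory window); the derivative is
estimated with a short Savitzky-Golay filter so that the extremum search
is not dominated by sample-to-sample noise amplification. Electrodes
see the same wavefront at slightly different times, so per-electrode
spikes are clustered into well-level beats before cycle lengths are
assigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import (ClusteringError, InsufficientCoverageError,
                     InvalidArgumentError, InvalidWindowError, SchemaError,
                     UnsupportedInputError)
from .rhythm import classify_ectopic
from .simulate import RecordingBundle

__all__ = [
    "DetectionParams", "detect_beats", "measure_slope", "measure_fpd",
    "cluster_well_beats", "fridericia_correct", "assemble_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["well_id", "differentiation_id", "genotype", "electrode_id",
                   "beat_index", "beat_class", "t_spike_s", "slope_v_per_s",
                   "t_twave_s", "fpd_ms", "cl_s", "fpdc_ms"]


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for spike detection and landmark measurement."""

    threshold_mad: float = 8.0        # detection threshold, multiples of MAD
    refractory_ms: float = 200.0      # minimum spacing between spikes
    spike_halfwidth_ms: float = 8.0   # slope search half-window around the trough
    slope_smooth_ms: float = 0.6      # Savitzky-Golay derivative window
    twave_start_ms: float = 80.0      # T-wave search starts this long after t_spike
    twave_max_s: float = 0.7          # search ceiling when the next beat is unknown
    twave_cl_fraction: float = 0.9    # ... else 0.9 x interval to the next spike
    twave_min_amplitude_mv: float = 0.01  # below this, flag the T-wave as missing
    cluster_window_ms: float = 100.0  # well-level beat clustering window
    ectopic_ratio: float = 0.6        # coupling threshold for ectopy classification


def _derivative(x: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    """First derivative in mV/s, Savitzky-Golay (quadratic) when the
    smoothing window spans >= 5 samples, plain central differences otherwise."""
    m = int(round(smooth_ms / 1000.0 * fs))
    if m % 2 == 0:
        m += 1
    if m >= 5 and x.size > m:
        return savgol_filter(x, m, polyorder=2, deriv=1, delta=1.0 / fs)
    return np.gradient(x, 1.0 / fs)


def measure_slope(trace: np.ndarray, fs: float, start: int, stop: int,
                  smooth_ms: float = 0.6) -> float:
    """Most negative first derivative over ``[start, stop)``, in V/s.

    ``trace`` is in mV. Ties break to the earliest sample.
    """
    slope, _ = _slope_and_index(np.asarray(trace, float), fs, start, stop, smooth_ms)
    return slope


def _slope_and_index(trace: np.ndarray, fs: float, start: int, stop: int,
                     smooth_ms: float) -> tuple[float, int]:
    n = trace.size
    if not (0 <= start < stop <= n):
        raise InvalidWindowError(f"window [{start}, {stop}) outside trace of {n} samples")
    # pad the slice so the filter has context at the window edges
    m = int(round(smooth_ms / 1000.0 * fs)) + 2
    lo, hi = max(0, start - m), min(n, stop + m)
    deriv = _derivative(trace[lo:hi], fs, smooth_ms)
    seg = deriv[start - lo:stop - lo]
    idx = int(np.argmin(seg))  # argmin returns the earliest tie
    return float(seg[idx] / 1000.0), start + idx


def detect_beats(bundle: RecordingBundle,
                 params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Detect depolarisation spikes on every electrode.

    Returns a tidy table (electrode_id, beat_index, t_spike_s,
    slope_v_per_s, amplitude_mv); silent electrodes contribute no rows.
    """
    fs = bundle.sampling_rate
    if fs < 1000.0:
        raise UnsupportedInputError(f"sampling rate {fs} Hz < 1 kHz is unsupported")
    if bundle.duration < 2.0:
        raise UnsupportedInputError("need >= 2 s of signal")
    refractory = max(1, int(params.refractory_ms / 1000.0 * fs))
    half = max(2, int(params.spike_halfwidth_ms / 1000.0 * fs))
    rows = []
    for e, eid in enumerate(bundle.layout.electrode_ids):
        x = bundle.signals[:, e]
        dev = x - np.median(x)
        neg = -dev
        peak_neg = neg.max()
        if peak_neg <= 0:
            continue
        mad = float(np.median(np.abs(dev)))
        # MAD floor guards the noise-free case where most samples sit at
        # exact baseline (MAD 0): fall back to a fraction of the largest
        # negative excursion.
        thr = max(params.threshold_mad * mad, 0.25 * peak_neg)
        troughs, _ = find_peaks(neg, height=thr, distance=refractory)
        for b, p in enumerate(troughs):
            w0, w1 = max(0, p - half), min(x.size, p + half + 1)
            slope, i_spike = _slope_and_index(x, fs, w0, w1, params.slope_smooth_ms)
            rows.append((eid, b, i_spike / fs, slope, float(neg[p])))
    return pd.DataFrame(rows, columns=["electrode_id", "beat_index", "t_spike_s",
                                       "slope_v_per_s", "amplitude_mv"])


def measure_fpd(trace: np.ndarray, fs: float, t_spike: float,
                window: tuple[float, float],
                min_amplitude_mv: float = 0.01,
                baseline: float | None = None) -> tuple[float, float]:
    """Locate the T-wave peak and return ``(t_twave_s, fpd_ms)``.

    The T-wave is the maximum positive deflection (relative to the trace
    median, or ``baseline`` when precomputed) inside ``window`` (s). When
    no deflection exceeds ``min_amplitude_mv`` the beat is flagged
    missing-T-wave by returning ``(nan, nan)`` — callers exclude such
    beats rather than fail.
    """
    x = np.asarray(trace, float)
    t0, t1 = window
    if t0 < t_spike:
        raise InvalidWindowError("T-wave search window must start after t_spike")
    i0, i1 = int(np.ceil(t0 * fs)), int(np.floor(t1 * fs)) + 1
    if not (0 <= i0 < i1 <= x.size):
        raise InvalidWindowError(f"window {window} outside trace bounds")
    if baseline is None:
        baseline = float(np.median(x))
    seg = x[i0:i1]
    idx = int(np.argmax(seg))
    if seg[idx] - baseline < min_amplitude_mv:
        return float("nan"), float("nan")
    t_twave = (i0 + idx) / fs
    return t_twave, (t_twave - t_spike) * 1000.0


def cluster_well_beats(events: pd.DataFrame,
                       window_ms: float = 100.0) -> tuple[np.ndarray, pd.DataFrame]:
    """Group per-electrode spikes into well-level beats.

    The wavefront spreads spike times across the array by up to tens of
    ms, so events within ``window_ms`` of the first event of a cluster
    are one beat. Returns the well-level beat times (median of member
    spike times) and a copy of ``events`` with a ``well_beat`` column.
    """
    if events.empty:
        raise InsufficientCoverageError("no events to cluster")
    window_s = window_ms / 1000.0
    # guard against a window as long as the rhythm itself
    med_cls = [np.median(np.diff(g.values)) for _, g in
               events.groupby("electrode_id")["t_spike_s"] if len(g) >= 2]
    if med_cls and window_s >= min(med_cls):
        raise ClusteringError(
            f"clustering window {window_ms} ms >= minimum per-electrode median "
            f"cycle length ({min(med_cls) * 1000:.0f} ms)")
    ev = events.sort_values("t_spike_s", kind="stable").reset_index(drop=True)
    labels = np.empty(len(ev), dtype=int)
    anchor, beat = ev.t_spike_s.iloc[0], 0
    for i, t in enumerate(ev.t_spike_s.values):
        if t - anchor > window_s:
            beat += 1
            anchor = t
        labels[i] = beat
    ev["well_beat"] = labels
    beat_times = ev.groupby("well_beat")["t_spike_s"].median().values
    return beat_times, ev


def fridericia_correct(fpd_ms, cl_s):
    """Fridericia cube-root rate correction: ``FPD_c = FPD / CL^(1/3)``.

    ``fpd_ms`` in ms, ``cl_s`` in s; vectorised over array inputs.
    """
    fpd = np.asarray(fpd_ms, float)
    cl = np.asarray(cl_s, float)
    if np.any(fpd <= 0) or np.any(cl <= 0):
        raise InvalidArgumentError("FPD and CL must both be positive")
    out = fpd / np.cbrt(cl)
    return float(out) if np.isscalar(fpd_ms) and np.isscalar(cl_s) else out


def assemble_feature_table(bundles: list[RecordingBundle],
                           params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Run detection, clustering and landmark measurement over a cohort.

    Returns one row per (well, electrode, well-level beat) with the
    columns in :data:`FEATURE_COLUMNS`. The first beat of each well has
    no preceding cycle length, hence no FPD_c; beats whose T-wave is
    below the detection floor carry NaN FPD.
    """
    frames = []
    ref = None
    for bundle in bundles:
        meta = bundle.metadata
        for key in ("well_id", "genotype", "differentiation_id"):
            if not meta.get(key):
                raise SchemaError(f"bundle metadata missing {key!r}")
        if ref is None:
            ref = (bundle.layout.to_dict(), bundle.sampling_rate)
        elif (bundle.layout.to_dict(), bundle.sampling_rate) != ref:
            raise SchemaError("bundles must share layout and sampling rate")
        frames.append(_well_features(bundle, params))
    if not frames:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[FEATURE_COLUMNS]


def _well_features(bundle: RecordingBundle, params: DetectionParams) -> pd.DataFrame:
    fs = bundle.sampling_rate
    events = detect_beats(bundle, params)
    if events.empty:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    beat_times, ev = cluster_well_beats(events, params.cluster_window_ms)
    n_beats = beat_times.size
    if n_beats >= 4:
        classes = classify_ectopic(beat_times, params.ectopic_ratio)
    else:
        classes = np.array(["regular"] * n_beats, dtype=object)
    cl = np.full(n_beats, np.nan)
    if n_beats >= 2:
        cl[1:] = np.diff(beat_times)

    eid_to_col = {eid: i for i, eid in enumerate(bundle.layout.electrode_ids)}
    # interval to the next spike on the same electrode bounds the T-wave search
    ev = ev.sort_values(["electrode_id", "t_spike_s"], kind="stable")
    ev["t_next"] = ev.groupby("electrode_id")["t_spike_s"].shift(-1)
    # one row per (electrode, well beat); duplicates cannot arise within the
    # refractory window but guard anyway
    ev = ev.drop_duplicates(subset=["electrode_id", "well_beat"], keep="first")

    n_samples = bundle.n_samples
    baselines = {eid: float(np.median(bundle.signals[:, c]))
                 for eid, c in eid_to_col.items()}
    rows = []
    for r in ev.itertuples(index=False):
        x = bundle.signals[:, eid_to_col[r.electrode_id]]
        t_spike = r.t_spike_s
        gap = (r.t_next - t_spike) if pd.notna(r.t_next) else None
        t_end = t_spike + (min(params.twave_cl_fraction * gap, params.twave_max_s)
                           if gap is not None else params.twave_max_s)
        t_end = min(t_end, (n_samples - 1) / fs)
        t_start = t_spike + params.twave_start_ms / 1000.0
        if t_end <= t_start:
            t_twave, fpd = float("nan"), float("nan")
        else:
            t_twave, fpd = measure_fpd(x, fs, t_spike, (t_start, t_end),
                                       params.twave_min_amplitude_mv,
                                       baseline=baselines[r.electrode_id])
        b = int(r.well_beat)
        fpdc = (fridericia_correct(fpd, cl[b])
                if np.isfinite(fpd) and np.isfinite(cl[b]) else float("nan"))
        rows.append((bundle.metadata["well_id"], bundle.metadata["differentiation_id"],
                     bundle.metadata["genotype"], r.electrode_id, b, classes[b],
                     t_spike, r.slope_v_per_s, t_twave, fpd, cl[b], fpdc))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
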