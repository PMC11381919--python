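"""Activation mapping, conduction velocity and repolarisation dispersion.

For each beat, per-electrode spike times referenced to the earliest
electrode form an activation map. Two summaries follow:

* maximum propagation — the longest activation-time difference across
  the array for one beat (max - min), averaged over regular beats per
  well; the vendor-style statistic for how long the wavefront needs to
  cross the array;
* plane-fit conduction velocity — least squares of activation time
  against electrode position, ``t = t0 + g.(x, y)``; the wavefront speed
  is ``1/|g|`` and the propagation direction ``g/|g|``.

Spatial dispersion of repolarisation is the electrode-to-electrode
variability of FPD within one well: the sample SD and range of
per-electrode mean FPD over regular beats, plus the per-electrode grid
for spatial maps. Ectopic beats are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InsufficientCoverageError
from .layout import ElectrodeLayout

__all__ = ["ActivationMap", "ConductionFit", "DispersionSummary",
           "activation_map", "max_propagation", "plane_velocity",
           "fpd_dispersion", "conduction_summary"]


@dataclass
class ActivationMap:
    """Per-electrode activation times (ms) for one beat, earliest = 0."""

    beat_index: int
    electrode_ids: tuple[str, ...]
    times_ms: np.ndarray
    layout: ElectrodeLayout


@dataclass
class ConductionFit:
    speed_mm_s: float
    direction: np.ndarray      # unit vector of propagation
    residual_rms_ms: float


@dataclass
class DispersionSummary:
    well_id: str
    sd_ms: float               # sample SD of per-electrode mean FPD
    range_ms: float
    electrode_fpd: pd.Series   # per-electrode mean FPD (ms), layout order


def activation_map(features: pd.DataFrame, well: str, beat: int,
                   layout: ElectrodeLayout, min_electrodes: int = 3) -> ActivationMap:
    """Activation times for one (well, beat), relative to the earliest electrode."""
    sel = features[(features.well_id == well) & (features.beat_index == beat)]
    sel = sel.dropna(subset=["t_spike_s"])
    if len(sel) < min_electrodes:
        raise InsufficientCoverageError(
            f"beat {beat} of {well}: only {len(sel)} electrodes detected it")
    t = sel.t_spike_s.values
    return ActivationMap(beat_index=beat,
                         electrode_ids=tuple(sel.electrode_id),
                         times_ms=(t - t.min()) * 1000.0,
                         layout=layout)


def max_propagation(amap: ActivationMap) -> float:
    """Maximum - minimum activation time (ms); the minimum is 0 by construction."""
    return float(amap.times_ms.max() - amap.times_ms.min())


def plane_velocity(amap: ActivationMap, layout: ElectrodeLayout | None = None,
                   min_gradient_ms_per_mm: float = 1e-6) -> ConductionFit:
    """Least-squares plane fit of activation time over electrode position.

    Raises :class:`DegenerateGeometryError` for collinear electrodes or a
    synchronous map (zero gradient means no finite speed).
    """
    layout = layout or amap.layout
    pos = {eid: xy for eid, xy in zip(layout.electrode_ids, layout.coordinates_mm())}
    xy = np.array([pos[e] for e in amap.electrode_ids])
    a = np.column_stack([np.ones(len(xy)), xy])
    if np.linalg.matrix_rank(a) < 3:
        raise DegenerateGeometryError("electrodes are collinear; plane fit is singular")
    coef, _, _, _ = np.linalg.lstsq(a, amap.times_ms, rcond=None)
    g = coef[1:]                       # ms per mm
    gnorm = float(np.linalg.norm(g))
    if gnorm < min_gradient_ms_per_mm:
        raise DegenerateGeometryError("synchronous activation: zero time gradient "
                                      "(speed unbounded)")
    resid = amap.times_ms - a @ coef
    return ConductionFit(speed_mm_s=1000.0 / gnorm,
                         direction=g / gnorm,
                         residual_rms_ms=float(np.sqrt(np.mean(resid ** 2))))


def conduction_summary(features: pd.DataFrame, layout: ElectrodeLayout,
                       min_electrodes: int = 3) -> pd.DataFrame:
    """Per-well conduction statistics over regular beats.

    Columns: well_id, n_beats, mean/sd of per-beat max propagation (ms),
    plane-fit speed (mm/s, mean over beats) and residual RMS (ms).
    """
    rows = []
    for well, wf in features.groupby("well_id"):
        props, speeds, resids = [], [], []
        regular = wf[wf.beat_class == "regular"]
        for beat in sorted(regular.beat_index.unique()):
            try:
                amap = activation_map(regular, well, int(beat), layout, min_electrodes)
            except InsufficientCoverageError:
                continue
            props.append(max_propagation(amap))
            try:
                fit = plane_velocity(amap, layout)
                speeds.append(fit.speed_mm_s)
                resids.append(fit.residual_rms_ms)
            except DegenerateGeometryError:
                pass
        if not props:
            continue
        rows.append((well, len(props), float(np.mean(props)),
                     float(np.std(props, ddof=1)) if len(props) > 1 else 0.0,
                     float(np.mean(speeds)) if speeds else float("nan"),
                     float(np.mean(resids)) if resids else float("nan")))
    return pd.DataFrame(rows, columns=["well_id", "n_beats", "max_propagation_ms",
                                       "max_propagation_sd_ms", "plane_speed_mm_s",
                                       "plane_residual_rms_ms"])


def fpd_dispersion(features: pd.DataFrame, well: str,
                   layout: ElectrodeLayout) -> DispersionSummary:
    """Spatial dispersion of repolarisation for one well.

    Per-electrode mean FPD over regular beats; sample SD (n-1) and range
    across electrodes. Needs >= 2 electrodes with a valid mean FPD.
    """
    wf = features[(features.well_id == well) & (features.beat_class == "regular")]
    per_el = wf.dropna(subset=["fpd_ms"]).groupby("electrode_id")["fpd_ms"].mean()
    if len(per_el) < 2:
        raise InsufficientCoverageError(
            f"{well}: {len(per_el)} electrodes with valid FPD (need >= 2)")
    per_el = per_el.reindex([e for e in layout.electrode_ids if e in per_el.index])
    return DispersionSummary(
        well_id=well,
        sd_ms=float(per_el.std(ddof=1)),
        range_ms=float(per_el.max() - per_el.min()),
        electrode_fpd=per_el,
    )
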