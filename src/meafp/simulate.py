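"""Synthetic extracellular field-potential recordings with ground truth.

The generator emulates a spontaneously beating cardiomyocyte monolayer on
a regular MEA grid: each beat launches a planar activation wavefront that
crosses the array at a configurable conduction speed; every electrode sees
a narrow negative depolarisation spike followed, one field-potential
duration (FPD) later, by a broad positive repolarisation T-wave. Beat-to-
beat cycle-length variability, tightly coupled ectopic (premature) beats,
per-electrode repolarisation heterogeneity and white measurement noise are
all configurable, and every generated quantity is echoed into a
``GroundTruth`` table so downstream feature extraction can be tested by
parameter recovery.

Waveform templates are phenomenological, not biophysical:

* depolarisation spike: negative Gaussian pulse. For a pulse
  ``-A exp(-(t-t0)^2 / (2 s^2))`` the most negative time-derivative is
  ``-A e^{-1/2} / s`` and occurs at ``t0 - s``, so the amplitude is solved
  analytically from the requested maximum downward slope and the spike
  width, and the instant of maximum downward slope (the activation marker
  used throughout the pipeline) is placed exactly at the wavefront arrival
  time.
* T-wave: positive Gaussian whose *peak* sits exactly one true FPD after
  the spike's maximum-slope instant, matching the FPD landmark definition
  (max-slope point to T-wave peak).

Two calibration presets, ``"wt"`` and ``"r403q"``, reproduce the group
means reported for isogenic MYH7 R403Q iPSC-cardiomyocyte monolayers
(depolarisation slope, rate-corrected FPD, cycle-length COV, maximum
propagation time across the array, per-array FPD dispersion, and — for the
mutant — frequent tightly coupled ectopy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError
from .layout import ElectrodeLayout, make_layout

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RecordingBundle",
    "CohortMetadata",
    "PRESETS",
    "preset_config",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
    "simulate_study",
    "iter_study",
    "projection_span_mm",
]

#: Default propagation direction: along the array diagonal (the example
#: wavefront travels from the bottom-right corner to the top-left).
_DIAGONAL = (-1.0 / math.sqrt(2.0), -1.0 / math.sqrt(2.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulated well.

    Units: times in s unless the name says ms; voltages in mV; slope in
    V/s; speed in mm/s; COV in percent.
    """

    layout: ElectrodeLayout = field(default_factory=lambda: make_layout(4, 4, 300.0))
    sampling_rate: float = 12_500.0
    duration: float = 120.0
    mean_cycle_length: float = 1.0
    cycle_length_cov: float = 7.0
    ectopic_probability: float = 0.0
    ectopic_coupling_ratio: float = 0.4
    wavefront_speed: float = 97.9
    wavefront_direction: tuple[float, float] = _DIAGONAL
    spike_amplitude: float | None = None   # informational; derived from slope+width
    spike_width: float = 2.0               # Gaussian sigma of the spike, ms
    target_max_slope: float = -0.14        # V/s, signed (negative)
    mean_fpd: float = 281.0                # ms
    fpd_spatial_sd: float = 11.4           # ms, per-electrode heterogeneity
    fpd_gradient: float = 0.0              # ms/mm along the wavefront direction
    twave_amplitude: float = 0.10          # mV
    twave_width: float = 25.0              # Gaussian sigma of the T-wave, ms
    noise_sd: float = 5e-4                 # mV (0.5 µV RMS white noise)
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if not 0.0 <= self.ectopic_probability < 1.0:
            raise ConfigurationError("ectopic_probability must be in [0, 1)")
        if not 0.0 < self.ectopic_coupling_ratio < 1.0:
            raise ConfigurationError("ectopic_coupling_ratio must be in (0, 1)")
        if self.wavefront_speed <= 0:
            raise ConfigurationError("wavefront_speed must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.mean_fpd <= 0 or self.spike_width <= 0 or self.twave_width <= 0:
            raise ConfigurationError("mean_fpd, spike_width, twave_width must be > 0")
        if self.target_max_slope >= 0:
            raise ConfigurationError("target_max_slope must be negative (downward spike)")
        if self.mean_fpd / 1000.0 + 0.1 >= self.mean_cycle_length:
            raise ConfigurationError(
                "mean_fpd + 100 ms (the cycle-length floor) must stay below "
                "the mean cycle length")
        # Waveform placement feasibility: the spike+T-wave complex must fit
        # inside the shortest interval the beat schedule can produce.
        min_cl_ms = self._min_cycle_length() * 1000.0
        if self.mean_fpd + self.spike_width >= min_cl_ms:
            raise ConfigurationError(
                f"FPD ({self.mean_fpd} ms) + spike width cannot fit in the minimum "
                f"cycle length ({min_cl_ms:.0f} ms); waveforms would overlap"
            )

    def _min_cycle_length(self) -> float:
        """Shortest inter-beat interval the schedule can produce (s)."""
        floor = self.mean_fpd / 1000.0 + 0.1
        if self.ectopic_probability > 0:
            return min(floor, self.ectopic_coupling_ratio * self.mean_cycle_length)
        return floor

    @property
    def spike_amplitude_mv(self) -> float:
        """Rendered spike amplitude (mV), solved from slope and width."""
        sigma_s = self.spike_width / 1000.0
        return abs(self.target_max_slope) * 1000.0 * sigma_s * math.sqrt(math.e)


@dataclass
class GroundTruth:
    """Generator-side truth for one well.

    ``table`` has one row per (beat, electrode) with the true activation
    time, maximum downward slope and FPD; well-level arrays carry the beat
    schedule and wavefront speed.
    """

    table: pd.DataFrame
    beat_times: np.ndarray
    beat_classes: np.ndarray       # "regular" | "ectopic", aligned with beat_times
    cycle_lengths: np.ndarray      # diffs of beat_times, s
    wavefront_speed: float         # mm/s


@dataclass
class RecordingBundle:
    """One well: voltage matrix + geometry + metadata (+ truth if simulated)."""

    signals: np.ndarray            # (n_samples, n_electrodes), mV
    sampling_rate: float
    layout: ElectrodeLayout
    metadata: dict
    truth: GroundTruth | None = None

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class CohortMetadata:
    """Nested replication structure: N differentiations x n wells each."""

    n_differentiations: int
    wells_per_differentiation: int

    def __post_init__(self):
        if self.n_differentiations < 1 or self.wells_per_differentiation < 1:
            raise InvalidArgumentError("N and n must both be >= 1")


def projection_span_mm(layout: ElectrodeLayout,
                       direction: Sequence[float] = _DIAGONAL) -> float:
    """Extent of the array projected onto the propagation direction (mm)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    proj = layout.coordinates_mm() @ d
    return float(proj.max() - proj.min())


def _preset_speed(propagation_ms: float) -> float:
    """Wavefront speed giving the target max propagation time on the
    default 4x4 @ 300 µm grid (diagonal projection span 1.27279 mm)."""
    span = projection_span_mm(make_layout(4, 4, 300.0))
    return span / (propagation_ms / 1000.0)


#: Calibration presets: group means of the two genotypes.
PRESETS: dict[str, dict] = {
    "wt": dict(
        target_max_slope=-0.14, mean_fpd=281.0, cycle_length_cov=7.0,
        wavefront_speed=_preset_speed(13.0), fpd_spatial_sd=11.4,
        ectopic_probability=0.0,
    ),
    "r403q": dict(
        target_max_slope=-0.04, mean_fpd=318.0, cycle_length_cov=17.8,
        wavefront_speed=_preset_speed(25.0), fpd_spatial_sd=22.5,
        ectopic_probability=0.05, ectopic_coupling_ratio=0.4,
    ),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a registered preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; registered: {sorted(PRESETS)}")
    params = {**PRESETS[name], **overrides}
    return SimulationConfig(**params)


def _draw_cycle_lengths(rng: np.random.Generator, cfg: SimulationConfig,
                        n: int) -> np.ndarray:
    """Truncated-normal cycle lengths (floor at FPD + 100 ms)."""
    mean = cfg.mean_cycle_length
    sd = cfg.cycle_length_cov / 100.0 * mean
    floor = cfg.mean_fpd / 1000.0 + 0.1
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[draw > floor][: n - filled]
        out[filled:filled + draw.size] = draw
        filled += draw.size
    return out


def _beat_schedule(rng: np.random.Generator, cfg: SimulationConfig,
                   t_last: float) -> tuple[np.ndarray, np.ndarray]:
    """Regular beat times plus inserted ectopics, up to ``t_last``.

    Ectopics are interpolated between regular beats (the underlying sinus
    schedule is not reset), at a coupling interval of
    ``ectopic_coupling_ratio x median cycle length`` after the preceding
    regular beat.
    """
    n_guess = int(t_last / cfg.mean_cycle_length * 1.5) + 20
    cls = _draw_cycle_lengths(rng, cfg, n_guess)
    t0 = 0.3
    reg = t0 + np.concatenate([[0.0], np.cumsum(cls)])
    reg = reg[reg <= t_last]
    median_cl = float(np.median(cls))
    coupling = cfg.ectopic_coupling_ratio * median_cl
    min_gap = cfg.mean_fpd / 1000.0 + 0.05
    times: list[float] = []
    classes: list[str] = []
    ect_flags = (rng.random(len(reg)) < cfg.ectopic_probability
                 if cfg.ectopic_probability > 0 else np.zeros(len(reg), bool))
    for i, t in enumerate(reg):
        times.append(float(t))
        classes.append("regular")
        if i + 1 < len(reg) and ect_flags[i]:
            t_ect = t + coupling
            # only insert when the complex fits on both sides
            if t_ect - t > min_gap and reg[i + 1] - t_ect > min_gap:
                times.append(float(t_ect))
                classes.append("ectopic")
    return np.asarray(times), np.asarray(classes, dtype=object)


def simulate_recording(config: SimulationConfig) -> RecordingBundle:
    """Render one well and its ground truth.

    Identical ``(config, seed)`` gives bit-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n_samples = int(cfg.duration * fs)
    layout = cfg.layout
    n_el = layout.n_electrodes

    d = np.asarray(cfg.wavefront_direction, float)
    d = d / np.linalg.norm(d)
    proj_mm = layout.coordinates_mm() @ d
    offsets = (proj_mm - proj_mm.min()) / cfg.wavefront_speed  # s, min 0

    sigma_w = cfg.spike_width / 1000.0
    sigma_t = cfg.twave_width / 1000.0
    amp = cfg.spike_amplitude_mv

    # schedule beats so the last complex fits entirely in the record
    tail = offsets.max() + cfg.mean_fpd / 1000.0 + 4 * sigma_t + 4 * sigma_w
    beat_times, beat_classes = _beat_schedule(rng, cfg, cfg.duration - tail)

    # per-electrode true FPD: mean + linear gradient along the wavefront
    # axis + independent heterogeneity (fixed per electrode for the well)
    grad = cfg.fpd_gradient * (proj_mm - proj_mm.mean())
    jitter = rng.normal(0.0, cfg.fpd_spatial_sd, size=n_el) if cfg.fpd_spatial_sd > 0 \
        else np.zeros(n_el)
    fpd_el = cfg.mean_fpd + grad + jitter  # ms
    if np.any(fpd_el <= 0):
        raise ConfigurationError("per-electrode FPD became non-positive; "
                                 "reduce fpd_spatial_sd or fpd_gradient")

    signals = np.zeros((n_samples, n_el))

    def _add_gaussian(col: int, centre: float, sigma: float, amplitude: float) -> None:
        lo = max(0, int((centre - 6 * sigma) * fs))
        hi = min(n_samples, int((centre + 6 * sigma) * fs) + 1)
        if hi <= lo:
            return
        t = np.arange(lo, hi) / fs
        signals[lo:hi, col] += amplitude * np.exp(-0.5 * ((t - centre) / sigma) ** 2)

    rows = []
    for b, (t_beat, klass) in enumerate(zip(beat_times, beat_classes)):
        for e in range(n_el):
            t_act = t_beat + offsets[e]          # instant of max downward slope
            _add_gaussian(e, t_act + sigma_w, sigma_w, -amp)
            t_peak = t_act + fpd_el[e] / 1000.0  # T-wave peak = FPD landmark
            _add_gaussian(e, t_peak, sigma_t, cfg.twave_amplitude)
            rows.append((b, layout.electrode_ids[e], klass, t_act,
                         cfg.target_max_slope, fpd_el[e]))

    if cfg.noise_sd > 0:
        signals += rng.normal(0.0, cfg.noise_sd, size=signals.shape)

    truth = GroundTruth(
        table=pd.DataFrame(rows, columns=["beat_index", "electrode_id", "beat_class",
                                          "t_activation_s", "slope_v_per_s", "fpd_ms"]),
        beat_times=beat_times,
        beat_classes=beat_classes,
        cycle_lengths=np.diff(beat_times),
        wavefront_speed=cfg.wavefront_speed,
    )
    metadata = {"well_id": "well-0", "genotype": "unspecified",
                "differentiation_id": "diff-0", "seed": int(cfg.seed),
                "preset": None}
    return RecordingBundle(signals=signals, sampling_rate=fs, layout=layout,
                           metadata=metadata, truth=truth)


#: Preset parameters that receive a differentiation-level multiplicative offset.
_OFFSET_PARAMS = ("target_max_slope", "mean_fpd", "cycle_length_cov",
                  "wavefront_speed", "fpd_spatial_sd")


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def iter_cohort(preset: str, cohort: CohortMetadata, seed: int,
                between_diff_sd: float = 0.05,
                genotype: str | None = None,
                **overrides):
    """Lazily simulate N differentiations x n wells of one genotype.

    Each differentiation draws an independent multiplicative offset
    (mean 1, SD ``between_diff_sd``) for each preset mean, emulating
    batch-to-batch variability between differentiations; wells within a
    differentiation share those generating means. Child seeds are derived
    deterministically from (seed, differentiation, well).
    """
    base = preset_config(preset, **overrides)
    genotype = genotype or preset
    off_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD1F]))
    for di in range(cohort.n_differentiations):
        factors = {p: 1.0 + (off_rng.normal(0.0, between_diff_sd)
                             if between_diff_sd > 0 else 0.0)
                   for p in _OFFSET_PARAMS}
        cfg_d = replace(base, **{p: getattr(base, p) * f for p, f in factors.items()})
        for wi in range(cohort.wells_per_differentiation):
            cfg_w = replace(cfg_d, seed=_child_seed(int(seed), di, wi))
            bundle = simulate_recording(cfg_w)
            bundle.metadata.update(
                well_id=f"{genotype}-d{di}-w{wi}",
                genotype=genotype,
                differentiation_id=f"{genotype}-d{di}",
                preset=preset,
            )
            yield bundle


def simulate_cohort(preset: str, cohort: CohortMetadata, seed: int,
                    between_diff_sd: float = 0.05,
                    genotype: str | None = None,
                    **overrides) -> list[RecordingBundle]:
    """Materialised :func:`iter_cohort` (see there for semantics)."""
    return list(iter_cohort(preset, cohort, seed, between_diff_sd=between_diff_sd,
                            genotype=genotype, **overrides))


def iter_study(cohort: CohortMetadata, seed: int,
               presets: Sequence[str] = ("wt", "r403q"),
               between_diff_sd: float = 0.05, **overrides):
    """Two-genotype study: one cohort per preset, disjoint seed streams."""
    for gi, name in enumerate(presets):
        yield from iter_cohort(name, cohort, _child_seed(int(seed), 0xC0, gi),
                               between_diff_sd=between_diff_sd, **overrides)


def simulate_study(cohort: CohortMetadata, seed: int,
                   presets: Sequence[str] = ("wt", "r403q"),
                   between_diff_sd: float = 0.05,
                   **overrides) -> list[RecordingBundle]:
    """Materialised :func:`iter_study`."""
    return list(iter_study(cohort, seed, presets=presets,
                           between_diff_sd=between_diff_sd, **overrides))
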