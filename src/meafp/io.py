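"""On-disk formats: recording bundles, expression tables, run manifests.

A recording bundle is a directory per well:

* ``signals.csv`` — column 1 the time in s, one column per electrode
  (header = electrode ids), voltages in mV;
* ``meta.json``   — sampling rate, layout, genotype, well/differentiation
  ids, seed, preset;
* ``truth.csv``   — optional generator ground truth, one row per
  (beat, electrode).

Floats are written with 9 significant digits so re-runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .layout import ElectrodeLayout, make_layout
from .simulate import GroundTruth, RecordingBundle

__all__ = ["FLOAT_FORMAT", "write_bundle", "read_bundle", "write_counts",
           "read_counts", "RunManifest", "write_manifest"]

FLOAT_FORMAT = "%.9g"


def _layout_to_json(layout: ElectrodeLayout) -> dict:
    return {"rows": layout.rows, "cols": layout.cols, "pitch_um": layout.pitch}


def _layout_from_json(d: dict) -> ElectrodeLayout:
    return make_layout(int(d["rows"]), int(d["cols"]), float(d["pitch_um"]))


def write_bundle(bundle: RecordingBundle, path: str | Path) -> Path:
    """Write one well to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = bundle.times()
    df = pd.DataFrame(bundle.signals, columns=list(bundle.layout.electrode_ids))
    df.insert(0, "time_s", t)
    df.to_csv(path / "signals.csv", index=False, float_format=FLOAT_FORMAT)
    meta = {
        "sampling_rate_hz": bundle.sampling_rate,
        "layout": _layout_to_json(bundle.layout),
        **{k: bundle.metadata.get(k) for k in
           ("well_id", "genotype", "differentiation_id", "seed", "preset")},
    }
    if bundle.truth is not None:
        meta["wavefront_speed_mm_s"] = bundle.truth.wavefront_speed
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if bundle.truth is not None:
        bundle.truth.table.to_csv(path / "truth.csv", index=False,
                                  float_format=FLOAT_FORMAT)
    return path


def read_bundle(path: str | Path) -> RecordingBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    meta_path, signals_path = path / "meta.json", path / "signals.csv"
    if not meta_path.exists():
        raise ParseError(f"{meta_path}: file missing")
    if not signals_path.exists():
        raise ParseError(f"{signals_path}: file missing")
    try:
        meta = json.loads(meta_path.read_text())
        layout = _layout_from_json(meta["layout"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{meta_path}: malformed metadata ({exc})")
    try:
        df = pd.read_csv(signals_path)
    except Exception as exc:
        raise ParseError(f"{signals_path}: {exc}")
    expected = ["time_s"] + list(layout.electrode_ids)
    if list(df.columns) != expected:
        raise ParseError(f"{signals_path}: expected columns {expected}, "
                         f"got {list(df.columns)}")
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).values)) + 2  # header = line 1
        raise ParseError(f"{signals_path}: missing value near line {bad}")
    truth = None
    truth_path = path / "truth.csv"
    if truth_path.exists():
        table = pd.read_csv(truth_path)
        beat_times = table.groupby("beat_index")["t_activation_s"].min()
        classes = table.groupby("beat_index")["beat_class"].first()
        truth = GroundTruth(
            table=table,
            beat_times=beat_times.values,
            beat_classes=classes.values.astype(object),
            cycle_lengths=np.diff(beat_times.values),
            wavefront_speed=float(meta.get("wavefront_speed_mm_s", np.nan)),
        )
    metadata = {k: meta.get(k) for k in
                ("well_id", "genotype", "differentiation_id", "seed", "preset")}
    return RecordingBundle(signals=df[list(layout.electrode_ids)].values,
                           sampling_rate=float(meta["sampling_rate_hz"]),
                           layout=layout, metadata=metadata, truth=truth)


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame,
                 counts_path: str | Path, samples_path: str | Path) -> None:
    """Expression matrix (genes x samples, with housekeeping flag) + sample sheet."""
    counts.to_csv(counts_path, float_format=FLOAT_FORMAT)
    samples.to_csv(samples_path, index=False)


def read_counts(counts_path: str | Path,
                samples_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, index_col="gene")
    if "housekeeping" not in counts.columns:
        raise ParseError(f"{counts_path}: missing 'housekeeping' column")
    counts["housekeeping"] = counts["housekeeping"].astype(bool)
    samples = pd.read_csv(samples_path)
    for col in ("sample_id", "group"):
        if col not in samples.columns:
            raise ParseError(f"{samples_path}: missing '{col}' column")
    return counts, samples


@dataclass
class RunManifest:
    """Record of one pipeline invocation: config hash, seed, outputs."""

    tool_version: str
    command: str
    config_hash: str
    seed: int | None
    files: list[str] = field(default_factory=list)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, command: str, config: dict,
                   seed: int | None, files: list[Path | str]) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        command=command,
        config_hash=config_hash(config),
        seed=seed,
        files=sorted(str(Path(f).relative_to(out_dir)) if Path(f).is_relative_to(out_dir)
                     else str(f) for f in files),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    p = out_dir / "manifest.json"
    p.write_text(manifest.to_json())
    return p
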