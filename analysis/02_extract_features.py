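#!/usr/bin/env python
"""Extract per-beat landmarks from the simulated bundles.

Reads every bundle under scratch/bundles/, detects depolarisation
spikes, measures slope / T-wave / FPD / Fridericia-corrected FPD, and
writes the full beat table to scratch/features/beats.csv (large) plus a
compact per-well overview to results/feature_overview.csv.
"""

from pathlib import Path

from meafp.io import read_bundle
from meafp.pipeline import extract_features

ROOT = Path(__file__).resolve().parents[1]
BUNDLES = ROOT / "scratch" / "bundles"
FEATURES = ROOT / "scratch" / "features"
RESULTS = ROOT / "results"


def main() -> None:
    dirs = sorted(p for p in BUNDLES.iterdir() if (p / "signals.csv").exists())
    if not dirs:
        raise SystemExit("no bundles found; run 01_simulate_cohort.py first")
    features, layout = extract_features(read_bundle(d) for d in dirs)
    FEATURES.mkdir(parents=True, exist_ok=True)
    features.to_csv(FEATURES / "beats.csv", index=False, float_format="%.9g")
    (FEATURES / "layout.json").write_text(
        __import__("json").dumps(layout.to_dict()))
    overview = (features.groupby(["well_id", "genotype"])
                .agg(n_rows=("beat_index", "size"),
                     n_beats=("beat_index", "nunique"),
                     mean_slope_v_per_s=("slope_v_per_s", "mean"),
                     mean_fpd_ms=("fpd_ms", "mean"),
                     missing_twave_frac=("fpd_ms", lambda s: s.isna().mean()))
                .reset_index())
    RESULTS.mkdir(exist_ok=True)
    overview.to_csv(RESULTS / "feature_overview.csv", index=False,
                    float_format="%.6g")
    print(f"{len(features)} beat rows from {len(dirs)} wells")
    print(overview.groupby("genotype")[["mean_slope_v_per_s",
                                        "mean_fpd_ms"]].mean().round(4))


if __name__ == "__main__":
    main()
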