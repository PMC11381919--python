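#!/usr/bin/env python
"""Activation mapping, conduction velocity and repolarisation dispersion.

Per well: mean max propagation time (wavefront crossing time), plane-fit
conduction speed, and the across-electrode SD / range of FPD. Also
exports one example activation map and FPD map per genotype as small CSV
grids under results/maps/ for plotting.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from meafp.conduction import activation_map, conduction_summary, fpd_dispersion
from meafp.layout import make_layout
from meafp.pipeline import dispersion_table

ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "scratch" / "features"
RESULTS = ROOT / "results"


def _grid(layout, series):
    g = np.full(layout.n_electrodes, np.nan)
    for i, eid in enumerate(layout.electrode_ids):
        if eid in series.index:
            g[i] = series[eid]
    return pd.DataFrame(g.reshape(layout.rows, layout.cols))


def main() -> None:
    features = pd.read_csv(FEATURES / "beats.csv")
    d = json.loads((FEATURES / "layout.json").read_text())
    layout = make_layout(d["rows"], d["cols"], d["pitch_um"])

    cond = conduction_summary(features, layout)
    disp = dispersion_table(features, layout)
    cond.to_csv(RESULTS / "conduction.csv", index=False, float_format="%.6g")
    disp.to_csv(RESULTS / "dispersion.csv", index=False, float_format="%.6g")

    maps_dir = RESULTS / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    for genotype in features.genotype.unique():
        well = features.loc[features.genotype == genotype, "well_id"].iloc[0]
        amap = activation_map(features, well, 1, layout)
        t = pd.Series(amap.times_ms, index=list(amap.electrode_ids))
        _grid(layout, t).to_csv(maps_dir / f"activation_{genotype}.csv",
                                index=False, float_format="%.4g")
        dsp = fpd_dispersion(features, well, layout)
        _grid(layout, dsp.electrode_fpd).to_csv(
            maps_dir / f"fpd_{genotype}.csv", index=False, float_format="%.5g")

    merged = cond.merge(features[["well_id", "genotype"]].drop_duplicates())
    print(merged.groupby("genotype")[["max_propagation_ms",
                                      "plane_speed_mm_s"]].mean().round(3))
    md = disp.merge(features[["well_id", "genotype"]].drop_duplicates())
    print(md.groupby("genotype")[["fpd_sd_ms", "fpd_range_ms"]].mean().round(3))


if __name__ == "__main__":
    main()
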