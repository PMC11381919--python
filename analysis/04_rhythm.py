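#!/usr/bin/env python
"""Beat-rhythm analysis: cycle-length variability and ectopy.

Per well: mean cycle length, COV (the beat-irregularity metric), beat
and ectopic counts; plus the pooled Poincare pair table (CL_k vs
CL_{k+1}) used for the classic irregularity scatter plots.
"""

from pathlib import Path

import pandas as pd

from meafp.pipeline import rhythm_tables

ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "scratch" / "features"
RESULTS = ROOT / "results"


def main() -> None:
    features = pd.read_csv(FEATURES / "beats.csv")
    rhythm, poincare = rhythm_tables(features)
    rhythm = rhythm.merge(features[["well_id", "genotype"]].drop_duplicates())
    rhythm.to_csv(RESULTS / "rhythm.csv", index=False, float_format="%.6g")
    poincare.to_csv(RESULTS / "poincare.csv", index=False, float_format="%.6g")
    print(rhythm.groupby("genotype")[["mean_cl_s", "cov_pct",
                                      "n_ectopic"]].mean().round(3))
    print(f"{len(poincare)} Poincare pairs -> {RESULTS / 'poincare.csv'}")


if __name__ == "__main__":
    main()
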