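#!/usr/bin/env python
"""Targeted-panel differential expression with two-stage adaptive FDR.

Simulates a 200-gene two-group counting panel with 20 spiked genes at
2.3-fold (up and down), runs housekeeping normalisation, per-gene Welch
tests, the two-stage adaptive FDR step-up at q = 0.05 and the dual
FDR + 2-fold significance rule, and reports recovery of the spiked set.
"""

from pathlib import Path

import numpy as np

from meafp.expression import run_de
from meafp.io import write_counts
from meafp.synth_expression import make_expression_truth, simulate_expression

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20246


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = make_expression_truth(200, n_spiked=20, spike_fold_change=2.3,
                                  seed=SEED)
    counts, samples = simulate_expression(truth, samples_per_group=4,
                                          seed=SEED + 1)
    write_counts(counts, samples, RESULTS / "counts.csv",
                 RESULTS / "samples.csv")
    res = run_de(counts, samples, q=0.05, fc_threshold=2.0)
    res.reset_index().to_csv(RESULTS / "de_results.csv", index=False,
                             float_format="%.6g")
    is_alt = truth.table.fold_change.values != 1.0
    called = res.significant.values
    tp = int((called & is_alt).sum())
    fp = int((called & ~is_alt).sum())
    print(f"{called.sum()} genes significant (FDR 5 % + 2-fold rule): "
          f"{tp}/{is_alt.sum()} spiked recovered, {fp} false positives")
    spiked_up = res.log2fc[is_alt & (truth.table.fold_change.values > 1)]
    print(f"mean |log2FC| of spiked genes: {np.abs(res.log2fc[is_alt]).mean():.3f} "
          f"(expected {np.log2(2.3):.3f}); up-spiked mean {spiked_up.mean():.3f}")


if __name__ == "__main__":
    main()
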