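"""Synthetic targeted-panel count matrices with known fold changes.

Emulates a small hybridisation-counting expression panel (a few hundred
genes, a handful of housekeeping genes) measured in two groups of
samples. Counts are negative binomial — mean ``mu``, variance
``mu + dispersion * mu^2`` — with a per-sample technical scaling factor
shared by *all* genes (housekeeping included), which is what makes
housekeeping normalisation identifiable. Group mean ratios equal the
configured per-gene fold change, so the DE stage can be tested by
recovery; housekeeping genes have fold change exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError

__all__ = ["ExpressionTruth", "make_expression_truth", "simulate_expression"]


@dataclass
class ExpressionTruth:
    """Per-gene generating parameters.

    ``table`` columns: gene, fold_change (group1 mean / group2 mean),
    housekeeping (bool), base_mean (group2 mean before scaling).
    """

    table: pd.DataFrame
    dispersion: float

    def __post_init__(self):
        t = self.table
        if np.any(t.fold_change <= 0):
            raise ConfigurationError("fold changes must be > 0")
        if np.any(t.loc[t.housekeeping, "fold_change"] != 1.0):
            raise ConfigurationError("housekeeping genes must have fold change 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")


def make_expression_truth(n_genes: int, n_spiked: int = 0,
                          spike_fold_change: float = 2.3,
                          n_housekeeping: int = 6,
                          dispersion: float = 0.01,
                          base_mean_range: tuple[float, float] = (200.0, 5000.0),
                          seed: int = 0) -> ExpressionTruth:
    """Truth table with ``n_spiked`` differential genes (alternating up/down
    at ``spike_fold_change``), ``n_housekeeping`` housekeeping genes and the
    rest null. Base means are log-uniform over ``base_mean_range``."""
    if n_genes < n_spiked + n_housekeeping:
        raise InvalidArgumentError("n_genes must cover spiked + housekeeping genes")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(base_mean_range[0]),
                              np.log(base_mean_range[1]), size=n_genes))
    fc = np.ones(n_genes)
    hk = np.zeros(n_genes, bool)
    hk[:n_housekeeping] = True
    for i in range(n_spiked):
        fc[n_housekeeping + i] = (spike_fold_change if i % 2 == 0
                                  else 1.0 / spike_fold_change)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    table = pd.DataFrame({"gene": genes, "fold_change": fc,
                          "housekeeping": hk, "base_mean": base})
    return ExpressionTruth(table=table, dispersion=float(dispersion))


def simulate_expression(truth: ExpressionTruth, samples_per_group: int,
                        seed: int, sample_scale_sd: float = 0.15,
                        group_labels: tuple[str, str] = ("wt", "r403q"),
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genes x samples count matrix plus a sample sheet.

    Group 1 means are ``base_mean * fold_change``, group 2 means
    ``base_mean``; each sample gets a lognormal technical scale factor
    applied to every gene. Deterministic under ``seed``.

    Returns ``(counts, samples)``: counts indexed by gene with a
    ``housekeeping`` column and one column per sample; samples with
    columns sample_id, group.
    """
    if samples_per_group < 2:
        raise InvalidArgumentError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    t = truth.table
    n_genes = len(t)
    sample_ids, groups, cols = [], [], []
    for gi, label in enumerate(group_labels):
        mu_g = t.base_mean.values * (t.fold_change.values if gi == 0 else 1.0)
        for s in range(samples_per_group):
            scale = float(np.exp(rng.normal(0.0, sample_scale_sd)))
            mu = mu_g * scale
            if truth.dispersion > 0:
                r = 1.0 / truth.dispersion
                counts = rng.negative_binomial(r, r / (r + mu), size=n_genes)
            else:
                counts = rng.poisson(mu, size=n_genes)
            sid = f"{label}_{s}"
            sample_ids.append(sid)
            groups.append(label)
            cols.append(pd.Series(counts, name=sid))
    counts = pd.concat(cols, axis=1)
    counts.insert(0, "housekeeping", t.housekeeping.values)
    counts.index = pd.Index(t.gene.values, name="gene")
    samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return counts, samples
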