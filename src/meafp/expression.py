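"""Targeted-panel differential expression with adaptive FDR control.

Stages:

1. housekeeping normalisation — each sample's scale factor is the
   geometric mean of its housekeeping-gene counts; counts are rescaled by
   (cohort mean scale factor / sample scale factor), so housekeeping
   geometric means agree across samples afterwards;
2. per-gene statistics — log2 fold change as the difference of group
   means of log2(normalised + pseudocount) (i.e. the log ratio of
   geometric means), with an unequal-variance (Welch) two-sample t test
   on the same log scale;
3. two-stage adaptive FDR (Benjamini-Krieger-Yekutieli): a first linear
   step-up at q' = q/(1+q) estimates the number of true nulls
   m0_hat = m - r1, then a second step-up runs at q' * m / m0_hat;
4. the dual significance rule: a gene is called significant when it is
   rejected at FDR q *and* its linear fold change is at least
   ``fc_threshold`` in either direction (|log2FC| >= log2(threshold)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, NormalizationError, SchemaError

__all__ = ["normalize", "de_test", "bky_adjust", "call_significant", "run_de"]


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Housekeeping geometric-mean normalisation.

    ``counts`` is gene-indexed with a boolean ``housekeeping`` column and
    one numeric column per sample. Every housekeeping gene must have a
    positive count in every sample.
    """
    if "housekeeping" not in counts.columns:
        raise SchemaError("counts table needs a 'housekeeping' column")
    hk = counts.index[counts.housekeeping.astype(bool)]
    if len(hk) == 0:
        raise SchemaError("no housekeeping genes flagged")
    samples = [c for c in counts.columns if c != "housekeeping"]
    mat = counts[samples].astype(float)
    hk_mat = mat.loc[hk]
    for s in samples:
        if (hk_mat[s] <= 0).any():
            bad = hk_mat.index[hk_mat[s] <= 0][0]
            raise NormalizationError(
                f"sample {s!r}: housekeeping gene {bad!r} has zero count")
    scale = np.exp(np.log(hk_mat).mean(axis=0))          # per-sample factor
    factors = scale.mean() / scale
    out = mat * factors
    out.insert(0, "housekeeping", counts.housekeeping.values)
    return out


def de_test(normalized: pd.DataFrame, samples: pd.DataFrame,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-test p value.

    Fold change is group1/group2 on the geometric-mean scale (groups in
    the order they appear in ``samples``). Genes constant in both groups
    get p = 1.
    """
    if samples.group.nunique() != 2:
        raise SchemaError("exactly two groups are required")
    groups = list(dict.fromkeys(samples.group))
    cols = {g: samples.loc[samples.group == g, "sample_id"].tolist() for g in groups}
    for g, ids in cols.items():
        if len(ids) < 2:
            raise SchemaError(f"group {g!r} has fewer than 2 samples")
    mat = normalized.drop(columns=["housekeeping"], errors="ignore").astype(float)
    log1 = np.log2(mat[cols[groups[0]]].values + pseudocount)
    log2_ = np.log2(mat[cols[groups[1]]].values + pseudocount)
    log2fc = log1.mean(axis=1) - log2_.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log1, log2_, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no evidence
    return pd.DataFrame({"gene": mat.index, "log2fc": log2fc, "p": p}
                        ).set_index("gene")


def _step_up(p: np.ndarray, level: float) -> np.ndarray:
    """Linear (Benjamini-Hochberg) step-up at the given level."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    reject = np.zeros(m, bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[:k + 1]] = True
    return reject


def bky_adjust(pvalues, q: float = 0.05) -> np.ndarray:
    """Two-stage adaptive false-discovery-rate step-up.

    Stage 1: linear step-up at q' = q/(1+q), giving r1 rejections. If
    r1 = 0 nothing is rejected; if r1 = m everything is. Otherwise the
    null count is estimated as m0_hat = m - r1 and stage 2 reruns the
    linear step-up at q' * m / m0_hat. Returns a boolean rejection mask.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must be finite and in [0, 1]")
    if not 0.0 < q < 1.0:
        raise InvalidArgumentError("q must be in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _step_up(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0_hat = m - r1
    return _step_up(p, q1 * m / m0_hat)


def call_significant(results: pd.DataFrame, q: float = 0.05,
                     fc_threshold: float = 2.0) -> pd.DataFrame:
    """Apply the dual rule: BKY rejection at FDR ``q`` AND linear fold
    change >= ``fc_threshold`` in either direction."""
    out = results.copy()
    out["bky_rejected"] = bky_adjust(out.p.values, q)
    out["significant"] = out.bky_rejected & (out.log2fc.abs() >= np.log2(fc_threshold))
    out["neg_log10_p"] = -np.log10(np.maximum(out.p.values, np.finfo(float).tiny))
    return out


def run_de(counts: pd.DataFrame, samples: pd.DataFrame, q: float = 0.05,
           fc_threshold: float = 2.0, pseudocount: float = 0.5) -> pd.DataFrame:
    """Normalise, test and call significance in one pass."""
    return call_significant(de_test(normalize(counts), samples, pseudocount),
                            q=q, fc_threshold=fc_threshold)
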