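"""End-to-end orchestration shared by the CLI, the analysis scripts and
the acceptance checks.

``run_study`` takes an iterable of recording bundles (typically the lazy
cohort generators, so signals never accumulate in memory), extracts
features well by well, and returns every result table the pipeline
produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conduction import conduction_summary, fpd_dispersion
from .errors import InsufficientCoverageError
from .features import DetectionParams, assemble_feature_table
from .layout import ElectrodeLayout
from .mixedstats import (METRICS, MixedModelResult, fit_all_metrics,
                         summarize_wells, superplot_export)
from .rhythm import BeatSeries, rhythm_summary

__all__ = ["StudyResults", "extract_features", "run_study", "rhythm_tables",
           "dispersion_table"]


@dataclass
class StudyResults:
    features: pd.DataFrame
    wells: pd.DataFrame
    conduction: pd.DataFrame
    dispersion: pd.DataFrame
    rhythm: pd.DataFrame
    poincare: pd.DataFrame
    models: dict[str, MixedModelResult] = field(default_factory=dict)

    def stats_json(self) -> dict:
        return {m: r.to_dict() for m, r in self.models.items()}


def extract_features(bundles, params: DetectionParams = DetectionParams(),
                     ) -> tuple[pd.DataFrame, ElectrodeLayout | None]:
    """Feature table for an iterable of bundles, plus the shared layout."""
    layout = None

    def _tap():
        nonlocal layout
        for b in bundles:
            if layout is None:
                layout = b.layout
            yield b

    features = assemble_feature_table(_tap(), params)
    return features, layout


def rhythm_tables(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well rhythm summary plus the pooled Poincare pair table."""
    summary_rows, pair_rows = [], []
    for well, wf in features.groupby("well_id"):
        per_beat = (wf.groupby("beat_index")
                    .agg(t=("t_spike_s", "median"), klass=("beat_class", "first"))
                    .sort_values("t"))
        if len(per_beat) < 2:
            continue
        series = BeatSeries(well_id=well, beat_times=per_beat.t.values,
                            beat_classes=per_beat.klass.values)
        s = rhythm_summary(series)
        summary_rows.append({"well_id": well, "mean_cl_s": s.mean_cl_s,
                             "sd_cl_s": s.sd_cl_s, "cov_pct": s.cov_pct,
                             "n_beats": s.n_beats, "n_ectopic": s.n_ectopic})
        for a, b in s.poincare:
            pair_rows.append({"well_id": well, "cl_k_s": a, "cl_k1_s": b})
    return (pd.DataFrame(summary_rows),
            pd.DataFrame(pair_rows, columns=["well_id", "cl_k_s", "cl_k1_s"]))


def dispersion_table(features: pd.DataFrame, layout: ElectrodeLayout) -> pd.DataFrame:
    rows = []
    for well in features.well_id.unique():
        try:
            d = fpd_dispersion(features, well, layout)
        except InsufficientCoverageError:
            continue
        rows.append({"well_id": well, "fpd_sd_ms": d.sd_ms,
                     "fpd_range_ms": d.range_ms})
    return pd.DataFrame(rows, columns=["well_id", "fpd_sd_ms", "fpd_range_ms"])


def run_study(bundles, params: DetectionParams = DetectionParams(),
              fit_models: bool = True) -> StudyResults:
    """Feature extraction -> per-well summaries -> mixed-model contrasts."""
    features, layout = extract_features(bundles, params)
    if features.empty:
        raise InsufficientCoverageError("no beats detected in any bundle")
    wells = summarize_wells(features, layout)
    rhythm_df, poincare = rhythm_tables(features)
    results = StudyResults(
        features=features,
        wells=wells,
        conduction=conduction_summary(features, layout),
        dispersion=dispersion_table(features, layout),
        rhythm=rhythm_df,
        poincare=poincare,
    )
    if fit_models and wells.genotype.nunique() == 2:
        results.models = fit_all_metrics(wells, METRICS)
    return results
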