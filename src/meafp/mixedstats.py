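"""Nested mixed-model inference on well-level metrics.

Wells are technical replicates nested in differentiations (biological
batches), so the genotype comparison must not treat wells as independent.
Each metric is modelled as

    y_ij = mu + genotype + b_i + e_ij,   b_i ~ N(0, s2_diff), e_ij ~ N(0, s2_res)

with a random intercept per differentiation, fitted by REML
(statsmodels ``MixedLM``). Estimated marginal means (EMMs) per genotype
come from the fixed effects, and the genotype contrast is a Wald z test
against the normal reference distribution (no small-sample df
correction; with few differentiations the test is mildly anti-
conservative, which is documented rather than corrected).

A method-of-moments closed form for the balanced two-level design
(`fit_mixed_mom`) provides an independent oracle: on balanced data REML
and the ANOVA estimators coincide, so the two routes must agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .conduction import (InsufficientCoverageError, conduction_summary,
                         fpd_dispersion)
from .errors import ConvergenceError, DesignError, SchemaError
from .layout import ElectrodeLayout

__all__ = ["METRICS", "MixedModelResult", "summarize_wells", "fit_mixed",
           "fit_mixed_mom", "emmeans", "wald_contrast", "superplot_export",
           "fit_all_metrics"]

#: The five well-level MEA metrics carried through inference.
METRICS = ["slope_v_per_s", "fpdc_ms", "cov_pct", "max_propagation_ms", "fpd_sd_ms"]

_KEYS = ["well_id", "differentiation_id", "genotype"]


@dataclass
class MixedModelResult:
    """Genotype contrast for one metric from the nested model."""

    metric: str
    genotypes: tuple[str, str]
    emm: dict[str, float]
    emm_se: dict[str, float]
    effect: float                  # EMM[genotypes[1]] - EMM[genotypes[0]]
    effect_se: float
    z: float
    p: float
    var_between: float             # differentiation-level variance
    var_residual: float            # well-level (residual) variance
    n_differentiations: dict[str, int]
    n_wells: dict[str, int]
    method: str = "reml"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "genotypes": list(self.genotypes),
            "emm": self.emm, "emm_se": self.emm_se,
            "effect": self.effect, "effect_se": self.effect_se,
            "z": self.z, "p": self.p,
            "var_between": self.var_between, "var_residual": self.var_residual,
            "n_differentiations": self.n_differentiations, "n_wells": self.n_wells,
            "method": self.method, "degenerate": self.degenerate,
        }


def summarize_wells(features: pd.DataFrame, layout: ElectrodeLayout) -> pd.DataFrame:
    """Collapse the beat-level feature table to one row per well.

    slope and FPD_c average over regular beats and electrodes; COV comes
    from the well-level beat-time series (ectopy included); maximum
    propagation averages per-beat max-min activation spread over regular
    beats; FPD SD is the across-electrode dispersion of mean FPD.
    """
    for key in _KEYS:
        if key not in features.columns:
            raise SchemaError(f"feature table missing column {key!r}")
    if features.empty:
        return pd.DataFrame(columns=_KEYS + METRICS)
    cond = conduction_summary(features, layout).set_index("well_id")
    rows = []
    for well, wf in features.groupby("well_id"):
        regular = wf[wf.beat_class == "regular"]
        meta = wf.iloc[0]
        # well-level beat times: per-beat median spike time across electrodes
        bt = wf.groupby("beat_index")["t_spike_s"].median().sort_values().values
        cl = np.diff(bt)
        cov = (100.0 * np.std(cl, ddof=1) / np.mean(cl)) if cl.size >= 3 else np.nan
        try:
            disp = fpd_dispersion(features, well, layout).sd_ms
        except InsufficientCoverageError:
            disp = np.nan
        rows.append({
            "well_id": well,
            "differentiation_id": meta.differentiation_id,
            "genotype": meta.genotype,
            "slope_v_per_s": regular.slope_v_per_s.mean(),
            "fpdc_ms": regular.fpdc_ms.mean(),
            "cov_pct": cov,
            "max_propagation_ms": cond.max_propagation_ms.get(well, np.nan),
            "fpd_sd_ms": disp,
        })
    return pd.DataFrame(rows)


def _prepare(table: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, tuple[str, str]]:
    if metric not in table.columns:
        raise SchemaError(f"metric {metric!r} not in table")
    df = table.dropna(subset=[metric]).copy()
    genotypes = tuple(sorted(df.genotype.unique()))
    if len(genotypes) < 2:
        raise DesignError(f"need two genotypes for a contrast, found {genotypes}")
    if len(genotypes) > 2:
        raise DesignError("exactly two genotypes are supported")
    for g in genotypes:
        if df.loc[df.genotype == g, "differentiation_id"].nunique() < 1:
            raise DesignError(f"genotype {g} has no differentiations")
    return df, genotypes


def _counts(df: pd.DataFrame, genotypes) -> tuple[dict, dict]:
    nd = {g: int(df.loc[df.genotype == g, "differentiation_id"].nunique())
          for g in genotypes}
    nw = {g: int((df.genotype == g).sum()) for g in genotypes}
    return nd, nw


def _degenerate_result(df, metric, genotypes) -> MixedModelResult:
    emm = {g: float(df.loc[df.genotype == g, metric].mean()) for g in genotypes}
    nd, nw = _counts(df, genotypes)
    effect = emm[genotypes[1]] - emm[genotypes[0]]
    return MixedModelResult(metric=metric, genotypes=genotypes, emm=emm,
                            emm_se={g: 0.0 for g in genotypes},
                            effect=effect, effect_se=0.0,
                            z=float("inf") if effect != 0 else 0.0,
                            p=0.0 if effect != 0 else 1.0,
                            var_between=0.0, var_residual=0.0,
                            n_differentiations=nd, n_wells=nw,
                            method="degenerate", degenerate=True)


def fit_mixed(table: pd.DataFrame, metric: str,
              assume_zero_between_variance: bool = False) -> MixedModelResult:
    """Fit the nested model for one metric and test the genotype contrast.

    ``assume_zero_between_variance=True`` drops the random intercept and
    fits ordinary least squares on wells — the documented equivalence
    route when differentiations contribute no variance.
    """
    import statsmodels.api as sm

    df, genotypes = _prepare(table, metric)
    y = df[metric].values.astype(float)
    g2 = (df.genotype == genotypes[1]).values.astype(float)
    # noise-free degenerate data: zero variance within both genotypes
    pooled = sum(df.loc[df.genotype == g, metric].var(ddof=0) for g in genotypes)
    scale_ref = max(1.0, float(np.mean(np.abs(y))) ** 2)
    if pooled < 1e-12 * scale_ref:
        return _degenerate_result(df, metric, genotypes)

    exog = np.column_stack([np.ones_like(y), g2])
    nd, nw = _counts(df, genotypes)
    # fit on a standardised response for numerical stability; the Wald z
    # is scale invariant and location/scale transform back exactly
    loc, scale = float(np.mean(y)), float(np.std(y, ddof=0))
    ys = (y - loc) / scale
    if assume_zero_between_variance:
        res = sm.OLS(ys, exog).fit()
        params, cov = res.params, res.cov_params()
        var_between, var_residual = 0.0, float(res.mse_resid) * scale ** 2
        method = "ols"
    else:
        for g in genotypes:
            if nd[g] < 2:
                raise DesignError(f"genotype {g}: need >= 2 differentiations")
        model = sm.MixedLM(ys, exog, groups=df.differentiation_id.values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = None
            for methods in (["lbfgs", "powell"], ["cg"], ["nm"]):
                try:
                    res = model.fit(reml=True, method=methods)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if res is None:
                raise ConvergenceError(f"mixed model failed for {metric}")
        if not np.all(np.isfinite(res.params)):
            raise ConvergenceError(f"mixed model produced non-finite estimates "
                                   f"for {metric}")
        params = res.params[:2]
        cov = np.asarray(res.cov_params())[:2, :2]
        var_between = max(0.0, float(np.asarray(res.cov_re)[0, 0])) * scale ** 2
        var_residual = float(res.scale) * scale ** 2
        method = "reml"

    cov = np.asarray(cov) * scale ** 2
    params = np.asarray(params, float) * scale
    params[0] += loc
    emm = {genotypes[0]: float(params[0]),
           genotypes[1]: float(params[0] + params[1])}
    emm_se = {genotypes[0]: float(np.sqrt(cov[0, 0])),
              genotypes[1]: float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))}
    effect, effect_se = float(params[1]), float(np.sqrt(cov[1, 1]))
    if effect_se == 0.0:
        return _degenerate_result(df, metric, genotypes)
    z = effect / effect_se
    p = float(2.0 * norm.sf(abs(z)))
    return MixedModelResult(metric=metric, genotypes=genotypes, emm=emm,
                            emm_se=emm_se, effect=effect, effect_se=effect_se,
                            z=float(z), p=max(p, np.finfo(float).tiny),
                            var_between=var_between, var_residual=var_residual,
                            n_differentiations=nd, n_wells=nw, method=method)


def fit_mixed_mom(table: pd.DataFrame, metric: str) -> MixedModelResult:
    """Method-of-moments closed form for the *balanced* two-level design.

    Classical one-way nested ANOVA estimators: with N differentiations of
    n wells per genotype, ``MSE`` estimates the well-level variance,
    ``(MSB - MSE)/n`` (clipped at 0) the differentiation-level variance,
    and ``Var(genotype mean) = MSB/(nN)``. On balanced data this equals
    the REML fit, which is why it serves as the independent oracle.
    """
    df, genotypes = _prepare(table, metric)
    nd, nw = _counts(df, genotypes)
    d_means = df.groupby(["genotype", "differentiation_id"])[metric].agg(["mean", "count", "var"])
    n_per = d_means["count"].unique()
    if len(n_per) != 1 or len(set(nd.values())) != 1:
        raise DesignError("method-of-moments closed form requires a balanced design")
    n = int(n_per[0])
    N = nd[genotypes[0]]
    G = 2
    if N < 2:
        raise DesignError("need >= 2 differentiations per genotype")
    ssw = float(((d_means["var"].fillna(0.0)) * (n - 1)).sum())
    mse = ssw / (G * N * (n - 1)) if n > 1 else 0.0
    g_means = d_means["mean"].groupby("genotype").mean()
    ssb = float(sum((d_means.loc[g, "mean"] - g_means[g]).pow(2).sum()
                    for g in genotypes))
    msb = n * ssb / (G * (N - 1))
    var_between = max(0.0, (msb - mse) / n)
    se_g = np.sqrt(msb / (n * N))
    emm = {g: float(g_means[g]) for g in genotypes}
    emm_se = {g: float(se_g) for g in genotypes}
    effect = emm[genotypes[1]] - emm[genotypes[0]]
    effect_se = float(np.sqrt(2.0) * se_g)
    if effect_se == 0.0:
        return _degenerate_result(df, metric, genotypes)
    z = effect / effect_se
    return MixedModelResult(metric=metric, genotypes=genotypes, emm=emm,
                            emm_se=emm_se, effect=effect, effect_se=effect_se,
                            z=float(z), p=float(2.0 * norm.sf(abs(z))),
                            var_between=var_between, var_residual=mse,
                            n_differentiations=nd, n_wells=nw, method="mom")


def emmeans(result: MixedModelResult) -> dict[str, tuple[float, float]]:
    """Per-genotype estimated marginal mean and its standard error."""
    return {g: (result.emm[g], result.emm_se[g]) for g in result.genotypes}


def wald_contrast(result: MixedModelResult) -> tuple[float, float]:
    """Wald z and two-sided normal p for the genotype difference."""
    return result.z, result.p


def superplot_export(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy table for violin superplots: well-level points plus
    differentiation-level means, tagged by ``level``."""
    metrics = [m for m in METRICS if m in table.columns]
    wells = table[_KEYS + metrics].copy()
    wells.insert(0, "level", "well")
    diffs = (table.groupby(["genotype", "differentiation_id"], as_index=False)[metrics]
             .mean())
    diffs.insert(0, "level", "differentiation")
    diffs.insert(1, "well_id", pd.NA)
    return pd.concat([wells, diffs], ignore_index=True)[
        ["level"] + _KEYS + metrics]


def fit_all_metrics(table: pd.DataFrame,
                    metrics: list[str] | None = None) -> dict[str, MixedModelResult]:
    """Fit the nested model for every metric (listwise deletion per metric)."""
    out = {}
    for m in metrics or METRICS:
        out[m] = fit_mixed(table, m)
    return out
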