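"""Normalisation, DE testing and the two-stage adaptive FDR step-up."""

import numpy as np
import pandas as pd
import pytest

from meafp.errors import (ConfigurationError, InvalidArgumentError,
                          NormalizationError)
from meafp.expression import bky_adjust, call_significant, de_test, normalize
from meafp.synth_expression import (ExpressionTruth, make_expression_truth,
                                    simulate_expression)


# --- independent brute-force oracle for the two-stage step-up -----------
def _stepup_scan(p, level):
    """Exhaustive threshold scan: largest k with p_(k) <= level*k/m."""
    m = len(p)
    order = np.argsort(p)
    best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= level * k / m:
            best = k
    rej = np.zeros(m, bool)
    rej[order[:best]] = True
    return rej


def _two_stage_oracle(p, q):
    m = len(p)
    q1 = q / (1.0 + q)
    r1 = _stepup_scan(p, q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return _stepup_scan(p, q1 * m / (m - r1))
# ------------------------------------------------------------------------


def _counts(mat, hk_mask, genes=None):
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                      columns=[f"s{j}" for j in range(mat.shape[1])])
    df.insert(0, "housekeeping", hk_mask)
    return df


class TestNormalize:
    def test_identical_samples_unchanged(self):
        c = _counts(np.tile([[100.0], [200.0], [50.0]], (1, 4)),
                    [True, False, False])
        out = normalize(c)
        assert np.allclose(out.drop(columns="housekeeping").values,
                           c.drop(columns="housekeeping").values)

    def test_global_scale_factor_cancels(self):
        base = np.array([[100.0], [200.0], [50.0], [400.0]])
        mat = np.hstack([base, 2 * base])
        out = normalize(_counts(mat, [True, True, False, False]))
        v = out.drop(columns="housekeeping").values
        assert np.allclose(v[:, 0], v[:, 1])

    def test_single_housekeeping_gene_is_its_own_factor(self):
        mat = np.array([[100.0, 400.0], [10.0, 10.0]])
        out = normalize(_counts(mat, [True, False]))
        # scale factors 100 and 400, cohort mean 250
        assert out.iloc[0, 1] == pytest.approx(250.0)
        assert out.iloc[0, 2] == pytest.approx(250.0)

    def test_zero_housekeeping_count_names_sample(self):
        mat = np.array([[100.0, 0.0], [10.0, 10.0]])
        with pytest.raises(NormalizationError, match="s1"):
            normalize(_counts(mat, [True, False]))


class TestDeTest:
    def _samples(self, n):
        return pd.DataFrame({"sample_id": [f"s{j}" for j in range(2 * n)],
                             "group": ["g1"] * n + ["g2"] * n})

    def test_identical_groups_null(self):
        mat = np.tile([[100.0], [250.0]], (1, 8))
        res = de_test(_counts(mat, [False, False]), self._samples(4))
        assert np.allclose(res.log2fc, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_known_fold_changes(self):
        mat = np.array([[230.0] * 4 + [100.0] * 4,     # ratio 2.3
                        [200.0] * 4 + [100.0] * 4])    # ratio 2
        res = de_test(_counts(mat, [False, False]), self._samples(4),
                      pseudocount=0.0)
        assert res.log2fc.iloc[0] == pytest.approx(np.log2(2.3), abs=1e-9)
        assert res.log2fc.iloc[1] == pytest.approx(1.0, abs=1e-9)


class TestBky:
    def test_all_ones_rejects_nothing(self):
        assert not bky_adjust(np.ones(10), 0.05).any()

    def test_all_zeros_rejects_everything(self):
        assert bky_adjust(np.zeros(10), 0.05).all()

    def test_worked_vector_matches_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.9, 0.95, 1.0, 1.0])
        assert np.array_equal(bky_adjust(p, 0.05), _two_stage_oracle(p, 0.05))
        # and the adaptive stage is doing something: the two smallest reject
        assert bky_adjust(p, 0.05)[:2].all()

    def test_agrees_with_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            m = int(rng.integers(1, 51))
            k = int(rng.integers(0, m + 1))
            p = np.concatenate([rng.beta(0.15, 6.0, k), rng.uniform(0, 1, m - k)])
            rng.shuffle(p)
            assert np.array_equal(bky_adjust(p, 0.05), _two_stage_oracle(p, 0.05))

    def test_agrees_with_statsmodels_implementation(self):
        import statsmodels.stats.multitest as smm
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(0, 1, 30) ** 2
            ours = bky_adjust(p, 0.05)
            theirs = smm.multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(ours, theirs)

    def test_lowering_a_pvalue_never_shrinks_rejections(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = rng.uniform(0, 1, 25)
            base = bky_adjust(p, 0.05)
            i = int(rng.integers(0, 25))
            p2 = p.copy()
            p2[i] *= rng.uniform(0, 1)
            assert bky_adjust(p2, 0.05).sum() >= base.sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bky_adjust(np.array([0.1, 1.5]), 0.05)
        with pytest.raises(InvalidArgumentError):
            bky_adjust(np.array([0.1, np.nan]), 0.05)


class TestSignificanceRule:
    def _results(self, log2fc, p):
        return pd.DataFrame({"log2fc": log2fc, "p": p},
                            index=pd.Index([f"g{i}" for i in range(len(p))],
                                           name="gene"))

    def test_dual_gate(self):
        res = call_significant(self._results(
            log2fc=[np.log2(1.5), np.log2(10.0), np.log2(2.3)],
            p=[1e-6, 0.9, 1e-6]), q=0.05, fc_threshold=2.0)
        # rejected but small fold change -> not significant
        assert res.bky_rejected.iloc[0] and not res.significant.iloc[0]
        # huge fold change but not rejected -> not significant
        assert not res.bky_rejected.iloc[1] and not res.significant.iloc[1]
        # rejected at 2.3-fold -> significant
        assert res.significant.iloc[2]

    def test_downregulation_counts_too(self):
        res = call_significant(self._results([-1.5], [1e-8]), q=0.05)
        assert res.significant.iloc[0]


class TestSimulateExpression:
    def test_null_configuration_has_unit_ratio(self):
        truth = make_expression_truth(40, n_spiked=0, seed=1)
        counts, samples = simulate_expression(truth, 100, seed=2)
        norm = normalize(counts).drop(columns="housekeeping")
        g1 = norm.iloc[:, :100].mean(axis=1)
        g2 = norm.iloc[:, 100:].mean(axis=1)
        assert np.allclose(g1 / g2, 1.0, atol=0.08)

    def test_spiked_ratio_recovered(self):
        truth = make_expression_truth(30, n_spiked=1, spike_fold_change=2.3,
                                      n_housekeeping=4, seed=5)
        counts, samples = simulate_expression(truth, 400, seed=6)
        norm = normalize(counts).drop(columns="housekeeping")
        spiked = truth.table.index[truth.table.fold_change == 2.3][0]
        ratio = (norm.iloc[spiked, :400].mean() / norm.iloc[spiked, 400:].mean())
        assert ratio == pytest.approx(2.3, rel=0.05)

    def test_deterministic_under_seed(self):
        truth = make_expression_truth(25, n_spiked=2, seed=7)
        a, _ = simulate_expression(truth, 4, seed=8)
        b, _ = simulate_expression(truth, 4, seed=8)
        assert a.equals(b)

    def test_housekeeping_with_fold_change_rejected(self):
        t = make_expression_truth(10, n_spiked=0, seed=0)
        bad = t.table.copy()
        bad.loc[0, "fold_change"] = 2.0     # gene 0 is housekeeping
        with pytest.raises(ConfigurationError):
            ExpressionTruth(table=bad, dispersion=0.01)
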