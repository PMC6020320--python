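"""Association scan: filters, OLS correctness, classification, FDR."""

import numpy as np
import pandas as pd
import pytest

from eqtlnet._stats import bh_fdr
from eqtlnet.eqtl import (
    EqtlScan,
    classify_cis_trans,
    filter_variants,
    fit_additive_model,
    map_all,
)
from eqtlnet.simulate import SimConfig, simulate_dataset


def variant_frame(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "maf", "call_rate"]
    )


class TestFilter:
    def test_boundary_values(self):
        vt = variant_frame(
            [
                ("a", "1", 100, 0.05, 1.0),     # MAF exactly at threshold: removed
                ("b", "1", 200, 0.051, 0.96),   # just above both: retained
                ("c", "1", 300, 0.2, 0.95),     # call rate at threshold: removed
            ]
        )
        out = filter_variants(vt)
        assert list(out["variant_id"]) == ["b"]

    def test_sex_chromosomes_dropped_with_warning(self):
        vt = variant_frame([("a", "X", 100, 0.3, 1.0), ("b", "Y", 200, 0.3, 1.0)])
        with pytest.warns(UserWarning, match="removed every variant"):
            out = filter_variants(vt)
        assert out.empty


class TestAdditiveModel:
    def test_noiseless_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        beta, se, t, p = fit_additive_model(2 * g, g)
        assert beta == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_instance(self):
        # g=[0,1,1,2], y=[1,2,2,3]: Sxy/Sxx = 2/2 = 1 and the fit is exact
        beta, se, t, p = fit_additive_model([1, 2, 2, 3], [0, 1, 1, 2])
        assert beta == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_additive_model([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])

    def test_matches_statsmodels(self, dataset):
        import statsmodels.api as sm

        vid, gid, _ = dataset.truth.cis_truth[0]
        y = dataset.expression.loc[gid].to_numpy()
        g = dataset.dosage[vid].to_numpy()
        from eqtlnet.eqtl import design_matrix

        X, _ = design_matrix(dataset.covariates, samples=list(dataset.dosage.index))
        beta, se, t, p = fit_additive_model(y, g, X)
        fit = sm.OLS(y, np.column_stack([X, g])).fit()
        assert beta == pytest.approx(fit.params[-1], abs=1e-10)
        assert se == pytest.approx(fit.bse[-1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_null_calibration(self):
        # 10,000 independent null fits via the blocked scan
        d = simulate_dataset(
            SimConfig(seed=3, n_samples=200, n_variants=100, n_genes=100,
                      ld_copy_prob=0.0, n_cis_pairs=1, hotspot_n_targets=1,
                      cis_beta=0.0, hotspot_beta=0.0, target_gamma=0.0)
        )
        res = map_all(d.dosage, d.expression, d.gene_table, d.variant_table, d.covariates)
        frac = (res.records["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.007)

    def test_covariate_invariance(self):
        rng = np.random.default_rng(0)
        n = 100
        g = rng.integers(0, 3, n).astype(float)
        y = 0.5 * g + rng.standard_normal(n)
        b0, *_ = fit_additive_model(y, g)
        # a covariate orthogonal to both g and y leaves beta unchanged
        z = rng.standard_normal(n)
        M = np.column_stack([np.ones(n), g, y])
        z -= M @ np.linalg.lstsq(M, z, rcond=None)[0]
        b1, *_ = fit_additive_model(y, g, np.column_stack([np.ones(n), z]))
        assert b1 == pytest.approx(b0, abs=1e-8)


class TestClassification:
    def test_within_window_is_cis(self):
        v = {"chromosome": "1", "position": 500_000}
        g = {"chromosome": "1", "start": 1_400_000, "end": 1_450_000}
        cls, d = classify_cis_trans(v, g)
        assert (cls, d) == ("cis", 900_000)

    def test_exact_boundary_is_cis(self):
        v = {"chromosome": "1", "position": 1}
        g = {"chromosome": "1", "start": 1_000_001, "end": 1_100_000}
        cls, d = classify_cis_trans(v, g)
        assert (cls, d) == ("cis", 1_000_000)
        v = {"chromosome": "1", "position": 0}
        g = {"chromosome": "1", "start": 1_000_001, "end": 1_100_000}
        assert classify_cis_trans(v, g)[0] == "trans"

    def test_cross_chromosome_is_trans(self):
        v = {"chromosome": "1", "position": 5}
        g = {"chromosome": "2", "start": 1, "end": 10}
        cls, d = classify_cis_trans(v, g)
        assert cls == "trans"
        assert d == -1

    def test_inside_span_distance_zero(self):
        v = {"chromosome": "1", "position": 50}
        g = {"chromosome": "1", "start": 10, "end": 100}
        assert classify_cis_trans(v, g) == ("cis", 0)


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_identity(self):
        assert bh_fdr([0.5])[0] == pytest.approx(0.5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=37)
        q = bh_fdr(p)
        perm = rng.permutation(37)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_matches_hand_step_up(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestScan:
    def test_full_table_row_count(self, small_dataset):
        d = small_dataset
        res = map_all(d.dosage, d.expression, d.gene_table, d.variant_table, d.covariates)
        assert len(res.records) == d.dosage.shape[1] * len(d.expression)

    def test_blocked_scan_equals_per_pair_ols(self, small_dataset):
        d = small_dataset
        res = map_all(d.dosage, d.expression, d.gene_table, d.variant_table, d.covariates)
        from eqtlnet.eqtl import design_matrix

        X, _ = design_matrix(d.covariates, samples=list(d.dosage.index))
        rng = np.random.default_rng(0)
        rows = res.records.iloc[rng.choice(len(res.records), 20, replace=False)]
        for row in rows.itertuples():
            beta, se, t, p = fit_additive_model(
                d.expression.loc[row.gene_id].to_numpy(),
                d.dosage[row.variant_id].to_numpy(),
                X,
            )
            assert row.beta == pytest.approx(beta, abs=1e-10)
            assert row.t_stat == pytest.approx(t, abs=1e-8)
            assert row.p_value == pytest.approx(p, abs=1e-10)

    def test_planted_cis_recovered_with_sign(self, dataset):
        res = map_all(
            dataset.dosage, dataset.expression, dataset.gene_table,
            dataset.variant_table, dataset.covariates,
        )
        sig = res.significant("cis")
        found = {(r.variant_id, r.gene_id): r.beta for r in sig.itertuples()}
        recovered = [
            (v, g) in found and np.sign(found[(v, g)]) == np.sign(b)
            for v, g, b in dataset.truth.cis_truth
        ]
        assert np.mean(recovered) >= 0.95

    def test_sample_mismatch_names_offenders(self, small_dataset):
        d = small_dataset
        bad = d.dosage.rename(index={d.dosage.index[0]: "intruder"})
        with pytest.raises(ValueError, match="mismatch"):
            EqtlScan(d.expression, bad, d.variant_table, d.gene_table)

    def test_q_values_within_class(self, small_dataset):
        d = small_dataset
        res = map_all(d.dosage, d.expression, d.gene_table, d.variant_table, d.covariates)
        cis = res.cis
        np.testing.assert_allclose(
            cis["q_value"].to_numpy(), bh_fdr(cis["p_value"].to_numpy()), atol=1e-12
        )
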