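"""Statistical battery contracts: gates, tests, partial correlation, GLM, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmnrv.stats import (bh_adjust, build_association_tables, compare_groups,
                         fit_adjusted_glm, mann_whitney_p, mmse_band,
                         normality_gate, partial_correlation)


class TestMmseBand:
    @pytest.mark.parametrize("score, band", [
        (29, "normal"), (24, "normal"), (23, "mild"), (20, "mild"), (19, "mild"),
        (18, "moderate"), (10, "moderate"), (9, "severe"), (0, "severe"),
    ])
    def test_band_edges(self, score, band):
        assert mmse_band(score) == band

    @pytest.mark.parametrize("score", [-1, 31])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            mmse_band(score)


class TestNormalityGate:
    def test_gaussian_samples_usually_pass(self):
        hits = 0
        for seed in range(200):
            g = np.random.default_rng(seed).standard_normal(1000)
            hits += normality_gate([g]) == "normal"
        assert hits >= 0.95 * 200

    def test_exponential_samples_usually_fail(self):
        hits = 0
        for seed in range(200):
            g = np.random.default_rng(seed).exponential(size=50)
            hits += normality_gate([g]) == "non_normal"
        assert hits >= 0.90 * 200

    def test_tiny_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([[1.0, 2.0]])
        with pytest.raises(ValueError):
            normality_gate([[3.0] * 10])


def pheno_frame(cn_vals, mci_vals, variable="mmse"):
    rng = np.random.default_rng(99)
    rows = []
    for prefix, group, values in (("c", "CN", cn_vals), ("m", "MCI", mci_vals)):
        for i, v in enumerate(values):
            rows.append({"subject_id": f"{prefix}{i}", "group": group,
                         "age": float(rng.normal(71, 5)), "sex": i % 2,
                         "education": int(rng.integers(12, 21)),
                         "mmse": int(rng.integers(24, 31))})
            rows[-1][variable] = v
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_show_no_effect(self, rng):
        vals = rng.normal(70, 5, 25)
        pheno = pheno_frame(vals, vals, variable="age")
        age_row = [c for c in compare_groups(pheno) if c.variable == "age"][0]
        assert age_row.test == "t"
        assert age_row.p > 0.99

    def test_small_sample_mann_whitney_is_exact(self):
        # U = 0 for fully separated triples; 2 of 20 arrangements are as extreme
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_planted_mmse_shift_detected(self):
        """A 2-point MMSE shift (sd 1) at n = 25/23 is detected at p < 0.05 in
        at least 95% of 200 replicates, whichever branch the gate picks."""
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            cn = np.clip(np.round(r.normal(28, 1, 25)), 0, 30)
            mci = np.clip(np.round(r.normal(26, 1, 23)), 0, 30)
            pheno = pheno_frame(cn, mci)
            row = [c for c in compare_groups(pheno) if c.variable == "mmse"][0]
            hits += row.p < 0.05
        assert hits >= 0.95 * 200

    def test_sex_uses_count_based_test(self, rng):
        vals = rng.normal(70, 5, 25)
        rows = compare_groups(pheno_frame(vals, vals, variable="age"))
        sex_row = [c for c in rows if c.variable == "sex"][0]
        assert sex_row.test in ("chi_square", "fisher")
        assert 0 <= sex_row.p <= 1


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, p, n = partial_correlation(x, y)
        expected = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 40

    def test_pure_covariate_signal_partials_to_zero(self, rng):
        cov = rng.standard_normal((50, 2))
        y = cov @ np.array([2.0, -1.5]) + 3.0
        x = rng.standard_normal(50)
        r, _, _ = partial_correlation(x, y, cov)
        assert abs(r) < 1e-8

    def test_matches_residualization_oracle(self, rng):
        n = 30
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, 2))
        design = np.column_stack([np.ones(n), cov])
        h = design @ np.linalg.solve(design.T @ design, design.T)
        rx, ry = x - h @ x, y - h @ y
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _, _ = partial_correlation(x, y, cov)
        assert r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 35
        df = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.standard_normal(n),
                           "a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        ours_r, ours_p, _ = partial_correlation(df["x"], df["y"], df[["a", "b"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours_p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-10)


class TestAdjustedGlm:
    def test_perfect_fit(self, rng):
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 2))
        r2, beta, p = fit_adjusted_glm(x.copy(), x, cov)
        assert r2 >= 0.999
        assert beta == pytest.approx(1.0, abs=1e-8)
        assert p < 1e-10

    def test_independent_predictor_has_small_beta(self, rng):
        n = 2000
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        _, beta, _ = fit_adjusted_glm(y, x, cov)
        assert abs(beta) < 0.05

    def test_confound_absorbed_by_covariate(self, rng):
        n = 200
        age = rng.uniform(60, 85, n)
        sex = rng.integers(0, 2, n)
        y = 0.1 * age + rng.normal(0, 0.1, n)
        x = rng.standard_normal(n)
        r2, beta, _ = fit_adjusted_glm(y, x, np.column_stack([age, sex]))
        assert abs(beta) < 0.05
        assert r2 > 0.9

    def test_p_value_agrees_with_partial_correlation(self, rng):
        """Both procedures run the same t-test on the predictor coefficient."""
        n = 40
        y, x = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, 2))
        _, p_partial, _ = partial_correlation(x, y, cov)
        _, _, p_glm = fit_adjusted_glm(y, x, cov)
        assert p_glm == pytest.approx(p_partial, abs=1e-10)


def bh_oracle(p):
    """Definition-level BH: sort, q_i = p_i * m / i, reverse cummin, cap, unsort."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_worked_example(self):
        # q = (0.04, 0.04, 0.04, 0.04): each p_i * 4 / i cumulative-minimized
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)     # never smaller
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_adjust(np.asarray(pvals)[perm])
        assert np.allclose(adj_perm, adj[perm], atol=1e-13)  # equivariance
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-13)


class TestAssociationTables:
    @staticmethod
    def synthetic_inputs(rng, n=24):
        """Metrics and phenotypes with a strong planted CN GAP-43 effect."""
        from dmnrv.connectivity import METRIC_NAMES

        ids = [f"s{i:02d}" for i in range(2 * n)]
        groups = ["CN"] * n + ["MCI"] * n
        metrics = pd.DataFrame(rng.standard_normal((2 * n, 10)),
                               columns=list(METRIC_NAMES), index=ids)
        metrics.index.name = "subject_id"
        pheno = pd.DataFrame({
            "subject_id": ids, "group": groups,
            "age": rng.uniform(60, 85, 2 * n).round(1),
            "sex": rng.integers(0, 2, 2 * n),
            "education": rng.integers(12, 20, 2 * n),
            "mmse": rng.integers(24, 31, 2 * n),
            "gap43": 5000 + 100 * metrics["average to posterior"].to_numpy()
                     + rng.normal(0, 10, 2 * n),
            "abeta42": rng.normal(180, 50, 2 * n).clip(min=1),
            "ttau": rng.normal(90, 35, 2 * n).clip(min=1),
            "ptau181": rng.normal(30, 12, 2 * n).clip(min=1),
        })
        return metrics, pheno

    def test_shapes_labels_and_fdr_monotonicity(self, rng):
        metrics, pheno = self.synthetic_inputs(rng)
        records, tables = build_association_tables(metrics, pheno)
        assert len(records) == 2 * 4 * 10 * 2  # groups x biomarkers x metrics x kinds
        assert all(rec.p_fdr >= rec.p_raw - 1e-15 for rec in records)
        assert list(tables["table2"].index) == [
            "anterior to average", "anterior to posterior", "anterior to ventral",
            "average to posterior", "average to ventral", "posterior to ventral",
            "Median posterior", "Median anterior-posterior", "Median average",
            "Median ventral"]
        assert tables["table2"].shape == (10, 8)  # 4 biomarkers x 2 groups
        assert set(tables) == {"table1", "table2", "table_gap43", "table_abeta42",
                               "table_ttau", "table_ptau181"}

    def test_planted_effect_detected_in_right_cell(self, rng):
        metrics, pheno = self.synthetic_inputs(rng)
        records, _ = build_association_tables(metrics, pheno)
        hit = [r for r in records if r.kind == "partial_r" and r.group == "CN"
               and r.biomarker == "gap43" and r.metric == "average to posterior"][0]
        assert hit.estimate > 0.9
        assert hit.p_fdr < 0.001

    def test_missing_biomarker_column_rejected(self, rng):
        metrics, pheno = self.synthetic_inputs(rng)
        with pytest.raises(ValueError, match="ttau"):
            build_association_tables(metrics, pheno.drop(columns=["ttau"]))
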