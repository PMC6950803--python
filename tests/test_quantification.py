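"""Expression quantification, replicate QC and differential expression."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from anthoreg.quantification import (
    ExpressionMatrix,
    QpcrMeasurement,
    compute_tpm,
    ddct_relative_expression,
    differential_expression,
    sample_qc,
)


def _matrix(counts, lengths, conditions):
    return ExpressionMatrix.from_counts(
        pd.DataFrame(counts),
        pd.Series(lengths, index=pd.DataFrame(counts).index),
        pd.Series(conditions),
    )


class TestComputeTpm:
    def test_two_feature_worked_example(self):
        # rates 10/1000 and 10/2000 normalize 2:1 onto a 1e6 total
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        tpm = compute_tpm(counts, lengths)
        assert tpm["s1"].to_numpy() == pytest.approx([666666.67, 333333.33], rel=1e-6)

    def test_single_feature_saturates_scale(self):
        counts = pd.DataFrame({"s1": [7], "s2": [123456]}, index=["a"])
        tpm = compute_tpm(counts, pd.Series([500], index=["a"]))
        np.testing.assert_allclose(tpm.to_numpy(), [[1e6, 1e6]])

    def test_random_matrix_column_sums(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(50, 6)).astype(float))
        counts.iloc[0, :] += 1  # no all-zero column
        lengths = pd.Series(rng.integers(200, 5000, size=50).astype(float))
        tpm = compute_tpm(counts, lengths)
        # independent oracle: direct summation of the normalized rates
        rate = counts.to_numpy() / lengths.to_numpy()[:, None]
        expected = 1e6 * rate / rate.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(tpm.to_numpy(), expected, rtol=1e-12)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    @given(
        arrays(np.float64, (12, 4), elements=st.floats(0, 1e5)),
        arrays(np.float64, (12,), elements=st.floats(1, 1e4)),
    )
    def test_column_sum_conservation_property(self, counts, lengths):
        tpm = compute_tpm(pd.DataFrame(counts), pd.Series(lengths))
        sums = tpm.sum(axis=0).to_numpy()
        nonzero = counts.sum(axis=0) > 0
        np.testing.assert_allclose(sums[nonzero], 1e6, rtol=1e-6)
        assert (sums[~nonzero] == 0).all()

    def test_all_zero_sample_warns_and_stays_zero(self):
        counts = pd.DataFrame({"s1": [5.0, 5.0], "s2": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(counts, pd.Series([100.0, 100.0]))
        assert (tpm["s2"] == 0).all()

    @pytest.mark.parametrize("bad_length", [0.0, -10.0])
    def test_nonpositive_length_rejected(self, bad_length):
        counts = pd.DataFrame({"s1": [1.0, 1.0]})
        with pytest.raises(ValueError, match="lengths"):
            compute_tpm(counts, pd.Series([100.0, bad_length]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            compute_tpm(pd.DataFrame({"s1": [-1.0]}), pd.Series([100.0]))


class TestSampleQC:
    def test_identical_replicates_not_excluded(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, size=40).astype(float)
        counts = pd.DataFrame({f"G2_{i}": col for i in range(1, 4)} |
                              {f"G8_{i}": col * 2 for i in range(1, 4)})
        m = _matrix(counts, np.full(40, 1000.0),
                    {f"G2_{i}": "G2" for i in range(1, 4)} |
                    {f"G8_{i}": "G8" for i in range(1, 4)})
        qc = sample_qc(m)
        assert qc.excluded == [] and len(qc.retained) == 6

    def test_planted_outlier_is_the_only_exclusion(self, bundle, pipeline_result):
        assert pipeline_result.qc.excluded_ids == [bundle.truth.outlier_sample]

    def test_vacuous_threshold_excludes_nothing(self, pipeline_result, bundle):
        m = pipeline_result.matrix
        assert sample_qc(m, min_median_r=-1.0).excluded == []

    def test_exclusion_monotone_in_threshold(self, pipeline_result):
        m = pipeline_result.matrix
        low = set(sample_qc(m, min_median_r=0.5).excluded_ids)
        mid = set(sample_qc(m, min_median_r=0.9).excluded_ids)
        assert low <= mid

    def test_error_when_condition_would_drop_below_two(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 12, size=60)
        counts = pd.DataFrame({
            "G2_1": 2.0 ** (base + rng.normal(0, 0.05, 60)),
            "G2_2": 2.0 ** rng.uniform(1, 12, 60),  # uncorrelated: degraded
            "G8_1": 2.0 ** (base + rng.normal(0, 0.05, 60)),
            "G8_2": 2.0 ** (base + rng.normal(0, 0.05, 60)),
        })
        m = _matrix(counts, np.full(60, 1000.0),
                    {"G2_1": "G2", "G2_2": "G2", "G8_1": "G8", "G8_2": "G8"})
        with pytest.raises(ValueError, match="would leave"):
            sample_qc(m)


class TestDifferentialExpression:
    @staticmethod
    def _make(tpm_rows, conditions):
        # craft counts so TPM reproduces the requested rows exactly:
        # equal lengths make TPM proportional to counts columnwise
        df = pd.DataFrame(tpm_rows).astype(float)
        return _matrix(df, np.full(len(df), 1000.0), conditions)

    def test_flat_feature_not_significant(self):
        cond = {"a1": "G2", "a2": "G2", "a3": "G2", "b1": "G8", "b2": "G8", "b3": "G8"}
        m = self._make({s: [100.0, 50.0] for s in cond}, cond)
        de = differential_expression(m)
        assert de.loc[0, "log2fc"] == 0.0
        assert not de.loc[0, "significant"]

    def test_zero_to_high_fold_change_exceeds_gate(self):
        cond = {"a1": "G2", "a2": "G2", "a3": "G2", "b1": "G8", "b2": "G8", "b3": "G8"}
        rows = {s: ([0.0, 500.0] if c == "G2" else [1000.0, 500.0])
                for s, c in cond.items()}
        m = self._make(rows, cond)
        de = differential_expression(m)
        # pseudocount 1: log2((667+1)/(0+1)) is far above the |log2fc|>=1 gate
        assert abs(de.loc[0, "log2fc"]) >= 1.0

    def test_label_swap_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(3)
        cond = {"a1": "G2", "a2": "G2", "a3": "G2", "b1": "G8", "b2": "G8", "b3": "G8"}
        rows = {s: rng.uniform(1, 1000, size=25) for s in cond}
        m = self._make(rows, cond)
        de_fwd = differential_expression(m)
        de_rev = differential_expression(m, baseline="G8", contrast="G2")
        np.testing.assert_allclose(de_fwd["log2fc"], -de_rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de_fwd["p_value"], de_rev["p_value"], atol=1e-12)

    @pytest.mark.parametrize("seed", [100, 101, 102, 103, 104])
    def test_planted_effects_recovered_with_low_fdr(self, seed):
        # clean 3-vs-3 design isolates the test's power from replicate QC
        from anthoreg import SimulationConfig, simulate

        b = simulate(SimulationConfig(seed=seed, de_log2fc=4.0, outlier_replicate=None))
        m = ExpressionMatrix.from_counts(b.counts, b.lengths, b.conditions)
        de = differential_expression(m, retained=sample_qc(m).retained)
        genes = [f for f in de.index if f.startswith("GENE")]
        flagged = {f for f in genes if de.loc[f, "significant"]}
        assert b.truth.de_gene_ids <= flagged
        fdr = len(flagged - b.truth.de_gene_ids) / max(len(flagged), 1)
        assert fdr <= 0.1


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 18, 22, 18), 4.0),
            ((20, 20, 20, 20), 1.0),
            ((21, 20, 20, 20), 0.5),
        ],
    )
    def test_worked_examples(self, cts, expected):
        m = QpcrMeasurement(*map(float, cts))
        assert ddct_relative_expression(m) == pytest.approx(expected)

    @given(st.floats(1, 40), st.floats(1, 40))
    def test_equal_case_and_control_contrasts_give_unity(self, t, r):
        m = QpcrMeasurement(t, r, t, r)
        assert ddct_relative_expression(m) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), 0.0, -3.0])
    def test_invalid_ct_rejected(self, bad):
        with pytest.raises(ValueError):
            QpcrMeasurement(bad, 20.0, 20.0, 20.0)
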