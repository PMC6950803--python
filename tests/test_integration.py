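"""Correlation statistics and the two-step regulator filter."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anthoreg.integration import (
    correlation_bubble_table,
    find_regulators,
    pearson_p_from_r,
    pearson_with_p,
)
from anthoreg.oplsda import MetaboliteTable
from anthoreg.target_assignment import TargetPair


class TestPearson:
    @pytest.mark.parametrize(
        "r,expected,places",
        [(0.9101, 0.0319, 4), (-0.9243, 0.0247, 4), (-0.9776, 0.004, 3)],
    )
    def test_five_sample_closed_form(self, r, expected, places):
        assert round(pearson_p_from_r(r, 5), places) == expected

    def test_identity_gives_r_one_p_zero(self):
        x = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        rec = pearson_with_p(x, x)
        assert rec.r == 1.0 and rec.p_value == 0.0 and rec.passes

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 20):
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            rec = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert rec.r == pytest.approx(ref.statistic, abs=1e-12)
            assert rec.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(6), rng.standard_normal(6)
        a, b = pearson_with_p(x, y), pearson_with_p(x, -y)
        assert a.r == pytest.approx(-b.r, abs=1e-14)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-14)

    def test_constant_input_is_degenerate_never_passes(self):
        rec = pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert rec.degenerate and not rec.passes and np.isnan(rec.r)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_with_p([1.0, 2.0], [2.0, 1.0])

    def test_p_matches_permutation_null(self):
        # the t-transform p-value agrees with a resampled permutation null
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(50):
            x, y = rng.standard_normal(8), rng.standard_normal(8)
            rec = pearson_with_p(x, y)
            robs = abs(rec.r)
            perm = np.array(
                [abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(1000)]
            )
            diffs.append(abs(rec.p_value - float(np.mean(perm >= robs))))
        assert float(np.mean(diffs)) < 0.03
        assert max(diffs) < 0.15

    def test_df_convention(self):
        rec = pearson_with_p(np.arange(5.0), np.array([1.0, 2.0, 2.5, 4.0, 4.5]))
        assert rec.n == 5 and rec.df == 3


class TestBubbleTable:
    def test_self_pair_retained_with_unit_r(self):
        prof = pd.DataFrame([[1.0, 4.0, 2.0, 6.0, 3.0]], index=["x"])
        out = correlation_bubble_table(prof, prof.rename(index={"x": "y"}))
        assert len(out) == 1 and out.iloc[0]["r"] == pytest.approx(1.0)

    def test_planted_strong_pair_retained(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(5)
        from anthoreg import plant_correlation

        other = plant_correlation(base, 0.97, seed=3)
        a = pd.DataFrame([base], index=["g"])
        b = pd.DataFrame([other], index=["m"])
        out = correlation_bubble_table(a, b)
        assert len(out) == 1 and out.iloc[0]["p_value"] <= 0.05

    def test_mismatched_samples_rejected(self):
        a = pd.DataFrame(np.ones((1, 5)), columns=list("abcde"))
        b = pd.DataFrame(np.ones((1, 5)), columns=list("abcdf"))
        with pytest.raises(ValueError, match="sample set"):
            correlation_bubble_table(a, b)

    def test_independent_noise_near_nominal_alpha(self):
        rng = np.random.default_rng(3)
        kept = tot = 0
        for _ in range(10):
            a = pd.DataFrame(rng.standard_normal((15, 6)))
            b = pd.DataFrame(rng.standard_normal((15, 6)))
            kept += len(correlation_bubble_table(a, b))
            tot += 225
        assert 0.02 <= kept / tot <= 0.09


def _mini_setup(r_lnc_gene: float):
    """One lncRNA, one pathway gene, one anthocyanin compound."""
    from anthoreg import plant_correlation

    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(5)]
    gene = np.array([1.0, 1.2, 0.9, 6.0, 6.3])
    lnc = plant_correlation(gene, 1.0, seed=1) if r_lnc_gene >= 1.0 else None
    if lnc is None:
        # deterministic profile with the requested empirical correlation
        z = (gene - gene.mean()) / gene.std()
        e = rng.standard_normal(5)
        e -= e.mean()
        e -= (e @ z) / (z @ z) * z
        e /= e.std()
        lnc = r_lnc_gene * z + np.sqrt(1 - r_lnc_gene**2) * e
    expr = pd.DataFrame([lnc, gene], index=["lnc1", "geneA"], columns=samples)
    met = MetaboliteTable(
        abundances=pd.DataFrame(
            [2.0 ** (10 + 3 * (lnc - lnc.min()))], index=["metX"], columns=samples
        ),
        classes=pd.Series({"metX": "anthocyanin"}),
        conditions=pd.Series(["G2", "G2", "G2", "G8", "G8"], index=samples),
    )
    de = pd.DataFrame({"significant": [True, True]}, index=["lnc1", "geneA"])
    pairs = [TargetPair("lnc1", "geneA", "cis", offset=-1000)]
    return expr, pairs, de, met


class TestFindRegulators:
    def test_recovers_planted_triples_exactly(self, bundle, pipeline_result):
        planted = {(l, g) for l, g, m, s in bundle.truth.regulator_triples}
        got = {(c.lncrna_id, c.gene_id) for c in pipeline_result.candidates}
        assert got == planted
        for l, g, m, s in bundle.truth.regulator_triples:
            cand = next(c for c in pipeline_result.candidates
                        if (c.lncrna_id, c.gene_id) == (l, g))
            assert m in {x.id_b for x in cand.metabolite_correlations}
            assert cand.sign == ("positive" if s > 0 else "negative")

    def test_correlation_below_gate_excluded(self):
        expr, pairs, de, met = _mini_setup(0.69)
        out = find_regulators(expr, ["lnc1"], pairs, de, {"geneA": "DFR_1"}, met)
        assert out == []

    def test_strong_correlation_accepted(self):
        expr, pairs, de, met = _mini_setup(0.96)
        out = find_regulators(expr, ["lnc1"], pairs, de, {"geneA": "DFR_1"}, met)
        assert len(out) == 1 and out[0].gene_symbol == "DFR_1"

    def test_empty_pathway_list_gives_no_candidates(self, bundle, pipeline_result):
        out = find_regulators(
            pipeline_result.matrix.log_tpm[pipeline_result.qc.retained],
            pipeline_result.lncrna_ids,
            pipeline_result.target_pairs,
            pipeline_result.de,
            {},
            bundle.metabolites,
        )
        assert out == []

    def test_monotone_in_thresholds(self, bundle, pipeline_result):
        args = (
            pipeline_result.matrix.log_tpm[pipeline_result.qc.retained],
            pipeline_result.lncrna_ids,
            pipeline_result.target_pairs,
            pipeline_result.de,
            bundle.anthocyanin_genes,
            bundle.metabolites,
        )
        loose = {(c.lncrna_id, c.gene_id) for c in find_regulators(*args, r_min=0.7)}
        tight = {(c.lncrna_id, c.gene_id) for c in find_regulators(*args, r_min=0.96)}
        stricter_p = {
            (c.lncrna_id, c.gene_id) for c in find_regulators(*args, p_max=0.001)
        }
        assert tight <= loose and stricter_p <= loose

    def test_sample_mismatch_is_an_error(self):
        expr, pairs, de, met = _mini_setup(0.96)
        expr = expr.rename(columns={"s0": "weird"})
        with pytest.raises(ValueError, match="weird"):
            find_regulators(expr, ["lnc1"], pairs, de, {"geneA": "DFR_1"}, met)

    def test_candidates_sorted_by_correlation_strength(self, pipeline_result):
        rs = [abs(c.gene_correlation.r) for c in pipeline_result.candidates]
        assert rs == sorted(rs, reverse=True)
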