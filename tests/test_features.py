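"""TMB transform, signature scoring, PD-1-high proportions, aggregation."""

import numpy as np
import pandas as pd
import pytest

from irae_screen import (
    ExpressionMatrix,
    GeneSet,
    compute_tmb,
    median_factor_matrix,
    pd1_high_proportion,
    preprocess_expression,
    read_gmt,
    signature_score,
)
from irae_screen.errors import (
    DegenerateInputError,
    FeatureMissingError,
    InputError,
    InsufficientGroupsError,
)
from irae_screen.pharmacovigilance import ContingencyTable, RORResult


def _ror(ct, value):
    return RORResult(
        cancer_type=ct, ror=value, ci_low=value, ci_high=value,
        table=ContingencyTable(1, 1, 1, 1), n_reports=2, n_irae=1,
    )


class TestTMB:
    @pytest.mark.parametrize("count, expected", [(0, 0.0), (99, 2.0), (999, 3.0)])
    def test_log10_plus_one_convention(self, count, expected):
        assert compute_tmb(count) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            compute_tmb(-1)

    def test_strictly_increasing(self):
        values = [compute_tmb(c) for c in range(0, 200, 7)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_configurable_base(self):
        assert compute_tmb(7, base=2) == pytest.approx(3.0)


class TestSignatureScore:
    def _matrix(self, data):
        return ExpressionMatrix(values=pd.DataFrame(data), kind="mrna")

    def test_geometric_mean_cytolytic_convention(self):
        expr = self._matrix({"p1": [4.0, 9.0]})
        expr.values.index = ["GZMA", "PRF1"]
        gs = GeneSet("cyt", frozenset({"GZMA", "PRF1"}), scoring="geometric_mean")
        score = signature_score(expr, gs, epsilon=0.0)
        assert score["p1"] == pytest.approx(6.0)

    def test_mean_log_is_mean_of_log2_plus_one(self):
        expr = self._matrix({"p1": [1.0, 3.0]})
        expr.values.index = ["A", "B"]
        gs = GeneSet("sig", frozenset({"A", "B"}), scoring="mean_log")
        assert signature_score(expr, gs)["p1"] == pytest.approx(1.5)

    def test_single_gene_set_is_identity_transform(self):
        expr = self._matrix({"p1": [7.0], "p2": [15.0]})
        expr.values.index = ["A"]
        gs = GeneSet("one", frozenset({"A"}))
        assert signature_score(expr, gs)["p2"] == pytest.approx(4.0)

    def test_missing_genes_dropped_all_missing_raises(self):
        expr = self._matrix({"p1": [1.0]})
        expr.values.index = ["A"]
        partial = GeneSet("s", frozenset({"A", "ZZZ"}))
        assert signature_score(expr, partial)["p1"] == pytest.approx(1.0)
        with pytest.raises(FeatureMissingError):
            signature_score(expr, GeneSet("t", frozenset({"ZZZ"})))


class TestPD1HighProportion:
    def test_interpolated_quantile_oracle(self):
        # Pooled values 1..10: the 80th interpolated percentile is 8.2;
        # the first type holds {9, 10, 1, 2}, so 2 of 4 lie strictly above.
        values = [9, 10, 1, 2, 3, 4, 5, 6, 7, 8]
        expr = ExpressionMatrix(
            values=pd.DataFrame([values], index=["PDCD1"],
                                columns=[f"p{i}" for i in range(10)]),
            kind="mrna",
        )
        types = pd.Series(["A"] * 4 + ["B"] * 6, index=expr.values.columns)
        assert np.percentile(values, 80) == pytest.approx(8.2)
        prop = pd1_high_proportion(expr, types)
        assert prop["A"] == pytest.approx(0.5)  # 9 and 10 exceed 8.2
        assert prop["B"] == pytest.approx(0.0)  # B's maximum is 8 <= 8.2

    def test_all_equal_expression_gives_zero(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame([[5.0] * 6], index=["PDCD1"],
                                columns=[f"p{i}" for i in range(6)]),
            kind="mrna",
        )
        types = pd.Series(["A", "A", "A", "B", "B", "B"], index=expr.values.columns)
        assert (pd1_high_proportion(expr, types) == 0).all()

    def test_pooled_fraction_bounded(self, rng):
        n = 200
        expr = ExpressionMatrix(
            values=pd.DataFrame([rng.lognormal(size=n)], index=["PDCD1"],
                                columns=[f"p{i}" for i in range(n)]),
            kind="mrna",
        )
        types = pd.Series(rng.choice(["A", "B", "C"], size=n), index=expr.values.columns)
        prop = pd1_high_proportion(expr, types)
        assert ((prop >= 0) & (prop <= 1)).all()
        pooled = (prop * types.value_counts()).sum() / n
        assert pooled <= 0.2 + 1 / n

    def test_missing_gene_raises(self):
        expr = ExpressionMatrix(values=pd.DataFrame([[1.0]], index=["A"],
                                                    columns=["p1"]), kind="mrna")
        with pytest.raises(FeatureMissingError):
            pd1_high_proportion(expr, pd.Series(["A"], index=["p1"]), gene_id="PDCD1")


class TestPreprocess:
    def test_log2_transform_and_zero_median_filter(self):
        # three types of two patients each
        values = pd.DataFrame(
            {
                "p1": [7.0, 0.0, 0.0], "p2": [7.0, 0.0, 1.0],
                "p3": [7.0, 5.0, 0.0], "p4": [7.0, 6.0, 0.0],
                "p5": [7.0, 4.0, 0.0], "p6": [7.0, 4.0, 0.0],
            },
            index=["kept", "one_zero_type", "mostly_zero"],
        )
        types = pd.Series(["A", "A", "B", "B", "C", "C"], index=values.columns)
        out = preprocess_expression(
            ExpressionMatrix(values=values, kind="mrna"), types
        )
        # zero median in 1/3 of types is kept; in 2/3 (> half) it is dropped
        assert set(out.values.index) == {"kept", "one_zero_type"}
        assert out.values.loc["kept", "p1"] == pytest.approx(3.0)  # log2(8)

    def test_all_features_removed_is_degenerate(self):
        values = pd.DataFrame({"p1": [0.0], "p2": [0.0]}, index=["gone"])
        types = pd.Series(["A", "B"], index=values.columns)
        with pytest.raises(DegenerateInputError):
            preprocess_expression(ExpressionMatrix(values=values, kind="mrna"), types)

    def test_clean_matrix_keeps_dimensionality(self, rng):
        values = pd.DataFrame(
            rng.lognormal(size=(5, 8)) + 0.5,
            index=[f"g{i}" for i in range(5)],
            columns=[f"p{i}" for i in range(8)],
        )
        types = pd.Series(["A"] * 4 + ["B"] * 4, index=values.columns)
        out = preprocess_expression(ExpressionMatrix(values=values, kind="mrna"), types)
        assert out.values.shape == values.shape


class TestMedianFactorMatrix:
    def _patients(self):
        rows = []
        for k, ct in enumerate(["A", "B", "C"]):
            for i in range(4):
                rows.append(
                    {
                        "patient_id": f"{ct}{i}",
                        "cancer_type": ct,
                        "nonsynonymous_mutation_count": 10 * (k + 1) + i,
                        "DC": 0.1 * (k + 1) + 0.001 * i,
                    }
                )
        return pd.DataFrame(rows)

    def test_median_conventions_and_alignment(self):
        patients = self._patients()
        ror = [_ror("A", 1.0), _ror("B", 2.0), _ror("C", 3.0)]
        fm = median_factor_matrix(patients, {}, [], ror)
        # even group of four -> midpoint convention
        assert fm.values.loc["A", "DC"] == pytest.approx(0.1 + 0.0015)
        assert list(fm.outcome) == [1.0, 2.0, 3.0]
        assert fm.families["DC"] == "panel"

    def test_non_overlapping_types_dropped_and_minimum_enforced(self):
        patients = self._patients()
        ror = [_ror("A", 1.0), _ror("B", 2.0), _ror("Z", 9.0)]
        with pytest.raises(InsufficientGroupsError):
            median_factor_matrix(patients, {}, [], ror)

    def test_median_robust_to_single_outlier(self):
        patients = self._patients()
        spiked = patients.copy()
        spiked.loc[0, "DC"] = 1.0  # extreme but valid enrichment score
        ror = [_ror("A", 1.0), _ror("B", 2.0), _ror("C", 3.0)]
        base = median_factor_matrix(patients, {}, [], ror)
        out = median_factor_matrix(spiked, {}, [], ror)
        # the shift is bounded by the spread of the surviving order statistics
        group = np.sort(patients.query("cancer_type=='A'")["DC"])
        bound = (group[3] - group[1]) / 2
        assert abs(out.values.loc["A", "DC"] - base.values.loc["A", "DC"]) <= bound + 1e-12

    def test_enrichment_scores_validated(self):
        patients = self._patients()
        patients.loc[0, "DC"] = 1.5
        with pytest.raises(InputError):
            median_factor_matrix(patients, {}, [], [_ror("A", 1.0), _ror("B", 2.0), _ror("C", 3.0)])


def test_default_gmt_ships_four_signatures():
    from irae_screen.pipeline import default_gmt_file

    sets = read_gmt(default_gmt_file(), scoring={"CytolyticIndex": "geometric_mean"})
    names = {s.name: s for s in sets}
    assert names["CytolyticIndex"].scoring == "geometric_mean"
    assert names["CytolyticIndex"].genes == {"GZMA", "PRF1"}
    assert len(sets) == 4
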