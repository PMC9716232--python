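"""CES computation, classification, ranking, sensitivity and correlations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fhces.errors import (
    InsufficientDesignError,
    InvalidAssayError,
    InvalidRatioError,
    InvalidScoreError,
    MissingDataError,
)
from fhces.scoring import (
    AssayRatioSet,
    CESResult,
    assay_correlations,
    classify_assay_ratio,
    classify_ces,
    compute_ces,
    compute_ces_no_yield,
    rank_variants,
    score_panel,
    sensitivity_rank_shift,
)


def ratio_set(name="v", **kw):
    base = dict(binding_vc=1.0, daa_vc=1.0, ca_cv=1.0, ap_cv=1.0,
                yield_vc=1.0, hemolysis_score=1.0)
    base.update(kw)
    return AssayRatioSet(variant_name=name, **base)


class TestComputeCES:
    def test_control_scores_exactly_100(self):
        r = ratio_set("Control")
        assert compute_ces(r) == 100.0
        assert compute_ces_no_yield(r) == 100.0

    def test_linearity_half_components(self):
        r = AssayRatioSet("v", 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        assert compute_ces(r) == pytest.approx(50.0)

    def test_worst_case_composite(self):
        # the per-assay published minima assembled into one composite set
        r = AssayRatioSet("worst", binding_vc=0.65, daa_vc=0.08, ca_cv=0.07,
                          ap_cv=0.01, yield_vc=0.26, hemolysis_score=0.0)
        assert compute_ces(r) == pytest.approx(100.0 / 6.0 * 1.07)
        assert compute_ces(r) == pytest.approx(17.8333, abs=1e-3)

    @given(delta=st.floats(-0.5, 2.0))
    def test_linear_in_each_component(self, delta):
        base = compute_ces(ratio_set())
        bumped = compute_ces(ratio_set(binding_vc=1.0 + delta))
        assert bumped - base == pytest.approx(100.0 * delta / 6.0, abs=1e-9)

    def test_no_capping_above_one(self):
        r = ratio_set(binding_vc=1.27, ca_cv=1.13)
        assert compute_ces(r) > 100.0

    def test_yield_omission_ignores_yield(self):
        r = ratio_set(yield_vc=0.26)
        assert compute_ces_no_yield(r) == 100.0
        assert compute_ces(r) < 100.0

    def test_missing_component_strict_vs_partial(self):
        r = ratio_set(ap_cv=None)
        with pytest.raises(MissingDataError):
            compute_ces(r)
        # partial mode renormalizes over the 5 available components
        assert compute_ces(r, partial=True) == pytest.approx(100.0)

    def test_negative_component_rejected(self):
        with pytest.raises(InvalidRatioError):
            compute_ces(ratio_set(daa_vc=-0.1))

    def test_bad_hemolysis_score_rejected(self):
        with pytest.raises(InvalidRatioError):
            compute_ces(ratio_set(hemolysis_score=0.7))


class TestClassification:
    @pytest.mark.parametrize("ces,expected", [
        (100.0, "minimal_impact"), (80.0, "marginal"), (50.0, "defective"),
        (84.0, "marginal"), (75.0, "marginal"),  # boundaries inclusive to marginal
        (84.0001, "minimal_impact"), (74.9999, "defective"),
    ])
    def test_banding(self, ces, expected):
        assert classify_ces(ces) == expected

    @given(ces=st.floats(0.0, 200.0))
    def test_partition_no_gaps_no_overlaps(self, ces):
        cat = classify_ces(ces)
        assert cat in ("minimal_impact", "marginal", "defective")
        if cat == "minimal_impact":
            assert ces > 84.0
        elif cat == "defective":
            assert ces < 75.0
        else:
            assert 75.0 <= ces <= 84.0

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidScoreError):
            classify_ces(float("nan"))


class TestAssayBands:
    @pytest.mark.parametrize("assay,ratio,call", [
        ("binding", 1.0, "normal"), ("binding", 0.65, "impacted"),
        ("binding", 0.9, "normal"), ("binding", 1.2, "normal"),
        ("daa", 1.05, "normal"), ("daa", 0.89, "impacted"),
        ("ca", 1.13, "normal"), ("ca", 0.07, "impacted"),
        ("ap", 0.5, "impacted"), ("ap", 1.25, "normal"),
    ])
    def test_band_calls(self, assay, ratio, call):
        assert classify_assay_ratio(assay, ratio).call == call

    def test_unknown_assay(self):
        with pytest.raises(InvalidAssayError):
            classify_assay_ratio("hemolysis", 1.0)


def result(name, ces, ces_ny=None):
    return CESResult(name, ces, ces if ces_ny is None else ces_ny,
                     classify_ces(ces))


class TestRanking:
    def test_ascending_ranks(self):
        ranked = rank_variants([result("a", 100), result("b", 17), result("c", 50)])
        assert [(r.variant_name, r.rank) for r in ranked] == [
            ("b", 1), ("c", 2), ("a", 3)]

    def test_tie_broken_lexicographically(self):
        ranked = rank_variants([result("Arg303Trp", 80), result("Arg303Gln", 80)])
        assert ranked[0].variant_name == "Arg303Gln"
        assert ranked[0].rank == 1

    def test_single_element(self):
        assert rank_variants([result("only", 90)])[0].rank == 1


class TestSensitivityRankShift:
    def test_uninformative_yield_shifts_nothing(self):
        sets = [ratio_set(f"v{i}", binding_vc=0.5 + 0.05 * i) for i in range(10)]
        results = score_panel(sets)
        shift = sensitivity_rank_shift(results)
        assert (shift.table["shift"] == 0).all()
        assert shift.left_bottom == frozenset() == shift.entered_bottom

    def test_low_yield_high_activity_variant_rises_without_yield(self):
        sets = [ratio_set(f"v{i}", binding_vc=0.3 + 0.1 * i) for i in range(6)]
        # fully active protein secreted poorly: penalized only through yield
        sets.append(ratio_set("lowyield", yield_vc=0.1))
        results = score_panel(sets)
        shift = sensitivity_rank_shift(results, k=3)
        row = shift.table.set_index("variant_name").loc["lowyield"]
        assert row["rank_without_yield"] > row["rank_with_yield"]

    def test_missing_no_yield_score_rejected(self):
        bad = CESResult("x", 90.0, float("nan"), "minimal_impact")
        with pytest.raises(MissingDataError):
            sensitivity_rank_shift([bad])


class TestCorrelations:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        sets = []
        for i in range(10):
            b = float(rng.uniform(0.2, 1.2))
            sets.append(ratio_set(f"v{i}", binding_vc=b, daa_vc=b,
                                  ca_cv=float(rng.uniform(0.2, 1.2))))
        corr = assay_correlations(sets)
        assert corr.loc["binding_vc", "daa_vc"] == pytest.approx(1.0)
        assert corr.shape == (5, 5)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)

    def test_independent_columns_weakly_correlated(self):
        # 200 variants, 200 replicates: median |rho| stays below 0.2
        rng = np.random.default_rng(1)
        off_diag = []
        for _ in range(200):
            sets = [
                ratio_set(f"v{i}",
                          **{k: float(rng.uniform(0.1, 1.3))
                             for k in ("binding_vc", "daa_vc", "ca_cv",
                                       "ap_cv", "yield_vc")})
                for i in range(200)
            ]
            corr = assay_correlations(sets).to_numpy()
            off_diag.append(np.abs(corr[np.triu_indices(5, 1)]))
        assert np.median(np.array(off_diag), axis=0).max() < 0.2

    def test_constant_column_is_undefined_not_zero(self):
        sets = [ratio_set(f"v{i}", binding_vc=1.0,
                          daa_vc=0.5 + 0.1 * i) for i in range(5)]
        corr = assay_correlations(sets)
        assert np.isnan(corr.loc["binding_vc", "daa_vc"])

    def test_too_few_variants(self):
        with pytest.raises(InsufficientDesignError):
            assay_correlations([ratio_set("a"), ratio_set("b")])
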