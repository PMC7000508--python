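
import numpy as np
import pandas as pd
import pytest

import nactscore as ns
from nactscore.association import AssociationResult
from nactscore.errors import ValidationError
from nactscore.signatures import SignatureDefinition


class TestSingleScore:
    def test_positive_generator_effect_yields_or_above_one(self, small_scores, small_study):
        res = ns.single_score_association(small_scores, small_study.clinical, "ms12")
        row = res.table.loc["z_ms12"]
        assert row["or"] > 1.0
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
        assert 0 < row["p"] <= 1

    def test_sign_flip_of_score_inverts_or_and_keeps_p(self, small_scores, small_study):
        res = ns.single_score_association(small_scores, small_study.clinical, "ms12")
        flipped = small_scores.copy()
        flipped["z_ms12"] = -flipped["z_ms12"]
        res2 = ns.single_score_association(flipped, small_study.clinical, "ms12")
        assert res2.table.loc["z_ms12", "or"] == pytest.approx(
            1.0 / res.table.loc["z_ms12", "or"], rel=1e-9
        )
        assert res2.table.loc["z_ms12", "p"] == pytest.approx(
            res.table.loc["z_ms12", "p"], rel=1e-9
        )

    def test_affine_rescaling_of_raw_score_leaves_result_unchanged(
        self, small_gene_expression, small_study, signatures
    ):
        ms12, rs21 = signatures
        scaled_ms = SignatureDefinition(
            "ms12",
            singleton_weights={g: 2.5 * w for g, w in ms12.singleton_weights.items()},
        )
        t1 = ns.build_score_table(small_gene_expression, small_study.clinical, ms12, rs21)
        t2 = ns.build_score_table(small_gene_expression, small_study.clinical, scaled_ms, rs21)
        r1 = ns.single_score_association(t1, small_study.clinical, "ms12")
        r2 = ns.single_score_association(t2, small_study.clinical, "ms12")
        np.testing.assert_allclose(
            r1.table.to_numpy(), r2.table.to_numpy(), rtol=1e-9
        )

    def test_cohort_relabeling_does_not_change_score_or(self, small_scores, small_study):
        res = ns.single_score_association(small_scores, small_study.clinical, "ms12")
        renamed_scores = small_scores.copy()
        # rename so a different cohort becomes the alphabetical reference
        mapping = {"sim0": "zzz0", "sim1": "aaa1", "sim2": "mid2"}
        renamed_scores["cohort"] = renamed_scores["cohort"].map(mapping)
        clin = ns.ClinicalTable(
            small_study.clinical.data.assign(
                cohort=small_study.clinical.data["cohort"].map(mapping)
            )
        )
        res2 = ns.single_score_association(renamed_scores, clin, "ms12")
        assert res2.reference_cohort == "aaa1"
        np.testing.assert_allclose(
            res.table.loc["z_ms12"].to_numpy(),
            res2.table.loc["z_ms12"].to_numpy(),
            rtol=1e-8,
        )


class TestCombined:
    def test_two_predictor_rows_reported(self, small_scores, small_study):
        res = ns.combined_association(small_scores, small_study.clinical)
        assert list(res.table.index) == ["z_ms12", "z_rs21"]
        assert res.events == small_study.clinical.data["pcr"].sum() or res.events > 0

    def test_entering_same_score_twice_raises_collinearity_error(
        self, small_scores, small_study
    ):
        dup = small_scores.copy()
        dup["z_rs21"] = dup["z_ms12"]
        with pytest.raises(ValidationError, match="near-collinear"):
            ns.combined_association(dup, small_study.clinical)


def _manual_result(params: dict, cohorts: list[str]) -> AssociationResult:
    idx = [f"s{i}" for i in range(len(cohorts))]
    return AssociationResult(
        model="single:ms12",
        table=pd.DataFrame(
            [{"predictor": "z_ms12", "coef": params["z_ms12"], "se": 0.1,
              "or": np.exp(params["z_ms12"]), "ci_low": 1.0, "ci_high": 1.0, "p": 0.5}]
        ).set_index("predictor"),
        n=len(cohorts),
        events=1,
        cohorts=sorted(set(cohorts)),
        reference_cohort=sorted(set(cohorts))[0],
        converged=True,
        loglik=0.0,
        params=pd.Series(params),
        sample_cohorts=pd.Series(cohorts, index=idx),
    )


class TestResponseCurve:
    def test_null_model_curve_is_flat_at_marginal_rate(self):
        res = _manual_result({"intercept": np.log(0.1 / 0.9), "z_ms12": 0.0}, ["a"] * 4)
        curve = ns.response_probability_curve(res, grid=np.linspace(-3, 3, 13))
        np.testing.assert_allclose(curve["probability"], 0.1, atol=1e-12)

    def test_curve_strictly_increasing_for_positive_coefficient(self):
        res = _manual_result({"intercept": -2.0, "z_ms12": 0.6}, ["a"] * 4)
        curve = ns.response_probability_curve(res)
        assert (np.diff(curve["probability"]) > 0).all()
        assert ((curve["probability"] > 0) & (curve["probability"] < 1)).all()

    def test_marginal_standardization_matches_hand_average_on_two_cohorts(self):
        params = {"intercept": -2.0, "z_ms12": 0.5, "cohort[b]": 0.8}
        res = _manual_result(params, ["a", "a", "b"])
        curve = ns.response_probability_curve(res, grid=np.array([0.0, 1.0]))

        def invlogit(x):
            return 1 / (1 + np.exp(-x))

        for z, prob in zip(curve["z"], curve["probability"]):
            expect = (
                2 * invlogit(-2.0 + 0.5 * z) + invlogit(-2.0 + 0.8 + 0.5 * z)
            ) / 3
            assert prob == pytest.approx(expect, abs=1e-12)

    def test_grid_outside_range_warns_but_computes(self):
        res = _manual_result({"intercept": -2.0, "z_ms12": 0.5}, ["a"] * 3)
        with pytest.warns(UserWarning, match=r"\[-5, 5\]"):
            curve = ns.response_probability_curve(res, grid=np.array([-6.0, 0.0]))
        assert len(curve) == 2


class TestCorrelation:
    def test_identical_scores_have_unit_correlation(self):
        idx = [f"s{i}" for i in range(10)]
        z = np.linspace(-1, 1, 10)
        scores = pd.DataFrame(
            {"cohort": "c", "z_ms12": z, "z_rs21": z}, index=idx
        )
        pooled, per_cohort = ns.score_correlation(scores)
        assert pooled == pytest.approx(1.0)
        assert per_cohort["c"] == pytest.approx(1.0)

    def test_independent_scores_have_near_zero_correlation(self):
        rng = np.random.default_rng(123)
        n = 10000
        scores = pd.DataFrame(
            {
                "cohort": np.repeat(["a", "b"], n // 2),
                "z_ms12": rng.standard_normal(n),
                "z_rs21": rng.standard_normal(n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        pooled, _ = ns.score_correlation(scores)
        assert abs(pooled) < 0.05

    def test_generated_scores_are_substantially_correlated(self, small_scores, small_study):
        ids = ns.select_er_pos_her2_neg(small_study.clinical)
        pooled, per_cohort = ns.score_correlation(small_scores, ids)
        assert 0.4 < pooled < 0.9
        assert len(per_cohort) == 3

    def test_zero_variance_raises(self):
        scores = pd.DataFrame(
            {"cohort": "c", "z_ms12": [0.0] * 5, "z_rs21": np.arange(5.0)},
            index=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(ValidationError, match="zero variance"):
            ns.score_correlation(scores)


class TestSensitivitySweep:
    def test_one_row_per_requested_percentile(
        self, small_gene_expression, small_study, signatures
    ):
        ms12, rs21 = signatures
        table = ns.sensitivity_sweep(
            small_gene_expression, small_study.clinical, ms12, rs21, (75.0, 85.0)
        )
        assert list(table.index) == [75.0, 85.0]
        assert {"rs_single_or", "comb_ms_p", "comb_rs_p"} <= set(table.columns)

    def test_zero_percentile_equals_unthresholded_signature(
        self, small_gene_expression, small_study, signatures
    ):
        ms12, rs21 = signatures
        no_floor = SignatureDefinition(
            "rs21",
            groups={g: dict(m) for g, m in rs21.groups.items()},
            group_weights=dict(rs21.group_weights),
            singleton_weights=dict(rs21.singleton_weights),
            threshold=None,
        )
        swept = ns.sensitivity_sweep(
            small_gene_expression, small_study.clinical, ms12, rs21, (0.0,)
        )
        t_plain = ns.build_score_table(
            small_gene_expression, small_study.clinical, ms12, no_floor
        )
        plain = ns.single_score_association(t_plain, small_study.clinical, "rs21")
        assert swept.loc[0.0, "rs_single_coef"] == pytest.approx(
            plain.table.loc["z_rs21", "coef"], abs=1e-12
        )
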