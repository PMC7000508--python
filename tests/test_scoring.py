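import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nactscore as ns
from nactscore.errors import ValidationError
from nactscore.signatures import SignatureDefinition, ThresholdPolicy


def _gene_expression(values: dict[str, list[float]], samples=None) -> ns.GeneExpression:
    df = pd.DataFrame(values).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ns.GeneExpression("c", df, {g: 1 for g in values})


class TestGroupScores:
    def test_unweighted_two_gene_group_is_mean(self):
        sig = SignatureDefinition(
            "t", groups={"g": {"A": 1.0, "B": 1.0}}, group_weights={"g": 1.0}
        )
        g = _gene_expression({"A": [2.0], "B": [4.0]})
        gs = ns.compute_group_scores(g, sig)
        assert gs.loc["s0", "g"] == 3.0

    def test_one_gene_group_with_unit_weight_equals_gene(self):
        sig = SignatureDefinition("t", groups={"g": {"A": 1.0}}, group_weights={"g": 2.0})
        g = _gene_expression({"A": [1.5, 7.0]})
        gs = ns.compute_group_scores(g, sig)
        np.testing.assert_array_equal(gs["g"], [1.5, 7.0])

    def test_missing_member_dropped_and_weights_renormalized(self):
        sig = SignatureDefinition(
            "t",
            groups={"g": {f"G{i}": 1.0 for i in range(5)}},
            group_weights={"g": 1.0},
        )
        g = _gene_expression({f"G{i}": [float(i)] for i in range(4)})  # G4 absent
        gs = ns.compute_group_scores(g, sig, missing_policy="renormalize")
        assert gs.loc["s0", "g"] == pytest.approx(np.mean([0, 1, 2, 3]))

    def test_fully_missing_group_is_an_error(self):
        sig = SignatureDefinition("t", groups={"g": {"X": 1.0}}, group_weights={"g": 1.0})
        g = _gene_expression({"A": [1.0]})
        with pytest.raises(ValidationError, match="all genes of group 'g'"):
            ns.compute_group_scores(g, sig)

    def test_missing_singleton_is_an_error(self):
        sig = SignatureDefinition("t", singleton_weights={"X": 1.0})
        g = _gene_expression({"A": [1.0]})
        with pytest.raises(ValidationError, match="singleton gene 'X'"):
            ns.compute_group_scores(g, sig)

    def test_weighted_means_match_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        genes = [f"G{i}" for i in range(9)]
        weights = rng.uniform(0.2, 2.0, size=9)
        sig = SignatureDefinition(
            "t",
            groups={
                "a": dict(zip(genes[:4], weights[:4])),
                "b": dict(zip(genes[4:7], weights[4:7])),
            },
            group_weights={"a": 1.0, "b": 1.0},
            singleton_weights=dict(zip(genes[7:], weights[7:])),
        )
        for _ in range(50):
            vals = {g: rng.normal(size=6).tolist() for g in genes}
            g = _gene_expression(vals)
            gs = ns.compute_group_scores(g, sig)
            arr = {k: np.array(v) for k, v in vals.items()}
            expect_a = sum(arr[g] * w for g, w in zip(genes[:4], weights[:4])) / weights[:4].sum()
            expect_b = sum(arr[g] * w for g, w in zip(genes[4:7], weights[4:7])) / weights[4:7].sum()
            np.testing.assert_allclose(gs["a"], expect_a, atol=1e-12)
            np.testing.assert_allclose(gs["b"], expect_b, atol=1e-12)
            np.testing.assert_allclose(gs[genes[7]], arr[genes[7]], atol=1e-12)


class TestPercentileFloor:
    def test_floor_of_one_to_ten_at_p80_is_interpolated_order_statistic(self):
        values = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        out = ns.apply_percentile_floor(values, values.index, 80.0)
        # h = (n-1)p/100 + 1 = 8.2 -> x_8 + 0.2 (x_9 - x_8) = 8.2
        assert out.min() == pytest.approx(8.2)
        np.testing.assert_allclose(out[:8], 8.2)
        np.testing.assert_allclose(out[8:], [9.0, 10.0])

    def test_p0_is_identity(self):
        values = pd.Series([3.0, -1.0, 5.0], index=list("abc"))
        out = ns.apply_percentile_floor(values, values.index, 0.0)
        pd.testing.assert_series_equal(out, values)

    @given(p1=st.floats(0, 100), p2=st.floats(0, 100))
    def test_variance_non_increasing_in_percentile(self, p1, p2):
        lo, hi = sorted([p1, p2])
        rng = np.random.default_rng(99)
        values = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        v_lo = ns.apply_percentile_floor(values, values.index, lo).var()
        v_hi = ns.apply_percentile_floor(values, values.index, hi).var()
        assert v_hi <= v_lo + 1e-12

    def test_empty_reference_is_an_error(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError, match="empty reference"):
            ns.apply_percentile_floor(values, ["zz"], 50.0)

    def test_floor_uses_reference_subset_only_but_applies_to_all(self):
        values = pd.Series([0.0, 1.0, 2.0, 100.0], index=list("abcd"))
        out = ns.apply_percentile_floor(values, ["a", "b", "c"], 50.0)
        assert out["d"] == 100.0
        assert out["a"] == 1.0  # median of the reference {0,1,2}


class TestMs12:
    def test_zero_expression_gives_zero_score(self, signatures):
        ms12, _ = signatures
        g = _gene_expression({gene: [0.0, 0.0] for gene in ms12.genes})
        np.testing.assert_allclose(ns.compute_ms12(g, ms12), 0.0, atol=1e-12)

    @pytest.mark.parametrize("gene,direction", [("BIRC5", 1), ("UBE2C", 1), ("STC2", -1), ("IL6ST", -1)])
    def test_sign_convention_of_shipped_weights(self, signatures, gene, direction):
        ms12, _ = signatures
        base = _gene_expression({g: [1.0] for g in ms12.genes})
        bumped_vals = {g: [1.0 + (1.0 if g == gene else 0.0)] for g in ms12.genes}
        bumped = _gene_expression(bumped_vals)
        delta = ns.compute_ms12(bumped, ms12).iloc[0] - ns.compute_ms12(base, ms12).iloc[0]
        assert np.sign(delta) == direction

    def test_matches_dot_product_oracle(self, signatures):
        ms12, _ = signatures
        rng = np.random.default_rng(21)
        for _ in range(50):
            vals = {g: rng.normal(8, 2, size=5).tolist() for g in ms12.genes}
            g = _gene_expression(vals)
            score = ns.compute_ms12(g, ms12)
            expect = sum(np.array(vals[gene]) * w for gene, w in ms12.singleton_weights.items())
            np.testing.assert_allclose(score, expect, atol=1e-12)

    def test_any_missing_target_gene_is_an_error(self, signatures):
        ms12, _ = signatures
        vals = {g: [1.0] for g in ms12.genes if g != "MGP"}
        with pytest.raises(ValidationError, match="MGP"):
            ns.compute_ms12(_gene_expression(vals), ms12)


class TestRs21:
    def test_linear_in_proliferation_above_floor(self, signatures):
        _, rs21 = signatures
        rng = np.random.default_rng(4)
        vals = {g: rng.normal(8, 1, size=8).tolist() for g in rs21.genes}
        g = _gene_expression(vals)
        samples = g.sample_ids
        base = ns.compute_rs21(g, rs21, er_positive_ids=samples, percentile=0.0)
        bumped_vals = {
            gene: (np.array(v) + (1.0 if gene in rs21.groups["proliferation"] else 0.0)).tolist()
            for gene, v in vals.items()
        }
        bumped = ns.compute_rs21(
            _gene_expression(bumped_vals), rs21, er_positive_ids=samples, percentile=0.0
        )
        np.testing.assert_allclose(
            bumped - base, rs21.group_weights["proliferation"], atol=1e-9
        )

    def test_matches_independent_floor_and_dot_product_oracle(self, signatures):
        _, rs21 = signatures
        rng = np.random.default_rng(31)
        for _ in range(25):
            vals = {g: rng.normal(8, 1.5, size=12).tolist() for g in rs21.genes}
            g = _gene_expression(vals)
            samples = g.sample_ids
            score = ns.compute_rs21(g, rs21, er_positive_ids=samples, percentile=80.0)

            # independent oracle: weighted means, numpy-free interpolation
            arr = {k: np.array(v) for k, v in vals.items()}
            groups = {}
            for gname, members in rs21.groups.items():
                w = np.array(list(members.values()))
                block = np.vstack([arr[gene] for gene in members])
                groups[gname] = (block * w[:, None]).sum(axis=0) / w.sum()
            ref = np.sort(groups["proliferation"])
            h = (len(ref) - 1) * 0.8
            lo = int(np.floor(h))
            t = ref[lo] + (h - lo) * (ref[min(lo + 1, len(ref) - 1)] - ref[lo])
            groups["proliferation"] = np.maximum(groups["proliferation"], t)
            expect = sum(groups[gname] * w for gname, w in rs21.group_weights.items())
            expect = expect + sum(arr[gene] * w for gene, w in rs21.singleton_weights.items())
            np.testing.assert_allclose(score, expect, atol=1e-12)

    def test_flat_in_proliferation_below_floor(self, signatures):
        _, rs21 = signatures
        rng = np.random.default_rng(8)
        vals = {g: rng.normal(8, 1, size=20).tolist() for g in rs21.genes}
        g = _gene_expression(vals)
        samples = g.sample_ids
        base = ns.compute_rs21(g, rs21, er_positive_ids=samples, percentile=90.0)
        prolif = ns.compute_group_scores(g, rs21)["proliferation"]
        below = prolif.idxmin()
        # lowering the lowest sample's proliferation genes further changes nothing
        vals2 = {
            gene: [
                v - (0.5 if gene in rs21.groups["proliferation"] and s == below else 0.0)
                for v, s in zip(vs, g.sample_ids)
            ]
            for gene, vs in vals.items()
        }
        out = ns.compute_rs21(
            _gene_expression(vals2), rs21, er_positive_ids=samples, percentile=90.0
        )
        assert out[below] == pytest.approx(base[below], abs=1e-12)


class TestZScore:
    def test_three_point_cohort(self):
        raw = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        cohorts = pd.Series(["c"] * 3, index=list("abc"))
        np.testing.assert_allclose(ns.zscore_by_cohort(raw, cohorts), [-1.0, 0.0, 1.0])

    def test_location_shift_of_one_cohort_leaves_z_unchanged(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(40)]
        raw = pd.Series(rng.normal(size=40), index=idx)
        cohorts = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        z1 = ns.zscore_by_cohort(raw, cohorts)
        shifted = raw.copy()
        shifted[cohorts == "b"] += 10.0
        z2 = ns.zscore_by_cohort(shifted, cohorts)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(30)]
        raw = pd.Series(rng.normal(size=30), index=idx)
        cohorts = pd.Series(["a"] * 15 + ["b"] * 15, index=idx)
        z1 = ns.zscore_by_cohort(raw, cohorts)
        z2 = ns.zscore_by_cohort(3.7 * raw + 11.0, cohorts)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_matches_per_cohort_brute_force(self):
        rng = np.random.default_rng(17)
        idx = [f"s{i}" for i in range(50)]
        raw = pd.Series(rng.normal(size=50), index=idx)
        cohorts = pd.Series(["a"] * 30 + ["b"] * 20, index=idx)
        z = ns.zscore_by_cohort(raw, cohorts)
        for c in ("a", "b"):
            vals = raw[cohorts == c]
            expect = (vals - vals.mean()) / vals.std(ddof=1)
            np.testing.assert_allclose(z[cohorts == c], expect, atol=1e-12)

    def test_zero_variance_cohort_error_names_cohort(self):
        raw = pd.Series([1.0, 1.0, 2.0, 3.0], index=list("abcd"))
        cohorts = pd.Series(["flat", "flat", "ok", "ok"], index=list("abcd"))
        with pytest.raises(ValidationError, match="flat"):
            ns.zscore_by_cohort(raw, cohorts)

    def test_subset_defines_standardization_but_all_samples_scored(self):
        raw = pd.Series([1.0, 2.0, 3.0, 50.0], index=list("abcd"))
        cohorts = pd.Series(["c"] * 4, index=list("abcd"))
        z = ns.zscore_by_cohort(raw, cohorts, subset=["a", "b", "c"])
        np.testing.assert_allclose(z[["a", "b", "c"]], [-1.0, 0.0, 1.0])
        assert z["d"] == pytest.approx((50.0 - 2.0) / 1.0)


class TestScoreTable:
    def test_z_columns_standardized_over_analysis_subset(self, small_scores, small_study):
        ids = set(ns.select_er_pos_her2_neg(small_study.clinical, require_response=True))
        for cohort, sub in small_scores.groupby("cohort"):
            z = sub.loc[sub.index.isin(ids), ["z_ms12", "z_rs21"]]
            np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_signature_threshold_config_round_trip(self, tmp_path, signatures):
        _, rs21 = signatures
        modified = rs21.with_percentile(85.0)
        assert modified.threshold.percentile == 85.0
        assert rs21.threshold.percentile == 80.0

    def test_structure_validation_rejects_wrong_sign(self):
        with pytest.raises(ValidationError):
            SignatureDefinition(
                "bad",
                groups={"g": {"A": 1.0}},
                group_weights={"g": 1.0, "phantom": 2.0},
            )
        with pytest.raises(ValidationError, match="not in"):
            ThresholdPolicy("g", 120.0)
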