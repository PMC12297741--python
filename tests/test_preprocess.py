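"""Reverse-scoring, dichotomization, exclusion rules, redundancy, SES, residuals."""

import numpy as np
import pandas as pd
import pytest

from lonenet import (
    compute_ses_index,
    detect_redundant_items,
    dichotomize,
    filter_missing,
    residualize,
    reverse_score,
)
from lonenet.params import LikertSurvey


def survey_from(values, reverse=(), columns=None) -> LikertSurvey:
    df = pd.DataFrame(values, columns=columns)
    df.columns = [str(c) for c in df.columns]
    return LikertSurvey(df.astype("Int64"), set(reverse))


class TestReverseScore:
    def test_five_point_mapping(self):
        survey = survey_from({"i1": [5, 3, 1], "i2": [2, 2, 2]}, reverse={"i1"})
        out = reverse_score(survey)
        assert out.responses["i1"].tolist() == [1, 3, 5]
        assert out.responses["i2"].tolist() == [2, 2, 2]

    def test_empty_item_set_is_identity(self):
        survey = survey_from({"i1": [1, 4], "i2": [5, 2]})
        out = reverse_score(survey, items=set())
        pd.testing.assert_frame_equal(out.responses, survey.responses)

    def test_involution(self):
        survey = survey_from({"i1": [1, 2, 3, 4, 5], "i2": [5, 4, 3, 2, 1]})
        twice = reverse_score(reverse_score(survey, {"i1", "i2"}), {"i1", "i2"})
        pd.testing.assert_frame_equal(twice.responses, survey.responses)

    def test_missing_preserved(self):
        df = pd.DataFrame({"i1": pd.array([1, None, 5], dtype="Int64")})
        out = reverse_score(LikertSurvey(df), {"i1"})
        assert out.responses["i1"].isna().tolist() == [False, True, False]

    def test_unknown_item_rejected(self):
        survey = survey_from({"i1": [1]})
        with pytest.raises(ValueError, match="unknown"):
            reverse_score(survey, {"nope"})


class TestDichotomize:
    @pytest.mark.parametrize(
        "response,expected", [(1, 0), (2, 0), (3, 1), (4, 1), (5, 1)]
    )
    def test_symptom_present_cut(self, response, expected):
        survey = survey_from({"i1": [response], "i2": [1]})
        assert dichotomize(survey)["i1"].iloc[0] == expected

    def test_missing_preserved_and_all_absent(self):
        df = pd.DataFrame(
            {"i1": pd.array([1, 1, None], dtype="Int64"), "i2": pd.array([3, 4, 5], dtype="Int64")}
        )
        out = dichotomize(LikertSurvey(df))
        assert out["i1"].tolist()[:2] == [0, 0] and out["i1"].isna().iloc[2]
        assert out["i2"].tolist() == [1, 1, 1]

    def test_out_of_range_reports_location(self):
        df = pd.DataFrame({"a": [1.0, 7.0], "b": [2.0, 2.0]}, index=["r0", "r1"])
        with pytest.raises(ValueError, match="r1.*'a'"):
            dichotomize(df)


class TestFilterMissing:
    def make(self, missing_per_row):
        cols = [f"i{k}" for k in range(16)]
        rows = []
        for miss in missing_per_row:
            row = [3] * 16
            for j in range(miss):
                row[j] = None
            rows.append(row)
        return pd.DataFrame(rows, columns=cols, dtype="float").astype("Int64")

    def test_thirty_percent_rule(self):
        # 5/16 = 31.25% missing drops the row; 4/16 = 25% keeps it
        data = self.make([5, 4, 0])
        kept, log = filter_missing(data, scale_columns=list(data.columns))
        assert list(kept.index) == [1, 2]
        assert len(log) == 1 and "0.312" in log["reason"].iloc[0]

    def test_entirely_missing_scale(self):
        data = self.make([16, 0])
        kept, log = filter_missing(data, scale_columns=list(data.columns))
        assert list(kept.index) == [1]
        assert log["reason"].iloc[0] == "missing required scale"

    def test_empty_scale_columns_rejected(self):
        with pytest.raises(ValueError, match="scale_columns"):
            filter_missing(self.make([0]), scale_columns=[])


class TestRedundancy:
    def test_exact_duplicates_flagged(self, rng):
        base = rng.standard_normal((300, 5))
        df = pd.DataFrame(base, columns=[f"i{k}" for k in range(5)])
        df["dup"] = df["i0"]
        report = detect_redundant_items(df)
        flagged = report.pairs[report.pairs.flagged]
        assert {"i0", "dup"} in [set(t) for t in zip(flagged.item_a, flagged.item_b)]
        assert (flagged.prop_significant < 0.25).all()

    def test_independent_items_not_flagged(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((2000, 10)), columns=[f"i{k}" for k in range(10)]
        )
        report = detect_redundant_items(df)
        assert not report.pairs.flagged.any() and report.suggested_removals == []

    def test_noisy_copy_flagged_and_weaker_member_removed(self, rng):
        # i0 weakly drives several bystanders; copy = i0 + noise has attenuated
        # correlations everywhere, so the copy is the suggested removal
        n = 2000
        driver = rng.standard_normal(n)
        cols = {"i0": driver}
        for k in range(1, 9):
            cols[f"i{k}"] = 0.15 * driver + rng.standard_normal(n)
        cols["copy"] = driver + 0.3 * rng.standard_normal(n)
        report = detect_redundant_items(pd.DataFrame(cols))
        flagged = report.pairs[report.pairs.flagged]
        assert {"i0", "copy"} in [set(t) for t in zip(flagged.item_a, flagged.item_b)]
        assert "copy" in report.suggested_removals

    def test_false_flag_rate_on_null_data(self, rng):
        flags = 0
        for _ in range(50):
            df = pd.DataFrame(
                rng.standard_normal((500, 8)), columns=[f"i{k}" for k in range(8)]
            )
            flags += detect_redundant_items(df).pairs.flagged.sum()
        assert flags / (50 * 28) <= 0.01

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        df["d"] = 1.0
        with pytest.raises(ValueError, match="'d'"):
            detect_redundant_items(df)


class TestSesIndex:
    def test_two_perfectly_correlated_indicators(self, rng):
        edu = rng.normal(3, 1, 200)
        df = pd.DataFrame({"edu": edu, "occ": 2 * edu + 5})
        res = compute_ses_index(df)
        assert res.variance_explained == pytest.approx(1.0)
        z = (edu - edu.mean()) / edu.std(ddof=1)
        np.testing.assert_allclose(res.scores, 2 * z / np.sqrt(2), atol=1e-8)

    def test_independent_indicators_low_variance_share(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((5000, 5)),
            columns=["edu", "occ", "inc", "hou", "sub"],
        )
        res = compute_ses_index(df)
        assert 0.18 < res.variance_explained < 0.30

    def test_education_loading_sign_convention(self, rng):
        base = rng.standard_normal(500)
        df = pd.DataFrame({"edu": base, "occ": base + 0.1 * rng.standard_normal(500)})
        assert compute_ses_index(df).loadings["edu"] > 0
        flipped = compute_ses_index(-df)
        assert flipped.loadings["edu"] > 0

    def test_affine_rescaling_invariance(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((300, 3)) + [[3, 3, 3]], columns=["edu", "occ", "inc"]
        )
        a = compute_ses_index(df)
        df2 = df.copy()
        df2["inc"] = 100 * df2["inc"] - 7
        b = compute_ses_index(df2)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_partial_rows_scored_and_flagged(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["edu", "occ", "inc"])
        df.iloc[0, 2] = np.nan
        res = compute_ses_index(df)
        assert res.partial.iloc[0] and not res.partial.iloc[1:].any()
        assert np.isfinite(res.scores.iloc[0])

    def test_zero_variance_indicator_rejected(self, rng):
        df = pd.DataFrame({"edu": rng.standard_normal(50), "occ": np.ones(50)})
        with pytest.raises(ValueError, match="occ"):
            compute_ses_index(df)


class TestResidualize:
    def test_removes_covariate_signal(self, rng):
        n = 500
        sex = rng.integers(0, 2, n).astype(float)
        y = 2 * sex + rng.standard_normal(n)
        data = pd.DataFrame({"y": y})
        cov = pd.DataFrame({"sex": sex})
        res = residualize(data, cov)
        assert abs(np.corrcoef(res["y"], sex)[0, 1]) < 1e-10
        assert res["y"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_covariate_only_centers(self, rng):
        n = 200
        y = rng.standard_normal(n)
        x = np.tile([1.0, -1.0], n // 2)
        y = y - (y @ x) / (x @ x) * x  # orthogonalize by construction
        res = residualize(pd.DataFrame({"y": y}), pd.DataFrame({"x": x}))
        np.testing.assert_allclose(res["y"], y - y.mean(), atol=1e-10)

    def test_idempotent(self, rng):
        data = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        cov = pd.DataFrame(
            {"sex": rng.integers(0, 2, 100), "grade": rng.choice(["g3", "g4"], 100)}
        )
        once = residualize(data, cov)
        twice = residualize(once, cov)
        pd.testing.assert_frame_equal(once, twice, atol=1e-10, rtol=0)

    def test_collinear_design_reported(self, rng):
        cov = pd.DataFrame({"a": rng.standard_normal(50)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="collinear"):
            residualize(pd.DataFrame({"y": rng.standard_normal(50)}), cov)
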