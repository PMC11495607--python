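"""Exclusion rules, recodes, and table containers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrpsup as m
from mrpsup.surveys import COMPARISON_LEVELS


def _public_raw(n_fail=474, n_nonbinary=25, n_total=1999):
    """Raw public sample shaped like the study's: failures and non-binary
    respondents flagged, the remainder clean."""
    n_pass = n_total - n_fail
    sex = np.array(["Female", "Male"] * (n_total // 2 + 1))[:n_total]
    sex[n_fail : n_fail + n_nonbinary] = "Non-binary"
    df = pd.DataFrame(
        {
            "respondent_id": np.arange(n_total),
            "sex": sex,
            "comprehension_pass": np.arange(n_total) >= n_fail,
            "support_treatments": np.full(n_total, 4),
        }
    )
    return m.SurveyDataset(df=df, items={"support_treatments": 7},
                           demographics=["sex"])


class TestApplyExclusions:
    def test_public_study_counts(self):
        # 1999 fielded, 474 comprehension failures, 25 non-binary -> 1500
        kept = m.apply_exclusions(_public_raw(), mode="public")
        assert len(kept) == 1500

    def test_no_failures_is_identity(self):
        raw = _public_raw(n_fail=0, n_nonbinary=0, n_total=100)
        kept = m.apply_exclusions(raw, mode="public")
        pd.testing.assert_frame_equal(
            kept.df.reset_index(drop=True), raw.df.reset_index(drop=True)
        )

    def test_idempotent_and_never_grows(self):
        raw = _public_raw()
        once = m.apply_exclusions(raw, mode="public")
        twice = m.apply_exclusions(once, mode="public")
        assert len(once) <= len(raw)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_personnel_hct_filter_by_outcome(self):
        # 33 personnel, 13 have conducted an HCT; one missing rating
        df = pd.DataFrame(
            {
                "respondent_id": np.arange(33),
                "conducted_hct": np.arange(33) < 13,
                "support_treatments": np.full(33, 5.0),
                "importance_risk": np.r_[np.full(32, 8.0), np.nan],
            }
        )
        ds = m.SurveyDataset(
            df=df, items={"support_treatments": 7, "importance_risk": 10},
            demographics=[],
        )
        support = m.apply_exclusions(ds, "personnel", outcome_context="support")
        assert len(support) == 20
        ratings = m.apply_exclusions(ds, "personnel", outcome_context="importance")
        assert len(ratings) == 33
        assert len(ratings.complete_case(["importance_risk"])) == 32

    def test_missing_flag_column_is_named(self):
        df = pd.DataFrame({"sex": ["Male"], "support_treatments": [4]})
        ds = m.SurveyDataset(df=df, items={"support_treatments": 7})
        with pytest.raises(ValueError, match="comprehension_pass"):
            m.apply_exclusions(ds, mode="public")


class TestCollapseSupport:
    @pytest.mark.parametrize(
        "rating,expected",
        [(1, "oppose"), (3, "oppose"), (4, "neutral"), (5, "support"), (7, "support")],
    )
    def test_mapping(self, rating, expected):
        assert m.collapse_support(rating) == expected

    def test_vector_proportions(self):
        out = m.collapse_support([2, 4, 6, 6])
        counts = pd.Series(out).value_counts(normalize=True)
        assert counts["oppose"] == 0.25
        assert counts["neutral"] == 0.25
        assert counts["support"] == 0.5

    @pytest.mark.parametrize("bad", [0, 8, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            m.collapse_support(bad)

    @given(st.lists(st.integers(1, 7), min_size=1, max_size=30))
    def test_total_and_pure_on_domain(self, ratings):
        out = m.collapse_support(ratings)
        assert set(out) <= {"oppose", "neutral", "support"}
        np.testing.assert_array_equal(out, m.collapse_support(ratings))


class TestDeriveComparison:
    @pytest.mark.parametrize(
        "a,b,expected", [(5, 3, "greater"), (4, 4, "equal"), (1, 7, "less")]
    )
    def test_sign_mapping(self, a, b, expected):
        assert m.derive_comparison(a, b) == expected

    def test_scale_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            m.derive_comparison([9], [3], k=7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            m.derive_comparison([1, 2], [1])

    @given(
        st.lists(st.tuples(st.integers(1, 7), st.integers(1, 7)), min_size=1,
                 max_size=30)
    )
    def test_antisymmetric(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        fwd = m.derive_comparison(a, b, k=7)
        rev = m.derive_comparison(b, a, k=7)
        flip = {"greater": "less", "less": "greater", "equal": "equal"}
        assert [flip[x] for x in fwd] == list(rev)


class TestZscoreStateCovariate:
    def test_two_state_hand_computation(self):
        z = m.zscore_state_covariate({"A": 0.1, "B": 0.3})
        assert z["A"] == pytest.approx(-np.sqrt(0.5))
        assert z["B"] == pytest.approx(+np.sqrt(0.5))

    def test_idempotent_on_zscored_input(self):
        z = m.zscore_state_covariate({"A": 0.1, "B": 0.2, "C": 0.4})
        z2 = m.zscore_state_covariate(z)
        for s in z:
            assert z2[s] == pytest.approx(z[s], abs=1e-12)

    def test_location_invariance(self):
        base = {"A": 0.1, "B": 0.2, "C": 0.4}
        shifted = {k: v + 5.0 for k, v in base.items()}
        za, zb = m.zscore_state_covariate(base), m.zscore_state_covariate(shifted)
        for s in base:
            assert za[s] == pytest.approx(zb[s], abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.zscore_state_covariate({"A": 0.1})
        with pytest.raises(ValueError, match="constant"):
            m.zscore_state_covariate({"A": 0.1, "B": 0.1})


class TestContainers:
    def test_survey_roundtrip(self, tmp_path, small_table):
        roster = m.sample_respondents(small_table, 50, seed=1)
        ds = m.simulate_ordinal_responses(roster, m.TruthSpec(cutpoints=[0.0]), 2,
                                          seed=2)
        ds.write_csv(tmp_path / "survey.csv")
        back = m.SurveyDataset.read_csv(tmp_path / "survey.csv")
        assert back.items == ds.items
        pd.testing.assert_frame_equal(
            back.df, ds.df, check_dtype=False, check_exact=False
        )

    def test_poststrat_roundtrip_and_marginalize(self, tmp_path, small_table):
        small_table.write_csv(tmp_path / "ps.csv")
        back = m.PoststratTable.read_csv(tmp_path / "ps.csv")
        assert back.total == small_table.total
        marg = back.marginalize("party")
        assert marg.total == pytest.approx(small_table.total)
        assert "party" not in marg.demographics

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame({"sex": ["F", "F"], "count": [1, 2]})
        with pytest.raises(ValueError, match="duplicate"):
            m.PoststratTable(df=df, demographics=["sex"])

    def test_out_of_scale_responses_rejected(self):
        df = pd.DataFrame({"item": [1, 9]})
        with pytest.raises(ValueError, match="outside"):
            m.SurveyDataset(df=df, items={"item": 7})
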