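"""Scoring: participation recoding, the five criteria, the 0-5 index,
cut-off classification, loneliness dichotomization, derived covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socisol import scoring
from socisol.scoring import (
    CONTACT_NONE,
    CRITERION_NAMES,
    PARTICIPATION_COLUMNS,
    classify_isolated,
    classify_lonely,
    compute_isolation_index,
    derive_covariates,
    evaluate_criteria,
    recode_participation,
)

from conftest import make_participant, participant_frame


# ---------------------------------------------------------------- oracle --
def oracle_index(marital, household_size, children, siblings, friends,
                 neighbors, retired, participation_score):
    """Independent rule-by-rule evaluator of the isolation criteria.

    Plain-python restatement of the scoring rules; contact values are codes
    1-6 or the string "NONE".
    """
    def bad_contact(v):
        return v == "NONE" or v >= 4

    crit1 = household_size == 1 and marital != "married_commonlaw"
    # friends/neighbours jointly: the point only when both channels are
    # infrequent or absent
    fr = 7 if friends == "NONE" else friends
    ne = 7 if neighbors == "NONE" else neighbors
    crit2 = min(fr, ne) >= 4
    crit3 = bad_contact(siblings)
    crit4 = bad_contact(children)
    crit5 = retired and participation_score <= 1
    return int(crit1) + int(crit2) + int(crit3) + int(crit4) + int(crit5)


def participation_items(score):
    """Eight item codes realizing a given 0-8 participation score."""
    return [2] * score + [5] * (8 - score)


# ------------------------------------------------------------ recoding ---
@pytest.mark.parametrize("codes,expected", [
    ([2] * 8, 8),                      # all at-least-weekly
    ([5] * 8, 0),                      # all never
    ([1, 2, 3, 4, 5, 4, 5, 3], 4),     # mixed, hand-enumerated
    ([3] * 8, 8),                      # boundary: monthly counts
    ([4] * 8, 0),                      # boundary: yearly does not
])
def test_participation_recoding(codes, expected):
    assert recode_participation(codes) == expected


def test_participation_rejects_out_of_range_code():
    with pytest.raises(ValueError, match="slot 3"):
        recode_participation([1, 2, 6, 1, 1, 1, 1, 1])
    with pytest.raises(ValueError, match="expected 8"):
        recode_participation([1, 2, 3])


def test_participation_missing_item_gives_missing_score():
    assert np.isnan(recode_participation([1, 2, np.nan, 1, 1, 1, 1, 1]))


# ------------------------------------------------------------ criteria ---
def test_fully_connected_case_meets_no_criteria():
    df = participant_frame([{}])
    crit = evaluate_criteria(df)
    assert not crit.iloc[0].any()
    assert compute_isolation_index(df)["index"].iloc[0] == 0


def test_widowed_solitary_case_meets_four_criteria():
    # widowed, alone, no children, distant siblings, weekly friends,
    # yearly neighbours, retired with participation score 1
    df = participant_frame([{
        "marital_status": "widowed", "household_size": 1,
        "contact_children": CONTACT_NONE, "contact_siblings": 5,
        "contact_close_friends": 2, "contact_neighbors": 6,
        "retired": "retired",
        **{c: code for c, code in zip(PARTICIPATION_COLUMNS,
                                      participation_items(1))},
    }])
    crit = evaluate_criteria(df).iloc[0]
    assert crit.tolist() == [True, False, True, True, True]
    assert compute_isolation_index(df)["index"].iloc[0] == 4


def test_retired_with_participation_two_not_low_participation():
    df = participant_frame([{
        "retired": "retired",
        **{c: code for c, code in zip(PARTICIPATION_COLUMNS,
                                      participation_items(2))},
    }])
    assert not evaluate_criteria(df)["retired_low_participation"].iloc[0]


def test_friend_neighbor_point_requires_both_channels_infrequent():
    base = {"contact_close_friends": 6, "contact_neighbors": 6}
    df = participant_frame([
        base,
        {**base, "contact_close_friends": 2},   # one frequent channel
        {**base, "contact_close_friends": CONTACT_NONE,
         "contact_neighbors": CONTACT_NONE},    # both absent
    ])
    got = evaluate_criteria(df)["low_friend_neighbor_contact"].tolist()
    assert got == [True, False, True]


def test_exhaustive_grid_matches_brute_force_oracle():
    """Scoring agrees with an independent rule evaluator on the full grid
    of marital x household x four contact slots x retirement x
    participation combinations."""
    recency = [1, 4, "NONE"]
    rows, expected = [], []
    for marital in scoring.MARITAL_LEVELS:
        for hh in (1, 2):
            for ch in recency:
                for sib in recency:
                    for fr in recency:
                        for ne in recency:
                            for retired in (True, False):
                                for ps in (0, 1, 2):
                                    conv = lambda v: CONTACT_NONE if v == "NONE" else v
                                    rows.append({
                                        "marital_status": marital,
                                        "household_size": hh,
                                        "contact_children": conv(ch),
                                        "contact_siblings": conv(sib),
                                        "contact_close_friends": conv(fr),
                                        "contact_neighbors": conv(ne),
                                        "retired": "retired" if retired else "working",
                                        **{c: code for c, code in zip(
                                            PARTICIPATION_COLUMNS,
                                            participation_items(ps))},
                                    })
                                    expected.append(oracle_index(
                                        marital, hh, ch, sib, fr, ne,
                                        retired, ps))
    df = participant_frame(rows)
    got = compute_isolation_index(df)["index"].to_numpy(dtype=int)
    assert len(rows) >= 1620
    np.testing.assert_array_equal(got, np.asarray(expected))


# ------------------------------------------------- monotonicity property --
recency_code = st.sampled_from([1, 2, 3, 4, 5, 6, CONTACT_NONE])


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    base=st.tuples(recency_code, recency_code, recency_code, recency_code),
    slot=st.integers(0, 3),
    marital=st.sampled_from(scoring.MARITAL_LEVELS),
    hh=st.integers(1, 3),
    retired=st.booleans(),
    ps=st.integers(0, 8),
)
def test_less_recent_contact_never_decreases_index(base, slot, marital, hh,
                                                   retired, ps):
    worse = list(base)
    worse[slot] = CONTACT_NONE  # the least-contact state
    def frame(contacts):
        ch, sib, fr, ne = contacts
        return participant_frame([{
            "marital_status": marital, "household_size": hh,
            "contact_children": ch, "contact_siblings": sib,
            "contact_close_friends": fr, "contact_neighbors": ne,
            "retired": "retired" if retired else "working",
            **{c: code for c, code in zip(PARTICIPATION_COLUMNS,
                                          participation_items(ps))},
        }])
    i0 = compute_isolation_index(frame(list(base)))["index"].iloc[0]
    i1 = compute_isolation_index(frame(worse))["index"].iloc[0]
    assert i1 >= i0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(ps=st.integers(0, 7), retired=st.booleans())
def test_more_participation_never_increases_index(ps, retired):
    def frame(score):
        return participant_frame([{
            "retired": "retired" if retired else "working",
            **{c: code for c, code in zip(PARTICIPATION_COLUMNS,
                                          participation_items(score))},
        }])
    i_lo = compute_isolation_index(frame(ps + 1))["index"].iloc[0]
    i_hi = compute_isolation_index(frame(ps))["index"].iloc[0]
    assert i_lo <= i_hi


# ------------------------------------------------------------- cut-offs --
def test_cutoff_semantics_and_nesting():
    idx = pd.Series(range(6), dtype="Int64")
    at3 = classify_isolated(idx, 3)
    at2 = classify_isolated(idx, 2)
    assert at3.tolist() == [False, False, False, True, True, True]
    assert at2.tolist() == [False, False, True, True, True, True]
    # the 3-5 classification is nested within the 2-5 classification
    assert (at3 & ~at2).sum() == 0


def test_unconventional_cutoff_warns():
    with pytest.warns(UserWarning, match="cut-off"):
        classify_isolated(pd.Series([1]), 5)


# ----------------------------------------------------------- loneliness --
def test_lonely_partitions_all_codes():
    got = classify_lonely(pd.Series([1, 2, 3, 4]))
    assert got.tolist() == [True, True, False, False]
    assert got.notna().all()


def test_lonely_rejects_bad_code():
    with pytest.raises(ValueError, match="1-4"):
        classify_lonely(5)


# ------------------------------------------------------------ covariates --
def test_derived_covariates():
    df = participant_frame([
        {"age_years": 65, "functional_level": "mild", "household_size": 1},
        {"age_years": 54, "functional_level": "none", "household_size": 4},
    ])
    df.loc[0, "chronic_05"] = 1
    df.loc[0, "chronic_17"] = 1
    cov = derive_covariates(df)
    assert cov["age_group"].tolist() == ["65_74", "45_54"]
    assert cov["functional_binary"].tolist() == ["any_impairment", "no_impairment"]
    assert cov["chronic_count"].tolist() == [2, 0]
    assert cov["living_alone"].tolist() == [True, False]


def test_age_outside_study_range_rejected():
    with pytest.raises(ValueError, match="45-85"):
        derive_covariates(participant_frame([{"age_years": 40}]))
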