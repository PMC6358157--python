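"""Derivation of the social isolation index, the loneliness indicator and
personal covariates from raw questionnaire responses.

The social isolation index counts five deficit criteria (0-5):

1. living alone while not married / in a common-law relationship;
2. in-person contact with close friends *and* neighbours no more recent than
   "within the past 6 months" (or having neither);
3. the same for siblings/relatives;
4. the same for children;
5. retired with little social participation (0 or 1 of eight activity types
   engaged in at least monthly).

Contact-recency items are coded 1 (within the last day or two) .. 6 (more
than 1 year ago); "has no such network members" is ordered past 6 and coded
:data:`CONTACT_NONE` internally.  Participation items are coded 1 (at least
once a day) .. 5 (never) and recoded to at-least-monthly indicators before
summing into a 0-8 participation score.

All functions are vectorised over :class:`pandas.DataFrame` rows; unknown /
refused responses (NaN) propagate to a missing outcome for the affected
record rather than being imputed.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

__all__ = [
    "CONTACT_NONE",
    "CONTACT_CHANNELS",
    "CONTACT_COLUMNS",
    "PARTICIPATION_COLUMNS",
    "CHRONIC_COLUMNS",
    "CRITERION_NAMES",
    "N_CHRONIC_CONDITIONS",
    "recode_participation",
    "evaluate_criteria",
    "compute_isolation_index",
    "classify_isolated",
    "classify_lonely",
    "derive_covariates",
    "validate_participants",
]

#: Internal code for "has no such network members": ordered as the
#: least-contact state, past code 6 ("more than 1 year ago").
CONTACT_NONE = 7

CONTACT_CHANNELS = ("children", "siblings", "close_friends", "neighbors")
CONTACT_COLUMNS = tuple(f"contact_{c}" for c in CONTACT_CHANNELS)
PARTICIPATION_COLUMNS = tuple(f"part_act{i}" for i in range(1, 9))

N_CHRONIC_CONDITIONS = 33
CHRONIC_COLUMNS = tuple(f"chronic_{i:02d}" for i in range(1, N_CHRONIC_CONDITIONS + 1))

CRITERION_NAMES = (
    "alone_unpartnered",
    "low_friend_neighbor_contact",
    "low_sibling_contact",
    "low_child_contact",
    "retired_low_participation",
)

MARITAL_LEVELS = ("married_commonlaw", "never_married", "widowed", "divorced", "separated")
SEX_LEVELS = ("woman", "man")
EDUCATION_LEVELS = ("less_than_postsecondary", "postsecondary")
INCOME_LEVELS = ("lt20k", "20to50k", "50to100k", "100to150k", "ge150k", "missing")
FUNCTIONAL_LEVELS = ("none", "mild", "moderate", "severe", "total")
URBAN_RURAL_LEVELS = ("rural", "urban_core", "urban_fringe", "urban_outside_cma_ca", "not_defined")
RETIRED_LEVELS = ("retired", "working")
AGE_GROUP_LEVELS = ("45_54", "55_64", "65_74", "75_85")


def recode_participation(codes) -> np.ndarray | float:
    """Recode eight activity-frequency items into a 0-8 participation score.

    Each item is coded 1-5 (1 = at least once a day .. 5 = never); codes 1-3
    (at least monthly) count as 1 and codes 4-5 as 0, and the eight
    indicators are summed.

    Parameters
    ----------
    codes
        Sequence of 8 codes, or array-like of shape ``(n, 8)``.  NaN marks an
        unknown/refused item and yields a NaN score for that row.

    Returns
    -------
    Integer score(s) in [0, 8]; float NaN where any item is missing.
    """
    arr = np.asarray(codes, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 8:
        raise ValueError(f"expected 8 participation codes, got {arr.shape[-1]}")
    finite = ~np.isnan(arr)
    bad = finite & ((arr < 1) | (arr > 5) | (arr != np.round(arr)))
    if bad.any():
        row, slot = np.argwhere(bad)[0]
        raise ValueError(
            f"participation code out of range 1-5 in activity slot {slot + 1}"
            f" (row {row}): {arr[row, slot]!r}"
        )
    score = np.where(np.isnan(arr).any(axis=1), np.nan, (arr <= 3).sum(axis=1))
    return float(score[0]) if scalar else score


def _contact_array(df: pd.DataFrame) -> np.ndarray:
    """Contact codes as float matrix (n, 4) in channel order; validates range."""
    arr = df.loc[:, list(CONTACT_COLUMNS)].to_numpy(dtype=float)
    finite = ~np.isnan(arr)
    ok = (arr >= 1) & (arr <= CONTACT_NONE) & (arr == np.round(arr))
    if (finite & ~ok).any():
        i, j = np.argwhere(finite & ~ok)[0]
        raise ValueError(
            f"contact code out of range 1-6/NONE for {CONTACT_COLUMNS[j]}"
            f" (row {df.index[i]}): {arr[i, j]!r}"
        )
    return arr


def evaluate_criteria(df: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the five isolation criteria for each participant row.

    Requires columns ``marital_status``, ``household_size``, the four
    ``contact_*`` columns, ``retired`` and the eight ``part_act*`` columns.
    Returns a nullable-boolean DataFrame with one column per criterion
    (see :data:`CRITERION_NAMES`); missing items yield ``pd.NA``.
    """
    contact = _contact_array(df)
    children = contact[:, CONTACT_CHANNELS.index("children")]
    siblings = contact[:, CONTACT_CHANNELS.index("siblings")]
    friends = contact[:, CONTACT_CHANNELS.index("close_friends")]
    neighbors = contact[:, CONTACT_CHANNELS.index("neighbors")]

    household = df["household_size"].to_numpy(dtype=float)
    marital = df["marital_status"].astype("string")
    retired = df["retired"].astype("string")
    pscore = recode_participation(df.loc[:, list(PARTICIPATION_COLUMNS)].to_numpy())
    pscore = np.atleast_1d(pscore)

    out = pd.DataFrame(index=df.index)
    alone = (household == 1) & (marital != "married_commonlaw").to_numpy(na_value=False)
    alone = np.where(np.isnan(household) | marital.isna().to_numpy(), np.nan, alone)
    # best (most frequent = smallest) contact across the two channels; a
    # single point only when BOTH channels are infrequent or absent
    friend_neighbor_best = np.minimum(friends, neighbors)
    out["alone_unpartnered"] = alone
    out["low_friend_neighbor_contact"] = _ge4(friend_neighbor_best)
    out["low_sibling_contact"] = _ge4(siblings)
    out["low_child_contact"] = _ge4(children)
    rlp = (retired == "retired").to_numpy(na_value=False) & (pscore <= 1)
    rlp = np.where(retired.isna().to_numpy() | np.isnan(pscore), np.nan, rlp)
    out["retired_low_participation"] = rlp
    return out.astype("boolean")


def _ge4(codes: np.ndarray) -> np.ndarray:
    """Infrequent-contact indicator: code >= 4 (past 6 months or less, or NONE)."""
    return np.where(np.isnan(codes), np.nan, codes >= 4)


def compute_isolation_index(df: pd.DataFrame) -> pd.DataFrame:
    """Compute the 0-5 social isolation index with its audit trail.

    Returns a DataFrame with the recoded ``participation_score``, the five
    criterion booleans and the ``index`` (count of true criteria).  A record
    missing any input item gets ``pd.NA`` for the affected criterion and for
    the index.
    """
    crit = evaluate_criteria(df)
    pscore = recode_participation(df.loc[:, list(PARTICIPATION_COLUMNS)].to_numpy())
    out = pd.DataFrame(index=df.index)
    out["participation_score"] = pd.array(np.atleast_1d(pscore), dtype="Int64")
    for name in CRITERION_NAMES:
        out[name] = crit[name]
    # sum of nullable booleans: NA if any criterion is NA
    counts = crit.astype("Int64").sum(axis=1, skipna=False)
    out["index"] = counts.astype("Int64")
    return out


def classify_isolated(index, cutoff: int = 3):
    """Dichotomize the isolation index: isolated iff ``index >= cutoff``.

    The primary classification uses cutoff 3 (scores 3-5 isolated); the
    sensitivity classification uses cutoff 2.  Other cut-offs are allowed
    but warned about.
    """
    if cutoff not in (2, 3):
        warnings.warn(f"unconventional isolation cut-off {cutoff}; primary is 3, sensitivity 2",
                      stacklevel=2)
    if isinstance(index, pd.Series):
        return (index >= cutoff).astype("boolean")
    arr = np.asarray(index)
    result = arr >= cutoff
    return bool(result) if np.isscalar(index) or arr.ndim == 0 else result


def classify_lonely(cesd_lonely):
    """Dichotomize the single CES-D loneliness item (codes 1-4).

    Lonely iff the response is 1 ("all of the time", 5-7 days) or 2
    ("occasionally", 3-4 days); codes 3-4 are not lonely.
    """
    arr = np.asarray(cesd_lonely, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    finite = ~np.isnan(arr)
    bad = finite & ((arr < 1) | (arr > 4) | (arr != np.round(arr)))
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise ValueError(f"cesd_lonely code out of range 1-4 (position {i}): {arr[i]!r}")
    out = np.where(finite, arr <= 2, np.nan)
    if scalar:
        return bool(out[0]) if finite[0] else None
    if isinstance(cesd_lonely, pd.Series):
        return pd.Series(out, index=cesd_lonely.index).astype("boolean")
    return out


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Derive the personal covariates used in descriptive tables and models.

    Age is binned into 45-54 / 55-64 / 65-74 / 75-85 (closed bins);
    functional status is dichotomized (no impairment vs any impairment);
    chronic conditions are counted over the 33 flags; income keeps its
    explicit "missing" level; living alone means household size 1.
    """
    age = df["age_years"].to_numpy(dtype=float)
    if np.nanmin(age) < 45 or np.nanmax(age) > 85:
        raise ValueError("age_years outside the 45-85 study range")
    out = pd.DataFrame(index=df.index)
    bins = [44, 54, 64, 74, 85]
    out["age_group"] = pd.Categorical(
        pd.cut(df["age_years"], bins=bins, labels=AGE_GROUP_LEVELS),
        categories=AGE_GROUP_LEVELS,
    )
    out["sex"] = pd.Categorical(df["sex"], categories=SEX_LEVELS)
    out["marital_status"] = pd.Categorical(df["marital_status"], categories=MARITAL_LEVELS)
    out["education_binary"] = pd.Categorical(df["education"], categories=EDUCATION_LEVELS)
    out["income_band"] = pd.Categorical(df["income_band"], categories=INCOME_LEVELS)
    functional = pd.Categorical(df["functional_level"], categories=FUNCTIONAL_LEVELS)
    out["functional_binary"] = pd.Categorical(
        np.where(pd.isna(functional), None,
                 np.where(np.asarray(functional) == "none", "no_impairment", "any_impairment")),
        categories=("no_impairment", "any_impairment"),
    )
    out["chronic_count"] = df.loc[:, list(CHRONIC_COLUMNS)].astype(int).sum(axis=1)
    out["living_alone"] = (df["household_size"] == 1).astype("boolean")
    out["urban_rural"] = pd.Categorical(df["urban_rural"], categories=URBAN_RURAL_LEVELS)
    return out


_CATEGORICAL_DOMAINS = {
    "sex": SEX_LEVELS,
    "marital_status": MARITAL_LEVELS,
    "education": EDUCATION_LEVELS,
    "income_band": INCOME_LEVELS,
    "functional_level": FUNCTIONAL_LEVELS,
    "urban_rural": URBAN_RURAL_LEVELS,
    "retired": RETIRED_LEVELS,
}


def validate_participants(df: pd.DataFrame, *, strict: bool = True) -> list[str]:
    """Validate a raw participant table against the data dictionary.

    Checks column presence, code ranges, the 45-85 age range, positive
    weights and household size >= 1.  Returns a list of human-readable
    problems; with ``strict`` (default) a non-empty list raises ValueError.
    """
    problems: list[str] = []
    required = (
        ["participant_id", "fsa_code", "age_years", "sex", "marital_status",
         "household_size", "retired", "cesd_lonely", "education", "income_band",
         "functional_level", "urban_rural", "weight"]
        + list(CONTACT_COLUMNS) + list(PARTICIPATION_COLUMNS) + list(CHRONIC_COLUMNS)
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        problems.append(f"missing columns: {missing_cols}")
        if strict:
            raise ValueError("; ".join(problems))
        return problems

    age = df["age_years"].to_numpy(dtype=float)
    if np.nanmin(age) < 45 or np.nanmax(age) > 85:
        problems.append("age_years outside [45, 85]")
    if (df["household_size"].to_numpy(dtype=float) < 1).any():
        problems.append("household_size < 1")
    if (df["weight"].to_numpy(dtype=float) <= 0).any():
        problems.append("non-positive analytic weight")
    for col, levels in _CATEGORICAL_DOMAINS.items():
        vals = df[col].dropna()
        bad = set(vals.unique()) - set(levels)
        if bad:
            problems.append(f"{col}: unknown levels {sorted(bad)}")
    try:
        _contact_array(df)
    except ValueError as exc:
        problems.append(str(exc))
    try:
        recode_participation(df.loc[:, list(PARTICIPATION_COLUMNS)].to_numpy())
    except ValueError as exc:
        problems.append(str(exc))
    cesd = df["cesd_lonely"].to_numpy(dtype=float)
    finite = ~np.isnan(cesd)
    if ((cesd[finite] < 1) | (cesd[finite] > 4)).any():
        problems.append("cesd_lonely outside 1-4")
    if problems and strict:
        raise ValueError("; ".join(problems))
    return problems
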