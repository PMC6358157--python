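"""Reading and writing the participant / census CSV dialects.

The participant CSV has one column per data-dictionary field, with the
four contact-recency slots and eight participation slots as suffixed
columns (``contact_children`` ... ``part_act8``).  "Has no such network
members" is encoded by a configurable sentinel (default ``NA_NONE``);
an empty field means unknown/refused (missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geolink import CENSUS_MEASURES, validate_census
from .scoring import CONTACT_COLUMNS, CONTACT_NONE, validate_participants

__all__ = ["read_participants", "write_participants", "read_census", "write_census"]

DEFAULT_NONE_SENTINEL = "NA_NONE"


def write_participants(df: pd.DataFrame, path, *, none_sentinel: str = DEFAULT_NONE_SENTINEL) -> None:
    """Write a participant table; NONE contact codes become the sentinel."""
    out = df.copy()
    for col in CONTACT_COLUMNS:
        vals = out[col].astype(object)
        vals = vals.where(out[col] != CONTACT_NONE, none_sentinel)
        vals = vals.mask(pd.isna(out[col]), "")
        out[col] = vals
    out.to_csv(path, index=False)


def read_participants(path, *, none_sentinel: str = DEFAULT_NONE_SENTINEL,
                      strict: bool = True) -> pd.DataFrame:
    """Read and validate a participant CSV.

    The sentinel in a contact column maps to the internal NONE code;
    empty fields map to missing.  Header and code-range validation is
    strict by default.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "fsa_code": str},
                     keep_default_na=False, na_values=[""])
    for col in CONTACT_COLUMNS:
        if col not in df.columns:
            continue
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.StringDtype):
            s = s.where(s != none_sentinel, other=str(CONTACT_NONE))
        df[col] = pd.to_numeric(s, errors="raise")
    for col in df.columns:
        if col in ("participant_id", "fsa_code") or col in CONTACT_COLUMNS:
            continue
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                df[col] = df[col].replace({"": np.nan})
    validate_participants(df, strict=strict)
    return df


def write_census(df: pd.DataFrame, path) -> None:
    df.loc[:, ["fsa_code", *CENSUS_MEASURES]].to_csv(path, index=False)


def read_census(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"fsa_code": str})
    return validate_census(df)
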