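"""Linkage of participants to area-level census measures.

Participants are linked to census measures through the Forward Sortation
Area (FSA) — the first three characters of a Canadian postal code, a
letter-digit-letter prefix.  Areas contributing fewer than a minimum number
of participants (default 10) are excluded from analyses, since area-level
estimates are unstable in such small clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CENSUS_MEASURES",
    "LinkReport",
    "normalize_fsa",
    "link_fsa",
    "filter_small_fsas",
    "fsa_descriptives",
]

#: The five FSA-level census measures, all in percentage points.
CENSUS_MEASURES = (
    "pct_women",
    "pct_65plus",
    "pct_nonofficial_language",
    "pct_65plus_low_income",
    "pct_living_alone",
)

_FSA_PATTERN = re.compile(r"^[A-Z][0-9][A-Z]$")


@dataclass
class LinkReport:
    """Bookkeeping for one linkage / filtering pass."""

    n_input: int = 0
    n_linked: int = 0
    n_unmatched: int = 0
    unmatched_codes: list = field(default_factory=list)
    n_fsas_dropped: int = 0
    n_participants_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_linked": self.n_linked,
            "n_unmatched": self.n_unmatched,
            "unmatched_codes": sorted(set(map(str, self.unmatched_codes))),
            "n_fsas_dropped": self.n_fsas_dropped,
            "n_participants_dropped": self.n_participants_dropped,
        }


def normalize_fsa(codes) -> pd.Series:
    """Uppercase, strip and validate FSA codes; invalid codes become NA."""
    s = pd.Series(codes).astype("string").str.strip().str.upper()
    valid = s.str.match(_FSA_PATTERN.pattern).fillna(False)
    return s.where(valid)


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Validate the six-column census table; returns a normalized copy."""
    required = ["fsa_code", *CENSUS_MEASURES]
    missing = [c for c in required if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    out = census.loc[:, required].copy()
    out["fsa_code"] = normalize_fsa(out["fsa_code"])
    if out["fsa_code"].isna().any():
        bad = census.loc[out["fsa_code"].isna(), "fsa_code"].tolist()
        raise ValueError(f"invalid FSA codes in census table: {bad}")
    dup = out["fsa_code"][out["fsa_code"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate FSA codes in census table: {sorted(set(dup))}")
    vals = out.loc[:, list(CENSUS_MEASURES)].to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 100).any():
        raise ValueError("census measures must be percentages in [0, 100]")
    return out


def link_fsa(
    participants: pd.DataFrame,
    census: pd.DataFrame,
    *,
    max_unmatched_frac: float = 0.05,
) -> tuple[pd.DataFrame, LinkReport]:
    """Left-join participants to census measures on the FSA code.

    Participants whose (normalized) FSA code is absent from the census
    table — or malformed — are dropped from the linked table and collected
    in the report.  More than ``max_unmatched_frac`` unmatched participants
    is a hard error, as is a duplicated census FSA.

    Returns
    -------
    (linked, report)
        ``linked`` carries every participant column plus the five census
        measures; ``report`` is a :class:`LinkReport`.
    """
    census = validate_census(census)
    report = LinkReport(n_input=len(participants))
    fsa = normalize_fsa(participants["fsa_code"])
    out = participants.copy()
    out["fsa_code"] = fsa
    merged = out.merge(census, on="fsa_code", how="left", validate="many_to_one")
    merged.index = participants.index
    unmatched = merged["pct_women"].isna() | fsa.isna()
    report.n_unmatched = int(unmatched.sum())
    report.unmatched_codes = (
        participants.loc[unmatched.to_numpy(), "fsa_code"].astype(str).tolist()
    )
    if report.n_input and report.n_unmatched / report.n_input > max_unmatched_frac:
        raise ValueError(
            f"{report.n_unmatched}/{report.n_input} participants unmatched to census "
            f"(> {max_unmatched_frac:.0%} allowed): {sorted(set(report.unmatched_codes))[:10]}"
        )
    linked = merged.loc[~unmatched.to_numpy()].copy()
    report.n_linked = len(linked)
    return linked, report


def filter_small_fsas(
    records: pd.DataFrame,
    min_fsa_size: int = 10,
    *,
    report: LinkReport | None = None,
) -> tuple[pd.DataFrame, LinkReport]:
    """Drop all records in FSAs with fewer than ``min_fsa_size`` participants.

    Adds/refreshes an ``fsa_n`` column (participants per FSA after the
    filter) on the returned table and logs the dropped counts in the report.
    """
    if report is None:
        report = LinkReport(n_input=len(records))
    sizes = records.groupby("fsa_code", observed=True)["fsa_code"].transform("size")
    keep = sizes >= min_fsa_size
    dropped = records.loc[~keep]
    report.n_fsas_dropped = int(dropped["fsa_code"].nunique())
    report.n_participants_dropped = int(len(dropped))
    out = records.loc[keep].copy()
    out["fsa_n"] = sizes[keep].astype(int)
    return out, report


def fsa_descriptives(census: pd.DataFrame) -> pd.DataFrame:
    """Per-measure summary of the FSA census table (mean, SD, SE, min, max).

    Both the SD and the SE (= SD / sqrt(N)) are reported, since published
    area-level summaries are ambiguous about which the parenthetical is.
    """
    if len(census) < 2:
        raise ValueError("need at least 2 FSAs for descriptives")
    rows = []
    for m in CENSUS_MEASURES:
        v = census[m].to_numpy(dtype=float)
        rows.append({
            "measure": m,
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n_fsa": len(v),
        })
    return pd.DataFrame(rows)
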