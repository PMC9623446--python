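"""ICD-10 cause grouping and demographic stratification of ED-visit claims.

Visits are classified into 21 cause groups plus all-cause from packaged
ICD-10 code ranges.  Groups are mutually exclusive except for asthma (nested
in respiratory), bacterial enteritis (nested in infectious/parasitic) and
suicidality/depression (overlapping mental/behavioral and signs/symptoms).
Heat-related illness (T67, E86, E87) is the only group matched on *any
mention* — a qualifying code in the principal or any secondary position;
every other group matches on the principal diagnosis only.

Range membership is prefix-inclusive on the normalized (dot-free) code:
T67.0XXA belongs to T67, J45.909 to J45.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

AGE_GROUPS = ("0-5", "6-12", "13-17")
_ICD_RE = re.compile(r"^[A-Z]\d[0-9A-Z](?:\.?[0-9A-Z]{1,4})?$")


def normalize_code(code: str) -> str:
    """Uppercase, strip whitespace and the decimal point."""
    return str(code).strip().upper().replace(".", "")


def is_valid_code(code: str) -> bool:
    return bool(_ICD_RE.match(str(code).strip().upper()))


@dataclass(frozen=True)
class CauseGroup:
    """One cause group: a set of ICD-10 ranges and a matching scope."""

    name: str
    label: str
    ranges: tuple[tuple[str, str], ...]   # normalized (start, end) pairs
    match_scope: str                      # "principal" or "any_mention"
    overlap: bool = False

    def __post_init__(self):
        for start, end in self.ranges:
            if len(start) != len(end) or start > end:
                raise ValueError(f"malformed ICD range {start}-{end} in {self.name}")

    def contains(self, code: str) -> bool:
        """Prefix-inclusive range membership of a normalized code."""
        for start, end in self.ranges:
            trunc = code[: len(start)]
            if len(trunc) == len(start) and start <= trunc <= end:
                return True
        return False


def load_cause_groups() -> list[CauseGroup]:
    """The packaged cause-group table (21 groups plus all-cause)."""
    with resources.files("heatlagccx.data").joinpath("cause_groups.csv").open() as fh:
        df = pd.read_csv(fh)
    groups = []
    for name, sub in df.groupby("group", sort=False):
        ranges = tuple(
            (normalize_code(s), normalize_code(e))
            for s, e in zip(sub["range_start"], sub["range_end"]))
        groups.append(CauseGroup(
            name=name,
            label=sub["label"].iloc[0],
            ranges=ranges,
            match_scope="any_mention" if (sub["scope"] == "any_mention").any()
            else "principal",
            overlap=bool(sub["overlap"].iloc[0]),
        ))
    return groups


def classify_visit(principal_dx: str, secondary_dx=(),
                   groups: list[CauseGroup] | None = None) -> set[str]:
    """Cause-group names for one visit.

    Every visit belongs to ``all_cause``.  Principal-scope groups match the
    principal code only; the heat-related group matches a qualifying code in
    the principal or any secondary position.  An unparseable principal code
    leaves the visit in all-cause only.
    """
    if groups is None:
        groups = load_cause_groups()
    out = {"all_cause"}
    principal_ok = is_valid_code(principal_dx)
    p = normalize_code(principal_dx) if principal_ok else None
    secondaries = [normalize_code(c) for c in secondary_dx if is_valid_code(c)]
    for g in groups:
        if g.name == "all_cause":
            continue
        if g.match_scope == "any_mention":
            codes = ([p] if principal_ok else []) + secondaries
            if any(g.contains(c) for c in codes):
                out.add(g.name)
        elif principal_ok and g.contains(p):
            out.add(g.name)
    return out


def classify_visits(visits: pd.DataFrame,
                    groups: list[CauseGroup] | None = None) -> pd.DataFrame:
    """Vectorized classification: one boolean column per cause group.

    ``visits`` needs columns ``principal_dx`` and ``secondary_dx`` (list of
    codes, or a pipe-delimited string).  Returns the input with the label
    columns appended.
    """
    if groups is None:
        groups = load_cause_groups()
    out = visits.copy()
    principal = visits["principal_dx"].astype(str).map(
        lambda c: normalize_code(c) if is_valid_code(c) else "")
    sec = visits.get("secondary_dx")
    if sec is None:
        sec_lists = [[] for _ in range(len(visits))]
    else:
        sec_lists = [
            [normalize_code(c) for c in
             (s if isinstance(s, (list, tuple)) else
              ([] if (s is None or (isinstance(s, float) and np.isnan(s)) or s == "")
               else str(s).split("|")))
             if is_valid_code(c)]
            for s in sec
        ]
    for g in groups:
        if g.name == "all_cause":
            out[g.name] = True
        elif g.match_scope == "any_mention":
            out[g.name] = np.array([
                (p != "" and g.contains(p)) or any(g.contains(c) for c in sl)
                for p, sl in zip(principal, sec_lists)], dtype=bool)
        else:
            out[g.name] = np.array(
                [p != "" and g.contains(p) for p in principal], dtype=bool)
    return out


# ---------------------------------------------------------------------------
# count summaries
# ---------------------------------------------------------------------------

def percent_of_allcause(counts: dict[str, int],
                        allcause_key: str = "all_cause") -> dict[str, float]:
    """Percent of the all-cause total, rounded to 2 decimals.

    Accepts any mapping of group -> count (e.g. a published table's printed
    counts) and divides by the all-cause entry.
    """
    total = counts[allcause_key]
    out = {}
    for name, n in counts.items():
        if name == allcause_key:
            continue
        out[name] = round(100.0 * n / total, 2) if total > 0 else 0.0
    return out


def summarize_counts(labeled: pd.DataFrame,
                     groups: list[CauseGroup] | None = None) -> pd.DataFrame:
    """Per-group visit counts and percent of all-cause (2 decimals)."""
    if groups is None:
        groups = load_cause_groups()
    counts = {g.name: (int(labeled[g.name].sum()) if g.name in labeled else 0)
              for g in groups}
    pct = percent_of_allcause(counts)
    rows = [{"group": g.name, "label": g.label, "n": counts[g.name],
             "percent": pct.get(g.name, float("nan"))} for g in groups]
    return pd.DataFrame(rows)


def heat_related_shares(labeled: pd.DataFrame,
                        groups: list[CauseGroup] | None = None) -> dict[str, float]:
    """Heat-related share of all visits under both tabulation rules.

    ``any_mention``: a heat code in the principal or any secondary position
    (the group's definition).  ``principal_only``: a heat code in the
    principal position.  Published summaries have used both conventions, so
    the two are reported side by side rather than reconciled.
    """
    if groups is None:
        groups = load_cause_groups()
    heat = next(g for g in groups if g.name == "heat_related")
    total = int(labeled["all_cause"].sum()) if "all_cause" in labeled else len(labeled)
    any_mention = int(labeled["heat_related"].sum())
    principal_only = int(labeled["principal_dx"].astype(str).map(
        lambda c: is_valid_code(c) and heat.contains(normalize_code(c))).sum())
    return {
        "any_mention_pct": round(100.0 * any_mention / total, 2) if total else 0.0,
        "principal_only_pct": round(100.0 * principal_only / total, 2) if total else 0.0,
    }


# ---------------------------------------------------------------------------
# demographic strata
# ---------------------------------------------------------------------------

def age_group(age_years: int) -> str:
    """Printed age bins: 0-5, 6-12, 13-17 (boundaries inclusive)."""
    a = int(age_years)
    if not 0 <= a <= 17:
        raise ValueError(f"age {a} outside pediatric range 0-17")
    if a <= 5:
        return AGE_GROUPS[0]
    if a <= 12:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def assign_stratum(age_years: int, sex: str, county_id,
                   county_region: dict) -> tuple[str, str, str]:
    """(age_group, sex, NCA4 region) key for one visit."""
    if county_id not in county_region:
        raise KeyError(f"county {county_id!r} not in region lookup")
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    return (age_group(age_years), sex, county_region[county_id])


def assign_strata(visits: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Vectorized stratum assignment; adds age_group and region columns.

    ``regions`` maps county_id -> NCA4 region label.
    """
    lookup = dict(zip(regions["county_id"], regions["region"]))
    missing = set(visits["county_id"]) - set(lookup)
    if missing:
        raise KeyError(f"counties without region mapping: {sorted(missing)[:5]}")
    out = visits.copy()
    ages = out["age_years"].astype(int)
    if (ages < 0).any() or (ages > 17).any():
        raise ValueError("age outside pediatric range 0-17")
    out["age_group"] = pd.cut(ages, bins=[-1, 5, 12, 17],
                              labels=list(AGE_GROUPS)).astype(str)
    out["region"] = out["county_id"].map(lookup)
    return out


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def read_visits(path) -> tuple[pd.DataFrame, int]:
    """Read the visits CSV; returns (valid visits, n_rejected_age).

    Records outside the pediatric age range (<18 years) are rejected at
    ingest.  ``secondary_dx`` is pipe-delimited in the file and parsed to a
    list.
    """
    df = pd.read_csv(path, dtype={"principal_dx": str, "secondary_dx": str})
    df["date"] = pd.to_datetime(df["date"])
    df["secondary_dx"] = df["secondary_dx"].fillna("").map(
        lambda s: [c for c in str(s).split("|") if c])
    ok = (df["age_years"] >= 0) & (df["age_years"] < 18)
    return df[ok].reset_index(drop=True), int((~ok).sum())


def write_visits(visits: pd.DataFrame, path) -> None:
    out = visits.copy()
    if "secondary_dx" in out.columns:
        out["secondary_dx"] = out["secondary_dx"].map(
            lambda s: "|".join(s) if isinstance(s, (list, tuple)) else (s or ""))
    out.to_csv(path, index=False, date_format="%Y-%m-%d")
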