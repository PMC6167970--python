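"""Morphometric standardization, diagnosability, and type-series assignment.

Measured characters are expressed on the "times-into" scale: the standardized
value is reference length / raw measurement, so a head length of 3.5 means the
head fits 3.5 times into the standard length.  This convention is used because
published range tables for characters smaller than the reference length exceed
1.  Meristic (count) characters pass through unchanged and use integer interval
membership.

A specimen is "consistent" with a name-bearing type series for a character when
its standardized value lies inside that series' inclusive [min, max] envelope;
the assignment score for a series is the proportion of scored variables that
are consistent.  Because envelopes of different series overlap, per-specimen
proportions across series may sum to more than 1.
"""

from __future__ import annotations

import logging
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REFERENCE_COLUMNS = {"SL": "standard_length", "HL": "head_length", "BD": "body_depth"}


@dataclass
class TypeSeriesRange:
    """Per-character [min, max] envelope of one name-bearing type series."""

    name: str
    intervals: dict[str, tuple[float, float]]
    n_specimens: int = 0

    def __post_init__(self) -> None:
        for char, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"{self.name}/{char}: min {lo} > max {hi}")


@dataclass
class AssignmentResult:
    """Per-series consistency proportions for one specimen (2 dp)."""

    specimen_id: str
    proportions: dict[str, float]
    unclassified: float
    n_variables: int
    skipped: tuple[str, ...] = field(default=())


def _normalize(name: str) -> str:
    return " ".join(str(name).lower().split())


def standardize_measurements(
    specimens: pd.DataFrame, reference_map: Mapping[str, str]
) -> pd.DataFrame:
    """Standardize raw measurements to the times-into scale.

    ``reference_map`` assigns each measured character to its reference length
    (``SL``, ``HL`` or ``BD``); characters absent from the map (meristics,
    precomputed ratios) pass through unchanged.  Standardized value =
    reference length / raw measurement.
    """
    out = specimens.copy()
    cols = {_normalize(c): c for c in specimens.columns}
    for char, ref in reference_map.items():
        if ref not in REFERENCE_COLUMNS:
            raise ValueError(f"unknown reference tag {ref!r} for {char!r}")
        col = cols.get(_normalize(char))
        if col is None:
            continue
        ref_col = REFERENCE_COLUMNS[ref]
        raw = specimens[col].astype(float)
        ref_len = specimens[ref_col].astype(float)
        if (raw <= 0).any() or (ref_len <= 0).any():
            raise ValueError(f"non-positive measurement in {col!r} or {ref_col!r}")
        out[col] = ref_len / raw
    return out


def invert_standardization(
    standardized: pd.DataFrame, reference_map: Mapping[str, str]
) -> pd.DataFrame:
    """Recover raw measurements (ref length / standardized value)."""
    return standardize_measurements(standardized, reference_map)


def test_allometry(specimens: pd.DataFrame, characters: Sequence[str]) -> pd.DataFrame:
    """OLS regression of each raw character on standard length.

    Reports slope, intercept, r^2 and the p-value of the slope; scaling
    consistent with linearity shows a significant slope and an intercept near
    zero.  Requires >= 3 specimens and non-constant standard length.
    """
    if len(specimens) < 3:
        raise ValueError("allometry test needs >= 3 specimens")
    sl = specimens["standard_length"].astype(float)
    if np.ptp(sl.to_numpy()) == 0:
        raise ValueError("standard length is constant; regression is degenerate")
    rows = []
    for c in characters:
        res = stats.linregress(sl, specimens[c].astype(float))
        rows.append(
            {
                "character": c,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.rvalue**2,
                "p_value": res.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("character")


def test_preservation_effects(
    type_values: Iterable[float], fresh_values: Iterable[float], alpha: float = 0.05
) -> dict:
    """Two-sample comparison of preserved type material against fresh material.

    A two-sided F-test on the variance ratio chooses between the pooled and
    the unequal-variance (Welch) t-test at ``alpha``; both the F and t results
    are reported, along with which t variant was used.
    """
    a = np.asarray(list(type_values), dtype=float)
    b = np.asarray(list(fresh_values), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.allclose(a.mean(), b.mean()):
            return {
                "f_statistic": 1.0, "f_p": 1.0,
                "t_statistic": 0.0, "t_p": 1.0, "variant": "pooled",
            }
        raise ValueError("zero variance in both samples")
    f_stat = va / vb if vb > 0 else np.inf
    if np.isfinite(f_stat):
        cdf = stats.f.cdf(f_stat, a.size - 1, b.size - 1)
        f_p = 2 * min(cdf, 1 - cdf)
    else:
        f_p = 0.0
    equal_var = f_p >= alpha
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "f_statistic": float(f_stat),
        "f_p": float(f_p),
        "t_statistic": float(t_stat),
        "t_p": float(t_p),
        "variant": "pooled" if equal_var else "welch",
    }


def summarize_group_ranges(
    specimens: pd.DataFrame, grouping: str, characters: Sequence[str]
) -> pd.DataFrame:
    """Inclusive per-group [min, max] for each character (long format)."""
    if specimens.empty:
        raise ValueError("no specimens")
    rows = []
    for g, sub in specimens.groupby(grouping, sort=True):
        for c in characters:
            vals = sub[c].dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "group": g,
                    "character": c,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def ranges_to_type_series(ranges: pd.DataFrame) -> list[TypeSeriesRange]:
    """Convert a long-format range table to TypeSeriesRange objects."""
    out = []
    for g, sub in ranges.groupby("group", sort=True):
        intervals = {
            r.character: (float(r.min), float(r.max)) for r in sub.itertuples(index=False)
        }
        n = int(sub["n"].max()) if "n" in sub.columns else 0
        out.append(TypeSeriesRange(name=str(g), intervals=intervals, n_specimens=n))
    return out


def _intervals_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def _overlap_length(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def character_diagnosability(ranges: Sequence[TypeSeriesRange]) -> pd.DataFrame:
    """Pairwise diagnosability of every character across groups.

    A character is diagnostic for a pair of groups iff their [min, max]
    intervals are disjoint; otherwise the overlap length is reported.
    """
    if len(ranges) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for ra, rb in itertools.combinations(ranges, 2):
        for char in sorted(set(ra.intervals) & set(rb.intervals)):
            ia, ib = ra.intervals[char], rb.intervals[char]
            rows.append(
                {
                    "character": char,
                    "group_a": ra.name,
                    "group_b": rb.name,
                    "diagnostic": _intervals_disjoint(ia, ib),
                    "overlap_length": _overlap_length(ia, ib),
                }
            )
    return pd.DataFrame(rows)


def diagnostic_characters(diagnosability: pd.DataFrame) -> list[str]:
    """Characters that are diagnostic for every group pair they were scored on."""
    per_char = diagnosability.groupby("character")["diagnostic"].all()
    return sorted(per_char[per_char].index)


def assign_to_type_series(
    specimen: "pd.Series | Mapping[str, float]",
    ranges: Sequence[TypeSeriesRange],
    variables: Sequence[str],
) -> AssignmentResult:
    """Score one standardized specimen against every type-series envelope.

    For each series the score is the proportion of scored variables whose
    value lies inside that series' inclusive interval; the unclassified
    proportion counts variables inside no series' interval.  Variables with a
    missing value are skipped (denominator reduced) with a warning.
    Proportions are rounded to 2 decimals for reporting.
    """
    get = specimen.get if hasattr(specimen, "get") else specimen.__getitem__
    sid = str(get("specimen_id", "?") if hasattr(specimen, "get") else "?")
    scored: list[str] = []
    skipped: list[str] = []
    for v in variables:
        val = get(v, None)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            skipped.append(v)
        else:
            scored.append(v)
    if skipped:
        logger.warning(
            "specimen %s: skipping %d variable(s) with missing values: %s",
            sid, len(skipped), ", ".join(skipped),
        )
    if not scored:
        raise ValueError("no scorable variables")

    hits = {r.name: 0 for r in ranges}
    unclassified = 0
    for v in scored:
        val = float(get(v))
        in_any = False
        for r in ranges:
            if v not in r.intervals:
                continue
            lo, hi = r.intervals[v]
            if lo <= val <= hi:
                hits[r.name] += 1
                in_any = True
        if not in_any:
            unclassified += 1
    n = len(scored)
    return AssignmentResult(
        specimen_id=sid,
        proportions={k: round(c / n, 2) for k, c in hits.items()},
        unclassified=round(unclassified / n, 2),
        n_variables=n,
        skipped=tuple(skipped),
    )


def average_assignment_proportions(results: Sequence[AssignmentResult]) -> dict[str, float]:
    """Arithmetic mean of the 2-dp per-specimen proportions, rounded to 2 dp.

    The average is taken over the rounded per-specimen values so that it
    reproduces the arithmetic of published assignment tables, which print
    2-decimal proportions.
    """
    if not results:
        raise ValueError("no assignment results")
    series = sorted({k for r in results for k in r.proportions})
    out = {
        s: round(float(np.mean([r.proportions.get(s, 0.0) for r in results])), 2)
        for s in series
    }
    out["unclassified"] = round(float(np.mean([r.unclassified for r in results])), 2)
    return out


def clade_morphology_overlap(
    specimens: pd.DataFrame, clade_column: str, characters: Sequence[str]
) -> dict:
    """Cross-clade interval overlap for each character, plus a verdict.

    Builds per-clade ranges and reports, for every character and clade pair,
    the overlap fraction (intersection length / union length; identical
    intervals score 1, disjoint intervals 0).  The verdict lists characters
    diagnostic between at least one clade pair.  Singleton clades (degenerate
    zero-width ranges) are flagged.
    """
    if specimens[clade_column].isna().any():
        raise ValueError("every specimen must be assigned a clade")
    ranges_df = summarize_group_ranges(specimens, clade_column, characters)
    ranges = ranges_to_type_series(ranges_df)
    singletons = sorted(
        g for g, sub in specimens.groupby(clade_column) if len(sub) == 1
    )
    rows = []
    for ra, rb in itertools.combinations(ranges, 2):
        for char in sorted(set(ra.intervals) & set(rb.intervals)):
            ia, ib = ra.intervals[char], rb.intervals[char]
            inter = _overlap_length(ia, ib)
            union = max(ia[1], ib[1]) - min(ia[0], ib[0])
            frac = 1.0 if union == 0 else inter / union
            rows.append(
                {
                    "character": char,
                    "clade_a": ra.name,
                    "clade_b": rb.name,
                    "overlap_fraction": frac,
                    "diagnostic": _intervals_disjoint(ia, ib),
                }
            )
    table = pd.DataFrame(rows)
    diagnostic = sorted(table.loc[table["diagnostic"], "character"].unique())
    return {
        "overlap": table,
        "diagnostic_characters": diagnostic,
        "singleton_clades": singletons,
        "ranges": ranges_df,
    }
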