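"""Published reference tables for the roundtail-chub species complex.

Three tables ship with the package as plain CSV, transcribed from the
published range and assignment summaries for the *Gila robusta* complex:

* type-series character ranges (standardized times-into scale) for the
  *G. robusta*, *G. nigra*, *G. intermedia* and *G. grahamii* name-bearing
  type material;
* the same characters for fresh material of the three nominal species;
* per-specimen type-series assignment proportions for 17 fresh specimens.

Two printed values were repaired during transcription: a garbled dorsal-fin
range ("4.4.6.0" read as 4.4-6.0) and one reversed interval (2.8-2.1 stored
as 2.1-2.8).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from gilakit.morphometrics import AssignmentResult, TypeSeriesRange


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("gilakit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_type_series_table() -> pd.DataFrame:
    """Wide table of type-series character ranges (one min/max pair per series)."""
    return _read_csv("type_series_ranges.csv")


def load_fresh_material_table() -> pd.DataFrame:
    """Wide table of fresh-material character ranges per nominal species."""
    return _read_csv("fresh_material_ranges.csv")


def load_assignment_proportions() -> pd.DataFrame:
    """Per-specimen assignment proportions (rows: series; columns: specimens)."""
    return _read_csv("assignment_proportions.csv").set_index("series")


def _wide_to_ranges(table: pd.DataFrame, series: list[str]) -> list[TypeSeriesRange]:
    out = []
    for s in series:
        sub = table.dropna(subset=[f"{s}_min", f"{s}_max"])
        intervals = {
            row["character"]: (float(row[f"{s}_min"]), float(row[f"{s}_max"]))
            for _, row in sub.iterrows()
        }
        out.append(TypeSeriesRange(name=s, intervals=intervals))
    return out


def type_series_ranges(include_grahamii: bool = True) -> list[TypeSeriesRange]:
    """Type-series envelopes as :class:`TypeSeriesRange` objects."""
    series = ["robusta", "nigra", "intermedia"] + (
        ["grahamii"] if include_grahamii else []
    )
    return _wide_to_ranges(load_type_series_table(), series)


def fresh_material_ranges() -> list[TypeSeriesRange]:
    """Fresh-material envelopes as :class:`TypeSeriesRange` objects."""
    return _wide_to_ranges(
        load_fresh_material_table(), ["robusta", "nigra", "intermedia"]
    )


def assignment_results() -> list[AssignmentResult]:
    """The published per-specimen assignment proportions as result objects."""
    table = load_assignment_proportions()
    results = []
    for specimen in table.columns:
        results.append(
            AssignmentResult(
                specimen_id=str(specimen),
                proportions={
                    s: float(table.loc[s, specimen])
                    for s in table.index
                    if s != "unclassified"
                },
                unclassified=float(table.loc["unclassified", specimen]),
                n_variables=22,
            )
        )
    return results
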