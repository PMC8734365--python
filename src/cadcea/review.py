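"""Curated literature-review table of CMR-for-CAD cost-effectiveness studies.

The packaged CSV transcribes a 15-study review: per study the setting(s),
the comparators evaluated against CMR, the authors' conclusion on CMR value,
the outcome metric (cost-per-QALY/life-year versus other economic metrics),
the analytic perspective, the time horizon category, and the reported key
drivers of results.  ``summarize`` reproduces the review tabulations —
counts and integer percentages per attribute level, with an optional record
filter (e.g. restricting to cost-per-QALY/life-year studies).

Transcription notes: the source table's comparator rows contain two
duplicated citations under SPECT (kept once each, so that row tallies 10
unique studies) and one study listed under two perspectives (transcribed
under the more specific "hospital" level); a set-valued attribute
(settings, comparators, key_drivers) can therefore tally to more than the
number of studies, while single-valued attributes always sum to the
filtered total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = ["StudyRecord", "load_review_table", "summarize"]

SET_ATTRIBUTES = ("settings", "comparators", "key_drivers")
SINGLE_ATTRIBUTES = ("conclusion", "outcome_metric", "perspective", "time_horizon")


@dataclass(frozen=True)
class StudyRecord:
    """One study row of the curated review table."""

    citation_key: str
    reference: int
    settings: frozenset[str]
    comparators: frozenset[str]
    conclusion: str
    outcome_metric: str
    perspective: str
    time_horizon: str
    key_drivers: frozenset[str]


def _split(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def load_review_table() -> list[StudyRecord]:
    """Load the packaged 15-study transcription."""
    ref = resources.files("cadcea").joinpath("data", "cmr_cad_cea_studies.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    records = [
        StudyRecord(
            citation_key=row.citation_key,
            reference=int(row.reference),
            settings=_split(row.settings),
            comparators=_split(row.comparators),
            conclusion=row.conclusion,
            outcome_metric=row.outcome_metric,
            perspective=row.perspective,
            time_horizon=row.time_horizon,
            key_drivers=_split(row.key_drivers),
        )
        for row in df.itertuples(index=False)
    ]
    keys = [r.citation_key for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate citation keys in review table")
    return records


def summarize(records: Sequence[StudyRecord],
              where: Callable[[StudyRecord], bool] | None = None) -> pd.DataFrame:
    """Counts and integer percentages per attribute level after filtering.

    Percentages are 100 × count / filtered total, rounded to the nearest
    integer.  An empty filter result yields zero counts and 0% with a
    warning.  Levels of set-valued attributes may sum to more than the
    filtered total because one study can carry several values.
    """
    if not records:
        raise ValueError("no records to summarize")
    kept = [r for r in records if where is None or where(r)]
    total = len(kept)
    if total == 0:
        warnings.warn("filter matched no records; percentages reported as 0",
                      stacklevel=2)

    def levels(values: Iterable[str]) -> list[str]:
        return sorted(set(values))

    rows = []
    for attr in SINGLE_ATTRIBUTES:
        for level in levels(getattr(r, attr) for r in records):
            count = sum(1 for r in kept if getattr(r, attr) == level)
            rows.append((attr, level, count))
    for attr in SET_ATTRIBUTES:
        all_levels = set()
        for r in records:
            all_levels |= getattr(r, attr)
        for level in levels(all_levels):
            count = sum(1 for r in kept if level in getattr(r, attr))
            rows.append((attr, level, count))
    return pd.DataFrame(
        [{"attribute": a, "level": lv, "count": c,
          "percentage": round(100.0 * c / total) if total else 0}
         for a, lv, c in rows]
    )
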