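"""TerritorialPanel: yearly per-TU observations of population and flow totals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constraints import MacroState, Ordering, TUYearRecord
from .exceptions import PanelError
from .maxent_core import ProbabilityVector

PANEL_COLUMNS = [
    "year",
    "tu_id",
    "tu_name",
    "population",
    "students",
    "electricity_kwh",
    "water_m3",
]

_NUMERIC = ["population", "students", "electricity_kwh", "water_m3"]


@dataclass(frozen=True)
class TerritorialPanel:
    """A validated long-format table, one row per (year, territorial unit).

    Columns: year, tu_id, tu_name, population (inhabitants), students,
    electricity_kwh, water_m3.  Rows are kept sorted by (year, tu_id) and the
    key must be unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"panel is missing columns {missing}")
        df = df[PANEL_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["tu_id"] = df["tu_id"].astype(str)
        df["tu_name"] = df["tu_name"].astype(str)
        for c in _NUMERIC:
            df[c] = pd.to_numeric(df[c], errors="raise")
        dup = df.duplicated(subset=["year", "tu_id"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise PanelError(f"duplicate (year, tu_id) keys at rows {rows}")
        if (df["population"] <= 0).any():
            bad = df.index[df["population"] <= 0].tolist()[:5]
            raise PanelError(f"non-positive population at rows {bad}")
        neg = df[_NUMERIC[1:]].lt(0).any(axis=1)
        if neg.any():
            raise PanelError(f"negative flow totals at rows {df.index[neg].tolist()[:5]}")
        df = df.sort_values(["year", "tu_id"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    # -- basic accessors ---------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    @property
    def tu_ids(self) -> list[str]:
        return sorted(self.df["tu_id"].unique().tolist())

    @property
    def n_tu(self) -> int:
        return len(self.tu_ids)

    def year_frame(self, year: int) -> pd.DataFrame:
        sub = self.df[self.df["year"] == year]
        if sub.empty:
            raise PanelError(f"panel has no rows for year {year}")
        if set(sub["tu_id"]) != set(self.tu_ids):
            missing = sorted(set(self.tu_ids) - set(sub["tu_id"]))
            raise PanelError(f"year {year} is missing TUs {missing}")
        return sub.set_index("tu_id")

    def records(self, year: int) -> list[TUYearRecord]:
        sub = self.year_frame(year)
        return [
            TUYearRecord(
                tu_id=t,
                year=year,
                b=float(row["population"]),
                u=float(row["students"]),
                ce=float(row["electricity_kwh"]),
                cw=float(row["water_m3"]),
            )
            for t, row in sub.iterrows()
        ]

    def macro(self, year: int) -> MacroState:
        return MacroState.from_records(self.records(year))

    def populations(self, year: int) -> dict[str, float]:
        return self.year_frame(year)["population"].to_dict()

    def shares(self, year: int, ordering: Ordering | None = None) -> ProbabilityVector:
        """Observed population shares, optionally re-expressed in an ordering.

        With an ordering, entry ``i`` of the result is the share of the unit
        at index ``i + 1``; ``tu_index`` records ``1..N``.
        """
        sub = self.year_frame(year)
        b = sub["population"].to_numpy(dtype=float)
        p = b / b.sum()
        if ordering is None:
            return ProbabilityVector(p)
        pos = ordering.indices_for(list(sub.index)) - 1
        out = np.empty_like(p)
        out[pos] = p
        return ProbabilityVector(out)

    def rates(self, year: int, ordering: Ordering | None = None) -> dict[str, np.ndarray]:
        """Per-capita rates alpha, epsilon, w per TU (index order if given)."""
        sub = self.year_frame(year)
        b = sub["population"].to_numpy(dtype=float)
        out = {
            "students": sub["students"].to_numpy(dtype=float) / b,
            "electricity": sub["electricity_kwh"].to_numpy(dtype=float) / b,
            "water": sub["water_m3"].to_numpy(dtype=float) / b,
        }
        if ordering is not None:
            pos = ordering.indices_for(list(sub.index)) - 1
            for k, v in out.items():
                arr = np.empty_like(v)
                arr[pos] = v
                out[k] = arr
        return out

    def totals_matrix(self, years: list[int], column: str) -> pd.DataFrame:
        """Years x TU matrix of one numeric column (for trend regressions)."""
        sub = self.df[self.df["year"].isin(years)]
        return sub.pivot(index="year", columns="tu_id", values=column)
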