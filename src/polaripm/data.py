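"""Tabular data containers and delimited-text readers/writers.

Four primary data types feed the integrated model: state-specific capture
counts, age-one litter-size counts, dependent/independent age-two counts, and
individual capture/telemetry histories.  All readers validate invariants and
report row-level errors naming the offending id/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import parse_event
from .exceptions import InvalidInputError
from .lifecycle import FEMALE, MALE, FEMALE_STATES, MALE_STATES

__all__ = ["CountData", "CaptureData"]

_COUNTABLE_STATES = [f"F:{s}" for s in FEMALE_STATES.states[:-1]] + [
    f"M:{s}" for s in MALE_STATES.states[:-1]
]


@dataclass
class CountData:
    """Annual count data keyed by calendar year.

    ``state_counts``: captures per state (columns like ``F:AFNC_in``,
    ``M:AM_in``); ``litter_counts``: numbers of age-one litters of size 1-3
    (columns 1, 2, 3); ``c2_counts``: columns ``n_c2`` (all observed
    two-year-olds) and ``n_wean_c2`` (the independent ones).
    ``sampled``: boolean Series, False in years with no fieldwork.
    """

    years: np.ndarray
    sampled: pd.Series
    state_counts: pd.DataFrame
    litter_counts: pd.DataFrame
    c2_counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for df in (self.state_counts, self.litter_counts, self.c2_counts):
            missing = set(self.years) - set(df.index)
            if missing:
                raise InvalidInputError(f"count table missing years {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        for name, df in (
            ("state_counts", self.state_counts),
            ("litter_counts", self.litter_counts),
            ("c2_counts", self.c2_counts),
        ):
            if (df.to_numpy() < 0).any():
                raise InvalidInputError(f"{name}: negative counts")
        bad = self.c2_counts["n_wean_c2"] > self.c2_counts["n_c2"]
        if bad.any():
            raise InvalidInputError(
                f"c2_counts: n_wean_c2 > n_c2 in years {list(self.c2_counts.index[bad])}"
            )
        for year in self.years:
            if not self.sampled.loc[year]:
                tot = (
                    self.state_counts.loc[year].sum()
                    + self.litter_counts.loc[year].sum()
                    + self.c2_counts.loc[year].sum()
                )
                if tot != 0:
                    raise InvalidInputError(
                        f"year {year}: nonzero counts in a non-sampling year"
                    )

    @classmethod
    def empty(cls, years, sampled=None) -> "CountData":
        years = np.asarray(years, dtype=int)
        if sampled is None:
            sampled = pd.Series(True, index=years)
        else:
            sampled = pd.Series(np.asarray(sampled, dtype=bool), index=years)
        return cls(
            years=years,
            sampled=sampled,
            state_counts=pd.DataFrame(0, index=years, columns=_COUNTABLE_STATES),
            litter_counts=pd.DataFrame(0, index=years, columns=[1, 2, 3]),
            c2_counts=pd.DataFrame(0, index=years, columns=["n_c2", "n_wean_c2"]),
        )

    # ---- delimited text round trip -------------------------------------
    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = self.state_counts.stack()
        pd.DataFrame(
            {"year": rows.index.get_level_values(0),
             "state": rows.index.get_level_values(1),
             "count": rows.to_numpy()}
        ).to_csv(directory / "counts_states.csv", index=False)
        rows = self.litter_counts.stack()
        pd.DataFrame(
            {"year": rows.index.get_level_values(0),
             "size": rows.index.get_level_values(1),
             "count": rows.to_numpy()}
        ).to_csv(directory / "counts_litters.csv", index=False)
        c2 = self.c2_counts.reset_index(names="year")
        c2.to_csv(directory / "counts_c2.csv", index=False)
        pd.DataFrame(
            {"year": self.years, "sampled": self.sampled.loc[self.years].astype(int)}
        ).to_csv(directory / "sampling_years.csv", index=False)

    @classmethod
    def read(cls, directory) -> "CountData":
        directory = Path(directory)
        sy = pd.read_csv(directory / "sampling_years.csv")
        years = sy["year"].to_numpy(dtype=int)
        sampled = pd.Series(sy["sampled"].astype(bool).to_numpy(), index=years)
        sc = pd.read_csv(directory / "counts_states.csv")
        bad = ~sc["state"].isin(_COUNTABLE_STATES)
        if bad.any():
            raise InvalidInputError(
                f"counts_states.csv: unknown states {sorted(set(sc['state'][bad]))}"
            )
        state_counts = (
            sc.pivot(index="year", columns="state", values="count")
            .reindex(index=years, columns=_COUNTABLE_STATES)
            .fillna(0)
            .astype(int)
            .rename_axis(index=None, columns=None)
        )
        lc = pd.read_csv(directory / "counts_litters.csv")
        litter_counts = (
            lc.pivot(index="year", columns="size", values="count")
            .reindex(index=years, columns=[1, 2, 3])
            .fillna(0)
            .astype(int)
            .rename_axis(index=None, columns=None)
        )
        c2 = pd.read_csv(directory / "counts_c2.csv").set_index("year")
        c2 = (c2.reindex(years).fillna(0).astype(int)[["n_c2", "n_wean_c2"]]
              .rename_axis(index=None))
        return cls(years=years, sampled=sampled, state_counts=state_counts,
                   litter_counts=litter_counts, c2_counts=c2)


@dataclass
class CaptureData:
    """Individual capture/telemetry histories, one row per individual-year.

    Columns: ``id``, ``sex`` ("female"/"male"), ``year`` (integer year index
    or calendar year; interpretation is the caller's), ``event_code`` and
    ``collar_active`` (0/1; always 0 for males).
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("id", "sex", "year", "event_code", "collar_active")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"capture table missing columns {sorted(missing)}")
        self.table = self.table[list(self.COLUMNS)].copy()
        self.table["year"] = self.table["year"].astype(int)
        self.table["collar_active"] = self.table["collar_active"].astype(int)
        self.validate()

    def validate(self) -> None:
        spaces = {FEMALE: FEMALE_STATES, MALE: MALE_STATES}
        errors = []
        for (ind, sex), hist in self.table.groupby(["id", "sex"], sort=False):
            space = spaces.get(sex)
            if space is None:
                errors.append(f"id {ind!r}: unknown sex {sex!r}")
                continue
            hist = hist.sort_values("year")
            first = hist.iloc[0]
            if not str(first["event_code"]).startswith("C:"):
                errors.append(
                    f"id {ind!r} year {first['year']}: first event "
                    f"{first['event_code']!r} is not a physical capture"
                )
            for _, row in hist.iterrows():
                code = str(row["event_code"])
                try:
                    parse_event(code, space)
                except InvalidInputError as exc:
                    errors.append(f"id {ind!r} year {row['year']}: {exc}")
                    continue
                if sex == MALE and row["collar_active"]:
                    errors.append(f"id {ind!r} year {row['year']}: collared male")
                if code.startswith("T") and not row["collar_active"]:
                    errors.append(
                        f"id {ind!r} year {row['year']}: telemetry event "
                        "without an active collar"
                    )
        if errors:
            raise InvalidInputError("; ".join(errors))

    @property
    def n_individuals(self) -> int:
        return self.table["id"].nunique()

    @classmethod
    def empty(cls) -> "CaptureData":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "CaptureData":
        return cls(pd.read_csv(path))
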