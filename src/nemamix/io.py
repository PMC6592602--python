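"""CSV schemas shared by the endpoint pipeline and the simulator.

All tables are plain UTF-8 CSV with a header row and '.' decimals;
missing values are empty fields. Schemas:

- counts:    treatment, replicate, day, counted_n
- schedule:  treatment, time_h, split_divisor
- lengths:   treatment, replicate, day, length_mm
- mortality: treatment, replicate, time_h, n_start, n_alive
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .endpoints import DilutionSchedule, MortalityRecord, PopulationSeries

__all__ = [
    "read_counts",
    "write_counts",
    "read_schedules",
    "write_schedules",
    "read_lengths",
    "read_mortality",
    "write_mortality",
    "series_from_tables",
]


def _require(df: pd.DataFrame, columns: set[str], what: str) -> None:
    missing = columns - set(df.columns)
    if missing:
        raise ValueError(f"{what} CSV missing columns: {sorted(missing)}")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, {"treatment", "replicate", "day", "counted_n"}, "counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_schedules(path) -> dict[str, DilutionSchedule]:
    df = pd.read_csv(path)
    _require(df, {"treatment", "time_h", "split_divisor"}, "schedule")
    schedules: dict[str, DilutionSchedule] = {}
    for treatment, grp in df.groupby("treatment", sort=False):
        grp = grp.sort_values("time_h")
        schedules[str(treatment)] = DilutionSchedule(
            tuple(
                (float(r.time_h), int(r.split_divisor)) for r in grp.itertuples()
            )
        )
    return schedules


def write_schedules(schedules: dict[str, DilutionSchedule], path) -> None:
    rows = [
        {"treatment": treatment, "time_h": t, "split_divisor": d}
        for treatment, schedule in schedules.items()
        for t, d in schedule.events
    ]
    pd.DataFrame(rows, columns=["treatment", "time_h", "split_divisor"]).to_csv(
        path, index=False
    )


def read_lengths(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, {"treatment", "replicate", "day", "length_mm"}, "lengths")
    return df


def read_mortality(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, {"treatment", "replicate", "time_h", "n_start", "n_alive"}, "mortality")
    return df


def write_mortality(records: Sequence[MortalityRecord], path) -> None:
    rows = [
        {
            "treatment": r.treatment,
            "replicate": r.replicate,
            "time_h": r.time_h,
            "n_start": r.n_start,
            "n_alive": r.n_alive,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["treatment", "replicate", "time_h", "n_start", "n_alive"]
    ).to_csv(path, index=False)


def series_from_tables(
    counts: pd.DataFrame, schedules: dict[str, DilutionSchedule]
) -> list[PopulationSeries]:
    """Assemble PopulationSeries objects from a counts table and schedules.

    Treatments without a schedule row get an empty (no-dilution) schedule.
    """
    series = []
    for (treatment, replicate), grp in counts.groupby(
        ["treatment", "replicate"], sort=False
    ):
        grp = grp.sort_values("day")
        series.append(
            PopulationSeries(
                treatment=str(treatment),
                replicate=replicate,
                days=tuple(float(d) for d in grp["day"]),
                counted_n=tuple(int(n) for n in grp["counted_n"]),
                schedule=schedules.get(str(treatment), DilutionSchedule()),
            )
        )
    return series
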