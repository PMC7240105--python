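"""Canonical plate-layout and measurement I/O.

The package works from two tidy CSV contracts that deliberately hide
instrument-specific export formats:

* layout CSV — ``plate_id,well_id,role,strain,condition,mutant_channel``,
  one row per well. ``role`` assigns each well to the competitive-aging
  design: ``mutant_competition`` (deletion strain co-cultured with the
  wild-type reference), ``reference_competition`` (the two wild-type
  strains, one per fluorophore), ``rfp_monoculture`` / ``cfp_monoculture``
  (single-fluorophore autofluorescence controls) or ``blank``.
* measurements CSV — ``plate_id,well_id,day,hour,od600,rfp,cfp``, one row
  per plate-reader read: stationary-phase age ``day`` (T_i), outgrowth time
  ``hour`` (t_j), culture density and the two raw fluorescence channels.

Well names use the common letter-row + unpadded-column convention
("A1".."H12", never "A01"). Days and hours are real-valued; sampling
schedules are irregular in practice and no integer grid is assumed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ROLES",
    "CHANNELS",
    "PlateLayout",
    "LayoutError",
    "MeasurementError",
    "read_layout",
    "read_measurements",
    "write_measurements",
    "write_layout",
]

ROLES = (
    "mutant_competition",
    "reference_competition",
    "rfp_monoculture",
    "cfp_monoculture",
    "blank",
)
COMPETITION_ROLES = ("mutant_competition", "reference_competition")
CHANNELS = ("RFP", "CFP")

LAYOUT_COLUMNS = ["plate_id", "well_id", "role", "strain", "condition", "mutant_channel"]
MEASUREMENT_COLUMNS = ["plate_id", "well_id", "day", "hour", "od600", "rfp", "cfp"]

#: fixed decimal format used when writing measurement tables; round-trips
#: through text exactly for values representable at this precision.
FLOAT_FORMAT = "%.10g"

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class LayoutError(ValueError):
    """Structural problem in a plate-layout table."""


class MeasurementError(ValueError):
    """Structural problem in a measurement table."""


@dataclass
class PlateLayout:
    """Role/strain/condition assignment of every well on one plate.

    ``entries`` is a DataFrame with the layout CSV columns, one row per
    well, validated on construction.
    """

    plate_id: str
    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in LAYOUT_COLUMNS if c not in self.entries.columns]
        if missing:
            raise LayoutError(f"layout missing required column(s): {', '.join(missing)}")
        ent = self.entries.reset_index(drop=True)
        dup = ent["well_id"][ent["well_id"].duplicated()].unique()
        if len(dup):
            raise LayoutError(f"duplicate well_id in layout: {', '.join(map(str, dup))}")
        bad_role = sorted(set(ent["role"]) - set(ROLES))
        if bad_role:
            raise LayoutError(
                f"unknown role(s) {bad_role}; allowed roles are {list(ROLES)}"
            )
        bad_chan = sorted(set(ent["mutant_channel"]) - set(CHANNELS))
        if bad_chan:
            raise LayoutError(
                f"unknown mutant_channel value(s) {bad_chan}; allowed: {list(CHANNELS)}"
            )
        bad_wells = [w for w in ent["well_id"] if not _WELL_RE.match(str(w))]
        if bad_wells:
            raise LayoutError(
                f"malformed well id(s) {bad_wells}; expected letter A-H + column 1-12 "
                "without zero padding (e.g. 'A1', 'H12')"
            )
        self.entries = ent

    def wells(self, role: str | None = None) -> list[str]:
        """Well ids, optionally restricted to one role, in plate order."""
        ent = self.entries
        if role is not None:
            if role not in ROLES:
                raise LayoutError(f"unknown role {role!r}; allowed roles are {list(ROLES)}")
            ent = ent[ent["role"] == role]
        return list(ent["well_id"])

    @property
    def reference_wells(self) -> list[str]:
        return self.wells("reference_competition")

    @property
    def mutant_wells(self) -> list[str]:
        return self.wells("mutant_competition")

    @property
    def competition_wells(self) -> list[str]:
        ent = self.entries
        return list(ent.loc[ent["role"].isin(COMPETITION_ROLES), "well_id"])

    def role_of(self, well_id: str) -> str:
        row = self.entries[self.entries["well_id"] == well_id]
        if row.empty:
            raise LayoutError(f"well {well_id!r} not present in layout {self.plate_id!r}")
        return row["role"].iloc[0]

    def mutant_channel_of(self, well_id: str) -> str:
        row = self.entries[self.entries["well_id"] == well_id]
        if row.empty:
            raise LayoutError(f"well {well_id!r} not present in layout {self.plate_id!r}")
        return row["mutant_channel"].iloc[0]

    def strain_of(self, well_id: str) -> str:
        row = self.entries[self.entries["well_id"] == well_id]
        if row.empty:
            raise LayoutError(f"well {well_id!r} not present in layout {self.plate_id!r}")
        return row["strain"].iloc[0]


def read_layout(path) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    Raises :class:`LayoutError` on duplicate wells, unknown roles or
    channels, malformed well ids, a missing column, or multiple plates in
    one file.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(
            f"layout file {path} missing required column(s): {', '.join(missing)}"
        )
    plates = df["plate_id"].unique()
    if len(plates) != 1:
        raise LayoutError(
            f"layout file {path} must describe exactly one plate, found {list(plates)}"
        )
    return PlateLayout(plate_id=str(plates[0]), entries=df[LAYOUT_COLUMNS])


def write_layout(layout: PlateLayout, path) -> None:
    layout.entries.to_csv(path, index=False)


def read_measurements(path, layout: PlateLayout) -> pd.DataFrame:
    """Read a measurement CSV and validate it against ``layout``.

    Returns a DataFrame with :data:`MEASUREMENT_COLUMNS`, sorted by
    (well_id, day, hour). Raises :class:`MeasurementError` on wells absent
    from the layout, non-numeric or negative signals, or duplicate
    (well, day, hour) rows.
    """
    raw = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise MeasurementError(
            f"measurement file {path} missing required column(s): {', '.join(missing)}"
        )
    df = raw[MEASUREMENT_COLUMNS].copy()
    for col in ("day", "hour", "od600", "rfp", "cfp"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise MeasurementError(
                f"non-numeric value {df.loc[bad.idxmax(), col]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        if num.isna().any():
            row = int(num.isna().idxmax()) + 2
            raise MeasurementError(f"missing value in column {col!r} at line {row} of {path}")
        df[col] = num.astype(float)
    return validate_measurements(df, layout)


def validate_measurements(df: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Validate an in-memory measurement table (shared by readers and the
    simulator) and return it sorted by (well_id, day, hour)."""
    unknown = sorted(set(df["well_id"]) - set(layout.wells()))
    if unknown:
        raise MeasurementError(
            f"measurement well(s) absent from layout {layout.plate_id!r}: "
            f"{', '.join(unknown)}"
        )
    foreign = sorted(set(df["plate_id"].astype(str)) - {layout.plate_id})
    if foreign:
        raise MeasurementError(
            f"measurements reference plate(s) {foreign} but layout is {layout.plate_id!r}"
        )
    for col in ("day", "hour", "od600", "rfp", "cfp"):
        neg = df[col] < 0
        if neg.any():
            i = neg.idxmax()
            raise MeasurementError(
                f"negative {col} value {df.loc[i, col]} for well "
                f"{df.loc[i, 'well_id']} (day {df.loc[i, 'day']}, hour {df.loc[i, 'hour']})"
            )
    keys = df[["plate_id", "well_id", "day", "hour"]]
    dup = keys.duplicated()
    if dup.any():
        i = dup.idxmax()
        raise MeasurementError(
            f"duplicate measurement for well {df.loc[i, 'well_id']} at "
            f"day {df.loc[i, 'day']}, hour {df.loc[i, 'hour']}"
        )
    return df.sort_values(["well_id", "day", "hour"], kind="stable").reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table in the canonical fixed decimal format."""
    out = df[MEASUREMENT_COLUMNS]
    if isinstance(path, io.TextIOBase):
        out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    else:
        with open(path, "w", newline="") as fh:
            out.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
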