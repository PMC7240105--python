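"""Autofluorescence background subtraction and log-ratio construction.

Raw RFP and CFP readings contain an autofluorescence component produced by
the cells themselves and the medium. It is measured directly on the plate:
the RFP reading of a CFP-only monoculture well is pure RFP background, and
vice versa. Backgrounds are estimated per (plate, day, hour) read — they
scale with culture density, which changes over the outgrowth — as the mean
across the control wells present at that read.

The quantity the competitive model fits is the background-corrected log
signal ratio y = ln((RFP − rfp_bg)/(CFP − cfp_bg)) of each competition
well at each read. A point is usable only when both corrected signals are
strictly positive and exceed ``min_signal_factor`` times their background
estimate; points failing the rule are kept with a reason string (invalidity
is data, not an error). Wells with too few valid points, or valid points on
fewer than two distinct days, cannot constrain a survivorship slope and are
excluded from fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import COMPETITION_ROLES, PlateLayout

__all__ = [
    "BackgroundModel",
    "estimate_background",
    "compute_log_ratios",
    "filter_fittable_wells",
]


@dataclass
class BackgroundModel:
    """Per-read channel backgrounds for one plate.

    ``table`` columns: day, hour, rfp_bg, cfp_bg, n_rfp_controls,
    n_cfp_controls. ``rfp_bg`` at a read is the mean RFP of the CFP-only
    monoculture wells (and symmetrically for ``cfp_bg``); the counts record
    how many control wells contributed.
    """

    plate_id: str
    table: pd.DataFrame = field(repr=False)

    def lookup(self, day: float, hour: float) -> tuple[float, float]:
        t = self.table
        row = t[(t["day"] == day) & (t["hour"] == hour)]
        if row.empty:
            raise KeyError(
                f"no background estimate for plate {self.plate_id!r} at "
                f"day={day}, hour={hour}"
            )
        return float(row["rfp_bg"].iloc[0]), float(row["cfp_bg"].iloc[0])


def estimate_background(
    measurements: pd.DataFrame,
    layout: PlateLayout,
    *,
    fallback_zero: bool = False,
) -> BackgroundModel:
    """Estimate per-read RFP/CFP backgrounds from monoculture controls.

    RFP background comes from ``cfp_monoculture`` wells (their RFP signal
    is autofluorescence only) and CFP background from ``rfp_monoculture``
    wells. If a channel has no control wells, ``fallback_zero=True``
    substitutes a zero background with a warning; otherwise it is an error.
    """
    cfp_only = set(layout.wells("cfp_monoculture"))
    rfp_only = set(layout.wells("rfp_monoculture"))
    reads = measurements[["day", "hour"]].drop_duplicates().sort_values(["day", "hour"])

    def _channel_bg(control_wells: set[str], signal_col: str) -> pd.DataFrame:
        name = f"{signal_col}_bg"
        ncol = f"n_{signal_col}_controls"
        if not control_wells:
            if not fallback_zero:
                raise ValueError(
                    f"no monoculture control wells available to estimate the "
                    f"{signal_col.upper()} background on plate {layout.plate_id!r}; "
                    "pass fallback_zero=True to proceed with zero background"
                )
            warnings.warn(
                f"plate {layout.plate_id!r}: no {signal_col.upper()}-background "
                "control wells; assuming zero background",
                stacklevel=3,
            )
            out = reads.copy()
            out[name] = 0.0
            out[ncol] = 0
            return out
        sub = measurements[measurements["well_id"].isin(control_wells)]
        grp = sub.groupby(["day", "hour"], as_index=False).agg(
            **{name: (signal_col, "mean"), ncol: (signal_col, "size")}
        )
        out = reads.merge(grp, on=["day", "hour"], how="left")
        if out[name].isna().any():
            # a read where every control well is missing: treat as zero
            gaps = out[out[name].isna()][["day", "hour"]].values.tolist()
            warnings.warn(
                f"plate {layout.plate_id!r}: no {signal_col.upper()}-background "
                f"control reads at {gaps}; assuming zero background there",
                stacklevel=3,
            )
            out[name] = out[name].fillna(0.0)
            out[ncol] = out[ncol].fillna(0)
        out[ncol] = out[ncol].astype(int)
        return out

    rfp_tab = _channel_bg(cfp_only, "rfp")
    cfp_tab = _channel_bg(rfp_only, "cfp")
    table = rfp_tab.merge(cfp_tab, on=["day", "hour"]).reset_index(drop=True)
    return BackgroundModel(plate_id=layout.plate_id, table=table)


def compute_log_ratios(
    measurements: pd.DataFrame,
    background: BackgroundModel,
    layout: PlateLayout,
    *,
    min_signal_factor: float = 1.0,
) -> pd.DataFrame:
    """Background-corrected ln(RFP/CFP) for every competition-well read.

    Returns a DataFrame with columns well_id, day, hour, y, valid,
    reason_invalid. Validity requires corrected RFP >
    ``min_signal_factor``·rfp_bg and likewise for CFP; when a background is
    zero the corrected signal need only be strictly positive.
    """
    comp_wells = set(layout.competition_wells)
    sub = measurements[measurements["well_id"].isin(comp_wells)].copy()
    sub = sub.merge(background.table[["day", "hour", "rfp_bg", "cfp_bg"]], on=["day", "hour"], how="left")
    if sub["rfp_bg"].isna().any():
        gaps = sub.loc[sub["rfp_bg"].isna(), ["day", "hour"]].drop_duplicates().values.tolist()
        raise ValueError(f"background undefined for read(s) {gaps}")

    rfp_c = sub["rfp"] - sub["rfp_bg"]
    cfp_c = sub["cfp"] - sub["cfp_bg"]

    reasons = np.full(len(sub), "", dtype=object)
    reasons[(cfp_c <= 0).to_numpy()] = "nonpositive corrected CFP"
    reasons[(rfp_c <= 0).to_numpy()] = "nonpositive corrected RFP"
    both_np = ((rfp_c <= 0) & (cfp_c <= 0)).to_numpy()
    reasons[both_np] = "nonpositive corrected RFP and CFP"
    below = (
        (rfp_c > 0)
        & (cfp_c > 0)
        & ((rfp_c <= min_signal_factor * sub["rfp_bg"]) | (cfp_c <= min_signal_factor * sub["cfp_bg"]))
    ).to_numpy()
    reasons[below] = "below signal threshold"
    valid = reasons == ""

    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(rfp_c.to_numpy() / cfp_c.to_numpy())
    y = np.where(valid, y, np.nan)

    out = pd.DataFrame(
        {
            "well_id": sub["well_id"].to_numpy(),
            "day": sub["day"].to_numpy(),
            "hour": sub["hour"].to_numpy(),
            "y": y,
            "valid": valid,
            "reason_invalid": reasons,
        }
    )
    return out.sort_values(["well_id", "day", "hour"], kind="stable").reset_index(drop=True)


def filter_fittable_wells(
    points: pd.DataFrame,
    *,
    min_points: int = 3,
    min_days: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop wells whose valid points cannot constrain a slope in day.

    A well stays only if it has at least ``min_points`` valid points
    spanning at least ``min_days`` distinct days. Returns (valid points of
    retained wells, list of excluded well ids).
    """
    valid = points[points["valid"]]
    keep: list[str] = []
    excluded: list[str] = []
    for well, grp in valid.groupby("well_id", sort=False):
        if len(grp) >= min_points and grp["day"].nunique() >= min_days:
            keep.append(well)
        else:
            excluded.append(well)
    return valid[valid["well_id"].isin(keep)].reset_index(drop=True), excluded
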