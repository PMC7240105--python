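"""Viability curves, death rates and half-lives from outgrowth kinetics.

The classical single-culture comparison method: a stationary-phase culture
sampled at age T days is inoculated into fresh medium and its OD600 is
followed through the outgrowth. Fewer viable cells in the inoculum delay
the curve; the delay Δt_n (hours) to reach a fixed density OD600 = 0.35,
relative to the first sampling day, converts to percent viability through
the doubling time δ:

    V_T = 100 * 2^(-Δt_n / δ)

— one extra doubling time of delay means half the viable inoculum. Death
rate r (per day) comes from fitting V_T = V0 * exp(-r T) over stationary-
phase days, and half-life is HL = ln(2)/r.

δ is estimated once, on the first sampling day's series, as ln(2) divided
by the slope of ln(OD600) vs hours restricted to an exponential window
(OD600 in [0.05, 0.30] by default, below the crossing threshold so the two
quantities stay independent).

All series here are blank-subtracted OD600 (the OD at outgrowth
inoculation removed); early reads may therefore be <= 0 and are simply
below any positive threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .plate_io import PlateLayout

__all__ = [
    "ViabilityCurve",
    "NoCrossingError",
    "time_to_threshold",
    "doubling_time",
    "viability_curve",
    "fit_decay",
    "estimate_r_wt",
]

DEFAULT_THRESHOLD = 0.35
DEFAULT_DELTA_WINDOW = (0.05, 0.30)


class NoCrossingError(ValueError):
    """The outgrowth series never reaches the threshold density."""


@dataclass
class ViabilityCurve:
    """Percent-viability curve of one well with its decay fit.

    ``points`` columns: day, crossing_hour, delta_t, viability (percent).
    ``delta`` is the doubling time in hours; ``r`` the exponential decay
    rate per day; ``half_life`` = ln(2)/r days (+inf when r <= 0).
    """

    well_id: str
    points: pd.DataFrame = field(repr=False)
    delta: float = float("nan")
    r: float = float("nan")
    v0: float = float("nan")
    half_life: float = float("nan")
    rss: float = float("nan")
    dropped_days: list[float] = field(default_factory=list)


def time_to_threshold(hours, od600, threshold: float = DEFAULT_THRESHOLD,
                      *, log_interpolation: bool = False) -> float:
    """Hour at which the series first reaches ``threshold``.

    Linear interpolation between the last sub-threshold and the first
    supra-threshold read (in OD by default, in ln OD with
    ``log_interpolation=True``). Raises :class:`NoCrossingError` if the
    series never reaches the threshold and ``ValueError`` if it starts at
    or above it (inoculum too dense to locate a crossing).
    """
    t = np.asarray(hours, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.ndim != 1 or t.shape != od.shape or len(t) < 2:
        raise ValueError("need matched 1-d hour/od600 arrays with >= 2 reads")
    if np.any(np.diff(t) <= 0):
        raise ValueError("hours must be strictly increasing")
    if od[0] >= threshold:
        if od[0] == threshold:
            return float(t[0])
        raise ValueError(
            f"series starts above threshold ({od[0]:.3g} >= {threshold:.3g}); "
            "inoculum too dense"
        )
    above = np.nonzero(od >= threshold)[0]
    if len(above) == 0:
        raise NoCrossingError(
            f"series never reaches OD600 = {threshold:g} (max {od.max():.3g})"
        )
    k = above[0]
    lo, hi = k - 1, k
    if od[hi] == threshold:
        return float(t[hi])
    if log_interpolation:
        if od[lo] <= 0:
            # cannot take a log of a nonpositive read; fall back to linear
            frac = (threshold - od[lo]) / (od[hi] - od[lo])
        else:
            frac = (math.log(threshold) - math.log(od[lo])) / (
                math.log(od[hi]) - math.log(od[lo])
            )
    else:
        frac = (threshold - od[lo]) / (od[hi] - od[lo])
    return float(t[lo] + frac * (t[hi] - t[lo]))


def doubling_time(hours, od600, window: tuple[float, float] = DEFAULT_DELTA_WINDOW) -> float:
    """Doubling time δ (hours) from the exponential stretch of one series.

    Least-squares slope of ln(OD600) vs hours over reads with OD600 inside
    ``window``; δ = ln(2)/slope. Requires >= 3 in-window reads and a
    positive slope.
    """
    t = np.asarray(hours, dtype=float)
    od = np.asarray(od600, dtype=float)
    lo, hi = window
    mask = (od >= lo) & (od <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 reads with OD600 in [{lo:g}, {hi:g}] to estimate the "
            f"doubling time; found {int(mask.sum())}"
        )
    slope = np.polyfit(t[mask], np.log(od[mask]), 1)[0]
    if slope <= 1e-12:
        raise ValueError(f"non-positive growth slope ({slope:.3g}/h) in the δ window")
    return float(math.log(2) / slope)


def viability_curve(
    series: pd.DataFrame,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    delta: float | None = None,
    delta_window: tuple[float, float] = DEFAULT_DELTA_WINDOW,
    log_interpolation: bool = False,
    well_id: str = "",
) -> ViabilityCurve:
    """Per-day percent viability of one well from its outgrowth series.

    ``series`` needs columns day, hour, od600 (blank-subtracted). The
    first sampling day anchors Δt = 0 (V = 100% by construction) and, when
    ``delta`` is not given, provides the doubling-time estimate. Days that
    never cross the threshold are dropped with a warning and recorded in
    ``dropped_days``.
    """
    days = sorted(series["day"].unique())
    if not days:
        raise ValueError("empty outgrowth series")
    first = series[series["day"] == days[0]].sort_values("hour")
    if delta is None:
        delta = doubling_time(first["hour"], first["od600"], window=delta_window)
    t0 = time_to_threshold(first["hour"], first["od600"], threshold,
                           log_interpolation=log_interpolation)

    rows, dropped = [], []
    for d in days:
        sub = series[series["day"] == d].sort_values("hour")
        try:
            tc = time_to_threshold(sub["hour"], sub["od600"], threshold,
                                   log_interpolation=log_interpolation)
        except NoCrossingError:
            warnings.warn(
                f"well {well_id or '?'} day {d:g}: outgrowth never reaches "
                f"OD600 = {threshold:g}; day dropped from the viability curve",
                stacklevel=2,
            )
            dropped.append(float(d))
            continue
        dt = tc - t0
        rows.append(
            {"day": float(d), "crossing_hour": tc, "delta_t": dt,
             "viability": 100.0 * 2.0 ** (-dt / delta)}
        )
    return ViabilityCurve(
        well_id=well_id,
        points=pd.DataFrame(rows),
        delta=float(delta),
        dropped_days=dropped,
    )


def fit_decay(days, viability) -> tuple[float, float, float, float]:
    """Exponential decay fit V_T = V0·exp(−r·T) of a viability curve.

    Returns (r per day, half_life days, V0, rss). V0 is free rather than
    pinned at 100 so first-day noise is absorbed. A non-positive fitted r
    is reported with half_life = +inf. Requires >= 3 points.
    """
    T = np.asarray(days, dtype=float)
    V = np.asarray(viability, dtype=float)
    if len(T) < 3:
        raise ValueError(f"need >= 3 viability points to fit a decay rate, got {len(T)}")

    med = float(np.median(T))
    r0 = math.log(2) / med if med > 0 else 0.1

    def model(t, v0, r):
        return v0 * np.exp(-r * t)

    try:
        popt, _ = curve_fit(model, T, V, p0=(100.0, r0), maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - pathological input
        raise ValueError(f"exponential decay fit did not converge: {err}") from err
    v0, r = float(popt[0]), float(popt[1])
    resid = V - model(T, *popt)
    rss = float(resid @ resid)
    hl = math.log(2) / r if r > 0 else float("inf")
    return r, hl, v0, rss


def fit_viability_curve(curve: ViabilityCurve) -> ViabilityCurve:
    """Attach the exponential decay fit (r, half-life) to a curve."""
    r, hl, v0, rss = fit_decay(curve.points["day"], curve.points["viability"])
    curve.r, curve.half_life, curve.v0, curve.rss = r, hl, v0, rss
    return curve


def subtract_inoculation_background(series: pd.DataFrame) -> pd.DataFrame:
    """Remove the OD600 baseline at outgrowth inoculation, per day.

    The earliest read of each day approximates the OD contributed by the
    inoculum and medium; subtracting it makes day-to-day series comparable.
    """
    out = series.sort_values(["day", "hour"]).copy()
    base = out.groupby("day")["od600"].transform("first")
    out["od600"] = out["od600"] - base
    return out


def estimate_r_wt(
    measurements: pd.DataFrame,
    layout: PlateLayout,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    delta_window: tuple[float, float] = DEFAULT_DELTA_WINDOW,
    log_interpolation: bool = False,
    subtract_background: bool = True,
    wells: list[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Average wild-type death rate r_wt (per day) on one plate.

    By default the OD600 of each reference-competition well is used: both
    subpopulations there are wild type, so the decay of the total culture
    estimates the wild-type death rate. Pass ``wells`` to use dedicated
    wild-type monoculture wells instead. Returns (r_wt, per-well table).
    """
    if wells is None:
        wells = layout.reference_wells
    rows = []
    for w in wells:
        series = measurements.loc[measurements["well_id"] == w, ["day", "hour", "od600"]]
        if series.empty:
            continue
        if subtract_background:
            series = subtract_inoculation_background(series)
        try:
            curve = viability_curve(series, threshold=threshold,
                                    delta_window=delta_window,
                                    log_interpolation=log_interpolation, well_id=w)
            curve = fit_viability_curve(curve)
        except (ValueError, NoCrossingError) as err:
            warnings.warn(f"well {w}: unusable OD600 series for r_wt ({err})", stacklevel=2)
            continue
        rows.append({"well_id": w, "delta": curve.delta, "r": curve.r,
                     "half_life": curve.half_life})
    if not rows:
        raise ValueError(
            f"plate {layout.plate_id!r}: no usable wild-type OD600 series to "
            "estimate r_wt"
        )
    table = pd.DataFrame(rows)
    return float(table["r"].mean()), table
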