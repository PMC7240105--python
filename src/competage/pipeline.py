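"""End-to-end conveniences tying preprocessing to the plate fit."""

from __future__ import annotations

import pandas as pd

from .competitive import CompetitiveFit, fit_plate
from .config import DEFAULTS
from .plate_io import PlateLayout
from .preprocess import compute_log_ratios, estimate_background, filter_fittable_wells

__all__ = ["prepare_points", "fit_from_measurements"]


def prepare_points(
    measurements: pd.DataFrame,
    layout: PlateLayout,
    config: dict | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Background-correct, filter and return fit-ready log-ratio points.

    Returns (valid points of fittable wells, excluded well ids).
    """
    cfg = {**DEFAULTS, **(config or {})}
    background = estimate_background(
        measurements, layout, fallback_zero=cfg["background.fallback_zero"]
    )
    points = compute_log_ratios(
        measurements, background, layout,
        min_signal_factor=cfg["logratio.min_signal_factor"],
    )
    return filter_fittable_wells(
        points, min_points=cfg["logratio.min_points"], min_days=cfg["logratio.min_days"]
    )


def fit_from_measurements(
    measurements: pd.DataFrame,
    layout: PlateLayout,
    config: dict | None = None,
) -> CompetitiveFit:
    """Full path: raw measurement table -> constrained plate fit."""
    cfg = {**DEFAULTS, **(config or {})}
    points, _ = prepare_points(measurements, layout, cfg)
    return fit_plate(points, layout, ci_level=cfg["model.ci_level"])
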