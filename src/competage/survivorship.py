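"""Replicate aggregation, cross-condition rescaling and reference testing.

Relative survivorship S (per day) is bounded above by the wild-type death
rate r_wt of its own condition — a strain cannot lose viability slower
than "not at all" relative to a reference that dies at rate r_wt — which
makes raw S values incomparable between conditions where r_wt differs
(e.g. with and without a lifespan-extending drug). The dimensionless
rescaled survivorship

    rS = -ln(1 - S / r_wt)

removes that ceiling: rS = 0 for a neutral strain, ln 2 when the strain
dies at half the wild-type rate, -ln 2 when it dies twice as fast, and it
diverges as S approaches r_wt, where only semi-quantitative statements
remain possible for extremely long-lived strains.

Mutants are called against the empirical wild-type distribution of S:
since reference wells are pinned at S = 0 by the model, each reference
well is relabeled as a mutant in turn (leave-one-out) and the plate refit,
yielding the spread of S a wild-type well shows under the fitted model;
mutant replicates are then compared to it with a Welch t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .competitive import fit_plate
from .plate_io import PlateLayout

__all__ = [
    "rescale_survivorship",
    "invert_rescaled",
    "aggregate_replicates",
    "test_vs_reference",
    "reference_s_distribution",
    "TestResult",
]


def rescale_survivorship(S: float, r_wt: float, *,
                         clamp: bool = False, eps: float = 1e-3) -> float:
    """Dimensionless rescaled survivorship rS = -ln(1 - S/r_wt).

    Requires r_wt > 0 and S < r_wt. For long-lived strains with S >= r_wt
    the transform is undefined (the saturation limit of the assay); with
    ``clamp=True`` such values are clamped to S = (1-eps)·r_wt instead of
    raising.
    """
    if r_wt <= 0:
        raise ValueError(f"r_wt must be positive, got {r_wt}")
    if S >= r_wt:
        if not clamp:
            raise ValueError(
                f"S = {S:g} >= r_wt = {r_wt:g}: rescaled survivorship is undefined "
                "at the long-lived saturation limit (S ≈ r_wt allows only "
                "semi-quantitative estimates); pass clamp=True to cap at "
                "(1 - eps)·r_wt"
            )
        S = (1.0 - eps) * r_wt
    return -math.log1p(-S / r_wt)


def invert_rescaled(rS: float, r_wt: float) -> float:
    """Inverse transform: S = r_wt·(1 - exp(-rS))."""
    return r_wt * -math.expm1(-rS)


def attach_rescaled(records: pd.DataFrame, r_wt: float, *,
                    clamp: bool = True, eps: float = 1e-3) -> pd.DataFrame:
    """Add rS and r_wt_used columns to a per-well survivorship table."""
    out = records.copy()
    out["r_wt_used"] = r_wt
    out["rS"] = [
        rescale_survivorship(s, r_wt, clamp=clamp, eps=eps) for s in out["S"]
    ]
    out["rS_clamped"] = out["S"] >= r_wt
    return out


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(strain, condition) replicate summaries.

    ``records`` needs columns strain, condition, S and optionally rS. Each
    row is one replicate well. Returns one row per group with n, mean and
    SEM (SEM is NaN for singleton groups), in deterministic
    (strain, condition) order.
    """
    required = {"strain", "condition", "S"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing column(s): {sorted(missing)}")
    out = []
    for (strain, cond), grp in records.groupby(["strain", "condition"], sort=True):
        row = {
            "strain": strain,
            "condition": cond,
            "n_replicates": len(grp),
            "mean_S": float(grp["S"].mean()),
            "sem_S": float(grp["S"].sem()) if len(grp) > 1 else float("nan"),
        }
        if "rS" in grp.columns:
            row["mean_rS"] = float(grp["rS"].mean())
            row["sem_rS"] = float(grp["rS"].sem()) if len(grp) > 1 else float("nan")
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class TestResult:
    p_value: float
    significant: bool | None
    statistic: float = float("nan")
    note: str = ""


def test_vs_reference(mutant_s, reference_s, alpha: float = 0.01,
                      *, equal_var: bool = True) -> TestResult:
    """Two-sample t-test of mutant S replicates vs the wild-type S spread.

    Pooled-variance Student form by default: both groups are wells of the
    same plate measured identically, and with as few as six mutant
    replicates the Welch-Satterthwaite approximation noticeably inflates
    the type-I error (about 1.6% at a nominal 1%) while the pooled test is
    exact under the shared-variance null. ``equal_var=False`` selects
    Welch for callers who suspect genuinely unequal spreads. Fewer than
    two values in either group, or zero variance in both, yields an
    undefined marker instead of a call.
    """
    a = np.asarray(mutant_s, dtype=float)
    b = np.asarray(reference_s, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return TestResult(float("nan"), None, note="insufficient replicates")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult(1.0, False, note="degenerate: identical constant groups")
        return TestResult(float("nan"), None, note="degenerate: zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return TestResult(p, bool(p < alpha), float(res.statistic))


def reference_s_distribution(points: pd.DataFrame, layout: PlateLayout,
                             *, ci_level: float = 0.95) -> pd.Series:
    """Leave-one-out S estimates for every reference well of a plate.

    Each reference well is relabeled mutant_competition in turn and the
    plate refit, so its S is estimated against the remaining references.
    Returns a Series indexed by well id — the empirical wild-type spread
    used by :func:`test_vs_reference`.
    """
    refs = layout.reference_wells
    if len(refs) < 2:
        raise ValueError(
            "need >= 2 reference wells for a leave-one-out wild-type distribution"
        )
    values = {}
    for w in refs:
        entries = layout.entries.copy()
        entries.loc[entries["well_id"] == w, "role"] = "mutant_competition"
        relabeled = PlateLayout(plate_id=layout.plate_id, entries=entries)
        fit = fit_plate(points, relabeled, ci_level=ci_level)
        values[w] = fit.s_of(w)
    return pd.Series(values, name="S")
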