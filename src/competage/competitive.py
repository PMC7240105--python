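"""Plate-wide constrained linear model for relative survivorship.

Each valid log-ratio observation of a competition well w at stationary-phase
day T_i and outgrowth hour t_j is modeled as

    y = A_w + S_w * T_i + G_w * t_j + C_{T_i,t_j}

where A_w is the log initial abundance ratio of the two subpopulations,
S_w (per day) is the death-rate difference between the mutant and the
wild-type reference carried in the same well, G_w (per hour) is their
outgrowth growth-rate difference, and C_{T_i,t_j} is a plate-wide batch
term shared by every well read at that (day, hour) — systematic drift of
the measurement at that sampling point.

Reference competitions (wild type vs wild type) anchor the model: their S
and G are structural zeros, so any coherent drift they show is attributed
to C, and mutant S is measured relative to that baseline. A constant can
trade freely between the A block and the C block; identifiability is fixed
by the single linear constraint sum over observed cells of C = 0, which
makes A_w the well's mean-batch-corrected intercept. Any other single
linear constraint on C yields identical S and G.

The fit is one ordinary-least-squares solve over all observations of the
plate (the constraint is eliminated by reparametrisation), with standard
errors from the OLS covariance and t-based confidence intervals.

Sign conventions: y is always ln(corrected RFP / corrected CFP). The S and
G regressors carry the well's channel orientation (+T_i, +t_j when the
mutant is the RFP subpopulation, negated when it is the CFP one), so a
positive fitted S always means the mutant outlives the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .plate_io import PlateLayout

__all__ = [
    "DesignSystem",
    "CompetitiveFit",
    "build_design",
    "fit_plate",
    "downsample_reference_analysis",
]


@dataclass
class DesignSystem:
    """Observation/parameter structure of one plate fit.

    ``X`` is the full design (one column per parameter in ``param_names``);
    ``constraint`` is the single row vector c with c @ beta = 0 fixing the
    batch block. ``reduction`` maps the constraint-free parametrisation
    back to the full one (beta_full = reduction @ beta_reduced).
    """

    y: np.ndarray
    X: np.ndarray
    param_names: list[str]
    constraint: np.ndarray
    reduction: np.ndarray
    wells: list[str]          # competition wells with data, plate order
    mutant_wells: list[str]   # subset carrying S/G columns
    cells: list[tuple[float, float]]  # observed (day, hour), lexicographic
    obs_index: pd.DataFrame = field(repr=False)  # well_id, day, hour per row


@dataclass
class CompetitiveFit:
    """Result of one plate fit.

    ``wells`` has one row per competition well: A, S, G with standard
    errors and the CI for S (reference wells carry exact zeros for S and
    G); ``batch_terms`` has one row per observed (day, hour) cell;
    ``diagnostics`` records residual variance, degrees of freedom and
    bookkeeping counts.
    """

    plate_id: str
    wells: pd.DataFrame = field(repr=False)
    batch_terms: pd.DataFrame = field(repr=False)
    diagnostics: dict = field(default_factory=dict)
    params: pd.Series = field(default=None, repr=False)
    cov: pd.DataFrame = field(default=None, repr=False)

    def s_of(self, well_id: str) -> float:
        return float(self.wells.set_index("well_id").loc[well_id, "S"])


def _channel_sign(layout: PlateLayout, well: str) -> float:
    # +1: mutant population reported on RFP, so S enters ln(RFP/CFP) with +T
    return 1.0 if layout.mutant_channel_of(well) == "RFP" else -1.0


def build_design(points: pd.DataFrame, layout: PlateLayout) -> DesignSystem:
    """Assemble the constrained design from valid log-ratio points.

    Parameter order is deterministic: A columns for wells in plate order,
    then (S, G) per mutant well in plate order, then C per observed
    (day, hour) cell in lexicographic order. Raises if the plate has no
    reference well with data; a cell observed only in mutant wells is kept
    with a warning (its batch term leans on the mutant wells alone).
    """
    pts = points[points["valid"]] if "valid" in points.columns else points
    wells_with_data = set(pts["well_id"])
    wells = [w for w in layout.competition_wells if w in wells_with_data]
    ref_wells = [w for w in layout.reference_wells if w in wells_with_data]
    mutant_wells = [w for w in layout.mutant_wells if w in wells_with_data]
    if not ref_wells:
        raise ValueError(
            f"plate {layout.plate_id!r}: no reference_competition well with valid "
            "points; the model cannot be anchored"
        )

    cells = sorted({(float(d), float(h)) for d, h in zip(pts["day"], pts["hour"])})
    ref_cells = {
        (float(d), float(h))
        for d, h in zip(
            pts.loc[pts["well_id"].isin(ref_wells), "day"],
            pts.loc[pts["well_id"].isin(ref_wells), "hour"],
        )
    }
    orphan = [c for c in cells if c not in ref_cells]
    if orphan:
        warnings.warn(
            f"plate {layout.plate_id!r}: cell(s) {orphan} have no reference "
            "observation; their batch terms are estimated from mutant wells only",
            stacklevel=2,
        )

    a_names = [f"A[{w}]" for w in wells]
    sg_names: list[str] = []
    for w in mutant_wells:
        sg_names += [f"S[{w}]", f"G[{w}]"]
    c_names = [f"C[{d:g},{h:g}]" for d, h in cells]
    param_names = a_names + sg_names + c_names

    n, p = len(pts), len(param_names)
    well_pos = {w: i for i, w in enumerate(wells)}
    sg_pos = {w: len(a_names) + 2 * i for i, w in enumerate(mutant_wells)}
    cell_pos = {c: len(a_names) + len(sg_names) + i for i, c in enumerate(cells)}

    X = np.zeros((n, p))
    y = pts["y"].to_numpy(dtype=float)
    rows_w = pts["well_id"].to_numpy()
    rows_d = pts["day"].to_numpy(dtype=float)
    rows_h = pts["hour"].to_numpy(dtype=float)
    mutset = set(mutant_wells)
    for i in range(n):
        w = rows_w[i]
        X[i, well_pos[w]] = 1.0
        if w in mutset:
            sgn = _channel_sign(layout, w)
            j = sg_pos[w]
            X[i, j] = sgn * rows_d[i]
            X[i, j + 1] = sgn * rows_h[i]
        X[i, cell_pos[(rows_d[i], rows_h[i])]] = 1.0

    constraint = np.zeros(p)
    constraint[len(a_names) + len(sg_names):] = 1.0

    # Eliminate the constraint: the last C coefficient is minus the sum of
    # the others. reduction maps the free parameters to the full vector.
    m = len(cells)
    reduction = np.zeros((p, p - 1))
    reduction[: p - m, : p - m] = np.eye(p - m)
    if m > 1:
        reduction[p - m : p - 1, p - m :] = np.eye(m - 1)
        reduction[p - 1, p - m :] = -1.0
    # m == 1: sum-zero forces the lone C to 0; its row stays all zero.

    obs_index = pts[["well_id", "day", "hour"]].reset_index(drop=True)
    return DesignSystem(
        y=y,
        X=X,
        param_names=param_names,
        constraint=constraint,
        reduction=reduction,
        wells=wells,
        mutant_wells=mutant_wells,
        cells=cells,
        obs_index=obs_index,
    )


def _check_rank(Xr: np.ndarray, names_reduced: list[str]) -> None:
    if Xr.shape[0] < Xr.shape[1]:
        raise ValueError(
            f"underdetermined fit: {Xr.shape[0]} observations for {Xr.shape[1]} "
            "free parameters"
        )
    _, R, piv = scipy.linalg.qr(Xr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Xr.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < Xr.shape[1]:
        aliased = [names_reduced[j] for j in piv[rank:]]
        raise ValueError(
            "rank-deficient design beyond the A/C aliasing handled by the "
            f"constraint; aliased parameter(s): {', '.join(sorted(aliased))}"
        )


def fit_plate(
    points: pd.DataFrame,
    layout: PlateLayout,
    *,
    ci_level: float = 0.95,
) -> CompetitiveFit:
    """Constrained OLS fit of the plate model.

    Returns per-well A, S, G estimates with standard errors and t-based
    confidence intervals for S, per-cell batch terms, and fit diagnostics.
    Degrees of freedom must be positive; a design that is rank deficient
    beyond the known A/C aliasing raises with the aliased parameters named.
    """
    design = build_design(points, layout)
    Xr = design.X @ design.reduction
    names_reduced = design.param_names[: Xr.shape[1]]
    _check_rank(Xr, names_reduced)

    beta_r, _, _, _ = np.linalg.lstsq(Xr, design.y, rcond=None)
    beta = design.reduction @ beta_r
    resid = design.y - design.X @ beta
    rss = float(resid @ resid)
    n_obs = len(design.y)
    n_free = Xr.shape[1]
    df = n_obs - n_free
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df}); more data needed")
    sigma2 = rss / df

    XtX_inv = np.linalg.inv(Xr.T @ Xr)
    cov_full = design.reduction @ (sigma2 * XtX_inv) @ design.reduction.T
    se = np.sqrt(np.clip(np.diag(cov_full), 0.0, None))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)

    idx = {name: i for i, name in enumerate(design.param_names)}
    rows = []
    ref_set = set(layout.reference_wells)
    for w in design.wells:
        a_i = idx[f"A[{w}]"]
        row = {
            "well_id": w,
            "role": layout.role_of(w),
            "strain": layout.strain_of(w),
            "A": beta[a_i],
            "se_A": se[a_i],
        }
        if w in ref_set:
            row.update(S=0.0, se_S=0.0, G=0.0, se_G=0.0,
                       ci_low_S=0.0, ci_high_S=0.0)
        else:
            s_i, g_i = idx[f"S[{w}]"], idx[f"G[{w}]"]
            row.update(
                S=beta[s_i], se_S=se[s_i], G=beta[g_i], se_G=se[g_i],
                ci_low_S=beta[s_i] - tcrit * se[s_i],
                ci_high_S=beta[s_i] + tcrit * se[s_i],
            )
        rows.append(row)
    wells_df = pd.DataFrame(rows)

    batch = pd.DataFrame(
        {
            "day": [c[0] for c in design.cells],
            "hour": [c[1] for c in design.cells],
            "C": [beta[idx[f"C[{d:g},{h:g}]"]] for d, h in design.cells],
            "se_C": [se[idx[f"C[{d:g},{h:g}]"]] for d, h in design.cells],
        }
    )

    diagnostics = {
        "rss": rss,
        "df": df,
        "sigma2": sigma2,
        "n_obs": n_obs,
        "n_params": len(design.param_names),
        "n_free_params": n_free,
        "ci_level": ci_level,
        "n_reference_wells": sum(1 for w in design.wells if w in ref_set),
        "n_mutant_wells": len(design.mutant_wells),
        "constraint": "sum_zero",
    }
    return CompetitiveFit(
        plate_id=layout.plate_id,
        wells=wells_df,
        batch_terms=batch,
        diagnostics=diagnostics,
        params=pd.Series(beta, index=design.param_names),
        cov=pd.DataFrame(cov_full, index=design.param_names, columns=design.param_names),
    )


def downsample_reference_analysis(
    points: pd.DataFrame,
    layout: PlateLayout,
    n_refs_grid: list[int],
    n_draws: int,
    seed: int,
    *,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """How the number of reference wells affects mutant-S precision.

    For each n in ``n_refs_grid``, draws ``n_draws`` random size-n subsets
    of the plate's reference wells, refits the plate with the remaining
    references' points dropped, and summarises (a) the standard deviation
    of each mutant's S across draws, averaged over mutants, and (b) the
    mean CI width of mutant S. Grid entries exceeding the number of
    available references are skipped with a warning. Fully deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    refs = [w for w in layout.reference_wells if w in set(points.loc[points["valid"], "well_id"])]
    n_avail = len(refs)
    results = []
    cache: dict[tuple[str, ...], CompetitiveFit] = {}
    for n in n_refs_grid:
        if n > n_avail:
            warnings.warn(
                f"requested {n} reference wells but only {n_avail} available; skipped",
                stacklevel=2,
            )
            continue
        s_draws: list[pd.Series] = []
        widths: list[float] = []
        for _ in range(n_draws):
            subset = tuple(sorted(rng.choice(refs, size=n, replace=False)))
            fit = cache.get(subset)
            if fit is None:
                drop = set(refs) - set(subset)
                pts = points[~points["well_id"].isin(drop)]
                fit = fit_plate(pts, layout, ci_level=ci_level)
                cache[subset] = fit
            mut = fit.wells[fit.wells["role"] == "mutant_competition"]
            s_draws.append(mut.set_index("well_id")["S"])
            widths.append(float((mut["ci_high_S"] - mut["ci_low_S"]).mean()))
        s_mat = pd.concat(s_draws, axis=1)
        mean_sd = float(s_mat.std(axis=1, ddof=1).mean()) if n_draws > 1 else float("nan")
        results.append(
            {
                "n_refs": n,
                "mean_sd_S": mean_sd,
                "mean_ci95_width": float(np.mean(widths)),
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(results)
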