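"""Synthetic competitive-aging plates with known ground truth.

The generative model mirrors the assay: every competition well holds two
subpopulations (a mutant tagged with one fluorophore and the wild-type
reference tagged with the other) mixed 2:1 at day zero and then aged in
stationary phase. Viability decays exponentially — after T days a strain
with death rate r retains a viable inoculum proportional to exp(-r·T).
Each sampling day an aliquot is outgrown in fresh medium; the two viable
subpopulations regrow, by default under shared-resource logistic dynamics
dN_i/dt = g_i·N_i·(1 - (N_1+N_2)/K), so late reads saturate the way real
outgrowths do. Plate-reader channels report a linear gain on the
population carrying that fluorophore plus a channel background, a shared
per-read batch factor exp(C) on the RFP channel (a plate-wide log-ratio
offset, mean zero across reads), and multiplicative log-normal measurement
noise. Single-fluorophore monoculture wells supply the autofluorescence
controls and blanks the medium background, exactly as on a real plate.

Ground truth per well is A = ln of the calibrated initial signal ratio,
S = r_ref - r_x (per day) and G = g_x - g_ref (per hour); the truth tables
accompany every simulated plate so estimator error is directly measurable.

Dead cells contribute no fluorescence in the outgrowth: the read signal
comes from regrown live cells, and the outgrowth dilution makes carcass
fluorescence negligible. The "exponential" growth mode (no capacity)
generates data that satisfy the linear log-ratio model exactly and exists
for noise-free recovery checks; under shared-resource logistics the G·t
term of the fitted model is an explicit pre-saturation approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .plate_io import PlateLayout, validate_measurements

__all__ = [
    "SimulationConfig",
    "SimulatedPlate",
    "simulate_plate",
    "make_null_pair",
    "draw_null_reference_sets",
    "draw_null_interaction_records",
    "draw_null_anova_rates",
]

#: default stationary-phase sampling days: daily at first, then the usual
#: 2-3 day spacing out to ~15 days of aging.
DEFAULT_DAYS = (0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 12.0, 15.0)
#: outgrowth read schedule (hours after inoculation into fresh medium); the
#: hour-0 read anchors the inoculation baseline used by blank subtraction
DEFAULT_HOURS = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0)


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults emulate one screening plate.

    96 wells: 31 reference competitions, 12 mutant strains × 5 replicate
    wells, two autofluorescence controls per channel and one blank. The
    wild-type death rate 0.0648/day corresponds to a 10.7-day half-life;
    mutant death rates scatter log-normally around it (sd 0.4 on the log,
    a realistic mix of short- and long-lived strains). Growth rate
    ln(2)/2 per hour is a 2-hour doubling time; mutants vary by ~3%.
    Fluorescence is gain x population + background per channel, with 5%
    multiplicative measurement noise and per-read batch offsets of sd 0.1
    on the log-ratio scale (mean-centered exactly).
    """

    seed: int = 0
    plate_id: str = "SIM1"
    condition: str = "SC"
    n_reference: int = 31
    n_mutant_strains: int = 12
    replicates_per_strain: int = 5
    n_rfp_monoculture: int = 2
    n_cfp_monoculture: int = 2
    n_blank: int = 1
    days: tuple[float, ...] = DEFAULT_DAYS
    hours: tuple[float, ...] = DEFAULT_HOURS
    # strain truth
    r_ref: float = 0.0648            # per day; half-life 10.7 d
    sigma_log_r: float = 0.4         # lognormal spread of mutant death rates
    g_ref: float = 0.34657359027997264   # ln(2)/2 per hour; 2 h doubling
    sigma_log_g: float = 0.03        # lognormal spread of mutant growth rates
    mutant_rates: dict | None = None  # optional explicit {strain: (r, g)}
    # culture and mixing
    mix_ratio: float = 2.0           # mutant:reference at day 0
    inoculum_od: float = 0.02        # total viable inoculum at day 0 (OD units)
    capacity: float = 2.0            # logistic capacity K (OD units)
    a_jitter_sd: float = 0.1         # per-well log jitter on the mixing ratio
    growth_model: str = "competitive_logistic"  # or "exponential"
    # measurement
    alpha_rfp: float = 2000.0        # fluorescence units per OD, RFP channel
    alpha_cfp: float = 1500.0
    beta_rfp: float = 80.0           # channel autofluorescence background
    beta_cfp: float = 120.0
    od_offset: float = 0.04          # OD600 of medium + inoculation carryover
    sigma_log: float = 0.05          # multiplicative measurement noise (log sd)
    c_sd: float = 0.1                # per-read batch offset sd (log-ratio scale)

    def __post_init__(self) -> None:
        if self.r_ref < 0 or self.sigma_log < 0 or self.c_sd < 0:
            raise ValueError("rates and noise scales must be non-negative")
        if self.g_ref <= 0 or self.capacity <= 0 or self.inoculum_od <= 0:
            raise ValueError("growth rate, capacity and inoculum must be positive")
        if self.inoculum_od >= self.capacity:
            raise ValueError("inoculum must be below the logistic capacity")
        if self.growth_model not in ("competitive_logistic", "exponential"):
            raise ValueError(f"unknown growth_model {self.growth_model!r}")
        n_wells = (self.n_reference
                   + self.n_mutant_strains * self.replicates_per_strain
                   + self.n_rfp_monoculture + self.n_cfp_monoculture + self.n_blank)
        if n_wells > 96:
            raise ValueError(f"layout needs {n_wells} wells; a plate has 96")


@dataclass
class SimulatedPlate:
    layout: PlateLayout
    measurements: pd.DataFrame = field(repr=False)
    well_truth: pd.DataFrame = field(repr=False)    # A_true, S_true, G_true per well
    strain_truth: pd.DataFrame = field(repr=False)  # r, g, half_life per strain
    batch_truth: pd.DataFrame = field(repr=False)   # C_true per (day, hour)


def _well_names() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def _build_layout(cfg: SimulationConfig) -> PlateLayout:
    names = _well_names()
    rows = []
    i = 0
    for _ in range(cfg.n_rfp_monoculture):
        rows.append((names[i], "rfp_monoculture", "WT_RFP", "RFP")); i += 1
    for _ in range(cfg.n_cfp_monoculture):
        rows.append((names[i], "cfp_monoculture", "WT_CFP", "RFP")); i += 1
    for _ in range(cfg.n_blank):
        rows.append((names[i], "blank", "blank", "RFP")); i += 1
    for _ in range(cfg.n_reference):
        rows.append((names[i], "reference_competition", "reference", "RFP")); i += 1
    for s in range(cfg.n_mutant_strains):
        strain = f"mut{s + 1:02d}"
        for _ in range(cfg.replicates_per_strain):
            rows.append((names[i], "mutant_competition", strain, "RFP")); i += 1
    entries = pd.DataFrame(
        {
            "plate_id": cfg.plate_id,
            "well_id": [r[0] for r in rows],
            "role": [r[1] for r in rows],
            "strain": [r[2] for r in rows],
            "condition": cfg.condition,
            "mutant_channel": [r[3] for r in rows],
        }
    )
    return PlateLayout(plate_id=cfg.plate_id, entries=entries)


def _draw_strain_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = [{"strain": "reference", "r": cfg.r_ref, "g": cfg.g_ref}]
    for s in range(cfg.n_mutant_strains):
        strain = f"mut{s + 1:02d}"
        if cfg.mutant_rates and strain in cfg.mutant_rates:
            r, g = cfg.mutant_rates[strain]
        else:
            r = cfg.r_ref * float(np.exp(rng.normal(0.0, cfg.sigma_log_r)))
            g = cfg.g_ref * float(np.exp(rng.normal(0.0, cfg.sigma_log_g)))
        rows.append({"strain": strain, "r": r, "g": g})
    df = pd.DataFrame(rows)
    df["half_life"] = np.where(df["r"] > 0, np.log(2) / df["r"], np.inf)
    return df


def _outgrow(n0: np.ndarray, g: np.ndarray, hours: np.ndarray,
             K: float, model: str) -> np.ndarray:
    """Population sizes (len(n0) x len(hours)) during one outgrowth."""
    n0 = np.asarray(n0, dtype=float)
    g = np.asarray(g, dtype=float)
    if model == "exponential":
        return n0[:, None] * np.exp(g[:, None] * hours[None, :])
    total0 = n0.sum()
    if total0 <= 0:
        raise ValueError("non-positive inoculum in outgrowth")
    if np.allclose(g, g[0], rtol=0.0, atol=1e-12):
        # equal rates: the total follows a closed-form logistic and the
        # subpopulation ratio is frozen at the inoculum ratio (exact)
        tot = K * total0 * np.exp(g[0] * hours) / (K + total0 * (np.exp(g[0] * hours) - 1.0))
        return (n0 / total0)[:, None] * tot[None, :]

    def rhs(_, n):
        return g * n * (1.0 - n.sum() / K)

    sol = solve_ivp(rhs, (0.0, float(hours.max())), n0, t_eval=hours,
                    rtol=1e-10, atol=1e-14, method="RK45")
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"outgrowth integration failed: {sol.message}")
    return sol.y


def simulate_plate(config: SimulationConfig) -> SimulatedPlate:
    """Generate one plate: layout, measurement table and truth tables.

    Fully reproducible from ``config.seed``; writing the measurement table
    with the canonical formatter yields byte-identical CSVs across runs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg)
    strain_truth = _draw_strain_truth(cfg, rng)
    rate_of = strain_truth.set_index("strain")

    days = np.asarray(cfg.days, dtype=float)
    hours = np.asarray(cfg.hours, dtype=float)
    cells = [(d, h) for d in days for h in hours]
    if cfg.c_sd > 0:
        c_vals = rng.normal(0.0, cfg.c_sd, size=len(cells))
        c_vals -= c_vals.mean()  # exact mean-zero across observed reads
    else:
        c_vals = np.zeros(len(cells))
    batch_truth = pd.DataFrame(
        {"day": [c[0] for c in cells], "hour": [c[1] for c in cells], "C_true": c_vals}
    )
    c_of = {(d, h): c for (d, h), c in zip(cells, c_vals)}

    frac_mut = cfg.mix_ratio / (1.0 + cfg.mix_ratio)
    frac_ref = 1.0 - frac_mut

    well_rows = []
    meas = {k: [] for k in ("plate_id", "well_id", "day", "hour", "od600", "rfp", "cfp")}

    def emit(well, day, hour, od, rfp, cfp):
        noise = np.exp(rng.normal(0.0, cfg.sigma_log, size=3))
        meas["plate_id"].append(cfg.plate_id)
        meas["well_id"].append(well)
        meas["day"].append(day)
        meas["hour"].append(hour)
        meas["od600"].append(od * noise[0])
        meas["rfp"].append(rfp * noise[1])
        meas["cfp"].append(cfp * noise[2])

    for _, ent in layout.entries.iterrows():
        well, role, strain = ent["well_id"], ent["role"], ent["strain"]
        if role in ("mutant_competition", "reference_competition"):
            mut_strain = strain if role == "mutant_competition" else "reference"
            r_m = float(rate_of.loc[mut_strain, "r"])
            g_m = float(rate_of.loc[mut_strain, "g"])
            r_r, g_r = cfg.r_ref, cfg.g_ref
            jitter = float(np.exp(rng.normal(0.0, cfg.a_jitter_sd))) if cfg.a_jitter_sd > 0 else 1.0
            n_mut0 = cfg.inoculum_od * frac_mut * jitter
            n_ref0 = cfg.inoculum_od * frac_ref
            # mutant carries RFP; reference carries CFP
            a_true = np.log((cfg.alpha_rfp * n_mut0) / (cfg.alpha_cfp * n_ref0))
            well_rows.append(
                {
                    "well_id": well, "strain": strain, "role": role,
                    "A_true": a_true,
                    "S_true": (r_r - r_m) if role == "mutant_competition" else 0.0,
                    "G_true": (g_m - g_r) if role == "mutant_competition" else 0.0,
                }
            )
            for day in days:
                inoc = np.array([n_mut0 * np.exp(-r_m * day), n_ref0 * np.exp(-r_r * day)])
                if inoc.min() <= 0:
                    raise ValueError(f"non-positive viable inoculum in well {well} at day {day}")
                pops = _outgrow(inoc, np.array([g_m, g_r]), hours, cfg.capacity, cfg.growth_model)
                for j, hour in enumerate(hours):
                    n_m, n_r = pops[0, j], pops[1, j]
                    rfp = cfg.alpha_rfp * n_m * np.exp(c_of[(day, hour)]) + cfg.beta_rfp
                    cfp = cfg.alpha_cfp * n_r + cfg.beta_cfp
                    emit(well, day, hour, n_m + n_r + cfg.od_offset, rfp, cfp)
        elif role in ("rfp_monoculture", "cfp_monoculture"):
            n0 = cfg.inoculum_od
            for day in days:
                inoc = np.array([n0 * np.exp(-cfg.r_ref * day)])
                pops = _outgrow(inoc, np.array([cfg.g_ref]), hours, cfg.capacity, cfg.growth_model)
                for j, hour in enumerate(hours):
                    n = pops[0, j]
                    if role == "rfp_monoculture":
                        rfp = cfg.alpha_rfp * n * np.exp(c_of[(day, hour)]) + cfg.beta_rfp
                        cfp = cfg.beta_cfp
                    else:
                        rfp = cfg.beta_rfp
                        cfp = cfg.alpha_cfp * n + cfg.beta_cfp
                    emit(well, day, hour, n + cfg.od_offset, rfp, cfp)
        else:  # blank
            for day in days:
                for hour in hours:
                    emit(well, day, hour, cfg.od_offset, cfg.beta_rfp, cfg.beta_cfp)

    measurements = validate_measurements(pd.DataFrame(meas), layout)
    return SimulatedPlate(
        layout=layout,
        measurements=measurements,
        well_truth=pd.DataFrame(well_rows),
        strain_truth=strain_truth,
        batch_truth=batch_truth,
    )


def make_null_pair(
    config: SimulationConfig,
    seed: int,
    *,
    rate_scale_b: float = 1.0,
    condition_b: str | None = None,
) -> tuple[SimulatedPlate, SimulatedPlate]:
    """Two plates with identical strain truths and independent noise.

    Condition B optionally scales every death rate (reference included) by
    ``rate_scale_b``, mimicking a lifespan-extending drug acting equally
    on all strains: S scales with r_wt, so the rescaled survivorship rS of
    every strain is unchanged — a true no-interaction null. Scale 0.69
    moves a 10.7-day wild-type half-life to 15.5 days.
    """
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    cfg_a = replace(config, seed=seed_a, plate_id=config.plate_id + "_A")
    plate_a = simulate_plate(cfg_a)
    truths = {
        row["strain"]: (row["r"] * rate_scale_b, row["g"])
        for _, row in plate_a.strain_truth.iterrows()
        if row["strain"] != "reference"
    }
    cfg_b = replace(
        config,
        seed=seed_b,
        plate_id=config.plate_id + "_B",
        condition=condition_b or (config.condition + "+drug"),
        r_ref=config.r_ref * rate_scale_b,
        mutant_rates=truths,
    )
    plate_b = simulate_plate(cfg_b)
    return plate_a, plate_b


# ---------------------------------------------------------------------------
# Record-level nulls for test calibration. Full-plate nulls (make_null_pair)
# carry the whole generative model; these draw directly at the level the
# statistical tests consume — replicate S/rS values and death rates with
# identical truth across groups — so thousands of null replicates are cheap.

def draw_null_reference_sets(
    rng: np.random.Generator, n_mutant: int = 6, n_reference: int = 31,
    sd: float = 0.01, mean: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutant and reference S replicate sets drawn from the same normal."""
    return (rng.normal(mean, sd, size=n_mutant),
            rng.normal(mean, sd, size=n_reference))


def draw_null_interaction_records(
    rng: np.random.Generator, n_strains: int = 1, n_replicates: int = 4,
    sd: float = 0.05, strain_effect_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain replicate rS tables for two conditions, identical truth.

    Each strain gets one true rS (normal, sd ``strain_effect_sd``) shared
    by both conditions; replicates add independent noise. Matched
    replicate indices make the pair usable in paired mode.
    """
    frames = []
    true_rs = rng.normal(0.0, strain_effect_sd, size=n_strains)
    for cond in ("A", "B"):
        frames.append(
            pd.DataFrame(
                {
                    "strain": np.repeat([f"s{i}" for i in range(n_strains)], n_replicates),
                    "replicate": np.tile(np.arange(n_replicates), n_strains),
                    "condition": cond,
                    "rS": np.repeat(true_rs, n_replicates)
                    + rng.normal(0.0, sd, size=n_strains * n_replicates),
                }
            )
        )
    return frames[0], frames[1]


def draw_null_anova_rates(
    rng: np.random.Generator, n_per_cell: int = 3, base: float = 0.065,
    genotype_effect: float = 0.02, treatment_effect: float = -0.02,
    sd: float = 0.005,
) -> pd.DataFrame:
    """2x2 death-rate table with additive effects and no interaction."""
    rows = []
    for geno, ge in (("wt", 0.0), ("mutant", genotype_effect)):
        for trt, te in (("ctrl", 0.0), ("drug", treatment_effect)):
            for _ in range(n_per_cell):
                rows.append(
                    {"genotype": geno, "treatment": trt,
                     "rate": base + ge + te + rng.normal(0.0, sd)}
                )
    return pd.DataFrame(rows)
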