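"""Gene–drug (gene–environment) interaction scoring.

A gene–drug interaction is a deletion strain whose lifespan phenotype,
expressed as rescaled survivorship rS, differs significantly between two
conditions (e.g. plain medium vs medium with a drug). Because rS is
dimensionless and zero-centered on the wild type, a strain with no
interaction sits on the diagonal rS_A = rS_B even when the drug changes
the absolute wild-type death rate.

Per strain, replicate rS values in the two conditions are compared with a
paired t-test when replicates are matched across conditions (replicate
plates run in both media) and Welch's two-sample t-test otherwise.
Significant strains are classified by direction relative to the neutral
rS = 0 line: *alleviated* (the phenotype moves toward zero under the
drug), *aggravated* (moves further from zero, same sign), *reverted*
(changes sign).

Companion statistics used to validate interaction calls with orthogonal
viability measurements: a Wilcoxon rank-sum comparison of half-life
groups, and a two-way fixed-effects ANOVA (genotype × treatment) of death
rates whose interaction-term p-value scores the gene–drug interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "InteractionResult",
    "score_interactions",
    "classify_direction",
    "compare_half_life",
    "anova_interaction",
]


@dataclass
class InteractionResult:
    strain: str
    rS_mean_A: float
    rS_mean_B: float
    delta_rS: float
    p_value: float
    test: str
    significant: bool | None
    direction: str  # alleviated | aggravated | reverted | none
    note: str = ""


def classify_direction(rS_A: float, rS_B: float, significant: bool,
                       *, neutral_band: float = 0.05) -> str:
    """Directional label of a condition change relative to rS = 0.

    aggravated: |rS_B| > |rS_A| with the same sign; alleviated: the
    phenotype shrinks toward zero (or lands within ``neutral_band`` of
    it); reverted: a significant sign change beyond the neutral band.
    Non-significant strains are always "none".
    """
    if not significant:
        return "none"
    if abs(rS_B) <= neutral_band and abs(rS_A) > neutral_band:
        return "alleviated"
    if np.sign(rS_A) == np.sign(rS_B) or abs(rS_B) <= neutral_band:
        return "aggravated" if abs(rS_B) > abs(rS_A) else "alleviated"
    return "reverted"


def _strain_test(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, str]:
    if paired:
        diff = b - a
        if np.ptp(diff) == 0:
            # all differences identical: zero spread, test degenerate
            return (1.0 if diff[0] == 0 else 0.0), "degenerate paired"
        res = stats.ttest_rel(a, b)
        return float(res.pvalue), ""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (1.0 if a[0] == b[0] else 0.0), "degenerate two-sample"
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue), ""


def score_interactions(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    *,
    alpha: float = 0.05,
    paired: bool | None = None,
    neutral_band: float = 0.05,
) -> pd.DataFrame:
    """Per-strain interaction tests between two conditions.

    Each records table needs columns strain, rS and, for pairing, a
    replicate column identifying matched replicates. ``paired=None``
    auto-detects: paired when every shared strain has identical replicate
    index sets in both conditions. Strains missing from either condition,
    or with < 2 replicates, get an undefined marker. Returns a DataFrame
    sorted by p-value.
    """
    if paired is None:
        paired = _pairing_possible(records_a, records_b)
    strains = sorted(set(records_a["strain"]) & set(records_b["strain"]))
    rows = []
    for strain in strains:
        ga = records_a[records_a["strain"] == strain]
        gb = records_b[records_b["strain"] == strain]
        note = ""
        if len(ga) < 2 or len(gb) < 2:
            rows.append(_undefined(strain, ga, gb, "insufficient replicates"))
            continue
        if paired:
            if "replicate" not in ga.columns or "replicate" not in gb.columns:
                rows.append(_undefined(strain, ga, gb, "no replicate column for pairing"))
                continue
            ga = ga.sort_values("replicate")
            gb = gb.sort_values("replicate")
            if list(ga["replicate"]) != list(gb["replicate"]):
                rows.append(_undefined(strain, ga, gb, "unmatched replicate pairing"))
                continue
        a = ga["rS"].to_numpy(dtype=float)
        b = gb["rS"].to_numpy(dtype=float)
        p, note = _strain_test(a, b, paired)
        sig = bool(p < alpha)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        rows.append(
            {
                "strain": strain,
                "rS_mean_A": mean_a,
                "rS_mean_B": mean_b,
                "delta_rS": mean_b - mean_a,
                "p_value": p,
                "test": "paired t-test" if paired else "Welch t-test",
                "significant": sig,
                "direction": classify_direction(mean_a, mean_b, sig,
                                                neutral_band=neutral_band),
                "note": note,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["p_value", "strain"], na_position="last").reset_index(drop=True)


def _pairing_possible(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if "replicate" not in a.columns or "replicate" not in b.columns:
        return False
    for strain in set(a["strain"]) & set(b["strain"]):
        ra = sorted(a.loc[a["strain"] == strain, "replicate"])
        rb = sorted(b.loc[b["strain"] == strain, "replicate"])
        if ra != rb:
            return False
    return True


def _undefined(strain, ga, gb, note):
    return {
        "strain": strain,
        "rS_mean_A": float(ga["rS"].mean()) if len(ga) else float("nan"),
        "rS_mean_B": float(gb["rS"].mean()) if len(gb) else float("nan"),
        "delta_rS": float("nan"),
        "p_value": float("nan"),
        "test": "undefined",
        "significant": None,
        "direction": "none",
        "note": note,
    }


def compare_half_life(group_a, group_b) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two half-life groups.

    Returns medians and the p-value (exact when there are no ties).
    Degenerate all-tied input yields p = 1 with a warning. Requires >= 3
    values per group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 half-life values per group")
    result = {"median_A": float(np.median(a)), "median_B": float(np.median(b)),
              "n_A": len(a), "n_B": len(b)}
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all half-life values identical; rank-sum test degenerate (p = 1)",
                      stacklevel=2)
        result["p_value"] = 1.0
        return result
    ties = len(np.unique(pooled)) < len(pooled)
    method = "auto" if ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    result["p_value"] = float(res.pvalue)
    return result


def anova_interaction(rates: pd.DataFrame, *, alpha: float = 0.01) -> dict:
    """Genotype × treatment interaction p-value by two-way ANOVA.

    ``rates`` needs columns rate (death rate), genotype and treatment,
    each factor with exactly two levels and >= 2 replicates per cell of
    the 2×2 design. Returns the full ANOVA table plus the interaction
    p-value and its significance at ``alpha``.
    """
    for col in ("rate", "genotype", "treatment"):
        if col not in rates.columns:
            raise ValueError(f"rates table missing column {col!r}")
    counts = rates.groupby(["genotype", "treatment"]).size()
    if len(counts) < 4:
        raise ValueError("empty cell in the 2x2 genotype x treatment design")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per cell of the 2x2 design")
    if np.ptp(rates["rate"].to_numpy(dtype=float)) == 0:
        raise ValueError("degenerate input: all death rates identical (zero variance)")
    model = smf.ols("rate ~ C(genotype) * C(treatment)", data=rates).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = float(table.loc["C(genotype):C(treatment)", "PR(>F)"])
    return {
        "p_interaction": p,
        "significant": bool(p < alpha),
        "anova_table": table,
    }
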