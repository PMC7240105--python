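# competage

Quantitative analysis of **competitive-aging** experiments: relative
chronological-lifespan (CLS) phenotypes of budding-yeast strains measured
from dual-fluorophore co-culture plate-reader data.

In a competitive-aging assay a mutant strain tagged with one fluorescent
protein (e.g. RFP) is mixed ~2:1 with a wild-type reference tagged with the
other (CFP), aged in stationary phase in the same well, and sampled over
~15 days. Each sampling day an aliquot is regrown in fresh medium while a
plate reader records OD600 and both fluorescence channels. Because dead
cells do not regrow, the drift of the fluorescence ratio across days reads
out the difference in death rates between the two subpopulations — both of
which experienced the identical microenvironment.

## The model

Every background-corrected log signal ratio of a competition well *w*,
sampled at stationary-phase day *T<sub>i</sub>* and outgrowth hour
*t<sub>j</sub>*, is modeled as

```
ln(RFP/CFP)_{Ti,tj} = A_w + S_w·T_i + G_w·t_j + C_{Ti,tj}
```

- **A_w** — log initial abundance ratio of the two subpopulations;
- **S_w** (per day) — *relative survivorship*, the death-rate difference
  between mutant and reference (positive = mutant outlives the reference);
- **G_w** (per hour) — relative growth rate during the outgrowth, a
  nuisance parameter separating growth from survival effects;
- **C_{Ti,tj}** — a plate-wide batch term shared by every well read at that
  (day, hour), capturing systematic measurement drift.

All observations of a 96-well plate are fit in a single constrained
least-squares system. Reference competitions (wild type vs wild type)
carry structural zeros for S and G, anchoring the scale; the batch block is
identified by the constraint ΣC = 0. Standard errors and t-based confidence
intervals come from the OLS covariance.

Companion modules provide:

- **monoculture** — the classical outgrowth-kinetics method: percent
  viability `V_T = 100·2^(−Δt/δ)` from the time shift Δt to reach
  OD600 = 0.35 and the doubling time δ; death rate from an exponential
  decay fit; half-life `HL = ln 2 / r`.
- **survivorship** — rescaled survivorship `rS = −ln(1 − S/r_wt)`, a
  dimensionless transform that makes phenotypes comparable between
  conditions with different wild-type death rates, plus replicate
  aggregation and tests against the empirical wild-type S distribution.
- **interactions** — per-strain gene–drug interaction tests on rS between
  two conditions (paired or two-sample t-tests), Wilcoxon rank-sum
  comparison of half-life groups, and two-way ANOVA (genotype × treatment)
  of death rates.
- **simulate** — a full generative model of a plate (exponential viability
  decay, shared-resource logistic outgrowth, fluorescence calibration with
  channel backgrounds, batch offsets, multiplicative noise) with known
  ground truth for every estimator.

## Worked example

Simulate a default screening plate (31 reference wells, 12 mutant strains
× 5 replicate wells, 8 sampling days, 10 outgrowth reads per day) and fit
it:

```sh
$ competage simulate --seed 3 --out sim
simulated plate SIM1: 7680 measurements -> sim
$ competage fit --layout sim/layout.csv --measurements sim/measurements.csv --out fit
fitted plate SIM1: 60 mutant wells, df=3464 -> fit
```

`fit/wells.csv` holds one row per competition well. Comparing the fitted
relative survivorship against the simulator's truth for the first strain:

```
well_id strain       S   se_S  S_true
     D1  mut01 -0.0832 0.0029 -0.0818
     D2  mut01 -0.0812 0.0029 -0.0818
     D3  mut01 -0.0888 0.0029 -0.0818
     D4  mut01 -0.0797 0.0029 -0.0818
     D5  mut01 -0.0858 0.0029 -0.0818
```

`mut01` dies ~0.08/day faster than the wild-type reference — a short-lived
mutant — and the five replicate wells recover the true value within their
standard errors. `fit/batch_terms.csv` holds the per-read batch terms and
`fit/diagnostics.json` the residual variance and degrees of freedom.

The `qc` subcommand quantifies how many reference wells a plate needs:

```sh
$ competage qc --layout sim/layout.csv --measurements sim/measurements.csv --seed 5 --out qc
 n_refs    mean_sd_S  mean_ci95_width  n_draws
      1 3.732222e-03         0.015881       20
      5 9.924323e-04         0.012288       20
     10 9.181740e-04         0.011771       20
     31 2.761453e-18         0.011311       20
```

The dispersion of mutant S across random reference subsets drops steeply
from one to five reference wells and flattens after about ten — 6–10
references per plate buy nearly all the attainable precision, freeing the
remaining wells for samples. Further subcommands: `monoculture`
(viability curves and half-lives from OD600 kinetics), `summarize`
(rS rescaling, replicate aggregation, tests vs the wild-type
distribution) and `interactions` (condition comparisons).

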