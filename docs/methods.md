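# Methods

## Model

The workflow rests on a steady-state mass-balance between chronic dietary
intake of a parent pyrethroid and urinary excretion of its metabolites.
For a daily dose `D` (mg/kg bw/day), a metabolite with molar urinary
excretion fraction `Fue` and molecular-weight ratio `MW_met/MW_parent`,
and a body-weight-adjusted daily urine output `U` (L/kg bw/day), the
expected urinary concentration is

    C = D · Fue · (MW_met / MW_parent) · 1000 / U    [µg/L]

(the factor 1000 converts mg to µg).  Intake-model outputs arrive as
percentages of the ADI, so `D = %ADI · ADI / 100`.  Evaluating the same
equation at `D = ADI` gives the human-biomonitoring guidance value
(HBM-GV Gen Pop); predictions can equivalently be computed as
`HBM-GV · %ADI / 100`, and the two paths agree to floating precision by
construction (asserted in the tests at 1e-9 relative tolerance).

Assumptions: chronic steady state (single-day kinetics are not modelled),
complete and linear absorption/excretion within the `Fue` lump, and
population variability captured entirely by the two age classes' `U`
values and the inter-diet spread of the intake estimates.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| ADI (per substance, two vintages) | see `data/default_parameters.yaml` | mg/kg bw/day | intake-era vintage drives dosimetry; current vintage drives risk. Permethrin: 0.05 → 0.01. Cyfluthrin and cypermethrin were also re-evaluated, but no revised figure is available in the source used for the defaults, so their current vintage equals the intake-era value; both are config-overridable. |
| MW parent / metabolite | idem | g/mol | |
| Fue | idem | – | molar fraction in (0, 1]. The 3-PBA value of 0.09 is deliberately conservative; its consequences are quantified by the misspecification study. |
| U adult / child | 0.0299 / 0.0197 | L/kg bw/day | **calibrated, not sourced**: chosen so permethrin at ADI 0.01 reproduces the published guidance values of 64 and 97 µg DCCA/L. Config-overridable. |

Guidance values are displayed rounded to the nearest integer µg/L; all
internal arithmetic is unrounded.

Metabolite identifiers are canonicalised (CFMP = CLF3CA; F3PBA = 4-FPBA =
4-F-3-PBA), so either spelling may appear in inputs.

## Allocation conventions

- Contribution percents are computed per (metabolite, diet, year,
  scenario) cell; substances excreting the metabolite but absent from the
  food data in that cell count as explicit 0%, since under the middle and
  upper censoring bounds absence means no quantified residues, not a
  missing measurement.  Cells with zero total prediction are missing and
  excluded from summaries.
- Percentiles use inclusive linear interpolation (the spreadsheet
  `PERCENTILE.INC` rule).  This preserves the two-contributor
  complementarity identity `p_q(A) + p_{100−q}(B) = 100` exactly.
- The middle censoring bound is the default for all allocation outputs;
  the lower bound (all censored residues set to zero) is computed but of
  low relevance because it zeroes whole cells.
- Deterministic risk pairs each measured percentile level with the
  allocation **median** (p50); cross-variability between levels and
  contributions is the Monte Carlo module's job.
- The cross-metabolite consistency check regresses selective-metabolite-
  based parent molar equivalents (`level · pct/100 / MW_met / Fue`, µmol/L)
  on 3-PBA-based ones, one pooled OLS (intercept included) over all
  (population group × substance) pairs.  If the 3-PBA `Fue` used in the
  analysis understates the true excretion by a factor k, the expected
  slope is 1/k.  The orientation can be flipped by swapping the arguments.

## Risk conventions

The combined total counts each substance once, through its most selective
measurable metabolite: deltamethrin→DBCA, cyfluthrin→F3PBA,
cypermethrin→DCCA, permethrin→DCCA, lambda-cyhalothrin→CFMP,
bifenthrin→CFMP.  3-PBA never enters combined totals (its conservative
`Fue` inflates HQs), though 3-PBA cumulative HQs are still reported.
Cyfluthrin's DCCA share contributes to the DCCA cumulative HQ but not to
the combined total (avoids double counting).

## Distribution fitting

Reported percentile triples (5/50/95 for levels, 10/50/90 for
contributions) are matched by minimising the sum of squared **relative**
quantile deviations, so heavy-tailed level distributions are not dominated
by the upper anchor; the objective is config-selectable in principle but
relative error is the default and the one used throughout.  Families:
gamma, lognormal, weibull (positive support), normal, triangular, uniform.
Location-scale families are solved in closed form (linear least squares on
the anchor quantile equations); gamma, weibull and triangular start from
moment/regression initialisers and are polished by Levenberg–Marquardt
least squares to machine precision.

Three quantiles do not always identify the family: any symmetric anchor
triple is fitted *exactly* by a normal, a uniform and a symmetric
triangular, so candidates whose objectives are within 1e-9 of the best are
treated as tied and resolved by the fixed gallery order (gamma, lognormal,
weibull, normal, triangular, uniform).  Skewed families are mutually
identifiable in practice.  All per-family fits are retained on the result
(`candidates`) for inspection.  Degenerate anchors (relative spread below
1e-6) are rejected.  For nonnegative quantities a triangular support
extending below zero is truncated at zero and logged.

## Monte Carlo

One seeded `numpy` generator; inverse-transform sampling with a documented
stream order (population level first, then each contributing substance in
mapping order), so runs are bit-reproducible given the seed.  Contribution
draws are clipped to [0, 100] (clip fractions are reported and expected
below 0.5% for realistic anchors); an optional flag renormalises each
iteration's contributions to a 100% simplex.  Contributions are sampled
independently per substance by default — no joint model of the shares is
imposed.  Default 10,000 iterations; exceedance is the fraction of
iterations whose total HQ exceeds the threshold (default 1.0).

## Synthetic data generator

The generator emulates the two input shapes with known truth:

- **Dietary table**: per (diet, year, substance), true dose = mean dose ×
  a shared mean-one lognormal diet factor (σ = 0.4) × a substance-specific
  factor (σ = 0.3; total inter-diet log-SD 0.5).  The shared factor models
  diets differing in overall residue-bearing produce; only the
  substance-specific part perturbs contribution shares, keeping the median
  share an essentially unbiased estimand of the analytic share.  A
  configurable fraction of residue mass (default 0.3) sits below the LOQ;
  the lower/middle/upper bounds substitute 0, half or all of it, giving
  ordered %ADI triples.  36 diets (a quarter children's) × 2016–2020.
- **Default mean doses** (mg/kg bw/day): cyfluthrin 2.5e-5, cypermethrin
  1.0e-4, permethrin 2.5e-5, deltamethrin 7.5e-5, lambda-cyhalothrin
  5.0e-5, bifenthrin 2.5e-5.  The ratios set contribution shares
  resembling a European food basket (cypermethrin dominating DCCA and
  3-PBA at ~66%/43%, lambda-cyhalothrin dominating CFMP at ~65%); the
  absolute scale puts predicted urinary medians at the sub-µg/L levels
  European surveys report and keeps combined HQs below 1 even at the 95th
  percentile of the most exposed synthetic group.
- **Urinary tables**: the population median per metabolite is the forward
  prediction at the mean doses using *generation-side* excretion fractions
  (`true_fue` overrides allow deliberately misspecified analyses, e.g.
  3-PBA generated at 0.45 but analysed at 0.09); percentiles follow a
  lognormal with geometric SD 2.0 (typical inter-individual spread of
  urinary biomarkers).  Synthetic countries are replicates whose medians
  carry a log-uniform factor on [1/3, 3] — a finite panel of national
  populations covers about an order of magnitude fairly evenly, and the
  log-uniform draw reproduces that span without the rare extreme groups an
  iid lognormal would inject (which would otherwise dominate the
  cross-metabolite regression through leverage) — plus optional
  multiplicative measurement noise (CV, default 0).

What the generator does **not** emulate: commodity-level residue
composition (censoring acts on aggregate %ADI), real national diet
composition or country matching, creatinine/urine-dilution adjustment,
within-person kinetics, and correlation between a population's level and
its contribution shares.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generating process, not
fidelity of any particular national estimate.

## Numerical choices and study sizes

- Percentile estimator: numpy `"linear"` (inclusive) everywhere.
- Equation-equivalence checks at 1e-9 relative tolerance; fit round-trips
  to <1% parameter error; tie tolerance 1e-9 on the fit objective.
- The misspecification study defaults to 24 synthetic countries × 2 age
  classes × 3 dual-metabolite substances (144 regression points) at 10%
  measurement CV — large enough for a stable pooled slope, small enough to
  run in seconds.  The allocation recovery study uses the full 36 × 5 grid.
  The child age class contributes only 45 diet-year cells there, so its
  p50 carries ~1.4 points of sampling error; the ±2-point recovery band
  holds at the default seed but is finite-sample-tight by nature.
- Monte Carlo checks use n = 10,000 with 3-standard-error bands.

## Known limitations

- The two `U` defaults are reverse-calibrated constants, not measured
  physiology; any downstream absolute concentration inherits them.
- Current-vintage ADIs for cyfluthrin and cypermethrin default to their
  intake-era values (no published revision in the defaults file).
- The symmetric distribution-family trio cannot be distinguished from
  three quantiles; family identity there is a documented convention.
- Deterministic risk uses allocation medians; tail co-variation between
  allocation shares and exposure levels is only captured by the Monte
  Carlo module, and even there shares are sampled independently.
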