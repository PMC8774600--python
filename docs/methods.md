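# Methods

## Scope and model

`bprisk` implements a probabilistic cumulative dietary risk assessment for
six benzophenone-type photoinitiators (BP, 2-OHBP, 4-OHBP, 4-MBP, M2BB,
PBZ) migrating from food packaging.  The exposure metric is the average
daily dose

ADD = Σ_f C_f · IR_f · AF / BW × 10⁻⁶  (mg/kg bw/day),

summed over food categories f, with C in ng/g, IR in g/day, AF an absorption
fraction and BW in kg.  Each Monte Carlo iteration simulates one person: a
single body-weight draw is shared across categories, while concentrations
and intake rates are drawn independently per category (no between-category
intake correlation, no usual-intake decomposition).  Liquid foods are
treated at density 1 g/mL, so ng/mL ≡ ng/g.

Assumptions: intake rates are lognormal, body weights normal (nonpositive
body-weight draws are rejected and redrawn — a negligible-probability event
at realistic parameters), concentrations independent of consumption, and
AF = 1 for every analyte (conservative).

## Censored occurrence data

Survey measurements below the quantification (LOQ) or detection (LOD)
limit are handled by substitution, not by censored-likelihood fitting:
lower bound (LB) sets non-detects to 0, upper bound (UB) to the relevant
limit.  Detected values are identical under both bounds, so every LB
statistic is bounded by its UB counterpart, and for a fully detected
analyte (BP in the default survey) the two bounds coincide and a single
simulation run labelled `not_applicable` is reported.

Summary statistics (min/max/mean/SD/GM) are computed over detected values
only; the geometric mean over LB zeros is undefined.  The packaged survey
summary (`data/occurrence_summary.csv`) transcribes the published
362-sample survey table row for row; a few of its GM cells are internally
inconsistent with their own row (GM above the mean or maximum, e.g. M2BB in
fresh juice).  Those cells are preserved verbatim in the fixture but are
never used to parameterize or validate anything.

## Concentration sampling in the survey scenario

Per iteration and category, a concentration is drawn by resampling the
bounded occurrence values (default) or from a parametric family selected by
maximum likelihood plus a Kolmogorov–Smirnov comparison (normal vs
lognormal, larger KS p-value wins, ties to lognormal — the conventional
right-skewed family for concentrations).  The KS p-values are a selection
heuristic only; no correction for estimated parameters is applied.  Two
numerical notes:

- **Why empirical resampling is the default.**  The LB and UB versions of a
  sparsely detected analyte are different mixtures (zeros vs limit values
  plus the same detected tail), and the KS step can select *different*
  families for them (a normal for the zero-inflated LB, a lognormal for the
  UB).  Sampling from two different fitted families does not preserve the
  LB ≤ UB ordering of exposure quantiles — in practice the UB P97.5 can fall
  below the LB P97.5.  Empirical resampling with common random numbers
  (below) preserves the ordering exactly, and is transparent about what the
  data support.  Fitted sampling remains available (`sampling="fitted"`);
  negative draws from a normal fitted to zero-inflated data are clipped
  to 0.
- **Family discrimination power.**  When the coefficient of variation is
  small the lognormal converges to the normal, and the KS selector needs
  large samples to tell them apart (≈95% correct at n = 5,000 for a normal
  with cv = 0.05; ≈99% at n = 10,000 and essentially always at n = 20,000).
  The tests evaluate the selection-frequency property at sample sizes where
  the families are actually distinguishable.

## Random-number management

A single user seed is expanded into independent substreams keyed by hashed
stage labels (stage, scenario, analyte, age group), so adding a stage or
analyte never perturbs existing draws and every output is reproducible
byte-for-byte.  The stream key deliberately **omits the censoring bound**:
LB and UB runs of the same analyte × group share common random numbers, and
the empirical concentration sampler draws record *indices*, so the two runs
resample the same records and differ only in the substituted values.  This
makes lb ≤ ub hold pointwise across iterations and hence for every
statistic.  Empirical quantiles (P50, P97.5) use linear interpolation
between order statistics.

## Hazard registry

Points of departure and endpoints ship as validated YAML
(`data/hazard_registry.yaml`): BP — TDI 0.03 mg/kg bw/day, noncarcinogenic
kidney BMDL10 3.1 (the conservative end of the reported 3.1–7.4 band; the
value used as the primary POD), carcinogenic kidney BMDL10 18.5 (BP is
treated as a threshold carcinogen; no linear low-dose slope-factor risk is
computed); 4-MBP — BMDL10 3.1 by read-across with target MOE 200 (two extra
uncertainty factors); M2BB — NOAEL 31.25 (kidney degeneration/hyperplasia);
PBZ — NOAEL 300; 4-OHBP — NOAEL 100; 2-OHBP — no usable animal data,
screened by TTC as Cramer class III.  The proposed BP+4-OHBP group TDI of
0.01 mg/kg bw/day is stored as metadata only.  Exactly one profile per
analyte is primary and anchors verdicts.

TTC thresholds are 1800/540/90 µg/person/day for Cramer classes I/II/III,
converted at a default 60 kg adult body weight (class III:
1.5 µg = 0.0015 mg/kg bw/day); the body weight is configurable per run.

## Risk characterization

- **MOE** = POD/ADD, computed for P50 and P97.5 of each bound; acceptable
  iff MOE ≥ target (≥ is protective).  A zero dose yields an infinite,
  flagged MOE rather than an error.
- **MOE_T** combines the kidney-endpoint members {BP, 4-MBP, M2BB} as the
  reciprocal of the sum of reciprocals; the verdict threshold is the most
  stringent member target (200).  A member without LB/UB splits (BP)
  contributes its single `not_applicable` run to both bounds.
- **RISK21** cells compare the exposure band [P50, P97.5] with the POD band
  of each analyte: low concern when P97.5 × target ≤ lowest POD, high when
  P50 reaches the POD band, moderate otherwise.  The TDI is excluded from
  the POD band because it already embeds uncertainty factors.
- **TTC screening** uses the UB P97.5 dose against the class threshold with
  a strict `<` for "below threshold".

## Sensitivity analysis

Contribution to variance is the normalized squared Spearman rank
correlation of each stochastic input (BW, per-category IR, per-category C)
with the simulated dose, expressed in percent; correlations with
|r| < 0.01 are reported as exactly 0 to keep small contributions stable.
Contributions sum to 100% over the retained inputs; the sign of r is kept
(BW, which divides the dose, is negative).  Sensitivity is reported at the
conservative bound (UB, or the single run for fully detected analytes).
This is a rank-correlation decomposition, not a variance-based Sobol
analysis; with independent inputs and a monotone dose model the two agree
qualitatively.

## Synthetic survey generator

The generator emulates the study conditions so the pipeline is testable
without the original data:

- **Occurrence** — for each of the 8 categories (3 cereal classes, 3 juice
  classes, 2 milk classes; 362 samples in total) and each analyte, records
  are detected with the published per-pair detection rate; detected values
  follow a lognormal left-truncated at the LOQ (so data are consistent with
  their censoring flags); censored records split 50/50 between `<LOD` and
  `<LOQ` (configurable).  Lognormal parameters are derived from the
  published mean/GM pairs (GSD = exp√(2·ln(AM/GM)), clipped to [1.2, 4]);
  where the printed GM is inconsistent (GM ≥ AM) the distribution is
  re-anchored on the arithmetic mean with a default GSD of 1.5.  The LOQ is
  the reported "<" limit for censored rows, half the minimum detected value
  otherwise, and LOD = 0.3 × LOQ (signal-to-noise 3 vs 10).
- **2-OHBP** is absent from the published summary (detected too rarely to
  tabulate) but is required for the TTC path, so the default config adds
  *synthetic* low-detection specs for it in the liquid categories
  (detection 5–8%, GM 0.3–0.4 ng/g, LOQ 0.5 ng/g).
- **Population** — seven age groups (0–3 … >65) with normal body weights
  and lognormal per-category intake rates.  The national consumption-survey
  appendix behind the original analysis is not public, so these parameters
  are synthetic: plausible round numbers (e.g. toddlers 12.5 ± 1.8 kg,
  adults 64 ± 10 kg; categorical intakes of 6–60 g/day with GSD 1.5) chosen
  once so that the SML scenario lands on the reported exposure scale for
  the youngest group (P97.5 ≈ 1.1 × 10⁻² mg/kg bw/day).  Consequently the
  pipeline's *qualitative* outputs (verdict patterns, rankings, bound
  orderings) are meaningful reproductions, while absolute synthetic-survey
  percentiles should not be quoted as population estimates.

What passing tests show — and do not show — about real data: the suite
verifies the arithmetic, the censoring algebra, the Monte Carlo machinery
(against closed-form lognormal quantiles), parameter recovery, and the
end-to-end verdict pattern at survey-scale magnitudes.  It cannot validate
the true national intake distributions, between-food intake correlations,
or sampling weights, which the generator does not model.

## Problem sizes and numerical choices

Default runs use 10,000 iterations (P97.5 has a cross-seed coefficient of
variation below 5% at that size); closed-form Monte Carlo checks use
100,000.  Tests run reduced sizes (300–10,000 iterations) chosen for
stability of the asserted property.  Quantiles interpolate linearly;
degenerate (zero-variance) distribution specs are allowed and propagate
exactly; a constant occurrence sample cannot be fitted parametrically and
falls back to empirical (constant) sampling.  All result files are written
without timestamps so identical configurations reproduce byte-identical
output.

## Known limitations

- Substitution-based censoring only; no Tobit/maximum-likelihood censored
  fits.
- No correlation between food-category intakes; exposures for a "person"
  are independent across categories apart from the shared body weight.
- The Cramer classification of 2-OHBP is taken as given (class III); the
  structural decision tree itself is out of scope.
- RISK21 output is coordinates and classifications plus a basic plot, not
  a faithful reproduction of the published matrix graphics.
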