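# Methods

## Scope and units

The package implements a deterministic dietary exposure assessment for
heavy metals in brewed tea. Canonical units: made (dry) tea in mg/kg
(numerically µg/g), infusion/blank/spike concentrations in µg/L, EDI in
µg per kg body weight per day, HQ/HI/TR dimensionless. Each
measurement's matrix tag carries its unit, so leaf and infusion values
cannot be pooled accidentally. The single µg→mg conversion of the
pipeline happens inside `risk.tr`, because oral slope factors are
conventionally quoted per mg/kg bw/day while RfDs here are per µg/kg
bw/day.

## Exposure model

For a subpopulation the only consumption quantity that enters the
algebra is the ratio r = D/B_w (g tea per kg bw per day); profiles may
be specified as (D, B_w) or as r directly, and r is canonical
internally. EDI = C·T·r applies the brewing transfer rate T to the leaf
concentration: the assessment deliberately scores only what is released
into the infusion, not the leaf burden. All quantities are homogeneous
of degree 1 in C and in r, which the property tests exploit.

The hazard index is the plain **sum** of hazard quotients. A
sum-divided-by-n reading of the usual HI formula circulates in parts of
the literature, but the aggregate printed in the source tables this
package reproduces equals the column sum (male column: Σ = 5.76×10⁻²
% → printed 5.8×10⁻² %), and the sum is the standard USEPA aggregation;
dividing by n would understate multi-contaminant risk.

Bioavailability-adjusted quantities multiply HQ (and, for the
carcinogenic series, TR) by the element's oral absorption fraction
(Cu 40%, Pb 60%, Cr 1%, Cd 50%, Ni 10%). For TR this adjustment is an
interpretation — the published figure flags a "bioavailability
considered" series without giving its formula — and is labelled
`tr_adjusted` to keep it distinct.

## Back-derived consumption profiles

The consumption survey behind the published tables reported neither D
nor B_w. Because HQ = C·T·r/RfD is invertible, r is recoverable from
any printed HQ cell as r = HQ·RfD/(C·T). Back-solving r from all five
elements of one column agrees to CV ≈ 1.3% (< 3%), which validates both
the inversion and the interpretation of C as the leaf concentration
with T applied. The shipped default profiles use the Cu cells:

r (g/kg bw/day): male 2.25×10⁻³, female 1.49×10⁻³, urban 1.92×10⁻³,
rural 1.77×10⁻³, ages 18–40 1.77×10⁻³, age ≥ 41 2.40×10⁻³.

These are computed at call time from the shipped reference constants,
not hardcoded, so changing the reference data propagates.

## QC stage

LOD = 3× and LOQ = 10× the sample SD (n−1 denominator; the blank sets
are small, so the sample SD is the defensible estimator) of ≥ 2 reagent
blanks, giving LOQ/LOD = 10/3 exactly. Non-detects are substituted by
the element's LOQ by default — the conservative reporting rule the
monitoring campaign used — with half-LOQ and zero offered; per-element
means are monotone in the policy (LOQ ≥ half-LOQ ≥ zero), and the
censored flag survives substitution as provenance. Spike recovery is
(measured − base)/nominal × 100 with base ≈ 0 for reagent-grade
infusion blanks. The CRM check passes when the detected-vs-certified
bias is within k = 2 combined standard deviations.

## Synthetic data generator

The generator stands in for the unpublished raw data (91 leaf samples ×
5 elements, per-sample infusions, blanks, spikes, survey ratios). What
it emulates, and how:

- **Leaf concentrations**: lognormal (positive, right-skewed, consistent
  with the wide published ranges), truncated to the published range,
  with (µ, σ) solved — via the closed-form moments of the truncated
  lognormal and `scipy.optimize.least_squares` — so the distribution
  **after truncation** carries the published mean/SD exactly. Fitting
  the untruncated moments and then truncating (the naive recipe) would
  bias the Cu mean ≈ 4% low and shrink SDs well beyond the 1%
  moment-recovery contract the tests enforce. Sampling is exact
  (truncated normal on the log scale), no rejection loop.
- **The Ni exception**: no lognormal confined to the published Ni range
  1.02–2.93 mg/kg can reach SD 0.70 mg/kg at mean 1.90 (the family maxes
  out near 0.55 there; even distribution-free the bound is ≈ 0.95 and
  requires bimodality). The published Ni range/SD pair is therefore
  internally inconsistent if the range is read as a support. A reported
  range is a 91-sample min/max, not a support, so when the truncated
  moment match is infeasible the generator falls back to the
  untruncated moment-matched lognormal; the moment contract always
  holds, and for Ni ≈ 14% of draws fall outside the printed min/max,
  as real resampling would produce.
- **Censoring**: `nd_fraction` (default 5% for Cd, whose published range
  bottoms out at "not detected"; no count was published, so a small
  realistic fraction was fixed once) sets the quantile of the fitted
  distribution below which draws are emitted as censored non-detects.
- **Transfer rates**: logit-normal — strictly inside (0, 1) — with
  moments matched by 101-node Gauss–Hermite quadrature. No dispersion
  was published; the SD defaults to 0.3× the mean, configurable.
  Infusion concentrations follow deterministically through the brewing
  algebra, so per-sample transfer rates computed back from the pair
  recover the configured distribution.
- **QC batches**: 10 blanks per element standardized to the exact
  sample SD implied by the published LODs (so blank-derived limits
  reproduce the published table to the digit) with a +5×SD offset
  keeping values positive; spikes at 10/50/100 µg/L with recoveries
  jittered ±1 percentage point around the published values.
- **Seeding**: one master seed split into per-element
  `numpy.random.SeedSequence` substreams; output is deterministic given
  the seed and insensitive to element order.

What the generator does **not** emulate: inter-element correlation,
plantation/region covariates, steep-time kinetics, instrument drift.
Passing tests therefore demonstrate the pipeline's arithmetic and its
statistical contracts, not field realism of any single simulated value.

## Numerical and reporting choices

- Full double precision everywhere inside; rounding only at the report
  layer.
- Report cells: percent scale, 2 significant figures, scientific
  notation ("1.7 x 10^-2"). Rounding goes through `Decimal(repr(x))`
  with ROUND_HALF_UP: the repr round-trip collapses binary noise to the
  shortest decimal, so a decimally half-way column sum (0.0455) rounds
  up to 4.6×10⁻² as a desk calculation would, instead of falling to the
  binary-below side.
- Agreement with a 2-sig-fig printed value is tested as |computed −
  printed| ≤ half a unit in the printed value's last digit; where the
  computation's *input* is itself a rounded printed value, its
  propagated half-ulp is added. This is an error-propagation bound, not
  a loosened tolerance.
- Degenerate inputs: zero leaf concentration makes the transfer rate an
  error (not infinity); transfer rates above 1 are allowed but flagged
  (measurement noise); zero transfer SD degenerates to the exact mean
  rate; empty element sets are errors for HI and TR totals.

## Known inconsistencies in the published tables

Reproduced faithfully rather than patched:

- The published Cd TR for the ≥ 41 group (1.60×10⁻⁵) is ~50× what the
  risk equation yields from the Cd EDI implied by the same table
  (≈ 3.2×10⁻⁷); consequently the "Cd contributes ≈ 97% of cancer risk"
  claim is not reproducible under consistent arithmetic (this package
  computes ≈ 55% for Cd). The package computes the equation
  consistently and makes no attempt to match the anomalous value.
- The published "minimum TR" (Cr, female, 1.62×10⁻⁷) is the Cr minimum
  but not the global one: Pb's small slope factor (0.0085) puts its TRs
  near 5×10⁻⁹.
- The adjusted-HI "decreased by approximately 20%" narrative conflicts
  with the printed values (the decrease is ≈ 72%); not used.
- Two printed adjusted-HQ cells (Cu male, and Pb urban under the
  printed-HQ × bioavailability route) are rounding casualties of
  double rounding; documented in the tests.

## Problem sizes

Tests and the acceptance script run the survey at its native n = 91;
generator moment contracts are additionally checked at n = 100 000,
where a 1% band is ≥ 3 standard errors for every element. Everything is
desk-scale: the full suite runs in seconds.

## Limitations

Deterministic point estimates only — no Monte-Carlo uncertainty
propagation, no multi-pathway aggregation (water, rice, vegetables),
no metal speciation (total Cr stands in for Cr(III)/Cr(VI)), and no
leaching kinetics beyond the single fixed brew.
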