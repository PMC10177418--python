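# Methods

## The forward model: what a synthetic lane is

A lane is a 1-D densitometric trace of `profile_length` samples
(default 1200), index 0 at the well, migration increasing down the
lane.  Each protein of molecular weight M (kDa) is placed at relative
migration Rf given by a cubic polynomial in x = log10(M):

    Rf(x) = 1.79788 − 1.05288·x + 0.255·x² − 0.05·x³

chosen strictly decreasing on the 10–250 kDa working range of a 4–20%
gradient gel, with Rf(250 kDa) = 0.05 and Rf(10 kDa) = 0.95.  Rf is
normalized to the dye front, taken as the profile end when no front is
marked; the band center in samples is Rf·(profile_length − 1).

Each band is a Gaussian of fixed width σ = 6 samples whose **area**
follows a saturating stain-response:

    A(c) = s_max · c / (c + k_half),   s_max = 3000 signal units,
                                       k_half = 150 mg/L.

The hyperbolic form reflects the visible saturation of Coomassie
staining at high load while staying linear (slope s_max/k_half = 20
units per mg/L) at low concentrations, and it inverts uniquely.  A
per-protein `stain_scales` factor exposes the non-uniformity of
Coomassie binding across proteins (default 1).  The lane adds a smooth
linear background (6 → 3 units) and white Gaussian noise of sd 1.0
units per sample.

### The calibrated detection regime

The noise level is the one free parameter of the regime and is set so
that the canonical 8-step 2-fold albumin dilution series (200 →
1.5625 mg/L) loses detectability between the 3.12 and 1.56 mg/L steps:
with σ = 6 and noise 1.0, the raw band SNR (peak amplitude over
per-sample noise) is A(c)/(σ√(2π)·noise), i.e. 4.06 at 3.12 mg/L and
2.05 at 1.56 mg/L, straddling the conventional k = 3 detection
criterion.  The closed-form limit of detection under this regime is

    LOD = k_half · T / (s_max − T),  T = 3·noise·σ·√(2π)  →  2.29 mg/L,

inside the (1.56, 3.12] interval the dilution design brackets.  The
sampling density (1200 samples, σ = 6) was chosen so that the
matched-filter amplitude estimator is precise enough for the
detect-at-3.12 / reject-at-1.56 decision to be reproducible across
noise realizations; it corresponds to a flatbed scan at ordinary
resolution, not a limit of the method.

### Cohort templates

`generate_cohort` draws truth patterns from caller-supplied weights and
builds compositions per pattern: normal = albumin 5–25 mg/L alone;
glomerular = albumin 250–400 mg/L plus transferrin (trace 4–4.3 mg/L
for grade 1, 80–160 mg/L for grades 2–3, ceruloplasmin added for
grade 3); tubular = α1-microglobulin precursor (AMBP, 38.97 kDa),
Zn-α2-glycoprotein (34.24) and retinol-binding protein 4 (22.99), with
cystatin C (15.79) and β2-microglobulin (13.71) added for the "lower"
type; mixed = both sets; FLC overload = the 46/23 kDa dimer/monomer
pair.  Concentrations keep every evidence band at SNR ≥ 5.  eGFR
metadata is lognormal per pattern (medians 95/66/71/31/45 for
normal/glomerular/upper/lower/mixed), encoding the clinical gradient
that "upper" tubular patients usually keep eGFR ≥ 60 while "lower"
patients usually do not.  ICD-10 codes are drawn from small
per-pattern pools.

What the generator does **not** emulate: lane warping and smiling,
streaking, variable band widths, spatially correlated scanner noise,
proteolytic degradation products, and the crowded minor-protein
background of real urine.  Passing recovery tests therefore shows the
analysis chain is correct and self-consistent under the stated noise
model — not that the classifier's error rate on scanned patient gels
is ≤ 5%.

## Densitometry

Images load inverted (dark bands on a light scan become positive
signal); lanes are contiguous runs of above-threshold columns averaged
across their width.  Background subtraction opens the lightly
pre-smoothed profile with a flat structuring element (default 101
samples): the rolling-minimum/maximum pair removes features narrower
than the window.  Because an opening cannot pass below the uphill side
of a peak on a sloped background, samples where the smoothed profile
exceeds the rough baseline by > 3× noise are excised and the baseline
linearly re-interpolated from the flanks; this makes the subtraction
exact for linear backgrounds and idempotent.  Noise is estimated from
the median absolute first difference of the *unclipped* residual
(zero-clipping first would bias the estimate toward zero); the output
profile is clipped at 0.

Band calling smooths with a Gaussian of σ = 6 samples (a matched
filter at the default band width), finds local maxima, and gates on
prominence and SNR.  The amplitude estimate divides the smoothed peak
by the known attenuation σ_band/√(σ_band² + σ_smooth²) and subtracts
any background pedestal in excess of the clipped-noise floor
(mean 0.399·sd).  Default `min_snr` = 3 — the conventional detection
criterion, consistent with the regime calibration above.  Overlapping
peaks split at the local minimum between them, which keeps the
detected-band count non-increasing in the prominence threshold; the
integrated signal is the trapezoidal area of the raw background-free
profile between the surrounding minima.

## MW calibration

`fit_mw_curve` least-squares fits log10(MW) as a polynomial in Rf
(default degree 3 — gradient gels are nonlinear in log-MW; linear and
polynomial fits are both standard).  Monotonicity is verified on a
512-point grid of the fitted range; a non-monotone fit falls back one
degree with a warning.  Commercial prestained standards migrate
differently from urinary proteins (the albumin fraction reads low
against a commercial curve), so `calibrate_internal` applies an affine
correction in log10-MW space anchored on proteins known to be present
— albumin 69.23 kDa and the FLC dimer/monomer at 46/23 kDa: one anchor
fixes an offset, two or more fit offset+scale by least squares, which
can only reduce the anchor residuals.  Anchors match bands through the
local slope of the curve so the matching tolerance is a migration
tolerance (default 0.05 Rf).

## Annotation

The packaged reference table lists the dominant proteins of the 15
fractions of a low-MW-rich urine sample (with PSM counts from in-gel
LC-MS/MS identification) plus two curated overload entries (FLC dimer
46 kDa, ovalbumin 45 kDa), categorized as glomerular, tubular or
overload indicators.  `match_bands` reports *all* reference proteins
within relative MW tolerance (default 0.10), nearest first — fractions
genuinely contain co-migrating proteins and forcing uniqueness would
fabricate certainty.  `shortlist_fraction_proteins` is the candidate
filter for fraction identification: keep candidates within `mw_rel_tol`
(default 0.25 — "similar MW" is not sharply defined) of the fraction
MW with PSM ≥ `min_psm` (default 10), sorted by PSM, ties stable.

## Classification

"Trace" and "intense" are operationalized as fractions of the total
integrated lane signal: trace < 5%, intense ≥ 20% (both configurable).
This is the largest interpretive gap between a visual read and an
algorithm, and every report carries the thresholds used.  The rules,
in order, on bands with calibrated MWs (post internal-anchor
correction, since the commercial-curve bias would otherwise shift the
20-kDa split):

1. LMW component: any non-trace band below the albumin window
   (62–75 kDa), excluding FLC-signature bands only when the lane is
   FLC-pure (dimer+monomer and nothing else below albumin) — tubular
   patterns involve several LMW proteins, not just light chains.
2. Glomerular component: albumin above trace AND ≥ 1 band above the
   albumin window (transferrin, 75–85 kDa, or higher).
3. Both ⇒ mixed; only (1) ⇒ tubular; only (2) ⇒ glomerular; neither ⇒
   normal.  An intense lone albumin band with no higher-MW companion
   is still "normal" under these rules (rule 2 requires the
   higher band); it is annotated "isolated albuminuria".
4. Tubular sublabel: "lower" iff any LMW evidence band < 20 kDa,
   else "upper".
5. Glomerular grade: 1 with non-intense transferrin, 2 with intense
   transferrin, 3 = grade 2 plus any band above the transferrin
   window.  A glomerular call established by a > 85 kDa band without
   transferrin grades 1 (the mildest definable), so adding bands never
   lowers the grade.
6. Overload flags, independent of the primary label: FLC iff a
   co-dominant ~46 + ~23 kDa pair (each above trace); hemoglobin β
   (15.99), myoglobin (17.17), lysozyme (16.53) and ovalbumin (45.0)
   iff a band within 3% relative MW at ≥ intense fraction.  The three
   ~16–17 kDa proteins are distinguishable at their exact MWs under
   the 3% tolerance but an intermediate estimate flags every
   compatible protein with a co-migration note — mobility alone cannot
   separate them.  Ovalbumin is suppressed when the 45–46 kDa band is
   accounted for by the FLC dimer signature.

## Quantification

`fit_concentration_curve` fits the saturating model (or a
through-origin line) to (concentration, signal) points;
`estimate_concentration` inverts it in closed form and qualifies the
result (`quantified` / `below_LOD` / `above_range`).  Estimates from
an albumin curve are labelled albumin-equivalent.  `estimate_lod`
defines the LOD as the smallest concentration whose predicted signal
reaches k × noise (default k = 3) — the empirical visual LOD of a
dilution series has no formula, so the conventional 3-sigma criterion
stands in; for a linear response this is exactly k·σ/slope.

## Cohort statistics

2×2 tables route to the Fisher exact test iff the minimum expected
count is < 5 (exactly 5 stays with Pearson); the Pearson statistic is
the classic Σ(O−E)²/E without continuity correction — the choice that
reproduces the published p-values from the printed counts.  The
two-sided Fisher p follows the probability-mass convention, computed
by exact integer enumeration: with fixed margins all candidate tables
share the denominator C(n, c1), so "no more probable than observed" is
an exact integer comparison of numerators C(r1,k)·C(r2,c1−k), immune
to floating-point ties.  Rank comparisons use Mann–Whitney (exact null
distribution for small untied samples, tie-corrected normal
approximation otherwise) or Kruskal–Wallis for ≥ 3 groups.  No
multiple-testing correction is applied.  Report percentages are always
recomputed from counts; p-values display with 1 decimal above 0.2 and
3 decimals below, the mixed precision of clinical tables.

Cohort-level quantities that exist only as published aggregates
(per-patient eGFR distributions, empirical albumin detection rates)
cannot be recomputed without raw patient data; the test suite instead
verifies that every summary the package reports is derived from the
supplied per-sample inputs at run time.

## Problem sizes and numerical choices

The test suite uses 500 lanes for classifier recovery, 300 for the
densitometry precision/recall property (500 in the acceptance script),
100 seeded replicates for the dilution-series detection rates, and
full enumeration of all 2×2 tables with total ≤ 30 for the Fisher
oracle.  Degenerate inputs are defined, not special-cased: an empty
composition yields background+noise and an empty truth; an empty band
list classifies as normal with a zero-evidence note; a blank image
yields no lanes.  All generator randomness flows from explicit integer
seeds; identical inputs and seed reproduce bit-identical profiles.

## Known limitations

* The classifier thresholds (trace/intense fractions, MW windows)
  mirror a visual convention; they are defensible defaults, not fitted
  constants.
* Mixed lanes with a *weak* glomerular or tubular component near the
  trace threshold flip between labels by construction; the cohort
  templates avoid that boundary, real samples will not.
* MW-based overload flags are suggestive only where proteins co-migrate
  (hemoglobin β / lysozyme / cystatin C around 16 kDa).
* Semiquantification across proteins inherits the non-uniformity of
  Coomassie staining; only albumin-equivalent values are reported
  unless a per-protein curve is supplied.
* The image pipeline assumes straight, vertical, non-overlapping lanes;
  warping correction is out of scope.
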