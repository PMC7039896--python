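# Methods

## Models and conventions

Angles are degrees, zero at the round window, increasing apically
(360° = one turn); lengths are millimetres. Both cochlear models evaluate
the duct length along the path of a lateral-wall electrode array, a fixed
offset inside the bony lateral wall.

**Adopted Escudé.** `CDL_i(θ) = p1 (A − 2·offset) ln(1 + θ/p2)` with
`p1 = 2.62`, `p2 = 235°`, offset 0.5 mm. The inversion is closed-form
(`θ = p2 (e^{L/(p1(A−2·offset))} − 1)`) and reproduces the forward length to
better than 1e−9 mm. An effective diameter `A − 2·offset ≤ 0` is a domain
error that names the offending A and offset.

**Elliptic-Circular Approximation (ECA).** The basal-turn length at
electrode level is `BTL_i = 1.18A′ + 2.69B′ − √(0.72A′B′)` with
`X′ = X − 2·0.35`; the duct length at angle θ is
`CDL_i(θ) = p_BTL(θ)/100 · BTL_i`, where
`p_BTL(θ) = 8.3·10⁻⁸θ³ − 2.4·10⁻⁴θ² + 0.34θ + 3.7` is a *percentage* of the
basal-turn length. The /100 follows from the percentage semantics and the
magnitude of the polynomial (3.7 → ~176 over [0°, 900°]); without it the
duct would exceed the basal turn a hundredfold. The polynomial's derivative
has negative discriminant, so it is strictly increasing on the whole valid
domain; the tests verify this on the 1° grid.

**Valid angular domain.** Fixed to [0°, 900°] — the tabulated range of the
percentage fit. Requests outside raise; nothing extrapolates.

**Round-window artefact.** `p_BTL(0) = 3.7 ≠ 0`, so the ECA length does not
vanish at the round window: `CDL(0) = 0.037·BTL ≈ 0.75 mm` for a typical
cochlea. This is a property of the published fit, not of this
implementation; it is *not* renormalised. Consequently `invert_eca` rejects
lengths below `CDL(0)` with a range error naming the minimum representable
length, rather than clipping to 0°.

**ECA inversion.** Bracketed Brent root finding on [0°, 900°] against the
target percentage (equivalent to a length tolerance far below 1e−6 mm,
`xtol = 1e−10°`). Monotonicity of the cubic guarantees a unique root. An
independent check used in the tests: linear interpolation of the 1°-step
percentage table agrees with the root finder to within 0.01°.

**Wall-offset sensitivity.** Both offsets are `ModelParams` fields
(`escude_offset = 0.5`, `eca_offset = 0.35` mm), so running the Escudé model
with the ECA's 0.35 mm offset is a parameter change. A smaller offset
lengthens the modelled duct and therefore shrinks the predicted angle for a
fixed electrode length, reducing the Escudé model's overestimation.

**Electrode.** `ElectrodeSpec(total_length, c1_to_stopper, tip_to_c1)` with
the consistency invariant `total = c1_to_stopper + tip_to_c1`; FLEX28
(28.0/26.8/1.2 mm) is built in, other arrays load from a key=value file.
Predictions assume a full insertion with the stopper at the round window;
partial insertion lives only on the observed side. Geometries whose
modelled duct at 900° is shorter than the array raise a
`FullInsertionError` carrying the maximum modellable length, and the cohort
pipeline excludes such rows with a logged reason and an explicit count.

## Validation statistics

Errors follow `actual − predicted` (negative = overestimation) in both the
angular and the linear domain; the observed angle is converted to a linear
depth through the *same* model's forward evaluation on the subject's own
measured geometry. Tip-referenced readings convert to C1 via the 1.2 mm
linear offset plus model inversion, which requires the geometry columns.
Summaries take the absolute value per record first, then average (mean and
SD of |error|), with signed means kept alongside. All SDs are sample SDs
(ddof = 1): the convention is never stated in the clinical literature this
mirrors, and n−1 is the default there; a single-record group therefore has
an undefined (NaN) SD rather than 0.

`exceedance_report` summarises how often the actual insertion exceeds the
prediction: empirical fractions above 0 and above a stated bound, plus the
fitted-normal tail probabilities at both points, plus the generic one- and
two-SD one-sided normal tails (15.87 % / 2.28 %). The latter pair is
reported because "about 16 % / 2.5 %" exceedance claims in the clinical
literature are one- and two-SD tail statements; note that a fitted normal
with mean −0.58 mm and SD 1.19 mm actually places 31 % of its mass above
zero, so the two readings differ and both are exposed.

## Agreement statistics

**Bland–Altman.** Differences `value_1 − value_2`, limits of agreement at
mean ± **2**·SD exactly (not 1.96), matching the 2-SD convention of the
plots this reproduces. Plot data (difference vs average plus the three
lines) is exported as CSV; no figure rendering is required for correctness.

**ICC.** Computed from the two-way ANOVA mean squares of the n×k rating
matrix. Default form: two-way random effects, absolute agreement, single
measures (Shrout–Fleiss ICC(2,1)) — observers are a random sample of
possible raters and the clinical question is absolute agreement. The form
is configurable (`icc1/2/3`, `k`-suffixed average-measures variants) and
recorded in every report. Qualitative labels use the Landis–Koch bands
(≤0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect; <0 poor). Zero total variance raises (ICC
undefined). The implementation is checked against pingouin's independent
ANOVA implementation to 1e−10.

**Wilcoxon signed-rank.** The method comparison is a two-sided paired test
on per-subject *absolute inter-observer disagreement* under the two models.
(The clinical phrasing "the SD of the differences reduced significantly
(Wilcoxon)" is not literally a paired test on SDs; this per-subject
construction is the documented choice, not asserted as the original one.)
For n ≤ 25 without ties the exact permutation distribution is used. The
large-sample path is a refined normal approximation computed from the
realised ranks — tie-robust moments (`Var = Σr²/4`), continuity correction,
and a fourth-cumulant Edgeworth term — because the plain normal
approximation deviates from exact enumeration by up to ~0.04 at n = 12
while the corrected one stays within ~0.002. All-zero differences return
p = 1 with a warning.

## Synthetic cohort design

The generator emulates a two-observer, two-observation CT measurement study
with postoperative validation; defaults are the emulated study conditions:

| parameter | default | basis |
|---|---|---|
| subjects | 46 | study design |
| true A | N(9.1, 0.4²) mm | assumption spanning the clinical range |
| true B | N(6.8, 0.4²) mm, ρ(A,B)=0.5 | assumption |
| truncation | A∈[7,11], B∈[5,8], A>B | rejection sampling, cap 1000 |
| per-measurement σ_A | 0.47/√2, 0.53/√2 mm (obs 1, 2) | back-calculated from reported intra-observer difference SDs (difference of two independent reads has SD σ√2) |
| per-measurement σ_B | 0.40/√2, 0.44/√2 mm | same |
| inter-observer bias | +0.12 (A), +0.10 (B) mm on observer 2 | reproduces reported observer-1−observer-2 mean differences of −0.12/−0.10 mm |
| insertion shortfall | truncated-at-0 N(0.58, 0.5²) mm | mean = reported average underestimation; spread consistent with a stopper-seating error of up to 1–2 mm |
| postop angle noise | 10° SD per observer | assumption; no postoperative repeatability is reported |
| generating model | ECA | named explicitly so recovery tests have unambiguous truth |

Actual insertions are generated by inverting the *generating model* on the
subject's true geometry at `26.8 mm − shortfall`; per-observer C1 readings
add the angular noise, and the tip reading follows from the noisy C1
reading through the generating model (+1.2 mm), mirroring how postoperative
tip depths are derived from C1 in practice. With every noise source zeroed
(`config.noise_free()`), measured = true, the actual linear depth is
exactly 26.8 mm, and the generating model's downstream errors are exactly
zero — the pipeline's self-consistency anchor.

All randomness flows through a single `numpy.random.default_rng(seed)`;
a fixed seed reproduces the cohort byte-identically.

**What the generator does not emulate — and what passing tests therefore do
not show.** Observer errors are independent across observers and across the
A/B axes. On real images the two observers share the same slice geometry and
an axis-placement error trades off between A and B, so real inter-observer
disagreement in ECA predictions is plausibly *smaller* than this generator
produces: the generator reproduces the *ordering* (ECA more reproducible
than Escudé, in the majority of replicate cohorts) but a weaker ICC gap
than a real cohort may show. Likewise no micro-blockages, electrode
bending, round-window-niche anatomy beyond the scalar shortfall, partial
insertions, malformed cochleae, or CT-resolution effects. Parameter-recovery
results on this generator validate the pipeline's statistics, not the
clinical accuracy of either model.

## Problem sizes

Tests and the acceptance script use the study-design cohort size (n = 46)
for pipeline runs, n = 500 for noise-calibration checks (√2-law recovery
within 15 %), 100 replicate seeds for the accuracy-ordering rate and 15 for
the ICC-ordering majority, and 2¹² enumeration for the Wilcoxon oracle.

## Known limitations

- The ECA percentage polynomial is an empirical fit; below ~0.75 mm of
  insertion it has no inverse (see the round-window artefact above).
- Escudé predictions are undefined for very small cochleae when the array
  is longer than the modelled duct at 900°; such subjects are excluded and
  counted rather than extrapolated.
- The Wilcoxon construction for "method variability" is one defensible
  reading of an ambiguous clinical convention (see above).
- Real per-subject clinical data is not redistributed with the package; all
  committed fixtures are synthetic (`tests/data/synthetic_cohort_n10_*`).
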