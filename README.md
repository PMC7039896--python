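# cochleaplan

Preoperative prediction of cochlear-implant electrode insertion depth from
two basal-turn CT measurements, with postoperative validation and
observer-agreement statistics.

## The problem

Before cochlear implantation, surgeons estimate how deep a lateral-wall
electrode array will sit inside the cochlear duct. The cochlea is highly
variable in size, but its basal turn is well visible on clinical CT: on an
oblique "cochlear view" one measures the basal-turn **diameter A** (round
window → helicotrema → opposite lateral wall) and the perpendicular
**width B**. `cochleaplan` converts these two lengths into the predicted
**angular insertion depth** (degrees past the round window; 360° = one turn)
of a given array under two analytical cochlear models, and evaluates such
predictions against postoperative readings.

## The models

Both models describe the duct length at the level of a lateral-wall
electrode array, a fixed offset inside the bony lateral wall:

* **Adopted Escudé** (offset 0.5 mm), a logarithmic spiral driven by A only:

  `CDL_i(θ) = 2.62 · (A − 2·0.5) · ln(1 + θ/235°)`  [mm]

  Inverted in closed form: `θ = 235° · (exp(L / (2.62(A−1))) − 1)`.

* **Elliptic-Circular Approximation (ECA)** (offset 0.35 mm), driven by A
  and B. The basal-turn length at electrode level is

  `BTL_i = 1.18·A′ + 2.69·B′ − √(0.72·A′·B′)`, `X′ = X − 2·0.35`,

  and the duct length at angle θ is a percentage of it,
  `CDL_i(θ) = p_BTL(θ)/100 · BTL_i`, with the cubic
  `p_BTL(θ) = 8.3·10⁻⁸θ³ − 2.4·10⁻⁴θ² + 0.34θ + 3.7` (strictly increasing on
  [0°, 900°]). The ECA is inverted by bracketed root finding.

An electrode array is described by its tip-to-stopper length, the
first-contact (C1) to stopper length, and the silicone tip segment
(FLEX28: 28.0 / 26.8 / 1.2 mm, built in). Predictions place the stopper at
the round window and invert the C1 and tip lengths to angles. Validation
follows the convention *error = actual − predicted*, so overestimation shows
up as a negative signed error; summaries report mean and SD of absolute
errors per observer and model. Agreement analysis provides Bland–Altman
statistics (limits of agreement at mean ± 2·SD), the intraclass correlation
(two-way random effects, absolute agreement, single measures by default)
with Landis–Koch labels, and a paired Wilcoxon signed-rank comparison of the
two models' per-subject observer disagreement.

## Worked example

```python
from cochleaplan import CochlearGeometry, flex28_spec, predict_insertion

g = CochlearGeometry(A=9.2, B=6.8)   # mm, measured on the cochlear view
for model in ("escude", "eca"):
    p = predict_insertion(g, flex28_spec(), model)
    print(f"{model:7s} C1: {p.angular_c1:6.1f} deg ({p.angular_c1/360:.2f} turns)"
          f"   tip: {p.angular_tip:6.1f} deg ({p.angular_tip/360:.2f} turns)")
```

prints

```
escude  C1:  583.1 deg (1.62 turns)   tip:  630.1 deg (1.75 turns)
eca     C1:  549.5 deg (1.53 turns)   tip:  589.5 deg (1.64 turns)
```

i.e. for this cochlea the Escudé model predicts the first contact about one
and five-eighths turns past the round window, while the ECA — which also
uses the width B — predicts a shallower insertion by roughly 34°. The tip
sits 1.2 mm (here ~40–47°) beyond C1.

Cohort-level analysis uses the statsmodels-style model/results pair:

```python
from cochleaplan import InsertionStudy, default_study_config, generate_cohort

cohort = generate_cohort(default_study_config(seed=1))   # synthetic study
res = InsertionStudy.from_cohort(cohort).fit()
print(res.summary())                 # error tables + agreement report
res.pooled_mean_abs_linear_error("eca")                  # e.g. 0.92 mm
```

`InsertionStudy` equally accepts real measurement/observation CSVs
(`InsertionStudy.from_csv(...)`; schemas in `cochleaplan.io`).

## Command line

```bash
cochleaplan simulate --n 46 --seed 1 --out-dir cohort/
cochleaplan predict --measurements cohort/measurements.csv --out pred.csv
cochleaplan error --measurements cohort/measurements.csv \
                  --observations cohort/observations.csv --out-dir results/
cochleaplan agreement --measurements cohort/measurements.csv \
                  --observations cohort/observations.csv --out-dir results/
cochleaplan pbtl-table --out pbtl.csv     # 1–900° percentage table
```

All analysis commands accept `--model {escude,eca,both}`,
`--escude-offset`, `--eca-offset` (e.g. the 0.35 mm Escudé sensitivity
variant) and `--electrode <key=value file>`. Exit codes: 0 success,
2 schema error, 3 computation error.

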