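# aortapwv

Local and regional **aortic pulse wave velocity (PWV)** analysis: foot-to-foot
transit-time estimation on velocity and pressure waveforms, centerline-chord
velocity sampling for in-plane velocity-encoded CMR, Bramwell–Hill
distensibility modeling, and the paired method-agreement statistics used to
validate one PWV method against another.

## Who this is for

Cardiovascular imaging and hemodynamics researchers who estimate aortic wall
stiffness from wave propagation — from velocity-encoded CMR (through-plane or
in-plane), from invasive catheter-pullback pressure recordings, or indirectly
from luminal area distension and pulse pressure — and need a tested, scripted
pipeline for the estimators and for the agreement battery that compares them.
A built-in synthetic cohort generator produces all of these data streams from
a known ground truth, so every estimator can be validated end to end.

## The model

PWV is the propagation speed of the systolic wave front,

```
PWV = Δx / Δt
```

with Δx the aortic path length between measurement sites and Δt the
foot-to-foot transit time of the systolic onset (the "foot", minimally
disturbed by reflected waves). With dense spatial sampling — 200 chords
perpendicular to the aortic centerline, or a stepwise catheter pullback at
5.8 cm spacing — the transit-time relation becomes a regression in the
distance–time plane, `onset(s) = α + β·s`, with `PWV = 1/β`.

The Bramwell–Hill model links PWV to vessel compliance:

```
PWV = (ρ · D)^(-1/2),      D = ΔA / (A_min · ΔP)
```

with ρ the blood density (1059 kg·m⁻³), D the distensibility, ΔA the
systolic–diastolic luminal area change, A_min the minimal area and ΔP the
local pulse pressure (1 mmHg = 133.322 Pa). The model inverts to estimate the
local pulse pressure from a measured PWV and area distension.

Velocity feet are detected as the intersection of a horizontal line modeling
the constant diastolic flow with the regression line through the systolic
upslope samples within 20–80% of the total range; pressure feet as the
minimal pressure prior to the systolic upslope. Method agreement is assessed
with Pearson correlation, coefficient of variation, mean unsigned error,
paired t-test with t-based 95% CI, Bland–Altman limits of agreement, and an
interaction-regression contrast of two methods' slopes on a common gold
standard.

## Worked example

Distensibility and modeled PWV for a vessel with ΔA = 50 mm², A_min =
400 mm², ΔP = 50 mmHg:

```sh
$ aortapwv bh --delta-a 50 --a-min 400 --delta-p 50
{
  "A_min_mm2": 400.0,
  "D_e-3_per_mmHg": 2.4999999999999996,
  "D_per_Pa": 1.8751593885480263e-05,
  "delta_A_mm2": 50.0,
  "delta_P_mmHg": 50.0,
  "pwv_m_per_s": 7.0963156595211885,
  "rho_kg_per_m3": 1059.0
}
```

The relative area change per unit pressure is D = (50/400)/(50·133.322 Pa)
= 1.875·10⁻⁵ Pa⁻¹ (2.5·10⁻³ mmHg⁻¹), and the wave speed this compliance
supports is (1059 · 1.875·10⁻⁵)^(-1/2) = 7.10 m/s.

Simulate a 17-subject cohort with known truth and run the full comparison
battery (every PWV variant against the pressure gold standard):

```sh
$ aortapwv simulate --n 17 --seed 42 --out demo/
$ aortapwv reproduce-study demo/
report written to demo/report (n_used=17/17)
```

Summarising `demo/report/agreement.csv`, per comparison (seed 42):

```
bh_cath_vs_pressure_local            r=0.90  mean diff=-0.06 +- 0.75 m/s  COV=10%  MUE=9%
bh_cuff_vs_pressure_local            r=0.82  mean diff=-0.90 +- 1.01 m/s  COV=15%  MUE=15%
ip_local_vs_pressure_local           r=0.87  mean diff=+0.11 +- 0.89 m/s  COV=12%  MUE=10%
ip_regional_vs_pressure_regional     r=0.82  mean diff=+0.14 +- 0.85 m/s  COV=13%  MUE=11%
tp_regional_vs_pressure_regional     r=0.44  mean diff=-0.20 +- 1.58 m/s  COV=24%  MUE=18%
```

Reading these: the dense local in-plane estimator tracks the invasive gold
standard far better than the two-site through-plane one (r 0.87 vs 0.44),
and the Bramwell–Hill modeled PWV computed from the biased brachial-cuff
pulse pressure underestimates the pressure-assessed PWV (mean difference
−0.90 m/s) more than the catheter-based one (−0.06 m/s) — the directional
behavior expected from the model and the measurement chain.

`demo/report/` also contains `report.json`, `per_subject.csv`,
`association.csv` (each PWV variant against distensibility^(-1/2) for both
pulse-pressure sources) and Bland–Altman/scatter plots; every output carries
the seed and a config hash for provenance.

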