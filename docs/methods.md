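# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `aortapwv`. It states how quantities are computed; every
empirical claim about performance is one that the test suite or
`scripts/acceptance.py` computes itself.

## Foot-to-foot transit-time estimation

The systolic wave front's onset ("foot") is the transit-time landmark because
it is minimally contaminated by reflected waves, which corrupt peak- or
pressure-amplitude-based timing.

**Velocity waveforms** (`detect_onset_velocity`). Within one cardiac cycle
(time zero at the ECG R-wave) the algorithm:

1. finds the systolic peak (earliest sample on ties) and the pre-peak cyclic
   minimum `v_tr`; the total range is `R = v_pk − v_tr`. If `R` is below 5%
   of the waveform's absolute maximum (configurable) the curve is flat and
   `NoUpslopeError` is raised;
2. anchors the rising limb at the last pre-peak sample at or below
   `v_tr + 0.2R`. Anchoring at the raw argmin instead would let a noise dip
   anywhere in diastole pull the baseline window onto the systolic decay —
   this choice is what makes the detector robust at realistic noise;
3. locates the 20% and 80% threshold crossings by linear interpolation and
   fits a least-squares line through the two interpolated crossing points
   plus every raw sample strictly between them. Including the crossings as
   anchor points keeps the fit well-posed at CMR temporal resolution
   (35 phases/cycle leaves only ~2 raw samples inside the band);
   `InsufficientSamplesError` if fewer than 3 fit points remain;
4. estimates the diastolic baseline as the median over the cyclic window
   covering the final 20% of the RR interval preceding the rising-limb
   anchor (a robust plateau estimate that ignores the dicrotic limb);
5. returns the real-valued intersection of baseline and upslope line —
   onsets are never snapped to the sampling grid.

The detector is equivariant under time shifts and invariant under positive
amplitude scaling (both properties are tested). Ties for peak/trough/minimum
resolve to the earliest sample index.

**Pressure waveforms** (`detect_onset_pressure`). The onset is the time of
the minimal pressure between cycle start and the systolic peak (earliest
sample on ties). A monotone-decreasing cycle has no upslope and raises; a
monotone-increasing cycle returns the first sample flagged with a warning
reason. Onsets from the ≥10 recorded cycles per pullback position are
aggregated by the median (mean available behind a flag): the aggregation
rule is a package policy, chosen for robustness to respiration-induced
outlier beats.

## PWV estimators

* `two_site_pwv`: Δx/Δt between two sites; Δt must be positive
  (`NonPhysicalPropagationError` otherwise).
* `multi_site_pwv`: ordinary least squares of onset time on arc position
  over all valid in-window sites, PWV = 1/slope, with slope standard error
  and R². OLS (not weighted or robust) is the deliberate default: the dense
  chord sampling gives homoskedastic onset errors, and the estimator must
  stay transparent against its normal-equations oracle. Sites whose foot
  detection failed are excluded silently and counted in diagnostics.
* `pullback_pwv`: regional mode applies the two-site estimator to the
  recordings nearest the two requested sites (each within half a 5.8 cm
  pullback step, else `SiteMatchError`); local mode regresses over all
  recordings within one step of the requested center — an 11.6 cm
  trajectory. Using all three in-window grid points (not just the outer
  two) is the decided default for the local estimate.

## Aortic geometry

Contours, centerlines and velocity maps share one planar mm frame, origin at
the image's top-left pixel center; rows increase in the anterior–posterior
(AP) direction, columns in the feet–head (FH) direction.

**Centerline.** The lumen polygon is rasterized at 0.5 mm/pixel; the
Euclidean distance transform gives each lumen pixel's distance to the
boundary; the centerline is the minimal-cost geodesic between the lumen
pixels nearest the two endpoint hints, with per-pixel cost 1/distance and
8-connected geometric steps. The cost ridge coincides with the medial axis,
so the path runs along the vessel middle (for an annular band of width 2w
and mid radius r the cost of a circular path at radius ρ, ~ρ/(w−|ρ−r|), is
minimized exactly at ρ = r). A raw medial-axis skeleton was rejected: its
diagonal corner branches in elongated bands pull the path off the midline
near the ends. The path is smoothed with a 5-point moving average and
resampled to uniform 0.5 mm arc spacing; tangents are central differences
over a ±2 mm baseline, which suppresses residual stair-step wiggle of the
raster path and is curvature-unbiased (the chord of a circular arc is
parallel to the tangent at its midpoint).

**Chords.** `n` chords (default 200) are placed at arc fractions k/(n−1),
endpoints included (n = 1 degenerates to s = 0). Each chord is the maximal
segment through its centerline point perpendicular to the local tangent,
clipped to the lumen polygon; a chord that does not reach the boundary on
both sides is a geometry error.

**Velocity sampling.** For each chord and cardiac phase, the AP and FH maps
are sampled by bilinear interpolation at 0.5 mm steps along the chord,
projected onto the chord's centerline direction (signed scalar product;
positive = ascending→descending flow), and the signed maximum over the chord
is kept. Maximizing the signed (not absolute) projection preserves flow
direction and rejects aliased/retrograde pixels. One contour set serves all
phases and both component series; only the lumen-area series uses per-phase
contours, with shoelace polygon areas.

## Bramwell–Hill module

`D = (ΔA/A_min)/ΔP` with ΔP converted at 1 mmHg = 133.322 Pa; areas enter
in mm² since only their ratio appears. `PWV = (ρD)^(−1/2)` with
ρ = 1059 kg·m⁻³ by default, and the inverse `ΔP = ρ·PWV²·(ΔA/A_min)`. The
volumetric strain of the underlying derivation is represented per unit
length by the luminal area, as is standard for thin slabs of vessel. The
three maps form exact algebraic roundtrips (tested to 1e-12 relative);
distensibilities are carried in Pa⁻¹ and also reported in 10⁻³ mmHg⁻¹.

## Agreement statistics

For paired per-subject series (method under test vs gold standard):
Pearson r with its two-sided p; COV = 100·SD(differences)/mean(all 2n
measurements); mean unsigned error = mean over subjects of
100·|difference|/reference (absolute-units variant behind a flag); paired
t-test; 95% CI of the mean difference as mean ± t(0.975, n−1)·SD/√n; and
Bland–Altman limits of agreement mean ± 1.96·SD. Correlation contrasts
between two methods sharing one gold standard use the interaction term of a
pooled regression (outcome = stacked measurements; predictors = reference,
method indicator, reference×method) — a slope contrast, which is what the
interaction tests; Steiger's z for dependent correlations is provided as a
clearly labeled alternative, never the default. No multiple-testing
correction is applied; significance is p < 0.05.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Each subject is an exactly Bramwell–Hill-consistent world:
`D = 1/(ρ·PWV_local²)` holds by construction, so model-recovery error
isolates pipeline error from model error. A `model_violation_sd` knob
(multiplicative perturbation of the area response) exists to create
realistic model scatter; it defaults to off.

**Cycle template.** Unit amplitude: zero late-diastolic level (velocity) or
a small declining tail reaching zero exactly at the foot (pressure, level
0.02 — making the pre-upslope minimum unique at the foot), a linear upstroke
from foot to peak, a raised-cosine systolic decay and a compact-support
raised-cosine dicrotic bump. The upstroke is linear rather than sigmoid so
that the 20–80% regression line extrapolates to the analytic foot exactly;
a curved upstroke would bias the line-intersection foot by a fixed fraction
of the upstroke duration (a shared bias cancels in transit times but would
make single-onset accuracy untestable). The foot sits at phase 3/35 and the
peak at 7/35 of RR so both land exactly on the 35-phase CMR sampling grid;
the noiseless distensibility identity is then exact rather than
quantization-limited. The upstroke must exceed 2 CMR phase intervals
(`ConfigError` otherwise).

**Default conditions** (`CohortConfig`): 17 subjects; local PWV ~
Normal(7.0, 1.6) m/s truncated at 3; aortic pulse pressure ~ Normal(53, 15)
mmHg truncated at 20; A_min ~ Normal(450, 80) mm² truncated at 200;
diastolic pressure ~ Normal(76, 13) mmHg; RR ~ Normal(1.0, 0.1) s; pressure
recordings at 2 kHz, 10 cycles, at six pullback positions 5.8 cm apart;
35 CMR phases/cycle; 200 chords over a 29 cm trajectory; transection sites
at 5.8 and 17.4 cm (11.6 cm apart). The regional (arch) wave speed is 0.95×
the local one; the arch-segment speed is set so the two-site transit between
the sites equals the regional truth exactly. Truncations are by resampling.

**Noise model.** Per-cycle pressure onset jitter ~ Normal(0, 3 ms) emulates
respiration-induced beat-to-beat variation; additive velocity noise of
0.015 m/s per phase sample emulates post-processing noise on
maximal-velocity curves (maxima over ~40 interpolated samples of spatially
smooth data, hence well below raw pixel noise; this level yields ~2 ms foot
jitter per chord, consistent with the reliability that dense in-plane
sampling is known to achieve). The brachial cuff reads the central pulse
pressure with a −8 mmHg bias plus 4 mmHg device noise: automated cuff
devices under-read central pulse pressure, and under the model a smaller ΔP
inflates D and deflates the modeled PWV — the sign needed for the cuff-based
model estimate to underestimate more than the catheter-based one. The
velocity amplitude varies ±20% per subject; foot-based PWV is invariant to
it by the scale-invariance property.

**What the generator does not emulate:** reflected-wave physics and
Windkessel load, MR k-space/phase noise and aliasing, arrhythmia, breathing
drift of the anatomy, day-to-day physiologic change between examinations.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated sampling and noise conditions, not robustness to every
clinical artifact.

**Rasterized phantom** (`rasterize_maps`): an ascending limb, half-annulus
arch (centerline radius 35 mm, tube radius 10 mm) and descending limb,
parabolic cross-profile, per-pixel velocity along the local tangent delayed
by arc-position/PWV, split into AP/FH components and clipped to the 1.5 m/s
encoding limit. It exercises the full geometric pipeline (centerline
extraction → chords → projection → feet → regression) against a known wave
speed.

## Numerical choices and degenerate inputs

* Sub-sample onset times are real-valued; the pressure foot is by definition
  a sample time, so single-site pressure onsets carry up to half a sampling
  interval of quantization. Cycle-to-cycle grid dithering plus the
  median across ≥10 cycles reduces this; at 2 kHz the residual per-subject
  pullback error is a fraction of a percent on average, which is why the
  pullback recovery check is stated as a cohort mean.
* Site windows and grid matching use a 1e-9 m tolerance; regional pullback
  matching accepts recordings within half a pullback step.
* Chord/lumen intersections, polygon validity and areas use shapely; a
  self-intersecting or zero-width lumen raises `DegenerateGeometryError`.
* Velocity maps are validated against their encoding limit (|v| ≤ VENC).
* Zero-variance series, zero reference values and n < 3 raise typed
  statistics errors rather than returning NaNs.
* Study subjects with any failed stage are excluded listwise from the paired
  battery (n is reported per study); the run continues if ≥3 remain.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning, so identical configs give
  byte-identical simulated studies.

## Problem sizes used in validation

The acceptance script and test suite validate at the study's native scale —
17 subjects, 2 kHz × 10-cycle pullbacks at 6 positions, 200 chords × 35
phases, a ~140×110 px phantom at 1 mm/px — and use 50 independent cohorts
for the directional (seed-fraction) checks, 100 cycles for the
foot-detection oracle, 1000 draws for the model roundtrip and 10 000 pairs
for the Bland–Altman coverage check.

## Known limitations

* The centerline is planar (the multi-slice stack is treated as one
  composite plane); no 3-D fusion.
* No wave-reflection separation or wavelet/cross-correlation transit-time
  estimators; the foot-to-foot choice is deliberate.
* The interaction-regression correlation contrast tests slope differences,
  not correlation differences per se (the labeled Steiger alternative tests
  the latter).
* Automated lumen segmentation is out of scope: contours are inputs, and
  the simulator emits ground-truth contours.
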