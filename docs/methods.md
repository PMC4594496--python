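# Methods

## The paradigm and what is modeled

The Circles-Lines task asks a participant to draw continuous vertical lines
with the right hand and, depending on condition, nothing (L), circles with
the left hand only (C), lines with both hands (LL), or circles with the
left hand while the right draws lines (CL). In neurotypical participants
the non-congruent CL condition "ovalizes" the right-hand lines — the
bimanual coupling effect. A session is an alternation of 15 s experimental
blocks and 15 s rests, 24 experimental blocks (6 per condition) in a
pseudo-random order, framed by 30 s initial and final rests (total 765 s).

The package simulates this design, computes trajectory metrics, and runs
the single-case inference used when one or two patients must be compared
against a small normative sample.

## Synthetic trajectories

Strokes are harmonic. With amplitude `A` (mm), frequency `f` (Hz) and
phase θ = 2πft:

- line: `y = A sin θ`, `x = α A cos θ` where α ∈ [0, 1] is the
  ovalization ratio (α = 0 a strict vertical line, α = 1 a circle);
- circle: `x = A cos θ`, `y = A sin θ`.

Isotropic Gaussian jitter (SD `noise_sd` mm) is added to both axes; the
sample count is `floor(duration × sampling_rate)`. Coordinates are in the
tablet frame: x lateral, y vertical increasing upward, millimetres; time in
seconds from session start. Defaults: `A = 50 mm` (a comfortable stroke on
an fMRI-compatible tablet), `f = 1.3 Hz` (the normative sample's mean
drawing frequency), `noise_sd = 1 mm` (2 % of amplitude — smooth, practiced
drawing), `sampling_rate = 100 Hz` (typical digitizing-tablet rate; a 20 Hz
floor is enforced so cycle segmentation stays well-posed).

**Coupling model.** The mechanism behind the interference is not modeled;
its signature is. In CL blocks the right-hand line receives additive
lateral contamination equal to `coupling × (left circle's noise-free
x-component)`. With equal amplitudes and synchronous hands this raises the
right hand's OI by ≈ 100 × coupling points over its LL value, which makes
the constructed effect recoverable by the metric (tested at ±3 points over
20 seeds). `coupling = 0` reproduces the motor-neglect phenotype (no
interference); the published healthy normative means (CL − LL ≈ 7.9 OI
points) correspond to `coupling ≈ 0.079`, the value the demo uses, and the
matching baseline line ovalization is α ≈ 0.055 (LL OI ≈ 5.5). An optional
`phase_lag` parameter can desynchronize the hands (patients with motor
neglect have been described as moving asynchronously in CL); it has no
published quantitative anchor, so its default is 0 and no pathology of
timing is modeled.

**Block order** is a seeded shuffle rejected until no condition repeats
more than 3 times in a row — a conventional reading of "pseudo-random
sequence". All randomness flows from explicit integer seeds;
identical seeds give bitwise-identical output.

**Normative cohorts** are drawn at the score level from a bivariate normal
whose population mean vector, SDs and correlation equal the targets (the
published behavioral targets are the defaults). Only mean ± SD and r are
published for the real sample, so a bivariate normal is the minimal
faithful choice; realized sample summaries converge to the targets
(verified within 2 % at n = 10⁴) but individual n = 12 draws scatter, as
real control samples do.

## Ovalization Index

Per complete drawing cycle,

    OI_cycle = 100 · sd(x − x̄) / (h / √2),   h = (max y − min y) / 2

and a block's OI is the mean over its cycles, clipped to [0, 100] (noise
can push sd(x) slightly above the circular bound). The `h/√2` scale is the
unique affine-invariant normalization that makes the scale anchors exact: a
circle of radius r has sd(x) = r/√2 and h = r, so OI = 100; a vertical line
has sd(x) = 0, so OI = 0; an ellipse with semi-axis ratio a/b scores
100·a/b. OI is invariant to translation, uniform scaling and time
reversal.

Cycles are delimited by successive maxima of y after moving-average
smoothing (0.1 s window, forced to an odd sample count so the filter is
symmetric and does not phase-shift extrema), keeping half-open
`[max_i, max_{i+1})` intervals; only complete cycles count. Maxima need a
prominence of at least 5 % of the block's y-range, which discards jitter
extrema; on a plateau the first sample is the extremum. Cycles with zero
y-range are skipped with a warning (an error if all are). Computing OI per
cycle and averaging — rather than pooling the SD over the block — keeps the
measure robust to slow drift across strokes. The "vertical" reference is
the device y-axis, not a per-stroke regression line: the index measures
deviation from the instructed absolute direction.

**Drawing frequency** is the number of complete cycles divided by the time
they span — identically the inverse mean cycle duration (the reciprocal
identity holds to 10⁻⁹ by construction and is tested).

## Single-case statistics

All tests refer a case to a control sample of size n through Student's t
with df = n − 1, and all p-values are two-tailed (no multiple-testing
correction is applied anywhere, matching the source analyses).

- **RSDT** (revised standardized difference test, Crawford & Garthwaite
  2005). With z_x, z_y the case's scores standardized by the control means
  and SDs, the statistic is the positive root of

      a ψ² + b ψ − c = 0,  a = (1+r)(1−r²),
      b = (1−r)[4(n−1)² + 4(1+r)(n−1) + (1+r)(5+r)],
      c = 2(z_x−z_y)² n(n−1)²/(n+1),

  signed by z_x − z_y. The quadratic embodies the small-sample correction
  for using estimated control SDs. In the large-n limit the statistic
  reduces to (z_x−z_y)/√(2−2r)·√(n/(n+1)) (verified to 0.1 % at n = 10⁵),
  and its empirical type-I error at n = 12, r = 0.8 sits in [0.03, 0.07]
  at α = .05 over 2000 null replicates — the method's defining calibration
  property.
- **UDT**: t = [(x−y) − (x̄−ȳ)] / [s_d √(1+1/n)] with
  s_d = √(s_x² + s_y² − 2 r s_x s_y); degenerate when r = 1 with equal SDs.
  Used as an internal cross-check of the RSDT.
- **Two-case comparison**: z = (d₁ − d₂)/(s √2) referred to t(n − 1),
  where s is the control SD of the compared score. The source never prints
  this formula; it is adopted because it reproduces three independent
  printed statistic/p pairs (−2.4/.03, 2.24/.05, 1.19/.26). The sign is
  reported as case1 − case2.
- **Deficit test** (Crawford & Howell): t = (x − x̄)/(s √(1+1/n)).

## Pipeline and fixtures

The pipeline scores each case (directly supplied scores, or trajectories
scored through the metrics module on the right hand, LL vs CL), runs an
RSDT per case against the normative summary, compares the two cases on
their CL − LL differences, and — when a normative frequency summary is
available — on drawing frequency; ROI beta values go through the same
machinery per region. Every report row carries the method, a digest of its
inputs, the statistic, df and p; skipped blocks are logged, never silently
dropped. Reports are byte-identical under a fixed seed.

The published worked-example data ship as JSON fixtures (normative
summaries, patient scores, printed statistics). Where a fixture supplies
the study's own printed CL − LL differences these are used for the
comparison (they were computed from unrounded means and are one rounding
step closer to the data than differences of doubly-rounded means); the
per-case score table always reports the difference recomputed from the
shipped scores. Printed statistics that are *not* recoverable from the
printed rounded summaries (the MN− behavioral RSDT of 0.6, the pre-SMA T
and Z values, the frequency Z, and one internally inconsistent right-PPC
p-value) are shipped as annotations with discrepancy notes and are never
asserted or reported as reproduced.

## Simulation study design

The power check pairs score-level control cohorts with a trajectory-level
patient: cohorts of n = 12 are drawn with the published normative
dispersion and correlation (SDs 1.5/6.8, r = 0.8) around a constructed
coupling of 0.25 (CL mean = LL mean + 25 OI points), while the patient is
a fully simulated session with coupling 0, scored by the metrics module.
Drawing the cohort at score level uses the documented cohort generator and
keeps the published inter-subject correlation structure, which a
trajectory-level cohort with independent per-subject parameters would not
reproduce. The uncoupled patient is flagged by the RSDT at α = .05 in
well over 90 % of 100 seeded runs.

Problem sizes throughout (full 765 s sessions at 100 Hz, 20-seed recovery
sweeps, 2000 Monte-Carlo null replicates, 100-run power sweeps) were chosen
so the whole suite completes in seconds on one CPU while leaving the
Monte-Carlo intervals narrow enough to be meaningful.

## Limitations

- The generator produces stationary harmonic strokes: no drift, fatigue,
  velocity asymmetries, pen lifts or within-block frequency wander. Passing
  recovery tests shows the metric chain is self-consistent, not that it is
  robust to every artifact of real tablet data.
- Temporal (phase-locking) coupling pathology is not modeled; only the
  spatial signature is.
- Patient-level OI condition means of the source study (e.g. 8.0/32.5) are
  not reproducible because the raw trajectories were never released; the
  package reproduces the inferential statistics from the printed summary
  scores instead.
- The RSDT inherits the bivariate-normality assumption of the control
  scores; with n = 12 controls, departures from normality are undetectable
  and the test's calibration is only as good as that assumption.
- fMRI beta extraction, whole-brain statistics and lesion analysis are out
  of scope; betas enter as tabular data only.
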