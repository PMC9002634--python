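# Methods

This note documents the models, algorithms and numerical choices behind
`tendonmetrics`, and what the synthetic-data tests do and do not show about
real recordings.

## 1. Measurement chain

One *trial* is a ramp isometric plantarflexion recorded by three
asynchronous instruments: three foot-plate load cells (nominally 100 Hz),
sagittal-plane LED marker cameras (8 markers, 15 Hz) and B-mode ultrasound
of the gastrocnemius medialis myotendinous junction (MTJ, 30 Hz). Each
stream carries its own clock plus the stream-local timestamp of a shared
trigger event.

**Synchronization.** Every stream is shifted so its trigger sits at t = 0
and the slower streams are linearly interpolated onto the force time base.
Linear interpolation is adequate because the signals are slow monotone
ramps; a higher-order scheme would add ringing without benefit. Samples
outside any stream's recorded span are flagged invalid, never extrapolated.

**Joint moment.** `M(t) = Σ Fᵢ(t)·xᵢ` after per-channel baseline
correction (mean over the first `rest_window_s = 0.8 s`, which must precede
force onset; the subtracted offsets are logged). The lever arms `xᵢ` are
measured from the projection of the ankle axis (malleoli marker midpoint at
rest) onto the plate — a fixed axis at rest, not an instantaneous axis,
because the rotations involved are < 3° and the axis migration is far below
the marker noise floor.

**Ankle angle.** The sagittal angle between the shank segment (fibula
head → lateral malleolus) and the foot-plate marker line; ≈ π/2 in neutral
position. Sign convention, used everywhere: a *decreasing* shank–plate
angle (plantarflexion) is a *positive* Δθ.

**Maximal-force sample.** Argmax of the joint moment after zero-phase
2nd-order low-pass smoothing at `lowpass_hz = 10 Hz` (a raw argmax is
unstable under sample-level noise; 10 Hz leaves the ≤ 1 Hz ramp intact).
The smoothing affects only *which* sample is selected; reported forces are
unsmoothed.

## 2. Tendon mechanics

* tendon force `F = M / (d/1000)` with the moment arm `d` in mm;
* rotation artefact by the tendon-excursion method, `e = d·Δθ`, *subtracted*
  from the measured MTJ displacement (plantarflexion rotation displaces the
  MTJ in the same direction as true elongation, so the raw measurement
  overestimates);
* strain `ε = Δl/L₀` stored as a fraction, printed as %;
* stiffness index `k = (F_max/1000)/ε_max` in kN per unit strain, evaluated
  from 0% to 100% of force.

The **rest frame** of the two-frame analysis is the first valid landmark
sample before force onset, defined as force < 2% of maximum. The **angle
change** Δθ is evaluated between the same two frames as the landmark pair.
The frame-by-frame route applies the per-sample correction
`Δl(t) = Δl_meas(t) − d·Δθ(t)` and returns the full force–elongation curve;
its *measured* (uncorrected) maximal strain is what enters method-agreement
comparisons, since digitization — not the rotation correction — is what
differs between the two routes.

**Aggregation rule.** Subject- and group-level stiffness summaries are
means of per-trial force/strain *ratios*, never the ratio of mean force to
mean strain; the two differ (Jensen) and only the former matches how
per-trial results are averaged in reliability tables.

A corrected strain ≤ 0 (possible when the rotation correction overshoots on
a corrupted trial) marks the result invalid and sets the stiffness to NaN
rather than raising, so a session analysis can continue past a bad trial.

## 3. Synthetic-trial generator

The generator emulates the study conditions end to end; its defaults *are*
the experiment design:

| parameter | default | rationale |
| --- | --- | --- |
| cohort design | 11 subjects × 4 trials × 2 days | standard test-retest design (88 trials) |
| sampling rates | 100 / 15 / 30 Hz | load cells / markers / ultrasound |
| trigger offsets | 0 / 0.12 / 0.25 s | distinct per-stream clocks, exercised by sync |
| force ramp | smoothstep 3u²−2u³ over 3 s, 1 s rest, 0.5 s hold | smooth, monotone, zero end-slopes |
| tendon law | linear through origin (`nonlinearity = 1`) | ramp loading at this joint configuration shows no clear toe region; a power-law toe exponent is available for robustness work |
| stiffness index | 73.9 ± 18.3 kN/strain (young); 49.4 ± 11.5 (older); 96.3 ± 11.7 (athletes) | published cohort distributions |
| maximal force | 4436 ± 898 N (young); 3000 / 5500 N group means (older/athletes) | young values published; the group ordering is published but not the numbers — chosen to keep strain roughly constant across groups |
| joint rotation | quasi-static compliance, Δθ = c·M with c = 1.8·10⁻⁴ rad/(N·m) | gives ≈ 2.3° and a ≈ 2 mm artefact at maximal force: the magnitude the correction exists to remove |
| landmark noise | SD 0.5 mm per digitized frame | 95% of digitization errors within the ±1 mm accuracy reported for ultrasound landmark tracking |
| force / marker noise | 5 N, 0.2 mm | typical instrument noise floors |
| trial-to-trial effort | 4.5% relative SD on maximal force | reproduces ~4–5% force CV |
| day bias | 0.3 mm landmark offset per day | emulates probe re-application between sessions |

All noise is zero-mean Gaussian, independent per sample, drawn from an
explicit `numpy` generator; a seed fully determines a cohort. The
frame-by-frame landmark series and the two-frame pair receive *independent*
noise realizations — in the real protocol they come from two independent
digitizations (different operators, different software) — otherwise the
two analysis routes would be trivially identical.

Ground truth is internally consistent by construction:
`k_true = (F_max/1000)/ε_true` exactly, so pipeline errors are attributable
to the measurement chain, not the generator.

**What the generator does not emulate:** out-of-plane probe motion, fascicle
kinematics, EMG-force dynamics, non-Gaussian digitization blunders,
attenuation/beamforming physics, and any real-tissue nonlinearity beyond
the optional power-law toe. Passing tests therefore demonstrate the
*analysis chain's* correctness and noise behaviour under the stated model,
not the clinical accuracy of ultrasound digitization itself.

## 4. Synthetic ultrasound and landmark tracking

Frames are a tissue-attached multiplicative speckle background (smoothed
white noise sampled from a canvas that translates rigidly with the
landmark, cubic-spline interpolation) times an analytic dark-wedge feature
centred on the landmark, so sub-pixel positions are exact; pixel pitch
(default 0.2 mm/px) makes the mm↔px conversion lossless.

Localization is normalized cross-correlation (via
`skimage.feature.match_template`) with sub-pixel refinement by a 1-D
parabolic fit per axis around the peak, clamped to ±0.5 px. Flat (zero
variance) templates or windows raise an undefined-correlation error.
Sequence tracking refreshes the template from each matched frame
(`"previous"` mode, adaptive but drift-prone) or keeps the frame-0 template
(`"anchor"`). Two details matter for drift:

* the sub-pixel residual discarded when the template is re-cut at an
  integer position must be carried forward and added back to the next
  match — otherwise it accumulates as a systematic walk;
* the template (default 25 px) must cover the feature's full support
  (~±16 px for the default wedge); a template that clips the feature
  mid-gradient biases the parabolic fit.

Frames with peak NCC below 0.6 are flagged for manual override (mirroring
operator correction in semi-automatic software); below 0.2 the feature is
declared lost and tracking aborts with the last good frame index. The
original study's software does not document its detector, so no claim of
algorithmic equivalence is made — only equivalence of the downstream
two-frame vs frame-by-frame agreement.

## 5. Statistics

* **ICC(A,1)** — two-way layout mean squares:
  `(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`. Between-day ICC
  feeds the per-subject day means into the same single-measures formula.
  Zero total variance is an error, not an ICC of 1.
* **Spearman–Brown**: `k = (t/(1−t))·((1−r)/r)`; reported as the exact value
  plus its enclosing integer bracket. The bracket is computed from the
  *overall* ICC (all trials pooled) — the variant that reproduces published
  minimum-trial ranges.
* **CV**: per subject `100·SD/|mean|` (sample SD) over the scope's trials,
  then the *mean* across subjects (median aggregation is a defensible
  alternative; mean is used and documented).
* **RMS differences**: within-day scopes pool all within-day trial pairs;
  *overall* pools all trial pairs regardless of day; *between-day* is the
  RMS over subjects of (day-1 mean − day-2 mean). The pooling definitions
  are logged with every report.
* **Repeated-measures ANOVA**: fully-within two-factor design
  (day × trial-within-day), each effect tested against its interaction with
  subjects. Type-I error is calibrated by simulation in the test suite.
* **Group comparison**: one-way ANOVA, then pairwise t-tests with Bonferroni
  correction (raw p × number of pairs, capped at 1). The trial-selection
  rule is conservative by design: older adults contribute their four
  *strongest* trials, athletes their four *weakest*, young subjects all
  eight trials of one leg.
* **Lilliefors normality**: KS statistic against a normal with estimated
  mean/SD; p-value from a seeded Monte-Carlo null (10⁴ standard-normal
  resamples of the same n, vectorized). With fewer than 4 subjects the
  report records NaN instead of failing.

α = 0.05 and two-sided tests throughout; all sample SDs use n−1.

## 6. Problem sizes and determinism

The test suite and the acceptance script run the full study design (88
trials), a 100-trial noisy-recovery cohort, one ~136-frame tracking
sequence, 500 null-ANOVA simulations and 200 group-comparison replicates;
together they complete in well under a minute on one core while keeping
every simulated check at its stated design size. Every random draw flows
from an explicit seed, hypothesis profiles are derandomized, and the CLI
echoes a config JSON sufficient to reproduce any run bit-for-bit.

## 7. Known limitations

* The two-frame stiffness index discards any force–strain nonlinearity by
  construction; with the power-law toe option the "index" is a chord, not a
  tangent stiffness.
* The rotation correction assumes the quasi-static excursion model
  `e = d·Δθ` with a constant moment arm; moment-arm change with joint angle
  is ignored.
* Marker-based angles are 2-D sagittal projections; out-of-plane motion is
  not modeled.
* The group-comparison power at the published cohort sizes is modest for
  the adjacent-group contrasts (analytic all-pairs power ≈ 0.5), so a
  single simulated study does not always reproduce all pairwise
  significances — only the ANOVA-level group effect is essentially certain.
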