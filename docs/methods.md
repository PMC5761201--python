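# Methods

This note documents the models, parameters and numerical choices behind
`cvreserve`, in the order data flows through the pipeline.

## 1. The synthetic LBNP cohort

The generator emulates the statistical and protocol structure of a
lower-body-negative-pressure experiment: a resting baseline (default
600 s, the usual final-10-minutes-of-rest convention), a single-step
LBNP phase whose duration is drawn per subject from a configurable range
(default 300–900 s, reflecting the wide inter-subject spread in time to
pre-syncope), and a terminal collapse occupying the final 5% of LBNP
that always ends the recording at pre-syncope.

**Pulse template.** Every heartbeat of the pressure and flow-velocity
channels is rendered from a piecewise analytic template: a raised-cosine
upstroke from the foot (diastolic value) to the systolic peak, a
raised-cosine decline to the dicrotic notch — a true local minimum with
zero left-derivative — and a dicrotic bump superimposed on an
exponential decay toward the next beat's foot. The template's landmark
times and values (foot, maximal-upstroke point at half the upstroke,
peak, notch) are therefore known in closed form and are attached to each
recording as ground truth; the landmark detector is tested against them
to within one sample. The notch time follows a systolic-interval rule
(0.30·√IBI, capped at 0.45·IBI), so LVET shortens as heart rate rises.

**Beat-to-beat trajectories.** During baseline all beat parameters are
constant in expectation; during LBNP pulse pressure declines linearly in
expectation (default −45% at pre-syncope), mean cerebral flow velocity
declines (−30%, distributed asymmetrically over systolic/diastolic
velocity), heart rate rises, and the slow channels drift (end-tidal CO₂
−8 mmHg, thoracic impedance +2 Ω, O₂Hb −5 µmol/L, HHb +3 µmol/L). These
effect sizes are representative of presyncopal LBNP responses in young
healthy adults. Per-beat white noise (1.5 mmHg SAP, 0.02 s IBI by
default) and AR(1) noise on the slow channels (ϕ = 0.95) provide the
within-subject variability.

**Responder phenotypes.** Each subject is drawn as either a
*resistance-dominant* compensator (diastolic pressure rises 8 mmHg,
heart rate rises only 18 bpm) or a *heart-rate-dominant* compensator
(diastolic pressure falls 5 mmHg, heart rate rises 45 bpm), mixed 50/50
by default. This prevents classifiers from exploiting one stereotyped
trajectory and mimics the documented inter-individual variance in
autonomic compensation strategies.

**Terminal collapse.** In the final 5% of LBNP, systolic pressure is
driven linearly to 72 mmHg, so the recording always satisfies the
SAP < 80 mmHg pre-syncope abort criterion. Heart rate holds its plateau
during collapse: the generator guarantees monotone-in-expectation
trajectories over LBNP (SV/PP/MCAv non-increasing, HR non-decreasing),
which downstream property tests rely on; a terminal vagal HR drop —
also a recognised abort sign — is deliberately not emulated. Subjects
who would tolerate the full protocol without pre-syncope are not
emulated either; every synthetic recording ends at pre-syncope.

**What the generator does not capture.** No baroreflex or Windkessel
dynamics, no respiratory modulation of the pressure wave, no measurement
artifacts (probe loss, movement), no ectopic beats, and slow channels
are trends plus stationary noise rather than physiology. Passing tests
on this cohort therefore demonstrate that the pipeline's machinery is
correct and that the protocol structure is recoverable — not that the
reported sensitivities would transfer to human recordings, where class
overlap is far larger.

## 2. Pulse landmarks

Beats are detected from the upstroke: local maxima of the first
derivative above 35% of its global maximum, at least 0.25 s apart, each
traced back (≤ 0.3 s) to the preceding minimum, which is taken as the
foot. The foot is the sampled minimum rather than an
intersecting-tangent estimate: on the template class used here the
tangent intersection lands systematically after the true foot, and the
sampled minimum recovers the analytic foot to within one sample, which
is the accuracy contract of the module.

Within a beat, *C* is the global maximum, *B* the maximal first
derivative before *C*, and *D* the most prominent local minimum between
*C* and the beat end (SciPy peak prominence on the inverted decay); when
hypotension leaves no interior minimum, *D* falls back to the maximum of
the second derivative on the decay. *E* is the next beat's foot; the
final open beat of a recording is discarded. Slope I is the derivative
at *B*; slopes II and III are least-squares slopes over C→D and D→E.
Areas are trapezoidal above the foot value, split at *D*, so
`area_total = area_sys + area_dia` holds exactly.

The 15-entry curve-dynamics vector is, in order: t_AB, t_AC, t_AD, t_AE,
h_B, h_C, h_D, slope I–III, area_sys, area_dia, area_total, h_D/h_C and
area_sys/area_total. The exact composition of such vectors varies in the
literature; this one is a reconstruction constrained to the documented
information classes (point times, amplitudes, tangents, areas) and to a
count of exactly 15, which is the binding contract.

Degenerate beats (no systolic peak, failed notch search) raise a typed
error; at the beat-table level such rows are filled by linear
interpolation from neighbouring beats — the automated analogue of manual
artifact removal — and identity-linked quantities (PP, HR, FV pulse
height) are re-derived afterwards so that per-beat identities hold on
every emitted row. At default noise the degenerate fraction is required
to stay below 1%.

## 3. Per-beat hemodynamics

* SAP = value at *C*; DAP = foot value; MAP = time average over the
  beat; PP = SAP − DAP; IBI = time to the next foot (accepted range
  0.25–2.5 s); HR = 60/IBI; LVET = t(D) − t(A).
* **Stroke volume** uses the Liljestrand–Zander pulse-contour form
  SV = k·PP/(SAP + DAP). The proprietary pulse-contour algorithms used
  with clinical finger-pressure devices are unpublished; this documented
  stand-in preserves the qualitative SV→PP coupling that the classifiers
  exploit. The calibration k is fixed per subject so that the
  baseline-mean SV equals the configured reference (80 mL by default).
  CO = SV·HR/1000 (L/min); TPR = MAP/CO (mmHg·min/L).
* **Slow channels** are linearly interpolated at beat times; the
  end-tidal CO₂ value is interpolated from the breath-wise envelope
  (one expiratory plateau peak per breath). Beats outside a channel's
  support take the edge value and are flagged.
* **NIRS block**: O₂Hb, HHb, tHb = O₂Hb + HHb, and the two ratios to
  tHb (which sum to 1 by construction).
* **Trend/variance block**: for each of SAP, DAP, HR, PP, SV and window
  lengths 30/60/90/120 s, the OLS slope (units/s) and sample variance
  over the beats in (t − w, t]. Windows are right-aligned and computed
  at every beat, baseline included: restricting them to LBNP would leak
  the class boundary into the features. A window with fewer than 3 beats
  or under 50% temporal coverage carries the value of the longest valid
  shorter window, else 0. "Variation" is implemented as the sample
  variance (squared units), consistent with reporting errors on a
  squared scale.
* **Transfer-function autoregulation**: MAP and MFV beat series are
  resampled to 4 Hz, and within each 3-min moving window (10-s step)
  cross- and auto-spectra are estimated by Welch averaging (100-s
  segments, 50% overlap, Hann taper, linear detrend). Gain
  |S_xy|/S_xx is averaged over the 0.06–0.15 Hz bins whose squared
  coherence reaches 0.5. Phase is the angle of the *summed*
  cross-spectrum over the qualifying bins (a magnitude-weighted circular
  mean): on noise-free test signals every leakage bin passes the
  coherence screen, and an unweighted per-bin phase average would be
  dominated by low-power bins with deviant phases. The sign convention
  follows the SciPy cross-spectrum: an output lagging the input has
  negative phase. Resampling rate, segment length and taper are standard
  cerebral-autoregulation practice and are recorded in the run manifest
  as assumed values. Windows with no qualifying bin are flagged invalid;
  at feature assembly, per-beat gain/phase are interpolated between
  valid window centres with edge carry-forward.

## 4. Feature sets, labels, normalization

The nine models are column selections over the beat table (counts
65/66/66/70/125/66/66/10/4). Model 5's 60-column flow-velocity block is
decomposed as: 15 FV curve-dynamics entries + 3 scalars (systolic,
diastolic, mean velocity; pulse height is omitted from the scalar set
because it is determined by the first two) + 40 trend/variance entries
over five FV parameters (SFV, DFV, MFV, pulse height, beat area) +
autoregulatory gain and phase. The exact historical split is not
recoverable; the count contract is the binding constraint and is
enforced by tests.

Labels are a deterministic function of time and protocol marks, with the
75% boundary assigned to class 2 (half-open convention — "the last
25%"). No class rebalancing is applied; the class mix follows the
protocol durations. Features are divided by their within-subject
baseline mean (features with |baseline mean| < 1e−9, e.g. trends, are
mean-subtracted instead), then min–max scaled to [0, 1] with bounds fit
on the **training cohort only** — per-subject scaling would erase the
inter-subject contrast the classifier needs. Test values are clipped to
[0, 1]; zero-range features map to 0.5. Decimation keeps every 10th row
per subject (stride decimation, not averaging, matching the stated
purpose of abridging computation).

## 5. Classification protocol

`SVC(kernel="rbf", probability=True)` provides the one-vs-one decision
machine with libsvm's pairwise sigmoid-coupled probability estimates;
this is recorded in the run manifest. Predictions are the argmax of the
probability triplet with ties broken toward the lower class index.

The hyperparameter space is C ∈ logspace(−2, 2, 8) ×
γ ∈ logspace(−3, 0, 8); all 16 distinct optimal values reported for this
method on reference data lie on these grids to printed precision, which
is what pins down the reconstruction. The grid search maximizes the mean
over tested subjects of Σ_classes (sensitivity + specificity) under the
leave-one-subject-out protocol; the random training subsets are shared
across the 64 configurations (variance reduction), and ties break toward
smaller C, then smaller γ.

LOSO draws 30 training subjects uniformly without replacement per test
subject (fresh draw each iteration, seeded); for cohorts smaller than
31 subjects the training-set size scales to ⌊0.7·(N−1)⌋ and is recorded
in the run. Scaler and classifier are fit on pooled training rows only.

## 6. Evaluation

* Sensitivity/specificity are one-vs-all from 3×3 confusion counts;
  a class absent from a subject's truth yields an undefined metric that
  is excluded from cohort medians. Cohort summaries are median and
  [25%; 75%] quartiles with the linear-interpolation quantile
  convention.
* Model error: centered moving average (default window 31 samples
  ≈ 30 beats after decimation; the window is a package choice, exposed
  in configuration and recorded with every report) of the integer
  predictions, truncated at the edges; per-class MSE against the true
  labels; the total is the **sum** of the three per-class errors.
* LOR = ln(max(p₂, ε)/max(p₀, ε)) with ε = 1e−6 guarding degenerate
  probabilities. Cutoff optimization scans all (low, high) pairs with
  low < high on a grid of step 0.01 spanning the observed LOR range
  (±1 step); the objective is the summed one-vs-all sensitivity and
  specificity of the induced three-class rule; ties break toward the
  smallest low, then the smallest high. The search is evaluated from
  per-class cumulative counts, so it is exactly equivalent to — and is
  tested against — brute-force enumeration. Cutoffs are optimized on the
  pooled cohort predictions.

## 7. Problem sizes used in tests

The test and acceptance suites run the full pipeline at desk scale:
2–3.5-minute baselines, 2–6-minute LBNP phases, cohorts of 4–12
subjects, and the parameter-recovery setting (12 subjects, strong effect
sizes, low noise) for the classification acceptance checks. These sizes
are the package's own testing choices; all protocol constants (class
split, windows, band, coherence threshold, decimation factor, grid
shape, n_train rule) are independent of them.

## 8. Known limitations

* The synthetic cohort is far more separable than human data; absolute
  sensitivities/specificities obtained here do not transfer.
* The pulse-contour SV stand-in tracks PP by construction, so SV adds
  no independent information in the synthetic setting (it does on real
  devices).
* TFA phase is reported un-unwrapped; with the band and signals used
  here wrap-around does not occur, but strongly delayed signals would
  need unwrapping.
* The curve-dynamics vector and model 5's internal split are documented
  reconstructions constrained by feature counts, not recovered
  definitions.
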