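# Methods

## Problem and signal model

A continuous-wave Doppler radar at carrier frequency f (24 GHz here,
wavelength lambda = c/f ~ 12.5 mm) illuminates a seated person.  Chest
motion x(t) phase-modulates the reflection, and a quadrature receiver
produces two baseband channels

    I(t) = A_I * cos(theta0 + 4*pi*x(t)/lambda + dtheta(t)) + DC_I + n_I(t)
    Q(t) = A_Q * sin(theta0 + 4*pi*x(t)/lambda + dtheta(t) + dphi) + DC_Q + n_Q(t)

where theta0 encodes the nominal target distance, A_I != A_Q and dphi
model amplitude/phase imbalance, DC_I/DC_Q are offsets, dtheta is
residual oscillator phase noise (negligible at short range, default
off) and n is additive white measurement noise.  A heartbeat moves the
chest sub-millimetrically: at 24 GHz a 0.3 mm excursion spans roughly
0.3 rad of baseband phase, a small ripple riding on the much larger
breathing modulation.

The detector treats heartbeat detection as per-sample binary
classification on the raw I/Q streams: no demodulation, no imbalance
calibration.  Both channels are decimated to 100 Hz; at each step the
last second of each channel (100 + 100 samples, oldest to newest,
in-phase first) forms a 200-long input vector for a shallow
feed-forward network -- the reference topology is one hidden layer of
20 tanh units and a sigmoid output ("FF 20 1").  The training label is
1 inside a 400 ms window starting 200 ms after each reference ECG R
peak, chosen to bracket the electro-mechanical R-J delay (203-290 ms
in the literature), and 0 elsewhere.  The output stream is smoothed by
a causal width-10 moving average; constrained peak picking (prominence
threshold, minimum spacing 0.5 s from the 120 beats/min physiological
bound) turns it into discrete events; a doubled-IPI rule interpolates
single missed beats at gap midpoints.

## Synthetic data generator

There is no public recording set, so the package ships a forward
simulator used by every test and benchmark.  Per subject it draws:

- a beat train with RR = 60/HR + N(0, hrv_sd), truncated to
  [0.5, 1.5] s (40-120 beats/min at rest); defaults HR 75, hrv_sd 50 ms;
- chest displacement: a breathing sinusoid (default 0.25 Hz, 1.2 mm --
  the spec's order-1e-3 m scale) plus one per-beat kernel delayed by a
  uniform R-J interval in [0.203, 0.290] s.  The default kernel is two
  opposite-sign Gaussian lobes (80 ms and 185 ms after onset, sigma
  30 ms, peak 0.3 mm), compact enough that the whole mechanical
  signature falls inside the 400 ms target window even at the longest
  R-J delay; single-Gaussian and damped-sine alternatives are
  selectable.  The true chest waveform is known to be complex and
  subject-specific; this kernel is a stand-in, not a physiological claim;
- baseband I/Q per the model above (A_I = 1, A_Q = 0.93, DC 0.12/-0.09,
  dphi 0.1 rad, white noise sd 0.02) at 1 kHz;
- a stereotyped P-QRS-T ECG at 250 Hz with the R apex exactly on each
  beat time (R amplitude 5x the P/T waves) plus baseline noise.

A cohort applies +/-15% multiplicative jitter to rates and amplitudes,
small additive jitter to offsets and phase imbalance, and draws theta0
uniformly per subject -- centimetre-scale distance differences
randomize the operating point completely, which is the main source of
cross-subject variability the detector must generalize over.

What the generator does **not** emulate: body-movement artifacts,
multipath and clutter, multiple persons, arrhythmias, waveform
variability of the mechanical pulse within a subject, and ECG
morphology pathology.  Passing benchmarks here therefore demonstrate
that the chain is implemented correctly and can learn the mapping
under controlled conditions, not that it reaches any particular
accuracy on real recordings.

## Training

Networks are trained by Levenberg-Marquardt on the residuals of the
configured loss (MSE by default; SSE and weight-regularized MSE are
selectable).  Each epoch accumulates the Gauss-Newton normal equations
J^T J and J^T r in row chunks (BLAS `syrk`, optionally in float32),
solves (J^T J + mu I) delta = J^T r by Cholesky, and accepts the step
only if the objective decreases (mu /= 10 on acceptance, mu *= 10 and
retry otherwise; mu0 = 1e-3).  Stopping: 1000-epoch cap, gradient
infinity-norm below 1e-7, or a 30% validation split (row-level,
stratified by subject) failing to improve for 6 consecutive epochs;
the returned weights are those with the best validation MSE.  Weight
initialization is symmetric uniform scaled by 1/sqrt(fan_in); all
randomness flows from explicit seeds, making training bit-reproducible.

Two numerical notes.  First, `max_train_rows` subsamples training rows
(windows at stride 1 are massively redundant: adjacent rows share 99 of
100 samples per channel) to bound the O(rows x params^2) epoch cost.
Second, the `standardize` flag rescales each recording's decimated
channels to zero mean and unit variance before windowing.  The
shipped default is OFF, keeping the raw ADC-scale input convention;
it exists because large per-recording DC offsets dominate J^T J and
visibly stall LM convergence -- with offsets drawn from a wide
per-subject range, 25 epochs reach a validation MSE of ~0.13
standardized versus ~0.22 raw on the same data.  The CV benchmark
(below) enables it.

The NARX variant augments the 200-sample exogenous window with the
previous 10 outputs: teacher-forced (target values as feedback) during
training, closed-loop at evaluation.  The interpretation of the
feedback depth and exogenous content is this package's own, as the
topology is under-specified in the source material.

## Postprocessing and timing conventions

Smoothing is causal (mean of the last 10 outputs), preserving the
sub-second detection latency of the chain; the first nine samples
average over the available history.  Peak picking keeps strict local
maxima with prominence at or above the detection amplitude, greedily
suppressing any peak within 0.5 s of a stronger one (ties keep the
earlier).  The detection amplitude is calibrated on the training
recordings by minimizing the mean absolute count error over a 50-point
grid spanning the observed smoothed range, ties resolving to the
larger (more conservative) threshold; one amplitude is then used for
all subjects.  Calibration uses *all* training-fold recordings rather
than one per fold: the grid search costs almost nothing next to
training, and a single-subject calibration was observed to under- or
over-shoot entire folds.

`HeartbeatDetector.predict` reports event times re-referenced by a
constant detector latency calibrated on the training recordings,
alongside the amplitude.  Two constant delays separate the smoothed
probability peak from the mechanical window centre at R + 400 ms: the
causal moving average's group delay ((width-1)/2 samples, 45 ms at
width 10) and the network's own response delay -- its evidence keeps
accruing until the whole beat signature has entered the causal input
window, so its confidence tends to peak late in the target pulse.
Both are fixed properties of a trained chain, so a single correction
is calibrated on the training recordings: the shift that places the
largest fraction of training peak-to-previous-R offsets inside the
mechanical window [delay, delay + width), ties resolving to the
smallest correction.  The filter itself stays causal (this is
bookkeeping, not lookahead), IPI statistics are invariant to the
constant shift, and held-out subjects never influence the calibration.
The residual timing error is detection *jitter* within the 400 ms
window, which no constant shift can remove; it shrinks only as the
network's probability pulses sharpen with more training.

Missed-beat interpolation keeps a running median of the last five
accepted IPIs (only values inside [0.5, 1.5] s enter the history) and
inserts one midpoint beat when an observed gap reaches twice the
median; gaps beyond three medians are treated as dropouts and left
alone, and inserted half-intervals never enter the history.

## Evaluation

Metrics: signed percentage count error 100*(N_det - N_ref)/N_ref;
IPI series (first differences of event times) and their medians; an
IPI mean relative error over greedily matched beat pairs (nearest
time, each beat used once, tolerance 0.5 s = the minimum-IPI
constraint) -- the matching rule is this package's own, since pairing
is otherwise undefined; and paired tests gated by a Lilliefors
normality check at alpha 0.05 (non-normal differences go to Wilcoxon
signed-rank, exact for n <= 25, otherwise the normal approximation;
normal ones to a paired t-test).  Cross-validation assigns whole
subjects to folds (seeded shuffle, round-robin, sizes within one), so
every reported prediction is on subjects unseen during training and
amplitude calibration.

## Benchmark configuration

The end-to-end benchmark (`radarbeat.benchmark.run_cv_benchmark`)
generates a 12-subject x 60 s cohort at the default (mid) noise level
and cross-validates FF 20 1 with three folds, 24000 subsampled
training rows, a 50-epoch LM cap with patience 9, float32 Jacobian
accumulation and per-recording standardization.  It reports the pooled
count error, the fraction of detections inside the 400 ms post-R
window, and the pooled median-IPI difference.  The problem size was
chosen so a full run takes minutes on one CPU; within that budget,
the number of *subjects* per training fold proved far more valuable
than per-subject duration, because cross-subject generalization over
the operating-point phase theta0 is the hard part of the task.

## Known limitations

- The LM trainer materializes J^T J (P x P); it is sized for shallow
  networks (P ~ 4e3), not deep ones.
- The ellipse-fit calibration estimator needs the I/Q trajectory to
  sweep a substantial arc; shallow-breathing segments can make the
  conic fit ill-conditioned.
- Pan-Tompkins is implemented with zero-phase/centered filtering and
  is intended for clean single-lead ECG; it is the label generator,
  not a general-purpose arrhythmia-grade detector.
- IPI accuracy of the detector is intrinsically limited by the width
  of the training window (a detection may sit anywhere within the
  400 ms target), so the chain tracks averaged rates well but is not
  an HRV instrument.
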