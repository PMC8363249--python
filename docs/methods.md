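# Methods

## Signal model and pipeline

An abdominal recording is modelled as, per channel c,

    x_c(t) = w_m,c · m_c(t) + w_f,c · f(t) + wander + powerline + noise

where f is the fetal source and m_c the maternal contribution *as seen by
electrode c*.  The pipeline assumes the mixture is instantaneous and
linear; its three stages target the three things that model leaves behind
after blind separation: isoline drift (FIR), maternal residue (RLS) and
broadband noise (EEMD).

**FIR prefilter.** Windowed-sinc (Hamming) band-pass, defaults 3–150 Hz,
order 500 (odd tap count, exactly linear phase).  The taps are shifted to
an exact DC null (the raw window design leaves ≈ −54 dB at DC, visible on
long constant segments).  Zero-phase behaviour comes from compensating the
constant group delay of order/2 samples — not from forward–backward
filtering — so the effective order is the stated one; the filter state is
initialized at steady state so edges stay at stopband level.  For records
sampled below 300 Hz the upper cutoff must be reduced (the scaled test
records at 250 Hz use 3–100 Hz).

**FastICA.** Channels are centred and whitened by eigendecomposition
(strongest directions kept when reducing to 3 components); the unmixing
matrix starts from a seeded random orthonormal matrix and iterates the
symmetric kurtosis fixed point W ← E[(WZ)³Zᵀ]/n − 3W with symmetric
decorrelation after every sweep.  The iteration budget is 20 sweeps; an
early stop triggers when every row's direction change falls below 1e−4.
Running out of sweeps is recorded, never raised.  With two input channels
only two components exist; role assignment then yields no noise role.

**Role assignment.** The beat detector is run on every component.  The
component with the lowest detected rate inside 50–110 bpm is the maternal
reference; among the rest, candidates inside 110–200 bpm are ranked by RR
coefficient of variation (most regular wins) and the leftover is noise.
If no component shows a maternal-band rate the record is rejected
(searches log the failure and score the trial 0).  The bands are
physiological conventions, not fitted numbers.

**Polarity.** For each detected beat event the positive and negative
extrema within ±50 samples are compared; a strict majority of
negative-dominant beats flips the whole component.  The window is
interpreted in samples at the native rate (that is how the setting is
specified), so it spans 100 ms at 500 Hz and 200 ms at 250 Hz; beats at
fetal rates remain well inside either.

**RLS cancellation.** Primary d = aECG\*, reference x = maternal
component, both mean-subtracted and scaled to unit variance, the reference
additionally shifted by the integer lag (±0.1 s) maximizing
cross-correlation.  Standard exponentially-weighted recursion with
P(0) = I/δ, δ = 0.01, w(0) = 0, λ = 1 by default; with λ = 1 the recursion
is algebraically the growing-window regularized least-squares solution
(Σuuᵀ + δI)⁻¹Σud, which the tests verify to 1e−6.  Non-finite error values
abort with the offending sample index.  The filter order M is the main
tunable: too low under-cancels (maternal residue remains), too high starts
fitting — and removing — the fetal component; the benchmark shows the
intermediate optimum (ACC at M = 16 beats both M = 6 and M = 100).

**EEMD.** Sifting uses cubic-spline envelopes through the local extrema
with two mirror-reflected extrema appended at each end, a Cauchy-style
stop (normalized mean-envelope energy < 0.2) combined with the IMF
condition |#extrema − #zero-crossings| ≤ 1, and a hard cap of 50 sifts.
The ensemble adds white noise of sd N_std·σ(input) per trial and averages
IMF rows (and residuals) across N trials; N_std is a *fraction of the
input sd*, the convention of the noise-assisted EMD literature.  Stacks
are zero-padded to 12 rows so IMF index sets like "2+3+4+7" always address
valid rows; the residual trend is never selectable.  Plain-EMD
completeness (ΣIMF + residual = input) is exact by construction.

**R-peak detection.** CWT with the first derivative of a Gaussian
(`gaus1`) at six log-spaced scales matched to QRS widths 20–120 ms.  The
per-sample modulus maximum over scales is smoothed by a 10 ms Gaussian
(the gaus1 response to a symmetric peak is zero *at* the peak, so the raw
modulus is bimodal per beat), thresholded at k = 0.4 of a rolling
95th-percentile amplitude (2 s half-overlapping windows, interpolated),
pruned by a refractory rule that keeps the larger response (0.25 s fetal /
0.4 s maternal), and each event is finally localized on the raw-signal
absolute extremum within ±20 ms.  Detection indices are invariant to
positive amplitude scaling and equivariant to time shifts (up to border
effects of the rolling threshold).

**QRS boundaries and T waves.** Boundaries use the same gaus1 transform at
the scale whose pseudo-frequency is the centre of the level-4 detail
octave of a four-level dyadic decomposition (3fs/64); onset is the last
sample before R below 0.35 of the local detail maximum, offset the first
after, clipped to ±100 ms.  The literal dyadic scale 2⁴ was tried first
and discarded: at 500 Hz it smears the detail over ±80 ms and cannot
localize boundaries of a 60 ms complex to the required ±10 ms.  For the T
wave the QRS (±30 ms margin) is excised and bridged by linear
interpolation *before* the zero-phase 0.5–10 Hz Butterworth band-pass —
filtering first lets the complex ring into the T window — and the T peak
is the signed absolute maximum within 0.35 s after the QRS offset.

**Beat matching and statistics.** Greedy one-to-one matching of candidate
pairs within 50 ms, nearest first.  For beats separated by more than twice
the tolerance (always true at physiological rates vs 50 ms) greedy
matching is provably optimal; the property test checks equality with a
brute-force maximum matching on such beat-like instances.  On arbitrary
point sets greedy matching is *not* optimal (refs {0,10}, dets {9,11},
tolerance 10 is a counterexample), which is why the oracle instances are
beat trains.  ACC/SE/PPV/F1 carry exact Clopper–Pearson intervals on their
(numerator, denominator) pairs, F1 treated as the proportion 2TP of
2TP+FP+FN — the convention that reproduces the published boundary CIs
(99.43% for 644/644, 99.71% for 1288/1288).

**Bland–Altman and fHR.** Differences est − ref at matched beats
(instantaneous 60/RR rates; matched-beat pairing needs no interpolation);
μ ± 1.96σ limits, t-based CI for μ, √3·σ/√n standard error for the
limits.  The fHR trace is the 30-beat centred moving average of 60/RR with
FIGO-style zones (110–150 physiological; 80–110 and 150–180 increased
risk; beyond 80/180 high risk).

**ST analysis.** Beats are windowed 190 ms before to 410 ms after R
(window length round(0.6·fs)+1), each divided by its *signed* R amplitude
— this scales and polarity-aligns the cycles, necessary because blind
separation leaves per-record (and, for biphasic extracted beats,
per-beat) polarity arbitrary — and averaged in non-overlapping blocks of
30.  T/QRS = signed T peak (0.5–10 Hz) over QRS peak-to-peak within the
detected boundaries.  The 600 ms window is embedded in 2 s of zero context
before T filtering: a 0.5 Hz high-pass corner needs more support than the
window itself.  Agreement between the extracted series and a reference
series is Bland–Altman on paired blocks; the reference signal is passed
through the same FIR prefilter as the estimate, because the 3 Hz high-pass
reshapes the low-frequency T lobe and only identically measured series
are comparable.

**Quality indices.** mR:fR reads mean absolute amplitudes at the annotated
maternal and fetal R positions per channel and averages the chosen
channels' ratios; amplitudes are read on the FIR-filtered signal (baseline
wander otherwise biases the ratio toward 1).  kSQI uses the Pearson
(non-excess) kurtosis convention — clean spiky ECG scores 10–26, far above
the Gaussian 3, which matches how the index is reported in the ECG quality
literature; the excess convention would shift all values down by 3.
Correlation with accuracy uses Pearson r with a Fisher-z 95% CI.

**Hyperparameter search.** Exhaustive Cartesian product over channel
subsets (all of size ≥ 2; 11 for four channels), RLS orders (2…100 step
2), EEMD N ∈ {10,30,60} and N_std ∈ {0.1…0.9}; each such cell runs the
pipeline once and all IMF subsets are scored on the cell's shared stack
(the tests verify scored counts equal full recomputation).  The default
IMF candidate set is all subsets of sizes 1–3 over indices 2–10 plus the
larger combinations observed among benchmark winners; the published
reduced grid (4 subsets × 9 orders × N = 10 × N_std ∈ {0.1,0.9} × 12 IMF
sets) is available as `reduced_space()`.  Failures score 0 and are
logged; ties break by enumeration order (size-then-lexicographic).  The
segment variant optimizes on the leading 15/30/60 s and applies the winner
to the whole record.

## The synthetic generator

Beats are trains of five Gaussian bumps (P,Q,R,S,T) with per-wave
amplitude, width and centre; RR intervals are i.i.d. Gaussian in rate,
truncated to 30–250 bpm.  Defaults emulate benchmark abdominal data:
500 Hz, 5 min, maternal 85 ± 3 bpm, fetal 140 ± 5 bpm, four channels,
target mR:fR 2 (the good-quality regime; the hard records run up to ~10),
0.1 mV baseline wander at 0.3 Hz, 50 Hz powerline at 0.02 mV, white noise
0.02 mV.  Fetal mixing weights are rescaled so the realized mean mR:fR
hits the target exactly on the clean sources.

The maternal contribution is deliberately **rank-2 across channels**: two
fixed morphologies (normal and deep-S/broad-R) mixed per channel with an
electrode-specific axis angle (defaults 0°, 20°, 40°, 60°).  A single
rescaled maternal waveform would satisfy the ICA model exactly, making the
RLS and EEMD stages redundant by construction and the ICA-only baseline
unbeatable; spatial variation of the maternal projection is a documented
property of real abdominal leads and is precisely what leaves maternal
residue in the ICA output.  Ground truth — beat positions of both
sources, clean component signals, the rendered-template T/QRS (measured
on a finely rendered isolated beat, because the overlapping Gaussian
tails shift the naive amplitude arithmetic by ~3 %) — is exact.

What the generator does *not* model: autocorrelated heart-rate
variability, fetal movement and position changes, uterine EMG, electrode
motion artifacts, nonstationary mixing.  Passing the synthetic benchmarks
therefore demonstrates correctness of the machinery and the qualitative
stage behaviour (residue cancellation, denoising, order trade-off), not
clinical performance on real recordings.

## Benchmark conditions and problem sizes

The tests and the acceptance script run at scaled study conditions chosen
once: 250 Hz sampling (hence a 3–100 Hz prefilter), 60 s records for
detection benchmarks, 120 s for ST analysis (9 blocks of 30 beats), 30 s
for searches over small spaces.  The end-to-end benchmark record uses
mR:fR 2 and white noise at 2 % of the fetal channel amplitude; its
hyperparameters are chosen by the reduced-grid search, exactly as the
method prescribes, and the ICA-only baseline reuses the winning
configuration with the mode switched.  The comparison lands on a
two-channel subset (enumerated first among equals), where the maternal
residue story above plays out: the full pipeline recovers all beats while
ICA alone loses roughly a third of its F1.

## Numerical choices and degenerate inputs

δ = 0.01 for P(0) (small standard regularization; the self-cancellation
floor of the recursion is δ/Σx², so tests probing that floor use a smaller
δ); alignment search ±0.1 s; unit-variance amplitude centring.  Envelope
splines use two mirrored extrema per side; signals without three extrema
terminate decomposition with the residual carrying the trend.  Detection
on an all-zero signal returns an empty annotation set; metrics with a zero
denominator are NaN with an `undefined` flag rather than an error;
constant signals make SQIs NaN and correlation NaN.  WFDB output is
format-16 integer with gain 200/mV — bit-exact round trips hold for
ADC-representable amplitudes, CSV round trips are exact for all floats.
Annotation rescaling uses round-half-to-even and drops exact duplicates.

## Known limitations

Absolute T/QRS values of densely overlapping fetal beats are biased by
neighbouring-cycle leakage into the 600 ms window; the analysis is
therefore framed (as in clinical ST monitoring) as agreement between
identically measured series.  The boundary detector's ±10 ms accuracy is
verified on template beats, not on noisy extractions.  The across-record
CI aggregation style seen in some published summaries (mean with a CI) is
not reconstructible from per-record data and is not provided: only
unweighted means of per-record statistics are computed.  Real-data
performance claims require the real datasets, which are external to this
package.
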