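# fecgkit

Non-invasive fetal electrocardiography extracts the fetal ECG (fECG) from
electrodes on the maternal abdomen.  Each abdominal channel is a mixture in
which the maternal ECG (mECG) dominates the much weaker fetal signal, on
top of baseline wander, powerline interference and broadband noise.
`fecgkit` implements a three-stage separation pipeline together with the
full evaluation apparatus used to judge such methods, for researchers and
engineers working on fetal monitoring algorithms.

## The method

1. **FIR prefilter** — linear-phase band-pass, 3–150 Hz, order 500
   (Hamming window, group delay compensated), removing isoline drift.
2. **FastICA** — symmetric fixed-point iteration with the kurtosis contrast
   (nonlinearity u³, 20 iterations) splits the chosen channel subset into
   up to three components.  Components are assigned roles from the rate and
   regularity of the beats they carry: the maternal component (50–110 bpm),
   the fetal-enhanced component *aECG\** (110–200 bpm, most regular RR),
   and noise; polarity is fixed by majority vote over beat extrema.
3. **RLS cancellation** — the maternal component x(n) is adapted to the
   maternal residue inside aECG\* by exponentially-weighted recursive least
   squares (forgetting factor λ = 1, order M searched over 2…100):

       k(n) = P(n−1)u(n) / (λ + uᵀ(n)P(n−1)u(n))
       w(n) = w(n−1) + k(n) e(n),   e(n) = d(n) − wᵀ(n−1)u(n)

   The error signal e(n) is the fetal estimate.
4. **EEMD denoising** — ensemble empirical mode decomposition (N trials of
   sifting with added white noise of sd N_std·σ(signal), IMFs averaged over
   trials); the enhanced fECG\* is the sum of a selected IMF subset.

Fetal R peaks are then detected with a continuous wavelet transform
(first-derivative-of-Gaussian mother wavelet), and a detection within 50 ms
of an annotated beat counts as correct:

    ACC = TP/(TP+FP+FN),  SE = TP/(TP+FN),  PPV = TP/(TP+FP),
    F1 = 2·TP/(2·TP+FP+FN)     (all in %, exact binomial 95% CIs)

On top of that the package provides Bland–Altman fetal-heart-rate
agreement (μ ± 1.96σ limits), FIGO-style fHR traces with a 30-beat moving
average, STAN-style T/QRS ST analysis over 30-cycle averaged complexes,
signal-quality indices (mR:fR amplitude ratio, skewness and kurtosis SQI),
and an exhaustive hyperparameter search (channel subsets × RLS order ×
EEMD N, N_std × IMF subsets) maximizing detection accuracy, including the
segment-based variant that optimizes on the leading 15/30/60 s.

A synthetic generator produces 4-channel abdominal mixtures from
Gaussian-bump beat templates with known maternal/fetal R positions, a
rank-2 maternal projection across electrodes, and an analytic T/QRS ground
truth, so every stage is testable without clinical recordings.

## Worked example

```python
import dataclasses
from fecgkit import (EEMDConfig, FIRSpec, PipelineConfig, RLSConfig,
                     SyntheticConfig, evaluate, generate_record)

record = generate_record(SyntheticConfig(fs=250.0, duration=60.0, seed=1,
                                         mr_fr_target=2.0, noise_sd=0.007))
cfg = PipelineConfig(channels=(0, 3),
                     fir=FIRSpec(low=3.0, high=100.0, order=500),
                     rls=RLSConfig(M=16),
                     eemd=EEMDConfig(N=10, N_std=0.1, seed=0),
                     imfs=frozenset({1, 2, 3}))
full = evaluate(record.recording, record.fetal_R, cfg)
ica  = evaluate(record.recording, record.fetal_R,
                dataclasses.replace(cfg, mode="ica_only"))
```

prints (`python examples/02_extract_and_score.py`):

```
full pipeline : TP=140 FP=0 FN=0  ACC=100.00%  SE=100.00%  PPV=100.00%  F1=100.00%
ICA only      : TP=83 FP=47 FN=57  ACC=44.39%  F1=61.48%
```

All 140 fetal beats of the minute-long record are recovered by the full
pipeline.  The ICA-only baseline on the same electrode pair misses beats
and fires on maternal residue — channels 1 and 4 see the maternal cardiac
vector from different angles, so two ICA components cannot isolate the
fetal signal; the RLS stage exists to cancel exactly that residue.

The `examples/` directory has one short script per capability (simulation,
extraction and scoring, published-table recomputation, fHR agreement, ST
analysis, hyperparameter search, quality indices).  A thin CLI mirrors
them: `fecgkit simulate | extract | evaluate | optimize | stan | quality`.

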