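"""Extract the fetal ECG with ICA-RLS-EEMD and score the detected beats.

Also runs the ICA-only baseline with the same settings: on channel pairs
whose maternal projections differ, ICA alone leaves a large maternal
residue and its detections degrade, which is exactly what the adaptive RLS
cancellation and the EEMD denoising are there to fix.
"""

import dataclasses

from fecgkit import (
    EEMDConfig,
    FIRSpec,
    PipelineConfig,
    RLSConfig,
    SyntheticConfig,
    evaluate,
    generate_record,
)

record = generate_record(
    SyntheticConfig(fs=250.0, duration=60.0, seed=1, mr_fr_target=2.0, noise_sd=0.007)
)

cfg = PipelineConfig(
    channels=(0, 3),                      # the electrode pair with the widest maternal-axis gap
    fir=FIRSpec(low=3.0, high=100.0, order=500),
    rls=RLSConfig(M=16),                  # adaptive filter order
    eemd=EEMDConfig(N=10, N_std=0.1, seed=0),
    imfs=frozenset({1, 2, 3}),            # IMFs summed into the enhanced fECG*
)

full = evaluate(record.recording, record.fetal_R, cfg)
ica = evaluate(record.recording, record.fetal_R, dataclasses.replace(cfg, mode="ica_only"))

m = full.metrics
print(f"full pipeline : TP={full.counts.TP} FP={full.counts.FP} FN={full.counts.FN}"
      f"  ACC={m.acc:.2f}%  SE={m.se:.2f}%  PPV={m.ppv:.2f}%  F1={m.f1:.2f}%")
mi = ica.metrics
print(f"ICA only      : TP={ica.counts.TP} FP={ica.counts.FP} FN={ica.counts.FN}"
      f"  ACC={mi.acc:.2f}%  F1={mi.f1:.2f}%")
print()
print("A detection counts as correct within 50 ms of the annotated R peak;")
print("ACC = TP/(TP+FP+FN). The maternal residue in the ICA-only output")
print("shows up as false positives at the maternal beat positions.")
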