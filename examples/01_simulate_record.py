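"""Generate a synthetic abdominal recording with known ground truth.

Four abdominal channels mix a maternal ECG (rank-2 across electrodes, the
way a cardiac vector projects differently per lead), a weaker fetal ECG,
baseline wander, powerline interference and white noise.
"""

import numpy as np

from fecgkit import SyntheticConfig, generate_record

cfg = SyntheticConfig(fs=250.0, duration=60.0, seed=1, mr_fr_target=2.0)
record = generate_record(cfg)

rec = record.recording
print(f"channels: {rec.n_channels}, samples: {rec.n_samples}, fs: {rec.fs} Hz")
print(f"maternal beats: {len(record.maternal_R)} (~{60 * len(record.maternal_R) / rec.duration:.0f} bpm)")
print(f"fetal beats:    {len(record.fetal_R)} (~{60 * len(record.fetal_R) / rec.duration:.0f} bpm)")
print(f"fetal template T/QRS (ground truth): {record.true_t_qrs:.4f}")
rms = np.sqrt(np.mean(rec.data**2, axis=1))
print("per-channel RMS (mV):", np.round(rms, 3))
print()
print("The fetal component is ~2x weaker than the maternal one (mR:fR = 2),")
print("which is a typical good-quality abdominal recording; every beat")
print("position is known exactly, so extraction accuracy can be scored.")
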