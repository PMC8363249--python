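"""Record-quality indices that predict how hard the extraction will be.

mR:fR is the maternal-to-fetal R amplitude ratio in the abdominal leads;
sSQI and kSQI are the skewness and (Pearson) kurtosis of the amplitude
distribution.  Heavier maternal dominance and noisier channels correlate
with worse fetal QRS detection.
"""

import numpy as np

from fecgkit import (
    FIRSpec, SyntheticConfig, correlate_with_accuracy, fir_bandpass,
    generate_record, sqi_report,
)

fir = FIRSpec(low=3.0, high=100.0, order=500)

ratios, noise_levels = [], [0.005, 0.02, 0.05]
for target in (1.8, 3.0, 6.0):
    rec = generate_record(
        SyntheticConfig(fs=250.0, duration=30.0, seed=3, mr_fr_target=target)
    )
    filtered = fir_bandpass(rec.recording, fir)
    rep = sqi_report(filtered, rec.maternal_R, rec.fetal_R)
    ratios.append(rep.mr_fr)
    print(f"target mR:fR {target:>4}:  measured {rep.mr_fr:5.2f}   "
          f"sSQI {rep.ssqi:+5.2f}   kSQI {rep.ksqi:5.2f}")

print()
print("kSQI far above 3 marks the spiky, ECG-like amplitude distribution;")
print("a rising mR:fR means the fetal component is increasingly buried.")

r, (lo, hi) = correlate_with_accuracy([1.9, 2.4, 2.7, 4.8, 9.8], [100, 95, 92, 47, 13])
print(f"\nexample mR:fR vs ACC correlation: r = {r:.2f} [{lo:.2f}, {hi:.2f}]")
print("(strong negative, matching the difficulty-proxy interpretation)")
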