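"""Recompute the benchmark detection statistics from published counts.

The bundled table holds TP/FP/FN per record for the FECGDARHA (12 records)
and PhysioNet Challenge 2013 (25 records) evaluations; the four statistics
and their exact binomial confidence intervals follow from those counts.
"""

from fecgkit import clopper_pearson
from fecgkit.tables import count_above, dataset_means, recompute_statistics

stats = recompute_statistics()
print(stats[["dataset", "record", "TP", "FP", "FN", "acc_rc", "se_rc", "ppv_rc", "f1_rc"]]
      .head(5).round(2).to_string(index=False))
print("...")

means = dataset_means().round(2)
print("\nunweighted dataset means (%):")
print(means.rename(columns={"acc_rc": "ACC", "se_rc": "SE", "ppv_rc": "PPV", "f1_rc": "F1"}))

above = count_above(80.0)
print(f"\nrecords with ACC > 80%: FECGDARHA {above['fecgdarha']}/12, "
      f"Challenge {above['challenge2013']}/25")

lo, hi = clopper_pearson(644, 644)
print(f"\nexact binomial 95% CI for 644/644 correct beats: [{lo:.2f}, {hi:.2f}]%")
print("(the lower bound of a perfect record is not 100%: with n beats one")
print(" can only claim the true rate exceeds (alpha/2)^(1/n).)")
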