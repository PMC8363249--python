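"""Hyperparameter search: pick channels, RLS order and EEMD settings.

Every configuration cell runs the pipeline once; the candidate IMF subsets
are scored on that cell's shared decomposition.  Here a small space keeps
the run quick; `reduced_space()` gives the published 4 x 9 x 1 x 2 x 12
grid and `default_space()` the full one.
"""

from fecgkit import (
    EEMDConfig, FIRSpec, PipelineConfig, RLSConfig, SearchSpace,
    SyntheticConfig, generate_record, grid_search,
)

record = generate_record(SyntheticConfig(fs=250.0, duration=30.0, seed=1))
base = PipelineConfig(
    channels=(0, 3), fir=FIRSpec(low=3.0, high=100.0, order=500),
    rls=RLSConfig(M=16), eemd=EEMDConfig(N=10, N_std=0.1, seed=0),
    imfs=frozenset({1, 2, 3}),
)
space = SearchSpace(
    channel_subsets=[(0, 3), (1, 2)],
    rls_orders=[8, 16, 32],
    eemd_N=[10],
    eemd_Nstd=[0.1],
    imf_subsets=[frozenset({1, 2, 3}), frozenset({2, 3}), frozenset({2, 4})],
)
opt = grid_search(record.recording, record.fetal_R, space, base=base)

print(f"evaluated {len(opt.trials)} trials "
      f"({space.n_pipeline_runs} pipeline runs x {len(space.imf_subsets)} IMF sets)")
best = opt.best_config
print(f"best ACC: {opt.best_score:.2f}% with channels "
      f"{tuple(c + 1 for c in best.channels)}, M={best.rls.M}, "
      f"N={best.eemd.N}, N_std={best.eemd.N_std}, IMFs={sorted(best.imfs)}")
print()
print(opt.trials.groupby("rls_order")["acc"].max().rename("best ACC per order").to_string())
print()
print("ACC is the matching-based accuracy TP/(TP+FP+FN); the winning")
print("setting is what `evaluate` would then apply to the whole record.")
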