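"""Hyperparameter search: combinatorics, exhaustiveness, segment variants."""

import dataclasses

import numpy as np
import pytest

from fecgkit import (
    Recording,
    SearchSpace,
    SyntheticConfig,
    enumerate_channel_subsets,
    evaluate,
    generate_record,
    grid_search,
    reduced_space,
    default_space,
)
from fecgkit.errors import ParameterError
from fecgkit.optimizer import segment_optimize

from conftest import base_pipeline


class TestCombinatorics:
    @pytest.mark.parametrize("n, expected", [(4, 11), (2, 1), (3, 4)])
    def test_subset_counts(self, n, expected):
        subsets = enumerate_channel_subsets(n)
        assert len(subsets) == expected
        assert len(subsets) == 2**n - n - 1

    def test_deterministic_order(self):
        subsets = enumerate_channel_subsets(3)
        assert subsets == [(0, 1), (0, 2), (1, 2), (0, 1, 2)]

    def test_single_channel_rejected(self):
        with pytest.raises(ParameterError):
            enumerate_channel_subsets(1)

    def test_reduced_space_matches_published_sizes(self):
        space = reduced_space()
        assert len(space.channel_subsets) == 4
        assert len(space.rls_orders) == 9
        assert space.rls_orders == [2, 16, 32, 42, 50, 64, 86, 94, 100]
        assert space.eemd_N == [10]
        assert space.eemd_Nstd == [0.1, 0.9]
        assert len(space.imf_subsets) == 12

    def test_default_space_run_count_closed_form(self):
        space = default_space(4)
        assert space.n_pipeline_runs == 11 * 50 * 3 * 9
        assert space.n_trials == space.n_pipeline_runs * len(space.imf_subsets)


@pytest.fixture(scope="module")
def small_record():
    return generate_record(
        SyntheticConfig(fs=250, duration=30, seed=1, mr_fr_target=2.0, noise_sd=0.007)
    )


def _tiny_space(**kw):
    defaults = dict(
        channel_subsets=[(0, 3)],
        rls_orders=[16],
        eemd_N=[10],
        eemd_Nstd=[0.1],
        imf_subsets=[frozenset({1, 2, 3}), frozenset({2, 3})],
    )
    defaults.update(kw)
    return SearchSpace(**defaults)


class TestGridSearch:
    def test_singleton_space_returns_that_config(self, small_record):
        space = _tiny_space(imf_subsets=[frozenset({1, 2, 3})])
        opt = grid_search(small_record.recording, small_record.fetal_R, space, base=base_pipeline())
        cfg = opt.best_config
        assert cfg.channels == (0, 3) and cfg.rls.M == 16
        assert cfg.imfs == frozenset({1, 2, 3})
        assert len(opt.trials) == 1

    def test_trial_log_is_exhaustive(self, small_record):
        space = _tiny_space(rls_orders=[8, 16], eemd_Nstd=[0.1, 0.3])
        opt = grid_search(small_record.recording, small_record.fetal_R, space, base=base_pipeline())
        assert len(opt.trials) == space.n_trials == 1 * 2 * 1 * 2 * 2
        assert opt.best_score == opt.trials["acc"].max()

    def test_imf_scoring_matches_full_recomputation(self, small_record):
        """Scoring IMF subsets on the shared stack must equal re-running the
        whole pipeline with that IMF choice."""
        space = _tiny_space()
        opt = grid_search(small_record.recording, small_record.fetal_R, space, base=base_pipeline())
        for _, row in opt.trials.iterrows():
            imfs = frozenset(int(t) for t in row["imfs"].split("+"))
            cfg = base_pipeline(channels=(0, 3), imfs=imfs)
            res = evaluate(small_record.recording, small_record.fetal_R, cfg)
            assert (res.counts.TP, res.counts.FP, res.counts.FN) == (
                row["TP"], row["FP"], row["FN"],
            )

    def test_failing_trials_score_zero_without_aborting(self, rng):
        noise = Recording(rng.standard_normal((4, 250 * 20)), 250.0, list("abcd"))
        ref = generate_record(SyntheticConfig(fs=250, duration=20, seed=0)).fetal_R
        opt = grid_search(noise, ref, _tiny_space(), base=base_pipeline())
        assert opt.best_score == 0.0
        assert opt.trials["error"].notna().all()

    def test_reduced_space_on_clean_record_reaches_95(self, bench_record, bench_search):
        best = bench_search.best_config
        res = evaluate(bench_record.recording, bench_record.fetal_R, best)
        assert res.metrics.f1 >= 95.0


class TestSegmentOptimize:
    def test_full_length_segment_equals_plain_search(self, small_record):
        space = _tiny_space()
        opt = grid_search(small_record.recording, small_record.fetal_R, space, base=base_pipeline())
        cfg, res = segment_optimize(
            small_record.recording, small_record.fetal_R, space,
            segment_s=small_record.recording.duration, base=base_pipeline(),
        )
        assert cfg.to_flat() == opt.best_config.to_flat()

    def test_60s_segment_matches_full_optimization_on_stationary_record(self):
        rec = generate_record(
            SyntheticConfig(fs=250, duration=120, seed=1, mr_fr_target=2.0, noise_sd=0.007)
        )
        space = _tiny_space(imf_subsets=[frozenset({1}), frozenset({1, 2, 3}), frozenset({2, 3})])
        opt_full = grid_search(rec.recording, rec.fetal_R, space, base=base_pipeline())
        _, ev = segment_optimize(rec.recording, rec.fetal_R, space, 60.0, base=base_pipeline())
        assert abs(ev.metrics.acc - opt_full.best_score) <= 2.0

    def test_short_segment_misleads_on_nonstationary_record(self):
        """Noise that appears after 15 s makes the 15 s-optimized setting
        strictly worse than the 60 s one on the full record."""
        rec = generate_record(
            SyntheticConfig(fs=250, duration=120, seed=1, mr_fr_target=2.0, noise_sd=0.007)
        )
        data = rec.recording.data.copy()
        onset = int(15 * 250)
        data[:, onset:] += 0.08 * np.random.default_rng(9).standard_normal(
            (4, data.shape[1] - onset)
        )
        noisy = Recording(data, 250.0, list(rec.recording.labels))
        space = _tiny_space(imf_subsets=[frozenset({1}), frozenset({1, 2, 3}), frozenset({2, 3})])
        _, ev15 = segment_optimize(noisy, rec.fetal_R, space, 15.0, base=base_pipeline())
        _, ev60 = segment_optimize(noisy, rec.fetal_R, space, 60.0, base=base_pipeline())
        assert ev15.metrics.acc < ev60.metrics.acc

    def test_segment_longer_than_record_rejected(self, small_record):
        with pytest.raises(ParameterError):
            segment_optimize(
                small_record.recording, small_record.fetal_R, _tiny_space(), 3600.0
            )
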