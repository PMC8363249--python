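"""FastICA separation, component role assignment, polarity correction."""

import numpy as np
import pytest

from fecgkit import (
    ICAConfig,
    SyntheticConfig,
    assign_roles,
    correct_polarity,
    fastica,
    fir_bandpass,
    generate_record,
    render_ecg,
    whiten,
)
from fecgkit.errors import DegenerateInputError, RoleAssignmentError
from fecgkit.synthetic import fetal_template, maternal_template, render_ecg

from conftest import FIR_250


def _abs_corr(a, b):
    return np.abs(np.corrcoef(np.vstack([a, b]))[: len(a), len(a):])


class TestWhiten:
    def test_output_has_identity_covariance(self, rng):
        X = rng.standard_normal((3, 3)) @ rng.standard_normal((3, 5000))
        Z, _, _ = whiten(X)
        cov = Z @ Z.T / Z.shape[1]
        assert np.max(np.abs(cov - np.eye(3))) <= 1e-8

    def test_white_input_gets_rotation_like_transform(self, rng):
        X = rng.standard_normal((2, 20000))
        Z, _, _ = whiten(X)
        cov = Z @ Z.T / Z.shape[1]
        assert np.max(np.abs(cov - np.eye(2))) <= 1e-8

    def test_duplicated_channel_is_degenerate(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(DegenerateInputError):
            whiten(np.vstack([x, x]))


class TestFastICA:
    def test_recovers_laplacian_sources_from_random_mixing(self, rng):
        S = rng.laplace(size=(3, 50_000))
        A = rng.standard_normal((3, 3))
        res = fastica(A @ S, ICAConfig(seed=0))
        assert np.all(_abs_corr(S, res.components).max(axis=1) > 0.95)

    def test_independent_white_input_is_identity_up_to_sign_permutation(self, rng):
        S = rng.laplace(size=(3, 50_000))
        res = fastica(S, ICAConfig(seed=0))
        assert np.all(_abs_corr(S, res.components).max(axis=1) > 0.99)

    def test_non_gaussian_source_recovered_among_gaussians(self, rng):
        S = np.vstack([rng.standard_normal((2, 50_000)), rng.laplace(size=(1, 50_000))])
        res = fastica(rng.standard_normal((3, 3)) @ S, ICAConfig(seed=1))
        assert _abs_corr(S[2:], res.components).max() > 0.95

    def test_components_are_standardized(self, rng):
        X = rng.standard_normal((3, 3)) @ rng.laplace(size=(3, 20_000))
        res = fastica(X, ICAConfig(seed=0))
        assert np.allclose(res.components.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(res.components.std(axis=1), 1.0, atol=1e-9)

    def test_channel_reordering_leaves_components_invariant(self, rng):
        X = rng.standard_normal((3, 3)) @ rng.laplace(size=(3, 30_000))
        r1 = fastica(X, ICAConfig(seed=0))
        r2 = fastica(X[::-1], ICAConfig(seed=0))
        assert np.all(_abs_corr(r1.components, r2.components).max(axis=1) > 0.99)

    def test_iteration_budget_is_honored(self, rng):
        X = rng.standard_normal((3, 3)) @ rng.laplace(size=(3, 5000))
        res = fastica(X, ICAConfig(seed=0, max_iter=20))
        assert res.n_iter <= 20

    def test_cross_check_against_sklearn(self, rng):
        sklearn_ica = pytest.importorskip("sklearn.decomposition")
        S = rng.laplace(size=(3, 40_000))
        X = rng.standard_normal((3, 3)) @ S
        ours = fastica(X, ICAConfig(seed=0)).components
        ref = sklearn_ica.FastICA(
            n_components=3, fun="cube", whiten="unit-variance", random_state=0,
            max_iter=400,
        ).fit_transform(X.T).T
        assert np.all(_abs_corr(ours, ref).max(axis=1) > 0.98)


class TestAssignRoles:
    def _components(self, seed=2):
        rec = generate_record(SyntheticConfig(fs=250, duration=30, seed=seed))
        rng = np.random.default_rng(seed)
        return rec, np.vstack([
            rec.clean_fECG / rec.clean_fECG.std(),
            rng.standard_normal(rec.clean_fECG.size),
            rec.clean_mECG / rec.clean_mECG.std(),
        ])

    def test_roles_found_by_rate_bands(self):
        _, comps = self._components()
        roles = assign_roles(comps, 250.0)
        assert roles == {"mecg": 2, "aecg_star": 0, "noise": 1}

    def test_permutation_invariance(self):
        _, comps = self._components()
        roles = assign_roles(comps[::-1], 250.0)
        assert roles == {"mecg": 0, "aecg_star": 2, "noise": 1}

    def test_pure_noise_raises(self, rng):
        with pytest.raises(RoleAssignmentError):
            assign_roles(rng.standard_normal((3, 5000)), 250.0)

    def test_recovery_rate_on_separated_records(self):
        """Across 20 seeded records, ICA + role assignment finds the fetal
        component and a maternal-subspace reference in >= 90% of trials."""
        from fecgkit.synthetic import maternal_template_b

        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                fs=250, duration=30, seed=100 + seed, mr_fr_target=2.5, noise_sd=0.01
            )
            rec = generate_record(cfg)
            mat_b = render_ecg(cfg.maternal_template_b, rec.maternal_R.times(), 250, 30)
            filtered = fir_bandpass(rec.recording, FIR_250)
            res = fastica(filtered.data, ICAConfig(seed=seed))
            try:
                roles = assign_roles(res.components, 250.0)
            except RoleAssignmentError:
                continue
            fetal_corr = np.abs(
                [np.corrcoef(c, rec.clean_fECG)[0, 1] for c in res.components]
            )
            fetal_ok = int(np.argmax(fetal_corr)) == roles["aecg_star"]
            basis = np.vstack([rec.clean_mECG, mat_b]).T
            comp = res.components[roles["mecg"]]
            beta, *_ = np.linalg.lstsq(basis, comp, rcond=None)
            maternal_r2 = 1 - np.sum((comp - basis @ beta) ** 2) / np.sum(comp**2)
            hits += fetal_ok and maternal_r2 > 0.4
        assert hits >= 18


class TestCorrectPolarity:
    def _ecg(self):
        beats = np.arange(0.5, 29.5, 0.7)
        return render_ecg(maternal_template(), beats, 250.0, 30.0), beats

    def test_upright_signal_unchanged(self):
        x, _ = self._ecg()
        out, flipped = correct_polarity(x, 250.0)
        assert not flipped and np.array_equal(out, x)

    def test_inverted_signal_restored(self):
        x, _ = self._ecg()
        out, flipped = correct_polarity(-x, 250.0)
        assert flipped and np.allclose(out, x)

    def test_majority_rule_against_per_beat_count(self):
        x, beats = self._ecg()
        # invert 60% of the beats individually
        rng = np.random.default_rng(0)
        chosen = rng.choice(len(beats), size=int(0.6 * len(beats)), replace=False)
        mixed = np.zeros_like(x)
        for i, b in enumerate(beats):
            beat = render_ecg(maternal_template(), np.array([b]), 250.0, 30.0)
            mixed += -beat if i in chosen else beat
        inverted_majority = len(chosen) * 2 > len(beats)
        _, flipped = correct_polarity(mixed, 250.0)
        assert flipped == inverted_majority

    def test_involution_on_flag(self):
        x, _ = self._ecg()
        once, f1 = correct_polarity(-x, 250.0)
        twice, f2 = correct_polarity(once, 250.0)
        assert f1 and not f2 and np.array_equal(once, twice)

    def test_flat_signal_untouched(self):
        out, flipped = correct_polarity(np.zeros(1000), 250.0)
        assert not flipped and not out.any()
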