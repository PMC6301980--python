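"""Marginalization algebra, demixed PCA, decoding."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from graspdyn.dpca import (
    DPCAConfig,
    MARGINALIZATIONS,
    _run_lengths_ok,
    decode_over_time,
    explained_variance,
    fit_dpca,
    make_pseudo_trials,
    marginalize,
)
from graspdyn.rates import AlignmentSpec
from graspdyn.synthetic import Latent, LatentSpec, default_latents


def small_config(**over):
    kw = dict(n_components=8, lambda_repetitions=2, cv_iterations=20,
              n_shuffles=20, rng_seed=0)
    kw.update(over)
    return DPCAConfig(**kw)


class TestMarginalize:
    def test_constant_tensor(self):
        t = np.full((4, 3, 2, 10), 7.5)
        m = marginalize(t)
        assert np.allclose(m.terms["mean"], 7.5)
        for k in ("t", "f", "g", "tf", "tg", "fg", "tfg"):
            assert np.allclose(m.terms[k], 0.0)

    def test_force_only_tensor_has_no_grip_or_interaction(self):
        t = np.zeros((2, 3, 2, 10))
        t += np.array([-1.0, 0.0, 1.0])[None, :, None, None]
        m = marginalize(t)
        assert np.allclose(m.combined("grip"), 0.0)
        assert np.allclose(m.combined("interaction"), 0.0)
        assert np.allclose(m.combined("condition_independent"), 0.0)
        assert (m.combined("force") ** 2).sum() > 0

    def test_reconstruction_to_machine_precision(self, rng):
        t = rng.normal(size=(20, 3, 2, 390))
        m = marginalize(t)
        rel = np.abs(m.reconstruct() - t).max() / np.abs(t).max()
        assert rel < 1e-10

    def test_balanced_shares_sum_to_one(self, rng):
        t = rng.normal(size=(5, 3, 2, 50))
        shares = marginalize(t).variance_shares()
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-10)


class TestFitDPCA:
    def test_one_latent_per_marginalization_recovered(self):
        lat = default_latents(n_units=30, rng=np.random.default_rng(0))
        t5 = lat.rate_tensor()[..., None].repeat(2, axis=-1)
        model = fit_dpca(t5, small_config(), lam=0.0)
        for m in MARGINALIZATIONS:
            comps = model.components_of(m)
            # one planted latent: the leading component carries >99% of
            # that marginalization's variance
            assert comps[0].explained_variance > 0.99 * model.marginalization_variance_raw[m]

    def test_lambda0_single_marginalization_matches_pca(self):
        # PCA oracle: with data confined to one marginalization the leading
        # dPCA axis equals the leading PCA axis (subspace angle < 1 degree)
        spec = AlignmentSpec()
        rng = np.random.default_rng(1)
        prof = np.cos(np.linspace(0, 3, spec.n_bins))
        lat = LatentSpec(
            [Latent("f", "force", prof, np.repeat([[-1.0], [0.5], [0.5]], 2, 1), 8.0)],
            mixing=rng.normal(size=(20, 1)),
            baselines=np.full(20, 40.0),
        )
        t5 = lat.rate_tensor(spec)[..., None].repeat(2, axis=-1)
        model = fit_dpca(t5, small_config(), lam=0.0)
        X = t5.mean(-1).reshape(20, -1)
        X = X - X.mean(axis=1, keepdims=True)
        pca = PCA(n_components=1).fit(X.T)
        enc = model.components_of("force")[0].encoder
        cos = abs(np.dot(enc, pca.components_[0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_cumulative_variance_bounded_by_pca(self, rng):
        lat = default_latents(n_units=25, rng=rng)
        noisy = lat.rate_tensor()[..., None] + rng.normal(
            0, 2.0, size=(25, 3, 2, 390, 5)
        )
        model = fit_dpca(noisy, small_config(), lam=0.0)
        X = noisy.mean(-1).reshape(25, -1)
        X = X - X.mean(axis=1, keepdims=True)
        total = (X**2).sum()
        pca_ev = np.sort(np.linalg.svd(X, compute_uv=False) ** 2)[::-1] / total
        dpc_ev = sorted((c.explained_variance for c in model.components), reverse=True)
        for k in range(1, min(len(dpc_ev), len(pca_ev)) + 1):
            assert sum(dpc_ev[:k]) <= sum(pca_ev[:k]) + 1e-9

    def test_explained_variance_report(self, rng):
        lat = default_latents(n_units=15, rng=rng)
        t5 = lat.rate_tensor()[..., None].repeat(2, axis=-1)
        model = fit_dpca(t5, small_config(), lam=0.0)
        rep = explained_variance(model)
        assert set(rep["marginalizations"]) == set(MARGINALIZATIONS)
        assert sum(rep["marginalizations"].values()) == pytest.approx(1.0, abs=0.02)
        assert all(0 <= c["explained_variance"] <= 1 for c in rep["components"])

    def test_degenerate_marginalization_yields_no_components(self):
        spec = AlignmentSpec()
        prof = np.sin(np.linspace(0, 2, spec.n_bins))
        lat = LatentSpec(
            [Latent("g", "grip", prof, np.repeat([[-1.0, 1.0]], 3, 0), 5.0)],
            mixing=np.ones((8, 1)),
            baselines=np.full(8, 30.0),
        )
        t5 = lat.rate_tensor(spec)[..., None].repeat(2, axis=-1)
        model = fit_dpca(t5, small_config(), lam=0.0)
        assert model.components_of("force") == []

    def test_seeded_determinism(self, rng):
        lat = default_latents(n_units=10, rng=rng)
        t5 = lat.rate_tensor()[..., None] + np.random.default_rng(0).normal(
            0, 1, size=(10, 3, 2, 390, 4)
        )
        m1 = fit_dpca(t5, small_config(rng_seed=9))
        m2 = fit_dpca(t5, small_config(rng_seed=9))
        assert m1.chosen_lambda == m2.chosen_lambda
        assert np.allclose(m1.components[0].decoder, m2.components[0].decoder)


class TestDecoding:
    def separated_tensor(self, rng, factor="grip", gap=30.0, r=8):
        t = np.full((12, 3, 2, 60, r), 20.0)
        if factor == "grip":
            t += np.arange(2)[None, None, :, None, None] * gap
        else:
            t += np.arange(3)[None, :, None, None, None] * gap
        return t + rng.normal(0, 1.0, size=t.shape)

    def test_separated_classes_decoded_near_perfectly(self, rng):
        t5 = self.separated_tensor(rng, "grip")
        model = fit_dpca(t5, small_config(), lam=0.0)
        res = decode_over_time(model, t5, "grip", small_config())
        assert res.accuracy.mean() > 0.95
        assert res.reported.any()
        assert all(b - a + 1 >= 10 for a, b in res.significant_intervals())

    def test_shuffled_labels_at_chance(self, rng):
        # chance level: 1/2 for grip, 1/3 for force
        t5 = self.separated_tensor(rng, "force", gap=0.0)
        model = fit_dpca(t5, small_config(), lam=0.0)
        res = decode_over_time(model, t5, "force", small_config())
        se = res.accuracy.std(ddof=1) / np.sqrt(len(res.accuracy))
        assert abs(res.accuracy.mean() - 1 / 3) < max(3 * se, 0.05)

    def test_nine_consecutive_bins_not_reported(self):
        mask = np.zeros(30, bool)
        mask[5:14] = True  # 9 consecutive bins
        assert not _run_lengths_ok(mask, 10).any()
        mask[14] = True  # 10th bin
        assert _run_lengths_ok(mask, 10).sum() == 10

    def test_pseudo_trial_bookkeeping(self, rng):
        proj = rng.normal(size=(4, 3, 2, 5, 6))
        test, train = make_pseudo_trials(proj, rng)
        total = proj.sum(axis=(0, -1))
        # held-out pseudo-trial plus scaled train mean restores the total
        assert np.allclose(test + train * (proj.shape[-1] - 1), total)

    def test_single_unit_passthrough(self, rng):
        proj = rng.normal(size=(1, 3, 2, 4, 3))
        test, _ = make_pseudo_trials(proj, rng)
        flat = proj[0].reshape(3, 2, 4, 3)
        # the pseudo-trial must be one of the unit's actual trials per condition
        for fi in range(3):
            for gi in range(2):
                assert any(
                    np.allclose(test[fi, gi], flat[fi, gi, :, r]) for r in range(3)
                )
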