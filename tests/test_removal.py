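"""Backward regression fit, purge algebra, streaming application, pipeline."""

import numpy as np
import pytest

from armbr.exceptions import ChannelMismatchError, DegenerateMaskError, NoBlinkError
from armbr.removal import (
    apply_pretrained,
    fit_and_purge,
    fit_spatial_filter,
    load_model,
    purge,
    save_model,
)
from armbr.signal_core import BandSpec, Recording, bandpass
from armbr.synthesis import make_scene


def random_fit(rng, n=2000, c=6):
    data = rng.standard_normal((n, c))
    mask = (rng.random(n) < 0.1).astype(float)
    mask[0], mask[1] = 0.0, 1.0
    rec = Recording(data, 128, [f"c{i}" for i in range(c)])
    return rec, mask


def cosine(u, v):
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestFitSpatialFilter:
    def test_matches_pseudoinverse_oracle(self, rng):
        """The stripped-intercept solution equals an independent
        pseudo-inverse solve of the same augmented design."""
        for _ in range(5):
            X = rng.standard_normal((50, 4))
            mask = (rng.random(50) < 0.3).astype(float)
            mask[:2] = [0.0, 1.0]
            rec = Recording(X, 128, list("abcd"))
            model = fit_spatial_filter(rec, mask)
            Xs = np.column_stack([X, np.ones(50)])
            w_star = np.linalg.pinv(Xs) @ mask
            w_oracle = w_star[:4] / (X @ w_star[:4]).std()
            np.testing.assert_allclose(model.W[:, 0], w_oracle, rtol=1e-8)

    def test_weight_concentrates_on_informative_channel(self, rng):
        n = 2000
        mask = (rng.random(n) < 0.15).astype(float)
        X = rng.standard_normal((n, 4))
        X[:, 0] = mask + 1e-2 * rng.standard_normal(n)
        rec = Recording(X, 128, list("abcd"))
        model = fit_spatial_filter(rec, mask)
        w = model.W[:, 0]
        assert abs(w[0]) / np.linalg.norm(w) > 0.99

    def test_offset_absorbed_by_intercept(self, rng):
        rec, mask = random_fit(rng)
        shifted = rec.copy_with(rec.data + 100.0)
        w0 = fit_spatial_filter(rec, mask).W
        w1 = fit_spatial_filter(shifted, mask).W
        np.testing.assert_allclose(w0, w1, rtol=1e-6, atol=1e-9)

    def test_degenerate_mask_raises(self, rng):
        rec, _ = random_fit(rng)
        with pytest.raises(DegenerateMaskError):
            fit_spatial_filter(rec, np.zeros(rec.n_samples))
        with pytest.raises(DegenerateMaskError):
            fit_spatial_filter(rec, np.ones(rec.n_samples))

    @pytest.mark.parametrize("seed", range(20))
    def test_projector_algebra(self, seed):
        """Unit training variance, A = Sigma W, M idempotent, X_purged W = 0."""
        rng = np.random.default_rng(seed)
        rec, mask = random_fit(rng, n=1500, c=8)
        model = fit_spatial_filter(rec, mask)
        Y = rec.data @ model.W
        assert Y.var(axis=0) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(model.A, model.Sigma @ model.W, atol=1e-9)
        M = model.M_purge
        assert np.abs(M @ M - M).max() < 1e-6
        purged = purge(rec, model).purged.data
        assert np.abs(purged @ model.W).max() < 1e-6 * rec.n_samples


class TestPurge:
    def test_idempotent(self, rng):
        rec, mask = random_fit(rng)
        model = fit_spatial_filter(rec, mask)
        once = purge(rec, model).purged
        twice = purge(once, model).purged
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_rank_drops_by_one(self, standard_scene):
        model, result, _ = fit_and_purge(standard_scene.mixed, ["Fp1", "Fp2"], alpha0=3.0)
        X, P = standard_scene.mixed.data, result.purged.data

        def num_rank(a):
            s = np.linalg.svd(a, compute_uv=False)
            return int((s > max(a.shape) * np.finfo(float).eps * s[0]).sum())

        assert num_rank(X) == 32
        assert num_rank(P) == 31

    def test_label_mismatch_raises(self, rng):
        rec, mask = random_fit(rng)
        model = fit_spatial_filter(rec, mask)
        other = Recording(rec.data, rec.fs, [f"z{i}" for i in range(rec.n_channels)])
        with pytest.raises(ChannelMismatchError):
            purge(other, model)

    def test_uncorrelated_residual_passes_through(self, rng):
        """Decompose the training data into its regression on the blink
        component, X = B_c A^T + E with cov(E_j, B_c) = 0, and verify the
        purge returns exactly E: content uncorrelated with the extracted
        blink time course is untouched (the zero-correlation assumption
        behind A = Sigma W)."""
        rec, mask = random_fit(rng, n=3000, c=6)
        model = fit_spatial_filter(rec, mask)
        Xc = rec.data - rec.data.mean(axis=0)
        bc = (Xc @ model.W)[:, 0]
        E = Xc - np.outer(bc, model.A[:, 0])
        # oracle: E is sample-decorrelated from the blink component
        assert np.abs(E.T @ bc).max() / len(bc) < 1e-9
        purged_c = Xc @ model.M_purge
        np.testing.assert_allclose(purged_c, E, rtol=1e-6, atol=1e-6 * np.abs(E).max())

    def test_channel_permutation_equivariance(self, rng):
        rec, mask = random_fit(rng, n=1200, c=5)
        perm = np.array([3, 0, 4, 1, 2])
        rec_p = Recording(rec.data[:, perm], rec.fs, [rec.channel_labels[i] for i in perm])
        m0 = fit_spatial_filter(rec, mask)
        m1 = fit_spatial_filter(rec_p, mask)
        np.testing.assert_allclose(m1.W[:, 0], m0.W[perm, 0], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(
            purge(rec_p, m1).purged.data,
            purge(rec, m0).purged.data[:, perm],
            rtol=1e-8,
            atol=1e-8,
        )


class TestApplyPretrained:
    def test_chunked_equals_batch_bitwise(self, rng):
        rec, mask = random_fit(rng, n=1280, c=4)
        model = fit_spatial_filter(rec, mask)
        batch = purge(rec, model).purged.data
        chunks = []
        for i in range(10):
            sub = Recording(rec.data[i * 128 : (i + 1) * 128], rec.fs, rec.channel_labels)
            chunks.append(apply_pretrained(sub, model).purged.data)
        np.testing.assert_array_equal(np.concatenate(chunks, axis=0), batch)

    def test_single_sample_chunk(self, rng):
        rec, mask = random_fit(rng)
        model = fit_spatial_filter(rec, mask)
        row = Recording(rec.data[:1], rec.fs, rec.channel_labels)
        out = apply_pretrained(row, model).purged.data
        np.testing.assert_array_equal(out, rec.data[:1] @ model.M_purge)

    def test_heldout_blink_energy_reduced(self):
        """A filter trained on the first half removes >= 90% of the 1-8 Hz
        energy along the planted pattern direction in the second half."""
        scene = make_scene(16, 128.0, 120.0, 20.0, peak_uV=100.0, background_rms_uV=10.0, seed=7)
        n_half = scene.mixed.n_samples // 2
        train = Recording(scene.mixed.data[:n_half], 128.0, scene.mixed.channel_labels)
        test = Recording(scene.mixed.data[n_half:], 128.0, scene.mixed.channel_labels)
        model, _, _ = fit_and_purge(train, ["Fp1", "Fp2"], alpha0="auto")
        out = apply_pretrained(test, model).purged
        a = scene.pattern / np.linalg.norm(scene.pattern)
        band = BandSpec(1, 8)
        e_in = (bandpass(test, band).data @ a) ** 2
        e_out = (bandpass(out, band).data @ a) ** 2
        assert e_out.sum() <= 0.1 * e_in.sum()


class TestFitAndPurge:
    def test_rmse_improves_on_blink_channels(self):
        scene = make_scene(16, 128.0, 60.0, 20.0, peak_uV=100.0, background_rms_uV=10.0, seed=2)
        _, result, _ = fit_and_purge(scene.mixed, ["Fp1", "Fp2"], alpha0="auto")
        affected = np.flatnonzero(scene.pattern > 0.3)
        for j in affected:
            err_purged = np.sqrt(np.mean((result.purged.data[:, j] - scene.clean.data[:, j]) ** 2))
            err_mixed = np.sqrt(np.mean((scene.mixed.data[:, j] - scene.clean.data[:, j]) ** 2))
            assert err_purged < err_mixed

    def test_zero_blink_scene_raises(self):
        scene = make_scene(8, 128.0, 30.0, 0.0, seed=4)
        with pytest.raises(NoBlinkError):
            fit_and_purge(scene.mixed, ["Fp1", "Fp2"], alpha0="auto")

    def test_pattern_recovery_single_scene(self):
        scene = make_scene(16, 128.0, 60.0, 20.0, peak_uV=100.0, background_rms_uV=10.0, seed=11)
        model, _, _ = fit_and_purge(scene.mixed, ["Fp1", "Fp2"], alpha0="auto")
        a = model.A[:, 0]
        assert abs(cosine(a, scene.pattern)) >= 0.99

    def test_pattern_recovery_median_over_seeds(self):
        cosines = []
        for seed in range(20):
            scene = make_scene(
                16, 128.0, 30.0, 20.0, peak_uV=100.0, background_rms_uV=10.0, seed=seed
            )
            model, _, _ = fit_and_purge(scene.mixed, ["Fp1", "Fp2"], alpha0=3.0)
            cosines.append(abs(cosine(model.A[:, 0], scene.pattern)))
        assert np.median(cosines) >= 0.99


class TestModelSerialization:
    def test_round_trip_bit_exact(self, rng, tmp_path):
        rec, mask = random_fit(rng)
        model = fit_spatial_filter(rec, mask)
        p = tmp_path / "model.json"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_array_equal(loaded.W, model.W)
        np.testing.assert_array_equal(loaded.A, model.A)
        np.testing.assert_array_equal(loaded.Sigma, model.Sigma)
        np.testing.assert_array_equal(loaded.intercept, model.intercept)
        assert loaded.channel_labels == model.channel_labels
        np.testing.assert_array_equal(
            purge(rec, loaded).purged.data, purge(rec, model).purged.data
        )
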