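import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from richfuse.dim_raising import (
    DEFAULT_WIDTHS,
    RaiserConfig,
    copy_raise,
    corrupt,
    dae_loss,
    encode,
    fit_raiser,
    load_raiser,
    poly_raise,
    reconstruct,
    save_raiser,
)

# Small topology that keeps unit-test fits under a second.
SMALL = RaiserConfig(layer_widths=(29, 116, 58, 116, 29), epochs=60, batch_size=16)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_dae_loss(recon, targets, weights, lam):
    recon = np.atleast_2d(recon)
    targets = np.atleast_2d(targets)
    total = 0.0
    for i in range(recon.shape[0]):
        for j in range(recon.shape[1]):
            total += (recon[i, j] - targets[i, j]) ** 2
    total /= recon.shape[0]
    for w in weights:
        for entry in np.ravel(w):
            total += lam * abs(entry)
    return total


def brute_force_poly(v):
    out = [1.0]
    out.extend(v)
    for i in range(len(v)):
        for j in range(i, len(v)):
            out.append(v[i] * v[j])
    return np.array(out)


class TestCopyRaise:
    def test_29_to_580_each_component_20_times(self):
        v = np.arange(29, dtype=float)
        out = copy_raise(v, 580)
        assert out.shape == (580,)
        for c in v:
            assert np.sum(out == c) == 20

    def test_identity_when_target_equals_dim(self):
        v = np.linspace(0, 1, 7)
        assert np.array_equal(copy_raise(v, 7), v)

    def test_partial_tile_465_to_580(self):
        v = np.arange(465, dtype=float)
        out = copy_raise(v, 580)
        assert out.shape == (580,)
        assert np.array_equal(out[:465], v)
        assert np.array_equal(out[465:], v[:115])

    def test_target_smaller_errors(self):
        with pytest.raises(ValueError):
            copy_raise(np.zeros(29), 28)


class TestPolyRaise:
    def test_29_gives_465(self):
        assert poly_raise(np.random.default_rng(0).random(29)).shape == (465,)

    def test_two_inputs_enumeration(self):
        a, b = 2.0, 3.0
        out = poly_raise(np.array([a, b]))
        assert np.allclose(out, [1.0, a, b, a * a, a * b, b * b])

    def test_zero_vector_only_bias(self):
        out = poly_raise(np.zeros(29))
        assert out[0] == 1.0
        assert np.all(out[1:] == 0.0)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_monomial_enumeration(self, n, rng):
        v = rng.random(n)
        out = poly_raise(v)
        assert out.shape == (1 + n + n * (n + 1) // 2,)
        assert np.allclose(out, brute_force_poly(v))


class TestCorrupt:
    def test_rate_zero_identity(self, rng):
        v = rng.random(29)
        out, mask = corrupt(v, 0.0, 1)
        assert np.array_equal(out, v)
        assert not mask.any()

    def test_rate_one_zeroes_all(self, rng):
        v = rng.random(29) + 0.5
        out, mask = corrupt(v, 1.0, 1)
        assert np.all(out == 0.0)
        assert mask.all()

    def test_kept_components_unchanged(self, rng):
        v = rng.random(29)
        out, mask = corrupt(v, 0.4, 2)
        assert np.array_equal(out[~mask], v[~mask])

    def test_reproducible_under_seed(self, rng):
        v = rng.random(29)
        a = corrupt(v, 0.3, seed=9)
        b = corrupt(v, 0.3, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mean_drop_count_converges(self):
        # law of large numbers: 10^4 draws of 29 components at rate 0.2
        v = np.ones((10_000, 29))
        _, mask = corrupt(v, 0.2, seed=3)
        mean_dropped = mask.sum(axis=1).mean()
        sigma = np.sqrt(29 * 0.2 * 0.8 / 10_000)
        assert abs(mean_dropped - 5.8) < 3 * sigma

    def test_bad_rate_errors(self):
        with pytest.raises(ValueError):
            corrupt(np.zeros(3), 1.5, 0)


class TestDaeLoss:
    def test_perfect_reconstruction_zero(self):
        x = np.random.default_rng(0).random((4, 29))
        assert dae_loss(x, x, [], 0.0) == 0.0

    def test_scalar_case(self):
        assert dae_loss([[0.4]], [[0.5]], [], 0.0) == pytest.approx(0.01)

    def test_scalar_case_with_l1(self):
        w = [np.array([1.0, -2.0])]
        assert dae_loss([[0.4]], [[0.5]], w, 0.1) == pytest.approx(0.31)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            dae_loss(np.zeros((2, 3)), np.zeros((2, 4)))

    @given(st.integers(0, 2**32 - 1), st.integers(1, 6), st.integers(1, 8))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed, n, d):
        gen = np.random.default_rng(seed)
        recon = gen.normal(size=(n, d))
        tgt = gen.normal(size=(n, d))
        weights = [gen.normal(size=(3, 4)), gen.normal(size=(4,))]
        lam = float(gen.random())
        assert dae_loss(recon, tgt, weights, lam) == pytest.approx(
            brute_force_dae_loss(recon, tgt, weights, lam), abs=1e-6
        )


class TestFitRaiser:
    def test_copy_fit_is_immediate(self, record_matrix):
        r = fit_raiser(record_matrix, RaiserConfig(method="copy"))
        assert r.fitted
        out = encode(r, record_matrix[0])
        assert np.array_equal(out, copy_raise(record_matrix[0], 580))

    def test_ip_goes_through_poly_then_copy(self, record_matrix):
        r = fit_raiser(record_matrix, RaiserConfig(method="interaction_polynomial"))
        out = encode(r, record_matrix[0])
        expected = copy_raise(poly_raise(record_matrix[0]), 580)
        assert np.array_equal(out, expected)

    def test_dae_l1_training_reduces_clean_mse(self, record_matrix):
        cfg = RaiserConfig(
            method="denoising_autoencoder_l1", layer_widths=SMALL.layer_widths,
            epochs=100, batch_size=16,
        )
        r = fit_raiser(record_matrix, cfg, seed=0)
        assert r.history["trained_clean_mse"] < r.history["untrained_clean_mse"]

    def test_l1_increases_weight_sparsity(self, record_matrix):
        near_zero = {}
        for lam in (0.0, 0.01):
            cfg = RaiserConfig(
                method="denoising_autoencoder_l1", layer_widths=SMALL.layer_widths,
                lam=lam, epochs=80, batch_size=16,
            )
            r = fit_raiser(record_matrix, cfg, seed=3)
            w = np.concatenate([np.ravel(m) for m in r.model.weight_matrices()])
            near_zero[lam] = np.mean(np.abs(w) < 1e-3)
        assert near_zero[0.01] > near_zero[0.0]

    def test_loss_history_non_increasing_up_to_tolerance(self, record_matrix):
        cfg = RaiserConfig(
            method="denoising_autoencoder_l1", layer_widths=SMALL.layer_widths,
            epochs=80, batch_size=16,
        )
        r = fit_raiser(record_matrix, cfg, seed=1)
        loss = np.array(r.history["epoch_loss"])
        tol = 0.05 * loss[0]
        assert np.all(np.diff(loss) <= tol)
        assert loss[-1] < loss[0]

    def test_asymmetric_widths_error(self):
        with pytest.raises(ValueError, match="symmetric"):
            RaiserConfig(layer_widths=(29, 100, 580, 290, 29))

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            fit_raiser(np.zeros((0, 29)), SMALL)

    def test_single_vector_errors(self):
        with pytest.raises(ValueError):
            fit_raiser(np.zeros((1, 29)), SMALL)


@pytest.fixture(scope="module")
def fitted(record_matrix):
    cfg = RaiserConfig(
        method="denoising_autoencoder", layer_widths=SMALL.layer_widths,
        epochs=100, batch_size=16,
    )
    return fit_raiser(record_matrix, cfg, seed=2)


class TestEncodeReconstruct:

    def test_default_topology_gives_580(self, record_matrix):
        cfg = RaiserConfig(epochs=3)
        r = fit_raiser(record_matrix[:40], cfg, seed=0)
        assert encode(r, record_matrix[0]).shape == (580,)
        assert cfg.layer_widths == DEFAULT_WIDTHS

    def test_encode_deterministic(self, fitted, record_matrix):
        a = encode(fitted, record_matrix[0])
        b = encode(fitted, record_matrix[0])
        assert np.array_equal(a, b)

    def test_zero_parameters_give_zero_code(self, record_matrix):
        r = fit_raiser(record_matrix[:10], RaiserConfig(layer_widths=SMALL.layer_widths, epochs=1), seed=0)
        for layer in r.model.layers:
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        assert np.all(encode(r, record_matrix[0]) == 0.0)

    def test_unfitted_encode_errors(self):
        from richfuse.dim_raising import DimensionRaiser

        r = DimensionRaiser(config=SMALL, fitted=False)
        with pytest.raises(ValueError):
            encode(r, np.zeros(29))

    def test_reconstruct_non_ae_errors(self, record_matrix):
        r = fit_raiser(record_matrix, RaiserConfig(method="copy"))
        with pytest.raises(ValueError):
            reconstruct(r, np.zeros(29))

    def test_reconstruction_in_unit_range_and_shape(self, fitted, rng):
        out = reconstruct(fitted, rng.random(29))
        assert out.shape == (29,)
        assert np.all(np.isfinite(out))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_reconstruction_beats_mean_baseline(self, fitted, record_matrix):
        mean = record_matrix.mean(axis=0)
        baseline = np.mean((record_matrix - mean) ** 2)
        recon = reconstruct(fitted, record_matrix)
        assert np.mean((recon - record_matrix) ** 2) < baseline

    def test_denoising_beats_identity_on_corrupted_inputs(self, fitted, record_matrix):
        corrupted, _ = corrupt(record_matrix, 0.2, seed=11)
        recon = reconstruct(fitted, corrupted)
        err_recon = np.mean((recon - record_matrix) ** 2)
        err_identity = np.mean((corrupted - record_matrix) ** 2)
        assert err_recon < err_identity


class TestSerialization:
    def test_round_trip(self, tmp_path, record_matrix):
        cfg = RaiserConfig(layer_widths=SMALL.layer_widths, epochs=5)
        r = fit_raiser(record_matrix[:50], cfg, seed=4)
        path = tmp_path / "raiser.npz"
        save_raiser(r, path)
        back = load_raiser(path)
        assert back.config == r.config
        x = record_matrix[0]
        assert np.array_equal(encode(back, x), encode(r, x))
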