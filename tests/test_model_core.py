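import numpy as np
import pytest

from pairvae import model_core as mc
from pairvae._nn import BatchNormCenter, Dense, Dropout, ReLU


def small_spec(**kw):
    defaults = dict(d=3, input_dim_x=7, input_dim_y=5,
                    decoder_widths=(4, 6), dropout_rate=0.0, seed=0)
    defaults.update(kw)
    return mc.ModelSpec(**defaults)


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            small_spec(d=0)
        with pytest.raises(ValueError):
            small_spec(decoder_widths=(4, -1))
        with pytest.raises(ValueError):
            small_spec(dropout_rate=1.0)
        with pytest.raises(ValueError):
            small_spec(lambda_weight=-0.1)

    def test_json_roundtrip(self):
        spec = small_spec(lambda_weight=2.5, seed=11)
        assert mc.ModelSpec.from_json(spec.to_json()) == spec


class TestBuildNetworks:
    def test_decoder_widths_follow_spec(self):
        spec = mc.ModelSpec(d=10, input_dim_x=2000, input_dim_y=17, seed=0)
        inf, gen = mc.build_networks(spec)
        dense_dims = [l.params["W"].shape for l in gen.decoder_x.layers
                      if isinstance(l, Dense)]
        assert dense_dims == [(10, 32), (32, 64), (64, 128), (128, 2000)]
        dense_dims_y = [l.params["W"].shape for l in gen.decoder_y.layers
                        if isinstance(l, Dense)]
        assert dense_dims_y == [(10, 32), (32, 64), (64, 128), (128, 17)]
        enc_dims = [l.params["W"].shape for l in inf.trunk.layers
                    if isinstance(l, Dense)]
        assert enc_dims == [(2000, 128), (128, 64), (64, 32)]
        assert inf.head_mu.layers[0].params["W"].shape == (32, 10)
        assert inf.head_logvar.layers[0].params["W"].shape == (32, 10)

    def test_layer_recipe_order(self):
        _, gen = mc.build_networks(small_spec(dropout_rate=0.05))
        kinds = [type(l) for l in gen.decoder_x.layers]
        assert kinds == [Dense, BatchNormCenter, ReLU, Dropout,
                         Dense, BatchNormCenter, ReLU, Dropout, Dense]

    def test_batchnorm_has_no_learnable_scale(self):
        _, gen = mc.build_networks(small_spec())
        bn = [l for l in gen.decoder_x.layers if isinstance(l, BatchNormCenter)]
        assert bn and all(set(l.params) == {"beta"} for l in bn)

    def test_dropout_zero_train_equals_eval_given_batch_stats(self):
        # with dropout disabled, the only train/eval difference is which
        # batch-norm statistics are used; forcing them equal must make the
        # two modes agree
        spec = small_spec(dropout_rate=0.0)
        _, gen = mc.build_networks(spec)
        rng = np.random.default_rng(1)
        z = rng.standard_normal((32, spec.d))
        out_train = gen.decoder_x.forward(z, training=True, rng=None)
        h = z
        for layer in gen.decoder_x.layers:
            if isinstance(layer, BatchNormCenter):
                layer.running_mean = h.mean(axis=0)
                layer.running_var = h.var(axis=0)
            h = layer.forward(h, training=False, rng=None)
        np.testing.assert_allclose(h, out_train, atol=1e-10)

    def test_seed_determinism_bitwise(self):
        spec = small_spec(seed=9)
        inf1, gen1 = mc.build_networks(spec)
        inf2, gen2 = mc.build_networks(spec)
        s1 = mc.get_state(inf1, gen1)
        s2 = mc.get_state(inf2, gen2)
        assert s1.keys() == s2.keys()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])


class TestEncode:
    def test_degenerate_variance_sample_equals_mu(self):
        spec = small_spec()
        inf, _ = mc.build_networks(spec)
        # pin logvar head to a huge negative constant: variance -> 0
        inf.head_logvar.layers[0].params["W"][:] = 0.0
        inf.head_logvar.layers[0].params["b"][:] = -80.0
        x = np.random.default_rng(0).standard_normal((6, spec.input_dim_x))
        code = mc.encode(x, inf, rng=np.random.default_rng(1))
        np.testing.assert_allclose(code.sample, code.mu, atol=1e-15)

    def test_reparameterized_mean_matches_mu(self):
        spec = small_spec()
        inf, _ = mc.build_networks(spec)
        x = np.random.default_rng(0).standard_normal((1, spec.input_dim_x))
        rng = np.random.default_rng(2)
        base = mc.encode(x, inf, rng=None)
        draws = np.empty((100_000, spec.d))
        std = np.exp(0.5 * base.logvar[0])
        eps = rng.standard_normal((100_000, spec.d))
        draws = base.mu[0] + std * eps  # same reparameterization as encode
        se = std / np.sqrt(100_000)
        assert np.all(np.abs(draws.mean(axis=0) - base.mu[0]) < 4 * se)

    def test_identical_rows_identical_mu(self):
        spec = small_spec()
        inf, _ = mc.build_networks(spec)
        row = np.random.default_rng(3).standard_normal(spec.input_dim_x)
        x = np.vstack([row, row, row])
        code = mc.encode(x, inf, rng=None)
        np.testing.assert_array_equal(code.mu[0], code.mu[1])
        np.testing.assert_array_equal(code.mu[0], code.mu[2])

    def test_nan_input_raises(self):
        spec = small_spec()
        inf, _ = mc.build_networks(spec)
        x = np.full((2, spec.input_dim_x), np.nan)
        with pytest.raises(ValueError, match="finite"):
            mc.encode(x, inf)


class TestDecode:
    def test_shape_contract(self):
        spec = small_spec()
        _, gen = mc.build_networks(spec)
        out = mc.decode(np.zeros((4, spec.d)), gen, "x")
        assert out.shape == (4, spec.input_dim_x)
        assert np.all(np.isfinite(out))

    def test_per_row_map(self):
        spec = small_spec()
        _, gen = mc.build_networks(spec)
        z = np.random.default_rng(4).standard_normal((5, spec.d))
        single = mc.decode(z, gen, "y")
        doubled = mc.decode(np.vstack([z, z]), gen, "y")
        np.testing.assert_allclose(doubled[:5], doubled[5:], atol=1e-12)
        np.testing.assert_allclose(doubled[:5], single, atol=1e-12)

    def test_linear_variant_exact_matrix_multiply(self):
        spec = small_spec(decoder_widths=())
        _, gen = mc.build_networks(spec)
        rng = np.random.default_rng(5)
        W = rng.standard_normal((spec.d, spec.input_dim_x))
        b = rng.standard_normal(spec.input_dim_x)
        gen.decoder_x.layers[0].params["W"] = W
        gen.decoder_x.layers[0].params["b"] = b
        z = rng.standard_normal((8, spec.d))
        np.testing.assert_array_equal(mc.decode(z, gen, "x"), z @ W + b)

    def test_bad_modality(self):
        _, gen = mc.build_networks(small_spec())
        with pytest.raises(ValueError, match="modality"):
            mc.decode(np.zeros((1, 3)), gen, "z")


class TestKlTerm:
    def test_prior_is_zero(self):
        assert mc.kl_term(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0

    def test_closed_form_half(self):
        assert mc.kl_term(np.array([[1.0, 0.0]]), np.zeros((1, 2))) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self):
        mu = np.array([[0.5, -0.5]])
        logvar = np.array([[np.log(0.25), 0.0]])
        rng = np.random.default_rng(6)
        std = np.exp(0.5 * logvar[0])
        z = mu[0] + std * rng.standard_normal((1_000_000, 2))
        log_q = -0.5 * (((z - mu[0]) / std) ** 2 + logvar[0] + np.log(2 * np.pi)).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc_est = (log_q - log_p).mean()
        assert mc.kl_term(mu, logvar) == pytest.approx(mc_est, rel=0.01)

    def test_nonnegative_on_grid(self):
        for m in np.linspace(-3, 3, 7):
            for lv in np.linspace(-3, 3, 7):
                val = mc.kl_term(np.array([[m]]), np.array([[lv]]))
                assert val >= 0.0
                if m == 0.0 and lv == 0.0:
                    assert val == 0.0
                else:
                    assert val > 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mc.kl_term(np.zeros((2, 3)), np.zeros((2, 4)))


class TestReconTerm:
    def test_identity_zero(self):
        x = np.random.default_rng(7).standard_normal((3, 4))
        assert mc.recon_term(x, x) == 0.0

    def test_unit_squared_error(self):
        assert mc.recon_term(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])) == 1.0

    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        obs, rec = rng.standard_normal((8, 5)), rng.standard_normal((8, 5))
        expected = np.mean([sum((obs[i, j] - rec[i, j]) ** 2 for j in range(5))
                            for i in range(8)])
        assert mc.recon_term(obs, rec) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mc.recon_term(np.zeros((2, 3)), np.zeros((3, 2)))


class TestElboObjective:
    def test_lambda_zero_objective_is_kl(self):
        spec = small_spec()
        inf, gen = mc.build_networks(spec)
        rng = np.random.default_rng(9)
        x = rng.standard_normal((6, spec.input_dim_x))
        y = rng.standard_normal((6, spec.input_dim_y))
        loss, *_ = mc.elbo_objective(x, y, inf, gen, 0.0, rng=np.random.default_rng(1))
        assert loss.objective == pytest.approx(loss.kl)

    def test_pinned_networks_zero_objective(self):
        spec = small_spec(decoder_widths=())
        inf, gen = mc.build_networks(spec)
        # encoder pinned to the prior
        for head in (inf.head_mu, inf.head_logvar):
            head.layers[0].params["W"][:] = 0.0
            head.layers[0].params["b"][:] = 0.0
        # decoders pinned to output the (all-zero) batch exactly
        for dec in (gen.decoder_x, gen.decoder_y):
            dec.layers[0].params["W"][:] = 0.0
            dec.layers[0].params["b"][:] = 0.0
        x = np.zeros((4, spec.input_dim_x))
        y = np.zeros((4, spec.input_dim_y))
        loss, *_ = mc.elbo_objective(x, y, inf, gen, 1.0, rng=np.random.default_rng(2))
        assert loss.objective == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        spec = small_spec()
        inf, gen = mc.build_networks(spec)
        rng = np.random.default_rng(10)
        x = rng.standard_normal((5, spec.input_dim_x))
        y = rng.standard_normal((5, spec.input_dim_y))
        l1, *_ = mc.elbo_objective(x, y, inf, gen, 1.5, rng=np.random.default_rng(3))
        l2, *_ = mc.elbo_objective(x, y, inf, gen, 1.5, rng=np.random.default_rng(3))
        assert l1 == l2

    def test_decomposition_exact(self):
        spec = small_spec()
        inf, gen = mc.build_networks(spec)
        rng = np.random.default_rng(11)
        for lam in (0.0, 0.5, 2.0):
            x = rng.standard_normal((7, spec.input_dim_x))
            y = rng.standard_normal((7, spec.input_dim_y))
            loss, *_ = mc.elbo_objective(x, y, inf, gen, lam, rng=rng)
            assert loss.objective - loss.kl - lam * (loss.recon_x + loss.recon_y) \
                == pytest.approx(0.0, abs=1e-12)

    def test_negative_lambda_raises(self):
        spec = small_spec()
        inf, gen = mc.build_networks(spec)
        with pytest.raises(ValueError, match="lambda"):
            mc.elbo_objective(np.zeros((2, spec.input_dim_x)),
                              np.zeros((2, spec.input_dim_y)),
                              inf, gen, -1.0, rng=np.random.default_rng(0))


class TestCheckpoint:
    def test_roundtrip_bit_identical_forward(self, tmp_path):
        spec = small_spec(dropout_rate=0.05, seed=21)
        inf, gen = mc.build_networks(spec)
        # perturb running stats so they are not the init defaults
        rng = np.random.default_rng(12)
        z = rng.standard_normal((16, spec.d))
        gen.decoder_x.forward(z, training=True, rng=rng)
        mc.save_checkpoint(tmp_path / "ckpt", spec, inf, gen)
        spec2, inf2, gen2 = mc.load_checkpoint(tmp_path / "ckpt")
        assert spec2 == spec
        x = rng.standard_normal((5, spec.input_dim_x))
        np.testing.assert_array_equal(
            mc.encode(x, inf).mu, mc.encode(x, inf2).mu)
        np.testing.assert_array_equal(
            mc.decode(z, gen, "x"), mc.decode(z, gen2, "x"))
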