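"""The dual-pathway VAE: architecture contracts, loss composition,
pathway ablations, determinism, and training behavior."""

import numpy as np
import pandas as pd
import pytest

import lorentzvae as lv
from lorentzvae import _autodiff as ad
from lorentzvae.model import LorentzVAE, ModelConfig, PosteriorParams
from lorentzvae.synthetic import SyntheticSpec, generate_rna

RNG = np.random.default_rng(123)


def tiny_dataset(n=60, d=30, seed=0):
    X, truth = generate_rna(SyntheticSpec(n_cells=n, n_features=d,
                                          n_clusters=2, hierarchy_depth=1,
                                          seed=seed))
    return lv.preprocess(X), truth


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=4, bottleneck_dim=4)
        with pytest.raises(ValueError):
            ModelConfig(likelihood="gaussian")
        with pytest.raises(ValueError):
            ModelConfig(lambda_geo=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(use_main_path=False, use_bn_path=False)
        with pytest.raises(ValueError):
            ModelConfig(batch_size=1)


class TestEncode:
    def test_shapes_and_determinism(self, trained_small, small_processed):
        model, _ = trained_small
        p = model.encode(small_processed.model_input)
        n = small_processed.n_cells
        assert p.mu.shape == (n, 10) and p.log_var.shape == (n, 10)
        p2 = model.encode(small_processed.model_input)
        assert np.array_equal(p.mu, p2.mu)
        assert np.array_equal(p.log_var, p2.log_var)

    def test_hidden_width_parameter_audit(self, trained_small, small_processed):
        model, _ = trained_small
        D = small_processed.n_features
        first = model.params["enc_W1"].data.size + model.params["enc_b1"].data.size
        assert first == D * 128 + 128

    def test_dimension_mismatch_rejected(self, trained_small):
        model, _ = trained_small
        with pytest.raises(ValueError):
            model.encode(np.zeros((3, 7)))


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        p = PosteriorParams(RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4)))
        assert np.array_equal(LorentzVAE.reparameterize(p, np.zeros((5, 4))), p.mu)

    def test_unit_logvar_shifts_by_one(self):
        p = PosteriorParams(RNG.normal(size=(5, 4)), np.zeros((5, 4)))
        z = LorentzVAE.reparameterize(p, np.ones((5, 4)))
        assert np.allclose(z, p.mu + 1.0)

    def test_monte_carlo_mean(self):
        p = PosteriorParams(np.full((1, 2), 0.7), np.zeros((1, 2)))
        draws = np.stack([LorentzVAE.reparameterize(
            p, RNG.standard_normal((1, 2))) for _ in range(100000)])
        assert np.allclose(draws.mean(axis=0), 0.7, atol=3 / np.sqrt(1e5))


class TestBottleneck:
    def test_default_shapes(self, trained_small):
        model, _ = trained_small
        le, ld = model.bottleneck_transform(RNG.normal(size=(7, 10)))
        assert le.shape == (7, 2) and ld.shape == (7, 10)

    def test_affine_at_zero(self, trained_small):
        model, _ = trained_small
        le, ld = model.bottleneck_transform(np.zeros((3, 10)))
        be = model.params["bn_be"].data
        assert np.allclose(le, be)
        assert np.allclose(ld, be @ model.params["bn_Wd"].data
                           + model.params["bn_bd"].data)

    def test_additivity(self, trained_small):
        model, _ = trained_small
        z1, z2 = RNG.normal(size=(4, 10)), RNG.normal(size=(4, 10))
        f = lambda z: model.bottleneck_transform(z)[1]
        zero = f(np.zeros((4, 10)))
        assert np.allclose(f(z1 + z2) - zero, (f(z1) - zero) + (f(z2) - zero),
                           atol=1e-10)

    def test_bundle_matches_exact_linear_maps(self, trained_small, small_processed):
        model, _ = trained_small
        b = model.latent_bundle(small_processed.model_input)
        We, be = model.params["bn_We"].data, model.params["bn_be"].data
        Wd, bd = model.params["bn_Wd"].data, model.params["bn_bd"].data
        assert np.allclose(b.l_e, b.z @ We + be, atol=1e-12)
        assert np.allclose(b.l_d, b.l_e @ Wd + bd, atol=1e-12)


class TestDecode:
    def test_softmax_mean_conserves_library(self, trained_small):
        model, _ = trained_small
        lib = RNG.uniform(500, 5000, 9)
        params = model.decode_params(RNG.normal(size=(9, 10)), lib)
        assert np.all(params.mean > 0)
        assert np.allclose(params.mean.sum(axis=1), lib, rtol=1e-4)

    def test_doubling_library_doubles_mean_only(self, trained_small):
        model, _ = trained_small
        code = RNG.normal(size=(5, 10))
        lib = RNG.uniform(100, 1000, 5)
        a = model.decode_params(code, lib)
        b = model.decode_params(code, 2 * lib)
        assert np.allclose(b.mean, 2 * a.mean, rtol=1e-10)
        assert np.allclose(a.dispersion, b.dispersion)

    def test_nonpositive_library_rejected(self, trained_small):
        model, _ = trained_small
        with pytest.raises(ValueError):
            model.decode_params(np.zeros((2, 10)), np.array([100.0, 0.0]))

    def test_shared_decoder_parameter_identity(self, trained_small):
        # both pathways call _decode_t on the same parameter store; there is
        # exactly one set of decoder weights
        model, _ = trained_small
        dec_names = [k for k in model.params if k.startswith("dec_")]
        assert set(dec_names) == {"dec_W1", "dec_b1", "dec_g1", "dec_beta1",
                                  "dec_Wout", "dec_bout"}


class TestLossComposition:
    def test_components_recombine(self):
        ds, _ = tiny_dataset()
        cfg = ModelConfig(latent_dim=6, bottleneck_dim=2, lambda_geo=5.0,
                          beta_kl=1.0, seed=0)
        model = LorentzVAE(ds.n_features, cfg)
        parts = model.loss_components(ds.raw_counts, ds.model_input,
                                      ds.library_sizes)
        manual = (cfg.lambda_recon1 * parts["recon1"]
                  + cfg.lambda_recon2 * parts["recon2"]
                  + cfg.lambda_geo * parts["geo"] + cfg.beta_kl * parts["kl"])
        assert parts["total"] == pytest.approx(manual, abs=1e-6)

    def test_zero_weights_leave_recon_sum(self):
        ds, _ = tiny_dataset()
        cfg = ModelConfig(latent_dim=6, bottleneck_dim=2, lambda_geo=0.0,
                          beta_kl=0.0, seed=0)
        model = LorentzVAE(ds.n_features, cfg)
        parts = model.loss_components(ds.raw_counts, ds.model_input,
                                      ds.library_sizes)
        assert parts["total"] == pytest.approx(parts["recon1"] + parts["recon2"],
                                               rel=1e-12)

    def test_default_geometry_weight_is_five(self):
        assert ModelConfig().lambda_geo == 5.0

    def test_ablations_zero_out_components(self):
        ds, _ = tiny_dataset()
        no_main = LorentzVAE(ds.n_features, ModelConfig(
            latent_dim=6, bottleneck_dim=2, use_main_path=False, seed=0))
        parts = no_main.loss_components(ds.raw_counts, ds.model_input,
                                        ds.library_sizes)
        assert parts["recon1"] == 0.0 and parts["recon2"] > 0
        no_bn = LorentzVAE(ds.n_features, ModelConfig(
            latent_dim=6, bottleneck_dim=2, use_bn_path=False, seed=0))
        parts = no_bn.loss_components(ds.raw_counts, ds.model_input,
                                      ds.library_sizes)
        assert parts["recon2"] == 0.0 and parts["geo"] == 0.0
        assert parts["recon1"] > 0

    def test_empty_batch_rejected(self):
        ds, _ = tiny_dataset()
        model = LorentzVAE(ds.n_features, ModelConfig(latent_dim=6,
                                                      bottleneck_dim=2))
        with pytest.raises(ValueError):
            model.loss_components(ds.raw_counts[:0], ds.model_input[:0],
                                  ds.library_sizes[:0])


class TestKL:
    def _kl(self, mu, lv_):
        n, d = mu.shape
        ds_cfg = ModelConfig(latent_dim=d, bottleneck_dim=d - 1)
        sig2 = np.exp(lv_)
        return (sig2 + mu ** 2 - 1 - lv_).sum() / (2 * n * d)

    def test_posterior_equal_prior_gives_zero(self):
        assert self._kl(np.zeros((4, 3)), np.zeros((4, 3))) == 0.0

    def test_hand_value(self):
        # N=1, d=1, mu=1, sigma^2=1 -> (1 + 1 - 1 - 0)/2 = 0.5
        assert self._kl(np.ones((1, 1)), np.zeros((1, 1))) == pytest.approx(0.5)

    def test_nonnegative_and_duplication_invariant(self):
        for _ in range(200):
            mu = RNG.normal(size=(6, 4))
            lv_ = RNG.normal(size=(6, 4))
            v = self._kl(mu, lv_)
            assert v >= 0
            assert self._kl(np.vstack([mu, mu]), np.vstack([lv_, lv_])) == \
                pytest.approx(v, rel=1e-12)


class TestFit:
    def test_loss_decreases_and_trace_schema(self, trained_small):
        _, trace = trained_small
        assert list(trace.columns) == ["epoch", "recon1", "recon2", "kl",
                                       "geo", "total"]
        assert trace["total"].iloc[-1] < trace["total"].iloc[0]

    def test_seeded_determinism(self):
        ds, _ = tiny_dataset()
        cfg = ModelConfig(latent_dim=6, bottleneck_dim=2, epochs=5,
                          early_stopping=False, seed=9, batch_size=32)
        _, t1 = lv.fit(ds, config=cfg)
        _, t2 = lv.fit(ds, config=cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_gradient_norms_clipped(self):
        ds, _ = tiny_dataset()
        cfg = ModelConfig(latent_dim=6, bottleneck_dim=2, epochs=3,
                          early_stopping=False, seed=0, batch_size=32)
        model = LorentzVAE(ds.n_features, cfg)
        model.fit(ds, collect_grad_norms=True)
        assert len(model.grad_norms_) > 0
        assert max(model.grad_norms_) <= cfg.grad_clip + 1e-6

    def test_plain_vae_equivalence_oracle(self):
        """With the bottleneck off and lambda_geo=0 the per-batch loss equals
        an independently coded minimal VAE on identical weights/noise."""
        ds, _ = tiny_dataset(n=40, d=20)
        cfg = ModelConfig(latent_dim=5, bottleneck_dim=2, use_bn_path=False,
                          lambda_geo=0.0, likelihood="poisson", seed=4)
        model = LorentzVAE(ds.n_features, cfg)
        eps = RNG.standard_normal((ds.n_cells, 5))
        parts = model.loss_components(ds.raw_counts, ds.model_input,
                                      ds.library_sizes, eps=eps)

        # --- minimal numpy VAE with the same weights ---
        p = {k: v.data for k, v in model.params.items()}

        def layer(x, W, b, g, beta):
            h = x @ W + b
            mu = h.mean(axis=1, keepdims=True)
            v = ((h - mu) ** 2).mean(axis=1, keepdims=True)
            return np.maximum((h - mu) / np.sqrt(v + 1e-5) * g + beta, 0.0)

        h = layer(ds.model_input, p["enc_W1"], p["enc_b1"], p["enc_g1"],
                  p["enc_beta1"])
        mu = h @ p["enc_Wmu"] + p["enc_bmu"]
        lv_ = np.clip(h @ p["enc_Wlv"] + p["enc_blv"], -10, 10)
        z = mu + np.exp(lv_ / 2) * eps
        hd = layer(z, p["dec_W1"], p["dec_b1"], p["dec_g1"], p["dec_beta1"])
        logits = hd @ p["dec_Wout"] + p["dec_bout"]
        logits -= logits.max(axis=1, keepdims=True)
        log_sm = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        log_mu = log_sm + np.log(ds.library_sizes)[:, None]
        from scipy.special import gammaln
        x = ds.raw_counts.astype(float)
        ll = x * log_mu - np.exp(log_mu) - gammaln(x + 1)
        recon = -ll.sum() / x.shape[0]
        kl = (np.exp(lv_) + mu ** 2 - 1 - lv_).sum() / (2 * x.shape[0] * 5)
        assert parts["recon1"] == pytest.approx(recon, rel=1e-10)
        assert parts["kl"] == pytest.approx(kl, rel=1e-10)
        assert parts["total"] == pytest.approx(recon + kl, rel=1e-10)

    def test_nan_abort_names_component(self):
        ds, _ = tiny_dataset(n=40, d=20)
        cfg = ModelConfig(latent_dim=5, bottleneck_dim=2, seed=0,
                          early_stopping=False)
        model = LorentzVAE(ds.n_features, cfg)
        model.params["dec_Wout"].data[:] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            model.fit(ds, epochs=1)

    def test_two_views_and_detach_variants_train(self):
        ds, _ = tiny_dataset(n=50, d=20)
        for kw in ({"geo_anchor": "two_views"}, {"detach_anchor": True}):
            cfg = ModelConfig(latent_dim=5, bottleneck_dim=2, epochs=3,
                              early_stopping=False, seed=1, **kw)
            _, trace = lv.fit(ds, config=cfg)
            assert np.isfinite(trace["total"]).all()
            assert (trace["geo"] > 0).all()


class TestEmbed:
    def test_mean_mode_deterministic_with_shape(self, trained_small,
                                                small_processed):
        model, _ = trained_small
        Z1 = model.embed(small_processed)
        Z2 = model.embed(small_processed)
        assert Z1.shape == (small_processed.n_cells, 10)
        assert np.array_equal(Z1, Z2)

    def test_sample_mode_seeded(self, trained_small, small_processed):
        model, _ = trained_small
        a = model.embed(small_processed, mode="sample", seed=5)
        b = model.embed(small_processed, mode="sample", seed=5)
        c = model.embed(small_processed, mode="sample", seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestPersistence:
    def test_checkpoint_roundtrip(self, trained_small, small_processed, tmp_path):
        model, _ = trained_small
        f = tmp_path / "ckpt.npz"
        model.save(f)
        back = LorentzVAE.load(f)
        assert back.config == model.config
        assert back.feature_ids == model.feature_ids
        assert np.array_equal(back.embed(small_processed),
                              model.embed(small_processed))
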