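"""The dual-pathway VAE with Lorentzian geometric regularization.

A single encoder (one 128-unit hidden layer with layer normalization and
ReLU) maps normalized expression to a diagonal Gaussian posterior; a latent
code z is drawn by reparameterization and flows through two pathways:

* the primary path decodes z directly;
* the bottleneck path compresses z to l_e (dimension d_c << d) and expands
  it back to l_d with two plain affine maps, then decodes l_d with the SAME
  decoder.

Both reconstructions are scored with a count likelihood on the raw selected
counts (decoder softmax scaled by each cell's library size, so the
predicted means conserve the library size exactly). The total loss is

    L = lambda_r1 * L_recon1 + lambda_r2 * L_recon2
        + lambda_geo * L_geo + beta * L_KL,

where L_geo is the mean squared hyperboloid distance between exp_o(z) and
exp_o(l_d) — it pulls the information-rich primary code and the compressed
bottleneck reconstruction of it toward geometric agreement in hyperbolic
space, where tree-like structure embeds with low distortion.

Training uses Adam with global-norm gradient clipping; single-threaded CPU
execution with a fixed seed is the reproducibility contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

from . import _autodiff as ad
from ._autodiff import Tensor
from .likelihoods import FAMILIES, LikelihoodParams
from .preprocessing import ProcessedDataset

_LOGVAR_CLAMP = 10.0  # keep posterior variances in a sane numeric range


@dataclass
class ModelConfig:
    """Hyperparameters and variant switches.

    Defaults are the reference configuration: d=10 latent units, a 2-unit
    information bottleneck, 128 hidden units, NB likelihood, unit
    reconstruction/KL weights, geometric weight 5.0, Adam at 1e-4 with
    batch size 128 and gradient clipping at 1.0.
    """

    latent_dim: int = 10
    bottleneck_dim: int = 2
    hidden_dim: int = 128
    likelihood: str = "nb"
    lambda_recon1: float = 1.0
    lambda_recon2: float = 1.0
    beta_kl: float = 1.0
    lambda_geo: float = 5.0
    learning_rate: float = 1e-4
    batch_size: int = 128
    grad_clip: float = 1.0
    epochs: int = 400
    seed: int = 0
    use_main_path: bool = True
    use_bn_path: bool = True
    geo_anchor: str = "bottleneck"      # or "two_views"
    detach_anchor: bool = False
    early_stopping: bool = True
    patience: int = 20
    min_delta: float = 1e-4

    def __post_init__(self):
        if self.bottleneck_dim >= self.latent_dim:
            raise ValueError("bottleneck_dim must be < latent_dim")
        if self.likelihood not in FAMILIES:
            raise ValueError(f"likelihood must be one of {FAMILIES}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if min(self.lambda_recon1, self.lambda_recon2, self.beta_kl,
               self.lambda_geo) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.geo_anchor not in ("bottleneck", "two_views"):
            raise ValueError("geo_anchor must be 'bottleneck' or 'two_views'")
        if not (self.use_main_path or self.use_bn_path):
            raise ValueError("at least one pathway must be enabled")


@dataclass
class PosteriorParams:
    mu: np.ndarray
    log_var: np.ndarray


@dataclass
class LatentBundle:
    z: np.ndarray
    l_e: np.ndarray
    l_d: np.ndarray


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, (fan_in, fan_out))


def _geo_alpha(z: Tensor, ld: Tensor) -> Tensor:
    """alpha = -<exp_o(z), exp_o(ld)>_L, row-wise, differentiably."""
    tiny = 1e-24
    nz = ad.sqrt((z * z).sum(axis=1) + tiny)
    nl = ad.sqrt((ld * ld).sum(axis=1) + tiny)
    dot = (z * ld).sum(axis=1)
    return ad.cosh(nz) * ad.cosh(nl) - ad.sinh(nz) / nz * (ad.sinh(nl) / nl) * dot


def geometric_loss_ad(z: Tensor, ld: Tensor) -> Tensor:
    """Differentiable mean squared Lorentz distance (clamp + branch rules
    identical to :func:`lorentzvae.geometry.geometric_loss`)."""
    d = ad.arccosh_clamped(_geo_alpha(z, ld))
    return (d * d).mean()


class LorentzVAE:
    """Dual-pathway VAE; parameters live in a flat name -> Tensor store."""

    def __init__(self, n_features: int, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()
        self.n_features = int(n_features)
        self.feature_ids: Optional[list] = None
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        D, h, d, dc = self.n_features, c.hidden_dim, c.latent_dim, c.bottleneck_dim
        p: Dict[str, Tensor] = {}

        def par(name, arr):
            p[name] = Tensor(arr, requires_grad=True)

        par("enc_W1", _glorot(rng, D, h)); par("enc_b1", np.zeros(h))
        par("enc_g1", np.ones(h)); par("enc_beta1", np.zeros(h))
        par("enc_Wmu", _glorot(rng, h, d)); par("enc_bmu", np.zeros(d))
        par("enc_Wlv", _glorot(rng, h, d)); par("enc_blv", np.zeros(d))
        par("bn_We", _glorot(rng, d, dc)); par("bn_be", np.zeros(dc))
        par("bn_Wd", _glorot(rng, dc, d)); par("bn_bd", np.zeros(d))
        par("dec_W1", _glorot(rng, d, h)); par("dec_b1", np.zeros(h))
        par("dec_g1", np.ones(h)); par("dec_beta1", np.zeros(h))
        par("dec_Wout", _glorot(rng, h, D)); par("dec_bout", np.zeros(D))
        if c.likelihood in ("zinb", "zip"):
            par("dec_Wpi", _glorot(rng, h, D)); par("dec_bpi", np.zeros(D))
        if c.likelihood in ("nb", "zinb"):
            par("log_theta", np.zeros(D))
        self.params = p
        self._rng = rng

    # ---- forward pieces (autodiff; numpy facades below) ------------------

    def _encode_t(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        p = self.params
        h = ad.relu(ad.layer_norm(ad.linear(x, p["enc_W1"], p["enc_b1"]),
                                  p["enc_g1"], p["enc_beta1"]))
        mu = ad.linear(h, p["enc_Wmu"], p["enc_bmu"])
        lv = ad.clamp(ad.linear(h, p["enc_Wlv"], p["enc_blv"]),
                      -_LOGVAR_CLAMP, _LOGVAR_CLAMP)
        return mu, lv

    def _bottleneck_t(self, z: Tensor) -> Tuple[Tensor, Tensor]:
        p = self.params
        le = ad.linear(z, p["bn_We"], p["bn_be"])
        ld = ad.linear(le, p["bn_Wd"], p["bn_bd"])
        return le, ld

    def _decode_t(self, code: Tensor, lib: np.ndarray):
        """Return (log_mu, pi_logit or None); same parameters for both paths."""
        p = self.params
        h = ad.relu(ad.layer_norm(ad.linear(code, p["dec_W1"], p["dec_b1"]),
                                  p["dec_g1"], p["dec_beta1"]))
        log_mu = ad.log_softmax(ad.linear(h, p["dec_Wout"], p["dec_bout"]),
                                axis=1) + np.log(lib)[:, None]
        pi_logit = None
        if self.config.likelihood in ("zinb", "zip"):
            pi_logit = ad.linear(h, p["dec_Wpi"], p["dec_bpi"])
        return log_mu, pi_logit

    def _nll_t(self, x: np.ndarray, log_mu: Tensor, pi_logit) -> Tensor:
        """Per-cell mean negative log-likelihood, differentiable."""
        fam = self.config.likelihood
        n = x.shape[0]
        const = special.gammaln(x + 1.0)
        if fam in ("nb", "zinb"):
            theta = ad.exp(self.params["log_theta"])
            mu = ad.exp(log_mu)
            log_theta_mu = ad.log(theta + mu)
            nb_ll = (ad.lgamma(theta + x) - ad.lgamma(theta) - const
                     + theta * (ad.log(theta) - log_theta_mu)
                     + x * (log_mu - log_theta_mu))
            if fam == "nb":
                ll = nb_ll
            else:
                s = pi_logit
                nb0 = theta * (ad.log(theta) - log_theta_mu)
                ll = ad.where(x == 0,
                              ad.logaddexp(s, nb0) - ad.softplus(s),
                              nb_ll - ad.softplus(s))
        else:
            mu = ad.exp(log_mu)
            pois_ll = x * log_mu - mu - const
            if fam == "poisson":
                ll = pois_ll
            else:  # zip
                s = pi_logit
                ll = ad.where(x == 0,
                              ad.logaddexp(s, -mu) - ad.softplus(s),
                              pois_ll - ad.softplus(s))
        return -ll.sum() / n

    def _loss_graph(self, x_raw: np.ndarray, x_norm: np.ndarray,
                    lib: np.ndarray, eps: np.ndarray,
                    eps2: Optional[np.ndarray] = None):
        """Build the full loss graph for one batch; returns (total, parts)."""
        c = self.config
        xin = Tensor(x_norm)
        mu, lv = self._encode_t(xin)
        z = mu + ad.exp(lv * 0.5) * eps
        zero = Tensor(0.0)
        parts: Dict[str, Tensor] = {"recon1": zero, "recon2": zero, "geo": zero}
        if c.use_main_path:
            log_mu1, pi1 = self._decode_t(z, lib)
            parts["recon1"] = self._nll_t(x_raw, log_mu1, pi1)
        if c.use_bn_path:
            _, ld = self._bottleneck_t(z)
            log_mu2, pi2 = self._decode_t(ld, lib)
            parts["recon2"] = self._nll_t(x_raw, log_mu2, pi2)
            if c.geo_anchor == "bottleneck":
                anchor = ld.detach() if c.detach_anchor else ld
                parts["geo"] = geometric_loss_ad(z, anchor)
            else:  # two_views: two posterior samples, distance between them
                if eps2 is None:
                    raise ValueError("two_views anchor needs a second noise draw")
                z2 = mu + ad.exp(lv * 0.5) * eps2
                anchor = z2.detach() if c.detach_anchor else z2
                parts["geo"] = geometric_loss_ad(z, anchor)
        sig2 = ad.exp(lv)
        parts["kl"] = (sig2 + mu * mu - 1.0 - lv).sum() / (2.0 * x_raw.shape[0] * c.latent_dim)
        total = (c.lambda_recon1 * parts["recon1"]
                 + c.lambda_recon2 * parts["recon2"]
                 + c.lambda_geo * parts["geo"]
                 + c.beta_kl * parts["kl"])
        return total, parts

    # ---- public numpy API -------------------------------------------------

    def encode(self, model_input: np.ndarray) -> PosteriorParams:
        """Posterior parameters (deterministic given the weights)."""
        x = np.asarray(model_input, dtype=np.float64)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.n_features}")
        if not np.all(np.isfinite(x)):
            raise ValueError("model input must be finite")
        mu, lv = self._encode_t(Tensor(x))
        return PosteriorParams(mu.data.copy(), lv.data.copy())

    @staticmethod
    def reparameterize(p: PosteriorParams, eps: np.ndarray) -> np.ndarray:
        """z = mu + sigma * eps with sigma = exp(log_var / 2)."""
        return p.mu + np.exp(0.5 * p.log_var) * eps

    def bottleneck_transform(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Affine compression to d_c and expansion back to d."""
        le, ld = self._bottleneck_t(Tensor(np.asarray(z, dtype=np.float64)))
        return le.data.copy(), ld.data.copy()

    def latent_bundle(self, model_input: np.ndarray,
                      eps: Optional[np.ndarray] = None) -> LatentBundle:
        p = self.encode(model_input)
        z = p.mu if eps is None else self.reparameterize(p, eps)
        le, ld = self.bottleneck_transform(z)
        return LatentBundle(z=z, l_e=le, l_d=ld)

    def decode_params(self, code: np.ndarray,
                      library_sizes: np.ndarray) -> LikelihoodParams:
        """Likelihood parameters from a latent code (either pathway)."""
        lib = np.asarray(library_sizes, dtype=np.float64)
        if np.any(lib <= 0):
            raise ValueError("library sizes must be strictly positive")
        log_mu, pi_logit = self._decode_t(
            Tensor(np.asarray(code, dtype=np.float64)), lib)
        mean = np.exp(log_mu.data)
        disp = None
        if self.config.likelihood in ("nb", "zinb"):
            disp = np.exp(self.params["log_theta"].data)
        pi = special.expit(pi_logit.data) if pi_logit is not None else None
        return LikelihoodParams(mean=mean, dispersion=disp, zero_inflation=pi)

    def loss_components(self, x_raw: np.ndarray, x_norm: np.ndarray,
                        lib: np.ndarray, eps: Optional[np.ndarray] = None,
                        eps2: Optional[np.ndarray] = None) -> Dict[str, float]:
        """Evaluate the loss and its breakdown (eps=0 gives the mean code)."""
        if x_raw.shape[0] == 0:
            raise ValueError("empty batch")
        if eps is None:
            eps = np.zeros((x_raw.shape[0], self.config.latent_dim))
        if eps2 is None and self.config.geo_anchor == "two_views":
            eps2 = np.zeros_like(eps)
        total, parts = self._loss_graph(np.asarray(x_raw, dtype=np.float64),
                                        x_norm, lib, eps, eps2)
        out = {k: float(v.data) for k, v in parts.items()}
        out["total"] = float(total.data)
        return out

    # ---- training ---------------------------------------------------------

    def fit(self, data: ProcessedDataset, epochs: Optional[int] = None,
            collect_grad_norms: bool = False) -> pd.DataFrame:
        """Train with Adam; returns the per-epoch loss trace.

        The trace has columns epoch, recon1, recon2, kl, geo, total (epoch
        means of the per-batch components). Training aborts with a
        diagnostic if any loss component goes non-finite. Early stopping
        (on total loss, configurable patience/min-delta) is applied when
        ``config.early_stopping``.
        """
        c = self.config
        n_epochs = c.epochs if epochs is None else epochs
        x_raw = np.asarray(data.raw_counts, dtype=np.float64)
        x_norm = np.asarray(data.model_input, dtype=np.float64)
        lib = np.asarray(data.library_sizes, dtype=np.float64)
        self.feature_ids = list(data.selected_features)
        n = x_raw.shape[0]
        bs = min(c.batch_size, n)
        opt = ad.Adam(list(self.params.values()), lr=c.learning_rate)
        rng = self._rng
        rows = []
        self.grad_norms_: list = []
        best, wait = np.inf, 0
        for epoch in range(n_epochs):
            perm = rng.permutation(n)
            sums = {"recon1": 0.0, "recon2": 0.0, "kl": 0.0, "geo": 0.0,
                    "total": 0.0}
            nb = 0
            for start in range(0, n, bs):
                idx = perm[start:start + bs]
                eps = rng.standard_normal((idx.size, c.latent_dim))
                eps2 = (rng.standard_normal((idx.size, c.latent_dim))
                        if c.geo_anchor == "two_views" else None)
                total, parts = self._loss_graph(x_raw[idx], x_norm[idx],
                                                lib[idx], eps, eps2)
                for name, t in [*parts.items(), ("total", total)]:
                    v = float(t.data)
                    if not np.isfinite(v):
                        raise RuntimeError(
                            f"loss component '{name}' became non-finite at "
                            f"epoch {epoch}, batch {nb}")
                    sums[name] += v
                opt.zero_grad()
                total.backward()
                opt.clip_global_norm(c.grad_clip)
                if collect_grad_norms:
                    post = np.sqrt(sum(float((p.grad ** 2).sum())
                                       for p in self.params.values()
                                       if p.grad is not None))
                    self.grad_norms_.append(post)
                opt.step()
                nb += 1
            row = {k: v / nb for k, v in sums.items()}
            row["epoch"] = epoch
            rows.append(row)
            if c.early_stopping:
                if row["total"] < best - c.min_delta:
                    best, wait = row["total"], 0
                else:
                    wait += 1
                    if wait >= c.patience:
                        break
        cols = ["epoch", "recon1", "recon2", "kl", "geo", "total"]
        return pd.DataFrame(rows)[cols]

    def embed(self, data, mode: str = "mean",
              seed: Optional[int] = None) -> np.ndarray:
        """Latent matrix for evaluation: posterior mean (default) or a
        seeded posterior sample."""
        x = data.model_input if isinstance(data, ProcessedDataset) else data
        p = self.encode(np.asarray(x, dtype=np.float64))
        if mode == "mean":
            return p.mu
        if mode == "sample":
            rng = np.random.default_rng(seed)
            return self.reparameterize(p, rng.standard_normal(p.mu.shape))
        raise ValueError("mode must be 'mean' or 'sample'")

    def heldout_nll(self, data: ProcessedDataset) -> float:
        """Per-cell mean negative log-likelihood at the posterior mean,
        scored through the primary pathway (model-comparison statistic)."""
        from .likelihoods import count_loglik
        z = self.embed(data, mode="mean")
        params = self.decode_params(z, data.library_sizes)
        return count_loglik(data.raw_counts, params, self.config.likelihood)

    # ---- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: parameters + config + feature list."""
        path = Path(path)
        meta = {"config": asdict(self.config), "n_features": self.n_features,
                "feature_ids": self.feature_ids}
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "LorentzVAE":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            model = cls(meta["n_features"], ModelConfig(**meta["config"]))
            model.feature_ids = meta["feature_ids"]
            for k in model.params:
                model.params[k].data = f[k].copy()
        return model


def fit(data: ProcessedDataset, config: Optional[ModelConfig] = None,
        **fit_kwargs) -> Tuple[LorentzVAE, pd.DataFrame]:
    """Convenience wrapper: build a model for `data` and train it."""
    model = LorentzVAE(data.n_features, config)
    trace = model.fit(data, **fit_kwargs)
    return model, trace
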