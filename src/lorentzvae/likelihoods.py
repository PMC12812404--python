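"""Count likelihoods for the decoder: Poisson, NB, ZIP, ZINB.

All negative-binomial forms use the mean-dispersion parameterization with
mean mu and gene-wise inverse-dispersion theta, so Var = mu + mu^2/theta:

    log NB(x; mu, theta) = lgamma(x+theta) - lgamma(theta) - lgamma(x+1)
                           + theta*log(theta/(theta+mu)) + x*log(mu/(theta+mu))

Zero-inflated mixtures put a point mass pi at zero:

    p(0) = pi + (1-pi) * f(0),      p(x>0) = (1-pi) * f(x),

with f the NB (ZINB) or Poisson (ZIP) pmf. This module is the numpy
reference used for evaluation (e.g. held-out NLL); the differentiable
training-path implementation lives in :mod:`lorentzvae.model` and is tested
against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

FAMILIES = ("nb", "zinb", "poisson", "zip")


@dataclass
class LikelihoodParams:
    """Decoder distribution parameters for a batch of N cells x D features.

    mean: N x D positive reals; each row sums to that cell's library size.
    dispersion: gene-wise theta (D,), required for nb/zinb.
    zero_inflation: N x D dropout probabilities in [0, 1], for zinb/zip.
    """

    mean: np.ndarray
    dispersion: Optional[np.ndarray] = None
    zero_inflation: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if np.any(self.mean <= 0):
            raise ValueError("mean must be strictly positive")
        if self.dispersion is not None:
            self.dispersion = np.asarray(self.dispersion, dtype=np.float64)
            if np.any(self.dispersion <= 0):
                raise ValueError("dispersion must be strictly positive")
        if self.zero_inflation is not None:
            self.zero_inflation = np.asarray(self.zero_inflation, dtype=np.float64)
            if np.any((self.zero_inflation < 0) | (self.zero_inflation > 1)):
                raise ValueError("zero_inflation must lie in [0, 1]")


def _check_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if not np.allclose(x, np.round(x)):
        raise ValueError("counts must be integers")
    return np.asarray(x, dtype=np.float64)


def poisson_logpmf(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * np.log(mu) - mu - special.gammaln(x + 1.0)


def nb_logpmf(x: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    lt = np.log(theta)
    ltm = np.log(theta + mu)
    return (special.gammaln(x + theta) - special.gammaln(theta)
            - special.gammaln(x + 1.0)
            + theta * (lt - ltm) + x * (np.log(mu) - ltm))


def zip_logpmf(x: np.ndarray, mu: np.ndarray, pi: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    pi = np.broadcast_to(np.asarray(pi, dtype=np.float64), np.broadcast_shapes(x.shape, np.shape(pi)))
    base = poisson_logpmf(x, mu)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    at_zero = np.logaddexp(log_pi, log_1mpi + poisson_logpmf(np.zeros_like(x), mu))
    return np.where(x == 0, at_zero, log_1mpi + base)


def zinb_logpmf(x: np.ndarray, mu: np.ndarray, theta: np.ndarray,
                pi: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    pi = np.broadcast_to(np.asarray(pi, dtype=np.float64), np.broadcast_shapes(x.shape, np.shape(pi)))
    base = nb_logpmf(x, mu, theta)
    nb_zero = theta * (np.log(theta) - np.log(theta + mu))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    at_zero = np.logaddexp(log_pi, log_1mpi + nb_zero)
    return np.where(x == 0, at_zero, log_1mpi + base)


def count_loglik(x: np.ndarray, params: LikelihoodParams, family: str) -> float:
    """Per-cell mean negative log-likelihood of counts under a family.

    Returns -(1/N) sum_i sum_j log p(x_ij | params), matching the
    reconstruction-loss convention used in training.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _check_counts(x)
    mu = params.mean
    if family == "poisson":
        ll = poisson_logpmf(x, mu)
    elif family == "nb":
        if params.dispersion is None:
            raise ValueError("nb requires dispersion")
        ll = nb_logpmf(x, mu, params.dispersion)
    elif family == "zip":
        if params.zero_inflation is None:
            raise ValueError("zip requires zero_inflation")
        ll = zip_logpmf(x, mu, params.zero_inflation)
    else:  # zinb
        if params.dispersion is None or params.zero_inflation is None:
            raise ValueError("zinb requires dispersion and zero_inflation")
        ll = zinb_logpmf(x, mu, params.dispersion, params.zero_inflation)
    n = x.shape[0] if x.ndim > 1 else 1
    return float(-ll.sum() / n)
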