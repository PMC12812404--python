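"""Hyperboloid (Lorentz-model) primitives.

The hyperboloid model represents d-dimensional hyperbolic space as the upper
sheet H^{d+1} = {u in R^{d+1} : <u,u>_L = -1, u0 >= 1} of a two-sheeted
hyperboloid under the Minkowski bilinear form

    <u, w>_L = -u0*w0 + sum_{k>=1} uk*wk.

Latent codes live in the tangent space at the origin o = (1, 0, ..., 0) and
are carried onto the manifold with the exponential map; geodesic distance is
d_H(u, w) = arccosh(-<u,w>_L).

Two numerical-stability rules apply everywhere: the arccosh argument alpha is
clamped to alpha >= 1 + 1e-8 (so the self-distance is the clamp floor
arccosh(1+1e-8) ~ 1.41e-4, not exactly zero), and for alpha > 1e4 the
asymptotic form log(2*alpha) replaces arccosh (the two branches agree to
better than 1e-8 at the switch point).

This module is the pure-numpy reference; the differentiable twin used inside
the training loss lives in :mod:`lorentzvae.model` on top of the autodiff
engine and is tested for agreement with these functions.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "ALPHA_CLAMP_FLOOR",
    "ALPHA_LARGE_BRANCH",
    "MANIFOLD_TOL",
    "exp_map_origin",
    "lorentz_inner",
    "lorentz_distance",
    "geometric_loss",
]

#: alpha = -<u,w>_L is clamped to at least this before arccosh.
ALPHA_CLAMP_FLOOR = 1.0 + 1e-8
#: above this alpha, arccosh(alpha) is replaced by log(2*alpha).
ALPHA_LARGE_BRANCH = 1e4
#: tolerance on |<u,u>_L + 1| for a point to count as on-manifold.
MANIFOLD_TOL = 1e-5

_ZERO_NORM = 1e-12  # below this, use the ||v|| = 0 branch of the exp map


def exp_map_origin(v: np.ndarray) -> np.ndarray:
    """Exponential map at the hyperboloid origin.

    Maps tangent vectors v in R^d (identified with (0, v1..vd) at the base
    point) to points on H^{d+1}:

        exp_o(v) = (cosh ||v||, sinh ||v|| * v/||v||),  exp_o(0) = (1, 0..0).

    Parameters
    ----------
    v
        Array of shape (d,) or (N, d).

    Returns
    -------
    Array of shape (d+1,) or (N, d+1) satisfying <u,u>_L = -1.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty tangent vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("tangent vector has non-finite entries")
    single = v.ndim == 1
    V = v[None, :] if single else v
    n = np.linalg.norm(V, axis=1, keepdims=True)
    # sinh(n)/n -> 1 as n -> 0; switch branches below _ZERO_NORM to avoid 0/0
    safe = np.maximum(n, _ZERO_NORM)
    coeff = np.where(n < _ZERO_NORM, 1.0, np.sinh(safe) / safe)
    out = np.concatenate([np.cosh(n), coeff * V], axis=1)
    return out[0] if single else out


def lorentz_inner(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minkowski bilinear form -u0*w0 + sum_{k>=1} uk*wk (elementwise rows)."""
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if u.shape[-1] != w.shape[-1]:
        raise ValueError(f"dimension mismatch: {u.shape[-1]} vs {w.shape[-1]}")
    prod = u * w
    return -prod[..., 0] + prod[..., 1:].sum(axis=-1)


def _check_on_manifold(u: np.ndarray, name: str) -> None:
    dev = np.abs(lorentz_inner(u, u) + 1.0)
    worst = float(np.max(dev))
    if worst > MANIFOLD_TOL:
        warnings.warn(
            f"{name} is off the hyperboloid by {worst:.3g} (tol {MANIFOLD_TOL:g}); "
            "distance computed after clamping",
            RuntimeWarning,
            stacklevel=3,
        )


def lorentz_distance(u: np.ndarray, w: np.ndarray, *, check: bool = True) -> np.ndarray:
    """Geodesic distance d_H(u, w) = arccosh(-<u,w>_L) on the hyperboloid.

    The argument is clamped to ``ALPHA_CLAMP_FLOOR`` and the large-argument
    branch log(2*alpha) is taken above ``ALPHA_LARGE_BRANCH``. Off-manifold
    inputs (beyond ``MANIFOLD_TOL``) raise a RuntimeWarning but are still
    evaluated after clamping.
    """
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if check:
        _check_on_manifold(u, "first argument")
        _check_on_manifold(w, "second argument")
    alpha = np.maximum(-lorentz_inner(u, w), ALPHA_CLAMP_FLOOR)
    return np.where(alpha > ALPHA_LARGE_BRANCH, np.log(2.0 * alpha), np.arccosh(alpha))


def geometric_loss(Z: np.ndarray, Ld: np.ndarray) -> float:
    """Mean squared hyperboloid distance between paired latent codes.

    Both batches are tangent vectors at the origin; each row is lifted with
    the exponential map and the squared geodesic distance between the paired
    points is averaged:

        L_geo = (1/N) sum_i d_H(exp_o(z_i), exp_o(l_{d,i}))^2.

    This reference version is numpy-only; the differentiable version used in
    training shares its formulas and clamp rules.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    Ld = np.atleast_2d(np.asarray(Ld, dtype=np.float64))
    if Z.shape != Ld.shape:
        raise ValueError(f"batch shapes differ: {Z.shape} vs {Ld.shape}")
    if Z.shape[0] == 0:
        raise ValueError("empty batch")
    d = lorentz_distance(exp_map_origin(Z), exp_map_origin(Ld), check=False)
    return float(np.mean(d ** 2))
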