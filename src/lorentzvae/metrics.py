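"""Embedding-evaluation battery: clustering quality, co-ranking fidelity,
eigenspectrum diagnostics, and batch-mixing (iLISI).

Four metric families are computed on a latent matrix Z (cells x k):

* clustering quality — NMI/ARI of k-means predictions against reference
  labels, plus silhouette (ASW), Calinski-Harabasz (CAL) and Davies-Bouldin
  (DAV) of the reference labels on Z, and the coupling degree COR (mean
  absolute pairwise Pearson correlation between latent dimensions);
* 2-D embedding fidelity — Spearman correlation of pairwise distances and
  co-ranking quality (Q_NX curve split into local/global regimes at the
  standard K_max = argmax_K [Q_NX(K) - K/(N-1)] boundary) against UMAP and
  t-SNE projections of Z;
* intrinsic manifold diagnostics — functions of the sorted covariance
  eigenvalues (effective dimensionality, spectral decay, participation
  ratio, anisotropy, trajectory directionality, noise resilience, and two
  weighted composites);
* batch integration — iLISI, the perplexity-weighted effective number of
  batches in each cell's neighborhood.

O(N^2) quantities (distance correlation, co-ranking) are computed on a
seeded uniform subsample of at most 1000 cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn import metrics as skm
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

EPS_STAB = 1e-8
SUBSAMPLE_N = 1000


@dataclass
class EigenSpectrum:
    """Nonincreasing, nonnegative eigenvalues of an embedding covariance."""

    values: np.ndarray
    k: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.k < 2 or self.values.size != self.k:
            raise ValueError("need at least 2 eigenvalues matching k")
        if np.any(np.diff(self.values) > 1e-12) or np.any(self.values < 0):
            raise ValueError("eigenvalues must be sorted nonincreasing and >= 0")


@dataclass
class MetricReport:
    """One flat serializable record of every computed metric."""

    scores: Dict[str, float]

    def to_json(self, path=None) -> str:
        s = json.dumps(self.scores, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_frame(self, **keys) -> pd.DataFrame:
        return pd.DataFrame([{**keys, **self.scores}])


# ---- clustering ----------------------------------------------------------

def clustering_metrics(Z: np.ndarray, labels: np.ndarray,
                       seed: int = 0) -> Dict[str, float]:
    """NMI/ARI of seeded k-means (k = #classes) vs labels, plus ASW/CAL/DAV
    of the reference labels on Z."""
    Z = np.asarray(Z, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 label classes")
    pred = KMeans(n_clusters=classes.size, n_init=10,
                  random_state=seed).fit_predict(Z)
    return {
        "nmi": float(skm.normalized_mutual_info_score(labels, pred)),
        "ari": float(skm.adjusted_rand_score(labels, pred)),
        "asw": float(skm.silhouette_score(Z, labels)),
        "cal": float(skm.calinski_harabasz_score(Z, labels)),
        "dav": float(skm.davies_bouldin_score(Z, labels)),
    }


def coupling_degree(Z: np.ndarray) -> float:
    """Mean absolute pairwise Pearson correlation between latent dimensions.

    COR = (1/(k(k-1))) * sum_{i != j} |rho_ij|; constant dimensions
    contribute zero correlation (with a warning).
    """
    Z = np.asarray(Z, dtype=np.float64)
    k = Z.shape[1]
    if k < 2:
        raise ValueError("need at least 2 latent dimensions")
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant latent dimension; its correlations set to 0",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Z, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    off = ~np.eye(k, dtype=bool)
    return float(np.abs(R[off]).sum() / (k * (k - 1)))


# ---- 2-D embedding fidelity ---------------------------------------------

def _subsample(n: int, seed: int) -> Optional[np.ndarray]:
    if n <= SUBSAMPLE_N:
        return None
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, SUBSAMPLE_N, replace=False))


def distance_correlation(Z: np.ndarray, E: np.ndarray, seed: int = 0) -> float:
    """Spearman correlation between the upper-triangle pairwise distances of
    the latent space and the 2-D embedding."""
    Z, E = np.asarray(Z, dtype=np.float64), np.asarray(E, dtype=np.float64)
    if Z.shape[0] != E.shape[0]:
        raise ValueError("Z and E must have the same number of rows")
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 points")
    sub = _subsample(Z.shape[0], seed)
    if sub is not None:
        Z, E = Z[sub], E[sub]
    dz, de = pdist(Z), pdist(E)
    if dz.max() == 0 or de.max() == 0:
        raise ValueError("all points identical in one of the spaces")
    return float(spearmanr(dz, de).statistic)


def _rank_matrix(D: np.ndarray) -> np.ndarray:
    """ranks[i, j] = rank (1-based) of j among i's neighbors by distance,
    ties broken by index; diagonal excluded (set to 0)."""
    n = D.shape[0]
    idx = np.broadcast_to(np.arange(n), (n, n))
    ranks = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx[i], D[i]))
        order = order[order != i]
        ranks[i, order] = np.arange(1, n)
    return ranks


def coranking_matrix(Z: np.ndarray, E: np.ndarray) -> np.ndarray:
    """(N-1) x (N-1) joint histogram of neighbor ranks in the two spaces."""
    DZ = squareform(pdist(np.asarray(Z, dtype=np.float64)))
    DE = squareform(pdist(np.asarray(E, dtype=np.float64)))
    rZ, rE = _rank_matrix(DZ), _rank_matrix(DE)
    n = DZ.shape[0]
    off = ~np.eye(n, dtype=bool)
    Q = np.zeros((n - 1, n - 1), dtype=np.int64)
    np.add.at(Q, (rZ[off] - 1, rE[off] - 1), 1)
    return Q


def coranking_quality(Z: np.ndarray, E: np.ndarray,
                      seed: int = 0) -> Tuple[float, float, int]:
    """(q_local, q_global, K_max) from the co-ranking matrix.

    Q_NX(K) = (1/(KN)) sum_{k<=K, l<=K} q_kl is the fraction of rank pairs
    preserved within neighborhood size K; K_max maximizes the
    chance-corrected Q_NX(K) - K/(N-1); q_local/q_global average Q_NX below
    and above the boundary.
    """
    Z, E = np.asarray(Z, dtype=np.float64), np.asarray(E, dtype=np.float64)
    if Z.shape[0] != E.shape[0]:
        raise ValueError("Z and E must have the same number of rows")
    sub = _subsample(Z.shape[0], seed)
    if sub is not None:
        Z, E = Z[sub], E[sub]
    n = Z.shape[0]
    Q = coranking_matrix(Z, E)
    cum = Q.cumsum(axis=0).cumsum(axis=1).diagonal()  # sum over k,l <= K
    K = np.arange(1, n)
    qnx = cum / (K * n)
    kmax = int(K[np.argmax(qnx - K / (n - 1))])
    q_local = float(qnx[:kmax].mean())
    q_global = float(qnx[kmax:].mean()) if kmax < n - 1 else float(qnx[-1])
    return q_local, q_global, kmax


def embedding_quality(rho_dist: float, q_local: float, q_global: float) -> float:
    """Arithmetic mean of the three embedding-fidelity components."""
    return (rho_dist + q_local + q_global) / 3.0


# ---- intrinsic (eigenspectrum) metrics ----------------------------------

def eigenspectrum(Z: np.ndarray) -> EigenSpectrum:
    """Sorted eigenvalues of the covariance of the (column-centered) latent."""
    Z = np.asarray(Z, dtype=np.float64)
    n, k = Z.shape
    if n < 2:
        raise ValueError("need at least 2 cells")
    Zc = Z - Z.mean(axis=0)
    C = Zc.T @ Zc / (n - 1)
    lam = np.linalg.eigvalsh(C)[::-1]
    return EigenSpectrum(np.maximum(lam, 0.0), k)


def intrinsic_metrics(spec: EigenSpectrum) -> Dict[str, float]:
    """Spectrum-based manifold diagnostics.

    m_dim: compactness, 1 - (d_eff - 1)/(k - 1) with d_eff the number of
      components reaching 95% cumulative variance.
    s_decay: logistic(|beta|) * lambda_1/sum(lambda), beta the slope of a
      least-squares fit of log(lambda_i + eps) on the index — increases
      with decay steepness (hierarchy clarity).
    p_ratio: participation ratio (sum lambda)^2 / (k * sum lambda^2); 1 for
      a flat spectrum, 1/k for rank one.
    a_score: anisotropy tanh((log(l1+eps) - log(lk+eps))/4).
    t_dir: dominance of the leading axis lambda_1 / (sum_{i>=2} + eps);
      unbounded, capped at 1 inside the composite.
    n_res: min(0.1*(l1+l2)/(sum_{i>=3} + eps), 1), a signal-to-noise proxy.
    q_core: mean of (m_dim, s_decay, p_ratio, a_score);
    q_overall = 0.5*q_core + 0.3*min(t_dir, 1) + 0.2*n_res.
    """
    lam = spec.values
    k = spec.k
    if k < 3:
        raise ValueError("noise resilience needs k >= 3 eigenvalues")
    eps = EPS_STAB
    total = lam.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all eigenvalues zero")
    cum = np.cumsum(lam) / total
    d_eff = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
    m_dim = 1.0 - (d_eff - 1) / (k - 1)
    beta = np.polyfit(np.arange(1, k + 1), np.log(lam + eps), 1)[0]
    s_decay = float(1.0 / (1.0 + np.exp(-abs(beta))) * lam[0] / total)
    p_ratio = float(total ** 2 / (k * (lam ** 2).sum()))
    a_score = float(np.tanh((np.log(lam[0] + eps) - np.log(lam[-1] + eps)) / 4.0))
    t_dir = float(lam[0] / (lam[1:].sum() + eps))
    n_res = float(min(0.1 * (lam[0] + lam[1]) / (lam[2:].sum() + eps), 1.0))
    q_core = (m_dim + s_decay + p_ratio + a_score) / 4.0
    q_overall = 0.5 * q_core + 0.3 * min(t_dir, 1.0) + 0.2 * n_res
    return {"m_dim": float(m_dim), "s_decay": s_decay, "p_ratio": p_ratio,
            "a_score": a_score, "t_dir": t_dir, "n_res": n_res,
            "q_core": float(q_core), "q_overall": float(q_overall)}


# ---- batch mixing --------------------------------------------------------

def ilisi(E: np.ndarray, batch_labels: np.ndarray,
          perplexity: float = 30.0) -> float:
    """Integration local inverse Simpson index.

    For each cell, a Gaussian kernel over its 3*perplexity nearest
    neighbors is calibrated by binary search so the kernel entropy matches
    log(perplexity); kernel mass is summed per batch into p_j and the
    cell's score is 1/sum_j p_j^2 — the effective number of batches in its
    neighborhood. The dataset score is the mean (1 = unmixed, B = fully
    mixed).
    """
    E = np.asarray(E, dtype=np.float64)
    batch_labels = np.asarray(batch_labels)
    n = E.shape[0]
    batches, codes = np.unique(batch_labels, return_inverse=True)
    if batches.size == 1:
        return 1.0
    k = int(3 * perplexity)
    if n < k + 1:
        warnings.warn(f"only {n} cells for neighborhood size {k}; shrinking",
                      RuntimeWarning)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    dist, idx = nn.kneighbors(E)
    dist, idx = dist[:, 1:], idx[:, 1:]      # drop self
    d2 = dist ** 2
    target = np.log(perplexity)
    lo = np.full(n, 1e-10)
    hi = np.full(n, 1e10)
    beta = np.ones(n)
    for _ in range(64):
        w = np.exp(-d2 * beta[:, None])
        sw = w.sum(axis=1)
        sw = np.maximum(sw, 1e-300)
        p = w / sw[:, None]
        ent = -(p * np.log(np.maximum(p, 1e-300))).sum(axis=1)
        too_flat = ent > target          # entropy too high -> sharpen
        hi = np.where(too_flat, hi, beta)
        lo = np.where(too_flat, beta, lo)
        beta = np.where(np.isfinite(hi * lo), np.sqrt(lo * hi), (lo + hi) / 2)
        beta = np.minimum(np.maximum(beta, lo), hi)
    w = np.exp(-d2 * beta[:, None])
    p = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    pb = np.zeros((n, batches.size))
    for b in range(batches.size):
        pb[:, b] = np.where(codes[idx] == b, p, 0.0).sum(axis=1)
    scores = 1.0 / (pb ** 2).sum(axis=1)
    return float(scores.mean())


# ---- orchestration -------------------------------------------------------

def _umap_embedding(Z: np.ndarray, seed: int) -> np.ndarray:
    import umap  # deferred: numba JIT import cost

    return umap.UMAP(n_components=2, random_state=seed).fit_transform(Z)


def _tsne_embedding(Z: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.manifold import TSNE

    perp = min(30.0, max(2.0, (Z.shape[0] - 1) / 4))
    return TSNE(n_components=2, random_state=seed,
                perplexity=perp, init="pca").fit_transform(Z)


def evaluate(Z: np.ndarray, labels: Optional[np.ndarray] = None,
             batch: Optional[np.ndarray] = None, *, umap_metrics: bool = True,
             tsne_metrics: bool = True, seed: int = 0) -> MetricReport:
    """Run the full battery on a latent matrix and bundle a MetricReport."""
    scores: Dict[str, float] = {}
    if labels is not None:
        scores.update(clustering_metrics(Z, labels, seed=seed))
    scores["cor"] = coupling_degree(Z)
    for name, on, embedder in (("umap", umap_metrics, _umap_embedding),
                               ("tsne", tsne_metrics, _tsne_embedding)):
        if not on:
            continue
        E = embedder(np.asarray(Z, dtype=np.float64), seed)
        rho = distance_correlation(Z, E, seed=seed)
        ql, qg, _ = coranking_quality(Z, E, seed=seed)
        scores[f"{name}_rho_dist"] = rho
        scores[f"{name}_q_local"] = ql
        scores[f"{name}_q_global"] = qg
        scores[f"{name}_q_embed"] = embedding_quality(rho, ql, qg)
    scores.update(intrinsic_metrics(eigenspectrum(Z)))
    if batch is not None:
        scores["ilisi"] = ilisi(Z, batch)
    return MetricReport(scores)
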