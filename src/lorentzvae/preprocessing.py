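"""Modality-specific feature selection and normalization.

The model consumes two matrices per dataset: the *raw* integer counts over a
selected feature subset (the likelihood target) and a normalized *model
input* over the same features (the encoder input). For scRNA-seq the
pipeline is: highly-variable-gene selection on raw counts, then log1p,
per-gene z-scoring and clipping at +/-10 SD. For scATAC-seq: an
accessibility band filter (peaks open in 1%-95% of cells), TF-IDF
normalization, variance ranking of the TF-IDF values, and optional
z-score/clip standardization of the selected peaks.

Library sizes are computed over the selected feature set, so that the
decoder's softmax-scaled means satisfy sum_j mu_ij == library_size_i
exactly. Raw counts are never mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Literal, Optional

import numpy as np

Modality = Literal["rna", "atac"]


@dataclass
class CountMatrix:
    """Raw integer cells x features counts with identifiers and modality."""

    counts: np.ndarray
    cell_ids: List[str]
    feature_ids: List[str]
    modality: Modality

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x features)")
        n, d = self.counts.shape
        if n < 2 or d < 2:
            raise ValueError("need at least 2 cells and 2 features")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral")
        if len(self.cell_ids) != n or len(self.feature_ids) != d:
            raise ValueError("id lengths do not match matrix shape")
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]


@dataclass
class ProcessedDataset:
    """Selected raw counts plus the normalized encoder input."""

    raw_counts: np.ndarray
    model_input: np.ndarray
    selected_features: List[str]
    library_sizes: np.ndarray
    cell_ids: List[str]
    modality: Modality
    selected_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        if not np.all(np.isfinite(self.model_input)):
            raise ValueError("model_input must be finite")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive; drop empty cells upstream")

    @property
    def n_cells(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.raw_counts.shape[1]


# ---- scRNA-seq -----------------------------------------------------------

def select_hvg_rna(X: CountMatrix, n_top: int = 5000) -> np.ndarray:
    """Highly-variable-gene indices by standardized variance under a
    mean-variance trend.

    The expected variance of each gene is modeled by a cubic polynomial
    regression of log10(variance) on log10(mean) over genes with positive
    mean and variance. Counts are standardized by the trend SD, clipped at
    sqrt(N), and genes are ranked by the variance of the clipped values.
    Indices are returned in ascending (original) order.
    """
    if X.modality != "rna":
        raise ValueError("select_hvg_rna expects an RNA CountMatrix")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    counts = np.asarray(X.counts, dtype=np.float64)
    n, d = counts.shape
    if d <= n_top:
        return np.arange(d)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    ok = (mean > 0) & (var > 0)
    if not np.any(ok):
        raise ValueError("all features are constant; nothing to rank")
    coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=3)
    exp_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12))))
    exp_sd = np.maximum(exp_sd, 1e-8)
    clip = np.sqrt(n)
    z = np.clip((counts - mean) / exp_sd, -clip, clip)
    score = np.where(ok, z.var(axis=0, ddof=1), -np.inf)
    # stable ranking: ties broken by original index
    order = np.lexsort((np.arange(d), -score))
    return np.sort(order[:n_top])


def normalize_rna(X_sel: np.ndarray, clip_sd: float = 10.0,
                  sd_floor: float = 1e-8) -> np.ndarray:
    """log1p -> per-gene z-score (SD floored) -> clip to [-clip_sd, clip_sd]."""
    X_sel = np.asarray(X_sel, dtype=np.float64)
    if np.any(X_sel < 0):
        raise ValueError("counts must be nonnegative")
    L = np.log1p(X_sel)
    mu = L.mean(axis=0)
    sd = np.maximum(L.std(axis=0, ddof=0), sd_floor)
    return np.clip((L - mu) / sd, -clip_sd, clip_sd)


# ---- scATAC-seq ----------------------------------------------------------

def tfidf_transform(counts: np.ndarray, s: float = 1e4) -> np.ndarray:
    """TF-IDF normalization of a peak count matrix.

    TF_ij = x_ij / sum_k x_ik (per-cell frequency), IDF_j = log(1 + N/n_j)
    with n_j the number of cells where peak j is accessible, output scaled
    by s. Peaks accessible in no cell must be filtered out beforehand; cells
    with zero totals are an error.
    """
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals.ravel() <= 0))
        raise ValueError(f"cell {bad} has zero total count; remove empty cells first")
    n_j = (counts > 0).sum(axis=0)
    if np.any(n_j == 0):
        bad = int(np.argmax(n_j == 0))
        raise ValueError(f"peak {bad} is accessible in no cell; remove it before TF-IDF")
    tf = counts / totals
    idf = np.log1p(counts.shape[0] / n_j)
    return tf * idf * s


def select_hvp_atac(X: CountMatrix, n_top: int = 10000, min_frac: float = 0.01,
                    max_frac: float = 0.95, s: float = 1e4) -> np.ndarray:
    """Highly-variable-peak indices.

    Peaks are first restricted to those accessible in [min_frac, max_frac]
    of cells, then ranked by the variance of their TF-IDF-normalized values
    (TF-IDF computed on the band-filtered submatrix). Indices returned in
    ascending original order.
    """
    if X.modality != "atac":
        raise ValueError("select_hvp_atac expects an ATAC CountMatrix")
    counts = np.asarray(X.counts, dtype=np.float64)
    n = counts.shape[0]
    frac = (counts > 0).sum(axis=0) / n
    band = np.where((frac >= min_frac) & (frac <= max_frac))[0]
    if band.size == 0:
        raise ValueError(
            f"no peaks accessible in between {min_frac:.0%} and {max_frac:.0%} of cells")
    sub = counts[:, band]
    keep_cells = sub.sum(axis=1) > 0
    if not np.all(keep_cells):
        warnings.warn(
            f"{int((~keep_cells).sum())} cells have zero counts on band-filtered "
            "peaks; they are ignored for variance ranking", RuntimeWarning)
    tfidf = tfidf_transform(sub[keep_cells], s=s)
    score = tfidf.var(axis=0, ddof=1)
    if band.size <= n_top:
        return band
    order = np.lexsort((band, -score))
    return np.sort(band[order[:n_top]])


# ---- end-to-end ----------------------------------------------------------

def preprocess(X: CountMatrix, *, n_top: Optional[int] = None, s: float = 1e4,
               standardize_atac: bool = True) -> ProcessedDataset:
    """Run the modality's selection + normalization and bundle the result.

    RNA: HVG selection (default top 5000) -> log1p/z-score/clip encoder
    input. ATAC: band filter + HVP selection (default top 10000) -> TF-IDF;
    when ``standardize_atac`` the TF-IDF values are additionally z-scored
    and clipped like RNA (stabilizes training; configurable).

    Cells left with zero counts on the selected features are rejected
    (library sizes must be positive).
    """
    if X.modality == "rna":
        idx = select_hvg_rna(X, n_top=5000 if n_top is None else n_top)
        raw = X.counts[:, idx].copy()
        model_input = normalize_rna(raw)
    else:
        idx = select_hvp_atac(X, n_top=10000 if n_top is None else n_top, s=s)
        raw = X.counts[:, idx].copy()
        model_input = tfidf_transform(raw, s=s)
        if standardize_atac:
            mu = model_input.mean(axis=0)
            sd = np.maximum(model_input.std(axis=0, ddof=0), 1e-8)
            model_input = np.clip((model_input - mu) / sd, -10.0, 10.0)
    lib = raw.sum(axis=1).astype(np.float64)
    return ProcessedDataset(
        raw_counts=raw,
        model_input=model_input,
        selected_features=[X.feature_ids[i] for i in idx],
        library_sizes=lib,
        cell_ids=list(X.cell_ids),
        modality=X.modality,
        selected_indices=np.asarray(idx),
    )
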