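"""Reference compartment callers to compare the max-cut method against.

* distance-based PCA — ensemble method: the population-mean pairwise
  distance matrix is normalized by the expected power-law distance at each
  genomic gap, turned into a row/column Pearson correlation matrix, and the
  sign pattern of its leading principal component splits the bins in two.
  One annotation is produced for the whole population.
* CG phasing — per-cell method: each locus is labelled by the mean CG
  content of its 3D spatial neighborhood (250 nm); loci above the cell's
  chromosome average (positive log fold change) are called A.
* Hi-C PCA — utility for a user-supplied dense ensemble matrix; the
  conventional PC1 compartment track.

Sign orientation of eigenvector-based callers is arbitrary; here the group
with smaller mean speckle distance (fallback: higher CG content) becomes A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .compartments import CompartmentProfile
from .trace_io import ChromatinTrace, TracePopulation

__all__ = [
    "DistancePcaModel",
    "powerlaw_fit",
    "distance_pca",
    "cg_phasing",
    "hic_pca",
    "orient_labels",
    "profile_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class DistancePcaModel:
    """Intermediate artifacts of the distance-PCA caller (for inspection)."""

    mean_distance: np.ndarray
    a: float
    b: float
    normalized: np.ndarray
    correlation: np.ndarray
    pc1: np.ndarray
    labels: np.ndarray  # 1 = A


def powerlaw_fit(mean_distances: np.ndarray, gaps: np.ndarray) -> tuple[float, float]:
    """OLS fit of log d = log a + b log gap; returns (a, b).

    The fitted a * gap**b is the expected distance at each genomic gap,
    used to normalize observed distances.
    """
    d = np.asarray(mean_distances, dtype=float)
    g = np.asarray(gaps, dtype=float)
    ok = (d > 0) & (g > 0)
    if ok.sum() < 3 or len(np.unique(g[ok])) < 3:
        raise ValueError("need >=3 distinct positive gaps with positive distances")
    b, loga = np.polyfit(np.log(g[ok]), np.log(d[ok]), 1)
    return float(np.exp(loga)), float(b)


def _leading_eigvec(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def orient_labels(split: np.ndarray, speckle_dist: np.ndarray | None = None,
                  cg: np.ndarray | None = None) -> np.ndarray:
    """Map a binary split to A/B: A = speckle-proximal side (or CG-rich side).

    ``split`` is any 0/1 partition of the bins; returns c with 1 = A.  With
    neither covariate available the split is returned unchanged (group 1 = A)
    with a warning.
    """
    split = np.asarray(split).astype(bool)
    if split.all() or (~split).all():
        return split.astype(int)
    if speckle_dist is not None:
        sd = np.asarray(speckle_dist, dtype=float)
        flip = sd[split].mean() > sd[~split].mean()
    elif cg is not None:
        cgv = np.asarray(cg, dtype=float)
        flip = cgv[split].mean() < cgv[~split].mean()
    else:
        log.warning("no speckle or CG covariate; A/B orientation is arbitrary")
        flip = False
    return (~split if flip else split).astype(int)


def distance_pca(pop: TracePopulation, speckle_dist: np.ndarray | None = None,
                 cg: np.ndarray | None = None) -> DistancePcaModel:
    """Ensemble A/B caller from the population-mean distance matrix.

    The same label vector applies to every cell.  ``speckle_dist`` (per-bin,
    e.g. population mean) or ``cg`` orients the sign; if omitted, the
    population-mean speckle distances of the traces are used when present.
    """
    if pop.K < 2:
        raise ValueError("distance PCA needs at least 2 traces")
    D = np.mean([squareform(pdist(tr.coords)) for tr in pop], axis=0)
    n = D.shape[0]
    idx = np.arange(n)
    gap = np.abs(np.subtract.outer(idx, idx))
    iu = np.triu_indices(n, 1)
    a, b = powerlaw_fit(D[iu], gap[iu])
    expected = a * np.power(gap, b, where=gap > 0, out=np.ones_like(D))
    N = D / expected
    np.fill_diagonal(N, 1.0)
    if np.allclose(N.std(axis=0), 0):
        raise ValueError("normalized distance matrix has zero variance")
    C = np.corrcoef(N)
    pc1 = _leading_eigvec(C)
    split = pc1 > 0
    if speckle_dist is None and cg is None:
        sds = [tr.speckle_dist for tr in pop if tr.speckle_dist is not None]
        speckle_dist = np.mean(sds, axis=0) if sds else None
    labels = orient_labels(split, speckle_dist, cg)
    return DistancePcaModel(mean_distance=D, a=a, b=b, normalized=N,
                            correlation=C, pc1=pc1, labels=labels)


def cg_phasing(trace: ChromatinTrace, cg: np.ndarray, radius: float = 250.0,
               reference_mean: float | None = None) -> CompartmentProfile:
    """Per-cell caller: smoothed CG content above average marks A.

    Each locus's CG is averaged over all loci (itself included) within
    ``radius`` nm in 3D; A wherever log2(smoothed / mean) > 0, with the mean
    taken over this cell's chromosome (or ``reference_mean``, e.g. a
    population-wide value).  Uniform CG therefore yields all-B (the strict
    inequality at the boundary).
    """
    cg = np.asarray(cg, dtype=float)
    if cg.shape != (trace.n_loci,):
        raise ValueError("CG track does not cover the locus panel")
    d = squareform(pdist(trace.coords))
    neigh = d <= radius
    smoothed = (neigh * cg[None, :]).sum(axis=1) / neigh.sum(axis=1)
    ref = smoothed.mean() if reference_mean is None else reference_mean
    with np.errstate(divide="ignore"):
        lfc = np.log2(smoothed / ref)
    return CompartmentProfile(cell_id=trace.cell_id, c=(lfc > 0).astype(int),
                              homolog=trace.homolog)


def hic_pca(matrix: np.ndarray, correlation_first: bool = True,
            speckle_dist: np.ndarray | None = None,
            cg: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PC1 compartment track of a dense ensemble contact matrix.

    Returns ``(pc1, labels)``: the unit-norm leading principal component of
    the (optionally correlation-transformed) matrix's covariance, and the
    oriented A/B labels from its sign pattern.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("Hi-C matrix must be square")
    X = np.corrcoef(M) if correlation_first else M
    C = np.cov(X)
    pc1 = _leading_eigvec(C)
    labels = orient_labels(pc1 > 0, speckle_dist, cg)
    return pc1, labels


def profile_correlation(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pearson r between profiles, over bins where both are defined and pred != 0."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(ref, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles are misaligned")
    ok = np.isfinite(x) & np.isfinite(y) & (x != 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable bins for correlation")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])
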