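"""Structural statistics of traces and compartmentalization scores.

Per-locus geometry features (radial position, radius of gyration, nuclear
body distances, interchromosomal contacts) characterize what distinguishes
A from B chromatin in 3D, and two scores quantify how well *any* binary
compartment annotation segregates a structure:

* CCS (contact compartmentalization score) — the fraction of spatial
  contacts (d <= cutoff_factor * r_bead) that join same-compartment loci;
  higher is better.
* DCS (distance compartmentalization score) — the intra-compartment share
  of the summed pairwise distances; lower means tighter compartments.

Both are annotation-quality metrics: they compare callers, they do not
define the call.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .trace_io import ChromatinTrace

__all__ = [
    "radial_position",
    "radial_variability",
    "radius_of_gyration",
    "interchrom_contacts",
    "contact_score",
    "distance_score",
    "speckle_variability",
    "score_table",
]

R_NUC_DEFAULT = 5000.0  # nm, modeled nuclei
R_SOFT_DEFAULT = 1000.0  # nm, interchromosomal contact range


def radial_position(coords: np.ndarray, nucleus_center: np.ndarray | None = None,
                    r_nuc: float = R_NUC_DEFAULT) -> np.ndarray:
    """r = ||x - center|| / R_nuc; 0 at the nuclear centre, 1 at the surface.

    For imaging data, where no absolute nuclear frame exists, pass the
    centroid of all imaged loci of the cell as ``nucleus_center``.
    """
    if r_nuc <= 0:
        raise ValueError("r_nuc must be positive")
    x = np.atleast_2d(np.asarray(coords, dtype=float))
    center = np.zeros(3) if nucleus_center is None else np.asarray(nucleus_center)
    return np.linalg.norm(x - center, axis=-1) / r_nuc


def radial_variability(radial: np.ndarray) -> np.ndarray:
    """Per-bin log2 ratio of across-cell sd to the chromosome-mean sd.

    ``radial`` is (K cells, N bins).  Delta_r_i = log2(sigma_i / sigma_bar)
    with sigma_i the population sd of bin i and sigma_bar the mean of the
    sigma over the chromosome's bins.
    """
    r = np.asarray(radial, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need a (K>=2, N) array of radial positions")
    sigma = r.std(axis=0)
    sigma_bar = sigma.mean()
    if sigma_bar == 0:
        raise ValueError("zero radial variability across the chromosome")
    with np.errstate(divide="ignore"):
        return np.log2(sigma / sigma_bar)


def radius_of_gyration(trace: ChromatinTrace, window_bins: int = 5) -> np.ndarray:
    """Sliding-window radius of gyration per locus (local fiber compaction).

    g_i = sqrt(mean_j d_j^2) over the ``window_bins`` loci centred on i,
    with d_j the distance of locus j to the window's centre of mass.  Edge
    loci use the shrunk window that fits.
    """
    x = trace.coords
    n = len(x)
    half = window_bins // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = x[lo:hi]
        com = w.mean(axis=0)
        out[i] = np.sqrt(np.mean(np.sum((w - com) ** 2, axis=1)))
    return out


def interchrom_contacts(traces: list[ChromatinTrace],
                        r_soft: float = R_SOFT_DEFAULT) -> dict[tuple, np.ndarray]:
    """Per-bin count of loci on *other* chromosomes within ``r_soft`` nm.

    ``traces`` are the chromosomes of one cell.  With fewer than two
    chromosomes the feature is undefined and an empty mapping is returned.
    """
    if len(traces) < 2:
        return {}
    out = {tr.key: np.zeros(tr.n_loci, dtype=int) for tr in traces}
    for a in range(len(traces)):
        for b in range(a + 1, len(traces)):
            ta, tb = traces[a], traces[b]
            if ta.chrom == tb.chrom and ta.homolog == tb.homolog:
                continue
            d = cdist(ta.coords, tb.coords)
            hit = d <= r_soft
            out[ta.key] += hit.sum(axis=1)
            out[tb.key] += hit.sum(axis=0)
    return out


def _contacts(trace: ChromatinTrace, cutoff: float,
              include_adjacent: bool) -> np.ndarray:
    d = squareform(pdist(trace.coords))
    n = len(d)
    mask = np.triu(d <= cutoff, 1)
    if not include_adjacent:
        adj = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
        mask &= ~adj
    return mask


def contact_score(trace: ChromatinTrace, c: np.ndarray, cutoff_factor: float = 3.0,
                  r_bead: float = 100.0, include_adjacent: bool = True) -> float:
    """CCS = n_intra / (n_intra + n_inter) over contacts d <= cutoff_factor*r_bead.

    ``c`` is the binary A/B profile.  ``cutoff_factor`` defaults to 3 (use 4
    for coarse 3-Mb-resolution imaging loci).  Returns NaN when the
    structure has no contacts at all.
    """
    c = np.asarray(c)
    mask = _contacts(trace, cutoff_factor * r_bead, include_adjacent)
    i, j = np.nonzero(mask)
    if len(i) == 0:
        return float("nan")
    intra = int(np.sum(c[i] == c[j]))
    return intra / len(i)


def distance_score(trace: ChromatinTrace, c: np.ndarray) -> float:
    """DCS = d_intra / (d_intra + d_inter), sums of pairwise distances.

    Lower values mean compartments are internally compact relative to their
    separation.  Undefined (NaN) when a compartment is empty or all
    distances vanish.
    """
    c = np.asarray(c)
    if c.min() == c.max():
        return float("nan")
    d = squareform(pdist(trace.coords))
    same = np.equal.outer(c, c)
    iu = np.triu_indices(len(c), 1)
    d_intra = float(d[iu][same[iu]].sum())
    d_inter = float(d[iu][~same[iu]].sum())
    total = d_intra + d_inter
    if total == 0:
        return float("nan")
    return d_intra / total


def mean_distance_score(trace: ChromatinTrace, c: np.ndarray) -> float:
    """Variant DCS using mean (not summed) intra/inter distances."""
    c = np.asarray(c)
    if c.min() == c.max():
        return float("nan")
    d = squareform(pdist(trace.coords))
    same = np.equal.outer(c, c)
    iu = np.triu_indices(len(c), 1)
    m_intra = float(d[iu][same[iu]].mean())
    m_inter = float(d[iu][~same[iu]].mean())
    if m_intra + m_inter == 0:
        return float("nan")
    return m_intra / (m_intra + m_inter)


def speckle_variability(speckle_dists: np.ndarray) -> np.ndarray:
    """Across-cell population sd of speckle distance per bin ((K, N) input)."""
    s = np.asarray(speckle_dists, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("need a (K>=2, N) array of speckle distances")
    return s.std(axis=0)


def score_table(population, profiles, method: str = "maxcomp",
                cutoff_factor: float = 3.0, r_bead: float = 100.0):
    """Per-trace CCS/DCS rows for a whole population (one annotation method)."""
    import pandas as pd

    by_key = {p_key: p for p_key, p in
              (((pr.cell_id, pr.homolog), pr) for pr in profiles)}
    rows = []
    for tr in population:
        pr = by_key.get((tr.cell_id, tr.homolog))
        if pr is None:
            continue
        rows.append((method, tr.cell_id, tr.homolog,
                     contact_score(tr, pr.c, cutoff_factor, r_bead),
                     distance_score(tr, pr.c)))
    return pd.DataFrame(rows, columns=["method", "cell_id", "homolog", "CCS", "DCS"])
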