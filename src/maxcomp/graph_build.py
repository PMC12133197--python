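"""Embedding one chromatin trace as the weighted graph that gets cut.

Each locus is a node.  The edge weight between loci i and j combines how
dissimilar their nuclear-speckle association is with how much farther apart
they sit than a polymer of that genomic separation would predict:

    w_ij = |z_i - z_j| * d_ij / sqrt(|g_i - g_j|)

where d_ij is the Euclidean 3D distance (nm), g is the sequence position
(bin index) and z is the per-trace z-score of the distance to the nearest
speckle.  Pairs farther apart than ``prune_factor * r_bead`` are removed
(compartments are decided by local structure), and the surviving weights are
scaled by their maximum so W lies in [0, 1].  A high-weight edge is one the
max-cut wants to cut: the two loci are far apart and differ in speckle
association, so they likely belong to different compartments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .trace_io import ChromatinTrace

__all__ = [
    "GraphParams",
    "StructureGraph",
    "DegenerateGraphError",
    "speckle_z_scores",
    "intensity_to_z",
    "expected_distance",
    "build_graph",
]

log = logging.getLogger(__name__)


class DegenerateGraphError(ValueError):
    """The trace yields a graph with no usable edge weight."""


@dataclass(frozen=True)
class GraphParams:
    """Graph construction parameters.

    r_bead : bead (excluded-volume) radius in nm; 100 nm for imaging data.
    prune_factor : edges with d_ij > prune_factor * r_bead are removed.
    epsilon_z : additive guard on |z_i - z_j| for degenerate inputs where
        many z-scores coincide exactly (default 0: the weight formula verbatim).
    gap_mode : 'index' uses the panel bin index as g_i; 'bp_over_resolution'
        uses bin_start / resolution for unevenly spaced panels.
    """

    r_bead: float = 100.0
    prune_factor: float = 16.0
    epsilon_z: float = 0.0
    gap_mode: str = "index"
    resolution: int | None = None

    def __post_init__(self) -> None:
        if self.r_bead <= 0 or self.prune_factor <= 0:
            raise ValueError("r_bead and prune_factor must be positive")
        if self.gap_mode not in {"index", "bp_over_resolution"}:
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass
class StructureGraph:
    """Adjacency W (symmetric, in [0,1], zero diagonal), degrees and Laplacian."""

    W: np.ndarray
    speckle_z: np.ndarray
    kept_edges: int

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def E(self) -> np.ndarray:  # noqa: N802 - degree matrix symbol
        return np.diag(self.degrees)

    @property
    def L(self) -> np.ndarray:  # noqa: N802 - Laplacian symbol
        return self.E - self.W


def speckle_z_scores(trace: ChromatinTrace) -> np.ndarray:
    """Per-trace z-scores of speckle distances (population sd over this trace).

    Falls back to converting marker intensities to pseudo-distances when
    explicit distances are absent.  Standardizing within the trace makes the
    scores comparable across cells imaged in different batches.
    """
    if trace.speckle_dist is not None:
        d = np.asarray(trace.speckle_dist, dtype=float)
    elif trace.speckle_intensity is not None:
        d = intensity_to_z(trace.speckle_intensity)
    else:
        raise ValueError(
            "trace carries neither speckle distances nor speckle intensities; "
            "supply one of them (columns speckle_dist / speckle_intensity)"
        )
    sd = d.std()  # population sd
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(d)
    return (d - d.mean()) / sd


def intensity_to_z(intensity: np.ndarray) -> np.ndarray:
    """Convert speckle-marker intensities to pseudo-distances 1/sqrt(s).

    Intensity is assumed to fall off quadratically with distance from the
    speckle, so 1/sqrt(s) is monotone in the true distance.  Non-positive
    readings are floored to the smallest positive intensity observed.
    """
    s = np.asarray(intensity, dtype=float).copy()
    bad = ~(s > 0)
    if bad.any():
        pos = s[s > 0]
        if pos.size == 0:
            raise ValueError("all speckle intensities are non-positive")
        log.warning("flooring %d non-positive speckle intensities", int(bad.sum()))
        s[bad] = pos.min()
    return 1.0 / np.sqrt(s)


def expected_distance(gap: np.ndarray | float) -> np.ndarray | float:
    """Expected spatial separation of loci |g_i - g_j| bins apart: gap ** 0.5."""
    return np.sqrt(gap)


def build_graph(trace: ChromatinTrace, params: GraphParams | None = None) -> StructureGraph:
    """Build the weighted graph for one preprocessed trace.

    Raises :class:`DegenerateGraphError` when every surviving weight is zero
    (e.g. constant speckle distances make all z-scores equal); a disconnected
    graph is allowed and merely logged.
    """
    params = params or GraphParams()
    if not trace.is_complete():
        raise ValueError("trace has missing coordinates; run interpolate_missing first")
    n = trace.n_loci
    z = speckle_z_scores(trace)

    if params.gap_mode == "index":
        g = trace.bin_index
    else:
        res = params.resolution
        if not res:
            raise ValueError("gap_mode='bp_over_resolution' requires resolution")
        g = np.array([l.bin_start for l in trace.loci], dtype=float) / res

    d = squareform(pdist(trace.coords))
    gap = np.abs(g[:, None] - g[None, :])
    np.fill_diagonal(gap, 1.0)  # unused on the diagonal; avoids 0/0
    dz = np.abs(z[:, None] - z[None, :]) + params.epsilon_z
    w = dz * d / expected_distance(gap)
    np.fill_diagonal(w, 0.0)
    w[d > params.prune_factor * params.r_bead] = 0.0

    wmax = w.max()
    if wmax <= 0:
        raise DegenerateGraphError(
            "all edge weights are zero (constant speckle z-scores or all pairs "
            "pruned); the trace carries no cut signal"
        )
    W = w / wmax  # min-max normalization over kept edges (min is 0)
    kept = int(np.count_nonzero(np.triu(W, 1)))
    if kept < n - 1:
        log.info("graph on %d nodes has only %d edges (may be disconnected)", n, kept)
    return StructureGraph(W=W, speckle_z=z, kept_edges=kept)
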