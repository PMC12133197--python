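"""From cuts to A/B compartment calls and population-level profiles.

The max cut splits a trace's loci into two sets; the set whose mean
speckle distance is smaller is the active compartment A (speckle proximity
marks active chromatin).  Per-cell binary profiles c_k (1 = A) are then
aggregated across the K traces of a population:

    c_ens,i  = (1/K) sum_k c_ki            fraction of cells calling bin i "A"
    f_i      = c_ens,i - I[c_ens,i < 0.5]  signed majority-compartment frequency
    f_norm,i = c_ens,i - 0.5               centred frequency, for correlating
                                           with Hi-C PC1 profiles
    delta_c,i = population sd of c_ki      call variability, = sqrt(c_ens(1-c_ens))

Note f is bimodal by construction (|f| >= 0.5): a bin always has a majority
compartment, however slim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxcut_sdp import CutSolution

__all__ = [
    "CompartmentProfile",
    "EnsembleCompartments",
    "DegenerateCutError",
    "assign_ab",
    "ensemble_vector",
    "compartment_frequency",
    "normalized_frequency",
    "compartment_variability",
    "ensemble_compartments",
    "transcription_ratio",
]

log = logging.getLogger(__name__)


class DegenerateCutError(ValueError):
    """The cut left one side empty; no two-compartment call is possible."""


@dataclass
class CompartmentProfile:
    """Binary per-bin calls for one trace: c_i = 1 iff bin i is compartment A."""

    cell_id: str
    c: np.ndarray
    homolog: int = 0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=int)
        if not np.all((self.c == 0) | (self.c == 1)):
            raise ValueError("profile entries must be 0 or 1")


@dataclass
class EnsembleCompartments:
    """Population-level compartment vectors over one locus panel."""

    c_ens: np.ndarray
    f: np.ndarray
    f_norm: np.ndarray
    delta_c: np.ndarray
    K: int


def assign_ab(cut: CutSolution, speckle_dist: np.ndarray,
              cell_id: str = "", homolog: int = 0) -> CompartmentProfile:
    """Label the cut sides: the side with smaller mean speckle distance is A.

    The assignment is invariant to the arbitrary sign of the cut labels.  On
    an exact tie of means, the side containing node 0 becomes A
    (deterministic, logged).
    """
    s = np.asarray(cut.s)
    d = np.asarray(speckle_dist, dtype=float)
    if s.shape != d.shape:
        raise ValueError("cut labels and speckle distances are misaligned")
    plus = s == 1
    if plus.all() or (~plus).all():
        raise DegenerateCutError("cut produced a trivial partition (one side empty)")
    mean_plus = d[plus].mean()
    mean_minus = d[~plus].mean()
    if mean_plus < mean_minus:
        a_side = plus
    elif mean_minus < mean_plus:
        a_side = ~plus
    else:
        log.info("speckle-distance tie in assign_ab; node-0 side becomes A")
        a_side = plus if plus[0] else ~plus
    return CompartmentProfile(cell_id=cell_id, c=a_side.astype(int), homolog=homolog)


def ensemble_vector(profiles: list[CompartmentProfile]) -> np.ndarray:
    """Per-bin fraction of traces calling A: c_ens = (1/K) sum_k c_k."""
    if not profiles:
        raise ValueError("need at least one profile")
    C = np.array([p.c for p in profiles], dtype=float)
    if C.ndim != 2:
        raise ValueError("profiles have inconsistent panel lengths")
    return C.mean(axis=0)


def compartment_frequency(c_ens: np.ndarray) -> np.ndarray:
    """f_i = c_ens,i - I[c_ens,i < 0.5]; positive = majority A, negative = majority B."""
    c = np.asarray(c_ens, dtype=float)
    return c - (c < 0.5)


def normalized_frequency(c_ens: np.ndarray) -> np.ndarray:
    """f_norm = c_ens - 0.5, the profile compared against Hi-C PC1."""
    return np.asarray(c_ens, dtype=float) - 0.5


def compartment_variability(profiles: list[CompartmentProfile]) -> np.ndarray:
    """Population (divide-by-K) standard deviation of the binary calls per bin."""
    C = np.array([p.c for p in profiles], dtype=float)
    return C.std(axis=0)  # ddof=0


def ensemble_compartments(profiles: list[CompartmentProfile]) -> EnsembleCompartments:
    """Aggregate per-trace profiles into all four population vectors."""
    c_ens = ensemble_vector(profiles)
    return EnsembleCompartments(
        c_ens=c_ens,
        f=compartment_frequency(c_ens),
        f_norm=normalized_frequency(c_ens),
        delta_c=compartment_variability(profiles),
        K=len(profiles),
    )


def transcription_ratio(
    profiles: list[CompartmentProfile],
    counts: pd.DataFrame,
    gene_bins: dict[str, int],
    bottom_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2 ratio of mean transcript counts in A-cells vs B-cells.

    ``counts`` is cells x genes (index = cell_id).  A cell is an "A cell"
    for a gene when the gene's bin is called A on *both* homolog traces of
    that cell; likewise for B.  For each gene, the bottom ``bottom_fraction``
    of cells by that gene's transcript count are removed first (guards
    against dropout zeros).  Genes whose A or B group is empty, or whose
    B-group mean is zero, get a missing (NaN) ratio, never 0.  Genes not in
    ``gene_bins`` or mapped outside the panel are skipped with a warning.

    Returns a DataFrame with columns gene, bin, n_A_cells, n_B_cells,
    t_A, t_B, trans.
    """
    by_cell: dict[str, dict[int, np.ndarray]] = {}
    for p in profiles:
        by_cell.setdefault(p.cell_id, {})[p.homolog] = p.c
    paired = {cid: homs for cid, homs in by_cell.items() if len(homs) >= 2}

    n_bins = len(profiles[0].c) if profiles else 0
    rows = []
    for gene in counts.columns:
        if gene not in gene_bins or not (0 <= gene_bins[gene] < n_bins):
            log.warning("gene %s not mappable to the locus panel; skipped", gene)
            continue
        b = gene_bins[gene]
        col = counts[gene].dropna()
        col = col[col.index.isin(paired)]
        n_drop = int(np.floor(bottom_fraction * len(col)))
        if n_drop > 0:
            col = col.sort_values(kind="stable").iloc[n_drop:]
        t_a, t_b = [], []
        for cid, cnt in col.items():
            homs = list(paired[cid].values())[:2]
            calls = {int(h[b]) for h in homs}
            if calls == {1}:
                t_a.append(cnt)
            elif calls == {0}:
                t_b.append(cnt)
        tA = float(np.mean(t_a)) if t_a else np.nan
        tB = float(np.mean(t_b)) if t_b else np.nan
        trans = np.log2(tA / tB) if t_a and t_b and tB > 0 and tA > 0 else np.nan
        rows.append((gene, b, len(t_a), len(t_b), tA, tB, trans))
    return pd.DataFrame(
        rows, columns=["gene", "bin", "n_A_cells", "n_B_cells", "t_A", "t_B", "trans"]
    )
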