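"""Synthetic trace populations with planted A/B compartments.

A phenomenological two-center model: a planted label sequence (two-state
Markov chain along the chromosome) assigns every bin to compartment A or B;
each cell's trace is a sequential Gaussian random walk whose steps are
pulled toward the bead's own compartment center, the two centers sitting
``separation`` nm apart inside a spherical nucleus.  Nuclear speckles are
placed near the A center, so A beads are speckle-proximal — exactly the two
regularities (intra-compartment spatial proximity, A-speckle association)
that the max-cut caller exploits, and nothing else.  Per-gene nascent
transcript counts are Poisson with an A/B-dependent rate.

All randomness flows from one seed through per-cell substreams, so any
population is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import CompartmentProfile
from .trace_io import ChromatinTrace, Locus, TracePopulation

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "plant_labels",
    "simulate_population",
    "truth_accuracy",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters (distances in nm, rates in counts/cell).

    ``switch_prob`` controls planted block length (expected 1/switch_prob
    bins); ``pull`` in [0, 1] is the per-step attraction toward the bead's
    compartment center (0 = pure random walk, no geometric label signal);
    ``label_noise`` is the per-bead probability that a bead's geometry
    follows the wrong center (cell-to-cell variability).  ``diploid`` emits
    two homolog traces per cell (needed for the transcription analysis).
    ``r_bead`` is the bead radius of these modeled beads, to be passed to
    graph construction and contact scoring when analysing the population.

    Each cell's walk starts at a uniformly random point in the nucleus
    (chromosome territories sit anywhere), so with ``pull = 0`` the bin
    index carries no systematic geometric information.
    """

    n_loci: int = 60
    n_cells: int = 100
    resolution: int = 200_000
    chrom: str = "chrS"
    switch_prob: float = 0.1
    separation: float = 2000.0
    step_sd: float = 200.0
    pull: float = 0.8
    nucleus_radius: float = 3000.0
    n_speckles: int = 3
    speckle_jitter_sd: float = 200.0
    speckle_noise_sd: float = 100.0
    label_noise: float = 0.05
    r_bead: float = 200.0
    transcript_rate_A: float = 10.0
    transcript_rate_B: float = 2.0
    n_genes: int = 20
    diploid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.switch_prob, self.pull, self.label_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.separation, self.step_sd, self.nucleus_radius) <= 0:
            raise ValueError("separation, step_sd and nucleus_radius must be positive")
        if not self.transcript_rate_A >= self.transcript_rate_B >= 0:
            raise ValueError("need transcript_rate_A >= transcript_rate_B >= 0")
        if self.separation > 2 * self.nucleus_radius:
            raise ValueError("centers do not fit inside the nucleus")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated population."""

    labels: np.ndarray                      # planted per-bin labels, 1 = A
    effective: dict[tuple, np.ndarray] = field(default_factory=dict)
    counts: pd.DataFrame | None = None      # cells x genes
    gene_bins: dict[str, int] = field(default_factory=dict)
    cg: np.ndarray | None = None            # synthetic CG-content covariate


def plant_labels(config: SyntheticConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Two-state Markov chain along the bins with flip probability switch_prob.

    Resamples (bounded) until both states are present; with switch_prob = 0
    a single uniform block is unavoidable and returned as is.
    """
    rng = rng or np.random.default_rng(config.seed)
    for _ in range(100):
        lab = np.empty(config.n_loci, dtype=int)
        lab[0] = rng.integers(2)
        flips = rng.random(config.n_loci - 1) < config.switch_prob
        for i, fl in enumerate(flips, start=1):
            lab[i] = 1 - lab[i - 1] if fl else lab[i - 1]
        if 0 < lab.sum() < config.n_loci or config.switch_prob == 0:
            return lab
    return lab


def _uniform_in_sphere(radius: float, rng: np.random.Generator) -> np.ndarray:
    while True:
        x = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(x) <= radius:
            return x


def _walk(eff: np.ndarray, centers: np.ndarray, cfg: SyntheticConfig,
          rng: np.random.Generator) -> np.ndarray:
    """AR(1) walk pulled toward per-bead compartment centers, clipped to the nucleus."""
    x = _uniform_in_sphere(cfg.nucleus_radius, rng)  # territory placement
    out = np.empty((len(eff), 3))
    steps = rng.normal(scale=cfg.step_sd, size=(len(eff), 3))
    for i, lab in enumerate(eff):
        x = x + cfg.pull * (centers[lab] - x) + steps[i]
        norm = np.linalg.norm(x)
        if norm > cfg.nucleus_radius:
            x = x * (cfg.nucleus_radius / norm)
        out[i] = x
    return out


def simulate_population(config: SyntheticConfig) -> tuple[TracePopulation, SyntheticTruth]:
    """Simulate a trace population plus ground truth under ``config``."""
    ss = np.random.SeedSequence(config.seed)
    n_hom = 2 if config.diploid else 1
    children = ss.spawn(2 + config.n_cells * n_hom + config.n_cells)
    rng0 = np.random.default_rng(children[0])
    labels = plant_labels(config, rng0)

    half = config.separation / 2.0
    centers = np.array([[half, 0.0, 0.0],     # B center (label 0)
                        [-half, 0.0, 0.0]])   # A center (label 1)
    speckles = centers[1] + rng0.normal(scale=config.speckle_jitter_sd,
                                        size=(max(config.n_speckles, 1), 3))

    rng_cg = np.random.default_rng(children[1])
    cg = np.clip(0.38 + 0.06 * labels + rng_cg.normal(scale=0.01, size=config.n_loci),
                 0.0, 1.0)

    panel = [Locus(config.chrom, i * config.resolution,
                   (i + 1) * config.resolution, i) for i in range(config.n_loci)]

    traces: list[ChromatinTrace] = []
    effective: dict[tuple, np.ndarray] = {}
    stream = 2
    for k in range(config.n_cells):
        cell = f"cell{k:04d}"
        for h in range(n_hom):
            rng = np.random.default_rng(children[stream]); stream += 1
            eff = labels.copy()
            flip = rng.random(config.n_loci) < config.label_noise
            eff[flip] = 1 - eff[flip]
            coords = _walk(eff, centers, config, rng)
            spd = np.min(np.linalg.norm(coords[:, None, :] - speckles[None, :, :],
                                        axis=2), axis=1)
            spd = np.clip(spd + rng.normal(scale=config.speckle_noise_sd,
                                           size=config.n_loci), 0.0, None)
            tr = ChromatinTrace(cell_id=cell, chrom=config.chrom, loci=list(panel),
                                coords=coords, speckle_dist=spd, homolog=h)
            traces.append(tr)
            effective[tr.key] = eff

    # nascent transcript counts: Poisson(rate_A) when the gene's bin is A on
    # every homolog, Poisson(rate_B) when B on every homolog, 50/50 mixture
    # otherwise
    gene_bins = {f"gene{j:03d}": int(b) for j, b in enumerate(
        np.linspace(0, config.n_loci - 1, config.n_genes).round())}
    rows = {}
    for k in range(config.n_cells):
        cell = f"cell{k:04d}"
        rng = np.random.default_rng(children[2 + config.n_cells * n_hom + k])
        effs = [effective[(cell, config.chrom, h)] for h in range(n_hom)]
        counts = {}
        for gene, b in gene_bins.items():
            states = {int(e[b]) for e in effs}
            if states == {1}:
                rate = config.transcript_rate_A
            elif states == {0}:
                rate = config.transcript_rate_B
            else:
                rate = (config.transcript_rate_A if rng.random() < 0.5
                        else config.transcript_rate_B)
            counts[gene] = int(rng.poisson(rate))
        rows[cell] = counts
    counts_df = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    pop = TracePopulation(traces=traces, resolution=config.resolution)
    truth = SyntheticTruth(labels=labels, effective=effective, counts=counts_df,
                           gene_bins=gene_bins, cg=cg)
    return pop, truth


def truth_accuracy(profiles: list[CompartmentProfile],
                   truth_labels: np.ndarray) -> np.ndarray:
    """Per-profile fraction of bins whose call matches the planted label.

    No label flipping is applied: compartment A is identified by speckle
    proximity on both sides, so a systematic inversion is a real error.
    """
    t = np.asarray(truth_labels)
    return np.array([float(np.mean(p.c == t)) for p in profiles])
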