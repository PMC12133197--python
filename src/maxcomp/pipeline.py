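"""End-to-end orchestration: trace -> graph -> SDP -> rounding -> A/B call.

One failing trace never aborts a population run; failures are logged and
reported alongside the successful profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compartments import CompartmentProfile, DegenerateCutError, assign_ab
from .graph_build import DegenerateGraphError, GraphParams, build_graph
from .maxcut_sdp import (GW_RATIO, SolverError, approx_factorize,
                         round_hyperplane, solve_sdp)
from .trace_io import ChromatinTrace, TracePopulation

__all__ = ["SolverSettings", "call_trace", "call_population"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverSettings:
    """SDP and rounding knobs for the compartment caller."""

    tolerance: float = 1e-6
    threshold_ratio: float = GW_RATIO
    max_rounds: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_ratio <= 1:
            raise ValueError("threshold_ratio must lie in (0, 1]")


def _trace_seed(base: int, index: int) -> int:
    # deterministic per-trace substream, kept within int32 range
    return (base * 1_000_003 + index) % (2**31 - 1)


def call_trace(trace: ChromatinTrace, graph_params: GraphParams | None = None,
               settings: SolverSettings | None = None,
               seed: int | None = None) -> CompartmentProfile:
    """Call A/B compartments for one preprocessed trace."""
    settings = settings or SolverSettings()
    seed = settings.seed if seed is None else seed
    graph = build_graph(trace, graph_params)
    sdp = solve_sdp(graph.L, tolerance=settings.tolerance, seed=seed)
    V = approx_factorize(sdp.A)
    cut = round_hyperplane(V, graph.L, sdp_bound=sdp.dual_bound,
                           threshold_ratio=settings.threshold_ratio,
                           max_rounds=settings.max_rounds, seed=seed)
    log.debug("trace %s: cut %.4g / bound %.4g in %d rounds",
              trace.key, cut.objective, cut.sdp_bound, cut.n_rounds)
    if trace.speckle_dist is not None:
        spd = trace.speckle_dist
    else:
        # intensities: 1/sqrt(s) is monotone in distance, so means compare the same
        from .graph_build import intensity_to_z
        spd = intensity_to_z(trace.speckle_intensity)
    return assign_ab(cut, spd, cell_id=trace.cell_id, homolog=trace.homolog)


def call_population(pop: TracePopulation, graph_params: GraphParams | None = None,
                    settings: SolverSettings | None = None,
                    ) -> tuple[list[CompartmentProfile], list[tuple]]:
    """Call every trace of a population; skip (and report) failing traces.

    Returns (profiles, failed_trace_keys).  Raises only if *every* trace
    fails.
    """
    settings = settings or SolverSettings()
    profiles: list[CompartmentProfile] = []
    failed: list[tuple] = []
    for i, tr in enumerate(pop):
        try:
            profiles.append(
                call_trace(tr, graph_params, settings,
                           seed=_trace_seed(settings.seed, i))
            )
        except (DegenerateGraphError, DegenerateCutError, SolverError,
                ValueError) as exc:
            log.warning("trace %s skipped: %s", tr.key, exc)
            failed.append(tr.key)
    if not profiles:
        raise RuntimeError("compartment calling failed for every trace")
    return profiles, failed
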