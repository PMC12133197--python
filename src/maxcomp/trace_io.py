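"""Reading, writing and preprocessing of single-cell chromosome trace tables.

A *chromatin trace* is the ordered set of 3D positions (nm) of the genomic
bins of one chromosome copy in one cell, as produced by multiplexed FISH
imaging or by genome-structure modeling.  Two table dialects are supported:

``simple``
    Plain CSV/TSV with columns ``cell_id, chrom, bin_start, bin_end, x, y, z``
    and optional ``homolog, speckle_dist, speckle_intensity, lamina_dist``.
``fofct``
    A FOF-CT-like chromatin-trace CSV whose column list is declared on a
    ``##columns`` header line, with ``Trace_ID, Chrom, Chrom_Start,
    Chrom_End, X, Y, Z`` fields.

Coordinates are nanometres internally; genomic intervals are 0-based
half-open.  Missing coordinate cells are kept (as NaN) and later removed by
:func:`interpolate_missing`, never silently dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "ChromatinTrace",
    "TracePopulation",
    "TraceFormatError",
    "PanelMismatchError",
    "PreprocessingError",
    "read_traces",
    "interpolate_missing",
    "preprocess_population",
    "write_calls_csv",
    "read_calls_csv",
    "write_ensemble_bedgraph",
    "write_ensemble_bed9",
    "read_bedgraph_track",
]


class TraceFormatError(ValueError):
    """Input table does not conform to the declared dialect."""


class PanelMismatchError(ValueError):
    """A trace's locus panel disagrees with the population panel."""


class PreprocessingError(ValueError):
    """A trace cannot be brought to a complete, finite state."""


@dataclass(frozen=True)
class Locus:
    """One genomic bin of the locus panel.

    ``bin_index`` is the integer sequence position g_i used in edge weights;
    it need not be proportional to base pairs (the weight formula is
    invariant to uniform rescaling of g).
    """

    chrom: str
    bin_start: int
    bin_end: int
    bin_index: int

    def __post_init__(self) -> None:
        if self.bin_end <= self.bin_start:
            raise ValueError(
                f"bin_end must exceed bin_start ({self.bin_start}, {self.bin_end})"
            )


@dataclass
class ChromatinTrace:
    """One chromosome copy in one cell.

    ``coords`` is an (n, 3) float array in nm; NaN marks a missing locus.
    ``speckle_dist`` / ``lamina_dist`` are distances (nm) to the nearest
    nuclear speckle / the lamina; ``speckle_intensity`` is a raw marker
    intensity (arbitrary units) convertible to a pseudo-distance.
    """

    cell_id: str
    chrom: str
    loci: list[Locus]
    coords: np.ndarray
    speckle_dist: np.ndarray | None = None
    speckle_intensity: np.ndarray | None = None
    lamina_dist: np.ndarray | None = None
    homolog: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.loci), 3):
            raise ValueError("coords must be (n_loci, 3)")
        for name in ("speckle_dist", "speckle_intensity", "lamina_dist"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.loci),):
                    raise ValueError(f"{name} must have one value per locus")
                setattr(self, name, v)
        idx = [l.bin_index for l in self.loci]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("bin_index must be strictly increasing")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def bin_index(self) -> np.ndarray:
        return np.array([l.bin_index for l in self.loci], dtype=float)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.cell_id, self.chrom, self.homolog)

    def is_complete(self) -> bool:
        """True when every coordinate is present and finite."""
        return bool(np.all(np.isfinite(self.coords)))


@dataclass
class TracePopulation:
    """A set of traces sharing one locus panel."""

    traces: list[ChromatinTrace]
    resolution: int | None = None
    panel: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("population must contain at least one trace")
        if not self.panel:
            self.panel = list(self.traces[0].loci)
        ref = [(l.chrom, l.bin_start, l.bin_end) for l in self.panel]
        for tr in self.traces:
            got = [(l.chrom, l.bin_start, l.bin_end) for l in tr.loci]
            if got != ref:
                raise PanelMismatchError(
                    f"trace {tr.key} indexes a different locus panel than the population"
                )

    @property
    def n_cells(self) -> int:
        return len({t.cell_id for t in self.traces})

    @property
    def K(self) -> int:  # noqa: N802 - population size symbol
        return len(self.traces)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def __iter__(self):
        return iter(self.traces)


_SIMPLE_REQUIRED = ["cell_id", "chrom", "bin_start", "bin_end", "x", "y", "z"]
_SIMPLE_OPTIONAL = ["homolog", "speckle_dist", "speckle_intensity", "lamina_dist"]
_FOFCT_MAP = {
    "Trace_ID": "cell_id",
    "Chrom": "chrom",
    "Chrom_Start": "bin_start",
    "Chrom_End": "bin_end",
    "X": "x",
    "Y": "y",
    "Z": "z",
    "Homolog": "homolog",
    "Speckle_Dist": "speckle_dist",
    "Speckle_Intensity": "speckle_intensity",
    "Lamina_Dist": "lamina_dist",
}


def _read_simple(path: Path) -> tuple[pd.DataFrame, float]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    unit_scale = 1.0
    with open(path) as fh:
        head = fh.readline()
        if head.startswith("#") and "units" in head.lower():
            if "um" in head.lower() or "µm" in head.lower() or "micro" in head.lower():
                unit_scale = 1000.0
        fh.seek(0)
        df = pd.read_csv(fh, sep=sep, comment="#", skip_blank_lines=True)
    return df, unit_scale


def _read_fofct(path: Path) -> tuple[pd.DataFrame, float]:
    columns: list[str] | None = None
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("##columns"):
                _, _, spec = stripped.partition("=")
                columns = [c.strip().strip("()") for c in spec.split(",") if c.strip()]
            elif stripped.startswith("#"):
                continue
            else:
                rows.append(stripped)
    if columns is None:
        raise TraceFormatError("fofct dialect requires a '##columns' header line")
    df = pd.read_csv(io.StringIO("\n".join(rows)), header=None, names=columns)
    df = df.rename(columns={k: v for k, v in _FOFCT_MAP.items() if k in df.columns})
    missing = [k for k, v in _FOFCT_MAP.items()
               if v in _SIMPLE_REQUIRED and v not in df.columns]
    if missing:
        raise TraceFormatError(f"fofct table lacks required column(s): {missing}")
    # FOF-CT coordinates are micrometres by convention
    return df, 1000.0


def read_traces(path: str | Path, dialect: str = "simple") -> TracePopulation:
    """Read a trace table into a :class:`TracePopulation`.

    One trace is built per (cell_id, chrom[, homolog]) combination; loci are
    sorted by ascending ``bin_start`` regardless of row order.  Unparseable
    or empty coordinate cells become NaN ("missing"), not dropped rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "simple":
        df, unit_scale = _read_simple(path)
        missing = [c for c in _SIMPLE_REQUIRED if c not in df.columns]
        if missing:
            raise TraceFormatError(f"missing required column(s): {missing}")
    elif dialect == "fofct":
        df, unit_scale = _read_fofct(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in ("x", "y", "z", "speckle_dist", "speckle_intensity", "lamina_dist"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "homolog" not in df.columns:
        df["homolog"] = 0

    traces: list[ChromatinTrace] = []
    resolution: int | None = None
    for (cell, chrom, hom), grp in df.groupby(
        ["cell_id", "chrom", "homolog"], sort=True
    ):
        grp = grp.sort_values("bin_start", kind="stable").reset_index(drop=True)
        loci = [
            Locus(str(chrom), int(r.bin_start), int(r.bin_end), i)
            for i, r in enumerate(grp.itertuples())
        ]
        widths = grp["bin_end"] - grp["bin_start"]
        if resolution is None and len(widths):
            resolution = int(widths.mode().iloc[0])
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float) * unit_scale

        def _opt(col: str, scale: float) -> np.ndarray | None:
            if col not in grp.columns or grp[col].isna().all():
                return None
            return grp[col].to_numpy(dtype=float) * scale

        traces.append(
            ChromatinTrace(
                cell_id=str(cell),
                chrom=str(chrom),
                loci=loci,
                coords=coords,
                speckle_dist=_opt("speckle_dist", unit_scale),
                speckle_intensity=_opt("speckle_intensity", 1.0),
                lamina_dist=_opt("lamina_dist", unit_scale),
                homolog=int(hom),
            )
        )
    if not traces:
        raise TraceFormatError(f"no traces parsed from {path}")
    return TracePopulation(traces=traces, resolution=resolution)


def _interp_1d(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation over ``grid`` for interior NaNs; nearest fill at ends."""
    out = values.astype(float).copy()
    obs = np.isfinite(out)
    if obs.sum() < 2:
        raise PreprocessingError(
            "fewer than 2 observed values; trace cannot be interpolated"
        )
    # np.interp already clamps to the boundary observed values (nearest fill)
    out[~obs] = np.interp(grid[~obs], grid[obs], out[obs])
    return out


def interpolate_missing(trace: ChromatinTrace) -> ChromatinTrace:
    """Fill missing values by linear interpolation along the genomic index.

    Interior gaps are interpolated between the flanking observed loci, per
    coordinate axis (and per auxiliary track); leading/trailing missing loci
    copy the nearest observed value, avoiding extrapolation.  A trace with
    fewer than two observed loci is rejected.
    """
    grid = trace.bin_index
    obs = np.all(np.isfinite(trace.coords), axis=1)
    if obs.sum() < 2:
        raise PreprocessingError(
            f"trace {trace.key} has {int(obs.sum())} observed loci (<2)"
        )
    coords = np.column_stack(
        [_interp_1d(trace.coords[:, k], grid) for k in range(3)]
    )

    def _fill(v: np.ndarray | None) -> np.ndarray | None:
        if v is None or np.all(np.isfinite(v)):
            return None if v is None else v.copy()
        if np.isfinite(v).sum() < 2:
            # a single observed value: propagate it (nearest fill everywhere)
            out = v.copy()
            out[~np.isfinite(out)] = v[np.isfinite(v)][0]
            return out
        return _interp_1d(v, grid)

    return replace(
        trace,
        coords=coords,
        speckle_dist=_fill(trace.speckle_dist),
        speckle_intensity=_fill(trace.speckle_intensity),
        lamina_dist=_fill(trace.lamina_dist),
    )


def preprocess_population(
    pop: TracePopulation, min_loci: int = 3
) -> tuple[TracePopulation, list[tuple]]:
    """Interpolate every trace; drop traces that cannot be completed.

    Returns the cleaned population and the keys of rejected traces.
    """
    kept: list[ChromatinTrace] = []
    rejected: list[tuple] = []
    for tr in pop.traces:
        if tr.n_loci < min_loci:
            rejected.append(tr.key)
            continue
        try:
            kept.append(interpolate_missing(tr))
        except PreprocessingError:
            rejected.append(tr.key)
    if not kept:
        raise PreprocessingError("all traces rejected during preprocessing")
    return TracePopulation(traces=kept, resolution=pop.resolution), rejected


# ---------------------------------------------------------------------------
# output writers


def write_calls_csv(profiles, panel: list[Locus], path: str | Path,
                    header_comment: str | None = None) -> None:
    """Long CSV of per-cell A/B calls: cell_id, homolog, chrom, bin_start, bin_end, label."""
    rows = []
    for p in profiles:
        for locus, ci in zip(panel, p.c):
            rows.append(
                (p.cell_id, getattr(p, "homolog", 0), locus.chrom,
                 locus.bin_start, locus.bin_end, "A" if ci else "B")
            )
    df = pd.DataFrame(
        rows, columns=["cell_id", "homolog", "chrom", "bin_start", "bin_end", "label"]
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_calls_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ensemble_bedgraph(ens, panel: list[Locus], path: str | Path,
                            track: str = "f_norm",
                            header_comment: str | None = None) -> None:
    """Write one ensemble track (f, f_norm, delta_c or c_ens) as 4-column bedGraph."""
    values = np.asarray(getattr(ens, track), dtype=float)
    if len(values) != len(panel) or len(panel) == 0:
        raise ValueError("ensemble vector does not match a non-empty locus panel")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f'track type=bedGraph name="{track}"\n')
        for locus, v in zip(panel, values):
            fh.write(f"{locus.chrom}\t{locus.bin_start}\t{locus.bin_end}\t{v:.6g}\n")


def write_ensemble_bed9(ens, panel: list[Locus], path: str | Path) -> None:
    """BED9 with majority-A bins red (255,0,0) and majority-B bins blue (0,0,255)."""
    c_ens = np.asarray(ens.c_ens, dtype=float)
    if len(c_ens) != len(panel) or len(panel) == 0:
        raise ValueError("ensemble vector does not match a non-empty locus panel")
    with open(path, "w") as fh:
        for locus, v in zip(panel, c_ens):
            a = v >= 0.5
            name, color = ("A", "255,0,0") if a else ("B", "0,0,255")
            fh.write(
                f"{locus.chrom}\t{locus.bin_start}\t{locus.bin_end}\t{name}\t0\t.\t"
                f"{locus.bin_start}\t{locus.bin_end}\t{color}\n"
            )


def read_bedgraph_track(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph (e.g. a CG-content track) into a DataFrame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = s.split()[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    if not rows:
        raise TraceFormatError(f"no bedGraph records in {path}")
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "value"])
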