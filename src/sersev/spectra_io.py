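"""Reading and writing single-vesicle SERS spectra.

The interchange formats are deliberately plain text:

* **map table** — long-format export of a Raman mapping measurement, one row
  per (position, wavenumber) with columns ``x_um, y_um, wavenumber_cm1,
  intensity``.  One spectrum is collected per map position (one position ==
  one vesicle on the SERS substrate).
* **spectrum CSV** — two columns ``wavenumber_cm1, intensity`` for a single
  spectrum (e.g. an averaged amino-acid reference spectrum).
* **manifest** — a YAML mapping ``sample_id -> {cell_line, fraction, file}``
  attaching biological metadata to spectral files.

Sample metadata never travels inside the numeric tables; a map table written
by :func:`write_spectrum_set` carries it in a ``<path>.meta.yaml`` sidecar
which :func:`read_map_table` re-attaches when present.

All axes are canonicalized to ascending wavenumber on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import GridError, SpectraFormatError

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "DEFAULT_GRID",
    "read_map_table",
    "read_spectrum_csv",
    "write_spectrum_set",
    "write_spectrum_csv",
    "load_manifest",
]

#: Relative tolerance used when checking that a parsed axis is uniform.
_UNIFORMITY_RTOL = 1e-6

_SEPARATORS = {"tsv": "\t", "csv": ","}

_MAP_COLUMNS = ("x_um", "y_um", "wavenumber_cm1", "intensity")


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift axis in cm^-1.

    The default grid (564-1681 cm^-1, 1117 points) matches the detection
    range and sampling of the 785 nm instrument configuration used for
    single-vesicle measurements; every downstream analysis treats the 1117
    sampled Raman shifts as the feature axis.
    """

    start: float = 564.0
    end: float = 1681.0
    n_points: int = 1117

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise GridError(f"grid start must be < end, got [{self.start}, {self.end}]")
        if self.n_points < 2:
            raise GridError(f"grid needs at least 2 points, got {self.n_points}")

    @cached_property
    def axis(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    @classmethod
    def from_axis(cls, axis: np.ndarray) -> "WavenumberGrid":
        """Build a grid from an explicit axis, requiring strict ascent and
        (approximate) uniform spacing."""
        axis = np.asarray(axis, dtype=float)
        if axis.ndim != 1 or axis.size < 2:
            raise GridError("axis must be a 1-D array with at least 2 points")
        steps = np.diff(axis)
        if np.any(steps <= 0):
            raise GridError("axis must be strictly increasing")
        mean_step = steps.mean()
        if np.any(np.abs(steps - mean_step) > _UNIFORMITY_RTOL * mean_step):
            raise GridError("axis is not uniformly spaced")
        return cls(float(axis[0]), float(axis[-1]), int(axis.size))


#: The instrument grid used throughout the study: 564-1681 cm^-1, 1117 points.
DEFAULT_GRID = WavenumberGrid()


@dataclass
class Spectrum:
    """One SERS spectrum on a :class:`WavenumberGrid`.

    ``meta`` carries string-keyed metadata such as ``sample_id``,
    ``cell_line``, ``fraction`` and the map position (``map_x``/``map_y``
    in micrometres).
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1:
            raise SpectraFormatError("intensities must be one-dimensional")
        if y.size != self.grid.n_points:
            raise GridError(
                f"intensity length {y.size} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(y)):
            raise SpectraFormatError("intensities must be finite")
        self.intensities = y

    def with_intensities(self, y: np.ndarray, grid: WavenumberGrid | None = None) -> "Spectrum":
        return Spectrum(grid or self.grid, y, dict(self.meta))


@dataclass
class SpectrumSet:
    """Ordered collection of spectra on a shared grid."""

    spectra: list

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        if self.spectra:
            g0 = self.spectra[0].grid
            for s in self.spectra[1:]:
                if s.grid != g0:
                    raise GridError("all spectra in a SpectrumSet must share one grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        out = self.spectra[i]
        if isinstance(i, slice):
            return SpectrumSet(out)
        return out

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise SpectraFormatError("empty SpectrumSet has no grid")
        return self.spectra[0].grid

    @property
    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix of intensities."""
        if not self.spectra:
            raise SpectraFormatError("empty SpectrumSet has no intensity matrix")
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self, key: str) -> np.ndarray:
        """Per-spectrum metadata values for ``key`` (missing -> '')."""
        return np.array([str(s.meta.get(key, "")) for s in self.spectra])

    def subset(self, key: str, value) -> "SpectrumSet":
        return SpectrumSet([s for s in self.spectra if str(s.meta.get(key, "")) == str(value)])

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])


def _read_table(path: Path, sep: str, n_cols: int) -> pd.DataFrame:
    """Read a delimited numeric table, skipping a single header line if the
    first row is not numeric.  Non-numeric data cells raise with the
    offending 1-based line number."""
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                      skip_blank_lines=True)
    if raw.shape[1] < n_cols:
        raise SpectraFormatError(
            f"{path}: expected at least {n_cols} columns, found {raw.shape[1]}"
        )
    raw = raw.iloc[:, :n_cols]
    offset = 1  # 1-based line numbers
    first = raw.iloc[0]
    try:
        first.astype(float)
    except (TypeError, ValueError):
        raw = raw.iloc[1:].reset_index(drop=True)
        offset = 2
    if raw.empty:
        raise SpectraFormatError(f"{path}: no data rows")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + offset
        raise SpectraFormatError(f"{path}: non-numeric value on line {line}")
    return numeric


def read_map_table(path, dialect: str = "tsv") -> SpectrumSet:
    """Read a long-format Raman map export into a :class:`SpectrumSet`.

    Rows hold ``(x_um, y_um, wavenumber_cm1, intensity)``; each unique
    position must sweep the same wavenumber axis.  Positions are ordered
    canonically by ``(x, y)`` and each spectrum sorted to ascending
    wavenumber, so the result is independent of row order in the file.
    """
    path = Path(path)
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, _SEPARATORS[dialect], 4)
    df.columns = list(_MAP_COLUMNS)

    sidecar = _read_sidecar(path)

    groups = df.groupby(["x_um", "y_um"], sort=True)
    sizes = groups.size()
    if sizes.nunique() != 1:
        modal = int(sizes.mode().iloc[-1])
        off = sizes[sizes != modal].index[0]
        raise SpectraFormatError(
            f"{path}: ragged map sweep at position (x={off[0]}, y={off[1]}): "
            f"{int(sizes[off])} points, expected {modal}"
        )

    spectra: list[Spectrum] = []
    ref_axis = None
    grid = None
    for (x, y), sub in groups:
        sub = sub.sort_values("wavenumber_cm1")
        axis = sub["wavenumber_cm1"].to_numpy()
        if ref_axis is None:
            if np.unique(axis).size != axis.size:
                raise SpectraFormatError(
                    f"{path}: duplicated wavenumber at position (x={x}, y={y})"
                )
            ref_axis = axis
            grid = WavenumberGrid.from_axis(axis)
        elif not np.allclose(axis, ref_axis, rtol=0, atol=1e-9):
            raise SpectraFormatError(
                f"{path}: position (x={x}, y={y}) sweeps a different wavenumber axis"
            )
        meta = {"map_x": float(x), "map_y": float(y)}
        meta.update(sidecar.get((float(x), float(y)), {}))
        spectra.append(Spectrum(grid, sub["intensity"].to_numpy(), meta))
    return SpectrumSet(spectra)


def read_spectrum_csv(path, dialect: str = "csv") -> Spectrum:
    """Read a two-column (wavenumber, intensity) file into a single
    :class:`Spectrum`, sorting to ascending wavenumber if needed."""
    path = Path(path)
    df = _read_table(path, _SEPARATORS[dialect], 2)
    df.columns = ["wavenumber_cm1", "intensity"]
    if len(df) < 2:
        raise SpectraFormatError(f"{path}: need at least 2 rows")
    if df["wavenumber_cm1"].duplicated().any():
        dup = df["wavenumber_cm1"][df["wavenumber_cm1"].duplicated()].iloc[0]
        raise SpectraFormatError(f"{path}: duplicated wavenumber {dup}")
    df = df.sort_values("wavenumber_cm1")
    grid = WavenumberGrid.from_axis(df["wavenumber_cm1"].to_numpy())
    return Spectrum(grid, df["intensity"].to_numpy())


def _fmt(v: float) -> str:
    # repr round-trips floats exactly through text
    return repr(float(v))


def _position(s: Spectrum, index: int) -> tuple[float, float]:
    return float(s.meta.get("map_x", index)), float(s.meta.get("map_y", 0.0))


def write_spectrum_set(sset: SpectrumSet, path, dialect: str = "tsv") -> None:
    """Write a :class:`SpectrumSet` as a long-format map table plus a
    ``<path>.meta.yaml`` metadata sidecar.

    The written table round-trips through :func:`read_map_table` exactly on
    the axis and to full float precision on intensities.
    """
    if len(sset) == 0:
        raise SpectraFormatError("refusing to write an empty SpectrumSet")
    sep = _SEPARATORS[dialect]
    path = Path(path)
    grid = sset.grid  # raises on mixed grids
    axis = grid.axis
    lines = [sep.join(_MAP_COLUMNS)]
    sidecar = []
    for i, s in enumerate(sset):
        x, y = _position(s, i)
        for wn, inten in zip(axis, s.intensities):
            lines.append(sep.join((_fmt(x), _fmt(y), _fmt(wn), _fmt(inten))))
        entry = {k: v for k, v in s.meta.items() if k not in ("map_x", "map_y")}
        sidecar.append({"map_x": x, "map_y": y, **entry})
    path.write_text("\n".join(lines) + "\n")
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump({"spectra": sidecar}, fh, sort_keys=False)


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Write a single spectrum as a two-column CSV."""
    lines = ["wavenumber_cm1,intensity"]
    for wn, inten in zip(s.grid.axis, s.intensities):
        lines.append(f"{_fmt(wn)},{_fmt(inten)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    sidecar_path = Path(f"{path}.meta.yaml")
    if not sidecar_path.exists():
        return {}
    payload = yaml.safe_load(sidecar_path.read_text()) or {}
    out = {}
    for entry in payload.get("spectra", []):
        entry = dict(entry)
        key = (float(entry.pop("map_x")), float(entry.pop("map_y")))
        out[key] = entry
    return out


def load_manifest(path) -> dict:
    """Load a sample manifest: ``sample_id -> {cell_line, fraction, file}``.

    File paths are resolved relative to the manifest location.
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, Mapping) or not payload:
        raise SpectraFormatError(f"{path}: manifest must be a non-empty mapping")
    out = {}
    for sample_id, entry in payload.items():
        if not isinstance(entry, Mapping) or "file" not in entry:
            raise SpectraFormatError(
                f"{path}: manifest entry {sample_id!r} must be a mapping with a 'file' key"
            )
        entry = dict(entry)
        entry["file"] = str((path.parent / entry["file"]).resolve())
        out[str(sample_id)] = entry
    return out
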