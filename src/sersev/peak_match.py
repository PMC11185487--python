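"""Peak detection and the peak-location matching-rate statistic.

Because absolute SERS intensities are not quantitative (hotspot enhancement
varies vesicle to vesicle), agreement between a simulated or fitted spectrum
and a measurement is judged qualitatively from peak *locations*: the
matching rate is the percentage of peaks in one spectrum that have a
counterpart within a wavenumber tolerance in the other.  Matching is greedy
one-to-one by ascending distance, so a single broad peak cannot absorb
several counterparts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import PeakMatchError
from .spectra_io import Spectrum

__all__ = ["PeakList", "MatchConfig", "detect_peaks", "matching_rate",
           "match_peaks", "matching_rate_spectra"]


@dataclass
class PeakList:
    """Detected peaks: ascending positions (cm^-1) with heights and
    prominences."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        pr = np.asarray(self.prominences, dtype=float)
        if not (p.shape == h.shape == pr.shape):
            raise PeakMatchError("positions, heights, prominences must match in length")
        if p.size and np.any(np.diff(p) <= 0):
            raise PeakMatchError("peak positions must be strictly increasing")
        if np.any(pr <= 0):
            raise PeakMatchError("prominences must be > 0")
        self.positions, self.heights, self.prominences = p, h, pr

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class MatchConfig:
    """Peak detection / matching parameters.

    tol_cm1
        Matching window half-width; 8 cm^-1 by default (about 8 grid steps
        on the 564-1681 cm^-1 / 1117-point axis).
    min_prominence_frac
        Peaks must rise at least this fraction of the spectrum maximum
        above their surroundings.
    min_separation_cm1
        Minimal distance between reported peaks; when two candidates are
        closer, the more prominent one wins.
    direction
        'a_in_b' (default; fraction of A's peaks found in B), 'b_in_a', or
        'symmetric' (mean of both).
    """

    tol_cm1: float = 8.0
    min_prominence_frac: float = 0.05
    min_separation_cm1: float = 10.0
    direction: str = "a_in_b"

    def __post_init__(self) -> None:
        if not self.tol_cm1 > 0:
            raise ValueError("tol_cm1 must be > 0")
        if not 0 < self.min_prominence_frac < 1:
            raise ValueError("min_prominence_frac must be in (0, 1)")
        if self.direction not in ("a_in_b", "b_in_a", "symmetric"):
            raise ValueError(f"unknown direction {self.direction!r}")


def detect_peaks(s: Spectrum, cfg: MatchConfig | None = None) -> PeakList:
    """Find local maxima with prominence >= min_prominence_frac * max(s) and
    pairwise separation >= min_separation_cm1.  A flat (or non-positive)
    spectrum yields an empty PeakList."""
    cfg = cfg or MatchConfig()
    y = s.intensities
    ymax = float(np.max(y))
    if ymax <= 0 or np.ptp(y) == 0:
        empty = np.array([])
        return PeakList(empty, empty, empty)
    distance = max(1, int(math.ceil(cfg.min_separation_cm1 / s.grid.spacing)))
    idx, props = find_peaks(y, prominence=cfg.min_prominence_frac * ymax,
                            distance=distance)
    return PeakList(s.grid.axis[idx], y[idx], props["prominences"])


def match_peaks(a: PeakList, b: PeakList, tol_cm1: float) -> list:
    """Greedy one-to-one assignment of A peaks to B peaks by ascending
    |distance|, within the tolerance window.  Returns (i_a, i_b, distance)
    triples; never more than min(|A|, |B|) pairs."""
    pairs = []
    for i, pa in enumerate(a.positions):
        for j, pb in enumerate(b.positions):
            d = abs(pa - pb)
            if d <= tol_cm1:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    matched = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, d))
    return matched


def _one_direction(a: PeakList, b: PeakList, tol: float, name: str) -> float:
    if len(b) == 0:
        raise PeakMatchError(f"empty reference peak list for direction {name}")
    if len(a) == 0:
        raise PeakMatchError(f"no peaks to match for direction {name}")
    return 100.0 * len(match_peaks(a, b, tol)) / len(a)


def matching_rate(a: PeakList, b: PeakList, cfg: MatchConfig | None = None) -> float:
    """Peak-location matching rate in percent.

    'a_in_b': share of A's peaks with a one-to-one counterpart in B within
    tol_cm1; 'symmetric': mean of both directions.
    """
    cfg = cfg or MatchConfig()
    if cfg.direction == "a_in_b":
        return _one_direction(a, b, cfg.tol_cm1, "a_in_b")
    if cfg.direction == "b_in_a":
        return _one_direction(b, a, cfg.tol_cm1, "b_in_a")
    return 0.5 * (_one_direction(a, b, cfg.tol_cm1, "a_in_b")
                  + _one_direction(b, a, cfg.tol_cm1, "b_in_a"))


def matching_rate_spectra(a: Spectrum, b: Spectrum,
                          cfg: MatchConfig | None = None) -> float:
    """Detect peaks in both spectra, then compute the matching rate.
    Convention: A is the simulated/fitted spectrum being evaluated, B the
    measured reference."""
    cfg = cfg or MatchConfig()
    return matching_rate(detect_peaks(a, cfg), detect_peaks(b, cfg), cfg)
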