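"""Forward simulation and unmixing of vesicle SERS spectra.

A vesicle spectrum is modelled as a non-negative linear combination of the
20 amino-acid reference spectra.  Two directions are supported:

* **simulate** — from an MS-derived amino-acid composition ``f`` and the
  per-amino-acid SERS activities (SNR ratios), mixing coefficients are
  ``c(a) = f(a) * activity(a) / sum_b f(b) * activity(b)`` and the simulated
  spectrum is ``S = sum_a c(a) B_a``.  The activity factor accounts for the
  very different Raman cross-sections of the amino acids: an abundant but
  weakly scattering residue contributes less signal than its molar fraction
  suggests.

* **fit** — given a measured (baseline-corrected, normalized) spectrum,
  recover the coefficients.  The reference method is non-negative least
  squares (NNLS), the well-posed convex formulation of "change the multiply
  factor of each of the 20 spectra to fit the measured spectrum".  A
  boosted-ensemble alternative is provided for compatibility with
  AdaBoost-style fitting: an AdaBoost.R2 ensemble of depth-1 regression
  trees is trained to predict the target intensity at each Raman shift from
  the 20 basis intensities at that shift, and the ensemble's feature
  importances are read out as (normalized) mixing coefficients.

Agreement between fitted coefficients and MS-derived coefficients is
summarized by :func:`mean_deviation` in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.ensemble import AdaBoostRegressor
from sklearn.tree import DecisionTreeRegressor

from .exceptions import FitError, GridError, SersevError
from .ms_composition import AMINO_ACIDS, CompositionVector
from .spectra_io import Spectrum, WavenumberGrid

__all__ = [
    "AminoAcidBasis",
    "FitResult",
    "derive_coefficients",
    "simulate_spectrum",
    "fit_composition",
    "mean_deviation",
]


@dataclass
class AminoAcidBasis:
    """The mixing dictionary: 20 reference SERS spectra plus SERS activities.

    Spectra are expected baseline-corrected and max-normalized (each peak
    max = 1); the intensity scale lives entirely in the ``activity`` values
    (SNR ratios), separating composition from SERS enhancement.
    """

    spectra: dict  # amino-acid code -> Spectrum
    activity: dict  # amino-acid code -> SNR ratio, > 0

    def __post_init__(self) -> None:
        if set(self.spectra) != set(AMINO_ACIDS):
            raise SersevError("basis must contain exactly the 20 standard amino acids")
        if set(self.activity) != set(AMINO_ACIDS):
            raise SersevError("activity map must cover the 20 standard amino acids")
        g0 = self.spectra[AMINO_ACIDS[0]].grid
        for a in AMINO_ACIDS:
            if self.spectra[a].grid != g0:
                raise GridError("all basis spectra must share one grid")
            if not float(self.activity[a]) > 0:
                raise SersevError(f"activity for {a} must be > 0")

    @property
    def grid(self) -> WavenumberGrid:
        return self.spectra[AMINO_ACIDS[0]].grid

    @property
    def matrix(self) -> np.ndarray:
        """(20, n_points) basis matrix in alphabetical amino-acid order."""
        return np.vstack([self.spectra[a].intensities for a in AMINO_ACIDS])

    @property
    def activity_array(self) -> np.ndarray:
        return np.array([float(self.activity[a]) for a in AMINO_ACIDS])


@dataclass
class FitResult:
    """Outcome of unmixing one spectrum against the amino-acid basis."""

    coefficients: CompositionVector
    raw_weights: np.ndarray
    residual_norm: float
    method: str

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise FitError("residual_norm must be >= 0")


def derive_coefficients(f: CompositionVector, basis: AminoAcidBasis) -> CompositionVector:
    """Mixing coefficients from molar composition and SERS activity:
    ``c(a) = f(a) activity(a) / sum_b f(b) activity(b)``."""
    prod = f.as_array() * basis.activity_array
    total = prod.sum()
    if total <= 0:
        raise SersevError("all composition*activity products are zero")
    return CompositionVector.from_array(prod / total)


def simulate_spectrum(c: CompositionVector, basis: AminoAcidBasis) -> Spectrum:
    """Linear combination of the 20 basis spectra, ``S = sum_a c(a) B_a``."""
    y = c.as_array() @ basis.matrix
    return Spectrum(basis.grid, y)


def _check_degenerate(B: np.ndarray) -> None:
    # rank deficiency means the unmixing has non-unique solutions
    if np.linalg.matrix_rank(B) < B.shape[0]:
        warnings.warn(
            "basis spectra are linearly dependent; unmixing weights are a "
            "minimum-norm tie-break and not unique",
            RuntimeWarning,
            stacklevel=3,
        )


def _fit_nnls(target: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    w, rnorm = scipy.optimize.nnls(B.T, target)
    return w, float(rnorm)


def _fit_boosted(target: np.ndarray, B: np.ndarray, seed: int,
                 n_rounds: int = 200) -> tuple[np.ndarray, float]:
    """AdaBoost.R2 reading of the fit: Raman shifts are samples, the 20
    basis intensities are features, the target intensity is the response;
    normalized feature importances serve as the mixing coefficients."""
    model = AdaBoostRegressor(
        estimator=DecisionTreeRegressor(max_depth=1, random_state=seed),
        n_estimators=n_rounds,
        random_state=seed,
    )
    model.fit(B.T, target)
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        raise FitError("boosted fit assigned zero importance to every basis spectrum")
    imp = imp / total
    # best non-negative amplitude for the implied mixture
    mix = imp @ B
    denom = float(mix @ mix)
    alpha = max(0.0, float(mix @ target) / denom) if denom > 0 else 0.0
    w = alpha * imp
    resid = float(np.linalg.norm(target - alpha * mix))
    return w, resid


def fit_composition(target: Spectrum, basis: AminoAcidBasis,
                    method: str = "nnls", seed: int = 0) -> FitResult:
    """Unmix a measured spectrum into non-negative amino-acid coefficients.

    ``method='nnls'`` (reference) minimizes ``||target - sum_a w_a B_a||_2``
    subject to ``w >= 0``; ``method='boosted'`` runs the deterministic
    boosted-ensemble fit.  Coefficients are the normalized weights.
    """
    if target.grid != basis.grid:
        raise GridError("target spectrum is not on the basis grid")
    y = target.intensities
    if np.linalg.norm(y) == 0:
        raise FitError("cannot fit an all-zero target spectrum")
    B = basis.matrix
    _check_degenerate(B)
    if method == "nnls":
        w, resid = _fit_nnls(y, B)
    elif method == "boosted":
        w, resid = _fit_boosted(y, B, seed)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    total = w.sum()
    if total <= 0:
        raise FitError("all fitted weights are zero; target has no basis support")
    return FitResult(
        coefficients=CompositionVector.from_array(w / total),
        raw_weights=w,
        residual_norm=resid,
        method=method,
    )


def mean_deviation(fit: CompositionVector, ref: CompositionVector,
                   mode: str = "relative") -> float:
    """Mean deviation between two compositions, in percent.

    ``relative`` (default): mean over amino acids with ``ref(a) > 0`` of
    ``|fit(a) - ref(a)| / ref(a)``, x100.  ``absolute``: mean of
    ``|fit(a) - ref(a)|``, x100.
    """
    fv, rv = fit.as_array(), ref.as_array()
    if mode == "relative":
        pos = rv > 0
        if not pos.any():
            raise SersevError("relative deviation undefined: reference is all zero")
        return float(np.mean(np.abs(fv[pos] - rv[pos]) / rv[pos])) * 100.0
    if mode == "absolute":
        return float(np.mean(np.abs(fv - rv))) * 100.0
    raise ValueError(f"unknown deviation mode {mode!r}")
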