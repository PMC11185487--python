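"""Synthetic datasets with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a single-vesicle SERS
study without any raw instrument data:

* 20 amino-acid **basis spectra** — sums of Lorentzian lines (the natural
  Raman line shape) with seeded random centres and widths, max-normalized,
  mutually distinguishable (pairwise cosine similarity < 0.95), each with a
  SERS-activity (SNR) value.
* **vesicle spectrum sets** — per group (e.g. a chromatography fraction),
  each vesicle's amino-acid composition is drawn from a Dirichlet around
  the group mean (within-group biological variability on the simplex); its
  spectrum is the activity-weighted linear combination of the bases plus a
  polynomial baseline and Gaussian noise.
* **MS fixtures** — a protein abundance table plus FASTA whose implied
  amino-acid frequencies equal a requested composition exactly (to float
  precision): sequences are residue-sampled from the composition, 20
  homopolymer adjustment proteins guarantee the target lies in the convex
  hull of per-protein compositions, and real-valued abundances solve the
  remaining exact-matching equations in closed form.

Every generator is a pure function of its spec/seed: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import SersevError
from .ms_composition import AMINO_ACIDS, CompositionVector, ProteinAbundanceTable
from .spectra_io import DEFAULT_GRID, Spectrum, SpectrumSet, WavenumberGrid
from .spectral_model import AminoAcidBasis

__all__ = [
    "GroupSpec",
    "SyntheticDatasetSpec",
    "default_spec",
    "generate_basis",
    "generate_vesicle_set",
    "generate_ms_fixture",
]


@dataclass(frozen=True)
class GroupSpec:
    """One group of vesicles (a chromatography fraction of one cell line)."""

    name: str
    n_spectra: int
    mean_composition: CompositionVector
    dirichlet_concentration: float = 50.0
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise SersevError(f"group {self.name}: n_spectra must be >= 1")
        if not self.dirichlet_concentration > 0:
            raise SersevError(f"group {self.name}: dirichlet_concentration must be > 0")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full parameterization of a synthetic dataset.

    noise_sd is the Gaussian noise standard deviation as a fraction of the
    per-spectrum signal maximum; baseline_amplitude scales a random
    polynomial background (order ``baseline_order``) the same way.
    activity_range bounds the per-amino-acid SERS-activity (SNR) draw.
    """

    seed: int = 0
    grid: WavenumberGrid = field(default_factory=lambda: DEFAULT_GRID)
    n_basis_peaks: tuple = (4, 8)
    peak_width_cm1: tuple = (6.0, 20.0)
    groups: tuple = ()
    noise_sd: float = 0.02
    baseline_order: int = 2
    baseline_amplitude: float = 0.1
    activity_range: tuple = (5.0, 50.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise SersevError("noise_sd and baseline_amplitude must be >= 0")
        if self.baseline_order < 0:
            raise SersevError("baseline_order must be >= 0")
        lo, hi = self.activity_range
        if not (0 < lo <= hi):
            raise SersevError("activity_range must be positive and ordered")
        object.__setattr__(self, "groups", tuple(self.groups))


#: Per-fraction spectrum counts of the two cell lines in the study design
#: this generator emulates (fractions 7-9).
_STUDY_COUNTS = {
    "HEK293": {"F7": 59, "F8": 115, "F9": 47},
    "HEK293+HRAS": {"F7": 65, "F8": 68, "F9": 31},
}


def default_spec(seed: int = 0) -> SyntheticDatasetSpec:
    """Study-shaped default: two cell lines x three SEC fractions with the
    per-fraction vesicle counts of the emulated design.  Fraction means are
    distinct random compositions; the second cell line's means are mixtures
    (50/50) of the first line's with fresh material, so the two populations
    are related — partially overlapping — yet separable."""
    rng = np.random.default_rng([int(seed), 0])
    groups = []
    hek_means = {}
    for frac in ("F7", "F8", "F9"):
        mean = CompositionVector.from_array(rng.dirichlet(np.full(20, 3.0)))
        hek_means[frac] = mean
        groups.append(GroupSpec(
            name=f"HEK293-{frac}",
            n_spectra=_STUDY_COUNTS["HEK293"][frac],
            mean_composition=mean,
            cell_line="HEK293",
        ))
    for frac in ("F7", "F8", "F9"):
        novel = rng.dirichlet(np.full(20, 3.0))
        mixed = 0.5 * hek_means[frac].as_array() + 0.5 * novel
        groups.append(GroupSpec(
            name=f"HEK293+HRAS-{frac}",
            n_spectra=_STUDY_COUNTS["HEK293+HRAS"][frac],
            mean_composition=CompositionVector.from_array(mixed, normalize=True),
            cell_line="HEK293+HRAS",
        ))
    return SyntheticDatasetSpec(seed=int(seed), groups=tuple(groups))


def _lorentzian(axis: np.ndarray, center: float, width: float) -> np.ndarray:
    # width = half width at half maximum
    return 1.0 / (1.0 + ((axis - center) / width) ** 2)


def _random_basis_spectrum(rng: np.random.Generator,
                           spec: SyntheticDatasetSpec) -> np.ndarray:
    axis = spec.grid.axis
    lo, hi = spec.grid.start + 20.0, spec.grid.end - 20.0
    if hi <= lo:
        raise SersevError("grid too narrow for basis peak placement")
    k_lo, k_hi = spec.n_basis_peaks
    n_peaks = int(rng.integers(k_lo, k_hi + 1))
    y = np.zeros_like(axis)
    for _ in range(n_peaks):
        center = rng.uniform(lo, hi)
        width = rng.uniform(*spec.peak_width_cm1)
        amp = rng.uniform(0.2, 1.0)
        y += amp * _lorentzian(axis, center, width)
    return y / y.max()


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def generate_basis(spec: SyntheticDatasetSpec) -> AminoAcidBasis:
    """Generate 20 max-normalized Lorentzian-line basis spectra with SERS
    activities drawn from ``activity_range``.  Pairs with cosine similarity
    >= 0.95 are regenerated so the dictionary stays well-conditioned."""
    rng = np.random.default_rng([int(spec.seed), 1])
    curves = [_random_basis_spectrum(rng, spec) for _ in AMINO_ACIDS]
    for _ in range(200):
        clash = None
        for i in range(len(curves)):
            for j in range(i + 1, len(curves)):
                if _cosine(curves[i], curves[j]) >= 0.95:
                    clash = j
                    break
            if clash is not None:
                break
        if clash is None:
            break
        curves[clash] = _random_basis_spectrum(rng, spec)
    else:
        raise SersevError("could not generate 20 mutually distinct basis spectra")
    activities = rng.uniform(*spec.activity_range, size=20)
    spectra = {
        a: Spectrum(spec.grid, curves[i], {"amino_acid": a})
        for i, a in enumerate(AMINO_ACIDS)
    }
    return AminoAcidBasis(spectra, dict(zip(AMINO_ACIDS, activities)))


def _dirichlet_on_support(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw that respects zero-mean components (they stay zero)."""
    out = np.zeros_like(alpha)
    support = alpha > 0
    if support.sum() == 1:
        out[support] = 1.0
        return out
    out[support] = rng.dirichlet(alpha[support])
    return out


def generate_vesicle_set(spec: SyntheticDatasetSpec,
                         basis: AminoAcidBasis) -> tuple:
    """Generate per-group vesicle spectra plus the true mixing coefficients.

    For each vesicle: composition ~ Dirichlet(concentration * group mean);
    mixing coefficients are the activity-weighted, normalized composition;
    the spectrum is the corresponding basis combination plus a random
    polynomial baseline and Gaussian noise (both scaled to the signal max).
    Returns ``(SpectrumSet, [CompositionVector])`` where the truth entries
    are the normalized mixing coefficients :func:`fit_composition` estimates.
    """
    if basis.grid != spec.grid:
        raise SersevError("basis is not on the dataset grid")
    if not spec.groups:
        raise SersevError("spec has no groups")
    rng = np.random.default_rng([int(spec.seed), 2])
    act = basis.activity_array
    B = basis.matrix
    x01 = np.linspace(0.0, 1.0, spec.grid.n_points)
    spectra = []
    truths = []
    for group in spec.groups:
        alpha = group.dirichlet_concentration * group.mean_composition.as_array()
        for i in range(group.n_spectra):
            comp = _dirichlet_on_support(rng, alpha)
            mix = comp * act
            coeff = mix / mix.sum()
            signal = coeff @ B
            smax = signal.max()
            baseline = np.zeros_like(signal)
            if spec.baseline_amplitude > 0:
                pcoef = rng.uniform(-1.0, 1.0, spec.baseline_order + 1)
                baseline = spec.baseline_amplitude * smax * np.polyval(pcoef, x01)
            noise = np.zeros_like(signal)
            if spec.noise_sd > 0:
                noise = spec.noise_sd * smax * rng.standard_normal(signal.size)
            meta = {
                "sample_id": f"{group.name}-{i:03d}",
                "fraction": group.name.rsplit("-", 1)[-1] if "-" in group.name else group.name,
                "group": group.name,
            }
            if group.cell_line is not None:
                meta["cell_line"] = group.cell_line
            spectra.append(Spectrum(spec.grid, signal + baseline + noise, meta))
            truths.append(CompositionVector.from_array(coeff))
    return SpectrumSet(spectra), truths


def generate_ms_fixture(comp: CompositionVector, n_proteins: int = 90,
                        seed: int = 0) -> tuple:
    """Protein abundance table + FASTA whose amino-acid frequencies equal
    ``comp`` to float precision.

    ``n_proteins`` sequences (length 100-600) are residue-sampled from
    ``comp``; one homopolymer adjustment protein per supported amino acid is
    appended and all abundances are solved in closed form so the
    abundance-weighted composition matches exactly.  Returns
    ``(ProteinAbundanceTable, fasta_text)`` — the table already carries the
    sequences.
    """
    if n_proteins < 1:
        raise SersevError("n_proteins must be >= 1")
    rng = np.random.default_rng(int(seed))
    p = comp.as_array()
    p = p / p.sum()
    support = np.flatnonzero(p > 0)
    codes = np.array(list(AMINO_ACIDS))

    ids, seqs, comps, lengths = [], [], [], []
    for k in range(n_proteins):
        length = int(rng.integers(100, 601))
        residues = rng.choice(codes, size=length, p=p)
        seq = "".join(residues)
        counts = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
        ids.append(f"SYNP{k + 1:04d}")
        seqs.append(seq)
        comps.append(counts / length)
        lengths.append(length)

    # molar mass alpha on the sampled proteins, chosen so the homopolymer
    # adjustment proteins can absorb the remainder with non-negative mass
    m = np.mean(comps, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(m > 0, p / np.where(m > 0, m, 1.0), np.inf)
    alpha = min(0.9, 0.9 * float(ratios[support].min())) if support.size else 0.0
    theta = np.full(n_proteins, alpha / n_proteins)

    remainder = np.clip(p - alpha * m, 0.0, None)
    for idx in support:
        a = codes[idx]
        length = int(rng.integers(100, 601))
        ids.append(f"SYNADJ_{a}")
        seqs.append(a * length)
        e = np.zeros(20)
        e[idx] = 1.0
        comps.append(e)
        lengths.append(length)
        theta = np.append(theta, remainder[idx])

    theta = theta / theta.sum()
    # molar mass theta_p corresponds to abundance weight w_p = theta_p / L_p
    w = theta / np.asarray(lengths, dtype=float)
    w = w / w.sum()

    df = pd.DataFrame({
        "protein_id": ids,
        "rel_abundance": w,
        "sequence": seqs,
        "nonstandard_residues": "",
    })
    table = ProteinAbundanceTable(df)

    fasta_lines = []
    for pid, seq in zip(ids, seqs):
        fasta_lines.append(f">{pid} synthetic protein")
        fasta_lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return table, "\n".join(fasta_lines) + "\n"
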