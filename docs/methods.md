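# Methods

## Model

A single-vesicle SERS spectrum on the shared Raman-shift grid (default
564–1681 cm⁻¹, 1117 uniformly spaced points) is modelled as a non-negative
linear combination of the 20 amino-acid reference spectra. The model makes
three simplifying assumptions: (i) the vesicle signal is dominated by
protein content — lipid and nucleic-acid contributions are not modelled and
are a known source of mismatch on real data; (ii) reference spectra add
linearly (no chemical interaction between residues on the substrate);
(iii) the very different Raman cross-sections of the amino acids can be
summarized by a single per-amino-acid SERS-activity scalar η(a), proxied by
the SNR of its reference spectrum. On the MS side, the molar amino-acid
composition of a protein mixture is the abundance-weighted residue count
divided by the abundance-weighted residue total; nonstandard residue
letters (B, J, O, U, X, Z) are excluded from both sums and reported,
because the spectral basis has exactly 20 members. Mixing coefficients are
the activity-weighted, renormalized composition:
c(a) = f(a)η(a)/Σ f(b)η(b).

## Preprocessing

Raw spectra are linearly interpolated onto the analysis grid, baseline
corrected by asymmetric least squares (smoothness λ = 1e5, asymmetry
p = 0.01, ≤15 reweighting iterations — the common defaults for Raman
baselines; both configurable), and ℓ2-normalized by default so that
vesicle-to-vesicle hotspot-enhancement variation drops out before unmixing
and LDA. Negative intensities left by baseline correction are kept (no
clipping) to avoid biasing small coefficients. SNR is
max(y)/σ with the robust first-difference noise estimate
σ = median(|Δy|)/(0.6745·√2), which needs no user-chosen signal-free
window and is invariant under positive rescaling; an exactly noiseless
spectrum returns a flagged infinite-SNR sentinel. An optional SNR gate
flags (never drops) low-SNR spectra.

## Unmixing

The reference solver is non-negative least squares (scipy's active-set
NNLS): min‖S − Σ w_a B_a‖₂ s.t. w ≥ 0, coefficients = w/Σw. Basis spectra
are max-normalized before fitting so the intensity scale lives in the
activities. A rank-deficient basis triggers a warning (the solution is then
a tie-break, not unique); an all-zero target is an error. The
boosted-ensemble alternative implements an AdaBoost-style reading of the
fit: an AdaBoost.R2 ensemble of 200 depth-1 regression trees is trained
with the Raman shifts as samples, the 20 basis intensities at each shift as
features and the target intensity as response; the ensemble's normalized
feature importances are read out as mixing coefficients and scaled by the
L2-optimal amplitude. This reading is deterministic given its seed, but it
is an interpretation — the convex NNLS formulation is the primary,
well-posed method, and all deviation statistics are reported for whichever
method is configured.

Fitted-vs-reference agreement is a mean deviation in percent, computed in
two modes because the convention is ambiguous: *relative* (mean of
|fit−ref|/ref over ref > 0 — sensitive to near-zero reference entries) and
*absolute* (mean |fit−ref| × 100, in percentage points). Both are reported.

## Peak matching

Peaks are local maxima with prominence ≥ 5 % of the spectrum maximum and
pairwise separation ≥ 10 cm⁻¹ (scipy `find_peaks`; of two close candidates
the more prominent survives). The matching rate between two peak lists is
the percentage of one list's peaks with a counterpart within ±8 cm⁻¹
(≈8 grid steps) in the other, under greedy one-to-one assignment by
ascending distance so a single broad peak cannot absorb several
counterparts. The default direction treats the simulated/fitted spectrum
as the probe and the measured average as the reference; both directions and
their mean are available, and the tolerance is always reported with the
rate.

## LDA and overlap rates

With ~10²–10³ spectra and 1117 features the within-class scatter is
rank-deficient, so Fisher directions are computed in the SVD subspace of
the centered data; there the within-class scatter is eigendecomposed and
inverted through a regularized inverse square root (eigenvalues floored at
1e-8 of the largest — effectively a pseudo-inverse that keeps the
null-space directions usable), and the discriminant directions are the top
eigenvectors of the whitened between-class scatter, mapped back to the full
space and normalized to unit within-class variance. Dimensionality is
min(n_groups − 1, 2): 1-D for a binary system, 2-D for three fractions.
Scores are reproducible bit for bit: the solver is deterministic and each
axis is sign-fixed so its first nonzero loading is positive.

A consequence of working at n ≪ p: on *training* scores the discriminant
can separate any labelled point cloud essentially completely, so overlap
rates computed on the training embedding of well-separated synthetic groups
are 0 % and should generally be read as lower bounds. Real-data analyses
that show partial overlap imply additional regularization (or out-of-sample
transforms), which can be emulated here by transforming held-out spectra
with `transform`.

Overlap rules: (1-D) share of group A scores inside [min, max] of group B's
scores; (2-D, default) share of A points inside the convex hull of B's
scores, boundary inclusive, with a distance-based fallback for degenerate
(collinear or coincident) hulls and an error for groups of fewer than 3
points; (classify) share of A points whose nearest class centroid in score
space is B's — the two 2-D rules are always reported side by side since the
"common vesicle" counting rule in 2-D is a convention. The pooled
two-cell-type analysis fits a binary 1-D LDA on cell type over all
fractions and reports, per fraction of the test cell type, the range-rule
overlap of that fraction's scores with the whole reference cell type.

## Synthetic data

The generator fixes the study conditions for all tests and the acceptance
script:

| parameter | default | rationale |
| --- | --- | --- |
| grid | 564–1681 cm⁻¹, 1117 pts | instrument detection range/sampling |
| basis peaks per amino acid | 4–8 Lorentzians, HWHM 6–20 cm⁻¹ | natural Raman line shape; realistic band counts |
| pairwise basis cosine | < 0.95 (regenerated) | keeps the dictionary identifiable |
| SERS activity η | uniform on [5, 50] | order-of-magnitude spread of SNRs across substances |
| group sizes | 59/115/47 and 65/68/31 | the per-fraction vesicle counts of the emulated design |
| within-group variability | Dirichlet, concentration 50 | simplex-respecting biological variability (~few % sd per coefficient) |
| cell-line relatedness | fraction means mixed 50/50 with fresh material | related but separable populations |
| noise | Gaussian, sd = 2 % of signal max | typical post-baseline single-spectrum noise |
| baseline | order-2 polynomial, amplitude 10 % of signal max | smooth dried-buffer/luminescence background |

Vesicle truth values are the normalized activity-weighted mixing
coefficients — exactly the quantity unmixing estimates. The MS fixture is
exact by construction rather than by sampling: n sequences (length
100–600) are residue-sampled from the target composition, one homopolymer
adjustment protein per supported amino acid is appended (guaranteeing the
target lies in the convex hull of per-protein compositions), and the
real-valued abundances are solved in closed form so the implied composition
equals the target to float precision. A single adjustment protein cannot do
this: with integer residue counts one sequence cannot hit 20 real-valued
targets.

What the generator does *not* emulate: lipid/nucleic-acid bands, cosmic-ray
spikes, wavelength-calibration drift, non-Gaussian hotspot intensity
statistics, and peptide-level MS quantification noise. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated model, not instrument-level robustness.

## Numerical choices and degenerate inputs

- Map-table reading canonicalizes positions by (x, y) and axes to ascending
  wavenumber, making results independent of file row order; written tables
  use `repr` floats so round trips are exact.
- Axis uniformity is checked to 1e-6 relative; ragged sweeps and
  non-numeric cells fail with the offending position/line.
- The ALS linear systems are solved with sparse Cholesky-style `spsolve` on
  the penalized normal equations; iteration stops at a weight fixed point.
- Grid comparisons are exact dataclass equality; resampling requires full
  coverage (no extrapolation).
- Greedy peak assignment sorts candidate pairs by (distance, index) for a
  deterministic tie-break.
- Composition vectors tolerate −1e-12 rounding negatives (clipped to 0) and
  must sum to 1 within 1e-9.
- Problem sizes in the test suite and acceptance script (200-point toy
  grids for unit tests, the full 1117-point grid with 3 × 60 or 385 spectra
  for end-to-end checks, 100 MS round trips at 20 proteins) were chosen to
  exercise every code path at desk scale; the full suite runs in well under
  a minute.

## Known limitations

- Amino-acid-only forward model (no lipids/nucleic acids) — deviations on
  real vesicles partly reflect model misspecification, not fit error.
- The relative deviation mode is dominated by near-zero reference
  coefficients; the absolute mode is the stabler summary.
- The boosted fit is one defensible reading of an AdaBoost-based fitting
  procedure; NNLS is the method of record.
- Training-score overlap rates at n ≪ p are lower bounds (see above).
- Preprocessing of real instrument exports (baseline parameters,
  normalization) materially affects downstream rates and must be matched to
  the acquisition conditions; the defaults here are generic Raman choices.
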