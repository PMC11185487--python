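"""Exception hierarchy for the sersev pipeline.

All library errors derive from :class:`SersevError` so callers can catch
pipeline failures without masking programming errors.
"""


class SersevError(Exception):
    """Base class for all sersev errors."""


class SpectraFormatError(SersevError, ValueError):
    """A spectral data file violates the expected layout (ragged map sweeps,
    duplicated wavenumbers, non-numeric cells, ...)."""


class GridError(SersevError, ValueError):
    """Wavenumber grids are incompatible (mismatched axes, non-uniform
    spacing, or a spectrum that does not cover the requested grid)."""


class CompositionError(SersevError, ValueError):
    """An amino-acid composition vector violates its invariants."""


class MissingSequenceError(SersevError, KeyError):
    """Protein ids in an abundance table could not be resolved in the
    supplied FASTA."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            "protein ids missing from FASTA: " + ", ".join(self.missing_ids)
        )


class FitError(SersevError, ValueError):
    """Spectral unmixing cannot be performed (zero target, empty basis...)."""


class PeakMatchError(SersevError, ValueError):
    """Peak matching is undefined for the given inputs (empty reference)."""


class LDAError(SersevError, ValueError):
    """Discriminant analysis preconditions violated (too few groups or
    group members, grid mismatch, degenerate hull)."""


class ValidationError(SersevError, ValueError):
    """Pipeline configuration failed pre-flight validation."""
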