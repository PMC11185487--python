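"""From MS protein relative abundances to amino-acid composition.

A bottom-up proteomics run reports relative abundances for the proteins of
a vesicle preparation.  Weighting each protein's residue counts by its
abundance and normalizing by the abundance-weighted total residue count
yields the molar fractions of the 20 standard amino acids:

    f(a) = sum_p w_p * n_{p,a} / sum_p w_p * L_p

where ``n_{p,a}`` counts residue ``a`` in protein ``p`` and ``L_p`` is the
number of standard residues.  Nonstandard residue letters (B, J, O, U, X, Z)
are excluded from both numerator and denominator and recorded per protein,
because the downstream spectral basis has exactly 20 members.

Sequences come from a local FASTA file rather than a live database lookup,
so results are reproducible against a fixed sequence snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .exceptions import CompositionError, MissingSequenceError, SersevError

__all__ = [
    "AMINO_ACIDS",
    "CompositionVector",
    "ProteinAbundanceTable",
    "load_protein_abundances",
    "attach_sequences",
    "amino_acid_frequencies",
    "compare_to_reference",
    "CompositionComparison",
    "write_composition_csv",
    "read_composition_csv",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / nonstandard residue letters excluded from compositions.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class CompositionVector:
    """Relative molar abundances of the 20 standard amino acids.

    Non-negative, sums to 1 (within 1e-9).  Used both for MS-derived ground
    truth and for fitted spectral coefficients.
    """

    weights: dict

    def __post_init__(self) -> None:
        w = dict(self.weights)
        extra = set(w) - set(AMINO_ACIDS)
        if extra:
            raise CompositionError(f"unknown amino-acid codes: {sorted(extra)}")
        full = {a: float(w.get(a, 0.0)) for a in AMINO_ACIDS}
        for a, v in full.items():
            if v < -1e-12:
                raise CompositionError(f"negative weight for {a}: {v}")
            if v < 0:
                full[a] = 0.0
        total = sum(full.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"weights sum to {total}, expected 1")
        object.__setattr__(self, "weights", full)

    @classmethod
    def from_array(cls, values, normalize: bool = False) -> "CompositionVector":
        v = np.asarray(values, dtype=float)
        if v.shape != (20,):
            raise CompositionError(f"expected 20 values, got shape {v.shape}")
        if normalize:
            total = v.sum()
            if total <= 0:
                raise CompositionError("cannot normalize non-positive weights")
            v = v / total
        return cls(dict(zip(AMINO_ACIDS, v)))

    @classmethod
    def uniform(cls) -> "CompositionVector":
        return cls.from_array(np.full(20, 0.05))

    @classmethod
    def delta(cls, code: str) -> "CompositionVector":
        v = np.zeros(20)
        v[_AA_INDEX[code]] = 1.0
        return cls.from_array(v)

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[a] for a in AMINO_ACIDS])

    def __getitem__(self, code: str) -> float:
        return self.weights[code]

    def allclose(self, other: "CompositionVector", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.as_array(), other.as_array(), rtol=0, atol=atol))


@dataclass
class ProteinAbundanceTable:
    """Protein relative abundances, optionally with sequences attached.

    Backed by a DataFrame with columns ``protein_id``, ``rel_abundance``
    (normalized to sum 1) and, after :func:`attach_sequences`, ``sequence``
    and ``nonstandard_residues``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for col in ("protein_id", "rel_abundance"):
            if col not in df.columns:
                raise SersevError(f"abundance table lacks column {col!r}")
        ab = df["rel_abundance"].to_numpy(dtype=float)
        if np.any(ab < 0):
            raise SersevError("negative relative abundance")
        if not np.any(ab > 0):
            raise SersevError("all relative abundances are zero")
        self.df = df

    @property
    def has_sequences(self) -> bool:
        return "sequence" in self.df.columns and self.df["sequence"].notna().all()

    def __len__(self) -> int:
        return len(self.df)


# candidate column-name fragments, in priority order
_ID_HINTS = ("accession", "protein", "uniprot", "id")
_ABUNDANCE_HINTS = ("abundance", "ibaq", "lfq", "intensity", "count")


def _pick_column(columns, hints, numeric_cols=None):
    lowered = {c: str(c).lower() for c in columns}
    for hint in hints:
        for c in columns:
            if hint in lowered[c] and (numeric_cols is None or c in numeric_cols):
                return c
    return None


def load_protein_abundances(path, id_col: str | None = None,
                            abundance_col: str | None = None) -> ProteinAbundanceTable:
    """Load a protein relative-abundance table from CSV/TSV or XLSX.

    Column names are configurable; when omitted they are guessed from
    common MS-export conventions (accession/protein id column, an
    abundance/iBAQ/LFQ/intensity column).  Abundances are renormalized to
    sum to 1; how the instrument quantified them (spectral counts, iBAQ,
    LFQ) is taken as given.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    if id_col is None:
        id_col = _pick_column(df.columns, _ID_HINTS) or df.columns[0]
    if id_col not in df.columns:
        raise SersevError(f"id column {id_col!r} not in table")
    if abundance_col is None:
        numeric = [c for c in df.columns
                   if c != id_col and pd.api.types.is_numeric_dtype(df[c])]
        abundance_col = _pick_column(df.columns, _ABUNDANCE_HINTS, set(numeric))
        if abundance_col is None and numeric:
            abundance_col = numeric[0]
    if abundance_col is None or abundance_col not in df.columns:
        raise SersevError("no abundance column found; pass abundance_col explicitly")
    ab = pd.to_numeric(df[abundance_col], errors="raise").to_numpy(dtype=float)
    if np.any(ab < 0):
        raise SersevError("negative relative abundance in table")
    total = ab.sum()
    if total <= 0:
        raise SersevError("abundances sum to zero")
    out = pd.DataFrame({
        "protein_id": df[id_col].astype(str),
        "rel_abundance": ab / total,
    })
    return ProteinAbundanceTable(out)


def _fasta_index(fasta_path) -> dict:
    """Map every plain id and pipe-delimited token (UniProt style
    ``sp|P12345|NAME``) of each FASTA record to its sequence."""
    index: dict = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        keys = {rec.id, *rec.id.split("|")}
        for k in keys:
            if k:
                index.setdefault(k, seq)
    return index


def attach_sequences(table: ProteinAbundanceTable, fasta_path) -> ProteinAbundanceTable:
    """Attach sequences from a FASTA file; every protein id must resolve.

    Missing ids raise :class:`MissingSequenceError` listing them all — no
    silent drops.  Nonstandard residues found in each sequence are recorded
    in a ``nonstandard_residues`` column.
    """
    index = _fasta_index(fasta_path)
    seqs, nonstd, missing = [], [], []
    for pid in table.df["protein_id"]:
        if pid not in index:
            missing.append(pid)
            continue
        seq = index[pid]
        seqs.append(seq)
        nonstd.append("".join(sorted(set(seq) & NONSTANDARD_RESIDUES)))
    if missing:
        raise MissingSequenceError(missing)
    df = table.df.copy()
    df["sequence"] = seqs
    df["nonstandard_residues"] = nonstd
    return ProteinAbundanceTable(df)


def _residue_counts(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in seq:
        i = _AA_INDEX.get(ch)
        if i is not None:
            counts[i] += 1
    return counts


def amino_acid_frequencies(table: ProteinAbundanceTable) -> CompositionVector:
    """Abundance-weighted molar amino-acid composition of a protein mixture.

    ``f(a) = sum_p w_p n_{p,a} / sum_p w_p L_p`` over standard residues
    only.  Invariant under common rescaling of the abundances.
    """
    if not table.has_sequences:
        raise SersevError("table has no sequences; call attach_sequences first")
    num = np.zeros(20)
    denom = 0.0
    for _, row in table.df.iterrows():
        counts = _residue_counts(row["sequence"])
        length = counts.sum()
        if length == 0:
            raise SersevError(
                f"protein {row['protein_id']} has no standard residues"
            )
        w = float(row["rel_abundance"])
        num += w * counts
        denom += w * length
    if denom <= 0:
        raise SersevError("zero total weighted residue count")
    return CompositionVector.from_array(num / denom)


@dataclass
class CompositionComparison:
    """Per-amino-acid differences plus summary statistics between a fitted
    or derived composition and a reference composition."""

    differences: dict           # code -> (value - reference)
    pearson_r: float
    mean_relative_deviation_pct: float  # mean over ref>0 of |diff|/ref, in %


def compare_to_reference(c: CompositionVector,
                         ref: CompositionVector) -> CompositionComparison:
    """Compare a composition against a reference 20-vector."""
    cv, rv = c.as_array(), ref.as_array()
    diff = cv - rv
    if np.allclose(cv, cv[0]) and np.allclose(rv, rv[0]):
        r = 1.0 if np.allclose(cv, rv) else 0.0  # degenerate constant vectors
    else:
        r = float(stats.pearsonr(cv, rv).statistic)
    pos = rv > 0
    mrd = float(np.mean(np.abs(diff[pos]) / rv[pos])) * 100.0 if pos.any() else 0.0
    return CompositionComparison(
        differences=dict(zip(AMINO_ACIDS, diff)),
        pearson_r=r,
        mean_relative_deviation_pct=mrd,
    )


def write_composition_csv(c: CompositionVector, path) -> None:
    lines = ["amino_acid,fraction"]
    lines += [f"{a},{repr(c[a])}" for a in AMINO_ACIDS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_composition_csv(path) -> CompositionVector:
    df = pd.read_csv(path)
    return CompositionVector(dict(zip(df["amino_acid"], df["fraction"].astype(float))))
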