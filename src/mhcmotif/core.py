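"""Shared domain types for the motif pipeline.

The pipeline converts quantitative peptide:MHC class I binding data
(IC50 in nM, one fixed peptide length per dataset) into a classical
binding motif: anchor positions plus per-position residue preferences.
These dataclasses are the common currency between the I/O, training,
motif-calling and rendering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 canonical amino acids, in the fixed row order used everywhere
#: (matrix files, one-hot encoding blocks, rendered tables).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


class FormatError(ValueError):
    """A file does not match the expected tabular layout."""


class EmptyDatasetError(ValueError):
    """No valid records survived validation."""


class MatrixParseError(ValueError):
    """A scoring-matrix file is malformed; the message names the line."""


@dataclass(frozen=True)
class BindingRecord:
    """One measured peptide:MHC binding affinity.

    Parameters
    ----------
    peptide : str
        Uppercase sequence over the 20-letter canonical alphabet.
    ic50 : float
        Half-maximal inhibitory concentration in nM; lower = stronger.
    """

    peptide: str
    ic50: float

    def __post_init__(self) -> None:
        if not self.peptide or any(c not in AA_INDEX for c in self.peptide):
            raise ValueError(f"non-canonical peptide: {self.peptide!r}")
        if not np.isfinite(self.ic50) or self.ic50 <= 0:
            raise ValueError(f"ic50 must be positive and finite, got {self.ic50}")


@dataclass
class BindingDataset:
    """All binding records for one allele at one fixed peptide length."""

    allele: str
    length: int
    records: list[BindingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.peptide) != self.length:
                raise ValueError(
                    f"peptide {rec.peptide!r} has length {len(rec.peptide)}, "
                    f"dataset expects {self.length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def peptides(self) -> list[str]:
        return [r.peptide for r in self.records]

    @property
    def ic50s(self) -> np.ndarray:
        return np.array([r.ic50 for r in self.records], dtype=float)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-allele/per-length record counts (total and binders)."""

    allele: str
    length: int
    n_total: int
    n_binders: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_binders <= self.n_total:
            raise ValueError(
                f"need 0 <= n_binders <= n_total, got {self.n_binders}/{self.n_total}"
            )


@dataclass
class ScoringMatrix:
    """A 20 x L position-specific scoring matrix in log10(IC50 nM) units.

    ``values[r, p]`` is the additive contribution of residue ``ALPHABET[r]``
    at position ``p`` (0-based internally, reported 1-based).  Lower values
    mean more favourable binding.  The intercept is the baseline predicted
    log10(IC50) for a hypothetical zero-contribution peptide.
    """

    allele: str
    values: np.ndarray
    intercept: float
    lambda_used: float | None = None
    cv_error: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(ALPHABET):
            raise ValueError(f"values must be 20 x L, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or not np.isfinite(self.intercept):
            raise ValueError("matrix values and intercept must be finite")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def column(self, position: int) -> np.ndarray:
        """Return the 20-vector for a 1-based peptide position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return self.values[:, position - 1]
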