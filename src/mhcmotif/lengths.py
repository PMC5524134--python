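"""Viable motif-length selection for an allele.

MHC class I grooves bind mostly 8-10-mers, and the amount of data per
length varies wildly.  The length with the most known binders becomes
the default motif; any other length is viable when it has at least
``threshold`` binders (default 200).  The default length is always kept
even below the threshold, so low-data alleles still get one motif.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DatasetSummary

DEFAULT_LENGTH_THRESHOLD = 200


@dataclass
class LengthSelection:
    """Viable (length, n_binders) pairs and the default length."""

    allele: str
    viable: list[tuple[int, int]]  # ascending by length
    default_length: int

    def __post_init__(self) -> None:
        if self.default_length not in {l for l, _ in self.viable}:
            raise ValueError("default_length must be viable")

    @property
    def viable_lengths(self) -> list[int]:
        return [l for l, _ in self.viable]


def select_lengths(
    summaries: list[DatasetSummary], threshold: int = DEFAULT_LENGTH_THRESHOLD
) -> LengthSelection:
    """Pick the default and viable motif lengths from per-length summaries.

    The default is the length with the most binders (ties break to the
    shorter length).  Viable = {default} plus every length with
    n_binders >= threshold.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    alleles = {s.allele for s in summaries}
    if len(alleles) != 1:
        raise ValueError(f"summaries mix alleles: {sorted(alleles)}")
    lengths = [s.length for s in summaries]
    if len(set(lengths)) != len(lengths):
        raise ValueError("duplicate length in summaries")

    by_length = {s.length: s.n_binders for s in summaries}
    default = min(by_length, key=lambda l: (-by_length[l], l))
    viable = sorted(
        l for l, nb in by_length.items() if nb >= threshold or l == default
    )
    return LengthSelection(
        allele=summaries[0].allele,
        viable=[(l, by_length[l]) for l in viable],
        default_length=default,
    )
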