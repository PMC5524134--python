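"""Evaluation of derived motifs against expert reference assignments.

Anchor calls are compared position-by-position to expert motifs
(pool-sequencing, combinatorial-library or database assignments),
yielding a confusion matrix with sensitivity/specificity, and the
preferred residue sets at reference anchors are compared by Jaccard
overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .core import AA_INDEX
from .motif import Motif


class UndefinedMetricError(ValueError):
    """Sensitivity/specificity requested with a zero denominator."""


@dataclass
class ReferenceMotif:
    """Expert motif: anchor positions plus primary/secondary residues."""

    allele: str
    length: int
    residue_sets: dict[int, tuple[set[str], set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, (primary, secondary) in self.residue_sets.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"anchor position {pos} outside 1..{self.length}")
            bad = (primary | secondary) - set(AA_INDEX)
            if bad:
                raise ValueError(f"non-canonical residues {sorted(bad)} at P{pos}")

    @property
    def anchors(self) -> set[int]:
        return set(self.residue_sets)

    def pooled(self, position: int) -> set[str]:
        """Primary union secondary residues at a reference anchor."""
        primary, secondary = self.residue_sets[position]
        return primary | secondary


def parse_residue_spec(spec: str) -> tuple[set[str], set[str]]:
    """Parse an expert residue string like ``"VL[MIAT]"``.

    Unbracketed letters are primary residues, bracketed ones secondary.
    Case anomalies and stray punctuation from scanned tables (``"R."``,
    ``"w"``) are normalized by uppercasing and dropping non-letters.
    """
    spec = spec.strip().upper()
    m = re.fullmatch(r"([^\[\]]*)(?:\[([^\[\]]*)\])?", spec)
    if m is None:
        raise ValueError(f"unbalanced brackets in residue spec {spec!r}")
    primary = {c for c in m.group(1) if c.isalpha()}
    secondary = {c for c in (m.group(2) or "") if c.isalpha()}
    return primary, secondary


@dataclass(frozen=True)
class ConfusionMatrix:
    """Position-level anchor agreement counts (predicted x actual)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def anchor_confusion(
    predicted: list[Motif], reference: list[ReferenceMotif]
) -> ConfusionMatrix:
    """Sum per-position anchor agreement over matched (allele, length) pairs.

    Every predicted motif must have a reference with the same allele and
    length; unmatched motifs raise an error naming the orphans.
    """
    refs = {(r.allele, r.length): r for r in reference}
    orphans = [
        f"{m.allele}/{m.length}" for m in predicted if (m.allele, m.length) not in refs
    ]
    if orphans:
        raise ValueError(f"no reference motif for: {', '.join(orphans)}")
    tp = fp = fn = tn = 0
    for m in predicted:
        ref = refs[(m.allele, m.length)]
        for p in range(1, m.length + 1):
            pred_a, ref_a = p in m.anchors, p in ref.anchors
            if pred_a and ref_a:
                tp += 1
            elif pred_a:
                fp += 1
            elif ref_a:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (Python's round is half-even)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def sensitivity(cm: ConfusionMatrix) -> float:
    """100 * tp / (tp + fn), half-up rounded to one decimal."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual anchors")
    return _round1(100.0 * cm.tp / (cm.tp + cm.fn))


def specificity(cm: ConfusionMatrix) -> float:
    """100 * tn / (tn + fp), half-up rounded to one decimal."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual non-anchors")
    return _round1(100.0 * cm.tn / (cm.tn + cm.fp))


@dataclass(frozen=True)
class PositionAgreement:
    position: int
    jaccard: float
    shared: frozenset[str]
    predicted_only: frozenset[str]
    reference_only: frozenset[str]


def residue_agreement(
    predicted: Motif, reference: ReferenceMotif
) -> dict[int, PositionAgreement]:
    """Jaccard overlap of preferred residues at each reference anchor.

    The predicted preferred set is compared to the reference primary
    union secondary pool; set differences are reported alongside.
    """
    if (predicted.allele, predicted.length) != (reference.allele, reference.length):
        raise ValueError("predicted and reference motifs must match allele and length")
    out = {}
    for pos in sorted(reference.anchors):
        pred = predicted.preferred(pos)
        ref = reference.pooled(pos)
        union = pred | ref
        out[pos] = PositionAgreement(
            position=pos,
            jaccard=len(pred & ref) / len(union) if union else 1.0,
            shared=frozenset(pred & ref),
            predicted_only=frozenset(pred - ref),
            reference_only=frozenset(ref - pred),
        )
    return out


def read_reference_motifs(
    path: str | Path, source: str | None = None, length: int = 9
) -> list[ReferenceMotif]:
    """Read reference motifs from a TSV.

    Expected columns: ``allele, length, position, role, primary,
    secondary`` and optionally a leading ``source`` column (filtered with
    the ``source`` argument).  Rows with role ``anchor`` carry residue
    sets; positions absent from the file are non-anchors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"allele", "length", "position", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if source is not None:
        if "source" not in df.columns:
            raise ValueError(f"{path}: no 'source' column to filter on")
        df = df[df["source"] == source]
        if df.empty:
            raise ValueError(f"{path}: no rows with source {source!r}")

    motifs: dict[tuple[str, int], ReferenceMotif] = {}
    for _, row in df.iterrows():
        key = (row["allele"], int(row["length"]))
        ref = motifs.setdefault(
            key, ReferenceMotif(allele=key[0], length=key[1])
        )
        if row["role"].strip().lower() == "anchor":
            primary, _ = parse_residue_spec(row.get("primary", "") or "")
            secondary, _ = parse_residue_spec(row.get("secondary", "") or "")
            ref.residue_sets[int(row["position"])] = (primary, secondary)
    return list(motifs.values())
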