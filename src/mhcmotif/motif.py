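"""Motif derivation from a scoring matrix.

Three rule-based steps turn a 20 x L scoring matrix into a classical
binding motif:

1. **Spread factors.**  For each column, sf = max - min matrix value —
   the log10(IC50) fold-difference between the best and worst residue
   at that position.  A large spread means the position matters.
2. **Anchor calling.**  A position is an anchor when its spread clears
   both an absolute floor (``sf_abs``, default 1.0 = 10-fold) and a
   fraction of the largest spread in the matrix (``sf_rel``, default
   0.5).
3. **Residue classification.**  At anchors the column *maximum* (worst
   residue) is the reference; residues close to the column minimum
   (within ``delta_pref`` of the best) are preferred, those within
   ``delta_tol`` tolerated, the rest deleterious.  At non-anchors the
   column *median* is the reference and residues are preferred /
   deleterious when they sit ``delta_pref_nonanchor`` / ``delta_del``
   below / above it.

All rules use only within-column differences, so the motif is invariant
under adding a constant to any column (and in particular to the choice
of intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import ALPHABET, ScoringMatrix

PREFERRED = "preferred"
TOLERATED = "tolerated"
DELETERIOUS = "deleterious"
CLASSES = (PREFERRED, TOLERATED, DELETERIOUS)


@dataclass(frozen=True)
class MotifConfig:
    """Thresholds for anchor calling and residue classification.

    All deltas are in log10(IC50) units: 0.5 ~ 3-fold, 1.0 = 10-fold.
    """

    sf_abs: float = 1.0        # minimum spread for an anchor
    sf_rel: float = 0.5        # fraction of the max spread an anchor must reach
    delta_pref: float = 0.5    # anchors: within this of the best residue
    delta_tol: float = 1.0     # anchors: within this of the best residue
    delta_del: float = 0.5     # non-anchors: this far above the median
    delta_pref_nonanchor: float = 0.5  # non-anchors: this far below the median

    def __post_init__(self) -> None:
        for name in ("sf_abs", "sf_rel", "delta_pref", "delta_tol",
                     "delta_del", "delta_pref_nonanchor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.delta_tol < self.delta_pref:
            raise ValueError("delta_tol must be >= delta_pref")


@dataclass
class SpreadProfile:
    """Per-position spread factors (column max - column min)."""

    sf: np.ndarray

    def __post_init__(self) -> None:
        self.sf = np.asarray(self.sf, dtype=float)
        if np.any(self.sf < 0):
            raise ValueError("spread factors must be non-negative")

    def __len__(self) -> int:
        return len(self.sf)


@dataclass
class PositionClass:
    """Classification of all 20 residues at one peptide position."""

    position: int  # 1-based
    is_anchor: bool
    classes: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.classes) != set(ALPHABET):
            raise ValueError("classes must cover the 20 canonical residues exactly")
        bad = {c for c in self.classes.values() if c not in CLASSES}
        if bad:
            raise ValueError(f"unknown class label(s) {bad}")

    def residues(self, cls: str) -> set[str]:
        return {aa for aa, c in self.classes.items() if c == cls}


@dataclass
class Motif:
    """Anchors plus per-position residue preferences for one allele/length."""

    allele: str
    length: int
    positions: list[PositionClass]
    is_default: bool = False
    source_matrix: ScoringMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if [pc.position for pc in self.positions] != list(range(1, self.length + 1)):
            raise ValueError("positions must cover 1..L in order")

    @property
    def anchors(self) -> set[int]:
        return {pc.position for pc in self.positions if pc.is_anchor}

    def preferred(self, position: int) -> set[str]:
        return self.positions[position - 1].residues(PREFERRED)


def spread_factors(matrix: ScoringMatrix) -> SpreadProfile:
    """Column-wise max minus min of the scoring matrix."""
    return SpreadProfile(matrix.values.max(axis=0) - matrix.values.min(axis=0))


def identify_anchors(
    profile: SpreadProfile | np.ndarray, config: MotifConfig = MotifConfig()
) -> set[int]:
    """Anchor positions: sf >= sf_abs and sf >= sf_rel * max(sf).

    Both comparisons are closed (a spread sitting exactly on a threshold
    counts).  Returns 1-based positions; an all-zero profile yields the
    empty set.
    """
    sf = profile.sf if isinstance(profile, SpreadProfile) else np.asarray(profile, float)
    if len(sf) == 0:
        return set()
    cutoff = max(config.sf_abs, config.sf_rel * sf.max())
    return {p + 1 for p in range(len(sf)) if sf[p] >= cutoff}


def classify_anchor(column, config: MotifConfig = MotifConfig()) -> dict[str, str]:
    """Classify residues at an anchor position against the column maximum.

    With ref = max(column) and delta_r = ref - value_r (the best residue
    has delta = sf): preferred when delta_r >= sf - delta_pref, tolerated
    when sf - delta_tol <= delta_r < sf - delta_pref, else deleterious.
    Equivalently, by distance above the best (minimum) value.
    """
    col = np.asarray(column, dtype=float)
    if col.shape != (len(ALPHABET),):
        raise ValueError("column must be a 20-vector")
    sf = col.max() - col.min()
    if sf <= 0:
        raise ValueError("flat column: anchor classification undefined (sf = 0)")
    lo = col.min()
    out = {}
    for aa, v in zip(ALPHABET, col):
        if v <= lo + config.delta_pref:
            out[aa] = PREFERRED
        elif v <= lo + config.delta_tol:
            out[aa] = TOLERATED
        else:
            out[aa] = DELETERIOUS
    return out


def classify_nonanchor(column, config: MotifConfig = MotifConfig()) -> dict[str, str]:
    """Classify residues at a non-anchor position against the column median.

    For 20 values the median is the mean of the 10th and 11th order
    statistics.  Boundary ties go to the more informative class
    (closed >= comparisons).
    """
    col = np.asarray(column, dtype=float)
    if col.shape != (len(ALPHABET),):
        raise ValueError("column must be a 20-vector")
    m = float(np.median(col))
    out = {}
    for aa, v in zip(ALPHABET, col):
        if v - m >= config.delta_del:
            out[aa] = DELETERIOUS
        elif m - v >= config.delta_pref_nonanchor:
            out[aa] = PREFERRED
        else:
            out[aa] = TOLERATED
    return out


def build_motif(
    matrix: ScoringMatrix,
    config: MotifConfig = MotifConfig(),
    is_default: bool = False,
) -> Motif:
    """Derive the full motif from a scoring matrix (deterministic)."""
    anchors = identify_anchors(spread_factors(matrix), config)
    positions = []
    for p in range(1, matrix.length + 1):
        col = matrix.column(p)
        if p in anchors:
            classes = classify_anchor(col, config)
        else:
            classes = classify_nonanchor(col, config)
        positions.append(PositionClass(position=p, is_anchor=p in anchors, classes=classes))
    return Motif(
        allele=matrix.allele,
        length=matrix.length,
        positions=positions,
        is_default=is_default,
        source_matrix=matrix,
    )


class MotifCaller(BaseEstimator):
    """Configured motif-calling transformer over scoring matrices.

    Exposes the same thresholds as :class:`MotifConfig` through the
    scikit-learn ``get_params``/``set_params`` protocol so the calling
    stage can sit inside model-selection machinery.
    """

    def __init__(
        self,
        sf_abs: float = 1.0,
        sf_rel: float = 0.5,
        delta_pref: float = 0.5,
        delta_tol: float = 1.0,
        delta_del: float = 0.5,
        delta_pref_nonanchor: float = 0.5,
    ):
        self.sf_abs = sf_abs
        self.sf_rel = sf_rel
        self.delta_pref = delta_pref
        self.delta_tol = delta_tol
        self.delta_del = delta_del
        self.delta_pref_nonanchor = delta_pref_nonanchor

    def config(self) -> MotifConfig:
        return MotifConfig(**self.get_params())

    def transform(self, matrices, is_default: bool = False):
        """Build motifs for one ScoringMatrix or a sequence of them."""
        cfg = self.config()
        if isinstance(matrices, ScoringMatrix):
            return build_motif(matrices, cfg, is_default=is_default)
        return [build_motif(m, cfg) for m in matrices]
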