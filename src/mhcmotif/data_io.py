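"""Reading and writing binding data, scoring matrices and motif files.

Binding data arrive as TSV/CSV tables with columns ``peptide`` and
``ic50_nM``.  Scoring matrices use a self-describing plain-text format
(header line + 20 residue rows); motifs serialize to JSON.  All readers
validate aggressively and report rejected rows rather than silently
dropping them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    ALPHABET,
    BindingDataset,
    BindingRecord,
    DatasetSummary,
    EmptyDatasetError,
    FormatError,
    MatrixParseError,
    ScoringMatrix,
)

DEFAULT_BINDER_THRESHOLD = 500.0  # nM; field-standard IC50 cutoff for "binder"


@dataclass(frozen=True)
class RowIssue:
    """One rejected (or flagged) input row and the reason."""

    row: int  # 1-based data-row index (excluding the header)
    peptide: str
    reason: str


@dataclass
class ValidationReport:
    """Outcome of loading one binding-data file."""

    n_read: int = 0
    n_kept: int = 0
    rejected: list[RowIssue] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_binding_data(
    path: str | Path,
    allele: str,
    length: int,
    *,
    filter_length: bool = False,
    collapse_duplicates: bool = False,
) -> tuple[BindingDataset, ValidationReport]:
    """Load and validate a binding-affinity table for one allele.

    Parameters
    ----------
    path : str or Path
        Delimited table with header columns ``peptide`` and ``ic50_nM``
        (tab-separated unless the extension is ``.csv``).
    allele, length : str, int
        Identity of the dataset; rows whose peptide length differs from
        ``length`` are rejected and listed in the report (with
        ``filter_length=True`` they are dropped as expected filtering
        instead of flagged as errors — either way they never enter the
        dataset silently).
    collapse_duplicates : bool
        If True, repeat measurements of the same peptide are collapsed
        to a single record holding their geometric-mean IC50.  Default
        keeps them as independent rows.

    Returns
    -------
    (BindingDataset, ValidationReport)
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    missing = {"peptide", "ic50_nM"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")

    report = ValidationReport(n_read=len(df))
    records: list[BindingRecord] = []
    for i, (pep_raw, ic50_raw) in enumerate(
        zip(df["peptide"], df["ic50_nM"]), start=1
    ):
        pep = str(pep_raw).strip().upper()
        bad = [c for c in pep if c not in AA_INDEX]
        if not pep or bad:
            report.rejected.append(
                RowIssue(i, pep, f"non-canonical character(s) {''.join(bad) or '<empty>'}")
            )
            continue
        try:
            ic50 = float(ic50_raw)
        except (TypeError, ValueError):
            report.rejected.append(RowIssue(i, pep, f"non-numeric ic50 {ic50_raw!r}"))
            continue
        if not math.isfinite(ic50) or ic50 <= 0:
            report.rejected.append(RowIssue(i, pep, f"non-positive ic50 {ic50!r}"))
            continue
        if len(pep) != length:
            reason = (
                f"length {len(pep)} != {length}"
                + ("" if filter_length else " (use filter_length to drop such rows)")
            )
            report.rejected.append(RowIssue(i, pep, reason))
            continue
        records.append(BindingRecord(pep, ic50))

    seen: dict[str, list[float]] = {}
    for rec in records:
        seen.setdefault(rec.peptide, []).append(rec.ic50)
    report.duplicates = sorted(p for p, v in seen.items() if len(v) > 1)

    if collapse_duplicates:
        records = [
            BindingRecord(pep, float(np.exp(np.mean(np.log(vals)))))
            for pep, vals in seen.items()
        ]

    if not records:
        raise EmptyDatasetError(
            f"{path}: no valid records for {allele} length {length} "
            f"({report.n_rejected} rejected)"
        )
    report.n_kept = len(records)
    return BindingDataset(allele=allele, length=length, records=records), report


def write_binding_data(dataset: BindingDataset, path: str | Path) -> None:
    """Write a dataset back out as a TSV with the standard header."""
    path = Path(path)
    sep = _detect_sep(path)
    with open(path, "w") as fh:
        fh.write(f"peptide{sep}ic50_nM\n")
        for rec in dataset.records:
            fh.write(f"{rec.peptide}{sep}{rec.ic50:.6g}\n")


def summarize(
    dataset: BindingDataset, binder_threshold: float = DEFAULT_BINDER_THRESHOLD
) -> DatasetSummary:
    """Count total records and binders (IC50 strictly below the threshold)."""
    if binder_threshold <= 0:
        raise ValueError("binder_threshold must be positive")
    n_binders = int(sum(1 for r in dataset.records if r.ic50 < binder_threshold))
    return DatasetSummary(
        allele=dataset.allele,
        length=dataset.length,
        n_total=len(dataset.records),
        n_binders=n_binders,
    )


# ---------------------------------------------------------------------------
# scoring-matrix files


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    """Write a scoring matrix as self-describing plain text.

    Line 1: ``#allele <id> length <L> intercept <float>`` (plus optional
    ``lambda``/``cv_error`` fields); line 2: position labels ``P1..PL``;
    then 20 rows ``<residue> v1 ... vL`` in fixed ``ALPHABET`` order.
    Floats use %.17g so the round-trip is lossless.
    """
    L = matrix.length
    lines = []
    header = f"#allele {matrix.allele} length {L} intercept {matrix.intercept:.17g}"
    if matrix.lambda_used is not None:
        header += f" lambda {matrix.lambda_used:.17g}"
    if matrix.cv_error is not None:
        header += f" cv_error {matrix.cv_error:.17g}"
    lines.append(header)
    lines.append("pos\t" + "\t".join(f"P{p}" for p in range(1, L + 1)))
    for r, aa in enumerate(ALPHABET):
        lines.append(aa + "\t" + "\t".join(f"{v:.17g}" for v in matrix.values[r]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> ScoringMatrix:
    """Parse a scoring-matrix file written by :func:`write_matrix`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#allele "):
        raise MatrixParseError(f"{path}: line 1 must start with '#allele'")
    toks = lines[0][1:].split()
    meta: dict[str, str] = dict(zip(toks[::2], toks[1::2]))
    if "allele" not in meta or "length" not in meta or "intercept" not in meta:
        raise MatrixParseError(f"{path}: line 1 must name allele, length, intercept")
    try:
        L = int(meta["length"])
        intercept = float(meta["intercept"])
    except ValueError as exc:
        raise MatrixParseError(f"{path}: line 1: {exc}") from exc

    body = lines[1:]
    if body and body[0].split("\t", 1)[0] == "pos":
        body = body[1:]
    if len(body) != len(ALPHABET):
        raise MatrixParseError(
            f"{path}: expected {len(ALPHABET)} residue rows, found {len(body)}"
        )
    values = np.empty((len(ALPHABET), L))
    for r, (aa, line) in enumerate(zip(ALPHABET, body)):
        lineno = 2 + (1 if lines[1].startswith("pos") else 0) + r
        fields = line.split("\t")
        if fields[0] != aa:
            raise MatrixParseError(
                f"{path}: line {lineno}: expected residue {aa!r}, found {fields[0]!r}"
            )
        if len(fields) != L + 1:
            raise MatrixParseError(
                f"{path}: line {lineno}: expected {L} values, found {len(fields) - 1}"
            )
        try:
            values[r] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise MatrixParseError(f"{path}: line {lineno}: {exc}") from exc

    return ScoringMatrix(
        allele=meta["allele"],
        values=values,
        intercept=intercept,
        lambda_used=float(meta["lambda"]) if "lambda" in meta else None,
        cv_error=float(meta["cv_error"]) if "cv_error" in meta else None,
    )


# ---------------------------------------------------------------------------
# motif JSON


def motif_to_dict(motif) -> dict:
    return {
        "allele": motif.allele,
        "length": motif.length,
        "is_default": motif.is_default,
        "anchors": sorted(motif.anchors),
        "positions": [
            {
                "position": pc.position,
                "is_anchor": pc.is_anchor,
                "classes": dict(pc.classes),
            }
            for pc in motif.positions
        ],
    }


def write_motif(motif, path: str | Path) -> None:
    Path(path).write_text(json.dumps(motif_to_dict(motif), indent=2) + "\n")


def read_motif(path: str | Path):
    from .motif import Motif, PositionClass

    doc = json.loads(Path(path).read_text())
    positions = [
        PositionClass(
            position=p["position"],
            is_anchor=p["is_anchor"],
            classes=dict(p["classes"]),
        )
        for p in doc["positions"]
    ]
    return Motif(
        allele=doc["allele"],
        length=doc["length"],
        is_default=doc["is_default"],
        positions=positions,
    )
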