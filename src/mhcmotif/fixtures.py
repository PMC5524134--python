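"""Packaged reference fixtures.

Three small text files ship with the package:

* ``benchmark_counts.tsv`` — published per-allele dataset sizes (total
  records and binders) for the 18-allele 9-mer benchmark panel.
* ``benchmark_confusion.json`` — the published position-level anchor
  confusion matrix from comparing the automatic pipeline with expert
  assignments on that panel.
* ``reference_motifs.tsv`` — expert motif assignments (pool sequencing,
  combinatorial library, SYFPEITHI database) and the published
  automatically derived motifs, one anchor row per position.

These are evaluation references, not training data: the underlying
peptide-level measurements live in the IEDB and are not redistributed
here.
"""

from __future__ import annotations

import json
from importlib.resources import files

import pandas as pd

from .core import DatasetSummary
from .evaluate import ConfusionMatrix, ReferenceMotif, read_reference_motifs

REFERENCE_SOURCES = (
    "pool_sequencing",
    "combinatorial_library",
    "syfpeithi",
    "automatic",
)


def _data(name: str):
    return files("mhcmotif.data").joinpath(name)


def load_benchmark_counts() -> list[DatasetSummary]:
    """Per-allele (n_total, n_binders) for the 18-allele benchmark panel."""
    with _data("benchmark_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        DatasetSummary(
            allele=row.allele,
            length=int(row.length),
            n_total=int(row.all),
            n_binders=int(row.binders),
        )
        for row in df.itertuples()
    ]


def load_benchmark_confusion() -> ConfusionMatrix:
    """The published anchor confusion matrix for the benchmark panel."""
    doc = json.loads(_data("benchmark_confusion.json").read_text())
    return ConfusionMatrix(tp=doc["tp"], fp=doc["fp"], fn=doc["fn"], tn=doc["tn"])


def load_reference_motifs(source: str = "pool_sequencing") -> list[ReferenceMotif]:
    """Expert (or published automatic) motif assignments by source."""
    if source not in REFERENCE_SOURCES:
        raise ValueError(f"source must be one of {REFERENCE_SOURCES}, got {source!r}")
    with _data("reference_motifs.tsv").open() as fh:
        return read_reference_motifs(fh, source=source)
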