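"""End-to-end pipeline: data -> matrices -> motifs -> renders -> report.

``run_pipeline`` wires the stages for a batch of alleles: read and
summarize each per-length binding table, pick viable motif lengths,
train a scoring matrix per viable length, call the motif, and write the
matrix/motif/cartoon/colored-table files plus a tab manifest per
allele.  A failure in one allele is recorded and does not abort the
batch.  The run log captures the full configuration and an inventory of
outputs so reruns are auditable (and byte-identical under a fixed
config).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .data_io import (
    DEFAULT_BINDER_THRESHOLD,
    read_binding_data,
    summarize,
    write_matrix,
    write_motif,
)
from .evaluate import (
    UndefinedMetricError,
    anchor_confusion,
    read_reference_motifs,
    residue_agreement,
    sensitivity,
    specificity,
)
from .lengths import DEFAULT_LENGTH_THRESHOLD, select_lengths
from .motif import MotifConfig, build_motif
from .render import render_cartoon, render_colored_matrix, render_manifest
from .smm import DEFAULT_LAMBDAS, train


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with field defaults.

    Serializes to/from a flat ``key = value`` text file; the lambda grid
    is written as a comma-separated list.
    """

    binder_threshold: float = DEFAULT_BINDER_THRESHOLD
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    folds: int = 5
    seed: int = 1
    sf_abs: float = 1.0
    sf_rel: float = 0.5
    delta_pref: float = 0.5
    delta_tol: float = 1.0
    delta_del: float = 0.5
    delta_pref_nonanchor: float = 0.5
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD

    def __post_init__(self) -> None:
        if self.binder_threshold <= 0 or self.length_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("lambdas must be positive")

    def motif_config(self) -> MotifConfig:
        return MotifConfig(
            sf_abs=self.sf_abs,
            sf_rel=self.sf_rel,
            delta_pref=self.delta_pref,
            delta_tol=self.delta_tol,
            delta_del=self.delta_del,
            delta_pref_nonanchor=self.delta_pref_nonanchor,
        )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "lambdas":
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            if key == "lambdas":
                kwargs[key] = tuple(float(x) for x in raw.split(","))
            elif key in ("folds", "seed", "length_threshold"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class AlleleResult:
    """Per-allele pipeline products (in-memory handles plus file paths)."""

    allele: str
    selection: object = None
    matrices: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    error: str | None = None


def _safe_name(allele: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", allele)


def run_pipeline(
    data_files: list[tuple[str | Path, str, int]],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "motif_out",
    reference_path: str | Path | None = None,
    reference_source: str | None = None,
) -> dict:
    """Run the full motif pipeline over a batch of binding tables.

    Parameters
    ----------
    data_files : list of (path, allele, length)
        One binding table per allele/length combination.
    config : PipelineConfig
    out_dir : directory for all products (created if needed).
    reference_path, reference_source : optional expert-motif TSV (and a
        ``source`` filter value) to score the derived motifs against.

    Returns
    -------
    dict report: per-allele outcomes, optional evaluation block, and the
    path of the machine-readable run log written under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mcfg = config.motif_config()

    by_allele: dict[str, list[tuple[Path, int]]] = {}
    for path, allele, length in data_files:
        by_allele.setdefault(allele, []).append((Path(path), int(length)))

    results: dict[str, AlleleResult] = {}
    for allele in sorted(by_allele):
        res = AlleleResult(allele=allele)
        results[allele] = res
        adir = out_dir / _safe_name(allele)
        try:
            datasets, summaries = {}, []
            for path, length in sorted(by_allele[allele], key=lambda t: t[1]):
                ds, _report = read_binding_data(path, allele, length)
                datasets[length] = ds
                summaries.append(summarize(ds, config.binder_threshold))
            selection = select_lengths(summaries, config.length_threshold)
            res.selection = selection
            adir.mkdir(exist_ok=True)
            for length in selection.viable_lengths:
                matrix = train(
                    datasets[length],
                    lambdas=config.lambdas,
                    folds=config.folds,
                    seed=config.seed,
                )
                motif = build_motif(
                    matrix, mcfg, is_default=(length == selection.default_length)
                )
                res.matrices[length] = matrix
                res.motifs[length] = motif
                stem = adir / f"L{length}"
                write_matrix(matrix, stem.with_suffix(".matrix.txt"))
                write_motif(motif, stem.with_suffix(".motif.json"))
                render_cartoon(motif, stem.with_suffix(".cartoon.svg"))
                render_colored_matrix(matrix, motif, stem.with_suffix(".table.html"))
                res.files += [
                    str(stem.with_suffix(s).relative_to(out_dir))
                    for s in (".matrix.txt", ".motif.json", ".cartoon.svg", ".table.html")
                ]
            manifest = render_manifest(selection, list(res.motifs.values()))
            mpath = adir / "manifest.json"
            mpath.write_text(json.dumps(manifest, indent=2) + "\n")
            res.files.append(str(mpath.relative_to(out_dir)))
        except Exception as exc:  # per-allele isolation
            res.error = f"{type(exc).__name__}: {exc}"

    report: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "alleles": {
            a: {
                "error": r.error,
                "files": r.files,
                "default_length": r.selection.default_length if r.selection else None,
                "anchors": {
                    str(l): sorted(m.anchors) for l, m in sorted(r.motifs.items())
                },
            }
            for a, r in results.items()
        },
        "n_failed": sum(1 for r in results.values() if r.error),
    }

    if reference_path is not None:
        refs = read_reference_motifs(reference_path, source=reference_source)
        ref_keys = {(r.allele, r.length) for r in refs}
        predicted = [
            m
            for r in results.values()
            for m in r.motifs.values()
            if (m.allele, m.length) in ref_keys
        ]
        cm = anchor_confusion(predicted, refs)
        evaluation: dict = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "n_motifs_compared": len(predicted),
        }
        try:
            evaluation["sensitivity_pct"] = sensitivity(cm)
            evaluation["specificity_pct"] = specificity(cm)
        except UndefinedMetricError as exc:
            evaluation["metric_note"] = str(exc)
        ref_by_key = {(r.allele, r.length): r for r in refs}
        agreement = {}
        for m in predicted:
            per_pos = residue_agreement(m, ref_by_key[(m.allele, m.length)])
            agreement[f"{m.allele}/{m.length}"] = {
                str(pos): {
                    "jaccard": round(a.jaccard, 3),
                    "shared": "".join(sorted(a.shared)),
                    "predicted_only": "".join(sorted(a.predicted_only)),
                    "reference_only": "".join(sorted(a.reference_only)),
                }
                for pos, a in per_pos.items()
            }
        evaluation["residue_agreement"] = agreement
        report["evaluation"] = evaluation

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["run_log"] = str(log_path)
    return report
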