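"""Motif display: cartoon SVG, colored-matrix HTML, and a tab manifest.

The cartoon gives the classical qualitative view — one box per peptide
position, anchors visually distinct, residues listed by preference
class, no numbers.  The colored matrix is the quantitative companion: a
20 x L table of scoring-matrix values (2 decimals) with cell colors by
class.  Colors come from the Okabe-Ito palette, which stays
distinguishable under red-green color-vision deficiency.

Both renderers are pure functions of their inputs: no timestamps, no
randomness, so identical inputs yield byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core import ALPHABET, ScoringMatrix
from .lengths import LengthSelection
from .motif import DELETERIOUS, PREFERRED, TOLERATED, Motif


@dataclass(frozen=True)
class ColorScheme:
    """Class-to-color mapping; defaults are Okabe-Ito (colorblind-safe)."""

    preferred: str = "#009E73"    # bluish green
    tolerated: str = "#999999"    # grey
    deleterious: str = "#D55E00"  # vermillion
    anchor: str = "#0072B2"       # blue (anchor headers/boxes)

    def __post_init__(self) -> None:
        colors = (self.preferred, self.tolerated, self.deleterious, self.anchor)
        if len(set(colors)) != 4:
            raise ValueError("the four class colors must be distinct")

    def for_class(self, cls: str) -> str:
        return {
            PREFERRED: self.preferred,
            TOLERATED: self.tolerated,
            DELETERIOUS: self.deleterious,
        }[cls]


DEFAULT_SCHEME = ColorScheme()

_BOX_W = 96
_BOX_H = 190
_PAD = 8


def _wrap(residues: set[str], width: int = 8) -> list[str]:
    s = "".join(sorted(residues))
    return [s[i : i + width] for i in range(0, len(s), width)] or [""]


def render_cartoon(
    motif: Motif, out: str | Path | None = None, scheme: ColorScheme = DEFAULT_SCHEME
) -> str:
    """Render the classical cartoon motif as an SVG 1.1 string.

    One box per position; anchor boxes carry the anchor color and a
    thicker border; preferred residues are listed prominently, tolerated
    below, and deleterious residues inside a struck-through block.  No
    quantitative values appear.  Returns the SVG text (and writes it to
    ``out`` when given).
    """
    L = motif.length
    width = _PAD * 2 + L * (_BOX_W + _PAD)
    height = _BOX_H + 70
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">',
        f'<title>Binding motif {motif.allele} length {L}'
        f'{" (default)" if motif.is_default else ""}</title>',
        '<style>text{font-family:monospace;font-size:13px}'
        '.hdr{font-weight:bold;fill:#ffffff}.lbl{font-size:10px;fill:#444444}'
        '</style>',
        f'<text x="{_PAD}" y="18" style="font-size:15px;font-weight:bold">'
        f'{motif.allele} / {L}-mer{" *" if motif.is_default else ""}</text>',
    ]
    for pc in motif.positions:
        x = _PAD + (pc.position - 1) * (_BOX_W + _PAD)
        y = 30
        box_cls = "position anchor" if pc.is_anchor else "position"
        hdr_fill = scheme.anchor if pc.is_anchor else "#666666"
        stroke_w = 3 if pc.is_anchor else 1
        parts.append(
            f'<g class="{box_cls}" data-pos="{pc.position}">'
            f'<rect x="{x}" y="{y}" width="{_BOX_W}" height="{_BOX_H}" '
            f'fill="#ffffff" stroke="{hdr_fill}" stroke-width="{stroke_w}"/>'
            f'<rect x="{x}" y="{y}" width="{_BOX_W}" height="22" fill="{hdr_fill}"/>'
            f'<text class="hdr" x="{x + 6}" y="{y + 16}">'
            f'{pc.position}{" &#9875;" if pc.is_anchor else ""}</text>'
        )
        ty = y + 40
        for label, cls, color in (
            ("preferred", PREFERRED, scheme.preferred),
            ("tolerated", TOLERATED, scheme.tolerated),
            ("avoid", DELETERIOUS, scheme.deleterious),
        ):
            parts.append(f'<text class="lbl" x="{x + 6}" y="{ty}">{label}</text>')
            ty += 13
            deco = ' text-decoration="line-through"' if cls == DELETERIOUS else ""
            for line in _wrap(pc.residues(cls)):
                parts.append(
                    f'<text class="{cls}" data-pos="{pc.position}" '
                    f'fill="{color}"{deco} x="{x + 6}" y="{ty}">{line}</text>'
                )
                ty += 15
            ty += 4
        parts.append("</g>")
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if out is not None:
        Path(out).write_text(svg)
    return svg


def render_colored_matrix(
    matrix: ScoringMatrix,
    motif: Motif,
    out: str | Path | None = None,
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> str:
    """Render the scoring matrix as a self-contained HTML table.

    Each of the 20 x L cells shows its value to two decimals on a
    background colored by the residue's class; anchor columns are
    flagged in the header.  Returns the HTML text (and writes it to
    ``out`` when given).
    """
    if (matrix.allele, matrix.length) != (motif.allele, motif.length):
        raise ValueError("matrix and motif must share allele and length")
    L = matrix.length
    head = [
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8"/>',
        f"<title>Scoring matrix {matrix.allele} / {L}-mer</title>",
        "<style>"
        "table{border-collapse:collapse;font-family:monospace}"
        "td,th{border:1px solid #333;padding:3px 6px;text-align:right}"
        f"th.anchor{{background:{scheme.anchor};color:#fff}}"
        "td{color:#000}"
        "</style></head><body>",
        f"<h1>{matrix.allele} &mdash; {L}-mer scoring matrix "
        f"(log10 IC50 contributions)</h1>",
        "<table>",
    ]
    hdr = ["<tr><th></th>"]
    for pc in motif.positions:
        cls = ' class="anchor"' if pc.is_anchor else ""
        mark = " &#9875;" if pc.is_anchor else ""
        hdr.append(f"<th{cls}>P{pc.position}{mark}</th>")
    hdr.append("</tr>")
    rows = ["".join(hdr)]
    for r, aa in enumerate(ALPHABET):
        cells = [f"<tr><th>{aa}</th>"]
        for pc in motif.positions:
            cls = pc.classes[aa]
            color = scheme.for_class(cls)
            v = matrix.values[r, pc.position - 1]
            cells.append(
                f'<td class="{cls}" data-residue="{aa}" data-pos="{pc.position}" '
                f'style="background:{color}">{v:.2f}</td>'
            )
        cells.append("</tr>")
        rows.append("".join(cells))
    tail = [
        "</table>",
        f'<p>Colors: <span style="color:{scheme.preferred}">preferred</span>, '
        f'<span style="color:{scheme.tolerated}">tolerated</span>, '
        f'<span style="color:{scheme.deleterious}">deleterious</span>; '
        "anchor columns flagged in the header. Lower values bind better.</p>",
        "</body></html>",
    ]
    html = "\n".join(head + rows + tail) + "\n"
    if out is not None:
        Path(out).write_text(html)
    return html


def render_manifest(selection: LengthSelection, motifs: list[Motif]) -> dict:
    """Build the multi-length tab manifest (JSON-serializable).

    Tabs are ordered by ascending length; the default length's label is
    suffixed with ``*``.  Every viable length must have a motif.
    """
    by_length = {m.length: m for m in motifs}
    missing = [l for l in selection.viable_lengths if l not in by_length]
    if missing:
        raise ValueError(f"no motif supplied for viable length(s) {missing}")
    tabs = []
    for length, n_binders in selection.viable:
        is_default = length == selection.default_length
        tabs.append(
            {
                "length": length,
                "label": f"{length}*" if is_default else str(length),
                "is_default": is_default,
                "n_binders": n_binders,
                "anchors": sorted(by_length[length].anchors),
            }
        )
    return {"allele": selection.allele, "tabs": tabs}
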