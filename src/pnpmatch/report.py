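"""Match reports: machine-readable JSON and a static self-contained HTML page.

The report collects everything one run produces: run metadata, the
annotated and unannotated peaks with Da/ppm mass errors, the fragment
table with the edge cuts that generate each fragment, and — in
modification mode — the mass shift and its proposed placement. The HTML
page is static XHTML with inline SVG (annotated peaks sky blue,
unannotated grey), so it can be shared as a single file.
"""

from __future__ import annotations

from dataclasses import dataclass
from html import escape
from typing import Optional, Sequence
import json

from .annotation import Annotation, annotation_rate
from .chem import Molecule, monoisotopic_mass
from .fragmentation import Fragment, PNPGraph
from .modification import ModificationPlacement
from .spectra import Spectrum

SCHEMA_VERSION = "1"


def _r(x: float, nd: int = 6) -> float:
    return round(float(x), nd)


@dataclass
class MatchReport:
    """One compound–spectrum match, held as the JSON-ready dict."""

    data: dict

    @property
    def mode(self) -> str:
        return self.data["metadata"]["mode"]

    @property
    def annotation_rate(self) -> float:
        return self.data["annotation_rate"]

    @property
    def annotations(self) -> list[dict]:
        return self.data["annotations"]

    @property
    def modification(self) -> Optional[dict]:
        return self.data.get("modification")


def build_report(
    s: Spectrum,
    m: Molecule,
    g: PNPGraph,
    fragments: Sequence[Fragment],
    annotations: Sequence[Annotation],
    mode: str = "pnp",
    tolerance: float = 0.03,
    adduct: str = "H",
    charge: Optional[int] = None,
    delta_mass: Optional[float] = None,
    placement: Optional[ModificationPlacement] = None,
    residue_suggestions: Optional[Sequence[tuple[str, float]]] = None,
    tool_version: str = "0",
) -> MatchReport:
    """Assemble a :class:`MatchReport` from one run's pieces.

    All floats are rounded on the way in (masses to 6 decimals, ppm to 1),
    so serialization round-trips byte-identically.
    """
    annotated_idx = {a.peak_index for a in annotations}
    metadata = {
        "spectrum_file": s.source_file,
        "scan_id": s.scan_id,
        "compound_name": m.name,
        "compound_formula": m.formula(),
        "compound_mass_da": _r(monoisotopic_mass(m)),
        "precursor_mz": _r(s.precursor_mz),
        "charge": int(charge if charge is not None else s.charge),
        "adduct": adduct,
        "mode": mode,
        "tolerance_da": _r(tolerance),
    }
    ann_rows = [
        {
            "peak_index": a.peak_index,
            "peak_mz": _r(a.peak_mz),
            "intensity": _r(a.peak_intensity, 4),
            "fragment_index": a.ion.fragment.index,
            "fragment_vertices": sorted(a.ion.fragment.vertex_set),
            "hydrogen_adjustment": a.ion.hydrogen_adjustment,
            "charge": a.ion.charge,
            "theoretical_mz": _r(a.ion.theoretical_mz),
            "error_da": _r(a.error_da),
            "error_ppm": _r(a.error_ppm, 1),
            "alternative_count": a.alternative_count,
        }
        for a in annotations
    ]
    unann_rows = [
        {"peak_index": i, "mz": _r(mz), "intensity": _r(inten, 4)}
        for i, (mz, inten) in enumerate(s.peaks)
        if i not in annotated_idx
    ]
    frag_rows = [
        {
            "index": f.index,
            "vertices": sorted(f.vertex_set),
            "labels": [g.vertices[v].label for v in sorted(f.vertex_set)],
            "neutral_mass_da": _r(f.neutral_mass),
            "generating_cuts": [sorted(c) for c in f.generating_cuts],
        }
        for f in fragments
    ]
    data = {
        "schema_version": SCHEMA_VERSION,
        "tool": {"name": "pnpmatch", "version": tool_version},
        "metadata": metadata,
        "annotation_rate": _r(annotation_rate(annotations, s), 6),
        "annotations": ann_rows,
        "unannotated_peaks": unann_rows,
        "fragments": frag_rows,
        "vertices": [
            {"index": v.index, "label": v.label, "mass_da": _r(v.mass)}
            for v in g.vertices
        ],
    }
    if mode == "pnp-mod":
        if delta_mass is None or placement is None:
            raise ValueError("pnp-mod report requires delta_mass and placement")
        data["modification"] = {
            "delta_da": _r(delta_mass),
            "delta_display": f"{delta_mass:+.3f} Da",
            "vertex_index": placement.vertex_index,
            "vertex_label": g.vertices[placement.vertex_index].label,
            "score": placement.score,
            "per_vertex_scores": {
                str(k): v for k, v in sorted(placement.per_vertex_scores.items())
            },
            "tie_broken": placement.tie_broken,
            "unmodified": placement.unmodified,
            "residue_suggestions": [
                {"residue": name, "mass_da": _r(mass, 5)}
                for name, mass in (residue_suggestions or [])
            ],
        }
    return MatchReport(data)


def write_json(r: MatchReport) -> str:
    """Serialize the report with stable key order."""
    return json.dumps(r.data, indent=2, sort_keys=False) + "\n"


def read_json(text: str) -> MatchReport:
    """Inverse of :func:`write_json`."""
    return MatchReport(json.loads(text))


# ---------------------------------------------------------------------------
# HTML rendering


def _svg_spectrum(r: MatchReport, width=820, height=260) -> str:
    ann = {row["peak_index"]: row for row in r.data["annotations"]}
    peaks = [(row["peak_index"], row["peak_mz"], row["intensity"]) for row in r.data["annotations"]]
    peaks += [(row["peak_index"], row["mz"], row["intensity"]) for row in r.data["unannotated_peaks"]]
    if not peaks:
        return "<svg xmlns='http://www.w3.org/2000/svg' width='820' height='40'></svg>"
    max_mz = max(p[1] for p in peaks) * 1.05
    max_i = max(p[2] for p in peaks) or 1.0
    pad, base = 40, height - 30
    lines = []
    for idx, mz, inten in sorted(peaks, key=lambda p: p[1]):
        x = pad + mz / max_mz * (width - 2 * pad)
        y = base - (inten / max_i) * (base - 20)
        color = "#87ceeb" if idx in ann else "#999999"
        lines.append(
            f'<line x1="{x:.1f}" y1="{base}" x2="{x:.1f}" y2="{y:.1f}" '
            f'stroke="{color}" stroke-width="1.5"/>'
        )
    axis = (
        f'<line x1="{pad}" y1="{base}" x2="{width - pad}" y2="{base}" stroke="#333"/>'
        f'<text x="{width // 2}" y="{height - 6}" font-size="11" text-anchor="middle">m/z</text>'
        f'<text x="{width - pad}" y="{base + 14}" font-size="10" text-anchor="end">{max_mz:.0f}</text>'
    )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
        + "".join(lines) + axis + "</svg>"
    )


def _svg_error_plot(r: MatchReport, key: str, label: str, width=400, height=220) -> str:
    rows = r.data["annotations"]
    pad, mid = 45, height // 2
    if not rows:
        return (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
            f'<text x="{width // 2}" y="{mid}" font-size="11" text-anchor="middle">'
            f"no annotations</text></svg>"
        )
    max_mz = max(row["peak_mz"] for row in rows) * 1.05
    max_err = max(abs(row[key]) for row in rows) * 1.2 or 1.0
    pts = []
    for row in rows:
        x = pad + row["peak_mz"] / max_mz * (width - 2 * pad)
        y = mid - row[key] / max_err * (mid - 20)
        pts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3" fill="#4682b4"/>')
    frame = (
        f'<line x1="{pad}" y1="{mid}" x2="{width - pad}" y2="{mid}" stroke="#333"/>'
        f'<text x="{width // 2}" y="{height - 6}" font-size="11" text-anchor="middle">m/z</text>'
        f'<text x="12" y="{mid}" font-size="11">{escape(label)}</text>'
        f'<text x="{pad}" y="16" font-size="10">&#177;{max_err:.3g}</text>'
    )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
        + "".join(pts) + frame + "</svg>"
    )


def _table(headers: list[str], rows: list[list], cls: str) -> str:
    head = "".join(f"<th>{escape(str(h))}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{escape(str(c))}</td>" for c in row) + "</tr>"
        for row in rows
    )
    return f'<table class="{cls}"><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>'


def write_html(r: MatchReport) -> str:
    """Render the report as one self-contained static XHTML page."""
    d = r.data
    md = d["metadata"]
    meta_rows = [[k.replace("_", " "), v] for k, v in md.items()]
    n_ann = len(d["annotations"])
    banner = (
        f"<p class='banner'>{n_ann} annotated peaks "
        f"({d['annotation_rate']:.1%} of {n_ann + len(d['unannotated_peaks'])})</p>"
        if n_ann
        else "<p class='banner'>0 annotated peaks</p>"
    )
    ann_table = _table(
        ["peak m/z", "intensity", "fragment", "vertices", "δH", "z",
         "theoretical m/z", "error (Da)", "error (ppm)", "alternatives"],
        [
            [f"{a['peak_mz']:.4f}", f"{a['intensity']:.1f}", a["fragment_index"],
             "+".join(map(str, a["fragment_vertices"])), a["hydrogen_adjustment"],
             a["charge"], f"{a['theoretical_mz']:.4f}", f"{a['error_da']:+.4f}",
             f"{a['error_ppm']:+.1f}", a["alternative_count"]]
            for a in d["annotations"]
        ],
        "annotations",
    )
    frag_table = _table(
        ["fragment", "vertices", "composition", "neutral mass (Da)", "generating cuts"],
        [
            [f["index"], "+".join(map(str, f["vertices"])), " | ".join(f["labels"]),
             f"{f['neutral_mass_da']:.4f}",
             "; ".join("{" + ",".join(map(str, c)) + "}" for c in f["generating_cuts"])]
            for f in d["fragments"]
        ],
        "fragments",
    )
    mod_html = ""
    if d.get("modification"):
        mo = d["modification"]
        sugg = ", ".join(
            f"{s['residue']} ({s['mass_da']:.5f} Da)" for s in mo["residue_suggestions"]
        ) or "none"
        scores = ", ".join(f"v{k}: {v:g}" for k, v in mo["per_vertex_scores"].items())
        mod_html = (
            "<h2>Modification</h2>"
            f"<p>Mass shift <b>{escape(mo['delta_display'])}</b> placed on vertex "
            f"<b>{mo['vertex_index']}</b> ({escape(mo['vertex_label'])}), "
            f"score {mo['score']:g}"
            + (", tie broken by rule" if mo["tie_broken"] else "")
            + ".</p>"
            f"<p>Per-vertex scores: {escape(scores)}.</p>"
            f"<p>Residue suggestions for the shift: {escape(sugg)}.</p>"
        )
    style = (
        "body{font-family:sans-serif;margin:2em;max-width:960px}"
        "table{border-collapse:collapse;font-size:12px;margin:1em 0}"
        "td,th{border:1px solid #ccc;padding:3px 7px;text-align:right}"
        "th{background:#f0f4f8}.banner{font-weight:bold}"
    )
    html = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<html xmlns="http://www.w3.org/1999/xhtml"><head>'
        f"<title>pnpmatch report</title><style>{style}</style></head><body>"
        f"<h1>Compound&#8211;spectrum match report</h1>"
        f"<h2>Metadata</h2>{_table(['parameter', 'value'], meta_rows, 'meta')}"
        f"<h2>Spectrum</h2>{banner}{_svg_spectrum(r)}"
        f"<h2>Mass errors</h2>{_svg_error_plot(r, 'error_da', 'Da')}"
        f"{_svg_error_plot(r, 'error_ppm', 'ppm')}"
        f"{mod_html}"
        f"<h2>Annotated peaks</h2>{ann_table}"
        f"<h2>Fragments</h2>{frag_table}"
        "</body></html>\n"
    )
    return html
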