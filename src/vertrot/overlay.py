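"""SVG overlay of the measurement construction.

Draws the numbered construction over the landmarks the way it would be
pencilled on film: body outline (1), its diagonals (2), pedicle
perpendiculars (3), inter-pedicle quadrangle diagonals (4), the base
perpendicular through A (5), and the measured ray — line 6 (C to B, lumbar)
or line 7 (C to D, thoracic) — plus labelled points A, B, C (and D).

Built with the stdlib XML tree so the output is well-formed by construction.
SVG's y axis points down, so the y-up millimetre coordinates are negated.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import LandmarkSet, Point2D, RotationResult, concave_fallback

__all__ = ["render_overlay"]

_STYLE = {
    "outline": {"stroke": "#222222", "stroke-width": "0.4", "fill": "none"},
    "diag": {"stroke": "#888888", "stroke-width": "0.25", "fill": "none"},
    "perp": {"stroke": "#1f77b4", "stroke-width": "0.25", "fill": "none"},
    "axis": {"stroke": "#2ca02c", "stroke-width": "0.35", "fill": "none"},
    "ray": {"stroke": "#d62728", "stroke-width": "0.35", "fill": "none"},
}


def _sv(p: Point2D) -> tuple[float, float]:
    return float(p.x), -float(p.y)


def _line(root, a: Point2D, b: Point2D, style: str, label: str) -> None:
    x1, y1 = _sv(a)
    x2, y2 = _sv(b)
    attrs = {
        "x1": f"{x1:.4f}",
        "y1": f"{y1:.4f}",
        "x2": f"{x2:.4f}",
        "y2": f"{y2:.4f}",
        "class": label,
        **_STYLE[style],
    }
    ET.SubElement(root, "line", attrs)


def _dot(root, p: Point2D, name: str) -> None:
    x, y = _sv(p)
    ET.SubElement(
        root,
        "circle",
        {"cx": f"{x:.4f}", "cy": f"{y:.4f}", "r": "0.8", "fill": "#d62728",
         "class": f"point-{name}"},
    )
    txt = ET.SubElement(
        root,
        "text",
        {"x": f"{x + 1.2:.4f}", "y": f"{y - 1.2:.4f}", "font-size": "3",
         "fill": "#000000"},
    )
    txt.text = name


def render_overlay(
    landmarks: LandmarkSet, result: RotationResult, path: str | Path
) -> None:
    """Render the construction for one measured vertebra to an SVG file."""
    ls = concave_fallback(landmarks)
    quad = ls.body_quad

    pts = np.array(
        [tuple(p) for p in quad]
        + [tuple(result.A), tuple(result.B), tuple(result.C)]
        + ([tuple(result.D)] if result.D is not None else []),
        dtype=float,
    )
    margin = 6.0
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "viewBox": f"{x0:.2f} {-y1:.2f} {x1 - x0:.2f} {y1 - y0:.2f}",
            "width": f"{(x1 - x0) * 4:.0f}",
            "height": f"{(y1 - y0) * 4:.0f}",
        },
    )

    # 1: body outline
    for i in range(4):
        _line(svg, quad[i], quad[(i + 1) % 4], "outline", "step1-outline")
    # 2: body diagonals
    _line(svg, quad[0], quad[2], "diag", "step2-diagonal")
    _line(svg, quad[1], quad[3], "diag", "step2-diagonal")
    # 3+4: pedicle perpendiculars and the quadrangle diagonals they bound
    from .geometry import _base_frame, _edge_hit, _quad_diag_length  # noqa: PLC0415

    _, u, v = _base_frame(quad)
    max_dist = 2.0 * _quad_diag_length(quad)
    feet = []
    for p in (ls.pedicle_left_inner, ls.pedicle_right_inner):
        bot = _edge_hit(p.to_array(), v, quad[0], quad[1], max_dist)
        top = _edge_hit(p.to_array(), v, quad[3], quad[2], max_dist)
        feet.append((Point2D(*bot), Point2D(*top)))
        _line(svg, Point2D(*bot), Point2D(*top), "perp", "step3-pedicle-perpendicular")
    (bl, tl), (br, tr) = sorted(feet, key=lambda bt: float(bt[0].to_array() @ u))
    _line(svg, bl, tr, "diag", "step4-quadrangle-diagonal")
    _line(svg, br, tl, "diag", "step4-quadrangle-diagonal")
    # 5: base perpendicular through A (shown through the full body height)
    top_a = _edge_hit(result.C.to_array(), v, quad[3], quad[2], max_dist)
    _line(svg, result.C, Point2D(*top_a), "axis", "step5-axis")
    # 6 or 7: the measured ray
    if result.rule == "lumbar":
        _line(svg, result.C, result.B, "ray", "step6-ray")
    else:
        _line(svg, result.C, result.D, "ray", "step7-ray")

    for name, p in (("A", result.A), ("B", result.B), ("C", result.C)):
        _dot(svg, p, name)
    if result.D is not None:
        _dot(svg, result.D, "D")

    caption = ET.SubElement(
        svg,
        "text",
        {"x": f"{x0 + 2:.2f}", "y": f"{-y0 - 2:.2f}", "font-size": "3.5",
         "fill": "#000000", "class": "caption"},
    )
    flagtxt = f" [{', '.join(result.flags)}]" if result.flags else ""
    caption.text = (
        f"{ls.level} ({result.rule}): alpha = {result.alpha_deg:.2f} deg{flagtxt}"
    )

    ET.ElementTree(svg).write(str(path), xml_declaration=True, encoding="utf-8")
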