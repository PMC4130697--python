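"""Planar geometry of the graphical rotation measurement.

Axial vertebral rotation is read off an AP radiograph from two landmarks of a
single vertebra: the projected vertebral-body outline (a quadrilateral) and
the inner contours of the two pedicle shadows.  The construction is purely
planar:

1. the body centre ``A`` is the intersection of the body-quad diagonals;
2. perpendiculars to the body's *bottom edge* through each pedicle point cut
   the top and bottom edges into a second quadrangle whose diagonal
   intersection is the inter-pedicle centre ``B``;
3. ``C`` is the foot of the perpendicular from ``A`` on the bottom edge;
4. for thoracic vertebrae (and L5) a fourth point ``D`` halves the distance
   from ``B`` up to the top edge, landing at three quarters of the body
   height.

The rotation angle is the signed angle at ``C`` between the base
perpendicular through ``A`` and the ray ``C -> B`` (lumbar L1-L4 rule,
effective lever ``0.5 z``) or ``C -> D`` (thoracic/L5 rule, lever ``0.75 z``),
where ``z`` is the vertebral body height.  The lever ratios encode the
anatomical proportion between the pedicle rotation radius ``x`` and the body
height: rotation displaces the pedicle midpoint by ``d = x tan(alpha)``, so a
protractor reading against a leg of height ``k z ~= x`` returns ``alpha``.

Everything is expressed relative to the base edge, never the image axes, so
measurements are invariant under rigid motion and scaling of the film.
All coordinates are continuous millimetres, y-up.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    GeometryError,
    MissingLandmarkError,
    UnmeasurableError,
    ValidationError,
)

__all__ = [
    "Point2D",
    "LandmarkSet",
    "RotationResult",
    "THORACIC_LEVELS",
    "LUMBAR_LEVELS",
    "ALL_LEVELS",
    "rule_for_level",
    "ratio_k",
    "intersect_diagonals",
    "body_center_A",
    "pedicle_midpoint_B",
    "base_foot_C",
    "thoracic_point_D",
    "measure_rotation",
    "concave_fallback",
    "wedge_substitute",
    "substitute_body",
    "small_angle_error",
    "WARN_LIMIT_DEG",
]

# validity limit of the method: the concave pedicle shadow merges with the
# body contour at larger rotations, so results beyond it are flagged
WARN_LIMIT_DEG = 30.0

# diagonal intersection parameter must stay within this range of the segment
_PARAM_RANGE = 10.0
# perpendicular/edge intersections may lie at most this many quad diagonals
# from the edge segment before the geometry is declared degenerate
_EXTENSION_FACTOR = 2.0
_MIN_AREA_MM2 = 1e-9

THORACIC_LEVELS = tuple(f"Th{i}" for i in range(1, 13))
LUMBAR_LEVELS = ("L1", "L2", "L3", "L4", "L5")
ALL_LEVELS = THORACIC_LEVELS + LUMBAR_LEVELS
_LEVEL_LOOKUP = {lv.lower(): lv for lv in ALL_LEVELS}


def normalize_level(level: str) -> str:
    """Canonicalise a vertebral level tag (``'th6'`` -> ``'Th6'``)."""
    try:
        return _LEVEL_LOOKUP[str(level).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown vertebral level {level!r}; expected Th1-Th12 or L1-L5"
        ) from None


def rule_for_level(level: str) -> str:
    """Measurement rule for a level: ``'lumbar'`` for L1-L4, else ``'thoracic'``.

    L5, although anatomically lumbar, follows the thoracic construction.
    """
    return "lumbar" if normalize_level(level) in ("L1", "L2", "L3", "L4") else "thoracic"


def ratio_k(rule: str) -> float:
    """Lever ratio k of a rule: 0.5 (lumbar) or 0.75 (thoracic)."""
    if rule == "lumbar":
        return 0.5
    if rule == "thoracic":
        return 0.75
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class Point2D:
    """A planar point in millimetres, image frame (x right, y up)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinate ({self.x}, {self.y})")

    def __iter__(self):
        yield self.x
        yield self.y

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _pt(a) -> Point2D:
    return Point2D(float(a[0]), float(a[1]))


@dataclass(frozen=True)
class LandmarkSet:
    """Landmarks of one vertebra on an AP film.

    ``body_quad`` lists the projected vertebral-body corners in the fixed
    order bottom-left, bottom-right, top-right, top-left; the bottom edge
    (first two corners) is the reference edge of every perpendicular in the
    construction.  Pedicle points are the *inner* contour of each pedicle
    shadow by convention (outer/middle annotations are accepted — the
    geometry is identical, only the landmark semantics change).

    ``concave_pedicle_missing`` records that one pedicle shadow has merged
    with the body contour (concave side, typically beyond ~30 deg rotation);
    the flagged side's point is then reconstructed by :func:`concave_fallback`.
    ``substituted`` marks a body_quad replaced by a compromise
    rectangle/rhomboid over a wedged (structurally deformed) body.
    """

    level: str
    body_quad: tuple[Point2D, Point2D, Point2D, Point2D]
    pedicle_left_inner: Point2D | None
    pedicle_right_inner: Point2D | None
    concave_pedicle_missing: str = "none"  # none | left | right
    substituted: bool = False

    def __post_init__(self):
        object.__setattr__(self, "level", normalize_level(self.level))
        if len(self.body_quad) != 4:
            raise ValidationError("body_quad must have exactly 4 corners")
        object.__setattr__(self, "body_quad", tuple(self.body_quad))
        if self.concave_pedicle_missing not in ("none", "left", "right"):
            raise ValidationError(
                "concave_pedicle_missing must be 'none', 'left' or 'right'"
            )

    def validate(self) -> "LandmarkSet":
        """Check geometric invariants; return self for chaining."""
        q = np.array([tuple(p) for p in self.body_quad], dtype=float)
        if _polygon_area(q) <= 0:
            raise ValidationError(
                f"{self.level}: body_quad must wind counter-clockwise "
                "(bottom-left, bottom-right, top-right, top-left) with positive area"
            )
        if not _is_simple_quad(q):
            raise ValidationError(f"{self.level}: body_quad is self-intersecting")
        # pedicle points must sit in/near the body extent in the base frame;
        # generous slack because a merged pedicle shadow can project past the
        # silhouette edge at large rotation
        origin, u, v = _base_frame(self.body_quad)
        s = (q - origin) @ u
        t = (q - origin) @ v
        s_lo, s_hi = s.min(), s.max()
        t_lo, t_hi = t.min(), t.max()
        slack_s = 0.5 * (s_hi - s_lo)
        slack_t = 0.5 * (t_hi - t_lo)
        for name, p in (
            ("pedicle_left_inner", self.pedicle_left_inner),
            ("pedicle_right_inner", self.pedicle_right_inner),
        ):
            if p is None:
                side = name.split("_")[1]
                if self.concave_pedicle_missing != side:
                    raise MissingLandmarkError(
                        f"{self.level}: {name} is absent but "
                        f"concave_pedicle_missing={self.concave_pedicle_missing!r}"
                    )
                continue
            ps = (p.to_array() - origin) @ u
            pt_ = (p.to_array() - origin) @ v
            if not (s_lo - slack_s <= ps <= s_hi + slack_s) or not (
                t_lo - slack_t <= pt_ <= t_hi + slack_t
            ):
                raise ValidationError(
                    f"{self.level}: {name} lies far outside the body extent"
                )
        return self


@dataclass(frozen=True)
class RotationResult:
    """Outcome of one rotation measurement.

    ``alpha_deg`` is signed: positive when the inter-pedicle centre lies on
    the +x side of the body-centre perpendicular, in the base-edge frame.
    ``z_mm`` is the effective body height used by the rule, so that
    ``alpha = atan(d / (k z))`` holds exactly.  ``flags`` may contain
    ``"over-30deg"`` (beyond the method's validity limit), ``"substituted"``
    and ``"concave-fallback"``.
    """

    alpha_deg: float
    d_mm: float
    z_mm: float
    rule: str
    k: float
    A: Point2D
    B: Point2D
    C: Point2D
    D: Point2D | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def over_limit(self) -> bool:
        return "over-30deg" in self.flags


# ---------------------------------------------------------------------------
# frame and line primitives


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _segments_cross(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    return (orient(a, b, c) * orient(a, b, d) < 0) and (
        orient(c, d, a) * orient(c, d, b) < 0
    )


def _is_simple_quad(q: np.ndarray) -> bool:
    # only the two pairs of opposite edges can cross in a quad
    return not _segments_cross(q[0], q[1], q[2], q[3]) and not _segments_cross(
        q[1], q[2], q[3], q[0]
    )


def _base_frame(quad) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Origin at bottom-left corner, u along the bottom edge, v = interior
    normal (90 deg counter-clockwise from u)."""
    p0 = quad[0].to_array()
    p1 = quad[1].to_array()
    e = p1 - p0
    n = float(np.hypot(*e))
    if n < 1e-12:
        raise DegenerateGeometryError("bottom edge has zero length")
    u = e / n
    v = np.array([-u[1], u[0]])
    return p0, u, v


def _line_intersection(p, d, q, e) -> tuple[float, float, np.ndarray]:
    """Intersection of lines p + t d and q + s e; returns (t, s, point)."""
    denom = d[0] * e[1] - d[1] * e[0]
    scale = max(float(np.hypot(*d)) * float(np.hypot(*e)), 1e-300)
    if abs(denom) < 1e-12 * scale:
        raise DegenerateGeometryError("lines are (near-)parallel")
    r = q - p
    t = (r[0] * e[1] - r[1] * e[0]) / denom
    s = (r[0] * d[1] - r[1] * d[0]) / denom
    return t, s, p + t * d


def _quad_diag_length(quad) -> float:
    q = np.array([tuple(p) for p in quad], dtype=float)
    return max(
        float(np.hypot(*(q[2] - q[0]))),
        float(np.hypot(*(q[3] - q[1]))),
    )


def _edge_hit(point_on_line, line_dir, edge_a, edge_b, max_dist) -> np.ndarray:
    """Intersect a line with the infinite extension of edge (a, b); declare
    the geometry degenerate when the hit lies more than ``max_dist`` beyond
    the edge segment."""
    a = edge_a.to_array() if isinstance(edge_a, Point2D) else np.asarray(edge_a, float)
    b = edge_b.to_array() if isinstance(edge_b, Point2D) else np.asarray(edge_b, float)
    e = b - a
    elen = float(np.hypot(*e))
    _, s, hit = _line_intersection(point_on_line, line_dir, a, e)
    overshoot = max(-s, s - 1.0, 0.0) * elen
    if overshoot > max_dist:
        raise DegenerateGeometryError(
            "perpendicular misses the edge within the extension range"
        )
    return hit


# ---------------------------------------------------------------------------
# construction points


def intersect_diagonals(quad) -> Point2D:
    """Intersection of the diagonals (p0, p2) and (p1, p3) of a quadrilateral.

    Raises :class:`DegenerateGeometryError` for (near-)zero area, parallel
    diagonals, or an intersection far outside both segments.
    """
    quad = tuple(p if isinstance(p, Point2D) else _pt(p) for p in quad)
    if len(quad) != 4:
        raise ValidationError("quad must have exactly 4 corners")
    arr = np.array([tuple(p) for p in quad], dtype=float)
    if abs(_polygon_area(arr)) < _MIN_AREA_MM2:
        raise DegenerateGeometryError("quad area below tolerance")
    p0, p1, p2, p3 = (p.to_array() for p in quad)
    t, s, hit = _line_intersection(p0, p2 - p0, p1, p3 - p1)
    if not (-_PARAM_RANGE <= t <= _PARAM_RANGE and -_PARAM_RANGE <= s <= _PARAM_RANGE):
        raise DegenerateGeometryError("diagonal intersection parameter out of range")
    return _pt(hit)


def body_center_A(landmarks: LandmarkSet) -> Point2D:
    """Centre A of the vertebral body: diagonal intersection of the body quad."""
    return intersect_diagonals(landmarks.body_quad)


def pedicle_midpoint_B(landmarks: LandmarkSet) -> Point2D:
    """Inter-pedicle centre B.

    Base-edge perpendiculars through both pedicle inner points are cut by the
    top and bottom body edges into a quadrangle ("very similar to a
    rectangle"); B is the intersection of its diagonals.
    """
    if landmarks.pedicle_left_inner is None or landmarks.pedicle_right_inner is None:
        raise MissingLandmarkError(
            f"{landmarks.level}: both pedicle points are required "
            "(apply concave_fallback first)"
        )
    quad = landmarks.body_quad
    origin, u, v = _base_frame(quad)
    max_dist = _EXTENSION_FACTOR * _quad_diag_length(quad)

    feet = []
    for p in (landmarks.pedicle_left_inner, landmarks.pedicle_right_inner):
        pa = p.to_array()
        bot = _edge_hit(pa, v, quad[0], quad[1], max_dist)
        top = _edge_hit(pa, v, quad[3], quad[2], max_dist)
        feet.append((bot, top))
    # order left/right along the base so the quadrangle is simple
    feet.sort(key=lambda bt: float((bt[0] - origin) @ u))
    (bot_l, top_l), (bot_r, top_r) = feet
    return intersect_diagonals((_pt(bot_l), _pt(bot_r), _pt(top_r), _pt(top_l)))


def base_foot_C(A: Point2D, landmarks: LandmarkSet) -> Point2D:
    """Foot C of the perpendicular from A on the (extended) bottom edge."""
    origin, u, _ = _base_frame(landmarks.body_quad)
    a = A.to_array()
    return _pt(origin + float((a - origin) @ u) * u)


def thoracic_point_D(B: Point2D, landmarks: LandmarkSet) -> Point2D:
    """Point D: on the base perpendicular through B, halfway from B to the
    top edge — three quarters of the body height."""
    quad = landmarks.body_quad
    _, _, v = _base_frame(quad)
    max_dist = _EXTENSION_FACTOR * _quad_diag_length(quad)
    b = B.to_array()
    top = _edge_hit(b, v, quad[3], quad[2], max_dist)
    return _pt(b + 0.5 * (top - b))


def concave_fallback(landmarks: LandmarkSet) -> LandmarkSet:
    """Reconstruct a merged concave-side pedicle from the body contour.

    When one pedicle shadow has merged with the body outline the pedicle is
    assumed to coincide with the lateral body contour: the missing inner
    point is replaced by the point of the corresponding lateral edge at the
    same height fraction (between bottom and top edges) as the visible
    pedicle point.  With flag ``'none'`` the landmark set is returned
    unchanged.
    """
    side = landmarks.concave_pedicle_missing
    if side == "none":
        return landmarks
    visible = (
        landmarks.pedicle_right_inner if side == "left" else landmarks.pedicle_left_inner
    )
    if visible is None:
        raise UnmeasurableError(
            f"{landmarks.level}: both pedicle shadows unavailable — unmeasurable"
        )
    quad = landmarks.body_quad
    _, _, v = _base_frame(quad)
    max_dist = _EXTENSION_FACTOR * _quad_diag_length(quad)
    pa = visible.to_array()
    bot = _edge_hit(pa, v, quad[0], quad[1], max_dist)
    top = _edge_hit(pa, v, quad[3], quad[2], max_dist)
    span = float((top - bot) @ v)
    if abs(span) < 1e-12:
        raise DegenerateGeometryError("zero body height at visible pedicle")
    frac = float((pa - bot) @ v) / span
    # lateral edge of the missing side: bottom corner -> top corner
    if side == "left":
        lo, hi = quad[0], quad[3]
    else:
        lo, hi = quad[1], quad[2]
    repl = _pt(lo.to_array() + frac * (hi.to_array() - lo.to_array()))
    kwargs = {f"pedicle_{side}_inner": repl}
    return dataclasses.replace(landmarks, **kwargs)


def measure_rotation(landmarks: LandmarkSet) -> RotationResult:
    """Measure the axial rotation angle of one vertebra.

    Applies the concave-pedicle fallback if flagged, builds A, B, C (and D
    for the thoracic rule), and returns the signed angle between the base
    perpendicular through A and the ray C->B (lumbar) or C->D (thoracic).
    Results beyond 30 deg magnitude are returned but flagged ``"over-30deg"``.
    """
    flags: list[str] = []
    if landmarks.substituted:
        flags.append("substituted")
    if landmarks.concave_pedicle_missing != "none":
        landmarks = concave_fallback(landmarks)
        flags.append("concave-fallback")
    if landmarks.pedicle_left_inner is None or landmarks.pedicle_right_inner is None:
        raise MissingLandmarkError(
            f"{landmarks.level}: pedicle landmark missing and no "
            "concave_pedicle_missing flag set"
        )

    rule = rule_for_level(landmarks.level)
    k = ratio_k(rule)
    _, u, v = _base_frame(landmarks.body_quad)

    A = body_center_A(landmarks)
    B = pedicle_midpoint_B(landmarks)
    C = base_foot_C(A, landmarks)
    D = thoracic_point_D(B, landmarks) if rule == "thoracic" else None

    target = D if rule == "thoracic" else B
    vec = target.to_array() - C.to_array()
    d_signed = float(vec @ u)
    h = float(vec @ v)
    if h <= 0:
        raise GeometryError(
            f"{landmarks.level}: construction point at or below the base edge; "
            "rotation is not measurable (|alpha| would reach 90 deg)"
        )
    alpha = math.degrees(math.atan2(d_signed, h))
    if abs(alpha) > WARN_LIMIT_DEG:
        flags.append("over-30deg")
    return RotationResult(
        alpha_deg=alpha,
        d_mm=d_signed,
        z_mm=h / k,
        rule=rule,
        k=k,
        A=A,
        B=B,
        C=C,
        D=D,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# wedged-vertebra substitution


def wedge_substitute(
    contour,
    pedicle_suture_direction,
    *,
    tol_mm: float = 0.5,
) -> tuple[tuple[Point2D, Point2D, Point2D, Point2D], bool]:
    """Compromise rectangle over a wedged vertebral-body contour.

    A wedged (compression-deformed) body has unequal lateral heights and its
    diagonal centre drifts toward the wedge apex, biasing the measurement.
    The substitute is a parallelogram whose base is parallel to the pedicle
    suture line and whose height equals the *convex* (undeformed) side's
    height; the contour width is preserved, so the habitual height/width
    ratio of the level is kept.

    Returns ``(quad, ambiguous)`` where ``quad`` is (bottom-left,
    bottom-right, top-right, top-left) and ``ambiguous`` is True when the two
    lateral heights agree within ``tol_mm`` — the contour is then enclosed in
    its minimal-area bounding parallelogram (the suture-aligned bounding
    rectangle) and flagged.
    """
    pts = np.array([tuple(p) for p in contour], dtype=float)
    if pts.shape[0] < 4:
        raise ValidationError("contour needs at least 4 points")
    e = np.asarray(tuple(pedicle_suture_direction), dtype=float)
    n = float(np.hypot(*e))
    if n < 1e-12:
        raise ValidationError("pedicle_suture_direction must be a nonzero vector")
    u = e / n
    v = np.array([-u[1], u[0]])

    s = pts @ u
    t = pts @ v
    mid = 0.5 * (s.min() + s.max())
    left = t[s <= mid]
    right = t[s >= mid]
    h_left = float(left.max() - left.min()) if left.size else 0.0
    h_right = float(right.max() - right.min()) if right.size else 0.0

    t_base = float(t.min())
    if abs(h_left - h_right) <= tol_mm:
        height = float(t.max()) - t_base
        ambiguous = True
    else:
        height = max(h_left, h_right)  # convex side is the taller one
        ambiguous = False

    s_lo, s_hi = float(s.min()), float(s.max())
    corners = [
        (s_lo, t_base),
        (s_hi, t_base),
        (s_hi, t_base + height),
        (s_lo, t_base + height),
    ]
    quad = tuple(_pt(si * u + ti * v) for si, ti in corners)
    return quad, ambiguous


def substitute_body(landmarks: LandmarkSet, *, tol_mm: float = 0.5) -> LandmarkSet:
    """Replace a (possibly wedged) body quad by its compromise rectangle.

    The suture direction is taken from the line through the two pedicle
    points when both are present (the body base is assumed parallel to the
    pedicle suture), otherwise from the existing bottom edge.
    """
    if landmarks.pedicle_left_inner is not None and landmarks.pedicle_right_inner is not None:
        suture = (
            landmarks.pedicle_right_inner.to_array()
            - landmarks.pedicle_left_inner.to_array()
        )
        if float(np.hypot(*suture)) < 1e-9:
            _, suture, _ = _base_frame(landmarks.body_quad)
    else:
        _, suture, _ = _base_frame(landmarks.body_quad)
    quad, _ambiguous = wedge_substitute(landmarks.body_quad, suture, tol_mm=tol_mm)
    return dataclasses.replace(landmarks, body_quad=quad, substituted=True)


# ---------------------------------------------------------------------------
# small-angle linearisation error


def small_angle_error(alpha_deg: float) -> float:
    """Discrepancy of the linearised reading, in degrees.

    The pedicle offset is ``d = x tan(alpha)``; reading it linearly as
    ``d / x`` (valid for small angles, where ``tan a ~ a`` in radians)
    overestimates the angle by ``deg(tan(rad(alpha))) - alpha``.
    """
    if not 0.0 <= alpha_deg < 90.0:
        raise ValueError("alpha_deg must be in [0, 90)")
    return math.degrees(math.tan(math.radians(alpha_deg))) - alpha_deg
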