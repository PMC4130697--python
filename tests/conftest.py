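"""Shared helpers: hand-built landmark sets and a randomized-vertebra factory."""

from __future__ import annotations

import math

import numpy as np

from vertrot.geometry import ALL_LEVELS, LandmarkSet, Point2D


def rect_landmarks(
    level: str = "L2",
    width: float = 40.0,
    height: float = 30.0,
    ped_x=(-8.0, 8.0),
    ped_h_frac: float = 0.5,
    missing: str = "none",
    centered: bool = True,
) -> LandmarkSet:
    """Axis-aligned rectangular body with pedicle points at given x offsets."""
    x0 = -width / 2 if centered else 0.0
    quad = (
        Point2D(x0, 0.0),
        Point2D(x0 + width, 0.0),
        Point2D(x0 + width, height),
        Point2D(x0, height),
    )
    y = ped_h_frac * height
    return LandmarkSet(
        level=level,
        body_quad=quad,
        pedicle_left_inner=Point2D(min(ped_x), y),
        pedicle_right_inner=Point2D(max(ped_x), y),
        concave_pedicle_missing=missing,
    )


def random_landmark_set(rng: np.random.Generator) -> LandmarkSet:
    """A generic (non-degenerate, possibly rhomboid/trapezoid) vertebra in a
    random rigid pose, with pedicles strictly inside the body."""
    w = rng.uniform(25.0, 50.0)
    h_l = rng.uniform(18.0, 35.0)
    h_r = rng.uniform(18.0, 35.0)
    shear_l = rng.uniform(-4.0, 4.0)
    shear_r = rng.uniform(-4.0, 4.0)
    quad = [
        (0.0, 0.0),
        (w, 0.0),
        (w + shear_r, h_r),
        (shear_l, h_l),
    ]
    s_l = rng.uniform(0.15, 0.42) * w
    s_r = rng.uniform(0.58, 0.85) * w
    f_l = rng.uniform(0.3, 0.7)
    f_r = rng.uniform(0.3, 0.7)
    h_min = min(h_l, h_r)
    peds = [(s_l, f_l * h_min), (s_r, f_r * h_min)]

    theta = rng.uniform(0.0, 2.0 * math.pi)
    c, s = math.cos(theta), math.sin(theta)
    tx, ty = rng.uniform(-100.0, 100.0, size=2)

    def xf(p):
        x, y = p
        return Point2D(c * x - s * y + tx, s * x + c * y + ty)

    level = str(rng.choice(ALL_LEVELS))
    return LandmarkSet(
        level=level,
        body_quad=tuple(xf(p) for p in quad),
        pedicle_left_inner=xf(peds[0]),
        pedicle_right_inner=xf(peds[1]),
    )


def rigid_transform(ls: LandmarkSet, theta_rad: float, tx: float, ty: float) -> LandmarkSet:
    c, s = math.cos(theta_rad), math.sin(theta_rad)

    def xf(p):
        if p is None:
            return None
        return Point2D(c * p.x - s * p.y + tx, s * p.x + c * p.y + ty)

    return LandmarkSet(
        level=ls.level,
        body_quad=tuple(xf(p) for p in ls.body_quad),
        pedicle_left_inner=xf(ls.pedicle_left_inner),
        pedicle_right_inner=xf(ls.pedicle_right_inner),
        concave_pedicle_missing=ls.concave_pedicle_missing,
        substituted=ls.substituted,
    )


def scale_landmarks(ls: LandmarkSet, factor: float) -> LandmarkSet:
    def xf(p):
        return None if p is None else Point2D(p.x * factor, p.y * factor)

    return LandmarkSet(
        level=ls.level,
        body_quad=tuple(xf(p) for p in ls.body_quad),
        pedicle_left_inner=xf(ls.pedicle_left_inner),
        pedicle_right_inner=xf(ls.pedicle_right_inner),
        concave_pedicle_missing=ls.concave_pedicle_missing,
        substituted=ls.substituted,
    )


def mirror_landmarks(ls: LandmarkSet, axis_point: Point2D) -> LandmarkSet:
    """Reflect about the base-perpendicular through ``axis_point`` and relabel
    left/right so the result is again a valid landmark set."""
    from vertrot.geometry import _base_frame

    origin, u, _ = _base_frame(ls.body_quad)
    a = axis_point.to_array()

    def ref(p):
        if p is None:
            return None
        v = p.to_array()
        return Point2D(*(v - 2.0 * float((v - a) @ u) * u))

    bl, br, tr, tl = ls.body_quad
    swap = {"none": "none", "left": "right", "right": "left"}
    return LandmarkSet(
        level=ls.level,
        body_quad=(ref(br), ref(bl), ref(tl), ref(tr)),
        pedicle_left_inner=ref(ls.pedicle_right_inner),
        pedicle_right_inner=ref(ls.pedicle_left_inner),
        concave_pedicle_missing=swap[ls.concave_pedicle_missing],
        substituted=ls.substituted,
    )
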