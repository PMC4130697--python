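"""Digital analog of the vertebral rotation device.

A parametric 3-D vertebra (body width, height ``z``, pedicle rotation radius
``x``, inter-pedicle gap, optional endplate wedging) is projected to AP-film
landmarks at a known axial rotation.  The physical device held real human
vertebrae at defined rotations from 0 to 45 degrees in 3-degree steps; here
the projection is computed, so the defined angle is exact and noise enters
only through a configurable per-coordinate Gaussian jitter that emulates
rater landmarking error.

Two forward models are provided for the pedicle-midpoint offset:

* ``"tan"`` (default) — ``d = x tan(alpha)``, the relation the measurement
  construction inverts exactly;
* ``"sin"`` — ``d = x sin(alpha)``, what an orthographic projection of a
  point at radius ``x`` rotating about the body axis gives.

The discrepancy between the two is a property of the projection geometry,
not of the measurement, and is deliberately surfaced rather than hidden.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import (
    LandmarkSet,
    Point2D,
    normalize_level,
    ratio_k,
    rule_for_level,
)

__all__ = [
    "Vertebra3DModel",
    "SimulatedObservation",
    "THORACIC_XZ_RATIO",
    "LUMBAR_XZ_RATIO",
    "DEFAULT_ALPHAS_DEG",
    "make_vertebra",
    "criterion_exact_vertebra",
    "apply_wedge",
    "project_ap",
    "generate_series",
]

# anatomical ratio of pedicle rotation radius x = LED/2 + SCD/2 to posterior
# body height z = VBHp
THORACIC_XZ_RATIO = 1.21
LUMBAR_XZ_RATIO = 0.86

# the rotation device: 0 to 45 degrees in 3-degree increments
DEFAULT_ALPHAS_DEG: tuple[float, ...] = tuple(float(a) for a in range(0, 46, 3))

DEFAULT_VISIBILITY_LIMIT_DEG = 30.0

# nominal body dimensions in millimetres by level class
_DEFAULT_DIMS = {
    # (z_mm, width_mm, pedicle_gap_mm)
    "thoracic": (20.0, 30.0, 17.0),
    "L1-L4": (28.0, 42.0, 24.0),
    "L5": (26.0, 46.0, 28.0),
}


def _level_class(level: str) -> str:
    level = normalize_level(level)
    if level.startswith("Th"):
        return "thoracic"
    return "L5" if level == "L5" else "L1-L4"


def _xz_ratio(level: str) -> float:
    # L5 is anatomically lumbar although it is *measured* with the thoracic rule
    return THORACIC_XZ_RATIO if _level_class(level) == "thoracic" else LUMBAR_XZ_RATIO


@dataclass(frozen=True)
class Vertebra3DModel:
    """Parametric vertebra: the solid mounted on the rotation device.

    ``x_mm`` is the transverse-plane lever arm of the pedicle midpoint
    (half lower-endplate depth plus half spinal-canal depth); by default it
    follows the anatomical ratio x/z = 1.21 (thoracic) or 0.86 (lumbar).
    ``wedge_deg`` tilts the upper endplate, shortening the left side while
    preserving the convex (right) height — the structural deformity seen at
    the apex of severe scoliotic curves.
    """

    level: str
    z_mm: float
    width_mm: float
    x_mm: float
    pedicle_gap_mm: float
    wedge_deg: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "level", normalize_level(self.level))
        for name in ("z_mm", "width_mm", "x_mm", "pedicle_gap_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.wedge_deg < 30.0:
            raise ValidationError("wedge_deg must be in [0, 30)")
        if self.short_height_mm <= 0:
            raise ValidationError("wedge_deg too large for this width/height")

    @property
    def short_height_mm(self) -> float:
        """Height of the compressed (left) side after wedging."""
        return self.z_mm - self.width_mm * math.tan(math.radians(self.wedge_deg))


@dataclass(frozen=True)
class SimulatedObservation:
    """One simulated rater reading: landmarks at a known defined rotation."""

    defined_alpha_deg: float
    landmarks: LandmarkSet
    rater_id: int
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.defined_alpha_deg <= 45.0:
            raise ValidationError("defined_alpha_deg must be in [0, 45]")


def make_vertebra(level: str, **overrides) -> Vertebra3DModel:
    """Build a vertebra with level-appropriate default proportions.

    Any of ``z_mm``, ``width_mm``, ``x_mm``, ``pedicle_gap_mm``, ``wedge_deg``
    may be overridden; ``x_mm`` defaults to the anatomical ratio times the
    (possibly overridden) ``z_mm``.
    """
    level = normalize_level(level)
    z0, w0, g0 = _DEFAULT_DIMS[_level_class(level)]
    z = float(overrides.pop("z_mm", z0))
    fields = {
        "level": level,
        "z_mm": z,
        "width_mm": float(overrides.pop("width_mm", w0)),
        "x_mm": float(overrides.pop("x_mm", _xz_ratio(level) * z)),
        "pedicle_gap_mm": float(overrides.pop("pedicle_gap_mm", g0)),
        "wedge_deg": float(overrides.pop("wedge_deg", 0.0)),
    }
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return Vertebra3DModel(**fields)


def criterion_exact_vertebra(level: str, **overrides) -> Vertebra3DModel:
    """Phantom whose radius satisfies the measurement criterion exactly,
    x = k z (k = 0.75 thoracic/L5, 0.5 L1-L4), so the tan-model projection is
    inverted without bias."""
    v = make_vertebra(level, **overrides)
    k = ratio_k(rule_for_level(level))
    return dataclasses.replace(v, x_mm=k * v.z_mm)


def apply_wedge(vertebra: Vertebra3DModel, wedge_deg: float) -> Vertebra3DModel:
    """Tilt the upper endplate by ``wedge_deg`` (convex height preserved)."""
    return dataclasses.replace(vertebra, wedge_deg=float(wedge_deg))


def project_ap(
    vertebra: Vertebra3DModel,
    alpha_deg: float,
    forward_model: str = "tan",
    *,
    pedicle_visibility_limit_deg: float | None = DEFAULT_VISIBILITY_LIMIT_DEG,
) -> LandmarkSet:
    """Project the vertebra to AP landmarks at axial rotation ``alpha_deg``.

    The body silhouette keeps its width under rotation (the projected width
    changes only slightly in practice); its height is ``z`` on the convex
    side and ``short_height_mm`` on the wedged side.  Both pedicle inner
    points start symmetric about the body midline and shift laterally by
    ``d = x tan(alpha)`` or ``d = x sin(alpha)``.

    Beyond ``pedicle_visibility_limit_deg`` the concave-side pedicle shadow
    is merged with the body contour: its stored point is clamped to the
    silhouette edge and the landmark set is flagged so measurement goes
    through the contour fallback.  Pass ``None`` to keep both true pedicle
    positions visible at every angle (the rotation-device setting).
    """
    a = float(alpha_deg)
    rad = math.radians(a)
    if forward_model == "tan":
        if abs(a) >= 90.0:
            raise ValidationError("tan forward model requires |alpha| < 90 deg")
        d = vertebra.x_mm * math.tan(rad)
    elif forward_model == "sin":
        d = vertebra.x_mm * math.sin(rad)
    else:
        raise ValidationError(f"unknown forward_model {forward_model!r}")

    w = vertebra.width_mm
    h_left = vertebra.short_height_mm
    h_right = vertebra.z_mm
    quad = (
        Point2D(-w / 2, 0.0),
        Point2D(w / 2, 0.0),
        Point2D(w / 2, h_right),
        Point2D(-w / 2, h_left),
    )
    # pedicle shadows sit mid-body; parallel to the base, per the suture assumption
    y_p = 0.5 * min(h_left, h_right)
    g = vertebra.pedicle_gap_mm
    left = Point2D(-g / 2 + d, y_p)
    right = Point2D(g / 2 + d, y_p)

    missing = "none"
    limit = pedicle_visibility_limit_deg
    if limit is not None and abs(a) > limit:
        # the concave-side pedicle (the one drifting toward the silhouette
        # edge) merges with the body contour
        missing = "right" if a >= 0 else "left"
        if missing == "right":
            right = Point2D(min(right.x, w / 2), y_p)
        else:
            left = Point2D(max(left.x, -w / 2), y_p)

    return LandmarkSet(
        level=vertebra.level,
        body_quad=quad,
        pedicle_left_inner=left,
        pedicle_right_inner=right,
        concave_pedicle_missing=missing,
    )


def _rater_rng(seed: int, rater_id: int, angle_index: int) -> np.random.Generator:
    """Deterministic per-record stream: SeedSequence(seed) spawned by
    (rater_id, angle_index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(rater_id), int(angle_index)))
    )


def _jitter(ls: LandmarkSet, rng: np.random.Generator, sd: float) -> LandmarkSet:
    """Add iid Gaussian jitter (mm) to every landmark coordinate.

    Standard-normal draws are made in a fixed order and scaled by ``sd``, so
    the same seed yields perfectly correlated perturbations across noise
    levels (and the sd=0 set is bit-identical to the clean one).
    """
    draws = rng.standard_normal(12) * sd
    quad = tuple(
        Point2D(p.x + draws[2 * i], p.y + draws[2 * i + 1])
        for i, p in enumerate(ls.body_quad)
    )
    ped = []
    for j, p in enumerate((ls.pedicle_left_inner, ls.pedicle_right_inner)):
        if p is None:
            ped.append(None)
        else:
            ped.append(Point2D(p.x + draws[8 + 2 * j], p.y + draws[9 + 2 * j]))
    return dataclasses.replace(
        ls, body_quad=quad, pedicle_left_inner=ped[0], pedicle_right_inner=ped[1]
    )


def generate_series(
    vertebra: Vertebra3DModel,
    alphas_deg=DEFAULT_ALPHAS_DEG,
    n_raters: int = 1,
    noise_sd_mm: float = 0.0,
    seed: int = 0,
    forward_model: str = "tan",
    *,
    pedicle_visibility_limit_deg: float | None = DEFAULT_VISIBILITY_LIMIT_DEG,
) -> list[SimulatedObservation]:
    """One observation per (angle, rater) over the rotation-device series.

    Rater noise is an independent Gaussian perturbation of each landmark
    coordinate, seeded deterministically from ``(seed, rater_id,
    angle_index)`` so any record can be regenerated in isolation.
    """
    if n_raters < 1:
        raise ValidationError("n_raters must be >= 1")
    if noise_sd_mm < 0:
        raise ValidationError("noise_sd_mm must be >= 0")
    alphas = [float(a) for a in alphas_deg]
    out: list[SimulatedObservation] = []
    for rater in range(n_raters):
        for idx, a in enumerate(alphas):
            clean = project_ap(
                vertebra,
                a,
                forward_model,
                pedicle_visibility_limit_deg=pedicle_visibility_limit_deg,
            )
            rng = _rater_rng(seed, rater, idx)
            noisy = _jitter(clean, rng, noise_sd_mm)
            out.append(
                SimulatedObservation(
                    defined_alpha_deg=a,
                    landmarks=noisy,
                    rater_id=rater,
                    seed=int(seed),
                )
            )
    return out
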