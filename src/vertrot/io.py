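"""Landmark / config file reading and result-table writing.

Landmark files are YAML with a versioned schema, one document per
radiograph::

    format: vertrot-landmarks
    version: 1
    frame: y-up            # or y-down (annotation tools' pixel frame)
    pixel_spacing_mm: 1.0
    vertebrae:
      - level: L2
        body_quad: [[-21.0, 0.0], [21.0, 0.0], [21.0, 28.0], [-21.0, 28.0]]
        pedicle_left_inner: [-12.0, 14.0]
        pedicle_right_inner: [12.0, 14.0]
        concave_pedicle_missing: none
        substituted: false

Corners are listed bottom-left, bottom-right, top-right, top-left *in the
anatomical sense* regardless of frame.  In a ``y-down`` file the y axis is
negated on read and ``pixel_spacing_mm`` converts pixel units to
millimetres, so the in-memory representation is always millimetres, y-up.
Unknown fields are rejected rather than ignored: a silently dropped flag
could change a clinical reading.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ParseError, ValidationError
from .geometry import LandmarkSet, Point2D

__all__ = [
    "LANDMARK_FORMAT",
    "SCHEMA_VERSION",
    "read_landmarks",
    "write_landmarks",
    "read_sim_config",
    "write_results",
    "config_hash",
]

LANDMARK_FORMAT = "vertrot-landmarks"
SIMCONFIG_FORMAT = "vertrot-simconfig"
SCHEMA_VERSION = 1

_VERTEBRA_KEYS = {
    "level",
    "body_quad",
    "pedicle_left_inner",
    "pedicle_right_inner",
    "concave_pedicle_missing",
    "substituted",
}
_REQUIRED_VERTEBRA_KEYS = {
    "level",
    "body_quad",
    "pedicle_left_inner",
    "pedicle_right_inner",
}
_TOP_KEYS = {"format", "version", "frame", "pixel_spacing_mm", "vertebrae"}


def _load_yaml(path: str | Path) -> Any:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else None
        raise ParseError(f"{path}: {exc}", line=line) from exc


def _check_keys(mapping: dict, allowed: set, required: set, what: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParseError(f"{what}: unknown field(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ParseError(f"{what}: missing field(s) {sorted(missing)}")


def _point(value, what: str, spacing: float, flip: bool) -> Point2D | None:
    if value is None:
        return None
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ParseError(f"{what}: expected [x, y], got {value!r}")
    try:
        x, y = float(value[0]), float(value[1])
    except (TypeError, ValueError):
        raise ParseError(f"{what}: non-numeric coordinate {value!r}") from None
    if flip:
        y = -y
    return Point2D(x * spacing, y * spacing)


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read and validate a landmark file; returns millimetre, y-up landmarks."""
    doc = _load_yaml(path)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    _check_keys(doc, _TOP_KEYS, {"format", "version", "vertebrae"}, str(path))
    if doc["format"] != LANDMARK_FORMAT:
        raise ParseError(f"{path}: format must be {LANDMARK_FORMAT!r}")
    if doc["version"] != SCHEMA_VERSION:
        raise ParseError(f"{path}: unsupported schema version {doc['version']!r}")
    frame = doc.get("frame", "y-up")
    if frame not in ("y-up", "y-down"):
        raise ParseError(f"{path}: frame must be 'y-up' or 'y-down'")
    spacing = float(doc.get("pixel_spacing_mm", 1.0))
    if spacing <= 0:
        raise ParseError(f"{path}: pixel_spacing_mm must be positive")
    flip = frame == "y-down"

    records = doc["vertebrae"]
    if not isinstance(records, list) or not records:
        raise ParseError(f"{path}: 'vertebrae' must be a non-empty list")

    out = []
    for i, rec in enumerate(records):
        what = f"{path}: vertebra #{i + 1}"
        if not isinstance(rec, dict):
            raise ParseError(f"{what}: expected a mapping")
        _check_keys(rec, _VERTEBRA_KEYS, _REQUIRED_VERTEBRA_KEYS, what)
        what = f"{what} ({rec.get('level')})"
        quad_raw = rec["body_quad"]
        if not isinstance(quad_raw, list) or len(quad_raw) != 4:
            raise ParseError(f"{what}: body_quad must list 4 corner points")
        quad = tuple(
            _point(p, f"{what} body_quad[{j}]", spacing, flip)
            for j, p in enumerate(quad_raw)
        )
        try:
            ls = LandmarkSet(
                level=rec["level"],
                body_quad=quad,
                pedicle_left_inner=_point(
                    rec["pedicle_left_inner"], f"{what} pedicle_left_inner", spacing, flip
                ),
                pedicle_right_inner=_point(
                    rec["pedicle_right_inner"], f"{what} pedicle_right_inner", spacing, flip
                ),
                concave_pedicle_missing=rec.get("concave_pedicle_missing", "none"),
                substituted=bool(rec.get("substituted", False)),
            ).validate()
        except ValidationError as exc:
            raise ValidationError(f"{what}: {exc}") from exc
        out.append(ls)
    return out


def write_landmarks(path: str | Path, landmark_sets: list[LandmarkSet]) -> None:
    """Write landmark sets as a y-up millimetre landmark file (round-trips
    through :func:`read_landmarks` exactly)."""

    def point(p: Point2D | None):
        return None if p is None else [float(p.x), float(p.y)]

    doc = {
        "format": LANDMARK_FORMAT,
        "version": SCHEMA_VERSION,
        "frame": "y-up",
        "pixel_spacing_mm": 1.0,
        "vertebrae": [
            {
                "level": ls.level,
                "body_quad": [point(p) for p in ls.body_quad],
                "pedicle_left_inner": point(ls.pedicle_left_inner),
                "pedicle_right_inner": point(ls.pedicle_right_inner),
                "concave_pedicle_missing": ls.concave_pedicle_missing,
                "substituted": ls.substituted,
            }
            for ls in landmark_sets
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# simulation / validation config

_SIM_KEYS = {
    "format",
    "version",
    "levels",
    "criterion_exact",
    "forward_model",
    "alphas_deg",
    "n_raters",
    "noise_sd_mm",
    "seed",
    "pedicle_visibility_limit_deg",
    "wedge_deg",
}


def read_sim_config(path: str | Path) -> dict:
    """Read a simulation/validation config file into a plain dict of
    keyword arguments (defaults filled by the consumers)."""
    doc = _load_yaml(path)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    _check_keys(doc, _SIM_KEYS, {"format", "version", "levels"}, str(path))
    if doc["format"] != SIMCONFIG_FORMAT:
        raise ParseError(f"{path}: format must be {SIMCONFIG_FORMAT!r}")
    if doc["version"] != SCHEMA_VERSION:
        raise ParseError(f"{path}: unsupported schema version {doc['version']!r}")
    levels = doc["levels"]
    if isinstance(levels, str):
        levels = [levels]
    if not isinstance(levels, list) or not levels:
        raise ParseError(f"{path}: 'levels' must be a level or non-empty list")
    cfg = {k: v for k, v in doc.items() if k not in ("format", "version")}
    cfg["levels"] = [str(lv) for lv in levels]
    return cfg


# ---------------------------------------------------------------------------
# result tables


def config_hash(config: dict) -> str:
    """Short stable hash of a config mapping (provenance stamp)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    path: str | Path,
    table: pd.DataFrame,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a result table as CSV with a provenance header.

    The header records tool version, config hash and seed; no timestamps, so
    reruns with the same config are byte-identical.
    """
    header = [f"# vertrot {__version__}"]
    if config is not None:
        header.append(f"# config_hash {config_hash(config)}")
    header.append(f"# seed {seed if seed is not None else 'none'}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        table.to_csv(fh, index=False)
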