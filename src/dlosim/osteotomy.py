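"""Wedge-osteotomy engine: cut/hinge placement and rigid fragment rotation.

Both opening- and closing-wedge osteotomies are modelled as a pure
rotation of the distal fragment about a cortical hinge point: opening a
wedge of angle theta on one cortex is the same rigid motion as closing a
resected wedge of theta on the other, so a single signed correction
angle (positive = valgus-producing) covers all four techniques.

Cut placement follows the planning protocol:

* DFO (femur): transverse cut 40 mm proximal to the reference epicondyle
  (lateral epicondyle for the lateral closing wedge, medial for the
  medial opening wedge); hinge on the opposite supracondylar cortex,
  inset a few millimetres from the cortex line.
* MOWHTO: transverse cut 35 mm distal to the medial tibial plateau; a
  5 mm lateral bone bridge (hinge) is left inside the lateral cortex.
* LCWHTO (hybrid closing wedge): cut from the lateral cortex 40 mm
  distal to the lateral plateau to the inflection point of the medial
  tibial cortex; the hinge divides the cut 3:1 from the lateral point.

Fragment membership is decided by y-comparison against the hinge level
(limbs are near-vertical in the canonical frame); a landmark lying on
the cut level within a small epsilon is an error.  Correction angles are
found by bracketed bisection on [0, 25] deg: the measured mLDFA (resp.
WBL ratio) is strictly monotone in the correction over the bracket, so
the root is unique.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .config import StudyConfig
from .geometry import (
    LimbGeometry,
    ValidationError,
    measure_mldfa,
    measure_wbl_ratio,
)

__all__ = [
    "OsteotomySpec",
    "InfeasibleGeometryError",
    "place_dfo_cut",
    "place_hto_cut",
    "apply_wedge",
    "solve_dfo_angle",
    "solve_hto_angle",
]

_DEFAULT = StudyConfig()


class InfeasibleGeometryError(ValidationError):
    """No correction angle inside the solver bracket reaches the target."""


@dataclass(frozen=True)
class OsteotomySpec:
    """One planned osteotomy.

    ``correction_deg`` is the signed wedge angle (positive =
    valgus-producing rotation of the distal fragment); ``None`` until a
    solver sets it.  ``cut_entry`` is the cortical entry point of the
    cut and ``cut_exit`` its far end (for transverse cuts, the opposite
    cortex at the same level; for the hybrid closing-wedge tibial cut,
    the medial cortical inflection point).
    """

    level: str                      # "femur" | "tibia"
    technique: str                  # "medial_open" | "lateral_closed"
    cut_entry: np.ndarray
    cut_exit: np.ndarray
    hinge: np.ndarray
    correction_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.level not in ("femur", "tibia"):
            raise ValidationError(f"unknown osteotomy level {self.level!r}")
        if self.technique not in ("medial_open", "lateral_closed"):
            raise ValidationError(f"unknown technique {self.technique!r}")
        for name in ("cut_entry", "cut_exit", "hinge"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        # Opening wedges hinge on the far (lateral-of-entry) cortex and
        # closing wedges on the near-axis medial side of the cut.
        if self.technique == "medial_open" and not self.hinge[0] < self.cut_entry[0]:
            raise ValidationError("medial_open requires the hinge lateral to the cut entry")
        if self.technique == "lateral_closed" and not self.hinge[0] > self.cut_entry[0]:
            raise ValidationError("lateral_closed requires the hinge medial to the cut entry")
        if self.correction_deg is not None and not abs(self.correction_deg) < 30.0:
            raise ValidationError("|correction_deg| must be < 30")

    def with_correction(self, correction_deg: float) -> "OsteotomySpec":
        return replace(self, correction_deg=float(correction_deg))

    def to_json_dict(self) -> dict:
        return {
            "level": self.level,
            "technique": self.technique,
            "cut_entry": [float(v) for v in self.cut_entry],
            "cut_exit": [float(v) for v in self.cut_exit],
            "hinge": [float(v) for v in self.hinge],
            "correction_deg": None if self.correction_deg is None else float(self.correction_deg),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)

    @classmethod
    def from_json_dict(cls, d: dict) -> "OsteotomySpec":
        return cls(
            level=d["level"],
            technique=d["technique"],
            cut_entry=d["cut_entry"],
            cut_exit=d["cut_exit"],
            hinge=d["hinge"],
            correction_deg=d.get("correction_deg"),
        )


# ---------------------------------------------------------------------------
# cut placement


def _line_at_y(point: np.ndarray, direction: np.ndarray, y: float) -> np.ndarray:
    """Point on the line ``point + t * direction`` with the given y-coordinate."""
    if abs(direction[1]) < 1e-9:
        raise ValidationError("cortex line is horizontal; cannot intersect a transverse level")
    t = (y - point[1]) / direction[1]
    return point + t * direction


def _toward(a_x: float, b_x: float) -> float:
    """Unit horizontal sign from a toward b."""
    return 1.0 if b_x > a_x else -1.0


def place_dfo_cut(
    g: LimbGeometry, technique: str, config: StudyConfig = _DEFAULT
) -> OsteotomySpec:
    """Place the distal femoral cut and hinge (correction angle unset).

    The transverse cut lies ``dfo_cut_offset_mm`` (40 mm) proximal to the
    reference epicondyle of the chosen technique.  Entry is on the
    technique's cortex; the hinge sits on the opposite supracondylar
    cortex line, inset ``hinge_inset_femur_mm`` toward the entry along
    the cut.
    """
    axis_dir = g.notch - g.hip_center
    if technique == "lateral_closed":
        y_cut = float(g.epicondyle_lateral[1]) + config.dfo_cut_offset_mm
        entry_cortex, hinge_cortex = g.condyle_lateral_cortex, g.condyle_medial_cortex
    elif technique == "medial_open":
        y_cut = float(g.epicondyle_medial[1]) + config.dfo_cut_offset_mm
        entry_cortex, hinge_cortex = g.condyle_medial_cortex, g.condyle_lateral_cortex
    else:
        raise ValidationError(f"unknown technique {technique!r}")
    if y_cut >= g.hip_center[1]:
        raise InfeasibleGeometryError("femoral cut level lies proximal to the hip centre")
    entry = _line_at_y(entry_cortex, axis_dir, y_cut)
    far = _line_at_y(hinge_cortex, axis_dir, y_cut)
    hinge = far + np.array([_toward(far[0], entry[0]) * config.hinge_inset_femur_mm, 0.0])
    return OsteotomySpec(
        level="femur", technique=technique, cut_entry=entry, cut_exit=far, hinge=hinge
    )


def place_hto_cut(
    g: LimbGeometry, technique: str, config: StudyConfig = _DEFAULT
) -> OsteotomySpec:
    """Place the high tibial cut and hinge (correction angle unset).

    MOWHTO: transverse cut ``hto_mow_cut_offset_mm`` (35 mm) distal to
    the medial plateau, hinge ``mow_hto_hinge_mm`` (5 mm) inside the
    lateral cortex at cut level.  LCWHTO: cut from the lateral cortex
    ``hto_lcw_cut_offset_mm`` (40 mm) distal to the lateral plateau to
    the medial cortical inflection landmark, hinge at parameter
    ``lcw_hto_hinge_ratio`` (0.75) from the lateral point.

    The lateral cortical silhouette at cut level is modelled as the line
    parallel to the tibial axis ``tibial_flare_mm`` lateral of the
    articular plateau edge (metaphyseal flare).
    """
    axis_dir = g.plafond_center - g.eminence_center
    norm = float(np.linalg.norm(axis_dir))
    if norm <= 0:
        raise ValidationError("degenerate tibial mechanical axis")
    d = axis_dir / norm
    lat_perp = np.array([d[1], -d[0]])   # unit, points laterally (-x for a vertical axis)
    lateral_cortex_ref = g.plateau_lateral + config.tibial_flare_mm * lat_perp

    if technique == "medial_open":
        y_cut = float(g.plateau_medial[1]) - config.hto_mow_cut_offset_mm
        if y_cut <= g.plafond_center[1]:
            raise InfeasibleGeometryError("tibial cut level lies distal to the plafond")
        entry = _line_at_y(g.plateau_medial, axis_dir, y_cut)
        far = _line_at_y(lateral_cortex_ref, axis_dir, y_cut)
        hinge = far + np.array([_toward(far[0], entry[0]) * config.mow_hto_hinge_mm, 0.0])
        return OsteotomySpec(
            level="tibia", technique=technique, cut_entry=entry, cut_exit=far, hinge=hinge
        )
    elif technique == "lateral_closed":
        y_cut = float(g.plateau_lateral[1]) - config.hto_lcw_cut_offset_mm
        if y_cut <= g.plafond_center[1]:
            raise InfeasibleGeometryError("tibial cut level lies distal to the plafond")
        entry = _line_at_y(lateral_cortex_ref, axis_dir, y_cut)
        exit_ = np.asarray(g.tibial_cortex_medial_inflection, dtype=float)
        if exit_[1] <= g.plafond_center[1]:
            raise InfeasibleGeometryError("medial inflection point lies distal to the plafond")
        hinge = entry + config.lcw_hto_hinge_ratio * (exit_ - entry)
        return OsteotomySpec(
            level="tibia", technique=technique, cut_entry=entry, cut_exit=exit_, hinge=hinge
        )
    raise ValidationError(f"unknown technique {technique!r}")


# ---------------------------------------------------------------------------
# wedge application


def apply_wedge(
    g: LimbGeometry, spec: OsteotomySpec, config: StudyConfig = _DEFAULT
) -> LimbGeometry:
    """Rotate every landmark distal to the cut about the hinge.

    The rotation angle is ``-correction_deg`` in the CCW convention: a
    positive (valgus-producing) correction swings the distal fragment so
    the ankle moves laterally.  Proximal landmarks are untouched and the
    hinge is an exact fixed point of the motion.
    """
    if spec.correction_deg is None:
        raise ValidationError("correction_deg is unset; solve or set it before applying")
    if spec.correction_deg == 0.0:
        return g.with_coords(g.coords.copy())
    level_y = float(spec.hinge[1])
    dy = g.coords[:, 1] - level_y
    if np.any(np.abs(dy) < config.cut_level_epsilon_mm):
        raise ValidationError(
            "a landmark lies exactly at the cut level; fragment membership is undecidable"
        )
    distal = dy < 0.0
    th = -math.radians(spec.correction_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    coords = g.coords.copy()
    coords[distal] = (coords[distal] - spec.hinge) @ rot.T + spec.hinge
    return g.with_coords(coords)


# ---------------------------------------------------------------------------
# correction-angle solvers


def _solve(
    spec: OsteotomySpec,
    residual_of_angle,
    config: StudyConfig,
    what: str,
    slack: float,
) -> OsteotomySpec:
    lo, hi = config.angle_bracket_deg
    f_lo = residual_of_angle(lo)
    if abs(f_lo) <= slack:
        # Already at the target within measurement slack: zero correction.
        return spec.with_correction(lo)
    f_hi = residual_of_angle(hi)
    if f_lo * f_hi > 0.0:
        raise InfeasibleGeometryError(
            f"no {what} correction in [{lo}, {hi}] deg reaches the target "
            f"(residuals {f_lo:.3f} and {f_hi:.3f})"
        )
    theta = bisect(residual_of_angle, lo, hi, xtol=config.angle_tol_deg)
    return spec.with_correction(float(theta))


def solve_dfo_angle(
    g: LimbGeometry,
    technique: str,
    target_mldfa_deg: float = _DEFAULT.mldfa_target_deg,
    config: StudyConfig = _DEFAULT,
) -> OsteotomySpec:
    """Find the femoral correction driving post-osteotomy mLDFA to the target.

    The naive guess theta = mLDFA - target is only approximate because
    rotating the notch perturbs the mechanical axis itself, so the signed
    angle is solved by bisection on the measured post-osteotomy mLDFA.
    """
    spec = place_dfo_cut(g, technique, config)

    def residual(theta: float) -> float:
        return measure_mldfa(apply_wedge(g, spec.with_correction(theta), config)) - target_mldfa_deg

    return _solve(spec, residual, config, "femoral", slack=0.009)


def solve_hto_angle(
    g_after_dfo: LimbGeometry,
    technique: str,
    target_wbl_pct: float = _DEFAULT.wbl_target_pct,
    config: StudyConfig = _DEFAULT,
) -> OsteotomySpec:
    """Find the tibial correction driving the WBL ratio to the target.

    Runs on the post-DFO geometry: the residual varus left after the
    femoral correction is taken up in the tibia.
    """
    spec = place_hto_cut(g_after_dfo, technique, config)

    def residual(theta: float) -> float:
        return measure_wbl_ratio(
            apply_wedge(g_after_dfo, spec.with_correction(theta), config)
        ) - target_wbl_pct

    return _solve(spec, residual, config, "tibial", slack=0.045)
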