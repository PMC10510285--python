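"""Canonical 2-D coronal limb model and radiographic alignment measurements.

A limb is represented by 13 named anatomical landmarks in a canonical
coronal frame: **+x is medial, +y is proximal**, units are millimetres.
Left limbs are mirrored on ingest so a single code path serves both sides.

All standard deformity measurements of the knee are derived from this
landmark set:

* HKA angle - angle between the femoral mechanical axis (femoral-head
  centre to intercondylar notch) and the tibial mechanical axis (tibial
  eminence centre to plafond centre).  Signed: positive = valgus,
  negative = varus.
* WBL ratio - where the whole-leg mechanical axis (hip centre to plafond
  centre) crosses the tibial plateau, as a percentage of plateau width
  from the medial edge (0%) to the lateral edge (100%).  Values outside
  [0, 100] are meaningful (the axis passes outside the plateau) and are
  returned as-is.
* mLDFA - lateral angle between the femoral mechanical axis and the
  distal femoral joint line.
* mMPTA - medial angle between the tibial mechanical axis and the
  proximal tibial joint line.
* JLCA - signed angle between the two joint lines, positive when the
  joint gap opens laterally.
* femoral / tibial / total leg lengths - Euclidean distances hip->notch,
  eminence->plafond and hip->plafond.

Angles are degrees and lengths are millimetres at every API boundary;
radians are used internally.  No small-angle approximations are used in
measurement code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "LimbGeometry",
    "AlignmentMeasures",
    "ValidationError",
    "canonicalize",
    "femoral_mech_axis",
    "tibial_mech_axis",
    "measure_hka",
    "measure_wbl_ratio",
    "measure_mldfa",
    "measure_mmpta",
    "measure_jlca",
    "measure_lengths",
    "measure_all",
]

#: Landmark order used by the internal (13, 2) coordinate array and by
#: the CSV/JSON schema (``<name>_x``, ``<name>_y`` columns).
LANDMARK_NAMES: tuple[str, ...] = (
    "hip_center",
    "notch",
    "epicondyle_medial",
    "epicondyle_lateral",
    "femoral_joint_medial",
    "femoral_joint_lateral",
    "condyle_medial_cortex",
    "condyle_lateral_cortex",
    "plateau_medial",
    "plateau_lateral",
    "eminence_center",
    "tibial_cortex_medial_inflection",
    "plafond_center",
)

_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}


class ValidationError(ValueError):
    """Raised when a landmark table or geometry violates its invariants."""


@dataclass(frozen=True)
class LimbGeometry:
    """Named 2-D landmark set for one limb in the canonical coronal frame.

    ``coords`` is a (13, 2) float array ordered as :data:`LANDMARK_NAMES`.
    ``side`` is informational only; coordinates are always stored with
    medial = +x regardless of side.
    """

    coords: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.shape != (len(LANDMARK_NAMES), 2):
            raise ValidationError(
                f"coords must have shape {(len(LANDMARK_NAMES), 2)}, got {arr.shape}"
            )
        object.__setattr__(self, "coords", arr)
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[_INDEX[name]]

    # Attribute-style access for every landmark keeps call sites readable.
    def __getattr__(self, name: str):
        idx = _INDEX.get(name)
        if idx is None:
            raise AttributeError(name)
        return self.coords[idx]

    def with_coords(self, coords: np.ndarray) -> "LimbGeometry":
        return LimbGeometry(coords=np.asarray(coords, dtype=float), side=self.side)

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0)) -> "LimbGeometry":
        """Apply a global rigid motion (rotation about the origin, then translation)."""
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        return self.with_coords(self.coords @ rot.T + np.asarray(translation, dtype=float))

    def validate(self) -> "LimbGeometry":
        """Check the canonical-frame invariants; return self if they hold."""
        c = self.coords
        if not np.all(np.isfinite(c)):
            raise ValidationError("all coordinates must be finite")
        if not (self.hip_center[1] > self.notch[1] > self.plafond_center[1]):
            raise ValidationError(
                "proximal-to-distal ordering violated: require "
                "hip_center.y > notch.y > plafond_center.y"
            )
        if not self.plateau_medial[0] > self.plateau_lateral[0]:
            raise ValidationError("plateau_medial.x must exceed plateau_lateral.x")
        if not self.femoral_joint_medial[0] > self.femoral_joint_lateral[0]:
            raise ValidationError(
                "femoral_joint_medial.x must exceed femoral_joint_lateral.x"
            )
        d = _point_segment_distance(
            self.eminence_center, self.plateau_medial, self.plateau_lateral
        )
        if d > 2.0:
            raise ValidationError(
                f"eminence_center lies {d:.3f} mm from the plateau segment (limit 2 mm)"
            )
        dists = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        off = ~np.eye(len(c), dtype=bool)
        if np.any(dists[off] <= 0.0):
            raise ValidationError("coincident landmarks: all inter-landmark distances must be > 0")
        return self


@dataclass(frozen=True)
class AlignmentMeasures:
    """Derived alignment scalars for one limb (degrees / millimetres / percent)."""

    hka_deg: float
    wbl_ratio_pct: float
    mldfa_deg: float
    mmpta_deg: float
    jlca_deg: float
    femur_len_mm: float
    tibia_len_mm: float
    total_len_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hka_deg": self.hka_deg,
            "wbl_ratio_pct": self.wbl_ratio_pct,
            "mldfa_deg": self.mldfa_deg,
            "mmpta_deg": self.mmpta_deg,
            "jlca_deg": self.jlca_deg,
            "femur_len_mm": self.femur_len_mm,
            "tibia_len_mm": self.tibia_len_mm,
            "total_len_mm": self.total_len_mm,
        }


# ---------------------------------------------------------------------------
# ingest


def canonicalize(raw_landmarks: Mapping[str, float] | Mapping[str, Iterable[float]],
                 side: str) -> LimbGeometry:
    """Build a canonical-frame :class:`LimbGeometry` from a raw landmark table.

    ``raw_landmarks`` maps either ``"<name>_x"``/``"<name>_y"`` scalars or
    ``"<name>"`` to an (x, y) pair.  Left limbs are mirrored about the
    vertical axis x = 0 so medial is always +x; mirroring preserves every
    inter-landmark distance.

    Raises
    ------
    ValidationError
        If a required landmark is missing or a frame invariant fails.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    coords = np.empty((len(LANDMARK_NAMES), 2), dtype=float)
    for i, name in enumerate(LANDMARK_NAMES):
        if name in raw_landmarks:
            xy = np.asarray(raw_landmarks[name], dtype=float)
            if xy.shape != (2,):
                raise ValidationError(f"landmark {name!r} must be a 2-D point")
            coords[i] = xy
        elif f"{name}_x" in raw_landmarks and f"{name}_y" in raw_landmarks:
            coords[i] = (float(raw_landmarks[f"{name}_x"]),
                         float(raw_landmarks[f"{name}_y"]))
        else:
            raise ValidationError(f"missing landmark {name!r}")
    if side == "left":
        coords[:, 0] = -coords[:, 0]
    return LimbGeometry(coords=coords, side=side).validate()


# ---------------------------------------------------------------------------
# axes


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n <= 0.0:
        raise ValidationError(f"degenerate {what}: coincident endpoints")
    return v / n


def femoral_mech_axis(g: LimbGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Directed femoral mechanical axis: (anchor=hip_center, unit direction toward notch)."""
    return g.hip_center.copy(), _unit(g.notch - g.hip_center, "femoral mechanical axis")


def tibial_mech_axis(g: LimbGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Directed tibial mechanical axis: (anchor=eminence_center, unit direction toward plafond)."""
    return g.eminence_center.copy(), _unit(
        g.plafond_center - g.eminence_center, "tibial mechanical axis"
    )


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """CCW signed angle from u to v, degrees in (-180, 180]."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return math.degrees(math.atan2(cross, dot))


def _unsigned_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return abs(_signed_angle_deg(u, v))


# ---------------------------------------------------------------------------
# measurements


def measure_hka(g: LimbGeometry) -> float:
    """Signed hip-knee-ankle angle in degrees; positive = valgus, negative = varus.

    Varus (bow-legged) limbs have the ankle deviated medially relative to
    the prolonged femoral axis, which carries the whole-leg axis medial to
    the knee; this convention makes varus HKA negative and varus WBL
    ratios below 50%.
    """
    _, df = femoral_mech_axis(g)
    _, dt = tibial_mech_axis(g)
    hka = -_signed_angle_deg(df, dt)
    if not -90.0 < hka < 90.0:
        raise ValidationError(f"HKA angle {hka:.1f} deg outside (-90, 90): degenerate axes")
    return hka


def measure_wbl_ratio(g: LimbGeometry) -> float:
    """Weight-bearing-line ratio in percent (medial edge 0, lateral edge 100).

    The whole-leg mechanical axis (hip centre -> plafond centre) is
    intersected with the *infinite* line through the plateau edges, so
    values below 0 or above 100 are returned when the axis passes outside
    the plateau.
    """
    p0 = g.hip_center
    d = g.plafond_center - g.hip_center
    if np.linalg.norm(d) <= 0:
        raise ValidationError("degenerate whole-leg axis: hip_center equals plafond_center")
    q0 = g.plateau_medial
    e = g.plateau_lateral - g.plateau_medial
    if np.linalg.norm(e) <= 0:
        raise ValidationError("degenerate plateau line: coincident plateau edges")
    # Solve p0 + t d = q0 + s e for s (the plateau parameter).
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-12 * np.linalg.norm(d) * np.linalg.norm(e):
        raise ValidationError("weight-bearing line is parallel to the plateau line")
    r = q0 - p0
    s = (d[1] * r[0] - d[0] * r[1]) / denom
    return 100.0 * s


def measure_mldfa(g: LimbGeometry) -> float:
    """Mechanical lateral distal femoral angle in degrees.

    Lateral angle between the femoral mechanical axis (taken proximally,
    notch -> hip) and the distal femoral joint line (taken laterally,
    medial -> lateral joint point).
    """
    u_prox = _unit(g.hip_center - g.notch, "femoral mechanical axis")
    w_lat = _unit(
        g.femoral_joint_lateral - g.femoral_joint_medial, "femoral joint line"
    )
    a = _unsigned_angle_deg(u_prox, w_lat)
    if not 0.0 < a < 180.0:
        raise ValidationError("degenerate mLDFA configuration")
    return a


def measure_mmpta(g: LimbGeometry) -> float:
    """Mechanical medial proximal tibial angle in degrees.

    Medial angle between the tibial mechanical axis (taken distally,
    eminence -> plafond) and the proximal tibial joint line (taken
    medially, lateral -> medial plateau edge).
    """
    u_dist = _unit(g.plafond_center - g.eminence_center, "tibial mechanical axis")
    w_med = _unit(g.plateau_medial - g.plateau_lateral, "tibial plateau line")
    a = _unsigned_angle_deg(u_dist, w_med)
    if not 0.0 < a < 180.0:
        raise ValidationError("degenerate mMPTA configuration")
    return a


def measure_jlca(g: LimbGeometry) -> float:
    """Joint-line convergence angle in degrees, positive = lateral opening.

    Signed CCW angle from the femoral joint line's medial direction to the
    plateau's medial direction; with this convention the exact closure
    identity HKA = (mMPTA - 90) + (90 - mLDFA) - JLCA holds for limbs
    whose joint lines are oriented consistently with their angles.
    """
    v_med_f = _unit(g.femoral_joint_medial - g.femoral_joint_lateral, "femoral joint line")
    v_med_t = _unit(g.plateau_medial - g.plateau_lateral, "tibial plateau line")
    return _signed_angle_deg(v_med_f, v_med_t)


def measure_lengths(g: LimbGeometry) -> tuple[float, float, float]:
    """(femur, tibia, total) lengths in mm: hip->notch, eminence->plafond, hip->plafond."""
    femur = float(np.linalg.norm(g.notch - g.hip_center))
    tibia = float(np.linalg.norm(g.plafond_center - g.eminence_center))
    total = float(np.linalg.norm(g.plafond_center - g.hip_center))
    return femur, tibia, total


def measure_all(g: LimbGeometry) -> AlignmentMeasures:
    """Bundle every measurement; fields agree bit-for-bit with the individual ops."""
    femur, tibia, total = measure_lengths(g)
    return AlignmentMeasures(
        hka_deg=measure_hka(g),
        wbl_ratio_pct=measure_wbl_ratio(g),
        mldfa_deg=measure_mldfa(g),
        mmpta_deg=measure_mmpta(g),
        jlca_deg=measure_jlca(g),
        femur_len_mm=femur,
        tibia_len_mm=tibia,
        total_len_mm=total,
    )


# ---------------------------------------------------------------------------


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))
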