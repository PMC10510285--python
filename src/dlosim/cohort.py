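"""Synthetic pre-operative cohort: virtual varus limbs with realistic statistics.

The generator stands in for the whole-leg standing radiographs of a
varus-osteoarthritis cohort.  Five quantities are drawn per limb from
truncated normal distributions (HKA, mLDFA, mMPTA, femoral and tibial
length); the joint-line convergence angle (JLCA) is *not* drawn but set
as the closure residual

    JLCA = (mMPTA - 90) + (90 - mLDFA) - HKA        (varus HKA negative)

with rejection outside physiologic bounds, because the three angles of
a standing varus knee are mutually inconsistent without a joint-line
convergence term (the default parameters imply a mean residual of about
5.8 deg, plausible for one-leg-standing varus knees with medial
cartilage loss).  Draws are independent before closure.

The weight-bearing-line ratio is never drawn either: it *emerges* from
the constructed geometry, which makes its cohort statistics a
non-circular check of the anatomy constants (plateau width above all).

Landmarks are built deterministically from the drawn values: a femoral
mechanical axis of the drawn length, joint lines tilted per mLDFA and
mMPTA, tibial axis per HKA, widths proportional to segment lengths, and
cortical/inflection landmarks at proportional offsets.  The limb is
then stood up so the hip centre lies vertically above the plafond
(one-leg stance).  Sampling is reproducible: one global seed, with
per-limb substreams derived by counter so the first k limbs of a cohort
do not depend on n.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .geometry import LANDMARK_NAMES, LimbGeometry, ValidationError

__all__ = [
    "TruncatedNormal",
    "CohortParams",
    "ParameterInconsistencyError",
    "build_limb",
    "sample_limb",
    "sample_cohort",
]


class ParameterInconsistencyError(ValidationError):
    """The drawn distributions are incompatible with the JLCA closure bounds."""


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated-normal parameters; sampled by inverse CDF on the truncated interval."""

    mean: float
    sd: float
    low: float
    high: float

    def validate(self, name: str) -> "TruncatedNormal":
        if not self.sd > 0:
            raise ValidationError(f"{name}: sd must be > 0")
        if not self.low < self.mean < self.high:
            raise ValidationError(f"{name}: require low < mean < high")
        return self

    def ppf(self, u: float) -> float:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class CohortParams:
    """Distribution parameters and anatomy constants for limb generation.

    Distribution defaults are the pre-operative cohort this package
    emulates (n = 44 varus knees), with the printed ranges as truncation
    bounds.  Anatomy constants the source statistics never pin down
    directly (widths, hinge-level silhouette offsets) are calibrated so
    the emergent WBL ratio distribution and the planned length changes
    match the reference statistics; see docs/methods.md.
    """

    n: int = 44
    seed: int = 0

    hka_deg: TruncatedNormal = TruncatedNormal(-11.0, 2.5, -16.4, -6.1)
    mldfa_deg: TruncatedNormal = TruncatedNormal(88.9, 1.9, 85.9, 93.3)
    mmpta_deg: TruncatedNormal = TruncatedNormal(83.7, 2.0, 79.9, 87.8)
    femur_len_mm: TruncatedNormal = TruncatedNormal(411.2, 37.0, 350.8, 542.3)
    tibia_len_mm: TruncatedNormal = TruncatedNormal(340.6, 27.5, 303.7, 422.1)

    plateau_width_frac: float = 0.20     # plateau width / tibial length
    condyle_width_frac: float = 0.195    # femoral condylar width / femoral length
    notch_eminence_gap_mm: float = 1.0   # knee-centre duality gap
    jlca_bounds_deg: tuple[float, float] = (0.0, 12.0)
    epicondyle_offset_mm: float = 25.0   # epicondyles proximal to the joint line
    supracondylar_offset_mm: float = 45.0  # condylar cortex landmarks proximal to the notch
    inflection_overhang_mm: float = 4.0    # medial inflection point medial of the plateau edge
    inflection_depth_mm: float = 55.0      # ... and distal to the medial plateau

    max_rejection_rate: float = 0.5

    def validate(self) -> "CohortParams":
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        for name in ("hka_deg", "mldfa_deg", "mmpta_deg", "femur_len_mm", "tibia_len_mm"):
            getattr(self, name).validate(name)
        for name in ("plateau_width_frac", "condyle_width_frac"):
            frac = getattr(self, name)
            if not 0.1 < frac < 0.3:
                raise ValidationError(f"{name} must lie in (0.1, 0.3), got {frac}")
        lo, hi = self.jlca_bounds_deg
        if not lo < hi:
            raise ValidationError("jlca_bounds_deg must be an increasing pair")
        return self

    def to_dict(self) -> dict:
        def tn(t: TruncatedNormal) -> dict:
            return {"mean": t.mean, "sd": t.sd, "low": t.low, "high": t.high}

        return {
            "n": self.n,
            "seed": self.seed,
            "hka_deg": tn(self.hka_deg),
            "mldfa_deg": tn(self.mldfa_deg),
            "mmpta_deg": tn(self.mmpta_deg),
            "femur_len_mm": tn(self.femur_len_mm),
            "tibia_len_mm": tn(self.tibia_len_mm),
            "plateau_width_frac": self.plateau_width_frac,
            "condyle_width_frac": self.condyle_width_frac,
            "notch_eminence_gap_mm": self.notch_eminence_gap_mm,
            "jlca_bounds_deg": list(self.jlca_bounds_deg),
            "epicondyle_offset_mm": self.epicondyle_offset_mm,
            "supracondylar_offset_mm": self.supracondylar_offset_mm,
            "inflection_overhang_mm": self.inflection_overhang_mm,
            "inflection_depth_mm": self.inflection_depth_mm,
            "max_rejection_rate": self.max_rejection_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        d = dict(d)
        for name in ("hka_deg", "mldfa_deg", "mmpta_deg", "femur_len_mm", "tibia_len_mm"):
            if name in d and isinstance(d[name], dict):
                d[name] = TruncatedNormal(**d[name])
        if "jlca_bounds_deg" in d:
            d["jlca_bounds_deg"] = tuple(d["jlca_bounds_deg"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def params_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# deterministic landmark construction


def _rot(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])


def build_limb(
    hka_deg: float,
    mldfa_deg: float,
    mmpta_deg: float,
    femur_len_mm: float,
    tibia_len_mm: float,
    params: Optional[CohortParams] = None,
) -> LimbGeometry:
    """Construct the canonical landmark set realising the given angles and lengths.

    Deterministic: the same inputs give bit-identical coordinates.  The
    JLCA of the result is the exact closure residual of the three input
    angles.  The limb is oriented with the hip centre vertically above
    the plafond centre (one-leg stance).
    """
    p = (params or CohortParams()).validate()
    f, t = float(femur_len_mm), float(tibia_len_mm)
    if f <= 0 or t <= 0:
        raise ValidationError("segment lengths must be positive")

    eminence = np.array([0.0, 0.0])
    notch = np.array([0.0, p.notch_eminence_gap_mm])
    u_prox = np.array([0.0, 1.0])          # femoral axis, proximal direction
    hip = notch + f * u_prox
    m_femur = np.array([1.0, 0.0])         # medial perpendicular of the femoral axis

    # Tibial axis tilted so the signed femorotibial angle equals HKA
    # (varus negative = ankle deviating medially).
    beta_t = -float(hka_deg)
    d_tib = _rot(beta_t) @ np.array([0.0, -1.0])
    plafond = eminence + t * d_tib
    m_tibia = _rot(90.0) @ d_tib           # medial perpendicular of the tibial axis

    # Distal femoral joint line: lateral direction at mLDFA from the proximal axis.
    w_f = p.condyle_width_frac * f
    v_lat_f = _rot(float(mldfa_deg)) @ u_prox
    joint_lat = notch + 0.5 * w_f * v_lat_f
    joint_med = notch - 0.5 * w_f * v_lat_f
    epi_lat = joint_lat + p.epicondyle_offset_mm * u_prox
    epi_med = joint_med + p.epicondyle_offset_mm * u_prox
    cortex_med = notch + p.supracondylar_offset_mm * u_prox + 0.5 * w_f * m_femur
    cortex_lat = notch + p.supracondylar_offset_mm * u_prox - 0.5 * w_f * m_femur

    # Proximal tibial joint line: medial direction at mMPTA from the distal axis.
    w_p = p.plateau_width_frac * t
    v_med_t = _rot(float(mmpta_deg)) @ d_tib
    plateau_med = eminence + 0.5 * w_p * v_med_t
    plateau_lat = eminence - 0.5 * w_p * v_med_t
    inflection = plateau_med + p.inflection_depth_mm * d_tib + p.inflection_overhang_mm * m_tibia

    coords = {
        "hip_center": hip,
        "notch": notch,
        "epicondyle_medial": epi_med,
        "epicondyle_lateral": epi_lat,
        "femoral_joint_medial": joint_med,
        "femoral_joint_lateral": joint_lat,
        "condyle_medial_cortex": cortex_med,
        "condyle_lateral_cortex": cortex_lat,
        "plateau_medial": plateau_med,
        "plateau_lateral": plateau_lat,
        "eminence_center": eminence,
        "tibial_cortex_medial_inflection": inflection,
        "plafond_center": plafond,
    }
    arr = np.array([coords[name] for name in LANDMARK_NAMES])

    # Stand the limb up: rotate about the eminence so the hip lies
    # vertically above the plafond (whole-leg axis vertical).
    v = arr[LANDMARK_NAMES.index("hip_center")] - arr[LANDMARK_NAMES.index("plafond_center")]
    tilt = 90.0 - math.degrees(math.atan2(v[1], v[0]))
    arr = arr @ _rot(tilt).T

    return LimbGeometry(coords=arr, side="right").validate()


# ---------------------------------------------------------------------------
# sampling


def _limb_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _draw_limb(params: CohortParams, rng: np.random.Generator,
               max_attempts: int = 1000) -> tuple[LimbGeometry, dict, int]:
    lo, hi = params.jlca_bounds_deg
    rejections = 0
    for _ in range(max_attempts):
        draws = {
            "hka_deg": params.hka_deg.ppf(rng.uniform()),
            "mldfa_deg": params.mldfa_deg.ppf(rng.uniform()),
            "mmpta_deg": params.mmpta_deg.ppf(rng.uniform()),
            "femur_len_mm": params.femur_len_mm.ppf(rng.uniform()),
            "tibia_len_mm": params.tibia_len_mm.ppf(rng.uniform()),
        }
        jlca = (draws["mmpta_deg"] - 90.0) + (90.0 - draws["mldfa_deg"]) - draws["hka_deg"]
        if lo <= jlca <= hi:
            limb = build_limb(params=params, **draws)
            draws["jlca_deg"] = jlca
            return limb, draws, rejections
        rejections += 1
    raise ParameterInconsistencyError(
        f"JLCA closure bounds {params.jlca_bounds_deg} rejected {max_attempts} "
        "consecutive draws; distribution parameters are inconsistent"
    )


def sample_limb(params: CohortParams, rng: np.random.Generator) -> LimbGeometry:
    """Draw one virtual limb (truncated-normal draws + JLCA closure rejection)."""
    limb, _, _ = _draw_limb(params.validate(), rng)
    return limb


def sample_cohort(params: CohortParams) -> tuple[list[LimbGeometry], dict]:
    """Draw a full cohort; returns (limbs, provenance record).

    Reproducible under ``params.seed``; limb i uses substream i of the
    global seed, so the first k limbs do not depend on ``params.n``.
    Raises :class:`ParameterInconsistencyError` if the JLCA closure
    rejects more than ``max_rejection_rate`` of all draws.
    """
    params = params.validate()
    limbs: list[LimbGeometry] = []
    total_rejections = 0
    for i in range(params.n):
        limb, _, rejections = _draw_limb(params, _limb_rng(params.seed, i))
        total_rejections += rejections
        limbs.append(limb)
    total_draws = params.n + total_rejections
    if params.n >= 10 and total_draws > 0:
        rate = total_rejections / total_draws
        if rate > params.max_rejection_rate:
            raise ParameterInconsistencyError(
                f"JLCA closure rejected {100 * rate:.1f}% of draws "
                f"(limit {100 * params.max_rejection_rate:.0f}%)"
            )
    provenance = {
        "seed": params.seed,
        "n": params.n,
        "rejections": total_rejections,
        "params_hash": params.params_hash(),
        "params": params.to_dict(),
    }
    return limbs, provenance
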