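"""End-to-end double-level-osteotomy planning and outcome variables.

A double level osteotomy (DLO) corrects severe varus at both deformity
levels: first the femoral cut is solved so the post-osteotomy mLDFA
equals its target (85 deg), then the residual varus is corrected in the
tibia by solving the HTO angle so the weight-bearing-line ratio reaches
its target (62.5%).  Four procedures arise from combining opening and
closing wedges at each level.

Outcome variables are the changes in femoral, tibial and total leg
length between the pre-operative and planned geometry (positive =
lengthening), and a symptomatic flag: a total change of strictly more
than 6 mm in either direction, the discrepancy linked to low-back
symptoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .config import StudyConfig
from .geometry import AlignmentMeasures, LimbGeometry, ValidationError, measure_all
from .osteotomy import OsteotomySpec, apply_wedge, place_dfo_cut, solve_dfo_angle, solve_hto_angle

__all__ = ["PROCEDURES", "DLOPlan", "classify_symptomatic", "plan_dlo", "plan_all"]

#: The four DLO variants, in the reporting order used throughout.
PROCEDURES: tuple[str, ...] = (
    "LCWDFO+MOWHTO",
    "LCWDFO+LCWHTO",
    "MOWDFO+MOWHTO",
    "MOWDFO+LCWHTO",
)

_TECHNIQUE = {"LCW": "lateral_closed", "MOW": "medial_open"}


def procedure_techniques(procedure: str) -> tuple[str, str]:
    """(femoral, tibial) wedge techniques for a procedure name."""
    if procedure not in PROCEDURES:
        raise ValidationError(f"unknown procedure {procedure!r}; expected one of {PROCEDURES}")
    dfo_name, hto_name = procedure.split("+")
    return _TECHNIQUE[dfo_name[:3]], _TECHNIQUE[hto_name[:3]]


@dataclass(frozen=True)
class DLOPlan:
    """One procedure executed on one limb, with pre/post measures and deltas."""

    procedure: str
    dfo: OsteotomySpec
    hto: OsteotomySpec
    pre: AlignmentMeasures
    post: AlignmentMeasures
    post_geometry: LimbGeometry
    delta_femur_mm: float
    delta_tibia_mm: float
    delta_total_mm: float
    symptomatic: bool


def classify_symptomatic(delta_total_mm: float, threshold_mm: float = 6.0) -> bool:
    """Strict two-sided test: |delta| > threshold (6 mm -> False, 6.0001 -> True)."""
    if not delta_total_mm == delta_total_mm:  # NaN
        raise ValidationError("delta_total_mm must be finite")
    return delta_total_mm > threshold_mm or delta_total_mm < -threshold_mm


def plan_dlo(
    g: LimbGeometry, procedure: str, config: Optional[StudyConfig] = None
) -> DLOPlan:
    """Execute one DLO procedure on a limb.

    The femoral osteotomy is solved to the mLDFA target and applied;
    the tibial osteotomy is then solved on the rotated geometry to the
    WBL target and applied.  A knee whose pre-operative mLDFA is already
    below the femoral target receives zero femoral correction (with a
    warning): producing varus in the femur is outside the protocol.
    """
    config = (config or StudyConfig()).validate()
    dfo_tech, hto_tech = procedure_techniques(procedure)
    pre = measure_all(g)

    if pre.mldfa_deg < config.mldfa_target_deg:
        warnings.warn(
            f"pre-operative mLDFA {pre.mldfa_deg:.2f} deg is below the "
            f"{config.mldfa_target_deg:.1f} deg target; femoral correction set to zero",
            stacklevel=2,
        )
        dfo = place_dfo_cut(g, dfo_tech, config).with_correction(0.0)
    else:
        dfo = solve_dfo_angle(g, dfo_tech, config.mldfa_target_deg, config)
    g_after_dfo = apply_wedge(g, dfo, config)

    hto = solve_hto_angle(g_after_dfo, hto_tech, config.wbl_target_pct, config)
    g_post = apply_wedge(g_after_dfo, hto, config)

    post = measure_all(g_post)
    d_femur = post.femur_len_mm - pre.femur_len_mm
    d_tibia = post.tibia_len_mm - pre.tibia_len_mm
    d_total = post.total_len_mm - pre.total_len_mm
    return DLOPlan(
        procedure=procedure,
        dfo=dfo,
        hto=hto,
        pre=pre,
        post=post,
        post_geometry=g_post,
        delta_femur_mm=d_femur,
        delta_tibia_mm=d_tibia,
        delta_total_mm=d_total,
        symptomatic=classify_symptomatic(d_total, config.symptomatic_threshold_mm),
    )


def plan_all(g: LimbGeometry, config: Optional[StudyConfig] = None) -> list[DLOPlan]:
    """Run all four DLO procedures on one limb (for paired analyses)."""
    return [plan_dlo(g, proc, config) for proc in PROCEDURES]
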