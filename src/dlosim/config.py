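"""Study configuration: correction targets, engine anatomy constants, tolerances.

Defaults reproduce the reference planning protocol this package
simulates: overcorrection to a weight-bearing-line ratio of 62.5% with
the femoral deformity corrected first to an mLDFA of 85 deg and the
residual corrected in the tibia.  The two silhouette constants the
engine needs (femoral hinge inset, tibial metaphyseal flare) are not
measurable from alignment statistics and are calibrated so planned
length changes match published planning behaviour; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["StudyConfig"]


@dataclass(frozen=True)
class StudyConfig:
    # correction targets
    wbl_target_pct: float = 62.5
    mldfa_target_deg: float = 85.0

    # cut / hinge placement rules (mm)
    dfo_cut_offset_mm: float = 40.0       # cut this far proximal to the reference epicondyle
    hto_mow_cut_offset_mm: float = 35.0   # MOWHTO cut this far distal to the medial plateau
    hto_lcw_cut_offset_mm: float = 40.0   # LCWHTO cut entry this far distal to the lateral plateau
    mow_hto_hinge_mm: float = 5.0         # lateral bone bridge left in MOWHTO
    lcw_hto_hinge_ratio: float = 0.75     # hinge divides the LCWHTO cut 3:1 from the lateral point
    hinge_inset_femur_mm: float = 5.0     # femoral hinge inset from the far cortex (calibrated)
    tibial_flare_mm: float = 14.0         # lateral cortical overhang beyond the plateau edge
                                          # at the HTO cut level (calibrated)

    # solver settings
    angle_bracket_deg: tuple[float, float] = (0.0, 25.0)
    angle_tol_deg: float = 1e-4
    cut_level_epsilon_mm: float = 1e-6

    # outcome classification
    symptomatic_threshold_mm: float = 6.0

    def validate(self) -> "StudyConfig":
        if not 0.0 < self.wbl_target_pct < 100.0:
            raise ValueError("wbl_target_pct must lie in (0, 100)")
        if not 0.0 < self.mldfa_target_deg < 180.0:
            raise ValueError("mldfa_target_deg must lie in (0, 180)")
        lo, hi = self.angle_bracket_deg
        if not 0.0 <= lo < hi <= 30.0:
            raise ValueError("angle_bracket_deg must satisfy 0 <= lo < hi <= 30")
        if self.angle_tol_deg <= 0 or self.symptomatic_threshold_mm <= 0:
            raise ValueError("tolerances and thresholds must be positive")
        if not 0.0 < self.lcw_hto_hinge_ratio < 1.0:
            raise ValueError("lcw_hto_hinge_ratio must lie in (0, 1)")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angle_bracket_deg"] = list(self.angle_bracket_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "angle_bracket_deg" in d:
            d["angle_bracket_deg"] = tuple(d["angle_bracket_deg"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
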