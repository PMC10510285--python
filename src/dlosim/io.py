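"""Landmark-table I/O: CSV and JSON mirrors of the same flat schema.

One row (or JSON record) per limb: ``limb_id``, ``side`` and
``<landmark>_x`` / ``<landmark>_y`` columns in millimetres for the 13
canonical landmarks.  Reading runs every record through
:func:`dlosim.geometry.canonicalize`, so left limbs are mirrored and
invariants checked on ingest; writing emits canonical-frame coordinates
as-is.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .geometry import LANDMARK_NAMES, LimbGeometry, ValidationError, canonicalize, measure_all

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "read_landmark_json",
    "write_landmark_json",
    "write_measures_csv",
]


def _limb_record(limb: LimbGeometry, limb_id) -> dict:
    rec: dict = {"limb_id": limb_id, "side": limb.side}
    for name in LANDMARK_NAMES:
        x, y = limb[name]
        rec[f"{name}_x"] = float(x)
        rec[f"{name}_y"] = float(y)
    return rec


def _record_to_limb(rec: dict) -> LimbGeometry:
    # Stored tables are already canonical (medial = +x), so ingest them
    # without re-mirroring and keep the side label informational.
    limb = canonicalize(rec, side="right")
    return LimbGeometry(coords=limb.coords, side=rec.get("side", "right"))


def write_landmark_csv(path, limbs: Sequence[LimbGeometry], limb_ids=None) -> None:
    ids = range(len(limbs)) if limb_ids is None else limb_ids
    df = pd.DataFrame([_limb_record(limb, i) for limb, i in zip(limbs, ids)])
    df.to_csv(path, index=False, float_format="%.10g")


def read_landmark_csv(path) -> tuple[list[LimbGeometry], list]:
    """Read a canonical landmark CSV; returns (limbs, limb_ids)."""
    df = pd.read_csv(path)
    missing = [c for c in ("limb_id", "side") if c not in df.columns]
    if missing:
        raise ValidationError(f"landmark CSV is missing columns {missing}")
    limbs = [_record_to_limb(row._asdict() if hasattr(row, "_asdict") else dict(row))
             for _, row in df.iterrows()]
    return limbs, df["limb_id"].tolist()


def write_landmark_json(path, limbs: Sequence[LimbGeometry], limb_ids=None) -> None:
    ids = range(len(limbs)) if limb_ids is None else limb_ids
    records = [_limb_record(limb, i) for limb, i in zip(limbs, ids)]
    Path(path).write_text(json.dumps(records, sort_keys=True, indent=1))


def read_landmark_json(path) -> tuple[list[LimbGeometry], list]:
    records = json.loads(Path(path).read_text())
    limbs = [_record_to_limb(rec) for rec in records]
    return limbs, [rec["limb_id"] for rec in records]


def write_measures_csv(path, limbs: Sequence[LimbGeometry], limb_ids=None) -> None:
    """Measure every limb and write the derived-scalars table."""
    ids = range(len(limbs)) if limb_ids is None else limb_ids
    rows = [{"limb_id": i, **measure_all(limb).as_dict()} for limb, i in zip(limbs, ids)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
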