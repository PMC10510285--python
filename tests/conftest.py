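"""Shared fixtures: deterministic reference limbs and a planned study cohort."""

from __future__ import annotations

import time

import numpy as np
import pytest

from dlosim.cohort import CohortParams, build_limb, sample_cohort
from dlosim.config import StudyConfig
from dlosim.planner import plan_all

#: Reference pre-operative means the synthetic cohort is calibrated to
#: (varus osteoarthritis, one-leg standing films).
MEAN_HKA, MEAN_MLDFA, MEAN_MMPTA = -11.0, 88.9, 83.7
MEAN_FEMUR, MEAN_TIBIA = 411.2, 340.6


@pytest.fixture(scope="session")
def mean_limb():
    """The deterministic limb realising the cohort's mean angles and lengths."""
    return build_limb(MEAN_HKA, MEAN_MLDFA, MEAN_MMPTA, MEAN_FEMUR, MEAN_TIBIA)


@pytest.fixture(scope="session")
def default_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-limb seeded cohort for property checks."""
    limbs, _ = sample_cohort(CohortParams(n=50, seed=7))
    return limbs


@pytest.fixture(scope="session")
def planned_cohort():
    """2,000 limbs with all four procedures planned, plus the wall time taken.

    This is the desk-scale reproduction cohort used by the acceptance
    checks; building it is the package's main workload, so the elapsed
    time doubles as the runtime budget measurement.
    """
    t0 = time.perf_counter()
    limbs, provenance = sample_cohort(CohortParams(n=2000, seed=1234))
    plans = [plan_all(limb) for limb in limbs]
    elapsed = time.perf_counter() - t0
    return {"limbs": limbs, "plans": plans, "provenance": provenance, "elapsed_s": elapsed}


def limb_coords(limbs):
    return np.array([g.coords for g in limbs])
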