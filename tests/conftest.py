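"""Shared fixtures: small deterministic volumes, phantoms, and cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edgescore.io import LesionMask, PETVolume
from edgescore.synthetic import CohortSpec, PhantomSpec, make_cohort, make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    affine = np.diag(list(spacing) + [1.0])
    return PETVolume(values=values, spacing=np.asarray(spacing, float),
                     affine=affine)


def make_mask(mask, spacing=(1.0, 1.0, 1.0)):
    mask = np.asarray(mask, dtype=bool)
    affine = np.diag(list(spacing) + [1.0])
    return LesionMask(values=mask, spacing=np.asarray(spacing, float),
                      affine=affine)


def cube_volume(n=8, suv=4.0, background=0.5, pad=3, spacing=(1.0, 1.0, 1.0)):
    """Uniform-SUV cube of side n inside a padded background box."""
    side = n + 2 * pad
    vals = np.full((side, side, side), background, dtype=float)
    sl = slice(pad, pad + n)
    vals[sl, sl, sl] = suv
    msk = np.zeros_like(vals, dtype=bool)
    msk[sl, sl, sl] = True
    return make_volume(vals, spacing), make_mask(msk, spacing)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Default phantom: radius-16 sphere, hotspot at half radius."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def cohort244():
    return make_cohort(CohortSpec(n=244, seed=11))


@pytest.fixture(scope="session")
def cohort_large():
    return make_cohort(CohortSpec(n=2000, seed=7))
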