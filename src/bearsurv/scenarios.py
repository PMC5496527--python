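"""Canonical synthetic-survey worlds used for estimator validation.

Each factory returns a :class:`~bearsurv.synth.TruthConfig` describing one
fixed data-generating world at the scale of the real surveys (hundreds of
transects, 15–25 km target lengths, 600–800 m truncation distances). The
parameter choices are part of the package's validation design and are
documented in docs/methods.md; they are deliberately not tunable knobs.

CDS and availability worlds use a single effective observer (p₁ = 1, p₂ = 0)
so the combined detection curve is exactly the half-normal shape the CDS
model assumes; MRDS worlds use two high-probability observers under point
independence.
"""
from __future__ import annotations

import datetime as dt

import numpy as np

from .synth import TruthConfig

__all__ = [
    "cds_recovery_world",
    "mrds_recovery_world",
    "availability_world",
    "small_n_world",
    "large_survey_world",
    "AVAILABILITY_MEAN",
    "AVAILABILITY_SD",
]

AVAILABILITY_MEAN = 0.65  # mean day-to-day availability in the open-model world
AVAILABILITY_SD = 0.10


def cds_recovery_world(seed: int) -> TruthConfig:
    """Half-normal CDS world: σ = 250 m, w′ = 600 m, N = 1,500 bears, n ≈ 300."""
    return TruthConfig(
        study_area_km2=1000.0, n_transects=65, transect_length_km=15.0,
        w_m=600.0, n_bears=1500.0, density_bears_km2=None, lambda_group=0.5,
        apex_c_m=0.0, sigma_left_m=250.0, sigma_right_m=250.0,
        p1=1.0, p2=0.0, seed=seed,
    )


def mrds_recovery_world(seed: int) -> TruthConfig:
    """Two-piece MRDS world: c = 300, σ₁ = 120, σ₂ = 260, p₁ = 0.9, p₂ = 0.85,
    N = 2,000 bears, n ≈ 350."""
    return TruthConfig(
        study_area_km2=3000.0, n_transects=117, transect_length_km=15.0,
        w_m=800.0, n_bears=2000.0, density_bears_km2=None, lambda_group=0.5,
        apex_c_m=300.0, sigma_left_m=120.0, sigma_right_m=260.0,
        p1=0.9, p2=0.85, seed=seed,
    )


def availability_world(seed: int) -> TruthConfig:
    """Six-day open-model world: N_super = 2,000, φ_t iid Beta(mean 0.65, sd 0.1).

    The design mirrors the real 6-day representative subset (324 transects
    over 6 days); per-date availability is drawn from the replicate's own
    seed, so each replicate has a different realized availability pattern
    around the 0.65 mean.
    """
    rng = np.random.default_rng(seed)
    nu = AVAILABILITY_MEAN * (1.0 - AVAILABILITY_MEAN) / AVAILABILITY_SD ** 2 - 1.0
    phi = tuple(rng.beta(AVAILABILITY_MEAN * nu, (1.0 - AVAILABILITY_MEAN) * nu, 6))
    dates = tuple(dt.date(2005, 5, 18) + dt.timedelta(days=k) for k in range(6))
    return TruthConfig(
        study_area_km2=4000.0, n_transects=324, transect_length_km=15.0,
        w_m=600.0, n_bears=2000.0, density_bears_km2=None, lambda_group=0.5,
        apex_c_m=0.0, sigma_left_m=250.0, sigma_right_m=250.0,
        p1=1.0, p2=0.0, dates=dates, phi_by_date=phi, seed=seed,
    )


def small_n_world(seed: int) -> TruthConfig:
    """Sparse survey near the conventional CDS minimum (n ≈ 60 detections)."""
    return TruthConfig(
        study_area_km2=400.0, n_transects=13, transect_length_km=15.0,
        w_m=600.0, n_bears=600.0, density_bears_km2=None, lambda_group=0.5,
        apex_c_m=0.0, sigma_left_m=250.0, sigma_right_m=250.0,
        p1=1.0, p2=0.0, seed=seed,
    )


def large_survey_world(seed: int) -> TruthConfig:
    """Large two-piece survey (n ≈ 2,000) with joint apex detection ≈ 0.99.

    Used to compare MRDS and apex-left-truncated CDS point estimates when
    detection at the apex is nearly certain, isolating the effect of
    discarding the capture histories.
    """
    return TruthConfig(
        study_area_km2=5000.0, n_transects=600, transect_length_km=15.0,
        w_m=800.0, density_bears_km2=0.8, lambda_group=0.5,
        apex_c_m=300.0, sigma_left_m=120.0, sigma_right_m=260.0,
        p1=0.9, p2=0.9, seed=seed,
    )
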