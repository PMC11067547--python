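"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcpoct import (
    apply_normalization,
    build_normative,
    extract_cohort,
    simulate_cohort,
    table2_scenario,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

ZERO_SDS = {"patient": 0.0, "visit": 0.0, "grid_point": 0.0, "residual": 0.0}


def small_config(**overrides):
    """Desk-scale cohort for unit tests: 7 AMD eyes, 4 controls, 64 px maps."""
    base = dict(
        n_patients_amd=6, n_eyes_amd=7, n_controls=4, n_visits_max=2,
        map_size_px=64,
    )
    base.update(overrides)
    return table2_scenario(seed=base.pop("seed", 11), **base)


def noise_free_config(**overrides):
    """All variance components and measurement noise switched off."""
    return small_config(
        random_effect_sds=dict(ZERO_SDS),
        random_effect_sds_intervisit=dict(ZERO_SDS),
        thickness_noise_sd_um=0.0,
        landmark_noise_sd_deg=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return extract_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_table):
    return apply_normalization(tiny_table, build_normative(tiny_table))


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_disc_mean(map2d, geometry, center_deg, diameter_deg):
    """Disc mean by explicit per-pixel enumeration over the whole map."""
    cx = geometry.fovea_px[0] + center_deg[0] * geometry.px_per_deg
    cy = geometry.fovea_px[1] + center_deg[1] * geometry.px_per_deg
    r = 0.5 * diameter_deg * geometry.px_per_deg
    total, count = 0.0, 0
    for row in range(geometry.shape[0]):
        for col in range(geometry.shape[1]):
            if (row - cy) ** 2 + (col - cx) ** 2 <= r * r:
                v = float(map2d[row, col])
                if math.isfinite(v):
                    total += v
                    count += 1
    return (total / count if count else float("nan")), count


def brute_disc_fraction(mask, geometry, center_deg, diameter_deg):
    """Covered fraction of disc pixels by explicit enumeration."""
    cx = geometry.fovea_px[0] + center_deg[0] * geometry.px_per_deg
    cy = geometry.fovea_px[1] + center_deg[1] * geometry.px_per_deg
    r = 0.5 * diameter_deg * geometry.px_per_deg
    inside, covered = 0, 0
    for row in range(geometry.shape[0]):
        for col in range(geometry.shape[1]):
            if (row - cy) ** 2 + (col - cx) ** 2 <= r * r:
                inside += 1
                if mask[row, col]:
                    covered += 1
    return (covered / inside if inside else float("nan")), inside


def fit_similarity_numerically(src, dst, weights):
    """Similarity fit via a generic numerical optimizer (oracle for the
    closed-form estimator)."""
    from scipy import optimize

    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    w = np.asarray(weights, float)

    def loss(params):
        s, th, tx, ty = params
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mapped = src @ (s * R).T + [tx, ty]
        return float((w * ((mapped - dst) ** 2).sum(axis=1)).sum())

    best = None
    for th0 in (-2.0, 0.0, 2.0):
        res = optimize.minimize(loss, [1.0, th0, 0.0, 0.0],
                                method="Nelder-Mead",
                                options=dict(xatol=1e-12, fatol=1e-14,
                                             maxiter=5000, maxfev=5000))
        if best is None or res.fun < best.fun:
            best = res
    s, th, tx, ty = best.x
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return s * R, np.array([tx, ty])
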