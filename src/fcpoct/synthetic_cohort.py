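"""Synthetic control + AMD cohort generator.

Emulates the study design end to end: a control cohort that defines the
normative reference, an AMD cohort (default 54 eyes of 49 patients, up to 4
annual visits) with structural lesions obeying the consensus size
definitions (PED basal diameter >= 1000 um and height >= 200 um; cRORA
extent >= 250 um; iRORA < 250 um), per-visit en-face layer-thickness maps
coupled to those lesions, landmark sets in the OCT and FCP frames related
by a known similarity transform plus click noise, and point-wise mesopic /
scotopic sensitivities drawn from the same linear mixed-effect structure
the analysis stage fits.

The generative model for the sensitivity of eye i, visit j, grid point k is

    y_ijk = m_k + b0 + b_age age_i + b_pseudo pseudo_i
            + sum_b beta_b presence_b(i, j, k) + u_i + v_ij + w_k + e_ijk

truncated to the device range, where m_k is the normative sensitivity
profile and the presence flags are the *graded* flags produced by the
extraction module from the rasterized lesion masks (closing the loop so
that grading conventions cannot bias parameter recovery).  In longitudinal
mode, later visits evolve from the baseline by the inter-visit change
model, with biomarker flags and layer z-scores taken at the earlier visit.

Default fixed effects are the published cross-sectional and inter-visit
coefficient sets; default variance components are package choices (the
source study does not report them) and are fully configurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    BIOMARKERS,
    ConfigError,
    EyeRecord,
    LAYERS,
    Lesion,
    LesionSet,
    MapGeometry,
    MICRONS_PER_DEGREE,
    PED_MIN_DIAMETER_UM,
    PED_MIN_HEIGHT_UM,
    RORA_EXTENT_THRESHOLD_UM,
    StimulusGrid,
    ThicknessStack,
    Transform2D,
    VisitRecord,
)
from .normalization import NormativeReference, build_normative
from .pointwise_extraction import (
    DEFAULT_MIN_FRACTION,
    default_grid,
    sample_stimuli,
)

# ---------------------------------------------------------------------------
# published coefficient sets used as generator defaults (dB)
# ---------------------------------------------------------------------------

#: Cross-sectional fixed effects per modality.
TABLE2_EFFECTS: dict[str, dict[str, float]] = {
    "mesopic": {
        "intercept": 5.06, "age": -0.09, "pseudophakic": -0.30,
        "flag_subrpe_drusen": -0.22, "flag_sdd": -0.38, "flag_ped": -1.30,
        "flag_vitelliform": -0.97, "flag_hrf": -0.89, "flag_refractile": -0.63,
        "flag_irora": -0.66, "flag_crora": -1.35,
    },
    "scotopic": {
        "intercept": 1.52, "age": -0.04, "pseudophakic": 0.03,
        "flag_subrpe_drusen": -0.18, "flag_sdd": -0.37, "flag_ped": -1.23,
        "flag_vitelliform": -0.66, "flag_hrf": -0.87, "flag_refractile": 0.37,
        "flag_irora": -0.86, "flag_crora": 0.47,
    },
}

#: Inter-visit change fixed effects per modality (dB per year for the time
#: term, dB per z-unit for the layer slopes).  The scotopic time-between-
#: visits coefficient uses the value implied by its reported CI and P.
TABLE3_EFFECTS: dict[str, dict[str, float]] = {
    "mesopic": {
        "intercept": 2.65, "age": -0.04, "years_elapsed": -0.49,
        "pseudophakic": 0.72,
        "flag_subrpe_drusen": 0.12, "flag_sdd": 0.03, "flag_ped": 0.74,
        "flag_vitelliform": 0.52, "flag_hrf": -0.07, "flag_refractile": -0.13,
        "flag_irora": 0.94, "flag_crora": -0.24,
        "z_RNFL": -0.07, "z_GCL": -0.03, "z_IPL": -0.01, "z_INL": 0.06,
        "z_OPL": 0.02, "z_ONL": 0.07, "z_IS": -0.001, "z_OS": 0.002,
        "z_RPEDC": -0.046,
    },
    "scotopic": {
        "intercept": 10.71, "age": -0.15, "years_elapsed": 0.13,
        "pseudophakic": 0.21,
        "flag_subrpe_drusen": -0.30, "flag_sdd": -0.06, "flag_ped": 0.40,
        "flag_vitelliform": 1.17, "flag_hrf": 0.65, "flag_refractile": -3.50,
        "flag_irora": 0.95, "flag_crora": -2.15,
        "z_RNFL": -0.01, "z_GCL": 0.04, "z_IPL": -0.02, "z_INL": 0.02,
        "z_OPL": 0.02, "z_ONL": 0.003, "z_IS": -0.0001, "z_OS": -0.01,
        "z_RPEDC": -0.0002,
    },
}

#: Which thickness layer each lesion type perturbs, and how.
_BUMP_LAYER = {
    "subrpe_drusen": "RPEDC", "ped": "RPEDC", "refractile": "RPEDC",
    "sdd": "OS", "vitelliform": "OS",
}
#: Atrophy thinning factors applied to ONL / OS / RPEDC inside the mask.
_ATROPHY_FACTOR = {"crora": 0.35, "irora": 0.7}
_ATROPHY_LAYERS = ("ONL", "OS", "RPEDC")

#: Per-eye thickness offset SDs (um); these are what the control cohort's
#: per-position SDs — and hence the z-score scale — derive from.  The RPEDC
#: value matches the reported ~1.98 um per normative SD.
DEFAULT_THICKNESS_OFFSET_SDS: dict[str, float] = {
    "RNFL": 2.0, "GCL": 3.0, "IPL": 2.5, "INL": 2.0, "OPL": 2.5,
    "ONL": 5.0, "IS": 1.5, "OS": 2.0, "RPEDC": 1.98,
}


@dataclass
class LesionParams:
    """Placement, size and growth rules for one biomarker."""

    prevalence: float            # P(an AMD eye carries the biomarker)
    count_range: tuple[int, int]  # lesions per carrier eye, uniform inclusive
    diameter_um: tuple[float, float]
    height_um: tuple[float, float] | None = None
    growth_um_per_year: float = 0.0
    onset: str = "baseline"      # "baseline" | "followup"

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("lesion prevalence must be in [0, 1]")
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ConfigError("invalid lesion count range")
        if self.diameter_um[0] <= 0 or self.diameter_um[1] < self.diameter_um[0]:
            raise ConfigError("invalid lesion diameter range")
        if self.onset not in ("baseline", "followup"):
            raise ConfigError(f"unknown lesion onset {self.onset!r}")


def default_lesion_params() -> dict[str, LesionParams]:
    return {
        "subrpe_drusen": LesionParams(0.95, (5, 20), (125.0, 500.0),
                                      (25.0, 75.0), 20.0),
        "sdd": LesionParams(0.30, (5, 15), (100.0, 300.0), (20.0, 40.0), 10.0),
        "ped": LesionParams(0.30, (1, 2), (1000.0, 2500.0), (200.0, 400.0),
                            100.0),
        "hrf": LesionParams(0.50, (2, 8), (40.0, 120.0), None, 5.0),
        "vitelliform": LesionParams(0.12, (1, 2), (300.0, 800.0),
                                    (50.0, 150.0), 30.0),
        "refractile": LesionParams(0.10, (1, 3), (100.0, 400.0),
                                   (20.0, 50.0), 10.0),
        "irora": LesionParams(0.25, (1, 3), (120.0, 240.0), None, 30.0),
        "crora": LesionParams(0.25, (1, 2), (250.0, 800.0), None, 200.0,
                              onset="followup"),
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults reproduce the study design."""

    n_patients_amd: int = 49
    n_eyes_amd: int = 54
    n_controls: int = 27
    n_visits_max: int = 4
    visit_interval_months: tuple[float, float] = (12.0, 2.0)  # mean, SD
    age_distribution: tuple[float, float] = (70.7, 9.1)       # AMD, years
    control_age_distribution: tuple[float, float] = (63.4, 8.9)
    pseudophakic_fraction: float = 14.0 / 54.0
    control_pseudophakic_fraction: float = 3.0 / 27.0
    fixed_effects_cross_sectional: dict = field(
        default_factory=lambda: copy.deepcopy(TABLE2_EFFECTS))
    fixed_effects_intervisit: dict = field(
        default_factory=lambda: copy.deepcopy(TABLE3_EFFECTS))
    random_effect_sds: dict = field(default_factory=lambda: {
        "patient": 1.5, "visit": 0.5, "grid_point": 0.8, "residual": 1.5})
    random_effect_sds_intervisit: dict = field(default_factory=lambda: {
        "patient": 0.5, "visit": 0.5, "grid_point": 0.3, "residual": 1.5})
    lesion_params: dict = field(default_factory=default_lesion_params)
    sensitivity_floor_db: float = 0.0
    sensitivity_ceiling_db: float = 20.0
    map_size_px: int = 256
    field_of_view_deg: float = 30.0
    microns_per_degree: float = MICRONS_PER_DEGREE
    normative_mesopic_db: float = 17.0
    normative_scotopic_db: float = 12.0
    normative_slope_db_per_deg: float = -0.15
    thickness_offset_sds_um: dict = field(
        default_factory=lambda: dict(DEFAULT_THICKNESS_OFFSET_SDS))
    thickness_noise_sd_um: float = 1.0
    n_vessels: int = 8
    landmark_noise_sd_deg: float = 0.05
    sensitivity_mode: str = "cross_sectional"  # | "intervisit"
    reader_flip_prob: float = 0.0
    irora_conversion_prob: float = 0.0
    lesion_field_radius_deg: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_patients_amd < 0 or c.n_eyes_amd < 0 or c.n_controls < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if c.n_eyes_amd > 0:
            if c.n_patients_amd == 0:
                raise ConfigError("AMD eyes require at least one patient")
            if c.n_eyes_amd < c.n_patients_amd:
                raise ConfigError("fewer AMD eyes than patients")
            if c.n_eyes_amd > 2 * c.n_patients_amd:
                raise ConfigError("more than 2 eyes per patient")
        if not 1 <= c.n_visits_max <= 5:
            raise ConfigError("n_visits_max must be in [1, 5]")
        if c.sensitivity_floor_db >= c.sensitivity_ceiling_db:
            raise ConfigError("sensitivity floor must be below the ceiling")
        for name, sds in (("random_effect_sds", c.random_effect_sds),
                          ("random_effect_sds_intervisit",
                           c.random_effect_sds_intervisit)):
            for key in ("patient", "visit", "grid_point", "residual"):
                if sds.get(key, 0.0) < 0:
                    raise ConfigError(f"{name}[{key!r}] must be >= 0")
        if c.thickness_noise_sd_um < 0 or c.landmark_noise_sd_deg < 0:
            raise ConfigError("noise SDs must be >= 0")
        if c.sensitivity_mode not in ("cross_sectional", "intervisit"):
            raise ConfigError(f"unknown sensitivity_mode {c.sensitivity_mode!r}")
        lp = c.lesion_params
        for b in lp:
            if b not in BIOMARKERS:
                raise ConfigError(f"unknown biomarker {b!r} in lesion_params")
        if "ped" in lp:
            if lp["ped"].diameter_um[0] < PED_MIN_DIAMETER_UM:
                raise ConfigError(
                    f"PED basal diameter must be >= {PED_MIN_DIAMETER_UM} um")
            h = lp["ped"].height_um
            if h is None or h[0] < PED_MIN_HEIGHT_UM:
                raise ConfigError(
                    f"PED height must be >= {PED_MIN_HEIGHT_UM} um")
        if "crora" in lp and lp["crora"].diameter_um[0] < RORA_EXTENT_THRESHOLD_UM:
            raise ConfigError(
                f"cRORA extent must be >= {RORA_EXTENT_THRESHOLD_UM} um")
        if "irora" in lp and lp["irora"].diameter_um[1] >= RORA_EXTENT_THRESHOLD_UM:
            raise ConfigError(
                f"iRORA extent must be < {RORA_EXTENT_THRESHOLD_UM} um")

    # -- geometry helpers ---------------------------------------------------

    def geometry(self, laterality: str) -> MapGeometry:
        n = self.map_size_px
        return MapGeometry(
            shape=(n, n),
            px_per_deg=n / self.field_of_view_deg,
            fovea_px=((n - 1) / 2.0, (n - 1) / 2.0),
            laterality=laterality,
        )

    def um_to_deg(self, um: float) -> float:
        return um / self.microns_per_degree

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = copy.deepcopy(d)
        if "lesion_params" in d:
            d["lesion_params"] = {
                b: lp if isinstance(lp, LesionParams) else LesionParams(
                    prevalence=lp["prevalence"],
                    count_range=tuple(lp["count_range"]),
                    diameter_um=tuple(lp["diameter_um"]),
                    height_um=tuple(lp["height_um"])
                    if lp.get("height_um") else None,
                    growth_um_per_year=lp.get("growth_um_per_year", 0.0),
                    onset=lp.get("onset", "baseline"),
                )
                for b, lp in d["lesion_params"].items()
            }
        for key in ("visit_interval_months", "age_distribution",
                    "control_age_distribution"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def table2_scenario(seed: int = 1, **overrides) -> CohortConfig:
    """Default cross-sectional scenario with the published effect set."""
    overrides.setdefault("sensitivity_mode", "cross_sectional")
    return CohortConfig(seed=seed, **overrides)


def table3_scenario(seed: int = 1, **overrides) -> CohortConfig:
    """Default longitudinal scenario driven by the inter-visit change model."""
    overrides.setdefault("sensitivity_mode", "intervisit")
    return CohortConfig(seed=seed, **overrides)


@dataclass
class Cohort:
    """Generated study cohort: eyes, per-visit artifacts, and the truth."""

    config: CohortConfig
    grid: StimulusGrid
    eyes: list
    visits: dict
    normative_thickness: NormativeReference | None = None
    true_transforms: dict = field(default_factory=dict)  # (eye_id, visit) -> fcp->oct
    truth: pd.DataFrame | None = None

    @property
    def control_eyes(self):
        return [e for e in self.eyes if e.group == "control"]

    @property
    def amd_eyes(self):
        return [e for e in self.eyes if e.group == "amd"]


# ---------------------------------------------------------------------------
# thickness model
# ---------------------------------------------------------------------------

def baseline_thickness(layer: str, r_deg: np.ndarray) -> np.ndarray:
    """Smooth radial baseline profile (um) of each layer around the fovea."""
    r = np.asarray(r_deg, dtype=float)
    if layer == "RNFL":
        return 4.0 + 1.2 * r
    if layer == "GCL":
        return 10.0 + 28.0 * np.exp(-((r - 3.5) / 2.0) ** 2)
    if layer == "IPL":
        return 18.0 + 16.0 * np.exp(-((r - 3.0) / 2.5) ** 2)
    if layer == "INL":
        return 14.0 + 20.0 * np.exp(-((r - 2.5) / 2.0) ** 2)
    if layer == "OPL":
        return 24.0 + 6.0 * np.exp(-((r - 2.0) / 2.5) ** 2)
    if layer == "ONL":
        return 55.0 + 35.0 * np.exp(-((r / 2.5) ** 2))
    if layer == "IS":
        return np.maximum(30.0 - 0.4 * r, 5.0)
    if layer == "OS":
        return np.maximum(36.0 - 1.0 * r, 10.0)
    if layer == "RPEDC":
        return np.maximum(30.0 - 0.3 * r, 5.0)
    raise ValueError(f"unknown layer {layer!r}")


def _radius_grid(geometry: MapGeometry) -> np.ndarray:
    nrow, ncol = geometry.shape
    fx, fy = geometry.fovea_px
    x = (np.arange(ncol) - fx) / geometry.px_per_deg
    y = (np.arange(nrow) - fy) / geometry.px_per_deg
    return np.hypot(x[None, :], y[:, None])


_BASELINE_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _baseline_maps(geometry: MapGeometry) -> dict[str, np.ndarray]:
    """Baseline per-layer maps, cached per geometry (radially symmetric, so
    identical for both lateralities)."""
    key = (geometry.shape, round(geometry.px_per_deg, 12), geometry.fovea_px)
    if key not in _BASELINE_CACHE:
        r = _radius_grid(geometry)
        _BASELINE_CACHE[key] = {
            layer: baseline_thickness(layer, r) for layer in LAYERS
        }
        if len(_BASELINE_CACHE) > 8:
            _BASELINE_CACHE.pop(next(iter(_BASELINE_CACHE)))
    return _BASELINE_CACHE[key]


def _bump(geometry: MapGeometry, center_deg, radius_deg: float,
          height: float) -> tuple[slice, slice, np.ndarray]:
    """Raised-cosine bump of peak ``height`` and support ``radius_deg``."""
    cx, cy = geometry.deg_to_px(np.asarray(center_deg, dtype=float))[0]
    r_px = radius_deg * geometry.px_per_deg
    nrow, ncol = geometry.shape
    lo_r = max(int(np.floor(cy - r_px)), 0)
    hi_r = min(int(np.ceil(cy + r_px)) + 1, nrow)
    lo_c = max(int(np.floor(cx - r_px)), 0)
    hi_c = min(int(np.ceil(cx + r_px)) + 1, ncol)
    if lo_r >= hi_r or lo_c >= hi_c:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    rr = np.arange(lo_r, hi_r) - cy
    cc = np.arange(lo_c, hi_c) - cx
    dist = np.hypot(rr[:, None], cc[None, :]) / r_px
    prof = np.where(dist <= 1.0, height * 0.5 * (1.0 + np.cos(np.pi * dist)),
                    0.0)
    return slice(lo_r, hi_r), slice(lo_c, hi_c), prof


def _disc_mask(geometry: MapGeometry, center_deg, radius_deg: float,
               out: np.ndarray) -> None:
    cx, cy = geometry.deg_to_px(np.asarray(center_deg, dtype=float))[0]
    r_px = radius_deg * geometry.px_per_deg
    nrow, ncol = geometry.shape
    lo_r = max(int(np.floor(cy - r_px)), 0)
    hi_r = min(int(np.ceil(cy + r_px)) + 1, nrow)
    lo_c = max(int(np.floor(cx - r_px)), 0)
    hi_c = min(int(np.ceil(cx + r_px)) + 1, ncol)
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    rr = np.arange(lo_r, hi_r) - cy
    cc = np.arange(lo_c, hi_c) - cx
    out[lo_r:hi_r, lo_c:hi_c] |= (
        rr[:, None] ** 2 + cc[None, :] ** 2 <= r_px**2
    )


def rasterize_lesions(
    lesions: dict[str, list[Lesion]], geometry: MapGeometry,
    microns_per_degree: float = MICRONS_PER_DEGREE,
) -> LesionSet:
    """Union of per-lesion discs per biomarker; iRORA is carved disjoint
    from cRORA (complete atrophy supersedes incomplete at the same site)."""
    masks = {}
    for b in BIOMARKERS:
        m = np.zeros(geometry.shape, dtype=bool)
        for lesion in lesions.get(b, []):
            _disc_mask(geometry, lesion.center_deg,
                       0.5 * lesion.diameter_um / microns_per_degree, m)
        masks[b] = m
    masks["irora"] &= ~masks["crora"]
    return LesionSet(masks=masks, lesions={b: list(lesions.get(b, []))
                                           for b in BIOMARKERS},
                     geometry=geometry)


def simulate_thickness_stack(
    eye: EyeRecord,
    lesions: LesionSet,
    config: CohortConfig,
    rng: np.random.Generator,
    offsets: dict[str, float] | None = None,
) -> ThicknessStack:
    """Per-layer maps: radial baseline + eye offset + lesion coupling + noise.

    PED / drusen / refractile deposits raise the RPE-drusen complex, SDD and
    vitelliform material raise the outer segments, and atrophic lesions thin
    ONL / OS / RPEDC inside their mask.  All thicknesses are clipped at 0.
    """
    geometry = lesions.geometry
    if offsets is None:
        offsets = {
            layer: rng.normal(0.0, config.thickness_offset_sds_um[layer])
            for layer in LAYERS
        }
    base_maps = _baseline_maps(geometry)
    layers = {layer: base_maps[layer] + offsets[layer] for layer in LAYERS}
    for b, layer in _BUMP_LAYER.items():
        for lesion in lesions.lesions.get(b, []):
            if lesion.height_um is None:
                continue
            radius_deg = 0.5 * lesion.diameter_um / config.microns_per_degree
            rs, cs, prof = _bump(geometry, lesion.center_deg, radius_deg,
                                 lesion.height_um)
            layers[layer][rs, cs] += prof
    for b, factor in _ATROPHY_FACTOR.items():
        mask = lesions.mask(b)
        if mask.any():
            for layer in _ATROPHY_LAYERS:
                layers[layer][mask] *= factor
    noise_sd = config.thickness_noise_sd_um
    for layer in LAYERS:
        arr = layers[layer]
        if noise_sd > 0:
            arr = arr + noise_sd * rng.standard_normal(
                geometry.shape, dtype=np.float32)
        layers[layer] = np.maximum(arr, 0.0).astype(np.float32)
    return ThicknessStack(layers=layers, geometry=geometry)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def simulate_landmarks(
    eye: EyeRecord,
    true_transform: Transform2D,
    n_vessels: int,
    noise_sd_deg: float,
    rng: np.random.Generator,
) -> tuple["LandmarkSet", "LandmarkSet"]:
    """OCT-frame landmarks plus their (noisy) images in the FCP frame.

    ``true_transform`` maps OCT coordinates to FCP coordinates; the FCP
    landmark of each OCT landmark is its transform image plus isotropic
    Gaussian click noise of SD ``noise_sd_deg``.
    """
    from .core import LandmarkSet

    if n_vessels < 2:
        raise ConfigError("need at least 2 vessel bifurcations")
    disc_x = -15.5 if eye.laterality == "left" else 15.5
    fovea = np.zeros(2)
    disc = np.array([disc_x, -1.5])
    radius = rng.uniform(4.0, 13.0, n_vessels)
    angle = rng.uniform(0.0, 2.0 * np.pi, n_vessels)
    vessels = np.column_stack([radius * np.cos(angle),
                               radius * np.sin(angle)])
    oct_pts = np.vstack([fovea, disc, vessels])
    fcp_pts = true_transform.apply(oct_pts)
    if noise_sd_deg > 0:
        fcp_pts = fcp_pts + rng.normal(0.0, noise_sd_deg, fcp_pts.shape)
    lm_oct = LandmarkSet(
        frame_id="oct", fovea=oct_pts[0], optic_disc=oct_pts[1],
        vessel_bifurcations=oct_pts[2:], laterality=eye.laterality,
    )
    lm_fcp = LandmarkSet(
        frame_id="fcp", fovea=fcp_pts[0], optic_disc=fcp_pts[1],
        vessel_bifurcations=fcp_pts[2:], laterality=eye.laterality,
    )
    return lm_oct, lm_fcp


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _normative_sensitivity(config: CohortConfig, modality: str,
                           radius_deg: np.ndarray) -> np.ndarray:
    base = (config.normative_mesopic_db if modality == "mesopic"
            else config.normative_scotopic_db)
    return base + config.normative_slope_db_per_deg * np.asarray(radius_deg)


def _draw_true_transform(rng: np.random.Generator) -> Transform2D:
    """OCT->FCP acquisition transform: mild resize, rotation and shift."""
    return Transform2D.similarity(
        scale=rng.uniform(0.97, 1.03),
        rotation_deg=rng.uniform(-2.0, 2.0),
        translation=rng.uniform(-0.5, 0.5, 2),
    )


def _draw_lesions(config: CohortConfig, rng: np.random.Generator):
    """Baseline lesion inventory for one AMD eye.

    Returns (lesions, crora_onset): lesion lists keyed by biomarker plus the
    visit index at which each cRORA lesion appears.
    """
    inventory: dict[str, list[Lesion]] = {b: [] for b in BIOMARKERS}
    crora_onset: list[int] = []
    field_r = config.lesion_field_radius_deg
    for b in BIOMARKERS:
        params = config.lesion_params.get(b)
        if params is None:
            continue
        if rng.random() >= params.prevalence:
            continue
        count = int(rng.integers(params.count_range[0],
                                 params.count_range[1] + 1))
        for _ in range(count):
            rad = field_r * np.sqrt(rng.random())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            center = (rad * np.cos(ang), rad * np.sin(ang))
            diameter = rng.uniform(*params.diameter_um)
            height = (rng.uniform(*params.height_um)
                      if params.height_um is not None else None)
            inventory[b].append(Lesion(b, center, diameter, height))
            if b == "crora":
                if params.onset == "followup" and config.n_visits_max > 1:
                    crora_onset.append(int(rng.integers(1, config.n_visits_max)))
                else:
                    crora_onset.append(0)
    return inventory, crora_onset


def _grown_lesions(config: CohortConfig, inventory, crora_onset,
                   visit_index: int, years: float):
    """Lesion inventory at a follow-up time, with diameter growth."""
    out: dict[str, list[Lesion]] = {}
    for b, lesions in inventory.items():
        params = config.lesion_params.get(b)
        grown = []
        for i, lesion in enumerate(lesions):
            if b == "crora" and visit_index < crora_onset[i]:
                continue
            d = lesion.diameter_um
            if params is not None:
                d = d + params.growth_um_per_year * years
            if b == "irora":
                # incomplete atrophy stays below the completeness threshold
                d = min(d, RORA_EXTENT_THRESHOLD_UM - 1.0)
            grown.append(Lesion(b, lesion.center_deg, d, lesion.height_um))
        out[b] = grown
    return out


def _truth_extract(config, grid, stack, lesions, transform_fcp_to_oct):
    """Graded flags and per-layer disc means at the true stimulus positions.

    The fovea-tracked grid sits on the true FCP fovea image, so the true
    OCT-frame stimulus positions are the grid centers through the linear
    part of the FCP->OCT transform (fovea maps to fovea).
    """
    centers = grid.centers @ transform_fcp_to_oct.A.T
    eff_diameter = grid.extraction_diameter_deg * transform_fcp_to_oct.scale
    thick, flags, _, _ = sample_stimuli(stack, lesions, centers, eff_diameter,
                                        DEFAULT_MIN_FRACTION)
    return flags, thick


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    grid = default_grid()
    grid_radius = np.hypot(grid.centers[:, 0], grid.centers[:, 1])
    floor, ceil = config.sensitivity_floor_db, config.sensitivity_ceiling_db
    sds = config.random_effect_sds
    modalities = ("mesopic", "scotopic")

    eyes: list[EyeRecord] = []
    visits: dict[str, list[VisitRecord]] = {}
    true_transforms: dict = {}
    truth_rows: list[dict] = []

    def _clip(y):
        clipped = np.clip(y, floor, ceil)
        return clipped, (y < floor) | (y > ceil)

    # ---- controls ---------------------------------------------------------
    w_ctrl = {m: rng.normal(0.0, sds["grid_point"], grid.n_points)
              for m in modalities}
    control_truth_rows = []
    for i in range(config.n_controls):
        eye = EyeRecord(
            patient_id=f"C{i + 1:03d}", eye_id=f"C{i + 1:03d}",
            laterality="left" if rng.random() < 0.5 else "right",
            age_at_baseline=float(np.clip(
                rng.normal(*config.control_age_distribution), 40.0, 95.0)),
            pseudophakic=bool(rng.random()
                              < config.control_pseudophakic_fraction),
            group="control",
        )
        eyes.append(eye)
        t_true = _draw_true_transform(rng)
        lm_oct, lm_fcp = simulate_landmarks(
            eye, t_true, config.n_vessels, config.landmark_noise_sd_deg, rng)
        geometry = config.geometry(eye.laterality)
        lesions = LesionSet.empty(geometry)
        stack = simulate_thickness_stack(eye, lesions, config, rng)
        sens = {}
        cens = {}
        for m in modalities:
            y = (_normative_sensitivity(config, m, grid_radius)
                 + rng.normal(0.0, sds["patient"])
                 + rng.normal(0.0, sds["visit"])
                 + w_ctrl[m]
                 + rng.normal(0.0, sds["residual"], grid.n_points))
            sens[m], cens[m] = _clip(y)
        visit = VisitRecord(
            eye_id=eye.eye_id, visit_index=0, months_since_baseline=0.0,
            nd_filter=2.0, thickness_stack=stack, lesion_set=lesions,
            landmarks_oct=lm_oct, landmarks_fcp=lm_fcp,
            mesopic_db=sens["mesopic"], scotopic_db=sens["scotopic"],
            mesopic_censored=cens["mesopic"],
            scotopic_censored=cens["scotopic"],
        )
        visits[eye.eye_id] = [visit]
        t_fcp_to_oct = t_true.inverse()
        true_transforms[(eye.eye_id, 0)] = t_fcp_to_oct
        _, thick = _truth_extract(config, grid, stack, lesions, t_fcp_to_oct)
        for k in range(grid.n_points):
            control_truth_rows.append({
                "eye_id": eye.eye_id, "group": "control", "grid_index": k,
                "valid": bool(np.all(np.isfinite(thick[k]))),
                "mesopic_db": sens["mesopic"][k],
                "scotopic_db": sens["scotopic"][k],
                **{f"thk_{layer}": thick[k, j]
                   for j, layer in enumerate(LAYERS)},
            })

    normative_thickness = None
    if config.n_controls >= 2:
        normative_thickness = build_normative(pd.DataFrame(control_truth_rows))
    elif config.sensitivity_mode == "intervisit" and config.n_eyes_amd > 0:
        raise ConfigError(
            "intervisit mode needs >= 2 controls for the internal z-score "
            "reference")

    # ---- AMD eyes ---------------------------------------------------------
    n_bilateral = config.n_eyes_amd - config.n_patients_amd
    eye_specs = []
    for p in range(config.n_patients_amd):
        pid = f"P{p + 1:03d}"
        age = float(np.clip(rng.normal(*config.age_distribution), 40.0, 95.0))
        sides = (["right", "left"] if p < n_bilateral
                 else [rng.choice(["left", "right"])])
        for side in sides:
            eye_specs.append((pid, age, side))
    eye_specs = eye_specs[: config.n_eyes_amd]

    w_amd = {m: rng.normal(0.0, sds["grid_point"], grid.n_points)
             for m in modalities}
    sds_iv = config.random_effect_sds_intervisit
    w_iv = {m: rng.normal(0.0, sds_iv["grid_point"], grid.n_points)
            for m in modalities}
    u_amd: dict[str, dict[str, float]] = {m: {} for m in modalities}
    u_iv: dict[str, dict[str, float]] = {m: {} for m in modalities}
    v_amd: dict[str, dict[tuple, float]] = {m: {} for m in modalities}
    v_iv: dict[str, dict[tuple, float]] = {m: {} for m in modalities}

    fe_cs = config.fixed_effects_cross_sectional
    fe_iv = config.fixed_effects_intervisit
    flag_cols = [f"flag_{b}" for b in BIOMARKERS]
    z_cols = [f"z_{layer}" for layer in LAYERS]

    for e, (pid, age, side) in enumerate(eye_specs):
        eye = EyeRecord(
            patient_id=pid, eye_id=f"E{e + 1:03d}", laterality=side,
            age_at_baseline=age,
            pseudophakic=bool(rng.random() < config.pseudophakic_fraction),
            group="amd",
        )
        eyes.append(eye)
        for m in modalities:
            if pid not in u_amd[m]:
                u_amd[m][pid] = rng.normal(0.0, sds["patient"])
                u_iv[m][pid] = rng.normal(0.0, sds_iv["patient"])
        offsets = {
            layer: rng.normal(0.0, config.thickness_offset_sds_um[layer])
            for layer in LAYERS
        }
        inventory, crora_onset = _draw_lesions(config, rng)
        months = [0.0]
        for _ in range(1, config.n_visits_max):
            months.append(months[-1] + max(
                rng.normal(*config.visit_interval_months), 6.0))
        geometry = config.geometry(eye.laterality)
        visits[eye.eye_id] = []
        y_latent = {m: None for m in modalities}

        for j in range(config.n_visits_max):
            years = months[j] / 12.0
            lesions = rasterize_lesions(
                _grown_lesions(config, inventory, crora_onset, j, years),
                geometry, config.microns_per_degree)
            stack = simulate_thickness_stack(eye, lesions, config, rng,
                                             offsets=offsets)
            t_true = _draw_true_transform(rng)
            lm_oct, lm_fcp = simulate_landmarks(
                eye, t_true, config.n_vessels, config.landmark_noise_sd_deg,
                rng)
            t_fcp_to_oct = t_true.inverse()
            true_transforms[(eye.eye_id, j)] = t_fcp_to_oct
            flags, thick = _truth_extract(config, grid, stack, lesions,
                                          t_fcp_to_oct)
            if config.reader_flip_prob > 0:
                flip = rng.random(flags.shape) < config.reader_flip_prob
                flags = flags ^ flip
            zscores = np.full_like(thick, np.nan)
            if normative_thickness is not None:
                ref = normative_thickness.table
                for col_j, layer in enumerate(LAYERS):
                    mean = ref[f"thk_{layer}_mean"].to_numpy()
                    sd = ref[f"thk_{layer}_sd"].to_numpy()
                    zscores[:, col_j] = (thick[:, col_j] - mean) / sd

            sens = {}
            cens = {}
            for m in modalities:
                if config.sensitivity_mode == "cross_sectional" or j == 0:
                    beta = fe_cs[m]
                    v_key = (pid, j)
                    if v_key not in v_amd[m]:
                        v_amd[m][v_key] = rng.normal(0.0, sds["visit"])
                    pred = (
                        _normative_sensitivity(config, m, grid_radius)
                        + beta["intercept"]
                        + beta["age"] * age
                        + beta["pseudophakic"] * float(eye.pseudophakic)
                        + flags @ np.array([beta[c] for c in flag_cols])
                        + u_amd[m][pid] + v_amd[m][v_key] + w_amd[m]
                    )
                    y = pred + rng.normal(0.0, sds["residual"], grid.n_points)
                else:
                    gamma = fe_iv[m]
                    v_key = (pid, j)
                    if v_key not in v_iv[m]:
                        v_iv[m][v_key] = rng.normal(0.0, sds_iv["visit"])
                    dyears = (months[j] - months[j - 1]) / 12.0
                    delta = (
                        gamma["intercept"]
                        + gamma["age"] * age
                        + gamma["years_elapsed"] * dyears
                        + gamma["pseudophakic"] * float(eye.pseudophakic)
                        + prev_flags @ np.array([gamma[c] for c in flag_cols])
                        + prev_z @ np.array([gamma[c] for c in z_cols])
                        + u_iv[m][pid] + v_iv[m][v_key] + w_iv[m]
                    )
                    y = (y_latent[m] + delta
                         + rng.normal(0.0, sds_iv["residual"], grid.n_points))
                y_latent[m] = y
                sens[m], cens[m] = _clip(y)

            visits[eye.eye_id].append(VisitRecord(
                eye_id=eye.eye_id, visit_index=j,
                months_since_baseline=float(months[j]), nd_filter=2.0,
                thickness_stack=stack, lesion_set=lesions,
                landmarks_oct=lm_oct, landmarks_fcp=lm_fcp,
                mesopic_db=sens["mesopic"], scotopic_db=sens["scotopic"],
                mesopic_censored=cens["mesopic"],
                scotopic_censored=cens["scotopic"],
            ))
            for k in range(grid.n_points):
                truth_rows.append({
                    "eye_id": eye.eye_id, "patient_id": pid, "visit_index": j,
                    "grid_index": k,
                    **{c: bool(flags[k, jj])
                       for jj, c in enumerate(flag_cols)},
                    **{c: zscores[k, jj] for jj, c in enumerate(z_cols)},
                })
            prev_flags, prev_z = flags, zscores

    truth = pd.DataFrame(truth_rows) if truth_rows else None
    return Cohort(
        config=config, grid=grid, eyes=eyes, visits=visits,
        normative_thickness=normative_thickness,
        true_transforms=true_transforms, truth=truth,
    )
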