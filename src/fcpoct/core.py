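"""Shared domain types for the microperimetry/OCT structure-function pipeline.

Coordinate conventions
----------------------
All retinal positions are fovea-centered visual-field coordinates in degrees,
with ``x`` increasing rightward and ``y`` increasing downward (image
convention).  Pixel grids are indexed ``[row, col]`` with pixel ``(0, 0)`` at
the top-left; a pixel's center maps to degrees via the stack geometry
(``px_per_deg`` scale and fovea pixel).  Left-eye orientation is canonical:
right-eye data are mirrored about the vertical axis through the fovea before
any cross-eye analysis, so the optic disc sits on the nasal (negative-x)
side at roughly (-15.5 deg, -1.5 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: OCT retinal layers, inner to outer.
LAYERS: tuple[str, ...] = (
    "RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "IS", "OS", "RPEDC",
)

#: Structural biomarkers graded at each stimulus position.
BIOMARKERS: tuple[str, ...] = (
    "subrpe_drusen", "sdd", "ped", "hrf",
    "vitelliform", "refractile", "irora", "crora",
)

#: Retinal scale of the emmetropic model eye used for lesion-size
#: constraints (configurable in the generator).
MICRONS_PER_DEGREE: float = 288.0

#: Goldmann stimulus diameters in degrees of visual angle.
GOLDMANN_III_DIAMETER_DEG: float = 0.43  # mesopic stimulus
GOLDMANN_V_DIAMETER_DEG: float = 1.7     # scotopic stimulus

#: Atrophy extent threshold separating incomplete from complete RPE and
#: outer retinal atrophy (iRORA < 250 um <= cRORA).
RORA_EXTENT_THRESHOLD_UM: float = 250.0

#: Minimum PED basal diameter / height.
PED_MIN_DIAMETER_UM: float = 1000.0
PED_MIN_HEIGHT_UM: float = 200.0


class FcpOctError(Exception):
    """Base class for pipeline errors."""


class GeometryError(FcpOctError):
    """Mismatched or invalid map geometry."""


class RegistrationError(FcpOctError):
    """Degenerate or insufficient landmark correspondences."""


class ConfigError(FcpOctError):
    """Invalid cohort or model configuration."""


class NormalizationError(FcpOctError):
    """Control cohort insufficient for a normative reference."""


class ConvergenceError(FcpOctError):
    """Mixed-model optimizer failed to converge."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite point: {p!r}")
    return a


@dataclass(frozen=True)
class MapGeometry:
    """Pixel grid geometry of an en-face map.

    Parameters
    ----------
    shape : (n_rows, n_cols)
    px_per_deg : pixels per degree of visual angle (isotropic).
    fovea_px : (col, row) position of the fovea in pixel units; may be
        fractional.
    laterality : "left" or "right".
    """

    shape: tuple[int, int]
    px_per_deg: float
    fovea_px: tuple[float, float]
    laterality: str = "left"

    def __post_init__(self):
        if self.px_per_deg <= 0:
            raise GeometryError(f"px_per_deg must be > 0, got {self.px_per_deg}")
        if self.laterality not in ("left", "right"):
            raise GeometryError(f"unknown laterality {self.laterality!r}")
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))
        object.__setattr__(
            self, "fovea_px", (float(self.fovea_px[0]), float(self.fovea_px[1]))
        )

    def deg_to_px(self, points_deg: np.ndarray) -> np.ndarray:
        """Map (x, y) degrees to fractional (col, row) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points_deg, dtype=float))
        fx, fy = self.fovea_px
        return pts * self.px_per_deg + np.array([fx, fy])

    def px_to_deg(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        fx, fy = self.fovea_px
        return (pts - np.array([fx, fy])) / self.px_per_deg

    def mirrored(self) -> "MapGeometry":
        """Geometry after a horizontal flip of the underlying array."""
        ncol = self.shape[1]
        fx, fy = self.fovea_px
        lat = "left" if self.laterality == "right" else "right"
        return MapGeometry(self.shape, self.px_per_deg, (ncol - 1 - fx, fy), lat)

    def compatible(self, other: "MapGeometry") -> bool:
        return (
            self.shape == other.shape
            and abs(self.px_per_deg - other.px_per_deg) < 1e-9
            and abs(self.fovea_px[0] - other.fovea_px[0]) < 1e-9
            and abs(self.fovea_px[1] - other.fovea_px[1]) < 1e-9
        )


@dataclass
class ThicknessStack:
    """Per-layer en-face thickness maps (um) sharing one geometry."""

    layers: dict[str, np.ndarray]
    geometry: MapGeometry

    def __post_init__(self):
        for name, arr in self.layers.items():
            arr = np.asarray(arr)
            if arr.shape != self.geometry.shape:
                raise GeometryError(
                    f"layer {name!r} shape {arr.shape} != geometry {self.geometry.shape}"
                )
            finite = arr[np.isfinite(arr)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"layer {name!r} has negative thickness")
            self.layers[name] = arr

    def layer(self, name: str) -> np.ndarray:
        return self.layers[name]


@dataclass(frozen=True)
class Lesion:
    """A single lesion in the OCT frame."""

    biomarker: str
    center_deg: tuple[float, float]
    diameter_um: float
    height_um: float | None = None

    def __post_init__(self):
        if self.biomarker not in BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.biomarker!r}")
        if self.diameter_um <= 0:
            raise ValueError("lesion diameter must be > 0")


@dataclass
class LesionSet:
    """Binary presence masks plus lesion metadata, one entry per biomarker."""

    masks: dict[str, np.ndarray]
    lesions: dict[str, list[Lesion]]
    geometry: MapGeometry

    def __post_init__(self):
        for b in self.masks:
            if b not in BIOMARKERS:
                raise ValueError(f"unknown biomarker {b!r}")
            m = np.asarray(self.masks[b], dtype=bool)
            if m.shape != self.geometry.shape:
                raise GeometryError(
                    f"mask {b!r} shape {m.shape} != geometry {self.geometry.shape}"
                )
            self.masks[b] = m
        for b in BIOMARKERS:
            self.masks.setdefault(b, np.zeros(self.geometry.shape, dtype=bool))
            self.lesions.setdefault(b, [])
        if np.any(self.masks["irora"] & self.masks["crora"]):
            raise ValueError("iRORA and cRORA masks must be disjoint")

    @classmethod
    def empty(cls, geometry: MapGeometry) -> "LesionSet":
        return cls(masks={}, lesions={}, geometry=geometry)

    def mask(self, biomarker: str) -> np.ndarray:
        return self.masks[biomarker]


@dataclass
class LandmarkSet:
    """Registration landmarks in one 2-D frame (degrees, fovea-relative or not).

    The point order used for correspondences is fovea, optic disc, then the
    vessel bifurcations in list order.
    """

    frame_id: str
    fovea: np.ndarray
    optic_disc: np.ndarray
    vessel_bifurcations: np.ndarray
    laterality: str = "left"
    units: str = "deg"

    def __post_init__(self):
        self.fovea = _as_point(self.fovea)
        self.optic_disc = _as_point(self.optic_disc)
        v = np.asarray(self.vessel_bifurcations, dtype=float)
        if v.size == 0:
            v = np.zeros((0, 2))
        v = v.reshape(-1, 2)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite vessel bifurcation coordinates")
        self.vessel_bifurcations = v
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def n_points(self) -> int:
        return 2 + len(self.vessel_bifurcations)

    def points(self) -> np.ndarray:
        """All landmarks stacked: fovea, disc, vessels."""
        return np.vstack([self.fovea, self.optic_disc, self.vessel_bifurcations])

    def default_weights(self, anchor_weight: float = 3.0) -> np.ndarray:
        """Fovea and optic disc weighted as primary anchors."""
        return np.concatenate(
            [[anchor_weight, anchor_weight], np.ones(len(self.vessel_bifurcations))]
        )


@dataclass(frozen=True)
class Transform2D:
    """2-D linear transform x -> A @ x + t.

    ``family`` is "similarity" (A = s R, s > 0, R orthogonal) or "affine"
    (A invertible).  Reflections are rejected for similarity transforms
    unless ``allow_reflection`` is set; eye mirroring is handled explicitly
    upstream, never inside the registration fit.
    """

    A: np.ndarray
    t: np.ndarray
    family: str = "similarity"
    allow_reflection: bool = False

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float).reshape(2, 2)
        t = np.asarray(self.t, dtype=float).reshape(2)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "t", t)
        det = np.linalg.det(A)
        if self.family == "similarity":
            s = np.sqrt(abs(det))
            if s <= 0:
                raise ValueError("similarity transform with zero scale")
            R = A / s
            if not np.allclose(R @ R.T, np.eye(2), atol=1e-6):
                raise ValueError("similarity linear part is not s*R")
            if det < 0 and not self.allow_reflection:
                raise ValueError("reflection not allowed for similarity transform")
        elif self.family == "affine":
            if abs(det) < 1e-12:
                raise ValueError("affine linear part is singular")
        else:
            raise ValueError(f"unknown transform family {self.family!r}")

    @classmethod
    def identity(cls, family: str = "similarity") -> "Transform2D":
        return cls(np.eye(2), np.zeros(2), family=family)

    @classmethod
    def similarity(
        cls, scale: float = 1.0, rotation_deg: float = 0.0,
        translation: Sequence[float] = (0.0, 0.0),
    ) -> "Transform2D":
        th = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(scale * R, np.asarray(translation, dtype=float))

    @property
    def scale(self) -> float:
        """Isotropic scale factor sqrt(|det A|)."""
        return float(np.sqrt(abs(np.linalg.det(self.A))))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.A.T + self.t

    def inverse(self) -> "Transform2D":
        Ainv = np.linalg.inv(self.A)
        return Transform2D(
            Ainv, -Ainv @ self.t, family=self.family,
            allow_reflection=self.allow_reflection,
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "A": self.A.tolist(),
            "t": self.t.tolist(),
            "allow_reflection": self.allow_reflection,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transform2D":
        return cls(
            np.asarray(d["A"], dtype=float), np.asarray(d["t"], dtype=float),
            family=d.get("family", "similarity"),
            allow_reflection=bool(d.get("allow_reflection", False)),
        )


@dataclass
class StimulusGrid:
    """Fovea-centered FCP test-point layout with per-modality stimulus sizes.

    The device grid spans a 10 x 10 degree field (56 points within +/-5 deg)
    centered on the fovea.  ``extraction_diameter_deg`` is the disc diameter
    used for thickness sampling and biomarker grading and defaults to the
    scotopic Goldmann V stimulus.
    """

    centers: np.ndarray
    mesopic_diameter_deg: float = GOLDMANN_III_DIAMETER_DEG
    scotopic_diameter_deg: float = GOLDMANN_V_DIAMETER_DEG
    extraction_diameter_deg: float = GOLDMANN_V_DIAMETER_DEG

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if c.shape[0] != 56:
            raise ValueError(f"stimulus grid must have 56 points, got {c.shape[0]}")
        if np.max(np.abs(c)) > 5.0 + 1e-9:
            raise ValueError("stimulus centers must lie within the 10x10 deg field")
        if np.max(np.abs(c.mean(axis=0))) > 1e-6:
            raise ValueError("stimulus grid centroid must be at the fovea")
        self.centers = c

    @property
    def n_points(self) -> int:
        return len(self.centers)

    def mirrored(self) -> "StimulusGrid":
        flipped = self.centers * np.array([-1.0, 1.0])
        return replace(self, centers=flipped)


@dataclass(frozen=True)
class EyeRecord:
    """One study eye of one participant."""

    patient_id: str
    eye_id: str
    laterality: str
    age_at_baseline: float
    pseudophakic: bool
    group: str  # "control" | "amd"

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.age_at_baseline <= 0:
            raise ValueError("age must be > 0")
        if self.group not in ("control", "amd"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class VisitRecord:
    """All per-visit artifacts of one eye.

    Sensitivities are 56-vectors in dB; values clipped at the device floor
    or ceiling are flagged in the matching ``*_censored`` vector.
    """

    eye_id: str
    visit_index: int
    months_since_baseline: float
    nd_filter: float
    thickness_stack: ThicknessStack
    lesion_set: LesionSet
    landmarks_oct: LandmarkSet
    landmarks_fcp: LandmarkSet
    mesopic_db: np.ndarray
    scotopic_db: np.ndarray
    mesopic_censored: np.ndarray = field(default=None)
    scotopic_censored: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mesopic_db = np.asarray(self.mesopic_db, dtype=float).reshape(-1)
        self.scotopic_db = np.asarray(self.scotopic_db, dtype=float).reshape(-1)
        if len(self.mesopic_db) != 56 or len(self.scotopic_db) != 56:
            raise ValueError("each visit carries 56 mesopic and 56 scotopic values")
        for attr in ("mesopic_censored", "scotopic_censored"):
            v = getattr(self, attr)
            v = np.zeros(56, dtype=bool) if v is None else np.asarray(v, dtype=bool)
            setattr(self, attr, v.reshape(56))
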