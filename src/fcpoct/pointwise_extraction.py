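"""Point-wise sampling of thickness maps and biomarker grading.

Each of the 56 stimulus positions is mapped into the OCT frame and a disc
of the scotopic Goldmann V stimulus size (1.7 deg, configurable) is sampled
on every layer map (arithmetic mean over pixels whose *centers* fall inside
the disc) and every biomarker mask (covered-pixel fraction vs a presence
threshold).  A disc with less than half of its pixels on the map yields an
explicit missing value with a reason code rather than a silent number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BIOMARKERS,
    EyeRecord,
    LAYERS,
    LesionSet,
    MapGeometry,
    StimulusGrid,
    ThicknessStack,
    Transform2D,
    VisitRecord,
)
from .registration import map_stimuli, mirror_to_left

#: Minimum fraction of a stimulus disc that must lie on the map.
MIN_DISC_COVERAGE: float = 0.5

#: Default presence threshold: any mask overlap flags the biomarker,
#: mirroring a reader who flags a lesion seen anywhere within the stimulus.
DEFAULT_MIN_FRACTION: float = 0.0


def default_grid(extraction_diameter_deg: float | None = None) -> StimulusGrid:
    """The packaged 56-point 10 x 10 degree stimulus layout.

    Three concentric, 4-fold-symmetric rings of 12, 20 and 24 points at
    radii 1, 3 and 5 degrees.  The device's exact pattern is not published;
    a measured pattern with 56 points can be substituted via
    :class:`~fcpoct.core.StimulusGrid` or the landmark CSV reader.
    """
    pts = []
    for n, r in ((12, 1.0), (20, 3.0), (24, 5.0)):
        ang = 2.0 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    centers = np.vstack(pts)
    # snap exact axis points so max |coordinate| is exactly the field half-width
    centers[np.abs(centers) < 1e-12] = 0.0
    kwargs = {}
    if extraction_diameter_deg is not None:
        kwargs["extraction_diameter_deg"] = extraction_diameter_deg
    return StimulusGrid(centers=centers, **kwargs)


@dataclass(frozen=True)
class DiscSample:
    """Result of sampling one disc on one map."""

    value: float  # mean thickness (um) or covered fraction; NaN when missing
    n_pixels: int  # pixels contributing to the value
    ok: bool
    reason: str = ""


def _disc_pixels(geometry: MapGeometry, center_deg, diameter_deg: float):
    """Rows/cols of pixels whose centers fall inside the disc.

    Returns (rows, cols, n_inside_disc) where ``n_inside_disc`` counts disc
    lattice pixels regardless of the map bounds (for edge coverage QC).
    """
    cx, cy = geometry.deg_to_px(np.asarray(center_deg, dtype=float))[0]
    r_px = 0.5 * diameter_deg * geometry.px_per_deg
    lo_c, hi_c = math.floor(cx - r_px), math.ceil(cx + r_px)
    lo_r, hi_r = math.floor(cy - r_px), math.ceil(cy + r_px)
    cols = np.arange(lo_c, hi_c + 1)
    rows = np.arange(lo_r, hi_r + 1)
    dc = cols - cx
    dr = rows - cy
    inside = (dr[:, None] ** 2 + dc[None, :] ** 2) <= r_px**2
    n_total = int(inside.sum())
    rr, cc = np.nonzero(inside)
    rr = rows[rr]
    cc = cols[cc]
    nrow, ncol = geometry.shape
    on_map = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
    return rr[on_map], cc[on_map], n_total


def sample_disc_mean(
    map2d: np.ndarray,
    geometry: MapGeometry,
    center_deg,
    diameter_deg: float,
) -> DiscSample:
    """Mean of ``map2d`` over the stimulus disc at ``center_deg``.

    NaN pixels are excluded from the mean but still count toward the disc
    footprint used for the edge-coverage check.
    """
    if diameter_deg <= 0:
        raise ValueError("disc diameter must be > 0")
    center = np.asarray(center_deg, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("disc center must be finite")
    rr, cc, n_total = _disc_pixels(geometry, center, diameter_deg)
    if n_total == 0:
        return DiscSample(np.nan, 0, False, "disc smaller than one pixel")
    if len(rr) < MIN_DISC_COVERAGE * n_total:
        return DiscSample(
            np.nan, len(rr), False,
            f"only {len(rr)}/{n_total} disc pixels on the map",
        )
    vals = np.asarray(map2d)[rr, cc].astype(float)
    valid = np.isfinite(vals)
    if not valid.any():
        return DiscSample(np.nan, 0, False, "all disc pixels missing")
    return DiscSample(float(vals[valid].mean()), int(valid.sum()), True)


def grade_presence(
    mask: np.ndarray,
    geometry: MapGeometry,
    center_deg,
    diameter_deg: float,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> DiscSample:
    """Grade biomarker presence within the stimulus disc.

    ``value`` is the covered fraction (lesion pixels / disc pixels on the
    map); the biomarker is present iff the fraction is >= ``min_fraction``,
    or, with ``min_fraction == 0``, iff there is any overlap.  Use
    :func:`presence_flag` for the boolean.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    sample = sample_disc_mean(
        np.asarray(mask, dtype=float), geometry, center_deg, diameter_deg
    )
    return sample


def presence_flag(sample: DiscSample, min_fraction: float = DEFAULT_MIN_FRACTION) -> bool:
    if not sample.ok:
        return False
    if min_fraction == 0.0:
        return sample.value > 0.0
    return sample.value >= min_fraction


def sample_stimuli(
    stack: ThicknessStack,
    lesions: LesionSet,
    centers_oct: np.ndarray,
    diameter_deg: float,
    min_fraction: float = DEFAULT_MIN_FRACTION,
):
    """Sample all layers and grade all biomarkers at each stimulus disc.

    Computes the disc pixel footprint once per stimulus and reuses it for
    every layer map and lesion mask (numerically identical to calling
    :func:`sample_disc_mean` / :func:`grade_presence` per map).

    Returns ``(thickness, flags, valid, reasons)`` with shapes
    (n, n_layers), (n, n_biomarkers), (n,), and a list of n strings.
    """
    geometry = stack.geometry
    layer_arrays = [np.asarray(stack.layer(layer)) for layer in LAYERS]
    mask_arrays = [np.asarray(lesions.mask(b)) for b in BIOMARKERS]
    n = len(centers_oct)
    thickness = np.full((n, len(LAYERS)), np.nan)
    flags = np.zeros((n, len(BIOMARKERS)), dtype=bool)
    valid = np.zeros(n, dtype=bool)
    reasons = [""] * n
    for k in range(n):
        rr, cc, n_total = _disc_pixels(geometry, centers_oct[k], diameter_deg)
        if n_total == 0 or len(rr) < MIN_DISC_COVERAGE * n_total:
            reasons[k] = (f"only {len(rr)}/{n_total} disc pixels on the map"
                          if n_total else "disc smaller than one pixel")
            continue
        ok = True
        for j, arr in enumerate(layer_arrays):
            vals = arr[rr, cc]
            finite = np.isfinite(vals)
            if finite.all():
                thickness[k, j] = vals.mean(dtype=np.float64)
            elif finite.any():
                thickness[k, j] = vals[finite].mean(dtype=np.float64)
            else:
                reasons[k] = f"{LAYERS[j]}: all disc pixels missing"
                ok = False
        n_on_map = len(rr)
        for j, arr in enumerate(mask_arrays):
            frac = arr[rr, cc].sum() / n_on_map
            flags[k, j] = (frac > 0.0 if min_fraction == 0.0
                           else frac >= min_fraction)
        valid[k] = ok
    return thickness, flags, valid, reasons


#: Fixed column schema of the point-wise observation table.
TABLE_COLUMNS: tuple[str, ...] = (
    "eye_id", "patient_id", "group", "laterality", "visit_index",
    "months_since_baseline", "age_years", "pseudophakic", "grid_index",
    "x_oct_deg", "y_oct_deg", "mesopic_db", "scotopic_db",
    "mesopic_censored", "scotopic_censored",
    *(f"thk_{layer}" for layer in LAYERS),
    *(f"flag_{b}" for b in BIOMARKERS),
    "valid", "invalid_reason",
)


def extract_visit(
    eye: EyeRecord,
    visit: VisitRecord,
    transform: Transform2D,
    grid: StimulusGrid,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    fcp_anchor=None,
) -> pd.DataFrame:
    """One observation row per stimulus position for one visit.

    ``transform`` maps the (left-oriented) FCP frame into the (left-oriented)
    OCT frame; right-eye stacks, masks and landmarks must be mirrored before
    calling (see :func:`extract_cohort` for the composed pipeline step).
    ``fcp_anchor`` is the fovea position in the FCP frame on which the
    fovea-tracked grid is centered (defaults to the frame origin).
    """
    stack = visit.thickness_stack
    lesions = visit.lesion_set
    if not stack.geometry.compatible(lesions.geometry):
        raise ValueError("thickness stack and lesion masks disagree on geometry")
    centers_oct, eff_diameter = map_stimuli(grid, transform, fcp_anchor)
    thickness, flags, valid, reasons = sample_stimuli(
        stack, lesions, centers_oct, eff_diameter, min_fraction
    )
    n = grid.n_points
    data = {
        "eye_id": eye.eye_id,
        "patient_id": eye.patient_id,
        "group": eye.group,
        "laterality": eye.laterality,
        "visit_index": visit.visit_index,
        "months_since_baseline": visit.months_since_baseline,
        "age_years": eye.age_at_baseline,
        "pseudophakic": eye.pseudophakic,
        "grid_index": np.arange(n),
        "x_oct_deg": centers_oct[:, 0],
        "y_oct_deg": centers_oct[:, 1],
        "mesopic_db": visit.mesopic_db,
        "scotopic_db": visit.scotopic_db,
        "mesopic_censored": visit.mesopic_censored,
        "scotopic_censored": visit.scotopic_censored,
    }
    for j, layer in enumerate(LAYERS):
        data[f"thk_{layer}"] = thickness[:, j]
    for j, b in enumerate(BIOMARKERS):
        data[f"flag_{b}"] = flags[:, j]
    data["valid"] = valid
    data["invalid_reason"] = reasons
    return pd.DataFrame(data, columns=list(TABLE_COLUMNS))


def extract_cohort(cohort, grid: StimulusGrid | None = None,
                   min_fraction: float = DEFAULT_MIN_FRACTION,
                   nd_filter: float | None = 2.0) -> pd.DataFrame:
    """Run mirror -> register -> extract over every visit of a cohort.

    The transform is re-estimated per visit from the (possibly noisy)
    landmark correspondences, exactly as it would be on real exported data.
    Scotopic thresholds are only comparable within one neutral-density
    filter, so visits tested with a different filter than ``nd_filter``
    are excluded (pass ``None`` to keep everything).
    """
    from .registration import estimate_transform  # local to avoid cycle noise

    if grid is None:
        grid = default_grid()
    frames = []
    for eye in cohort.eyes:
        # a right eye's grid mirrors with its frames, keeping each
        # sensitivity attached to the same retinal location
        eye_grid = grid if eye.laterality == "left" else mirror_to_left(
            grid, "right"
        )
        for visit in cohort.visits[eye.eye_id]:
            if nd_filter is not None and visit.nd_filter != nd_filter:
                continue
            lm_oct = mirror_to_left(visit.landmarks_oct)
            lm_fcp = mirror_to_left(visit.landmarks_fcp)
            fit = estimate_transform(lm_fcp, lm_oct, family="similarity")
            stack = mirror_to_left(visit.thickness_stack)
            lesions = mirror_to_left(visit.lesion_set)
            oriented = VisitRecord(
                eye_id=visit.eye_id,
                visit_index=visit.visit_index,
                months_since_baseline=visit.months_since_baseline,
                nd_filter=visit.nd_filter,
                thickness_stack=stack,
                lesion_set=lesions,
                landmarks_oct=lm_oct,
                landmarks_fcp=lm_fcp,
                mesopic_db=visit.mesopic_db,
                scotopic_db=visit.scotopic_db,
                mesopic_censored=visit.mesopic_censored,
                scotopic_censored=visit.scotopic_censored,
            )
            frames.append(
                extract_visit(eye, oriented, fit.transform, eye_grid,
                              min_fraction, fcp_anchor=lm_fcp.fovea)
            )
    if not frames:
        return pd.DataFrame(columns=list(TABLE_COLUMNS))
    return pd.concat(frames, ignore_index=True)
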