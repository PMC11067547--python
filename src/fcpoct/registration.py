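"""Landmark-based registration of the FCP frame to the OCT en-face frame.

The microperimeter's fundus image and the OCT en-face maps are related by a
resize-and-align step anchored on the foveal pit, the optic nerve head and
vessel bifurcations.  Correspondences are assumed given in matching order
(clicked point pairs); the transform is estimated by weighted least squares,
in closed form (scaled orthogonal Procrustes) for the similarity family.

Right-eye data are mirrored to left-eye orientation *before* registration,
so reflections are excluded from the similarity fit by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    LandmarkSet,
    LesionSet,
    RegistrationError,
    StimulusGrid,
    ThicknessStack,
    Transform2D,
)

#: Relative weight of the fovea and optic-disc anchors vs each vessel
#: bifurcation in the least-squares fit.
ANCHOR_WEIGHT: float = 3.0


@dataclass(frozen=True)
class TransformFit:
    """Estimated transform plus fit diagnostics."""

    transform: Transform2D
    rms_residual: float
    residuals: np.ndarray  # per-point Euclidean residuals, source order
    n_points: int


def _point_arrays(src, dst, weights):
    if isinstance(src, LandmarkSet):
        src_pts = src.points()
        if weights is None:
            weights = src.default_weights(ANCHOR_WEIGHT)
    else:
        src_pts = np.atleast_2d(np.asarray(src, dtype=float))
    if isinstance(dst, LandmarkSet):
        dst_pts = dst.points()
    else:
        dst_pts = np.atleast_2d(np.asarray(dst, dtype=float))
    if src_pts.shape != dst_pts.shape:
        raise RegistrationError(
            f"mismatched correspondence counts: {src_pts.shape[0]} source vs "
            f"{dst_pts.shape[0]} destination points"
        )
    if weights is None:
        weights = np.ones(len(src_pts))
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if len(weights) != len(src_pts):
        raise RegistrationError("weight vector length does not match point count")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise RegistrationError("weights must be non-negative with positive sum")
    return src_pts, dst_pts, weights


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[-1] <= tol * max(1.0, s[0])


def estimate_transform(
    src,
    dst,
    family: str = "similarity",
    weights: np.ndarray | None = None,
    allow_reflection: bool = False,
) -> TransformFit:
    """Estimate the transform T minimizing sum_i w_i ||T(src_i) - dst_i||^2.

    Parameters
    ----------
    src, dst : LandmarkSet or (n, 2) arrays
        Corresponding points, paired in order (fovea-fovea, disc-disc,
        vessel_i-vessel_i).  When landmark sets are given and no explicit
        weights, the fovea and disc receive weight 3 vs 1 per vessel.
    family : "similarity" or "affine"
        Similarity (scale + rotation + translation) is solved in closed form
        via weighted orthogonal Procrustes; affine by weighted least squares
        and needs >= 3 non-collinear pairs.

    Returns
    -------
    TransformFit with the transform, per-point residuals and RMS residual
    (unweighted RMS over all pairs).
    """
    src_pts, dst_pts, w = _point_arrays(src, dst, weights)
    n = len(src_pts)

    if family == "similarity":
        if n < 2:
            raise RegistrationError(
                f"similarity transform needs >= 2 correspondences, got {n}"
            )
        wsum = w.sum()
        mu_s = (w[:, None] * src_pts).sum(axis=0) / wsum
        mu_d = (w[:, None] * dst_pts).sum(axis=0) / wsum
        xc = src_pts - mu_s
        yc = dst_pts - mu_d
        # weighted cross-covariance (dst x src)
        C = (yc * w[:, None]).T @ xc / wsum
        var_s = float((w * (xc**2).sum(axis=1)).sum() / wsum)
        if var_s <= 1e-15:
            raise RegistrationError("source landmarks are coincident")
        U, S, Vt = np.linalg.svd(C)
        d = np.sign(np.linalg.det(U @ Vt))
        if allow_reflection:
            D = np.eye(2)
        else:
            D = np.diag([1.0, d])
        R = U @ D @ Vt
        scale = float((S * np.diag(D)).sum() / var_s)
        if scale <= 0:
            raise RegistrationError("degenerate correspondence: non-positive scale")
        A = scale * R
        t = mu_d - A @ mu_s
        transform = Transform2D(A, t, family="similarity",
                                allow_reflection=allow_reflection)
    elif family == "affine":
        if n < 3:
            raise RegistrationError(
                f"affine transform needs >= 3 correspondences, got {n}"
            )
        if _collinear(src_pts):
            raise RegistrationError(
                "affine transform needs non-collinear source correspondences"
            )
        X = np.hstack([src_pts, np.ones((n, 1))])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw[:, None] * dst_pts,
                                   rcond=None)
        A = coef[:2].T
        t = coef[2]
        transform = Transform2D(A, t, family="affine")
    else:
        raise RegistrationError(f"unknown transform family {family!r}")

    mapped = transform.apply(src_pts)
    residuals = np.linalg.norm(mapped - dst_pts, axis=1)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return TransformFit(transform=transform, rms_residual=rms,
                        residuals=residuals, n_points=n)


def mirror_to_left(data, laterality: str | None = None):
    """Return ``data`` in left-eye orientation.

    Left-eye input is returned unchanged (the same object); right-eye input
    is reflected about the vertical axis through the fovea.  Applies to
    LandmarkSet, StimulusGrid, ThicknessStack and LesionSet.  For objects
    that carry their own laterality the argument may be omitted.
    """
    if laterality is None:
        laterality = getattr(data, "laterality", None)
        if laterality is None and hasattr(data, "geometry"):
            laterality = data.geometry.laterality
    if laterality not in ("left", "right"):
        raise ValueError(f"unknown laterality {laterality!r}")
    if laterality == "left":
        return data

    if isinstance(data, LandmarkSet):
        fx = data.fovea[0]

        def refl(p):
            p = np.atleast_2d(p).copy()
            p[:, 0] = 2.0 * fx - p[:, 0]
            return p

        return LandmarkSet(
            frame_id=data.frame_id,
            fovea=data.fovea.copy(),
            optic_disc=refl(data.optic_disc)[0],
            vessel_bifurcations=refl(data.vessel_bifurcations)
            if len(data.vessel_bifurcations)
            else data.vessel_bifurcations.copy(),
            laterality="left",
            units=data.units,
        )
    if isinstance(data, StimulusGrid):
        return data.mirrored()
    if isinstance(data, ThicknessStack):
        geom = data.geometry.mirrored()
        layers = {k: v[:, ::-1] for k, v in data.layers.items()}
        return ThicknessStack(layers=layers, geometry=geom)
    if isinstance(data, LesionSet):
        geom = data.geometry.mirrored()
        masks = {k: v[:, ::-1] for k, v in data.masks.items()}
        lesions = {
            k: [
                replace(l, center_deg=(-l.center_deg[0], l.center_deg[1]))
                for l in ls
            ]
            for k, ls in data.lesions.items()
        }
        return LesionSet(masks=masks, lesions=lesions, geometry=geom)
    raise TypeError(f"cannot mirror object of type {type(data).__name__}")


def map_stimuli(
    grid: StimulusGrid, transform: Transform2D, fcp_anchor=None
) -> tuple[np.ndarray, float]:
    """Project stimulus centers into the OCT frame.

    The grid is fovea-tracked: when ``fcp_anchor`` (the fovea position in
    the FCP frame, typically the fovea landmark) is given, stimulus k sits
    at ``fcp_anchor + centers[k]`` in the FCP frame before transforming.

    Returns the transformed (56, 2) centers (order preserved) and the
    effective extraction diameter after rescaling by the transform's
    isotropic scale factor.
    """
    if abs(np.linalg.det(transform.A)) < 1e-12:
        raise RegistrationError("cannot map stimuli through a singular transform")
    centers_fcp = grid.centers
    if fcp_anchor is not None:
        centers_fcp = centers_fcp + np.asarray(fcp_anchor, dtype=float)
    centers = transform.apply(centers_fcp)
    if transform.family == "similarity":
        eff_diameter = grid.extraction_diameter_deg * transform.scale
    else:
        # affine: keep nominal stimulus size in degrees
        eff_diameter = grid.extraction_diameter_deg
    return centers, float(eff_diameter)
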