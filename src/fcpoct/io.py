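"""Readers and writers for on-disk artifacts.

Thickness maps and lesion masks are tab-delimited numeric grids (the export
format of the device's en-face analysis), with the map geometry carried in
``#`` comment headers for single-file portability::

    # px_per_deg: 8.533333
    # fovea_px: 127.5 127.5
    # laterality: left
    12.5<TAB>12.6<TAB>...

All other tables are UTF-8 comma-separated CSV with ``.`` decimals.  NaN
cells round-trip as ``nan``.  Errors on malformed grids name the offending
line.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    BIOMARKERS,
    EyeRecord,
    FcpOctError,
    LAYERS,
    LandmarkSet,
    LesionSet,
    MapGeometry,
    ThicknessStack,
    Transform2D,
    VisitRecord,
)
from .normalization import NormativeReference
from .synthetic_cohort import Cohort, CohortConfig


class IOFormatError(FcpOctError):
    """Malformed on-disk artifact."""


# ---------------------------------------------------------------------------
# tab-delimited grids
# ---------------------------------------------------------------------------

def _write_grid(path, array: np.ndarray, geometry: MapGeometry,
                fmt: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# px_per_deg: {geometry.px_per_deg!r}\n")
        fh.write(f"# fovea_px: {geometry.fovea_px[0]!r} "
                 f"{geometry.fovea_px[1]!r}\n")
        fh.write(f"# laterality: {geometry.laterality}\n")
        for row in np.asarray(array):
            fh.write("\t".join(fmt % v if math.isfinite(v) else "nan"
                               for v in row))
            fh.write("\n")


def _read_grid(path) -> tuple[np.ndarray, MapGeometry]:
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    width = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    header[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise IOFormatError(
                    f"{path.name}: ragged row at line {lineno} "
                    f"({len(cells)} cells, expected {width})")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise IOFormatError(
                    f"{path.name}: non-numeric cell at line {lineno}: {exc}"
                ) from None
    if not rows:
        raise IOFormatError(f"{path.name}: no data rows")
    for key in ("px_per_deg", "fovea_px", "laterality"):
        if key not in header:
            raise IOFormatError(f"{path.name}: missing geometry header {key!r}")
    fx, fy = (float(v) for v in header["fovea_px"].split())
    array = np.asarray(rows, dtype=float)
    geometry = MapGeometry(
        shape=array.shape, px_per_deg=float(header["px_per_deg"]),
        fovea_px=(fx, fy), laterality=header["laterality"],
    )
    return array, geometry


def write_thickness_map(path, array: np.ndarray,
                        geometry: MapGeometry) -> None:
    # %.17g guarantees a lossless float64 round trip
    _write_grid(path, np.asarray(array, dtype=float), geometry, "%.17g")


def read_thickness_map(path) -> tuple[np.ndarray, MapGeometry]:
    """Read a single-layer grid; NaN cells are preserved as missing."""
    return _read_grid(path)


def write_mask(path, mask: np.ndarray, geometry: MapGeometry) -> None:
    _write_grid(path, np.asarray(mask, dtype=float), geometry, "%d")


def read_mask(path) -> tuple[np.ndarray, MapGeometry]:
    array, geometry = _read_grid(path)
    if not np.isin(array, (0.0, 1.0)).all():
        raise IOFormatError(f"{Path(path).name}: mask cells must be 0 or 1")
    return array.astype(bool), geometry


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def write_landmarks(path, landmark_sets: list[LandmarkSet]) -> None:
    rows = []
    for lm in landmark_sets:
        rows.append((lm.frame_id, "fovea", 0, lm.fovea[0], lm.fovea[1],
                     lm.units, lm.laterality))
        rows.append((lm.frame_id, "disc", 0, lm.optic_disc[0],
                     lm.optic_disc[1], lm.units, lm.laterality))
        for i, v in enumerate(lm.vessel_bifurcations):
            rows.append((lm.frame_id, "vessel", i, v[0], v[1], lm.units,
                         lm.laterality))
    pd.DataFrame(rows, columns=["frame_id", "landmark_type", "index", "x",
                                "y", "units", "laterality"]).to_csv(
        path, index=False)


def read_landmarks(path) -> dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    out = {}
    for frame_id, g in df.groupby("frame_id"):
        def _one(kind):
            sel = g[g["landmark_type"] == kind]
            if len(sel) != 1:
                raise IOFormatError(
                    f"frame {frame_id!r}: expected exactly one {kind} landmark")
            return sel[["x", "y"]].to_numpy(dtype=float)[0]

        vessels = (g[g["landmark_type"] == "vessel"]
                   .sort_values("index")[["x", "y"]].to_numpy(dtype=float))
        out[str(frame_id)] = LandmarkSet(
            frame_id=str(frame_id), fovea=_one("fovea"),
            optic_disc=_one("disc"), vessel_bifurcations=vessels,
            laterality=str(g["laterality"].iloc[0]),
            units=str(g["units"].iloc[0]),
        )
    return out


# ---------------------------------------------------------------------------
# tables, transforms, configs
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = ("pseudophakic", "valid", "mesopic_censored",
                 "scotopic_censored",
                 *(f"flag_{b}" for b in BIOMARKERS))


def write_pointwise_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_pointwise_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "invalid_reason" in df.columns:
        df["invalid_reason"] = df["invalid_reason"].fillna("")
    return df


def write_normative(path, ref: NormativeReference) -> None:
    long = ref.table.reset_index().melt(
        id_vars="grid_index", var_name="column", value_name="value")
    parts = long["column"].str.rsplit("_", n=1)
    long["quantity"] = parts.str[0]
    long["stat"] = parts.str[1]
    out = long.pivot_table(index=["grid_index", "quantity"], columns="stat",
                           values="value").reset_index()
    out["n_controls"] = ref.n_controls
    out.to_csv(path, index=False)


def read_normative(path) -> NormativeReference:
    df = pd.read_csv(path)
    n_controls = int(df["n_controls"].iloc[0])
    wide = {}
    for _, row in df.iterrows():
        wide.setdefault(int(row["grid_index"]), {})[
            f"{row['quantity']}_mean"] = row["mean"]
        wide[int(row["grid_index"])][f"{row['quantity']}_sd"] = row["sd"]
    table = pd.DataFrame.from_dict(wide, orient="index").sort_index()
    table.index.name = "grid_index"
    return NormativeReference(table=table, n_controls=n_controls)


def write_transform(path, fit_or_transform) -> None:
    if isinstance(fit_or_transform, Transform2D):
        payload = {"transform": fit_or_transform.to_dict()}
    else:
        payload = {
            "transform": fit_or_transform.transform.to_dict(),
            "rms_residual": fit_or_transform.rms_residual,
            "residuals": [float(r) for r in fit_or_transform.residuals],
            "n_points": fit_or_transform.n_points,
        }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_transform(path) -> Transform2D:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return Transform2D.from_dict(payload["transform"])


def write_model_result(path_csv, result, path_json=None) -> None:
    result.to_frame().to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(result.to_dict(), indent=2),
                                   encoding="utf-8")


def read_model_result_frame(path_csv) -> pd.DataFrame:
    return pd.read_csv(path_csv)


def write_config(path, config: CohortConfig) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(config.to_dict()),
                                         sort_keys=False), encoding="utf-8")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_config(path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise IOFormatError(f"{Path(path).name}: config must be a mapping")
    try:
        return CohortConfig.from_dict(data)
    except TypeError as exc:
        raise IOFormatError(f"{Path(path).name}: {exc}") from None


# ---------------------------------------------------------------------------
# whole-cohort round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir, write_maps: bool = True) -> None:
    """Materialize a cohort as the per-visit artifact tree.

    ``write_maps=False`` skips the (large) thickness/mask grids and keeps
    the eye/visit tables, landmarks and sensitivities.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_config(out / "config.yaml", cohort.config)
    eye_rows = []
    for eye in cohort.eyes:
        eye_rows.append({
            "patient_id": eye.patient_id, "eye_id": eye.eye_id,
            "laterality": eye.laterality,
            "age_at_baseline": eye.age_at_baseline,
            "pseudophakic": eye.pseudophakic, "group": eye.group,
        })
    pd.DataFrame(eye_rows).to_csv(out / "eyes.csv", index=False)

    visit_rows = []
    for eye in cohort.eyes:
        for visit in cohort.visits[eye.eye_id]:
            vdir = out / eye.group / eye.eye_id / f"visit_{visit.visit_index}"
            vdir.mkdir(parents=True, exist_ok=True)
            visit_rows.append({
                "eye_id": eye.eye_id, "visit_index": visit.visit_index,
                "months_since_baseline": visit.months_since_baseline,
                "nd_filter": visit.nd_filter,
                "path": str(vdir.relative_to(out)),
            })
            write_landmarks(vdir / "landmarks.csv",
                            [visit.landmarks_oct, visit.landmarks_fcp])
            sens = pd.DataFrame({
                "grid_index": np.arange(56),
                "mesopic_db": visit.mesopic_db,
                "scotopic_db": visit.scotopic_db,
                "mesopic_censored": visit.mesopic_censored,
                "scotopic_censored": visit.scotopic_censored,
            })
            sens.to_csv(vdir / "sensitivities.csv", index=False)
            if write_maps:
                for layer in LAYERS:
                    write_thickness_map(
                        vdir / f"thickness_{layer}.tsv",
                        visit.thickness_stack.layer(layer),
                        visit.thickness_stack.geometry)
                for b in BIOMARKERS:
                    write_mask(vdir / f"mask_{b}.tsv",
                               visit.lesion_set.mask(b),
                               visit.lesion_set.geometry)
    pd.DataFrame(visit_rows).to_csv(out / "visits.csv", index=False)


def read_cohort(in_dir) -> Cohort:
    """Rebuild a cohort from the artifact tree written by write_cohort."""
    root = Path(in_dir)
    config = read_config(root / "config.yaml")
    eyes_df = pd.read_csv(root / "eyes.csv")
    visits_df = pd.read_csv(root / "visits.csv")
    eyes = [
        EyeRecord(
            patient_id=str(r.patient_id), eye_id=str(r.eye_id),
            laterality=str(r.laterality),
            age_at_baseline=float(r.age_at_baseline),
            pseudophakic=bool(r.pseudophakic), group=str(r.group),
        )
        for r in eyes_df.itertuples()
    ]
    visits: dict[str, list[VisitRecord]] = {e.eye_id: [] for e in eyes}
    for r in visits_df.itertuples():
        vdir = root / str(r.path)
        lms = read_landmarks(vdir / "landmarks.csv")
        sens = pd.read_csv(vdir / "sensitivities.csv")
        layers = {}
        geometry = None
        for layer in LAYERS:
            f = vdir / f"thickness_{layer}.tsv"
            if f.exists():
                layers[layer], geometry = read_thickness_map(f)
        masks = {}
        lesion_geometry = geometry
        for b in BIOMARKERS:
            f = vdir / f"mask_{b}.tsv"
            if f.exists():
                masks[b], lesion_geometry = read_mask(f)
        if geometry is None:
            raise IOFormatError(
                f"{vdir}: no thickness maps found (cohort written with "
                f"write_maps=False cannot be re-read as a full cohort)")
        visits[str(r.eye_id)].append(VisitRecord(
            eye_id=str(r.eye_id), visit_index=int(r.visit_index),
            months_since_baseline=float(r.months_since_baseline),
            nd_filter=float(r.nd_filter),
            thickness_stack=ThicknessStack(layers=layers, geometry=geometry),
            lesion_set=LesionSet(masks=masks, lesions={},
                                 geometry=lesion_geometry),
            landmarks_oct=lms["oct"], landmarks_fcp=lms["fcp"],
            mesopic_db=sens["mesopic_db"].to_numpy(),
            scotopic_db=sens["scotopic_db"].to_numpy(),
            mesopic_censored=sens["mesopic_censored"].to_numpy(dtype=bool),
            scotopic_censored=sens["scotopic_censored"].to_numpy(dtype=bool),
        ))
    for eye_id in visits:
        visits[eye_id].sort(key=lambda v: v.visit_index)
    from .pointwise_extraction import default_grid

    return Cohort(config=config, grid=default_grid(), eyes=eyes,
                  visits=visits)
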