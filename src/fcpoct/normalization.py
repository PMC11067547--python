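"""Deviation-from-control normalization of sensitivities and thicknesses.

Sensitivities become point-wise deviations (observed minus the control-cohort
mean at the same grid position; negative = loss, positive = supra-normal).
Layer thicknesses become z-scores against the control mean and sample SD at
the equivalent position.  Control SDs below a small floor are raised to the
floor so that a small control cohort cannot produce exploding z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import LAYERS, NormalizationError

#: Floors applied to per-position control SDs.
SENSITIVITY_SD_FLOOR_DB: float = 0.25
THICKNESS_SD_FLOOR_UM: float = 0.5

MODALITIES: tuple[str, ...] = ("mesopic", "scotopic")


@dataclass
class NormativeReference:
    """Per-grid-position control means/SDs for sensitivities and thicknesses.

    ``table`` is indexed by grid_index with columns ``{modality}_mean``,
    ``{modality}_sd``, ``thk_{layer}_mean``, ``thk_{layer}_sd``.  SDs are
    stored post-floor; ``floored`` marks which (position, quantity) pairs
    were raised.
    """

    table: pd.DataFrame
    n_controls: int
    floored: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.n_controls < 2:
            raise NormalizationError(
                f"a normative reference needs >= 2 controls, got {self.n_controls}"
            )
        if self.floored is None:
            self.floored = pd.DataFrame(
                False, index=self.table.index,
                columns=[c for c in self.table.columns if c.endswith("_sd")],
            )

    def mean(self, grid_index: int, quantity: str) -> float:
        return float(self.table.loc[grid_index, f"{quantity}_mean"])

    def sd(self, grid_index: int, quantity: str) -> float:
        return float(self.table.loc[grid_index, f"{quantity}_sd"])


def build_normative(control_table: pd.DataFrame) -> NormativeReference:
    """Estimate the normative reference from control point-wise observations.

    Every grid position must receive valid observations from at least two
    distinct control eyes; positions failing this raise an error naming them.
    """
    ctl = control_table
    if "group" in ctl.columns:
        ctl = ctl[ctl["group"] == "control"]
    if "valid" in ctl.columns:
        ctl = ctl[ctl["valid"].astype(bool)]
    if ctl.empty:
        raise NormalizationError("no valid control observations")
    n_controls = ctl["eye_id"].nunique()

    counts = ctl.groupby("grid_index")["eye_id"].nunique()
    all_positions = set(range(56))
    bad = sorted(all_positions - set(counts.index)) + sorted(
        counts.index[counts < 2]
    )
    if bad:
        raise NormalizationError(
            "positions with < 2 contributing controls: "
            + ", ".join(str(b) for b in bad)
        )

    quantities = {f"{m}": f"{m}_db" for m in MODALITIES}
    quantities.update({f"thk_{layer}": f"thk_{layer}" for layer in LAYERS})
    floors = {f"{m}": SENSITIVITY_SD_FLOOR_DB for m in MODALITIES}
    floors.update({f"thk_{layer}": THICKNESS_SD_FLOOR_UM for layer in LAYERS})

    grouped = ctl.groupby("grid_index")
    out = {}
    floored = {}
    for qty, col in quantities.items():
        mean = grouped[col].mean()
        sd = grouped[col].std(ddof=1)
        raised = sd < floors[qty]
        out[f"{qty}_mean"] = mean
        out[f"{qty}_sd"] = sd.where(~raised, floors[qty])
        floored[f"{qty}_sd"] = raised
    table = pd.DataFrame(out).sort_index()
    return NormativeReference(
        table=table, n_controls=int(n_controls),
        floored=pd.DataFrame(floored).sort_index(),
    )


def sensitivity_deviation(
    observed_db: float, reference: NormativeReference, grid_index: int,
    modality: str,
) -> float:
    """Observed minus control mean; negative values signify sensitivity loss."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if grid_index not in reference.table.index:
        return float("nan")
    return float(observed_db - reference.mean(grid_index, modality))


def thickness_zscore(
    observed_um: float, reference: NormativeReference, grid_index: int,
    layer: str,
) -> float:
    """(observed - control mean) / control SD at the same position."""
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    if grid_index not in reference.table.index:
        return float("nan")
    sd = reference.sd(grid_index, f"thk_{layer}")
    return float((observed_um - reference.mean(grid_index, f"thk_{layer}")) / sd)


def zscore_inverse(
    z: float, reference: NormativeReference, grid_index: int, layer: str
) -> float:
    """Raw thickness recovered from a z-score (inverse of thickness_zscore)."""
    sd = reference.sd(grid_index, f"thk_{layer}")
    return float(z * sd + reference.mean(grid_index, f"thk_{layer}"))


def apply_normalization(
    table: pd.DataFrame, reference: NormativeReference
) -> pd.DataFrame:
    """Add deviation and z-score columns to a point-wise table (vectorized)."""
    out = table.copy()
    ref = reference.table
    gi = out["grid_index"].to_numpy()
    for m in MODALITIES:
        mean = ref[f"{m}_mean"].reindex(gi).to_numpy()
        out[f"{m}_dev"] = out[f"{m}_db"].to_numpy() - mean
    for layer in LAYERS:
        mean = ref[f"thk_{layer}_mean"].reindex(gi).to_numpy()
        sd = ref[f"thk_{layer}_sd"].reindex(gi).to_numpy()
        out[f"z_{layer}"] = (out[f"thk_{layer}"].to_numpy() - mean) / sd
    return out
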