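"""Raw patch-area normalization: masking, plate, batch and edge steps.

The pipeline is order-dependent and applied plate -> batch -> edge,
then replicate aggregation; each step is a pure multiplicative scaling
so rank order of strains within a plate is preserved by the plate and
batch steps.

* masking: areas <= 2000 pixels (the approximate pin deposition area)
  are unreliable and replaced with missing values, boundary inclusive.
* plate: each plate's multiplicative factor is the geometric mean over
  its 8 founder control patches of (control value / across-plate
  geometric mean of that founder control).  Geometric averaging on the
  log scale is robust to founder-specific growth differences.
* batch: each (batch, condition, timepoint) group is scaled so its
  median matches the global median for that condition + timepoint.
* edge: the model value of an edge well is E(edge, timepoint) x
  C(condition, timepoint); factors are fit by least squares on log
  values of edge wells relative to their plate's interior mean, with
  the first condition as the reference level (C = 1).  Corner wells
  belong to the top/bottom edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import PhenotypeTable
from .simcross import well_edge

DEFAULT_MIN_AREA = 2000.0


@dataclass
class NormalizationModel:
    min_area: float = DEFAULT_MIN_AREA
    plate_factors: dict = field(default_factory=dict)
    batch_factors: dict = field(default_factory=dict)
    edge_factors: dict = field(default_factory=dict)
    condition_edge_factors: dict = field(default_factory=dict)
    n_masked: int = 0
    steps: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "min_area": self.min_area,
            "n_masked": self.n_masked,
            "steps": list(self.steps),
            "plate_factors": {str(k): v for k, v in self.plate_factors.items()},
            "batch_factors": {str(k): v for k, v in self.batch_factors.items()},
            "edge_factors": {str(k): v for k, v in self.edge_factors.items()},
            "condition_edge_factors": {
                str(k): v for k, v in self.condition_edge_factors.items()
            },
        }


def mask_small_patches(
    raw: PhenotypeTable, min_area: float = DEFAULT_MIN_AREA
) -> tuple[PhenotypeTable, NormalizationModel]:
    """Replace pixel areas <= min_area with missing values."""
    values = raw.frame["value"].to_numpy(dtype=float).copy()
    masked = np.isfinite(values) & (values <= min_area)
    values[masked] = np.nan
    model = NormalizationModel(min_area=min_area, n_masked=int(masked.sum()),
                               steps=["mask"])
    return raw.with_values(values, stage="masked"), model


def _gmean(x: np.ndarray) -> float:
    x = x[np.isfinite(x) & (x > 0)]
    if x.size == 0:
        return np.nan
    return float(np.exp(np.mean(np.log(x))))


def normalize_plates(
    table: PhenotypeTable, control_values: pd.DataFrame | None = None
) -> tuple[PhenotypeTable, NormalizationModel]:
    """Divide each plate by its control-estimated multiplicative factor.

    ``control_values`` needs columns plate, strain (the founder control
    id) and value; when omitted, rows flagged by a boolean ``control``
    column of the table itself are used.
    """
    df = table.frame
    if control_values is None:
        if "control" not in df.columns:
            raise ValueError("no control column and no control_values given")
        control_values = df.loc[df["control"], ["plate", "strain", "value"]]
    ctrl = control_values.rename(columns={control_values.columns[1]: "strain"})
    per_plate = (
        ctrl.groupby(["plate", "strain"])["value"]
        .apply(lambda v: _gmean(v.to_numpy(dtype=float)))
        .reset_index(name="value")
    )
    ref = per_plate.groupby("strain")["value"].apply(
        lambda v: _gmean(v.to_numpy())
    )
    per_plate["ratio"] = per_plate["value"] / per_plate["strain"].map(ref)
    factors = {}
    for plate in df["plate"].unique():
        ratios = per_plate.loc[per_plate["plate"] == plate, "ratio"].to_numpy()
        f = _gmean(ratios)
        if not np.isfinite(f):
            warnings.warn(f"plate {plate!r} has no usable controls; factor 1")
            f = 1.0
        factors[plate] = f
    values = df["value"].to_numpy(dtype=float) / df["plate"].map(factors).to_numpy()
    model = NormalizationModel(plate_factors=factors, steps=["plate"])
    return table.with_values(values, stage="plate_normalized"), model


def normalize_batches(
    table: PhenotypeTable,
) -> tuple[PhenotypeTable, NormalizationModel]:
    """Equalize the median value for each condition + timepoint across batches."""
    df = table.frame
    if "batch" not in df.columns:
        raise ValueError("batch ids required for batch normalization")
    global_med = df.groupby(["condition", "timepoint"])["value"].median()
    batch_med = df.groupby(["batch", "condition", "timepoint"])["value"].median()
    factors = {}
    for key, med in batch_med.items():
        g = global_med.loc[key[1:]]
        if not np.isfinite(med) or med <= 0:
            warnings.warn(f"batch group {key} has degenerate median; factor 1")
            factors[key] = 1.0
        else:
            factors[key] = float(g / med)
    mult = np.array(
        [factors.get((b, c, t), 1.0)
         for b, c, t in zip(df["batch"], df["condition"], df["timepoint"])]
    )
    model = NormalizationModel(batch_factors=factors, steps=["batch"])
    return table.with_values(df["value"].to_numpy(float) * mult,
                             stage="batch_normalized"), model


def normalize_edges(
    table: PhenotypeTable,
) -> tuple[PhenotypeTable, NormalizationModel]:
    """Fit and remove edge x condition multiplicative growth effects.

    Per timepoint, the response for each edge well is its log value
    minus the mean log value of the interior wells on its plate; the
    design has one column per edge and one per non-reference condition.
    """
    df = table.frame
    for col in ("well_row", "well_col"):
        if col not in df.columns:
            raise ValueError("well coordinates required for edge normalization")
    edges = np.array(
        [well_edge(int(r), int(c)) if np.isfinite(r) and np.isfinite(c)
         else None
         for r, c in zip(df["well_row"], df["well_col"])],
        dtype=object,
    )
    is_edge = np.array([e is not None for e in edges])
    value = df["value"].to_numpy(dtype=float)
    usable = np.isfinite(value) & (value > 0)
    interior = ~is_edge & usable
    if not interior.any():
        raise ValueError("no interior wells available")
    logv = np.where(usable, np.log(np.where(usable, value, 1.0)), np.nan)
    plate_interior = (
        pd.Series(logv[interior], index=df.index[interior])
        .groupby(df.loc[interior, "plate"])
        .mean()
    )
    edge_names = ["top", "bottom", "left", "right"]
    conditions = list(pd.unique(df["condition"]))
    edge_f: dict = {}
    cond_f: dict = {}
    out = value.copy()
    for tp in pd.unique(df["timepoint"]):
        sel = is_edge & usable & (df["timepoint"] == tp).to_numpy()
        sel &= df["plate"].map(plate_interior).notna().to_numpy()
        if not sel.any():
            continue
        resp = logv[sel] - df.loc[sel, "plate"].map(plate_interior).to_numpy()
        e_idx = np.array([edge_names.index(e) for e in edges[sel]])
        c_idx = np.array([conditions.index(c) for c in df.loc[sel, "condition"]])
        n_cols = 4 + max(len(conditions) - 1, 0)
        X = np.zeros((sel.sum(), n_cols))
        X[np.arange(len(resp)), e_idx] = 1.0
        nonref = c_idx > 0
        X[np.flatnonzero(nonref), 3 + c_idx[nonref]] = 1.0
        beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
        for k, e in enumerate(edge_names):
            edge_f[(e, tp)] = float(np.exp(beta[k]))
        cond_f[(conditions[0], tp)] = 1.0
        for k, c in enumerate(conditions[1:], start=1):
            cond_f[(c, tp)] = float(np.exp(beta[3 + k]))
        fitted = np.exp(X @ beta)
        out[sel] = value[sel] / fitted
    model = NormalizationModel(edge_factors=edge_f,
                               condition_edge_factors=cond_f, steps=["edge"])
    return table.with_values(out, stage="edge_normalized"), model


def aggregate_replicates(table: PhenotypeTable) -> PhenotypeTable:
    """Mean of non-missing normalized replicates per strain/condition/timepoint.

    Founder control patches (boolean ``control`` column) are excluded
    from the aggregated per-strain phenotypes.
    """
    df = table.frame
    if "control" in df.columns:
        df = df[~df["control"].astype(bool)]
    agg = (
        df.groupby(["strain", "condition", "timepoint"], as_index=False)
        ["value"]
        .mean()
    )
    return PhenotypeTable(agg, {**table.meta, "stage": "aggregated"})


def normalize_pipeline(
    raw: PhenotypeTable,
    min_area: float = DEFAULT_MIN_AREA,
    control_values: pd.DataFrame | None = None,
) -> tuple[PhenotypeTable, NormalizationModel]:
    """Full pipeline: mask -> plate -> batch -> edge -> aggregate."""
    masked, m0 = mask_small_patches(raw, min_area)
    plated, m1 = normalize_plates(masked, control_values)
    batched, m2 = normalize_batches(plated)
    edged, m3 = normalize_edges(batched)
    final = aggregate_replicates(edged)
    model = NormalizationModel(
        min_area=min_area,
        n_masked=m0.n_masked,
        plate_factors=m1.plate_factors,
        batch_factors=m2.batch_factors,
        edge_factors=m3.edge_factors,
        condition_edge_factors=m3.condition_edge_factors,
        steps=["mask", "plate", "batch", "edge", "aggregate"],
    )
    final.meta["normalization_order"] = model.steps
    return final, model
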