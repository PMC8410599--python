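"""Raw well traces to normalized per-condition ΔF/F measurements.

The assay conventions implemented here:

* baseline F = mean fluorescence over the 30 s before ligand addition
  (window ``[addition - baseline_s, addition)``, half-open at the
  addition sample);
* ΔF = mean over the last 10 s of the recording minus F (window
  ``(end - tail_s, end]``);
* ΔF/F = ΔF / F;
* each ΔF/F is normalized to the maximum ΔF/F of the plate's positive
  control (wild-type receptor + cognate agonist), cancelling the
  multiplicative plate effect of transfection efficiency and cell count;
* baseline activity = F divided by the mean F of the plate's
  indicator-only negative-control wells;
* the four technical-replicate wells of a condition are averaged into a
  single biological replicate.

Wells with non-positive baseline F or missing window samples are
excluded (never imputed) and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    MalformedTraceError,
    NormalizationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "WellTrace",
    "compute_baseline",
    "compute_delta_f",
    "normalize_to_positive_control",
    "baseline_activity",
    "average_technical_replicates",
    "load_traces",
    "process_wells",
    "normalize_plate_measurements",
    "measurements_from_traces",
]


@dataclass(frozen=True)
class Condition:
    receptor_id: str | None
    ligand_id: str | None
    concentration: float
    role: str
    technical_replicate_index: int = 1


@dataclass
class WellTrace:
    """One well's fluorescence time series plus its condition assignment."""

    plate_id: str
    well_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    addition_time: float
    condition: Condition

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise MalformedTraceError(
                f"well {self.well_id}: time and fluorescence lengths differ"
            )
        if np.any(np.diff(self.times) <= 0):
            raise MalformedTraceError(
                f"well {self.well_id}: sample times must be strictly increasing"
            )


def compute_baseline(trace: WellTrace, baseline_s: float = 30.0) -> float:
    """Mean fluorescence over the baseline window before ligand addition."""
    lo = trace.addition_time - baseline_s
    mask = (trace.times >= lo) & (trace.times < trace.addition_time)
    if trace.times[0] > lo or mask.sum() < 2:
        raise MalformedTraceError(
            f"well {trace.well_id}: no full {baseline_s:g} s baseline window "
            f"before addition at t={trace.addition_time:g} s"
        )
    return float(trace.fluorescence[mask].mean())


def compute_delta_f(trace: WellTrace, baseline_s: float = 30.0, tail_s: float = 10.0) -> float:
    """ΔF: mean over the recording's last ``tail_s`` seconds minus baseline F."""
    end = trace.times[-1]
    mask = trace.times > end - tail_s
    if mask.sum() < 2:
        raise MalformedTraceError(
            f"well {trace.well_id}: fewer than 2 samples in the final {tail_s:g} s"
        )
    return float(trace.fluorescence[mask].mean()) - compute_baseline(trace, baseline_s)


def normalize_to_positive_control(dff: float, control_max_dff: float) -> float:
    """Scale a ΔF/F by the plate positive control's maximum ΔF/F."""
    if control_max_dff <= 0:
        raise DegenerateControlError(
            f"positive-control max ΔF/F must be positive, got {control_max_dff}"
        )
    return dff / control_max_dff


def baseline_activity(F: float, negative_control_F) -> float:
    """Baseline fluorescence relative to the indicator-only control mean."""
    neg = np.asarray(negative_control_F, dtype=float)
    if neg.size == 0:
        raise NormalizationError("no negative-control F values supplied")
    return float(F / neg.mean())


def average_technical_replicates(values) -> float:
    """Collapse the valid technical replicates of one condition to their mean."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise MalformedTraceError("no valid technical replicates")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def load_traces(
    traces: pd.DataFrame | str,
    platemap: pd.DataFrame | str,
    addition_time: float = 30.0,
) -> list[WellTrace]:
    """Join a long-format trace table with its plate map into WellTraces.

    Accepts DataFrames or CSV paths (comment lines starting with '#' are
    provenance headers and are skipped).
    """
    if not isinstance(traces, pd.DataFrame):
        traces = pd.read_csv(traces, comment="#")
    if not isinstance(platemap, pd.DataFrame):
        platemap = pd.read_csv(platemap, comment="#", keep_default_na=False)

    meta = {}
    for row in platemap.itertuples(index=False):
        receptor = row.receptor_id if row.receptor_id not in ("", None) else None
        ligand = row.ligand_id if row.ligand_id not in ("", None) else None
        meta[(row.plate_id, row.well_id)] = Condition(
            receptor,
            ligand,
            float(row.concentration),
            row.role,
            int(row.technical_replicate_index),
        )

    out = []
    for (plate_id, well_id), grp in traces.groupby(["plate_id", "well_id"], sort=False):
        key = (plate_id, well_id)
        if key not in meta:
            raise NormalizationError(f"plate map has no entry for {key}")
        grp = grp.sort_values("time_s")
        out.append(
            WellTrace(
                plate_id,
                well_id,
                grp["time_s"].to_numpy(),
                grp["fluorescence"].to_numpy(),
                addition_time,
                meta[key],
            )
        )
    return out


def process_wells(
    traces: list[WellTrace], baseline_s: float = 30.0, tail_s: float = 10.0
) -> pd.DataFrame:
    """Per-well F, ΔF and ΔF/F; excluded wells are logged and dropped."""
    rows = []
    for tr in traces:
        try:
            F = compute_baseline(tr, baseline_s)
        except MalformedTraceError as exc:
            logger.warning("excluded well %s/%s: %s", tr.plate_id, tr.well_id, exc)
            continue
        if F <= 0:
            logger.warning(
                "excluded well %s/%s: non-positive baseline F=%g",
                tr.plate_id, tr.well_id, F,
            )
            continue
        dF = compute_delta_f(tr, baseline_s, tail_s)
        c = tr.condition
        rows.append(
            {
                "plate_id": tr.plate_id,
                "well_id": tr.well_id,
                "receptor_id": c.receptor_id,
                "ligand_id": c.ligand_id,
                "concentration": c.concentration,
                "role": c.role,
                "technical_replicate_index": c.technical_replicate_index,
                "F": F,
                "dF": dF,
                "dff": dF / F,
            }
        )
    return pd.DataFrame(rows)


def _positive_control_max(plate_df: pd.DataFrame, receptor_id) -> float:
    """Max technical-averaged ΔF/F over the plate positive control's
    concentration series, preferring the control matching the receptor."""
    pos = plate_df[plate_df["role"] == "positive_control"]
    if pos.empty:
        raise NormalizationError(
            f"plate {plate_df['plate_id'].iloc[0]!r} has no positive control"
        )
    matched = pos[pos["receptor_id"] == receptor_id]
    if not matched.empty:
        pos = matched
    per_conc = pos.groupby("concentration")["dff"].mean()
    cmax = float(per_conc.max())
    if cmax <= 0:
        raise DegenerateControlError(
            f"positive control on plate {plate_df['plate_id'].iloc[0]!r} "
            f"has non-positive max ΔF/F ({cmax:g})"
        )
    return cmax


def normalize_plate_measurements(well_df: pd.DataFrame) -> pd.DataFrame:
    """Add dff_norm (positive-control scaled) and baseline_ratio columns."""
    if well_df.empty:
        return well_df.assign(dff_norm=[], baseline_ratio=[])
    parts = []
    for plate_id, plate in well_df.groupby("plate_id", sort=False):
        neg = plate.loc[plate["role"] == "negative_control", "F"]
        if neg.empty:
            raise NormalizationError(f"plate {plate_id!r} has no negative control")
        neg_mean = float(neg.mean())
        plate = plate.copy()
        plate["dff_norm"] = [
            r.dff / _positive_control_max(plate, r.receptor_id)
            for r in plate.itertuples(index=False)
        ]
        plate["baseline_ratio"] = plate["F"] / neg_mean
        parts.append(plate)
    return pd.concat(parts, ignore_index=True)


def measurements_from_traces(
    traces: list[WellTrace], baseline_s: float = 30.0, tail_s: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stage: per-well table and technical-averaged biological replicates.

    The biological-replicate table carries one row per
    (plate, receptor, ligand, concentration, role): the mean normalized
    ΔF/F of the valid technical replicates, their count, and the mean
    baseline ratio.
    """
    wells = process_wells(traces, baseline_s, tail_s)
    wells = normalize_plate_measurements(wells)
    if wells.empty:
        logger.warning("no valid wells survived processing")
        empty = pd.DataFrame(
            columns=[
                "plate_id", "receptor_id", "ligand_id", "concentration",
                "role", "dff_norm", "baseline_ratio", "n_technical",
            ]
        )
        return wells, empty

    grouped = (
        wells.groupby(
            ["plate_id", "receptor_id", "ligand_id", "concentration", "role"],
            dropna=False,
            sort=True,
        )
        .agg(
            dff_norm=("dff_norm", "mean"),
            baseline_ratio=("baseline_ratio", "mean"),
            n_technical=("dff_norm", "size"),
        )
        .reset_index()
    )
    return wells, grouped
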