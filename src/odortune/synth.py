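"""Synthetic calcium plate-assay data with known ground truth.

This module emulates the high-throughput GCaMP fluorescence assay used to
deorphanize olfactory receptors in HEK cells: 384-well plates read
continuously, 30 s of baseline followed by ligand addition and a 2 min
read, seven-point three-fold dilution series topping at 0.5 mM, four
technical replicates per concentration, and per-plate positive
(wild-type receptor + cognate agonist) and negative (indicator-only)
controls. Steady-state responses follow a Hill curve per receptor x
ligand; the fluorescence rise after addition is a single-exponential
approach; plate-to-plate transfection efficiency enters as one
multiplicative scale per plate; noise is additive i.i.d. Gaussian.

Because every plate is generated from an explicit :class:`GroundTruthTuning`,
the whole downstream pipeline (trace windows, control normalization, Hill
fitting, censoring, tuning metrics, descriptor regression) has a recovery
test against known parameters. Simulation is deterministic under a fixed
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError

__all__ = [
    "DESCRIPTOR_NAMES",
    "DESCRIPTOR_INCOMPLETE_LIGANDS",
    "LigandTruth",
    "GroundTruthTuning",
    "Well",
    "PlateLayout",
    "Timing",
    "make_dilution_series",
    "hill_response",
    "default_plate_layout",
    "simulate_plate",
    "simulate_experiment",
    "simulate_descriptor_panel",
    "default_panel_names",
    "default_truth",
]

#: The 11 physicochemical descriptor columns of the ligand panel table.
DESCRIPTOR_NAMES = (
    "polar_surface_area",
    "logp",
    "water_solubility",
    "hbond_donors",
    "hbond_acceptors",
    "molecular_weight",
    "rotatable_bonds",
    "heavy_atoms",
    "aromatic_rings",
    "vapour_pressure",
    "density",
)

#: Panel members for which one or more descriptors are unavailable
#: (water-soluble tastants and the large synthetic modulator VUAA1).
DESCRIPTOR_INCOMPLETE_LIGANDS = (
    "acetic acid",
    "citric acid",
    "MSG",
    "sucrose",
    "denatonium",
    "VUAA1",
)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandTruth:
    """Forward-model Hill parameters for one receptor x ligand pair.

    Parameters
    ----------
    true_log_ec50 : float
        log10 of the half-maximal concentration in molar.
    true_amplitude : float
        Saturating ΔF/F. Negative values model inhibitory ligands
        (suppression of spontaneous channel activity, e.g. VUAA1).
    true_hill_slope : float
        Hill coefficient; must be positive.
    """

    true_log_ec50: float
    true_amplitude: float
    true_hill_slope: float = 1.0

    def __post_init__(self) -> None:
        if not self.true_hill_slope > 0:
            raise InvalidParameterError(
                f"Hill slope must be positive, got {self.true_hill_slope}"
            )


@dataclass(frozen=True)
class GroundTruthTuning:
    """The simulated receptor's tuning plus plate-level nuisance parameters.

    ``plate_scale`` models the multiplicative plate effect (transfection
    efficiency and cell count) that positive-control normalization is
    designed to cancel. ``baseline_factor`` lets mutants display elevated
    baseline fluorescence relative to the indicator-only control.
    """

    receptor_id: str
    ligands: dict[str, LigandTruth]
    kinetic_tau: float = 10.0          # s, exponential rise time constant
    noise_sd: float = 0.0              # fluorescence units per sample
    plate_scale: float = 1.0
    baseline_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plate_scale > 0:
            raise InvalidParameterError(
                f"plate_scale must be positive, got {self.plate_scale}"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not self.kinetic_tau > 0:
            raise InvalidParameterError("kinetic_tau must be positive")

    def with_scale(self, plate_scale: float) -> "GroundTruthTuning":
        return replace(self, plate_scale=plate_scale)


@dataclass(frozen=True)
class Well:
    well_id: str
    receptor_id: str | None
    ligand_id: str | None
    concentration: float
    role: str                       # experimental|positive_control|negative_control|buffer_control
    technical_replicate_index: int


_ROLES = {"experimental", "positive_control", "negative_control", "buffer_control"}


@dataclass
class PlateLayout:
    """Well-to-condition assignment for one plate."""

    plate_id: str
    wells: list[Well] = field(default_factory=list)

    def validate(self, n_technical: int = 4) -> None:
        roles = {w.role for w in self.wells}
        bad = roles - _ROLES
        if bad:
            raise InvalidParameterError(f"unknown well roles: {sorted(bad)}")
        if "positive_control" not in roles or "negative_control" not in roles:
            raise InvalidParameterError(
                f"plate {self.plate_id} must carry positive and negative controls"
            )
        counts: dict[tuple, int] = {}
        for w in self.wells:
            if w.role == "experimental":
                key = (w.receptor_id, w.ligand_id, w.concentration)
                counts[key] = counts.get(key, 0) + 1
        off = {k: v for k, v in counts.items() if v != n_technical}
        if off:
            raise InvalidParameterError(
                f"experimental conditions without exactly {n_technical} technical "
                f"replicates on plate {self.plate_id}: {sorted(off)[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well_id": w.well_id,
                "receptor_id": "" if w.receptor_id is None else w.receptor_id,
                "ligand_id": "" if w.ligand_id is None else w.ligand_id,
                "concentration": w.concentration,
                "role": w.role,
                "technical_replicate_index": w.technical_replicate_index,
            }
            for w in self.wells
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Timing:
    """Read protocol: baseline window, post-addition window, sampling rate."""

    baseline_s: float = 30.0
    read_s: float = 120.0
    sample_hz: float = 1.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.read_s, self.sample_hz) <= 0:
            raise InvalidParameterError("timing values must be positive")

    def times(self) -> np.ndarray:
        n = int(round((self.baseline_s + self.read_s) * self.sample_hz)) + 1
        return np.arange(n) / self.sample_hz


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def make_dilution_series(
    top_concentration: float, fold: float = 3.0, n_points: int = 7
) -> np.ndarray:
    """Descending serial dilution: element i is top / fold**i.

    The assay protocol default is a seven-point three-fold series from a
    0.5 mM top concentration.
    """
    if not top_concentration > 0:
        raise InvalidParameterError(
            f"top_concentration must be positive, got {top_concentration}"
        )
    if not fold > 1:
        raise InvalidParameterError(f"fold must exceed 1, got {fold}")
    if n_points < 1:
        raise InvalidParameterError(f"n_points must be >= 1, got {n_points}")
    return top_concentration / fold ** np.arange(n_points, dtype=float)


def hill_response(concentration, log_ec50: float, amplitude: float, slope: float):
    """Steady-state ΔF/F of the Hill model with a zero lower asymptote.

    response(c) = amplitude * c**slope / (c**slope + EC50**slope),
    so response(0) = 0, response(EC50) = amplitude / 2 and the sign of the
    response follows the sign of ``amplitude`` (inhibition is negative).

    Accepts scalars or arrays of non-negative molar concentrations.
    """
    if not slope > 0:
        raise InvalidParameterError(f"slope must be positive, got {slope}")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    ec50 = 10.0 ** float(log_ec50)
    cs = np.power(c, slope)
    out = amplitude * cs / (cs + ec50 ** slope)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# plate construction and simulation
# ---------------------------------------------------------------------------

def default_plate_layout(
    plate_id: str,
    receptor_id: str,
    ligand_ids: list[str],
    concentrations: np.ndarray | None = None,
    *,
    positive_control: tuple[str, str] | None = None,
    n_technical: int = 4,
) -> PlateLayout:
    """Assay plate for one receptor: a full dilution series per ligand plus
    the standard control block.

    positive_control is (receptor_id, ligand_id) of the wild-type/cognate
    pair run at the top concentration; it defaults to this receptor with
    eugenol. Negative-control wells carry the indicator alone (no
    receptor), and buffer-control wells receive no ligand.
    """
    if concentrations is None:
        concentrations = make_dilution_series(5e-4, 3.0, 7)
    concentrations = np.asarray(concentrations, dtype=float)
    top = float(concentrations.max())
    pc_receptor, pc_ligand = positive_control or (receptor_id, "eugenol")

    wells: list[Well] = []
    counter = itertools.count(1)

    def add(receptor, ligand, conc, role, rep):
        wells.append(
            Well(f"W{next(counter):04d}", receptor, ligand, conc, role, rep)
        )

    for ligand in ligand_ids:
        for conc in concentrations:
            for rep in range(1, n_technical + 1):
                add(receptor_id, ligand, float(conc), "experimental", rep)
    for rep in range(1, n_technical + 1):
        add(pc_receptor, pc_ligand, top, "positive_control", rep)
        add(None, pc_ligand, top, "negative_control", rep)
        add(receptor_id, None, 0.0, "buffer_control", rep)

    layout = PlateLayout(plate_id, wells)
    layout.validate(n_technical)
    return layout


def _truth_map(truth) -> dict[str, GroundTruthTuning]:
    if isinstance(truth, GroundTruthTuning):
        return {truth.receptor_id: truth}
    return dict(truth)


def simulate_plate(
    truth,
    layout: PlateLayout,
    timing: Timing = Timing(),
    seed: int | None = None,
    f0: float = 100.0,
) -> pd.DataFrame:
    """Simulate every well of a plate; returns a long-format trace table.

    ``truth`` is a :class:`GroundTruthTuning` or a mapping of receptor_id
    to one (mutant panels place wild-type positive controls next to mutant
    wells). Each trace is a constant baseline ``f0 * plate_scale *
    baseline_factor`` plus, from the addition time onward, an exponential
    approach (time constant ``kinetic_tau``) to the Hill steady state,
    with additive Gaussian noise at every sample. Negative-control wells
    (indicator alone) show no ligand response; buffer wells receive no
    ligand.

    Columns: plate_id, well_id, time_s, fluorescence. The addition time is
    ``timing.baseline_s`` from the first sample.
    """
    truths = _truth_map(truth)
    for well in layout.wells:
        if well.role in ("experimental", "positive_control"):
            t = truths.get(well.receptor_id)
            if t is None:
                raise ConsistencyError(
                    f"no ground truth for receptor {well.receptor_id!r} "
                    f"(well {well.well_id})"
                )
            if well.ligand_id not in t.ligands:
                raise ConsistencyError(
                    f"no ground truth for ligand {well.ligand_id!r} of "
                    f"receptor {well.receptor_id!r} (well {well.well_id})"
                )

    any_truth = next(iter(truths.values()))
    if seed is None:
        seed = any_truth.seed
    rng = np.random.default_rng(seed)

    times = timing.times()
    post = times >= timing.baseline_s
    rise = np.zeros_like(times)

    frames = []
    for well in layout.wells:
        t = truths.get(well.receptor_id, any_truth)
        base = f0 * t.plate_scale
        if well.role != "negative_control":
            base *= t.baseline_factor
        signal = np.full_like(times, base)
        responds = (
            well.role in ("experimental", "positive_control")
            and well.concentration > 0
        )
        if responds:
            lt = t.ligands[well.ligand_id]
            steady = hill_response(
                well.concentration, lt.true_log_ec50, lt.true_amplitude, lt.true_hill_slope
            )
            rise[:] = 0.0
            rise[post] = 1.0 - np.exp(-(times[post] - timing.baseline_s) / t.kinetic_tau)
            signal = signal * (1.0 + steady * rise)
        if t.noise_sd > 0:
            signal = signal + rng.normal(0.0, t.noise_sd, size=signal.shape)
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": layout.plate_id,
                    "well_id": well.well_id,
                    "time_s": times,
                    "fluorescence": signal,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(
    truths,
    ligand_ids: list[str],
    *,
    n_plates: int = 3,
    plate_scales: list[float] | None = None,
    concentrations: np.ndarray | None = None,
    timing: Timing = Timing(),
    positive_control: tuple[str, str] | None = None,
    seed: int = 0,
    f0: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiple biological replicates: one plate per receptor per replicate.

    Plate scales default to a lognormal spread around 1 (sd 0.25 in log
    space), drawn once per plate from the seed. Returns the concatenated
    trace table and plate map.
    """
    truths = _truth_map(truths)
    rng = np.random.default_rng(seed)
    if plate_scales is None:
        plate_scales = np.exp(rng.normal(0.0, 0.25, size=n_plates * len(truths)))
    plate_scales = list(plate_scales)

    traces, maps = [], []
    i = 0
    for receptor_id, truth in truths.items():
        for rep in range(1, n_plates + 1):
            plate_id = f"{receptor_id}_plate{rep:02d}"
            layout = default_plate_layout(
                plate_id,
                receptor_id,
                ligand_ids,
                concentrations,
                positive_control=positive_control,
            )
            scaled = {
                rid: t.with_scale(plate_scales[i]) for rid, t in truths.items()
            }
            plate_seed = int(rng.integers(0, 2**31 - 1))
            traces.append(simulate_plate(scaled, layout, timing, plate_seed, f0))
            maps.append(layout.to_frame())
            i += 1
    return pd.concat(traces, ignore_index=True), pd.concat(maps, ignore_index=True)


# ---------------------------------------------------------------------------
# descriptor panel
# ---------------------------------------------------------------------------

def default_panel_names(n_ligands: int = 54) -> list[str]:
    """Ligand names for a synthetic panel.

    The six descriptor-incomplete members keep their real names so the
    completeness filter exercises the documented 48-of-54 condition;
    the rest are eugenol, DEET and generated odorant labels.
    """
    named = ["eugenol", "DEET", *DESCRIPTOR_INCOMPLETE_LIGANDS]
    if n_ligands < len(named):
        return named[:n_ligands]
    generated = [f"odorant_{i:02d}" for i in range(1, n_ligands - len(named) + 1)]
    return named + generated


def simulate_descriptor_panel(
    n_ligands: int = 54,
    informative_weights: dict[str, float] | None = None,
    noise_sd: float = 0.25,
    n_missing: int = 6,
    seed: int = 0,
    *,
    intercept: float = 1.0,
    missing_ligands: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Ligand descriptor table with a planted linear activity relation.

    Descriptors are drawn i.i.d. standard normal (the regression stage is
    affine-invariant, so units are immaterial); the activity index is
    ``intercept + sum(weight * descriptor) + N(0, noise_sd)``. Exactly
    ``n_missing`` ligands are left with at least one empty descriptor
    cell, defaulting to the named water-soluble tastants/VUAA1 when the
    panel contains them.

    Returns (panel table with ligand_id + 11 descriptor columns +
    activity_index, activity series indexed by ligand, truth record with
    the weights and the missing set).
    """
    informative_weights = dict(informative_weights or {})
    unknown = set(informative_weights) - set(DESCRIPTOR_NAMES)
    if unknown:
        raise InvalidParameterError(f"unknown descriptors in weights: {sorted(unknown)}")
    if n_missing >= n_ligands:
        raise InvalidParameterError("n_missing must be smaller than n_ligands")

    rng = np.random.default_rng(seed)
    names = default_panel_names(n_ligands)
    X = pd.DataFrame(
        rng.standard_normal((n_ligands, len(DESCRIPTOR_NAMES))),
        columns=list(DESCRIPTOR_NAMES),
        index=pd.Index(names, name="ligand_id"),
    )
    activity = pd.Series(intercept, index=X.index, name="activity_index", dtype=float)
    for name, w in informative_weights.items():
        activity = activity + w * X[name]
    if noise_sd > 0:
        activity = activity + rng.normal(0.0, noise_sd, size=n_ligands)

    if missing_ligands is None:
        missing_ligands = [l for l in DESCRIPTOR_INCOMPLETE_LIGANDS if l in X.index]
        missing_ligands = missing_ligands[:n_missing]
        if len(missing_ligands) < n_missing:
            extra = [l for l in X.index if l not in missing_ligands]
            missing_ligands += extra[: n_missing - len(missing_ligands)]
    elif len(missing_ligands) != n_missing:
        raise InvalidParameterError("missing_ligands length must equal n_missing")

    missing_map: dict[str, list[str]] = {}
    for ligand in missing_ligands:
        k = int(rng.integers(1, 4))  # 1-3 absent descriptors per such ligand
        cols = [str(c) for c in rng.choice(DESCRIPTOR_NAMES, size=k, replace=False)]
        X.loc[ligand, cols] = np.nan
        missing_map[ligand] = sorted(cols)

    panel = X.reset_index()
    panel["activity_index"] = activity.to_numpy()
    truth = {
        "intercept": intercept,
        "weights": informative_weights,
        "noise_sd": noise_sd,
        "missing": missing_map,
        "seed": seed,
    }
    return panel, activity, truth


def default_truth(
    receptor_id: str = "MhOR5",
    ligand_ids: list[str] | None = None,
    *,
    noise_sd: float = 0.5,
    kinetic_tau: float = 10.0,
    seed: int = 0,
    n_inhibitors: int = 1,
) -> GroundTruthTuning:
    """A plausible broadly tuned receptor for demonstrations and pipelines.

    Agonist log EC50s are drawn uniformly in [-6, -3.8] (well inside the
    0.5 mM protocol window), amplitudes in [0.3, 2.5] ΔF/F, slopes in
    [0.8, 2]; the last ``n_inhibitors`` ligands get negative amplitudes,
    mirroring VUAA1-style inhibition. The cognate agonist eugenol is
    always present and strong (it anchors the positive control).
    """
    if ligand_ids is None:
        ligand_ids = ["eugenol"] + [f"odorant_{i:02d}" for i in range(1, 8)]
    rng = np.random.default_rng(seed)
    ligands: dict[str, LigandTruth] = {}
    for i, ligand in enumerate(ligand_ids):
        if ligand == "eugenol":
            ligands[ligand] = LigandTruth(-5.2, 2.0, 1.2)
            continue
        amp = float(rng.uniform(0.3, 2.5))
        if n_inhibitors and i >= len(ligand_ids) - n_inhibitors:
            amp = -abs(float(rng.uniform(0.2, 0.8)))
        ligands[ligand] = LigandTruth(
            float(rng.uniform(-6.0, -3.8)),
            amp,
            float(rng.uniform(0.8, 2.0)),
        )
    if "eugenol" not in ligands:
        ligands["eugenol"] = LigandTruth(-5.2, 2.0, 1.2)
    return GroundTruthTuning(
        receptor_id=receptor_id,
        ligands=ligands,
        kinetic_tau=kinetic_tau,
        noise_sd=noise_sd,
        seed=seed,
    )
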