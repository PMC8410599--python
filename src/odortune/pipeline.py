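"""Stage orchestration: simulate -> fit -> tune / regress.

Each stage reads the delimited-text interfaces (CSV, UTF-8, '.' decimal,
header row, empty cell = missing), writes its outputs with a provenance
header comment (config hash + stage version), and is deterministic under
a fixed seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .errors import StageOrderError
from .synth import (
    Timing,
    default_truth,
    make_dilution_series,
    simulate_descriptor_panel,
    simulate_experiment,
)
from .traces import load_traces, measurements_from_traces
from .doseresponse import fit_dose_response_table
from .tuning import (
    ActivityCriterion,
    TuningProfile,
    build_tuning_curve,
    compare_to_wildtype,
    count_active,
    lifetime_sparseness,
)
from .errors import ComparisonError, UndefinedSparsenessError
from .regression import DescriptorScan

logger = logging.getLogger(__name__)


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# odortune stage={stage} version={__version__} config={config.digest()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    if not Path(path).exists():
        raise StageOrderError(
            f"required input {path} is missing; run the prerequisite stage first"
        )
    return pd.read_csv(path, comment="#", **kwargs)


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate plates, plate map, ground truth and a ligand descriptor panel."""
    config.validate()
    out = _out(config)
    rng = np.random.default_rng(config.seed)

    ligand_ids = ["eugenol"] + [f"odorant_{i:02d}" for i in range(1, config.n_ligands)]
    truths = {
        config.receptor_id: default_truth(
            config.receptor_id, ligand_ids,
            noise_sd=config.noise_sd, kinetic_tau=config.kinetic_tau,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    }
    for mutant in config.mutant_ids:
        truths[mutant] = default_truth(
            mutant, ligand_ids,
            noise_sd=config.noise_sd, kinetic_tau=config.kinetic_tau,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    concs = make_dilution_series(config.top_concentration, config.fold, config.n_points)
    timing = Timing(config.baseline_s, config.read_s, config.sample_hz)
    traces, platemap = simulate_experiment(
        truths, ligand_ids,
        n_plates=config.n_plates, concentrations=concs, timing=timing,
        positive_control=(config.receptor_id, "eugenol"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    panel, _, panel_truth = simulate_descriptor_panel(
        config.panel_n_ligands,
        {"polar_surface_area": -0.8, "water_solubility": -0.6, "hbond_donors": -0.4},
        noise_sd=0.25,
        n_missing=config.panel_n_missing,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    paths = {
        "traces": out / "traces.csv",
        "platemap": out / "platemap.csv",
        "ligand_panel": out / "ligand_panel.csv",
        "truth": out / "ground_truth.yaml",
        "config": out / "config.yaml",
    }
    _write_csv(traces, paths["traces"], config, "simulate")
    _write_csv(platemap, paths["platemap"], config, "simulate")
    _write_csv(panel, paths["ligand_panel"], config, "simulate")

    truth_doc = {
        "receptors": {
            rid: {
                "kinetic_tau": t.kinetic_tau,
                "noise_sd": t.noise_sd,
                "ligands": {
                    l: {
                        "true_log_ec50": lt.true_log_ec50,
                        "true_amplitude": lt.true_amplitude,
                        "true_hill_slope": lt.true_hill_slope,
                    }
                    for l, lt in t.ligands.items()
                },
            }
            for rid, t in truths.items()
        },
        "descriptor_panel": panel_truth,
        "config": config.digest(),
    }
    paths["truth"].write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    config.to_yaml(paths["config"])
    return paths


def run_fit(config: PipelineConfig) -> dict[str, Path]:
    """traces + plate map -> well measurements, biological replicates, fits."""
    config.validate()
    out = _out(config)
    traces_path = Path(config.traces_path or out / "traces.csv")
    platemap_path = Path(config.platemap_path or out / "platemap.csv")
    if not traces_path.exists() or not platemap_path.exists():
        raise StageOrderError(
            f"traces/plate map not found at {traces_path} / {platemap_path}; "
            "run `odortune simulate` first or point the config at real exports"
        )
    traces = load_traces(
        _read_csv(traces_path),
        pd.read_csv(platemap_path, comment="#", keep_default_na=False),
        addition_time=config.baseline_s,
    )
    wells, bioreps = measurements_from_traces(
        traces, config.baseline_s, config.response_tail_s
    )
    if bioreps.empty:
        logger.warning("fit stage produced no measurements (empty plate?)")
    fits = fit_dose_response_table(
        bioreps, mode=config.fit_mode, censor_value=config.censor_value
    )
    n_censored = int(fits["censored"].sum()) if not fits.empty else 0
    logger.info("fit stage: %d curves, %d censored", len(fits), n_censored)

    paths = {
        "wells": out / "well_measurements.csv",
        "bioreps": out / "biological_replicates.csv",
        "fits": out / "fits.csv",
    }
    _write_csv(wells, paths["wells"], config, "fit")
    _write_csv(bioreps, paths["bioreps"], config, "fit")
    _write_csv(fits, paths["fits"], config, "fit")
    return paths


def run_tune(config: PipelineConfig) -> dict[str, Path]:
    """fits -> ordered tuning curve, sparseness summary, group comparisons."""
    config.validate()
    out = _out(config)
    fits = _read_csv(out / "fits.csv")

    receptors = sorted(fits["receptor_id"].unique())
    reference = config.receptor_id if config.receptor_id in receptors else receptors[0]
    profiles = [TuningProfile.from_fits(fits, r) for r in receptors]
    curve = build_tuning_curve(profiles, reference)

    sparse_rows = []
    for p in profiles:
        try:
            s = p.sparseness
        except UndefinedSparsenessError:
            s = float("nan")
        sparse_rows.append(
            {"receptor_id": p.receptor_id, "n_ligands": p.n, "lifetime_sparseness": s}
        )
    sparseness = pd.DataFrame(sparse_rows)

    criterion = ActivityCriterion(
        config.agonist_require_uncensored, config.agonist_min_activity
    )
    active = pd.DataFrame(
        [
            {"receptor_id": r, **count_active(fits[fits["receptor_id"] == r], criterion)}
            for r in receptors
        ]
    )

    comparisons = pd.DataFrame(
        columns=["mutant_id", "control_id", "ligand_id", "test_used",
                 "p_value", "significance_label", "bartlett_p"]
    )
    if len(receptors) > 1 and "replicate_log_ec50" in fits.columns:
        rows = []
        for ligand, sub in fits.groupby("ligand_id"):
            groups = {}
            for r in sub.itertuples(index=False):
                reps = [float(v) for v in str(r.replicate_log_ec50).split(";") if v]
                if len(reps) >= 2:
                    groups[r.receptor_id] = np.array(reps)
            if reference not in groups or len(groups) < 2:
                continue
            try:
                results = compare_to_wildtype(
                    groups, reference,
                    alpha_bartlett=config.alpha_bartlett,
                    censor_value=config.censor_value,
                    label_map=[tuple(t) for t in config.label_map],
                )
            except ComparisonError:
                continue
            for res in results:
                rows.append(
                    {
                        "mutant_id": res.mutant_id,
                        "control_id": res.control_id,
                        "ligand_id": ligand,
                        "test_used": res.test_used,
                        "p_value": res.p_value,
                        "significance_label": res.significance_label,
                        "bartlett_p": res.bartlett_p,
                    }
                )
        if rows:
            comparisons = pd.DataFrame(rows).sort_values(
                ["ligand_id", "mutant_id"]
            ).reset_index(drop=True)

    paths = {
        "tuning": out / "tuning_curve.csv",
        "sparseness": out / "sparseness.csv",
        "active": out / "agonist_fractions.csv",
        "comparisons": out / "comparisons.csv",
    }
    _write_csv(curve, paths["tuning"], config, "tune")
    _write_csv(sparseness, paths["sparseness"], config, "tune")
    _write_csv(active, paths["active"], config, "tune")
    _write_csv(comparisons, paths["comparisons"], config, "tune")
    return paths


def run_regress(config: PipelineConfig) -> dict[str, Path]:
    """ligand descriptor table -> exclusions + ranked regression table."""
    config.validate()
    out = _out(config)
    panel_path = Path(config.ligand_table_path or out / "ligand_panel.csv")
    panel = _read_csv(panel_path)
    scan = DescriptorScan(panel)
    ranked = scan.fit()
    paths = {
        "regression": out / "regression_ranking.csv",
        "exclusions": out / "regression_exclusions.csv",
    }
    _write_csv(ranked, paths["regression"], config, "regress")
    _write_csv(scan.exclusions_, paths["exclusions"], config, "regress")
    logger.info(
        "regression: %d ligands retained, %d excluded, %d models ranked",
        len(scan.retained_), len(scan.exclusions_), len(ranked),
    )
    return paths


def run_all(config: PipelineConfig) -> dict[str, Path]:
    paths = run_simulate(config)
    paths.update(run_fit(config))
    paths.update(run_tune(config))
    paths.update(run_regress(config))
    return paths
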