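import numpy as np
import pytest

from odortune import (
    GroundTruthTuning,
    LigandTruth,
    default_plate_layout,
    fit_dose_response_table,
    hill_response,
    load_traces,
    make_dilution_series,
    measurements_from_traces,
    simulate_plate,
)
from odortune.synth import Timing

PROTOCOL_CONCS = make_dilution_series(5e-4, 3.0, 7)

#: A small receptor with agonists, one inhibitor and the cognate agonist.
TRUTH_LIGANDS = {
    "eugenol": LigandTruth(-5.2, 2.0, 1.2),
    "odorant_01": LigandTruth(-5.0, 1.0, 1.0),
    "odorant_02": LigandTruth(-4.5, 0.8, 1.5),
    "vuaa1_like": LigandTruth(-5.0, -0.5, 1.0),
}


def normalized_amplitude(truth: GroundTruthTuning, ligand: str,
                         control_ligand: str = "eugenol",
                         top: float = 5e-4) -> float:
    """Expected fitted amplitude after positive-control normalization."""
    ctrl = truth.ligands[control_ligand]
    control_max = hill_response(top, ctrl.true_log_ec50, ctrl.true_amplitude,
                                ctrl.true_hill_slope)
    return truth.ligands[ligand].true_amplitude / control_max


def run_noise_free(plate_scale: float = 1.3, trace_gain: float = 1.0):
    """Simulate one noise-free plate and push it through the full pipeline.

    Returns (truth, fits table, biological replicate table).
    ``trace_gain`` multiplies every raw fluorescence sample, emulating an
    instrument gain change the normalization must cancel.
    """
    truth = GroundTruthTuning(
        "MhOR5", TRUTH_LIGANDS, kinetic_tau=5.0, noise_sd=0.0,
        plate_scale=plate_scale, seed=11,
    )
    layout = default_plate_layout(
        "plate01", "MhOR5", list(TRUTH_LIGANDS), PROTOCOL_CONCS
    )
    traces_df = simulate_plate(truth, layout, Timing(), seed=11)
    if trace_gain != 1.0:
        traces_df = traces_df.assign(fluorescence=traces_df["fluorescence"] * trace_gain)
    traces = load_traces(traces_df, layout.to_frame())
    _, bioreps = measurements_from_traces(traces)
    fits = fit_dose_response_table(bioreps)
    return truth, fits, bioreps


@pytest.fixture(scope="session")
def noise_free_run():
    return run_noise_free()


@pytest.fixture(scope="session")
def protocol_concs():
    return PROTOCOL_CONCS.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
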