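"""Synthetic plate and descriptor-panel generator contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odortune import (
    GroundTruthTuning,
    LigandTruth,
    default_plate_layout,
    hill_response,
    make_dilution_series,
    simulate_descriptor_panel,
    simulate_plate,
)
from odortune.errors import ConsistencyError, InvalidParameterError
from odortune.synth import Timing, default_panel_names


class TestDilutionSeries:
    @pytest.mark.parametrize(
        "top, fold, n, expected",
        [
            (5e-4, 3, 7, [5e-4, 1.6667e-4, 5.5556e-5, 1.8519e-5,
                          6.1728e-6, 2.0576e-6, 6.8587e-7]),
            (1.0, 2, 1, [1.0]),
            (5e-4, 3, 2, [5e-4, 1.6667e-4]),
        ],
    )
    def test_protocol_series(self, top, fold, n, expected):
        got = make_dilution_series(top, fold, n)
        np.testing.assert_allclose(got, expected, rtol=1e-4)

    @pytest.mark.parametrize("bad", [dict(top_concentration=0), dict(fold=1.0),
                                     dict(fold=0.5), dict(n_points=0)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(top_concentration=5e-4, fold=3.0, n_points=7) | bad
        with pytest.raises(InvalidParameterError):
            make_dilution_series(**kwargs)

    @settings(max_examples=50, derandomize=True)
    @given(
        top=st.floats(1e-9, 1e3),
        fold=st.floats(1.01, 100),
        n=st.integers(1, 12),
    )
    def test_strictly_decreasing_and_positive(self, top, fold, n):
        series = make_dilution_series(top, fold, n)
        assert np.all(series > 0)
        assert np.all(np.diff(series) < 0) or n == 1


class TestHillResponse:
    def test_half_max_at_ec50(self):
        for slope in (0.5, 1.0, 3.0):
            assert hill_response(1e-5, -5.0, 1.0, slope) == pytest.approx(0.5)

    def test_zero_dose_gives_zero(self):
        assert hill_response(0.0, -5.0, 2.0, 1.3) == 0.0

    def test_hand_computed_value(self):
        # 2 * 10 / 11 at c = 10*EC50, slope 1
        assert hill_response(1e-4, -5.0, 2.0, 1.0) == pytest.approx(2 * 10 / 11, abs=1e-6)

    def test_sign_follows_amplitude(self):
        assert hill_response(1e-4, -5.0, -0.5, 1.0) < 0

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            hill_response(-1e-6, -5.0, 1.0, 1.0)


def _truth(**kwargs):
    defaults = dict(
        receptor_id="R",
        ligands={"eugenol": LigandTruth(-5.0, 1.0, 1.0)},
        kinetic_tau=1.0,
        noise_sd=0.0,
    )
    return GroundTruthTuning(**(defaults | kwargs))


class TestSimulatePlate:
    def test_null_amplitude_gives_flat_traces(self):
        truth = _truth(ligands={"eugenol": LigandTruth(-5.0, 0.0, 1.0)},
                       plate_scale=1.7)
        layout = default_plate_layout("p", "R", ["eugenol"])
        df = simulate_plate(truth, layout, seed=0)
        np.testing.assert_allclose(df["fluorescence"], 100.0 * 1.7)

    def test_fast_kinetics_settle_to_hill_steady_state(self):
        truth = _truth(kinetic_tau=1.0)
        layout = default_plate_layout("p", "R", ["eugenol"])
        df = simulate_plate(truth, layout, seed=0)
        pm = layout.to_frame()
        well = pm[(pm.role == "experimental")].iloc[0]
        tr = df[df.well_id == well.well_id]
        f = tr.fluorescence.to_numpy()
        t = tr.time_s.to_numpy()
        F = f[t < 30].mean()
        dff = f[t > t[-1] - 10].mean() / F - 1
        expected = hill_response(well.concentration, -5.0, 1.0, 1.0)
        assert dff == pytest.approx(expected, abs=1e-3)

    def test_same_seed_identical_traces(self):
        truth = _truth(noise_sd=2.0)
        layout = default_plate_layout("p", "R", ["eugenol"])
        a = simulate_plate(truth, layout, seed=42)
        b = simulate_plate(truth, layout, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_control_mean_response_is_zero(self):
        noise_sd = 1.0
        truth = _truth(noise_sd=noise_sd)
        layout = default_plate_layout("p", "R", ["eugenol"], n_technical=4)
        dffs = []
        for seed in range(30):  # 120 simulated control wells
            df = simulate_plate(truth, layout, seed=seed)
            pm = layout.to_frame()
            for wid in pm.loc[pm.role == "negative_control", "well_id"]:
                tr = df[df.well_id == wid]
                f = tr.fluorescence.to_numpy()
                t = tr.time_s.to_numpy()
                F = f[t < 30].mean()
                dffs.append(f[t > t[-1] - 10].mean() / F - 1)
        dffs = np.asarray(dffs)
        # per-well dF/F noise sd ~ noise_sd/F0 * sqrt(1/10 + 1/30)
        sem = noise_sd / 100.0 * np.sqrt(1 / 10 + 1 / 30) / np.sqrt(dffs.size)
        assert abs(dffs.mean()) < 3 * sem

    def test_unknown_ligand_raises_consistency_error(self):
        truth = _truth()
        layout = default_plate_layout("p", "R", ["mystery"],
                                      positive_control=("R", "eugenol"))
        with pytest.raises(ConsistencyError):
            simulate_plate(truth, layout, seed=0)

    def test_layout_requires_controls_and_replicates(self):
        layout = default_plate_layout("p", "R", ["eugenol"])
        layout.wells = [w for w in layout.wells if w.role != "negative_control"]
        with pytest.raises(InvalidParameterError):
            layout.validate()


class TestDescriptorPanel:
    def test_48_of_54_descriptor_complete(self):
        panel, _, truth = simulate_descriptor_panel(54, n_missing=6, seed=1)
        complete = panel.drop(columns=["ligand_id", "activity_index"]).notna().all(axis=1)
        assert complete.sum() == 48
        assert len(truth["missing"]) == 6

    def test_noiseless_single_descriptor_is_exactly_linear(self):
        panel, activity, _ = simulate_descriptor_panel(
            20, {"logp": 2.0}, noise_sd=0.0, n_missing=0, seed=3
        )
        resid = activity - (1.0 + 2.0 * panel.set_index("ligand_id")["logp"])
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_unknown_descriptor_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_descriptor_panel(10, {"charisma": 1.0}, seed=0)

    def test_determinism(self):
        a, _, _ = simulate_descriptor_panel(30, {"logp": 1.0}, seed=9)
        b, _, _ = simulate_descriptor_panel(30, {"logp": 1.0}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_named_incomplete_ligands_present(self):
        names = default_panel_names(54)
        assert {"acetic acid", "citric acid", "MSG", "sucrose",
                "denatonium", "VUAA1"} <= set(names)
        assert len(names) == 54


def test_invalid_timing_rejected():
    with pytest.raises(InvalidParameterError):
        Timing(baseline_s=0)
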