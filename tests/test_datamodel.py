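"""Data model: tidy CSV I/O, utilization, depletion timing, fluxes."""

import numpy as np
import pandas as pd
import pytest

from vinoflux.datamodel import (
    FermentationDataset,
    SchemaError,
    UtilizationMatrix,
    ValidationError,
    compute_utilization,
    depletion_time,
    estimate_exchange_fluxes,
    nitrogen_group,
    od_to_dcw,
    read_fermentation_csv,
    write_fermentation_csv,
)

from conftest import make_dataset


class TestIO:
    def test_round_trip_single_series(self, tmp_path):
        ds = make_dataset({"Lys": ([0.0, 24.0, 48.0], [15.0, 5.0, 1.0], "mg/L")})
        path = tmp_path / "f.csv"
        write_fermentation_csv(ds, path)
        back = read_fermentation_csv(path)
        t, v, unit = back.series("S1", 1, "Lys")
        assert list(t) == [0.0, 24.0, 48.0]
        assert list(v) == [15.0, 5.0, 1.0]
        assert unit == "mg/L"
        # byte-identical round trip (column order is canonical)
        path2 = tmp_path / "g.csv"
        write_fermentation_csv(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_missing_unit_column_is_schema_error(self, tmp_path):
        df = pd.DataFrame(
            {"strain": ["S1"], "replicate": [1], "time_h": [0.0],
             "analyte": ["Lys"], "value": [1.0]}
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="unit"):
            read_fermentation_csv(path)

    def test_schema_renames_columns(self, tmp_path):
        df = pd.DataFrame(
            {"strain": ["S1"], "replicate": [1], "sample_time": [0.0],
             "analyte": ["Lys"], "value": [1.0], "unit": ["mg/L"]}
        )
        path = tmp_path / "renamed.csv"
        df.to_csv(path, index=False)
        ds = read_fermentation_csv(path, schema={"sample_time": "time_h"})
        assert ds.analytes == ["Lys"]

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (lambda df: df.assign(value=[-1.0, 5.0]), "negative concentration"),
            (lambda df: df.assign(time_h=[0.0, -2.0]), "negative time"),
            (lambda df: df.assign(time_h=[10.0, 24.0]), "lacks time 0"),
            (lambda df: df.assign(unit=["mg/L", "g/L"]), "inconsistent units"),
        ],
    )
    def test_invariant_violations_rejected(self, mutation, match):
        base = pd.DataFrame(
            {"strain": ["S1"] * 2, "replicate": [1] * 2, "time_h": [0.0, 24.0],
             "analyte": ["Lys"] * 2, "value": [15.0, 5.0], "unit": ["mg/L"] * 2}
        )
        with pytest.raises(ValidationError, match=match):
            FermentationDataset(mutation(base))


class TestUtilization:
    def test_zero_at_inoculation(self):
        ds = make_dataset({"Lys": ([0.0, 24.0], [15.0, 5.0], "mg/L")})
        assert compute_utilization(ds, "Lys", 0.0) == 0.0

    def test_difference_from_t0(self):
        ds = make_dataset({"A": ([0.0, 24.0, 48.0], [100.0, 60.0, 20.0], "mg/L")})
        assert compute_utilization(ds, "A", 24.0) == pytest.approx(40.0)
        assert compute_utilization(ds, "A", 48.0) == pytest.approx(80.0)

    def test_ammonia_fully_consumed(self):
        # 11 mg/L ammonium exhausted by 28 h -> utilization 11 mg/L
        ds = make_dataset({"NH3": ([0.0, 20.0, 28.0], [11.0, 2.0, 0.0], "mg/L")})
        assert compute_utilization(ds, "NH3", 28.0) == pytest.approx(11.0)

    def test_unsampled_time_names_neighbours(self):
        ds = make_dataset({"A": ([0.0, 24.0, 48.0], [3.0, 2.0, 1.0], "mg/L")})
        with pytest.raises(ValueError, match="24.*48"):
            compute_utilization(ds, "A", 30.0)

    def test_net_excretion_is_negative(self):
        # stationary-phase uptick must not be clipped
        ds = make_dataset({"Ala": ([0.0, 24.0], [10.0, 12.0], "mg/L")})
        assert compute_utilization(ds, "Ala", 24.0) == pytest.approx(-2.0)

    def test_monotone_series_gives_monotone_utilization(self):
        values = [100.0, 80.0, 80.0, 30.0, 5.0]
        times = [0.0, 12.0, 24.0, 48.0, 96.0]
        ds = make_dataset({"A": (times, values, "mg/L")})
        utils = [compute_utilization(ds, "A", t) for t in times]
        assert all(b >= a for a, b in zip(utils, utils[1:]))


class TestDepletionTime:
    def test_linear_decay_closed_form(self):
        ds = make_dataset({"A": ([0.0, 100.0], [50.0, 0.0], "mg/L")})
        assert depletion_time(ds, "A", fraction=0.95) == pytest.approx(95.0)

    def test_flat_series_never_depletes(self):
        ds = make_dataset({"Pro": ([0.0, 100.0, 404.0], [300.0] * 3, "mg/L")})
        assert depletion_time(ds, "Pro") is None

    def test_full_depletion_fraction_one(self):
        ds = make_dataset({"A": ([0.0, 50.0, 100.0], [10.0, 5.0, 0.0], "mg/L")})
        assert depletion_time(ds, "A", fraction=1.0) == pytest.approx(100.0)

    def test_zero_initial_returns_none_with_warning(self):
        ds = make_dataset({"A": ([0.0, 24.0], [0.0, 0.0], "mg/L")})
        with pytest.warns(UserWarning, match="starts at 0"):
            assert depletion_time(ds, "A") is None

    @pytest.mark.parametrize(
        "t95, group",
        [(20.0, "I"), (28.0, "I"), (40.0, "II"), (60.0, "III"),
         (80.0, None), (100.0, "IV"), (None, None)],
    )
    def test_group_thresholds(self, t95, group):
        assert nitrogen_group(t95) == group

    def test_late_glycine_like_series_is_group_four(self):
        # reaches 95% only at ~100 h
        ds = make_dataset(
            {"Gly": ([0.0, 48.0, 96.0, 150.0], [10.0, 8.0, 2.0, 0.0], "mg/L")}
        )
        t95 = depletion_time(ds, "Gly")
        assert t95 is not None and t95 > 96
        assert nitrogen_group(t95) == "IV"


class TestBiomassCalibration:
    @pytest.mark.parametrize(
        "od, slope, intercept, expected",
        [(0.0, 0.5, 0.0, 0.0), (1.0, 0.5, 0.0, 0.5), (0.1, 0.5, 0.0, 0.05)],
    )
    def test_affine_transform(self, od, slope, intercept, expected):
        assert od_to_dcw(od, slope, intercept) == pytest.approx(expected)

    def test_negative_output_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            out = od_to_dcw(np.array([0.01, 1.0]), 0.5, -0.1)
        assert out[0] == 0.0 and out[1] == pytest.approx(0.4)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            od_to_dcw(1.0, 0.0)


class TestExchangeFluxes:
    @staticmethod
    def _ds(glucose_unit="g/L", glucose_scale=1.0):
        return make_dataset(
            {
                "biomass": ([0.0, 10.0, 24.0], [1.0, 1.0, 1.0], "gDW/L"),
                "glucose": (
                    [0.0, 10.0, 24.0],
                    [100.0 * glucose_scale, 95.0 * glucose_scale,
                     86.0 * glucose_scale],
                    glucose_unit,
                ),
                "ethanol": ([0.0, 10.0, 24.0], [0.0, 2.0, 6.0], "g/L"),
            }
        )

    def test_hand_computed_glucose_uptake(self):
        # 9 g/L over 14 h at 1 gDW/L, M = 180.16 -> -3.568 mmol/gDW/h
        fm = estimate_exchange_fluxes(
            self._ds(), (10.0, 24.0), {"glucose": 180.16}, ["glucose"]
        )
        assert fm.values["glucose"] == pytest.approx(
            -9.0 * 1000 / (180.16 * 1.0 * 14.0), rel=1e-12
        )
        assert fm.values["glucose"] == pytest.approx(-3.568, abs=5e-3)

    def test_zero_delta_gives_zero_rate(self):
        ds = make_dataset(
            {
                "biomass": ([0.0, 10.0, 24.0], [1.0, 1.0, 1.0], "gDW/L"),
                "malate": ([0.0, 10.0, 24.0], [3.0, 3.0, 3.0], "g/L"),
            }
        )
        fm = estimate_exchange_fluxes(ds, (10.0, 24.0), {"malate": 134.09}, ["malate"])
        assert fm.values["malate"] == 0.0

    def test_secretion_is_positive(self):
        fm = estimate_exchange_fluxes(
            self._ds(), (10.0, 24.0), {"ethanol": 46.07}, ["ethanol"]
        )
        assert fm.values["ethanol"] > 0

    def test_unit_change_invariance(self):
        fm_g = estimate_exchange_fluxes(
            self._ds("g/L", 1.0), (10.0, 24.0), {"glucose": 180.16}, ["glucose"]
        )
        fm_mg = estimate_exchange_fluxes(
            self._ds("mg/L", 1000.0), (10.0, 24.0), {"glucose": 180.16}, ["glucose"]
        )
        assert fm_g.values["glucose"] == pytest.approx(
            fm_mg.values["glucose"], rel=1e-12
        )

    def test_missing_molar_mass_names_analyte(self):
        with pytest.raises(ValueError, match="glucose"):
            estimate_exchange_fluxes(self._ds(), (10.0, 24.0), {}, ["glucose"])


class TestUtilizationMatrix:
    def test_t0_row_must_be_zero(self):
        with pytest.raises(ValidationError, match="t=0"):
            UtilizationMatrix(
                row_ids=[("S1", 1, 0.0)], columns=["A"],
                X=np.array([[1.0]]), Y=np.array([[1.0]]), y_names=["y"],
            )

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="row counts"):
            UtilizationMatrix(
                row_ids=[("S1", 1, 10.0)], columns=["A"],
                X=np.array([[1.0]]), Y=np.array([[1.0], [2.0]]), y_names=["y"],
            )
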