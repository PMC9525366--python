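"""Parameter tables: derivation identities, loading, validation."""

import dataclasses

import pandas as pd
import pytest

from thyroblock.parameters import (
    COMPARTMENTS,
    SUPPORTED_WEEKS,
    derive_mm,
    fetal_wc_threshold,
    load_parameters,
    validate_tables,
)


class TestDeriveMM:
    @pytest.mark.parametrize(
        "k, vd, expected_tmax, expected_km",
        [
            (2.3, 7.0, 144.9, 63.0),   # maternal thyroid iodide route
            (33.0, 7.0, 2079.0, 63.0),  # placental iodide route
            (0.0, 7.0, 0.0, 63.0),      # inactive flow
        ],
    )
    def test_tmax_km_identities(self, k, vd, expected_tmax, expected_km):
        tmax, km_abs = derive_mm(k, vd)
        assert tmax == pytest.approx(expected_tmax, rel=1e-12)
        assert km_abs == pytest.approx(expected_km, rel=1e-12)

    def test_rejects_nonpositive_volume_or_km(self):
        with pytest.raises(ValueError):
            derive_mm(1.0, 0.0)
        with pytest.raises(ValueError):
            derive_mm(1.0, 7.0, km=-1.0)
        with pytest.raises(ValueError):
            derive_mm(-1.0, 7.0)


class TestLoadParameters:
    def test_week0_maternal_thyroid_carrier(self):
        f = load_parameters(0).flow("blood", "thyroid_iodide")
        assert f.law == "michaelis_menten"
        assert f.tmax == pytest.approx(144.9)
        assert f.km_abs == pytest.approx(63.0)

    def test_week12_fetal_thyroid_carrier(self):
        f = load_parameters(12).flow("fetal_iodide", "fetal_thyroid")
        assert f.tmax == pytest.approx(0.729)
        assert f.km_abs == pytest.approx(0.405)

    def test_unsupported_week_lists_supported_set(self):
        with pytest.raises(ValueError, match=r"0, 3, 8, 12, 16, 24, 32, 36, 38"):
            load_parameters(5)

    def test_fetal_physiology_absent_before_week_12(self):
        for week in (0, 3, 8):
            phys = load_parameters(week).physiology
            assert phys.fetal_weight_g is None
            assert not phys.has_fetal_thyroid
            assert load_parameters(week).wc_threshold_fetal_umol is None

    def test_fetal_flows_inactive_before_week_12(self):
        p = load_parameters(0)
        assert not p.flow("fetal_iodide", "fetal_thyroid").active
        assert not p.flow("blood", "uteroplacental_iodide").active

    def test_loading_is_pure(self):
        assert load_parameters(24) == load_parameters(24)

    def test_every_compartment_connected(self):
        p = load_parameters(38)
        seen = {c for f in p.flows for c in (f.source, f.target)}
        assert seen == set(COMPARTMENTS)

    @pytest.mark.parametrize(
        "week, km_abs",
        [(12, 0.405), (16, 0.999), (24, 4.059), (32, 10.404),
         (36, 14.337), (38, 16.2765)],
    )
    def test_fetal_km_tracks_distribution_volume(self, week, km_abs):
        p = load_parameters(week)
        f = p.flow("fetal_iodide", "fetal_thyroid")
        assert f.km_abs == pytest.approx(km_abs, rel=1e-6)
        assert f.km_abs == pytest.approx(9.0 * p.physiology.vd_fetal_l, rel=1e-3)

    def test_duplicate_linear_thyroid_route_not_doubled(self):
        # the constant-rate table repeats the thyroid iodide route with its
        # linear-regime k; only the carrier version must be instantiated
        p = load_parameters(0)
        n = sum(
            1 for f in p.flows
            if f.source == "blood" and f.target == "thyroid_iodide"
        )
        assert n == 1

    def test_fetal_wc_threshold_scales_with_gland_weight(self):
        # 4.375% of (500 ug/g x gland weight), in umol of stable iodine
        thr = fetal_wc_threshold(1.30)
        assert thr == pytest.approx(0.04375 * 500 * 1.30 / 126.904, rel=1e-9)


class TestValidateTables:
    def test_shipped_data_has_no_violations(self):
        assert validate_tables() == []

    def test_perturbed_tmax_is_flagged(self):
        from thyroblock.parameters import _read_csv

        carrier = _read_csv("carrier_flows.csv").copy()
        mask = (carrier["flow"] == "Blood to salivary gland") & (
            carrier["param"] == "tmax"
        )
        carrier.loc[mask, "w0"] = carrier.loc[mask, "w0"].astype(float) * 2
        problems = validate_tables(carrier)
        assert len(problems) == 1
        assert "salivary" in problems[0]

    def test_week16_fetal_consistency(self):
        p = load_parameters(16)
        f = p.flow("fetal_iodide", "fetal_thyroid")
        assert f.km_abs == pytest.approx(9 * 0.111, rel=1e-9)


def test_all_weeks_load_and_are_frozen():
    for week in SUPPORTED_WEEKS:
        p = load_parameters(week)
        with pytest.raises(dataclasses.FrozenInstanceError):
            p.week = 99
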