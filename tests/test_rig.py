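"""Plug-flow rig: volumes, conservation, dispersion, window readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramanline import ChannelGeometry, Rig, tube_volume
from ramanline.rig import RigError


class TestTubeVolume:
    # pi * r^2 * L oracle, 1 mm^3 = 1 uL
    @pytest.mark.parametrize(
        "length,diameter,expected",
        [(125.0, 0.508, np.pi * 0.254**2 * 125), (65.0, 0.508, np.pi * 0.254**2 * 65), (0.0, 0.508, 0.0)],
    )
    def test_cylinder_volume(self, length, diameter, expected):
        assert tube_volume(length, diameter) == pytest.approx(expected)

    def test_supply_tubes_match_rig_defaults(self, geometry):
        assert geometry.tube_well_to_valve == pytest.approx(25.335, abs=0.01)
        assert geometry.tube_valve_to_cuvette == pytest.approx(13.174, abs=0.01)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            tube_volume(-1.0, 0.5)


class TestGeometry:
    def test_window_inside_cuvette_enforced(self):
        with pytest.raises(Exception):
            ChannelGeometry(window_interval=(4.0, 30.0))

    def test_default_well_capacity(self, geometry):
        assert geometry.well_capacity == 125.0


class TestSelectChannel:
    def test_valve_switch_advances_clock(self, rig):
        rig.select_channel(1)
        rig.select_channel(3)
        assert rig.clock == pytest.approx(2 * 1.3)

    def test_reselecting_same_channel_still_costs_time(self, rig):
        rig.select_channel(2)
        rig.select_channel(2)
        assert rig.clock == pytest.approx(2 * 1.3)

    def test_out_of_range_channel(self, rig):
        with pytest.raises(RigError):
            rig.select_channel(9)
        with pytest.raises(RigError):
            rig.select_channel(0)


class TestPipette:
    def test_into_empty_well_keeps_concentration(self, rig):
        # wells start at dead volume of wash (5 uL), so account for it
        rig.channels[1].well_volume = 0.0
        rig.pipette_sample(1, 50.0, {"glucose": 10.0})
        assert rig.channels[1].well_conc["glucose"] == pytest.approx(10.0)

    def test_mass_balance_dilution(self, rig):
        ch = rig.channels[1]
        ch.well_volume, ch.well_conc = 50.0, {}
        rig.pipette_sample(1, 50.0, {"glucose": 10.0})
        assert ch.well_conc["glucose"] == pytest.approx(5.0)
        assert ch.well_volume == pytest.approx(100.0)

    def test_overflow_routed_to_waste(self, rig):
        ch = rig.channels[1]
        ch.well_volume = 100.0
        rig.pipette_sample(1, 50.0, {"glucose": 10.0})
        assert ch.well_volume == pytest.approx(125.0)
        assert rig.waste_volume == pytest.approx(25.0)


class TestPump:
    def test_zero_volume_only_advances_clock(self, rig):
        rig.select_channel(1)
        before = rig.snapshot()["channels"]
        rig.pump("forward", 0.0, rate=10.0)
        assert rig.snapshot()["channels"] == before

    def test_requires_selected_channel(self, rig):
        with pytest.raises(RigError):
            rig.pump("forward", 10.0, rate=10.0)

    def test_composition_two_steps_equal_one(self, geometry):
        """Pump V1 then V2 leaves the same state as pumping V1+V2."""
        def run(volumes):
            rig = Rig(geometry, rng=0)
            rig.pipette_sample(1, 50.0, {"glucose": 10.0})
            rig.select_channel(1)
            for v in volumes:
                rig.pump("forward", v, rate=10.0)
            snap = rig.snapshot()["channels"][1]
            return snap
        a = run([30.0, 25.0])
        b = run([55.0])
        assert a["well_volume"] == pytest.approx(b["well_volume"])
        for seg_a, seg_b in zip(a["segments"], b["segments"]):
            assert seg_a[0] == seg_b[0]
            assert seg_a[2] == pytest.approx(seg_b[2])

    def test_forward_with_empty_well_draws_air(self, rig):
        rig.select_channel(1)
        rig.pump("forward", 20.0, rate=10.0)  # well has only dead volume
        assert rig.channels[1].segments[0].label == "air"

    def test_reversibility_without_dispersion(self, geometry):
        """Forward V then reverse V restores the label profile.

        The well must hold enough wash that no air is drawn, and V must stay
        below the downstream volume so nothing irreversibly leaves the path.
        """
        rig = Rig(geometry, rng=0)
        ch = rig.channels[1]
        ch.well_volume = 120.0
        rig.pipette_sample(1, 5.0, {"glucose": 10.0})
        rig.select_channel(1)
        before = [(s.label, s.volume) for s in ch.segments]
        rig.pump("forward", 40.0, rate=10.0)
        rig.pump("reverse", 40.0, rate=10.0)
        after = [(s.label, s.volume) for s in ch.segments]
        assert len(before) == len(after)
        for (la, va), (lb, vb) in zip(before, after):
            assert la == lb and va == pytest.approx(vb)


@settings(max_examples=20, deadline=None)
@given(st.lists(st.tuples(st.sampled_from(["forward", "reverse"]),
                          st.floats(0.0, 80.0)), min_size=1, max_size=100),
       st.integers(0, 2**31 - 1))
def test_volume_conservation_through_action_sequences(actions, seed):
    """Liquid in (initial + pipetted + reservoir + tee) == liquid held + waste."""
    rig = Rig(rng=seed)
    rig.pipette_sample(1, 50.0, {"glucose": 10.0})
    rig.select_channel(1)
    for direction, volume in actions:
        rig.pump(direction, volume, rate=50.0,
                 well_draw_fraction=0.3 if direction == "forward" else 1.0)
    assert rig.liquid_inventory() == pytest.approx(rig.liquid_input(), abs=1e-6)


class TestDispersion:
    def test_kappa_zero_is_identity(self, rig):
        rig.pipette_sample(1, 50.0, {"glucose": 10.0})
        rig.select_channel(1)
        rig.pump("forward", 60.0, rate=10.0)
        before = rig.snapshot()["channels"][1]["segments"]
        rig.apply_dispersion(60.0, kappa=0.0)
        assert rig.snapshot()["channels"][1]["segments"] == before

    def test_mass_conserved_exactly(self, geometry):
        rig = Rig(geometry, rng=0)
        rig.pipette_sample(1, 50.0, {"glucose": 10.0, "acetate": 2.0})
        rig.select_channel(1)
        rig.pump("forward", 60.0, rate=10.0)
        mass = {a: rig.channels[1].analyte_mass(a) for a in ("glucose", "acetate")}
        rig.apply_dispersion(60.0, kappa=3.0)
        for analyte, before in mass.items():
            assert rig.channels[1].analyte_mass(analyte) == pytest.approx(before, rel=1e-9)

    def test_larger_kappa_lowers_peak_window_concentration(self, quiet_profile):
        def window_peak(kappa):
            geom = ChannelGeometry(dispersion_kappa=kappa)
            rig = Rig(geom, profile=quiet_profile, rng=0)
            rig.pipette_sample(1, 50.0, {"glucose": 10.0})
            rig.select_channel(1)
            rig.pump("forward", 115.0, rate=10.0)
            conc, _ = rig.window_contents()
            return conc.get("glucose", 0.0)
        peaks = [window_peak(k) for k in (0.0, 2.0, 4.0)]
        assert peaks[0] > peaks[1] > peaks[2] > 0


class TestWindowContents:
    def _fill_window_with(self, rig, conc, volume=60.0):
        rig.channels[1].well_volume = 0.0
        rig.pipette_sample(1, 120.0, conc)
        rig.select_channel(1)
        rig.pump("forward", rig.geometry.window_bounds[1] + 1.0, rate=10.0)

    def test_window_inside_single_plug(self, rig):
        self._fill_window_with(rig, {"glucose": 10.0})
        conc, air = rig.window_contents()
        assert conc["glucose"] == pytest.approx(10.0)
        assert air == 0.0

    def test_half_sample_half_wash_weighted_average(self, geometry):
        rig = Rig(geometry, rng=0)
        lo, hi = geometry.window_bounds
        mid = (lo + hi) / 2
        ch = rig.channels[1]
        from ramanline.rig import Segment
        ch.segments = [Segment("wash", {}, mid),
                       Segment("sample", {"glucose": 10.0}, geometry.path_volume - mid)]
        rig.selected = 1
        conc, air = rig.window_contents()
        assert conc["glucose"] == pytest.approx(5.0)
        assert air == 0.0

    def test_all_air_window(self, geometry):
        rig = Rig(geometry, rng=0)
        from ramanline.rig import Segment
        ch = rig.channels[1]
        ch.segments = [Segment("air", None, geometry.path_volume)]
        rig.selected = 1
        conc, air = rig.window_contents()
        assert air == 1.0
        assert conc == {}


class TestReadIntensity:
    def test_wash_window_gives_baseline_only(self, quiet_rig):
        quiet_rig.select_channel(1)
        s = quiet_rig.read_intensity()
        from ramanline.spectra import baseline
        np.testing.assert_allclose(s.intensities, baseline(quiet_rig.profile, s.wavenumbers))

    def test_sulfate_window_band_exceeds_wash(self, geometry, profile):
        from ramanline.calibration import band_mean
        rig = Rig(geometry, profile=profile, rng=0)
        rig.select_channel(1)
        wash = band_mean(rig.read_intensity(), 960, 1000)
        rig.channels[1].well_volume = 0.0
        rig.pipette_sample(1, 120.0, {"mgso4": 50.0})
        rig.pump("forward", geometry.window_bounds[1] + 1.0, rate=10.0)
        loaded = band_mean(rig.read_intensity(), 960, 1000)
        assert loaded - wash > 5 * profile.noise_sd

    def test_metadata_carries_channel_and_clock(self, rig):
        rig.select_channel(4)
        s = rig.read_intensity()
        assert s.meta["channel"] == 4
        assert s.meta["clock_s"] == pytest.approx(1.3)


def test_monotone_plug_arrival(quiet_profile, geometry):
    """Window occupancy rises from 0 to a maximum, then falls, as V_sc grows."""
    occupancies = []
    for v_sc in np.arange(0.0, 260.0, 10.0):
        rig = Rig(geometry, profile=quiet_profile, rng=0)
        rig.pipette_sample(1, 50.0, {"glucose": 10.0})
        rig.select_channel(1)
        if v_sc:
            rig.pump("forward", float(v_sc), rate=50.0)
        conc, _ = rig.window_contents()
        occupancies.append(conc.get("glucose", 0.0))
    peak = int(np.argmax(occupancies))
    assert occupancies[0] == 0.0
    assert occupancies[peak] > 0
    assert all(a <= b + 1e-9 for a, b in zip(occupancies[:peak], occupancies[1:peak + 1]))
    assert all(a >= b - 1e-9 for a, b in zip(occupancies[peak:], occupancies[peak + 1:]))


def test_snapshot_dump_is_json(tmp_path, rig):
    rig.select_channel(1)
    path = tmp_path / "state.json"
    rig.dump_json(path)
    import json
    snap = json.loads(path.read_text())
    assert snap["selected"] == 1
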