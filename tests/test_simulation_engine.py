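"""Engine orchestration: protocols, metrics, scans, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dendramp as dd
from dendramp.params import ProtocolError


class TestRunProtocol:
    def test_empty_protocol_uniform_rest(self):
        spec = dd.ProtocolSpec(name="empty", duration=15.0)
        field = dd.run_protocol(spec, positions=[0.0, 500.0, 1000.0])
        assert np.all(field.values == -65.0)

    def test_field_starts_at_rest(self, run_fig1c):
        assert np.all(run_fig1c.values[:, 0] == -65.0)

    def test_deterministic_bit_identical(self):
        a = dd.run_protocol(dd.get_preset("fig1c"), positions=[1000.0])
        b = dd.run_protocol(dd.get_preset("fig1c"), positions=[1000.0])
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.meta["soma_trace_full"],
                                      b.meta["soma_trace_full"])

    def test_invalid_positions_rejected(self):
        with pytest.raises(ProtocolError):
            dd.ProtocolSpec(name="bad",
                            inputs=(dd.SynapticInput(position=2000.0, onset=0.5),))

    def test_short_duration_rejected(self):
        with pytest.raises(ProtocolError):
            dd.ProtocolSpec(name="bad",
                            inputs=(dd.SynapticInput(position=0.0, onset=5.0),),
                            duration=10.0)

    def test_more_than_four_inputs_warns(self):
        inputs = tuple(dd.SynapticInput(position=float(i), onset=0.5)
                       for i in range(5))
        spec = dd.ProtocolSpec(name="many", inputs=inputs, duration=12.0)
        with pytest.warns(UserWarning):
            dd.run_protocol(spec, positions=[1000.0])


class TestMetrics:
    def test_constant_trace(self):
        s = dd.peak_metrics(np.full(5, -65.0), np.arange(5.0), rest=-65.0)
        assert s.peak_amplitude == 0.0
        assert s.peak_time == 0.0

    def test_simple_bump_earliest_tie(self):
        s = dd.peak_metrics(np.array([-65.0, -64.0, -64.0, -65.0]),
                            np.array([0.0, 1.0, 2.0, 3.0]), rest=-65.0)
        assert s.peak_amplitude == pytest.approx(1.0)
        assert s.peak_time == 1.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            dd.peak_metrics(np.array([]))

    def test_soma_trace_is_far_edge_row(self, run_fig1c):
        tr = dd.soma_trace(run_fig1c)
        assert tr.shape == (run_fig1c.times.size,)
        np.testing.assert_array_equal(
            tr, run_fig1c.values[np.argmax(run_fig1c.positions)])

    def test_amplification_gain(self, run_fig1a, run_fig1c):
        gain = dd.amplification_gain(run_fig1c, run_fig1a)
        assert gain > 1.0
        assert dd.amplification_gain(run_fig1a, run_fig1a) == pytest.approx(1.0)


class TestScans:
    def test_interval_scan_table_shape(self, interval_table):
        assert list(interval_table["interval"]) == [0.3, 1.3, 3.0]
        assert (interval_table["peak_amplitude"] > 0).all()

    def test_latency_zero_offset_matches_base(self):
        base = dd.get_preset("fig1c")
        a = dd.scan_latency(base, [0.0], order="cluster_first",
                            include_baseline=False)
        b = dd.scan_latency(base, [0.0], order="epsp_first",
                            include_baseline=False)
        assert a["peak_amplitude"][0] == pytest.approx(b["peak_amplitude"][0])
        assert a["peak_time"][0] == pytest.approx(b["peak_time"][0])

    def test_latency_amplitude_declines_with_delay(self):
        base = dd.get_preset("fig2b")
        tab = dd.scan_latency(base, [0.0, 3.0, 9.0], order="cluster_first",
                              include_baseline=True)
        amp = tab["peak_amplitude"].to_numpy()
        assert amp[0] > amp[1] > amp[2]
        # final row is the no-input baseline (offset = inf)
        assert np.isinf(tab["offset"].iloc[-1])
        assert amp[-1] < amp[2]

    def test_spacing_zero_matches_interval_scan(self, interval_table):
        base = dd.get_preset("fig2b")
        spaced = dd.scan_spacing(base, [0.3], spacing=1.0)
        assert spaced["peak_amplitude"][0] == pytest.approx(
            interval_table["peak_amplitude"][0])

    def test_position_scan_rows(self, position_table):
        assert list(position_table["position"]) == [200.0, 300.0, 400.0, 700.0]
        assert position_table["peak_amplitude"].is_monotonic_increasing

    def test_decay_scan_amplitude_increases_with_tau(self, decay_table):
        amp = decay_table["peak_amplitude"].to_numpy()
        assert np.all(np.diff(amp) > 0)

    def test_scans_without_cluster_rejected(self):
        base = dd.get_preset("fig1a")
        with pytest.raises(ProtocolError):
            dd.scan_cluster_position(base, [400.0])
        with pytest.raises(ProtocolError):
            dd.scan_decay_constant(base, [50.0])


class TestPresets:
    def test_registry_complete(self):
        names = {"fig1a", "fig1b", "fig1c", "fig2a", "fig2b", "fig3",
                 "fig4", "fig5", "fig6", "fig7"}
        assert names == set(dd.PRESETS)
        for name in names:
            spec = dd.get_preset(name)
            assert spec.name == name
            assert spec.duration > 10.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ProtocolError):
            dd.get_preset("fig99")


class TestNumericalStability:
    def test_dt_halving_changes_peak_below_one_percent(self):
        spec = dd.get_preset("fig1c")
        coarse = dd.run_protocol(spec, positions=[1000.0])
        cable = dataclasses.replace(spec.params.cable, dt=0.005)
        fine_spec = dataclasses.replace(
            spec, params=dataclasses.replace(spec.params, cable=cable))
        fine = dd.run_protocol(fine_spec, positions=[1000.0])
        a = coarse.meta["soma_trace_full"].max() + 65.0
        b = fine.meta["soma_trace_full"].max() + 65.0
        assert abs(a - b) / a < 0.01
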