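"""Shared fixtures: canonical protocol runs reused across test modules."""

import numpy as np
import pytest

import dendramp as dd

FAR_EDGE = 1000.0


@pytest.fixture(scope="session")
def membrane():
    return dd.MembraneParams()


@pytest.fixture(scope="session")
def cable():
    return dd.CableParams()


@pytest.fixture(scope="session")
def single_event():
    """One default synaptic event integrated against a resting baseline."""
    return dd.simulate_synaptic_event(
        dd.SynapticInput(position=0.0, onset=0.5), None,
        dd.MembraneParams(), dt=0.01, duration=40.0,
    )


def _far_edge_run(name):
    field = dd.run_protocol(dd.get_preset(name), positions=[FAR_EDGE])
    return field


@pytest.fixture(scope="session")
def run_fig1a():
    return _far_edge_run("fig1a")


@pytest.fixture(scope="session")
def run_fig1b():
    return _far_edge_run("fig1b")


@pytest.fixture(scope="session")
def run_fig1c():
    return _far_edge_run("fig1c")


@pytest.fixture(scope="session")
def run_fig2b():
    return _far_edge_run("fig2b")


@pytest.fixture(scope="session")
def interval_table():
    return dd.scan_interval(dd.get_preset("fig2b"), [0.3, 1.3, 3.0])


@pytest.fixture(scope="session")
def position_table():
    return dd.scan_cluster_position(dd.get_preset("fig6"),
                                    [200.0, 300.0, 400.0, 700.0])


@pytest.fixture(scope="session")
def decay_table():
    return dd.scan_decay_constant(dd.get_preset("fig2b"),
                                  [10.0, 20.0, 50.0, 100.0])


def far_trace(field):
    """Full-resolution far-edge trace and its time axis."""
    return field.meta["times_full"], field.meta["soma_trace_full"]


def far_peak(field, rest=-65.0):
    t, v = far_trace(field)
    s = dd.peak_metrics(v, t, rest=rest, location=FAR_EDGE)
    return s
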