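"""Cable kernel analytics and the discrete convolution machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendramp as dd
from dendramp.cable_propagation import discrete_kernel
from dendramp.params import ProtocolError


class TestKernel:
    def test_even_in_offset(self, cable):
        t = np.linspace(0.01, 40, 500)
        for x in (1.0, 50.0, 400.0, 999.0):
            np.testing.assert_allclose(
                dd.cable_kernel(x, t, cable), dd.cable_kernel(-x, t, cable))

    def test_rejects_nonpositive_time(self, cable):
        with pytest.raises(ValueError):
            dd.cable_kernel(10.0, 0.0, cable)

    @settings(max_examples=25, derandomize=True)
    @given(t=st.floats(0.05, 40.0))
    def test_decreasing_in_distance_at_fixed_time(self, t):
        cable = dd.CableParams()
        xs = np.linspace(0.0, 1000.0, 40)
        k = np.array([dd.cable_kernel(x, t, cable) for x in xs])
        assert np.all(np.diff(k) < 0)

    def test_time_integral_matches_closed_form(self, cable):
        """Numeric integration agrees with the erf-based antiderivative.

        Integration starts away from the 1/sqrt(t) onset; both sides use
        the same window [t0, 300] ms.
        """
        t0 = 0.5
        for x in (0.0, 100.0, 400.0):
            t = np.linspace(t0, 300.0, 2_000_001)
            numeric = np.trapezoid(dd.cable_kernel(x, t, cable), t)
            closed = (dd.cable_kernel_integral(x, 300.0, cable)
                      - dd.cable_kernel_integral(x, t0, cable))
            assert numeric == pytest.approx(closed, rel=1e-6)

    def test_steady_state_space_constant_attenuation(self, cable):
        """Integrated response decays as exp(-x/lambda): e-fold at 400 um."""
        total0 = dd.cable_kernel_integral(0.0, 1e5, cable)
        total400 = dd.cable_kernel_integral(400.0, 1e5, cable)
        assert total400 / total0 == pytest.approx(np.exp(-1.0), rel=1e-6)
        assert total0 == pytest.approx(cable.r_lambda, rel=1e-6)


class TestPropagation:
    def test_convolution_matches_brute_force(self, cable):
        """FFT path equals the O(T^2) direct sum on a 50-sample toy series."""
        rng = np.random.default_rng(7)
        i = rng.uniform(0, 20, 50)          # 0.5 ms of current at 10 us
        field = dd.propagate_current(0.0, i, cable, positions=[0.0, 5.0, 200.0])
        for row, x in zip(field.values, [0.0, 5.0, 200.0]):
            k = discrete_kernel(x, 50, cable)
            direct = np.array([
                sum(i[m] * k[j - m] for m in range(j + 1)) * cable.dt
                for j in range(50)
            ])
            np.testing.assert_allclose(row, direct, atol=1e-9)

    def test_zero_current_zero_field(self, cable):
        field = dd.propagate_current(0.0, np.zeros(100), cable,
                                     positions=[0.0, 500.0])
        assert np.all(field.values == 0.0)

    def test_linearity_in_current(self, cable):
        rng = np.random.default_rng(3)
        i1 = rng.uniform(0, 10, 200)
        i2 = rng.uniform(0, 10, 200)
        pos = [0.0, 100.0, 1000.0]
        f1 = dd.propagate_current(0.0, i1, cable, positions=pos)
        f2 = dd.propagate_current(0.0, i2, cable, positions=pos)
        f12 = dd.propagate_current(0.0, i1 + i2, cable, positions=pos)
        np.testing.assert_allclose(f12.values, f1.values + f2.values,
                                   atol=1e-9)
        fd = dd.propagate_current(0.0, 2.0 * i1, cable, positions=pos)
        np.testing.assert_allclose(fd.values, 2.0 * f1.values, atol=1e-9)

    def test_causal_before_first_nonzero_sample(self, cable):
        i = np.zeros(300)
        i[100:] = 5.0
        field = dd.propagate_current(0.0, i, cable, positions=[0.0, 50.0])
        assert np.all(field.values[:, :101] == 0.0)
        assert field.values[0, 150] > 0.0

    def test_peak_attenuates_and_slows_with_distance(self, cable):
        i = np.zeros(3000)
        i[50:150] = 15.0                     # 1 ms pulse
        xs = np.linspace(0.0, 900.0, 10)
        field = dd.propagate_current(0.0, i, cable, positions=xs)
        peaks = field.values.max(axis=1)
        assert np.all(np.diff(peaks) < 0)
        tpk = field.times[np.argmax(field.values, axis=1)]
        probe = tpk[[0, 4, 9]]
        assert probe[0] < probe[1] < probe[2]

    def test_source_outside_cable_rejected(self, cable):
        with pytest.raises(ProtocolError):
            dd.propagate_current(-5.0, np.zeros(10), cable)


class TestSuperpose:
    def test_empty_list_gives_uniform_rest(self):
        grid = (np.array([0.0, 1.0]), np.array([0.0, 0.5, 1.0]))
        f = dd.superpose([], v_rest=-65.0, grid=grid)
        assert np.all(f.values == -65.0)

    def test_single_contribution_offsets_by_rest(self, cable):
        i = np.ones(50) * 4.0
        c = dd.propagate_current(0.0, i, cable, positions=[0.0, 10.0])
        f = dd.superpose([c], v_rest=-65.0)
        np.testing.assert_allclose(f.values, c.values - 65.0)

    def test_four_identical_contributions_quadruple(self, cable):
        i = np.ones(50) * 4.0
        c = dd.propagate_current(0.0, i, cable, positions=[0.0, 10.0])
        f = dd.superpose([c] * 4, v_rest=0.0)
        np.testing.assert_allclose(f.values, 4.0 * c.values, atol=1e-12)

    def test_grid_mismatch_rejected(self, cable):
        a = dd.propagate_current(0.0, np.ones(50), cable, positions=[0.0])
        b = dd.propagate_current(0.0, np.ones(60), cable, positions=[0.0])
        with pytest.raises(ValueError):
            dd.superpose([a, b])
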