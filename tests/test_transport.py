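"""Depth-averaged advection–diffusion solver and transport arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from astrocal.transport import (DeviceGeometry, TransportParams,
                                cell_site_points, chamber_turnover, dilution,
                                groove_concentrations, peclet, solve_on_maps,
                                solve_steady)


@pytest.fixture(scope="module")
def default_field():
    geo = DeviceGeometry()
    return geo, solve_steady(geo, TransportParams())


class TestSolver:
    def test_zero_grooves_keeps_chambers_disconnected(self):
        geo = DeviceGeometry(n_grooves=0)
        field = solve_steady(geo, TransportParams())
        nxc = int(round(geo.chamber_width / 2.5))
        left, right = field.c[:, :nxc], field.c[:, -nxc:]
        np.testing.assert_allclose(left, 1.0, atol=1e-9)
        np.testing.assert_allclose(right, 0.0, atol=1e-9)

    def test_single_groove_no_flow_laplace_midpoint(self):
        """With Q = 0 and symmetric 1/0 boundaries the groove profile is
        linear; its midpoint sits at exactly 0.5 mM."""
        geo = DeviceGeometry(n_grooves=1)
        field = solve_steady(geo, TransportParams(Q=0.0))
        nxc = int(round(geo.chamber_width / 2.5))
        nxw = int(round(geo.groove_length / 2.5))
        y = (np.arange(field.c.shape[0]) + 0.5) * 2.5
        rows = np.abs(y - geo.groove_centers()[0]) <= geo.groove_width / 2
        mid = np.nanmean(field.c[rows, nxc + nxw // 2 - 1: nxc + nxw // 2 + 1])
        assert mid == pytest.approx(0.5, abs=1e-9)

    def test_1d_advection_diffusion_closed_form(self):
        """Single uniform channel with Dirichlet ends matches
        c(x) = (e^{Pe·x/L} − e^{Pe})/(1 − e^{Pe}) to < 1% L2 error."""
        D, L, Pe, N = 50.0, 1000.0, 5.0, 1000
        u = Pe * D / L
        h = np.ones((N, 1))
        c, resid = solve_on_maps(h, np.array([u]), L / N, D,
                                 inlet_value=np.array([1.0]),
                                 outlet_value=np.array([0.0]))
        assert resid < 1e-10
        x = (np.arange(N) + 0.5) * L / N
        exact = (np.exp(Pe * x / L) - np.exp(Pe)) / (1 - np.exp(Pe))
        err = np.linalg.norm(c[:, 0] - exact) / np.linalg.norm(exact)
        assert err < 0.01

    def test_maximum_principle_on_default_geometry(self, default_field):
        _, field = default_field
        assert np.nanmin(field.c) >= 0.0 - 1e-9
        assert np.nanmax(field.c) <= 1.0 + 1e-9
        assert field.residual < 1e-10

    def test_zero_diffusion_limit_flushes_groove_exit(self):
        """As D shrinks the groove flux vanishes, so the swept low chamber
        pins the concentration just outside the groove exit at c_right and
        the in-groove end value drops toward its geometric floor."""
        geo = DeviceGeometry()
        exit_pt = [(geo.chamber_width + geo.groove_length + 1.25,
                    float(geo.groove_centers()[6]))]
        small = solve_steady(geo, TransportParams(D=5e-9))
        default = solve_steady(geo, TransportParams())
        assert small.probe(exit_pt)[0] < 1e-3
        g_small = groove_concentrations(small, geo)["end_mM"].median()
        g_default = groove_concentrations(default, geo)["end_mM"].median()
        assert g_small < g_default

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="grid too coarse"):
            solve_steady(DeviceGeometry(), TransportParams(grid=6.0))

    def test_geometry_validation(self):
        with pytest.raises(ValueError, match="fit"):
            DeviceGeometry(n_grooves=50, groove_pitch=50.0)
        with pytest.raises(ValueError):
            DeviceGeometry(groove_depth=0.0)


class TestProbe:
    def test_inlet_probe_returns_boundary_value(self, default_field):
        geo, field = default_field
        assert field.probe([(10.0, 0.0)])[0] == 1.0
        x_right = geo.chamber_width + geo.groove_length + 10.0
        assert field.probe([(x_right, 0.0)])[0] == 0.0

    def test_probe_deterministic(self, default_field):
        _, field = default_field
        pt = [(100.0, 200.0)]
        assert field.probe(pt)[0] == field.probe(pt)[0]

    def test_probe_outside_domain_rejected(self, default_field):
        _, field = default_field
        with pytest.raises(ValueError, match="outside domain"):
            field.probe([(-5.0, 10.0)])

    def test_cell_sites_probe_near_zero(self, default_field):
        geo, field = default_field
        conc = field.probe(cell_site_points(geo))
        assert np.median(conc) < 0.01


class TestArithmetic:
    def test_chamber_turnover_worked_case(self):
        assert chamber_turnover(0.6, 0.03) == pytest.approx(20.0)
        assert chamber_turnover(1.0, 1.0) == 1.0

    @given(v=st.floats(0.1, 10.0), q=st.floats(0.01, 5.0))
    def test_turnover_halves_when_flow_doubles(self, v, q):
        assert chamber_turnover(v, 2 * q) == pytest.approx(chamber_turnover(v, q) / 2)

    def test_turnover_bad_flow_rejected(self):
        with pytest.raises(ValueError):
            chamber_turnover(0.6, 0.0)

    def test_dilution_worked_cases(self):
        assert dilution([100.0, 100.0], [100.0, 0.0]) == pytest.approx(50.0)
        assert dilution([7.0], [3.3]) == pytest.approx(3.3)
        assert dilution([50.0, 150.0], [4.0, 0.0]) == pytest.approx(1.0)

    def test_dilution_validation(self):
        with pytest.raises(ValueError):
            dilution([], [])
        with pytest.raises(ValueError):
            dilution([1.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            dilution([1.0], [1.0, 2.0])

    @given(st.lists(st.tuples(st.floats(0.1, 100.0), st.floats(0.0, 100.0)),
                    min_size=1, max_size=6))
    def test_dilution_bounded_by_inputs(self, pairs):
        v, c = zip(*pairs)
        out = dilution(list(v), list(c))
        assert min(c) - 1e-9 <= out <= max(c) + 1e-9

    def test_peclet_values(self):
        geo, par = DeviceGeometry(), TransportParams()
        pe = peclet(geo, par)
        assert pe["groove"] == 0.0
        assert pe["chamber_left"] == pytest.approx(250.0)
        pe0 = peclet(geo, TransportParams(Q=0.0))
        assert all(v == 0.0 for v in pe0.values())
        pe2 = peclet(geo, TransportParams(Q=0.06))
        assert pe2["chamber_left"] == pytest.approx(2 * pe["chamber_left"])
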