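"""Nodal analysis: assembly, solving, and the physical invariants of a
purely resistive network (superposition, reciprocity, conservation)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cochleanet as cn
from cochleanet.network import CurrentVector, transfer_resistance

from conftest import LADDER_NODES, ladder_decay_root


def tiny_model(n_nodes=2, shunt=np.inf, basal=np.inf, apical=np.inf, r_seg=1000.0):
    """n-node straight saline column with prescribed element values."""
    conductivity = 1.0
    area = 1000.0 / (conductivity * r_seg)
    length = float(max(n_nodes - 1, 1))
    geometry = cn.build_lumen(
        total_length=length, step=1.0, taper_shape="table",
        area_table=np.array([[0.0, area], [length, area]]),
    )
    return cn.CochleaModel(
        geometry=geometry,
        saline_conductivity=conductivity,
        transverse_resistances=np.full(geometry.n_nodes, shunt, dtype=float),
        basal_boundary_resistance=basal,
        apical_boundary_resistance=apical,
    )


class TestAssembleAndSolve:
    def test_floating_network_raises(self):
        m = tiny_model(n_nodes=2)  # no shunts, no boundaries
        net = cn.assemble(m)
        with pytest.raises(cn.FloatingNetworkError):
            cn.solve(net, CurrentVector(np.array([1.0, -1.0]), 0.0))

    def test_single_shunt_ohms_law(self):
        # two nodes, one grounded through 1 kohm at node 0; inject there
        m = tiny_model(n_nodes=2, shunt=np.array([1000.0, np.inf]))
        net = cn.assemble(m)
        v = cn.solve(net, CurrentVector(np.array([1000.0, 0.0]), -1000.0))
        assert v.voltages_mV[0] == pytest.approx(1000.0, rel=1e-12)
        # no current flows along the lumen, so node 1 floats at node 0's level
        assert v.voltages_mV[1] == pytest.approx(1000.0, rel=1e-12)

    def test_symmetric_injection_symmetric_voltages(self):
        m = tiny_model(n_nodes=3, shunt=500.0)
        net = cn.assemble(m)
        v = cn.solve(net, CurrentVector(np.array([0.0, 100.0, 0.0]), -100.0))
        assert v.voltages_mV[0] == pytest.approx(v.voltages_mV[2], rel=1e-12)

    def test_grounded_default_model_positive_definite(self, network):
        network.factorization()  # Cholesky must succeed

    def test_unbalanced_currents_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            CurrentVector(np.array([1.0, 0.0]), 0.0)

    def test_conductance_matrix_structure(self, network):
        g = network.conductance_matrix
        np.testing.assert_allclose(g, g.T)
        off = g[~np.eye(g.shape[0], dtype=bool)]
        assert np.all(off <= 0)
        np.testing.assert_allclose(g.sum(axis=1), 0.0, atol=1e-15)


class TestLadderOracle:
    def test_interior_decay_matches_closed_form(self, uniform_ladder):
        net = cn.assemble(uniform_ladder)
        n = LADDER_NODES
        inject = 100
        i = np.zeros(n)
        i[inject] = 1000.0
        v = cn.solve(net, CurrentVector(i, -1000.0)).voltages_mV
        rho = ladder_decay_root()
        # >= 10 sections from the injection, >= 20 from either end
        for k in range(inject + 10, n - 20):
            assert v[k + 1] / v[k] == pytest.approx(rho, rel=1e-3)
        for k in range(21, inject - 10):
            assert v[k - 1] / v[k] == pytest.approx(rho, rel=1e-3)

    def test_transfer_resistance_monotone_in_distance(self, uniform_ladder):
        net = cn.assemble(uniform_ladder)
        r = [transfer_resistance(net, 100, 100 + d) for d in range(0, 40, 5)]
        assert np.all(np.diff(r) < 0)


class TestResistiveInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_superposition(self, network, seed):
        rng = np.random.default_rng(seed)
        n = network.n_lumen_nodes
        i1 = rng.normal(size=n) * 100
        i2 = rng.normal(size=n) * 100
        v1 = cn.solve(network, CurrentVector(i1, -i1.sum())).voltages_mV
        v2 = cn.solve(network, CurrentVector(i2, -i2.sum())).voltages_mV
        v12 = cn.solve(
            network, CurrentVector(i1 + i2, -(i1 + i2).sum())
        ).voltages_mV
        np.testing.assert_allclose(
            v12, v1 + v2, rtol=1e-12, atol=1e-12 * np.abs(v12).max()
        )

    def test_reciprocity_random_pairs(self, network):
        rng = np.random.default_rng(7)
        n = network.n_lumen_nodes
        for _ in range(100):
            a, b = rng.integers(0, n, size=2)
            r_ab = transfer_resistance(network, int(a), int(b))
            r_ba = transfer_resistance(network, int(b), int(a))
            assert r_ab == pytest.approx(r_ba, rel=1e-9)

    def test_current_conservation(self, model, network):
        n = network.n_lumen_nodes
        i = np.zeros(n)
        i[n // 2] = 800.0
        v = cn.solve(network, CurrentVector(i, -800.0)).voltages_mV * 1e-3  # V
        # ground-path currents: shunts + boundaries, amps
        shunt_i = np.where(
            np.isfinite(model.transverse_resistances),
            v / model.transverse_resistances,
            0.0,
        ).sum()
        shunt_i += v[0] / model.basal_boundary_resistance
        shunt_i += v[-1] / model.apical_boundary_resistance
        assert shunt_i == pytest.approx(800e-6, rel=1e-9)

    def test_no_shunt_limit_flat_apical_profile(self, layout):
        # insulating walls, apex sealed: only the basal opening grounds the
        # tube, so no current flows apically of the injection point and the
        # apical wires sit at one common potential
        m = cn.default_model(transverse_r_ohm=np.inf)
        m = cn.CochleaModel(
            geometry=m.geometry,
            saline_conductivity=m.saline_conductivity,
            transverse_resistances=m.transverse_resistances,
            basal_boundary_resistance=m.basal_boundary_resistance,
            apical_boundary_resistance=np.inf,
        )
        prof = cn.siv_profile(m, layout, cn.StimulusSpec(mode="MP"))
        apical = prof.values[7:]  # wires 8..14, at and beyond the injection
        assert np.ptp(apical) / np.abs(apical).max() < 0.01
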