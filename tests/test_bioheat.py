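"""Heat transport and temperature control: exact balances, monotonicity,
controller behaviour, and the orchestrated run."""

import numpy as np
import pandas as pd
import pytest

import rdnsim as rd
from rdnsim.bioheat import (
    ControllerState,
    ThermalState,
    ThermalSystem,
    _electrode_adjacency,
)
from rdnsim.geometry import FlowField


def _uniform_state(grid, T0):
    return ThermalState(
        T=np.full(grid.shape, float(T0)),
        t=0.0,
        Tmax=np.full(grid.shape, float(T0)),
    )


def _no_flow(grid):
    return FlowField(vz=np.zeros(grid.shape))


def test_equilibrium_preserved_exactly(small_grid, small_invivo_config):
    system = ThermalSystem(
        small_grid, small_invivo_config.materials, _no_flow(small_grid),
        dt=0.1, boundary_temperature=37.0,
    )
    state = _uniform_state(small_grid, 37.0)
    for _ in range(5):
        state = system.step(state, np.zeros(small_grid.shape))
    assert np.all(state.T == 37.0)
    assert np.all(state.Tmax == 37.0)


def test_adiabatic_heating_closed_form(small_grid, small_invivo_config):
    # insulated homogeneous block: dT = Qr dt / (rho c), conduction
    # switched off by uniformity
    materials = {
        key: rd.material_preset("abdominal") for key in
        ("tissue", "lumen", "electrode")
    }
    system = ThermalSystem(
        small_grid, materials, _no_flow(small_grid),
        dt=1.0, boundary_temperature=37.0, dirichlet_boundary=False,
    )
    state = _uniform_state(small_grid, 37.0)
    qr = np.full(small_grid.shape, 1060.0 * 3600.0)  # rho c per degC
    state = system.step(state, qr)
    np.testing.assert_allclose(state.T, 38.0, atol=1e-6)


def test_energy_audit_closed_box(small_grid, small_invivo_config, small_basis):
    # insulated, no flow: enthalpy gain equals fed electrical energy
    cfg = small_invivo_config
    system = ThermalSystem(
        small_grid, cfg.materials, _no_flow(small_grid),
        dt=0.1, boundary_temperature=37.0, dirichlet_boundary=False,
    )
    a = np.full(6, 8.0)
    sol = rd.compose_field(small_basis, a)
    state = _uniform_state(small_grid, 37.0)
    n_steps = 20
    for _ in range(n_steps):
        state = system.step(state, sol.qr)
    fed = float(np.dot(a, sol.current)) * n_steps * 0.1
    gained = float(
        (system.rho_c * (state.T - 37.0).ravel()).sum()
        * small_grid.cell_volume
    )
    assert fed > 0
    assert abs(gained - fed) / fed < 0.05


def test_advected_slug_translates_at_flow_speed():
    # method-of-characteristics oracle: a warm slug in a uniform plug
    # flow moves at v; upwinding may smear it but must stay bounded and
    # its center of mass must advance by v*t
    from rdnsim.geometry import DomainGrid, LABEL_LUMEN

    n = (4, 4, 120)
    labels = np.full(n, LABEL_LUMEN, dtype=np.int32)
    grid = DomainGrid(
        spacing=0.5e-3, shape=n, origin=(0, 0, 0), labels=labels,
        lumen_radius=2e-3, n_electrodes=0,
    )
    materials = {
        key: rd.material_preset("blood") for key in
        ("tissue", "lumen", "electrode")
    }
    # suppress conduction so pure advection is tested
    for m in materials.values():
        m.k = 1e-12
    v = 0.01  # m/s -> CFL = v dt / h = 2
    flow = FlowField(vz=np.full(n, v))
    system = ThermalSystem(
        grid, materials, flow, dt=0.1, boundary_temperature=37.0,
        dirichlet_boundary=False,
    )
    state = _uniform_state(grid, 37.0)
    z = grid.axis_centers(2)
    slug = (z > 5e-3) & (z < 10e-3)
    state.T[:, :, slug] = 50.0
    state.Tmax[:] = state.T
    com0 = np.average(z, weights=state.T[0, 0] - 37.0 + 1e-30)
    t_total = 1.0
    for _ in range(10):
        state = system.step(state, np.zeros(n))
    assert state.T.max() <= 50.0 + 1e-9
    assert state.T.min() >= 37.0 - 1e-9
    com1 = np.average(z, weights=state.T[0, 0] - 37.0 + 1e-30)
    assert com1 - com0 == pytest.approx(v * t_total, rel=0.05)


def test_overheat_raises(small_grid, small_invivo_config):
    system = ThermalSystem(
        small_grid, small_invivo_config.materials, _no_flow(small_grid),
        dt=1.0, boundary_temperature=37.0,
    )
    state = _uniform_state(small_grid, 37.0)
    qr = np.full(small_grid.shape, 1e9)
    with pytest.raises(rd.OverheatError, match="110"):
        system.step(state, qr)


class TestElectrodeProbe:
    def test_uniform_field_reads_uniform(self, small_grid):
        state = _uniform_state(small_grid, 37.0)
        T = rd.electrode_temperature(state, small_grid)
        np.testing.assert_allclose(T, 37.0)

    def test_probe_is_mean_of_adjacent_cells(self, small_grid):
        adjacency = _electrode_adjacency(small_grid)
        state = _uniform_state(small_grid, 37.0)
        cells = adjacency[0]
        state.T.ravel()[cells[0]] = 60.0
        T = rd.electrode_temperature(state, small_grid)
        n = len(cells)
        assert T[0] == pytest.approx((60.0 + 37.0 * (n - 1)) / n)

    def test_probe_monotone_in_cell_temperature(self, small_grid):
        adjacency = _electrode_adjacency(small_grid)
        state = _uniform_state(small_grid, 37.0)
        before = rd.electrode_temperature(state, small_grid)
        state.T.ravel()[adjacency[2]] += 5.0
        after = rd.electrode_temperature(state, small_grid)
        assert np.all(after >= before)


class TestController:
    settings = rd.ControlSettings(
        setpoint=60.0, kp=3.0, ki=0.8, max_amplitude=30.0,
        mode="per-electrode",
    )

    def test_zero_error_leaves_amplitude(self):
        c = ControllerState.initial(6)
        c.u[:] = 50.0
        out = rd.controller_update(
            c, np.full(6, 60.0), self.settings, dt=0.1
        )
        np.testing.assert_allclose(out.u, 50.0)

    def test_below_setpoint_never_decreases(self):
        c = ControllerState.initial(6)
        c.u[:] = 10.0
        out = rd.controller_update(
            c, np.full(6, 45.0), self.settings, dt=0.1
        )
        assert np.all(out.u >= 10.0)

    def test_sustained_error_clamps_at_max(self):
        c = ControllerState.initial(1)
        settings = self.settings.model_copy(update={"mode": "common"})
        for _ in range(2000):
            c = rd.controller_update(
                c, np.array([37.0]), settings, dt=0.1
            )
            assert c.u[0] <= settings.max_amplitude**2 + 1e-12
        assert c.u[0] == pytest.approx(settings.max_amplitude**2)
        assert c.clamped[0]

    def test_power_ceiling_enforced(self):
        c = ControllerState.initial(2)
        settings = rd.ControlSettings(
            setpoint=60, kp=1000.0, ki=0.0, max_amplitude=100.0,
            max_power_per_electrode=5.0, mode="per-electrode",
        )
        g = np.array([0.01, 0.02])  # A/V per electrode
        out = rd.controller_update(
            c, np.array([37.0, 37.0]), settings, dt=0.1,
            unit_conductance=g,
        )
        assert np.all(out.u * g <= 5.0 + 1e-9)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    measured=st.lists(
        st.lists(st.floats(20.0, 100.0), min_size=3, max_size=3),
        min_size=1,
        max_size=30,
    ),
    kp=st.floats(0.0, 50.0),
    ki=st.floats(0.0, 10.0),
)
def test_controller_command_always_admissible(measured, kp, ki):
    """For any probe history and gains, the squared-amplitude command
    stays inside [0, max_amplitude^2] (anti-windup by clamping)."""
    settings_ = rd.ControlSettings(
        setpoint=60.0, kp=kp, ki=ki, max_amplitude=25.0,
        mode="per-electrode",
    )
    c = ControllerState.initial(3)
    for probes in measured:
        c = rd.controller_update(c, np.array(probes), settings_, dt=0.1)
        assert np.all(c.u >= 0.0)
        assert np.all(c.u <= 25.0**2 + 1e-9)


class TestRunAblation:
    def test_near_zero_setpoint_gap_does_nothing(self):
        cfg = rd.build_scenario(
            "in_vivo",
            {
                "domain_size": (13.0, 13.0, 15.0),
                "duration": 1.0,
                "layout": {"axial_pitch": 0.8},
                "control": {"setpoint": 37.05},
            },
        )
        res = rd.run_ablation(cfg)
        assert abs(res.state.T - 37.0).max() < 0.1

    def test_trace_bookkeeping(self, short_run):
        cfg = short_run.config
        n_rows_expected = (
            int(cfg.duration / cfg.control.update_interval) + 1
        ) * short_run.grid.n_electrodes
        assert len(short_run.traces) == n_rows_expected
        times = short_run.traces.t_s.unique()
        assert times[0] == 0.0
        assert np.all(np.diff(times) > 0)

    def test_tmax_dominates_T_and_monotone(self, short_run, small_invivo_config):
        assert np.all(short_run.state.Tmax >= short_run.state.T - 1e-12)
        assert np.all(
            short_run.state.Tmax
            >= small_invivo_config.initial_temperature - 1e-12
        )

    def test_heating_confined_near_electrodes(self, short_run):
        d = rd.distance_to_electrodes(short_run.grid)
        hottest = np.unravel_index(
            short_run.state.T.argmax(), short_run.grid.shape
        )
        assert d[hottest] <= 2 * short_run.grid.spacing

    def test_deterministic_rerun_bit_identical(self, small_invivo_config, short_run):
        again = rd.run_ablation(small_invivo_config)
        pd.testing.assert_frame_equal(
            again.traces, short_run.traces, check_exact=True
        )
        assert np.array_equal(again.state.Tmax, short_run.state.Tmax)
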