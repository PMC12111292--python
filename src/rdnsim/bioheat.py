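"""Transient heat transport and temperature-feedback power control.

Governing equation (per cell, SI):

    rho c dT/dt = div(k grad T) - rho c v_z dT/dz + Qr

i.e. conduction plus luminal blood advection plus the Joule source.  No
perfusion or metabolic term is included: intra-arterial flow is the only
blood-cooling mechanism modeled, matching the stated 0.5 m/s inlet
condition.  The outer surfaces of the block are held at the boundary
temperature (Dirichlet), and blood enters the lumen at that temperature.

Time integration is backward Euler (unconditionally stable; the luminal
CFL number is far above 1 at physiological velocities) with first-order
upwind advection.  Conductivities are temperature-independent, so the
system matrix is assembled and preconditioned once; each step is a
warm-started BiCGSTAB solve of a strongly diagonally dominant system.

The generator is modeled as a PI loop on the squared drive amplitude
(proportional to delivered power): at every control interval it reads
the electrode surface probes (mean temperature of the tissue cells
face-adjacent to each electrode), updates the amplitude command, and the
Joule source is rescaled through the precomputed potential basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ControlSettings, ScenarioConfig
from .efield import (
    ElectricalSolution,
    PotentialBasis,
    SolverError,
    build_sigma_map,
    compose_field,
    solve_basis_potentials,
)
from .geometry import (
    ELECTRODE_BASE,
    DomainGrid,
    FlowField,
    compute_flow_field,
    discretize,
    place_electrodes,
)

__all__ = [
    "OverheatError",
    "ThermalState",
    "ControllerState",
    "ThermalSystem",
    "AblationResult",
    "step_thermal",
    "electrode_temperature",
    "controller_update",
    "run_ablation",
]

#: model validity ceiling, degC — no vaporization physics beyond this
T_OVERHEAT = 110.0


class OverheatError(RuntimeError):
    """Temperature exceeded the model's validity range (no vaporization
    physics); raised with the offending time."""


@dataclass
class ThermalState:
    """Temperature field at time ``t`` plus its running cellwise maximum."""

    T: np.ndarray  # degC, grid shape
    t: float  # s
    Tmax: np.ndarray  # degC, running max over the simulation


@dataclass
class ControllerState:
    """PI controller memory.

    ``u`` is the squared-amplitude command (V^2) per channel (one entry
    in common mode), ``e_prev`` the previous temperature error; clamping
    ``u`` to its admissible box is the anti-windup.
    """

    u: np.ndarray
    e_prev: np.ndarray
    clamped: np.ndarray  # bool, per channel

    @classmethod
    def initial(cls, n_channels: int) -> "ControllerState":
        return cls(
            u=np.zeros(n_channels),
            e_prev=np.zeros(n_channels),
            clamped=np.zeros(n_channels, dtype=bool),
        )


def _rho_c_k_maps(grid: DomainGrid, materials: dict):
    rho_c = np.empty(grid.shape)
    k = np.empty(grid.shape)
    for region, mask in (
        ("tissue", grid.tissue_mask),
        ("lumen", grid.lumen_mask),
        ("electrode", grid.electrode_mask()),
    ):
        m = materials[region]
        rho_c[mask] = m.rho * m.c
        k[mask] = m.k
    return rho_c, k


class ThermalSystem:
    """Assembled backward-Euler operator for a fixed grid/flow/dt.

    Holds the sparse matrix  A = (rho c V / dt) I + K_cond + K_adv  and
    the constant boundary-source vector; :meth:`step` advances one dt.
    """

    def __init__(
        self,
        grid: DomainGrid,
        materials: dict,
        flow: FlowField,
        dt: float,
        boundary_temperature: float,
        rtol: float = 1e-10,
        dirichlet_boundary: bool = True,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.dt = dt
        self.rtol = rtol
        self.boundary_temperature = boundary_temperature
        self.dirichlet_boundary = dirichlet_boundary
        rho_c, k = _rho_c_k_maps(grid, materials)
        self.rho_c = rho_c.ravel()
        h = grid.spacing
        N = grid.n_cells
        shape = grid.shape
        idx = np.arange(N).reshape(shape)
        kf = k.ravel()

        rows, cols, vals = [], [], []
        b_const = np.zeros(N)  # W, constant boundary sources

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # conduction: harmonic-mean face conductance k_f * h
        for axis in range(3):
            n = shape[axis]
            a = np.take(idx, range(0, n - 1), axis=axis).ravel()
            b = np.take(idx, range(1, n), axis=axis).ravel()
            g = h * 2.0 * kf[a] * kf[b] / (kf[a] + kf[b])  # W/degC
            add(a, a, g)
            add(b, b, g)
            add(a, b, -g)
            add(b, a, -g)
        # Dirichlet outer faces (half-cell span); insulated when disabled
        if dirichlet_boundary:
            for axis in range(3):
                for side in (0, shape[axis] - 1):
                    cells = np.take(idx, [side], axis=axis).ravel()
                    g = 2.0 * h * kf[cells]
                    add(cells, cells, g)
                    b_const[cells] += g * boundary_temperature

        # implicit first-order upwind advection along +z (vz >= 0), in
        # advective (non-conservative) form: rho_c v (T_c - T_below) / h
        # per cell.  The discrete flow field is not solenoidal where
        # electrode cells interrupt the lumen; the advective form keeps
        # zero row sums (constants preserved, discrete maximum
        # principle) regardless.
        vz = flow.vz.ravel()
        if np.any(vz < 0):
            raise ValueError("flow field must be non-negative along z")
        if np.any(vz > 0):
            area = h * h
            nz = shape[2]
            moving = vz > 0
            cell_k = np.tile(np.arange(nz), N // nz)  # z index, C-order
            coef = self.rho_c * vz * area  # W/degC
            interior = moving & (cell_k > 0)
            add(
                np.flatnonzero(interior),
                np.flatnonzero(interior),
                coef[interior],
            )
            add(
                np.flatnonzero(interior),
                np.flatnonzero(interior) - 1,  # z is the fastest axis
                -coef[interior],
            )
            # inlet layer (k = 0): upstream value is the inflow temperature
            inlet = moving & (cell_k == 0)
            add(np.flatnonzero(inlet), np.flatnonzero(inlet), coef[inlet])
            b_const[inlet] += coef[inlet] * boundary_temperature

        K = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        )
        cap = self.rho_c * grid.cell_volume / dt  # W/degC
        self.A = (sp.diags(cap) + K).tocsr()
        self.cap = cap
        self.b_const = b_const
        inv_diag = 1.0 / self.A.diagonal()
        self.M = spla.LinearOperator(
            self.A.shape, matvec=lambda x: inv_diag * x
        )

    def step(self, state: ThermalState, qr: np.ndarray) -> ThermalState:
        """Advance one backward-Euler step under Joule source ``qr``."""
        b = (
            self.cap * state.T.ravel()
            + qr.ravel() * self.grid.cell_volume
            + self.b_const
        )
        T_new, info = spla.bicgstab(
            self.A,
            b,
            x0=state.T.ravel().copy(),
            rtol=self.rtol,
            atol=0.0,
            M=self.M,
            maxiter=2000,
        )
        if info != 0:
            # BiCGSTAB can break down on degenerate (e.g. advection-
            # dominated, near-triangular) systems; fall back to GMRES,
            # then to a direct solve.  All paths are deterministic.
            T_new, info = spla.gmres(
                self.A,
                b,
                x0=state.T.ravel().copy(),
                rtol=self.rtol,
                atol=0.0,
                M=self.M,
                maxiter=2000,
            )
        if info != 0:
            try:
                T_new = spla.spsolve(self.A.tocsc(), b)
            except Exception as exc:  # pragma: no cover
                raise SolverError(
                    f"thermal step at t={state.t:.2f}s failed "
                    f"(info={info}): {exc}"
                ) from exc
        T_new = T_new.reshape(self.grid.shape)
        t_new = state.t + self.dt
        if np.any(T_new > T_OVERHEAT):
            raise OverheatError(
                f"temperature exceeded {T_OVERHEAT} degC at t={t_new:.2f}s; "
                "the model has no vaporization physics"
            )
        return ThermalState(
            T=T_new, t=t_new, Tmax=np.maximum(state.Tmax, T_new)
        )


def step_thermal(
    state: ThermalState,
    qr: np.ndarray,
    flow: FlowField,
    materials: dict,
    dt: float,
    grid: DomainGrid,
    boundary_temperature: float,
    system: ThermalSystem | None = None,
) -> ThermalState:
    """One backward-Euler step; assembles the operator unless ``system``
    is supplied (the time loop reuses one assembled system)."""
    if system is None:
        system = ThermalSystem(grid, materials, flow, dt, boundary_temperature)
    return system.step(state, qr)


def _electrode_adjacency(grid: DomainGrid) -> list[np.ndarray]:
    """Flat indices of the probe cells of each electrode: tissue cells
    face-adjacent to it (fallback: any adjacent non-electrode cell)."""
    labels = grid.labels
    probes = []
    for i in range(grid.n_electrodes):
        mask = grid.electrode_mask(i)
        adj = np.zeros(grid.shape, dtype=bool)
        for axis in range(3):
            adj |= np.roll(mask, 1, axis=axis)
            adj |= np.roll(mask, -1, axis=axis)
        adj &= labels < ELECTRODE_BASE
        tissue_adj = adj & grid.tissue_mask
        chosen = tissue_adj if tissue_adj.any() else adj
        probes.append(np.flatnonzero(chosen.ravel()))
    return probes


def electrode_temperature(
    state: ThermalState,
    grid: DomainGrid,
    probe: str = "mean",
    _adjacency: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Electrode surface probe reading, degC per electrode.

    The reading is the mean (or max, per config) temperature over the
    tissue cells face-adjacent to each electrode's cells — a voxel
    rendering of a surface thermocouple.
    """
    adjacency = _adjacency or _electrode_adjacency(grid)
    Tf = state.T.ravel()
    stat = np.mean if probe == "mean" else np.max
    return np.array([stat(Tf[cells]) for cells in adjacency])


def controller_update(
    cstate: ControllerState,
    measured: np.ndarray,
    settings: ControlSettings,
    dt: float,
    unit_conductance: np.ndarray | None = None,
) -> ControllerState:
    """Incremental PI update of the squared-amplitude command.

    u += kp * (e - e_prev) + ki * e * dt, then clamp to
    [0, max_amplitude^2] and, when per-electrode unit conductances are
    supplied, to the power ceiling u <= P_max / g_i.  The clamp on the
    command is the anti-windup: no separate integrator can wind up.
    """
    measured = np.asarray(measured, dtype=float)
    if settings.mode == "common":
        e = np.array([settings.setpoint - measured.max()])
    else:
        e = settings.setpoint - measured
    u = cstate.u + settings.kp * (e - cstate.e_prev) + settings.ki * e * dt
    u_hi = np.full_like(u, settings.max_amplitude**2)
    if unit_conductance is not None:
        g = np.asarray(unit_conductance, dtype=float)
        g_eff = g.max() if settings.mode == "common" else g
        with np.errstate(divide="ignore"):
            p_cap = np.where(
                g_eff > 0, settings.max_power_per_electrode / g_eff, np.inf
            )
        u_hi = np.minimum(u_hi, p_cap)
    u_clamped = np.clip(u, 0.0, u_hi)
    return ControllerState(
        u=u_clamped, e_prev=e, clamped=u_clamped != u
    )


@dataclass
class AblationResult:
    """Everything a 120 s run produces."""

    config: ScenarioConfig
    grid: DomainGrid
    flow: FlowField
    basis: PotentialBasis
    state: ThermalState  # final
    traces: pd.DataFrame  # t_s, electrode_id, T_C, P_W, Z_ohm, amplitude_V
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    final_solution: ElectricalSolution | None = None


def run_ablation(config: ScenarioConfig) -> AblationResult:
    """Run a complete temperature-controlled ablation.

    Pipeline: voxelize -> place electrodes -> flow field -> unit-voltage
    basis solve -> time loop (thermal step + PI update per control
    interval).  Entirely deterministic.  ``snapshots`` holds copies of
    the running-maximum temperature field at the configured sample times
    (by default 5/30/60/120 s) for lesion bookkeeping.
    """
    grid = discretize(config)
    place_electrodes(grid, config.layout)
    flow = compute_flow_field(
        grid, config.inlet_mean_velocity, config.flow_profile
    )
    sigma = build_sigma_map(grid, config.materials)
    basis = solve_basis_potentials(grid, sigma)

    settings = config.control
    n_e = grid.n_electrodes
    n_ch = 1 if settings.mode == "common" else n_e

    # unit composition: common mode scales one precomputed solution
    unit_common = compose_field(basis, np.ones(n_e))
    unit_g = unit_common.current  # A per volt per electrode (common drive)

    system = ThermalSystem(
        grid, config.materials, flow, config.timestep,
        config.boundary_temperature,
    )
    adjacency = _electrode_adjacency(grid)
    state = ThermalState(
        T=np.full(grid.shape, config.initial_temperature, dtype=float),
        t=0.0,
        Tmax=np.full(grid.shape, config.initial_temperature, dtype=float),
    )
    cstate = ControllerState.initial(n_ch)

    dt_ctrl = settings.update_interval
    n_updates = int(round(config.duration / dt_ctrl))
    substeps = max(1, int(round(dt_ctrl / config.timestep)))
    dt_sub = dt_ctrl / substeps
    if abs(dt_sub - config.timestep) > 1e-9:
        # control cadence not an exact multiple; use the nearest sub-dt
        system = ThermalSystem(
            grid, config.materials, flow, dt_sub, config.boundary_temperature
        )

    sample_times = sorted(
        t for t in config.sample_times if t <= config.duration + 1e-9
    )
    snapshots: dict[float, np.ndarray] = {}
    rows = []
    solution = compose_field(basis, np.zeros(n_e))

    def record(t: float, amps: np.ndarray, sol: ElectricalSolution):
        probes = electrode_temperature(
            state, grid, settings.probe, _adjacency=adjacency
        )
        for i in range(n_e):
            rows.append(
                dict(
                    t_s=round(t, 9),
                    electrode_id=i,
                    T_C=probes[i],
                    P_W=sol.power[i],
                    Z_ohm=sol.impedance[i],
                    amplitude_V=amps[i],
                )
            )
        return probes

    probes = record(0.0, np.zeros(n_e), solution)
    next_sample = 0
    try:
        for step_i in range(n_updates):
            cstate = controller_update(
                cstate, probes, settings, dt_ctrl, unit_conductance=unit_g
            )
            amps_sq = (
                np.full(n_e, cstate.u[0])
                if settings.mode == "common"
                else cstate.u
            )
            amps = np.sqrt(amps_sq)
            if settings.mode == "common":
                u = float(cstate.u[0])
                qr = u * unit_common.qr
                sol = ElectricalSolution(
                    amplitudes=amps,
                    potential=np.sqrt(u) * unit_common.potential,
                    e_mag=np.sqrt(u) * unit_common.e_mag,
                    j_mag=np.sqrt(u) * unit_common.j_mag,
                    qr=qr,
                    current=np.sqrt(u) * unit_common.current,
                    power=u * unit_common.power,
                    impedance=np.where(
                        u > 0, unit_common.impedance, np.nan
                    ),
                    impedance_defined=np.full(n_e, u > 0),
                    total_joule_power=u * unit_common.total_joule_power,
                )
            else:
                sol = compose_field(basis, amps)
                qr = sol.qr
            for _ in range(substeps):
                state = system.step(state, qr)
            t_now = (step_i + 1) * dt_ctrl
            state.t = t_now  # avoid float drift in bookkeeping
            probes = record(t_now, amps, sol)
            while (
                next_sample < len(sample_times)
                and t_now >= sample_times[next_sample] - 1e-9
            ):
                snapshots[sample_times[next_sample]] = state.Tmax.copy()
                next_sample += 1
            solution = sol
    except (OverheatError, SolverError):
        raise

    traces = pd.DataFrame(rows)
    return AblationResult(
        config=config,
        grid=grid,
        flow=flow,
        basis=basis,
        state=state,
        traces=traces,
        snapshots=snapshots,
        final_solution=solution,
    )
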