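"""Quasi-static electric field and Joule heat source.

At 470 kHz the tissue behaves resistively (displacement current is
negligible), so at every instant the potential obeys the conductive
Laplace equation  div(sigma grad V) = 0  with the electrode surfaces as
driven Dirichlet boundaries and the grounded outer surfaces of the block
at V = 0.  The field problem is linear in the drive voltages, so it is
solved ONCE per geometry as a set of unit-voltage basis potentials
(electrode i at 1 V, everything else grounded); any amplitude vector is
then composed by superposition.  This is what makes the 120 s
temperature-controlled run cheap: the controller only rescales
amplitudes, never re-solves the field.

Discretization: 7-point finite volumes on the voxel grid with
harmonic-mean face conductivities (exact flux continuity across material
jumps).  The Joule source is accumulated per face as G_f * dV_f^2 and
attributed to the two adjacent cells in proportion to their share of the
face resistance, which makes the discrete energy balance
sum_i a_i I_i = integral(Qr) exact up to solver tolerance.  The gold
electrodes' metallic conductivity enters only through that face split:
electrode cells are equipotential Dirichlet regions and receive no heat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ELECTRODE_BASE, DomainGrid

__all__ = [
    "SolverError",
    "FaceData",
    "PotentialBasis",
    "ElectricalSolution",
    "build_sigma_map",
    "solve_basis_potentials",
    "compose_field",
    "electrode_current_power_impedance",
]


class SolverError(RuntimeError):
    """Iterative solver failed to reach the requested residual."""


def build_sigma_map(grid: DomainGrid, materials: dict) -> np.ndarray:
    """Per-cell electrical conductivity (S/m) from region labels."""
    sigma = np.empty(grid.shape)
    sigma[grid.tissue_mask] = materials["tissue"].sigma
    sigma[grid.lumen_mask] = materials["lumen"].sigma
    sigma[grid.electrode_mask()] = materials["electrode"].sigma
    return sigma


@dataclass
class FaceData:
    """Precomputed face geometry/conductance of the voxel grid.

    Internal faces connect flat cell indices ``a`` and ``b``;
    ``g`` is the face conductance (S) from the harmonic mean of the two
    cell conductivities, and ``wa`` the fraction of the face's Joule
    dissipation attributed to cell ``a`` (its share of the face
    resistance).  ``bnd_cell``/``bnd_g`` describe faces on the grounded
    outer surface.
    """

    a: np.ndarray
    b: np.ndarray
    g: np.ndarray
    wa: np.ndarray
    bnd_cell: np.ndarray
    bnd_g: np.ndarray


def _build_faces(grid: DomainGrid, sigma: np.ndarray) -> FaceData:
    h = grid.spacing
    shape = grid.shape
    idx = np.arange(grid.n_cells).reshape(shape)
    s = sigma.ravel()
    a_all, b_all = [], []
    for axis in range(3):
        n = shape[axis]
        a = np.take(idx, range(0, n - 1), axis=axis).ravel()
        b = np.take(idx, range(1, n), axis=axis).ravel()
        a_all.append(a)
        b_all.append(b)
    a = np.concatenate(a_all)
    b = np.concatenate(b_all)
    sa, sb = s[a], s[b]
    # conductance of the two half-cells in series, face area h^2, span h
    g = h * 2.0 * sa * sb / (sa + sb)
    wa = sb / (sa + sb)  # dissipation share of cell a (prop. to 1/sigma_a)
    bnd_cell, bnd_g = [], []
    for axis in range(3):
        for side in (0, shape[axis] - 1):
            cells = np.take(idx, [side], axis=axis).ravel()
            bnd_cell.append(cells)
            bnd_g.append(2.0 * h * s[cells])  # half-cell span h/2
    return FaceData(
        a=a,
        b=b,
        g=g,
        wa=wa,
        bnd_cell=np.concatenate(bnd_cell),
        bnd_g=np.concatenate(bnd_g),
    )


def _laplacian(n_cells: int, faces: FaceData) -> sp.csr_matrix:
    """Conductance Laplacian L = D - W including grounded-boundary diag."""
    rows = np.concatenate([faces.a, faces.b, faces.a, faces.b, faces.bnd_cell])
    cols = np.concatenate([faces.b, faces.a, faces.a, faces.b, faces.bnd_cell])
    vals = np.concatenate(
        [-faces.g, -faces.g, faces.g, faces.g, faces.bnd_g]
    )
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))


@dataclass
class PotentialBasis:
    """Unit-voltage basis potentials and cached discretization data."""

    grid: DomainGrid
    sigma: np.ndarray
    faces: FaceData
    v: np.ndarray  # (n_electrodes, n_cells) flat potentials, incl. Dirichlet
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))


def solve_basis_potentials(
    grid: DomainGrid,
    sigma_map: np.ndarray,
    rtol: float = 1e-8,
    maxiter: int = 50_000,
    grounded_boundary: bool = True,
) -> PotentialBasis:
    """Solve the unit-voltage potential for each electrode.

    For electrode i the Dirichlet data is 1 V on its cells, 0 V on every
    other electrode cell and on all outer surfaces.  Conjugate gradients
    with Jacobi preconditioning on the reduced (non-electrode) system,
    to relative residual ``rtol``.  ``grounded_boundary=False`` replaces
    the grounded outer surfaces with insulating ones (n.J = 0), the
    boundary condition of non-grounded surfaces.
    """
    if grid.n_electrodes < 1:
        raise ValueError("electrodes must be placed before the field solve")
    non_elec = ~grid.electrode_mask()
    if not np.all(sigma_map[non_elec] > 0):
        raise ValueError("sigma must be positive on all non-electrode cells")

    faces = _build_faces(grid, sigma_map)
    if not grounded_boundary:
        faces.bnd_g = np.zeros_like(faces.bnd_g)
    L = _laplacian(grid.n_cells, faces)
    labels = grid.labels.ravel()
    free = labels < ELECTRODE_BASE
    L_uu = L[free][:, free].tocsr()
    L_ud = L[free][:, ~free].tocsr()
    dirichlet_labels = labels[~free]

    inv_diag = 1.0 / L_uu.diagonal()
    M = spla.LinearOperator(L_uu.shape, matvec=lambda x: inv_diag * x)

    n_e = grid.n_electrodes
    v = np.zeros((n_e, grid.n_cells))
    residuals = np.zeros(n_e)
    for i in range(n_e):
        vd = (dirichlet_labels == ELECTRODE_BASE + i).astype(float)
        b = -L_ud @ vd
        x, info = spla.cg(L_uu, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
        res = np.linalg.norm(L_uu @ x - b) / max(np.linalg.norm(b), 1e-300)
        if info != 0:
            raise SolverError(
                f"potential solve for electrode {i} did not converge "
                f"(info={info}, relative residual={res:.2e})"
            )
        v[i, free] = x
        v[i, ~free] = vd
        residuals[i] = res
    return PotentialBasis(
        grid=grid, sigma=sigma_map, faces=faces, v=v, residuals=residuals
    )


@dataclass
class ElectricalSolution:
    """Composed field state for one amplitude vector.

    ``qr`` is the volumetric Joule source (W/m^3, zero in electrode
    cells); ``current``/``power``/``impedance`` are per electrode, with
    ``impedance_defined`` False (and Z = nan) when that electrode's
    amplitude is zero.
    """

    amplitudes: np.ndarray  # V, per electrode
    potential: np.ndarray  # V per cell (grid shape)
    e_mag: np.ndarray  # V/m
    j_mag: np.ndarray  # A/m^2
    qr: np.ndarray  # W/m^3
    current: np.ndarray  # A per electrode
    power: np.ndarray  # W per electrode
    impedance: np.ndarray  # Ohm per electrode
    impedance_defined: np.ndarray  # bool per electrode
    total_joule_power: float  # W, integral of qr


def compose_field(
    basis: PotentialBasis, amplitudes, sigma_map: np.ndarray | None = None
) -> ElectricalSolution:
    """Superpose basis potentials at the given drive amplitudes.

    Returns the composed potential, field magnitudes, the
    energy-consistent Joule source, and per-electrode current, power and
    impedance.
    """
    grid = basis.grid
    a_vec = np.asarray(amplitudes, dtype=float)
    if a_vec.shape != (grid.n_electrodes,):
        raise ValueError(
            f"expected {grid.n_electrodes} amplitudes, got {a_vec.shape}"
        )
    sigma = basis.sigma if sigma_map is None else sigma_map
    V = a_vec @ basis.v  # flat, n_cells

    faces = basis.faces
    dv = V[faces.a] - V[faces.b]
    face_power = faces.g * dv * dv  # W per internal face
    energy = np.zeros(grid.n_cells)
    np.add.at(energy, faces.a, faces.wa * face_power)
    np.add.at(energy, faces.b, (1.0 - faces.wa) * face_power)
    bnd_power = faces.bnd_g * V[faces.bnd_cell] ** 2
    np.add.at(energy, faces.bnd_cell, bnd_power)

    labels = grid.labels.ravel()
    elec_any = labels >= ELECTRODE_BASE
    energy[elec_any] = 0.0  # metal is a source boundary, not heated tissue
    qr = (energy / grid.cell_volume).reshape(grid.shape)

    # report-only field magnitudes (central differences)
    Vg = V.reshape(grid.shape)
    gx, gy, gz = np.gradient(Vg, grid.spacing)
    e_mag = np.sqrt(gx**2 + gy**2 + gz**2)
    j_mag = sigma * e_mag

    # per-electrode terminal current: flux through electrode/tissue faces
    n_e = grid.n_electrodes
    current = np.zeros(n_e)
    la, lb = labels[faces.a], labels[faces.b]
    flux = faces.g * dv  # A from a to b
    for i in range(n_e):
        lab = ELECTRODE_BASE + i
        m_a = (la == lab) & (lb < ELECTRODE_BASE)
        m_b = (lb == lab) & (la < ELECTRODE_BASE)
        current[i] = flux[m_a].sum() - flux[m_b].sum()
        on_bnd = labels[faces.bnd_cell] == lab
        if on_bnd.any():
            current[i] += (
                faces.bnd_g[on_bnd] * V[faces.bnd_cell[on_bnd]]
            ).sum()

    power = a_vec * current
    defined = a_vec != 0.0
    impedance = np.full(n_e, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        impedance[defined] = a_vec[defined] / current[defined]

    return ElectricalSolution(
        amplitudes=a_vec,
        potential=Vg,
        e_mag=e_mag,
        j_mag=j_mag,
        qr=qr,
        current=current,
        power=power,
        impedance=impedance,
        impedance_defined=defined,
        total_joule_power=float(energy.sum() + 0.0),
    )


def electrode_current_power_impedance(
    solution: ElectricalSolution, grid: DomainGrid | None = None
):
    """Per-electrode terminal current (A), power (W) and impedance (Ohm).

    Impedance is nan with its ``impedance_defined`` flag False for any
    electrode driven at zero amplitude.
    """
    return solution.current, solution.power, solution.impedance
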