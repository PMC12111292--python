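"""Quantification of the thermal lesion.

The lesion is defined on the *running-maximum* temperature field: tissue
(and the color-changing phantom gel) is irreversibly marked once it has
ever exceeded the 45 degC threshold, so any historical exceedance
counts, not just the final temperature.

Four metrics mirror how multi-electrode renal-denervation lesions are
reported:

* injury depth — the farthest the threshold isotherm reaches from the
  electrode surfaces (mm);
* circumferential coverage — the fraction of the 360 deg circumference,
  on a cylindrical evaluation shell just outside the vessel wall, where
  the threshold is exceeded at some axial position (renal nerves run
  axially, so axial-max coverage is the clinically meaningful statistic);
* band continuity — whether the covered set on the unrolled (theta, z)
  shell forms a single angle-spanning connected component;
* band dimensions — axial width and radial depth beyond the lumen wall,
  the quantities read off a cut gel phantom.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .bioheat import AblationResult
from .geometry import DomainGrid, distance_to_electrodes

__all__ = [
    "LesionReport",
    "injury_depth",
    "circumferential_coverage",
    "band_continuity",
    "band_dimensions",
    "build_report",
    "DEFAULT_SHELL_OFFSET_MM",
]

MM = 1e-3

#: default evaluation shell: lumen radius + 0.5 mm (peri-adventitial,
#: where the renal nerve plexus begins)
DEFAULT_SHELL_OFFSET_MM = 0.5


def injury_depth(
    tmax: np.ndarray,
    distance: np.ndarray,
    threshold: float = 45.0,
    exclude: np.ndarray | None = None,
) -> float:
    """Maximum distance (mm) from the electrode surface reached by the
    threshold isotherm; 0 if no cell qualifies.

    ``distance`` is the per-cell distance-to-electrode field in metres
    (:func:`rdnsim.geometry.distance_to_electrodes`).  ``exclude`` masks
    cells that cannot form a lesion; the report builder excludes
    electrode metal and the lumen, because flowing blood that once
    exceeded the threshold is not injured tissue (it is replaced within
    a fraction of a second), whereas the stationary wall is.
    """
    hot = tmax >= threshold
    if exclude is not None:
        hot &= ~exclude
    if not hot.any():
        return 0.0
    return float(distance[hot].max() / MM)


def _shell_samples(
    grid: DomainGrid, radius_m: float, angular_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear sample of a field on the (theta, z) cylinder shell.

    Returns fractional index coordinates with shape (3, n_theta, nz)
    and the theta bin centers (deg).
    """
    theta = (np.arange(angular_bins) + 0.5) * (2 * np.pi / angular_bins)
    z = grid.axis_centers(2)
    th, zz = np.meshgrid(theta, z, indexing="ij")
    x = radius_m * np.cos(th)
    y = radius_m * np.sin(th)
    h = grid.spacing
    ci = (x - grid.origin[0]) / h - 0.5
    cj = (y - grid.origin[1]) / h - 0.5
    ck = (zz - grid.origin[2]) / h - 0.5
    return np.stack([ci, cj, ck]), np.rad2deg(theta)


def _coverage_mask(
    tmax: np.ndarray,
    grid: DomainGrid,
    evaluation_radius_mm: float,
    threshold: float,
    angular_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (theta, z) exceedance mask on the evaluation shell."""
    r = evaluation_radius_mm * MM
    if r <= grid.lumen_radius:
        raise ValueError(
            f"evaluation radius {evaluation_radius_mm} mm must exceed the "
            f"lumen radius {grid.lumen_radius / MM} mm"
        )
    half_x = grid.shape[0] * grid.spacing / 2
    if r >= min(half_x, grid.shape[1] * grid.spacing / 2):
        raise ValueError(
            f"evaluation radius {evaluation_radius_mm} mm lies outside "
            "the domain cross-section"
        )
    coords, theta_deg = _shell_samples(grid, r, angular_bins)
    shell = ndimage.map_coordinates(
        tmax, coords.reshape(3, -1), order=1, mode="nearest"
    ).reshape(coords.shape[1:])
    return shell >= threshold, theta_deg


def circumferential_coverage(
    tmax: np.ndarray,
    grid: DomainGrid,
    evaluation_radius_mm: float,
    threshold: float = 45.0,
    angular_bins: int = 360,
) -> tuple[float, float]:
    """Circumferential coverage (percent of 360 deg, and degrees).

    The running-max field is resampled (trilinear) onto the cylindrical
    shell at ``evaluation_radius_mm``; an angular bin counts as covered
    if the threshold is exceeded at any axial position in that bin.
    """
    mask, _ = _coverage_mask(
        tmax, grid, evaluation_radius_mm, threshold, angular_bins
    )
    covered = mask.any(axis=1)
    percent = 100.0 * covered.sum() / angular_bins
    return percent, 3.6 * percent


def band_continuity(
    tmax: np.ndarray,
    grid: DomainGrid,
    evaluation_radius_mm: float,
    threshold: float = 45.0,
    angular_bins: int = 360,
) -> tuple[bool, list[tuple[float, float]]]:
    """Connectedness of the covered set on the unrolled shell.

    Connected components are computed on the (theta, z) mask with
    4-connectivity and periodic wrap in theta.  ``continuous`` is True
    iff a single component spans all angular bins.  ``gaps`` lists the
    maximal uncovered angular intervals (degrees), wrap-aware.
    """
    mask, _ = _coverage_mask(
        tmax, grid, evaluation_radius_mm, threshold, angular_bins
    )
    n_theta = angular_bins
    lab, n_lab = ndimage.label(mask)
    if n_lab:
        # merge components across the theta seam (periodicity)
        parent = np.arange(n_lab + 1)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        seam = mask[0] & mask[-1]
        for z in np.flatnonzero(seam):
            a, b = find(lab[0, z]), find(lab[-1, z])
            if a != b:
                parent[b] = a
        roots = np.array([find(x) for x in range(n_lab + 1)])
        lab = roots[lab]

    continuous = False
    for root in np.unique(lab[mask]) if mask.any() else []:
        spanned = np.unique(np.nonzero(lab == root)[0]).size
        if spanned == n_theta:
            continuous = True
            break

    covered = mask.any(axis=1)
    gaps: list[tuple[float, float]] = []
    if not covered.all():
        bin_deg = 360.0 / n_theta
        uncov = ~covered
        # find runs of uncovered bins, treating the array circularly
        if uncov.all():
            gaps = [(0.0, 360.0)]
        else:
            start = int(np.flatnonzero(covered)[0])
            rolled = np.roll(uncov, -start)
            run_start = None
            for i in range(len(rolled)):
                if rolled[i] and run_start is None:
                    run_start = i
                if not rolled[i] and run_start is not None:
                    gaps.append(
                        (
                            ((run_start + start) % n_theta) * bin_deg,
                            ((i + start - 1) % n_theta + 1) * bin_deg,
                        )
                    )
                    run_start = None
            if run_start is not None:
                gaps.append(
                    (
                        ((run_start + start) % n_theta) * bin_deg,
                        ((len(rolled) + start - 1) % n_theta + 1) * bin_deg,
                    )
                )
    return continuous, gaps


def band_dimensions(
    tmax: np.ndarray,
    grid: DomainGrid,
    threshold: float = 45.0,
) -> tuple[float, float]:
    """Axial width and radial depth (mm) of the extraluminal lesion.

    Width is the axial extent (max - min of cell-center z) of cells with
    running-max >= threshold outside the lumen; depth is the maximum
    radial penetration of those cells beyond the lumen wall.  Empty
    lesion returns (0, 0).  This matches how a cut gel block is read:
    depth measured from the channel wall.
    """
    r = grid.radius()
    outside = (tmax >= threshold) & (r > grid.lumen_radius)
    if not outside.any():
        return 0.0, 0.0
    z = (grid.cell_centers()[2] * np.ones(grid.shape))[outside]
    width = float((z.max() - z.min()) / MM)
    depth = float((r[outside].max() - grid.lumen_radius) / MM)
    return width, depth


@dataclass
class LesionReport:
    """Serializable summary of one ablation's lesion metrics."""

    threshold: float  # degC
    evaluation_radius_mm: float
    injury_depth_mm: float  # from the electrode surface
    coverage_percent: float
    coverage_degrees: float
    continuous: bool
    gaps_degrees: list[tuple[float, float]]
    band_width_mm: float
    band_depth_mm: float  # from the lumen wall
    sampled_times: list[tuple[float, float]]  # (t_s, depth_mm)
    scenario_kind: str = ""
    electrode_temperature_final: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LesionReport":
        data = json.loads(text)
        data["gaps_degrees"] = [tuple(g) for g in data["gaps_degrees"]]
        data["sampled_times"] = [tuple(s) for s in data["sampled_times"]]
        return cls(**data)


def build_report(
    result: AblationResult,
    evaluation_radius_mm: float | None = None,
    angular_bins: int = 360,
) -> LesionReport:
    """Assemble the full lesion report for a completed run."""
    config = result.config
    grid = result.grid
    threshold = config.lesion_threshold
    if evaluation_radius_mm is None:
        evaluation_radius_mm = (
            grid.lumen_radius / MM + DEFAULT_SHELL_OFFSET_MM
        )
    dist = distance_to_electrodes(grid)
    # lesion = irreversibly damaged *stationary* medium: exclude the
    # electrode metal and the flowing lumen from depth bookkeeping
    emask = grid.electrode_mask() | grid.lumen_mask
    tmax = result.state.Tmax
    depth = injury_depth(tmax, dist, threshold, emask)
    pct, deg = circumferential_coverage(
        tmax, grid, evaluation_radius_mm, threshold, angular_bins
    )
    cont, gaps = band_continuity(
        tmax, grid, evaluation_radius_mm, threshold, angular_bins
    )
    width, bdepth = band_dimensions(tmax, grid, threshold)
    sampled = [
        (t, injury_depth(snap, dist, threshold, emask))
        for t, snap in sorted(result.snapshots.items())
    ]
    # the generator's displayed temperature is its controlled variable:
    # the hottest electrode probe
    final_T = float("nan")
    if len(result.traces):
        last = result.traces[result.traces.t_s == result.traces.t_s.max()]
        final_T = float(last.T_C.max())
    return LesionReport(
        threshold=threshold,
        evaluation_radius_mm=float(evaluation_radius_mm),
        injury_depth_mm=depth,
        coverage_percent=pct,
        coverage_degrees=deg,
        continuous=cont,
        gaps_degrees=gaps,
        band_width_mm=width,
        band_depth_mm=bdepth,
        sampled_times=sampled,
        scenario_kind=config.scenario_kind,
        electrode_temperature_final=final_T,
    )
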