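"""Principal component analysis of Calpha coordinates and population maps.

A :class:`PCAModel` is fitted to a (pre-aligned) reference ensemble by
eigendecomposition of the population covariance (1/n normalisation) of the
flattened 3N Calpha coordinates. Ensembles are projected onto the leading
components and summarised as normalized population densities on a regular
grid in PC space; difference maps, convex map mixtures, local-maximum
substate detection and substate-average structures complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline, make_interp_spline

__all__ = [
    "PCAModel",
    "PopulationMap",
    "Substate",
    "fit_pca",
    "project",
    "mode_amplitudes",
    "population_map",
    "difference_map",
    "mix_maps",
    "find_substates",
    "substate_average_structure",
    "substate_populations",
    "write_map",
    "read_map",
]


@dataclass
class PCAModel:
    """Mean structure, orthonormal components over the 3N coordinates, and
    eigenvalues (A^2, descending) of the reference covariance."""

    mean_frame: np.ndarray        # (n_atoms, 3)
    components: np.ndarray        # (n_components, 3*n_atoms), orthonormal rows
    eigenvalues: np.ndarray       # descending, >= 0 up to round-off

    @property
    def eigenvalue_percent(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total


@dataclass
class PopulationMap:
    """Density on a regular 1D or 2D grid in principal-component space.

    Population maps are non-negative and sum to 1; difference maps are
    ``signed`` and sum to 0.
    """

    grid_origin: np.ndarray       # coordinate of the first cell center
    resolution: float             # A per cell
    densities: np.ndarray         # (nx,) or (nx, ny)
    dim: int
    signed: bool = False

    def __post_init__(self) -> None:
        self.grid_origin = np.atleast_1d(np.asarray(self.grid_origin, dtype=float))
        self.densities = np.asarray(self.densities, dtype=float)
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 or 2")
        if self.densities.ndim != self.dim:
            raise ValueError("densities dimensionality does not match dim")
        total = self.densities.sum()
        if self.signed:
            if abs(total) > 1e-9:
                raise ValueError("difference map must sum to 0 within 1e-9")
        else:
            if np.any(self.densities < -1e-12):
                raise ValueError("population map densities must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ValueError("population map must sum to 1 within 1e-9")

    def cell_centers(self, axis: int = 0) -> np.ndarray:
        n = self.densities.shape[axis]
        return self.grid_origin[axis] + self.resolution * np.arange(n)

    def same_grid(self, other: "PopulationMap") -> bool:
        return (
            self.dim == other.dim
            and self.densities.shape == other.densities.shape
            and abs(self.resolution - other.resolution) < 1e-12
            and np.allclose(self.grid_origin, other.grid_origin, atol=1e-12)
        )


@dataclass
class Substate:
    """A local maximum of a population map, i.e. a conformational substate."""

    label: str
    mode_location: np.ndarray
    peak_density: float
    member_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def fit_pca(frames: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Fit a PCA model to pre-aligned frames of shape (n_frames, n_atoms, 3).

    Uses the population covariance (1/n). All components up to
    min(3N, n_frames) are retained unless ``n_components`` caps them.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    d = frames.shape[1] * 3
    if n_components is not None and n_components > min(d, n_frames):
        raise ValueError(f"cannot extract {n_components} components from {n_frames} frames")
    mean_frame = frames.mean(axis=0)
    x = (frames - mean_frame).reshape(n_frames, d)
    # SVD of the centered data is numerically safer than forming X^T X
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / n_frames
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    components = vt[order]
    if n_components is not None:
        eigenvalues = eigenvalues[:n_components]
        components = components[:n_components]
    return PCAModel(mean_frame=mean_frame, components=components, eigenvalues=eigenvalues)


def project(frames: np.ndarray, model: PCAModel, n_components: int = 2) -> np.ndarray:
    """Project frames onto the leading components: inner product of the
    flattened deviation from the model mean with each component row."""
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    d = model.components.shape[1]
    if frames.shape[1] * 3 != d:
        raise ValueError("frame dimensionality does not match the PCA model")
    if n_components > model.components.shape[0]:
        raise ValueError("model holds fewer components than requested")
    x = (frames - model.mean_frame).reshape(frames.shape[0], d)
    proj = x @ model.components[:n_components].T
    return proj[0] if single else proj


def mode_amplitudes(model: PCAModel, component: int = 0) -> np.ndarray:
    """Per-residue relative amplitude of a principal mode: the Euclidean norm
    of each atom's (x,y,z) sub-vector, normalized to a maximum of 1."""
    if component >= model.components.shape[0]:
        raise ValueError("component index out of range")
    vec = model.components[component].reshape(-1, 3)
    amp = np.linalg.norm(vec, axis=1)
    peak = amp.max()
    return amp / peak if peak > 0 else amp


def _grid_edges(origin: float, resolution: float, n: int) -> np.ndarray:
    return origin - resolution / 2 + resolution * np.arange(n + 1)


def population_map(
    projections: np.ndarray,
    resolution: float,
    dim: int = 2,
    weights: np.ndarray | None = None,
    smoothing: bool = False,
    extent: tuple | None = None,
) -> PopulationMap:
    """Normalized population density of PC projections on a regular grid.

    The raw map is a weighted histogram with the given cell ``resolution``
    (A). With ``smoothing`` the histogram is first passed through a light
    Gaussian filter (1 cell wide, suppressing counting noise), then the
    cell-center values are spline-interpolated (bicubic in 2D, cubic in 1D)
    onto a 4x finer grid, clipped at zero and renormalized. ``extent``
    fixes the grid range ((min, max) per axis) so that maps built from
    different weightings share a grid.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.size == 0:
        raise ValueError("projections are empty")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if projections.ndim == 1:
        projections = projections[:, None]
    if projections.shape[1] < dim:
        raise ValueError(f"need at least {dim} projection columns for a {dim}D map")
    pts = projections[:, :dim]

    if extent is None:
        extent = tuple((pts[:, k].min(), pts[:, k].max()) for k in range(dim))
    edges = []
    origin = []
    for k in range(dim):
        lo, hi = extent[k]
        n_cells = max(int(np.ceil((hi - lo) / resolution + 1e-9)) + 1, 4)
        first_center = lo
        edges.append(_grid_edges(first_center, resolution, n_cells))
        origin.append(first_center)
    hist, _ = np.histogramdd(pts, bins=edges, weights=weights)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no projection falls inside the grid extent")
    hist /= total

    if not smoothing:
        dens = hist if dim == 2 else hist.ravel()
        return PopulationMap(np.array(origin), resolution, dens, dim)

    fine = 4
    hist = ndimage.gaussian_filter(hist, sigma=1.0, mode="constant")
    hist /= hist.sum()
    centers = [origin[k] + resolution * np.arange(hist.shape[k]) for k in range(dim)]
    if dim == 2:
        spline = RectBivariateSpline(centers[0], centers[1], hist, kx=3, ky=3, s=0)
        fx = np.linspace(centers[0][0], centers[0][-1], (hist.shape[0] - 1) * fine + 1)
        fy = np.linspace(centers[1][0], centers[1][-1], (hist.shape[1] - 1) * fine + 1)
        dens = spline(fx, fy)
        new_res = (centers[0][1] - centers[0][0]) / fine
        new_origin = np.array([fx[0], fy[0]])
    else:
        x = centers[0]
        spline = make_interp_spline(x, hist.ravel(), k=min(3, len(x) - 1))
        fx = np.linspace(x[0], x[-1], (len(x) - 1) * fine + 1)
        dens = spline(fx)
        new_res = (x[1] - x[0]) / fine
        new_origin = np.array([fx[0]])
    dens = np.clip(dens, 0.0, None)
    dens /= dens.sum()
    return PopulationMap(new_origin, new_res, dens, dim)


def difference_map(map_a: PopulationMap, map_b: PopulationMap) -> PopulationMap:
    """Signed cellwise difference a - b; total mass 0."""
    if not map_a.same_grid(map_b):
        raise ValueError("maps are on different grids")
    return PopulationMap(
        map_a.grid_origin,
        map_a.resolution,
        map_a.densities - map_b.densities,
        map_a.dim,
        signed=True,
    )


def mix_maps(map_a: PopulationMap, map_b: PopulationMap, weight_a: float) -> PopulationMap:
    """Convex combination weight_a * a + (1 - weight_a) * b."""
    if not 0.0 <= weight_a <= 1.0:
        raise ValueError("weight_a must be in [0, 1]")
    if not map_a.same_grid(map_b):
        raise ValueError("maps are on different grids")
    return PopulationMap(
        map_a.grid_origin,
        map_a.resolution,
        weight_a * map_a.densities + (1.0 - weight_a) * map_b.densities,
        map_a.dim,
    )


def find_substates(
    pop_map: PopulationMap,
    min_peak_fraction: float = 0.10,
    min_separation: float = 1.0,
) -> list[Substate]:
    """Detect substates as local maxima of a population map.

    Local maxima use the 8-neighborhood in 2D (2-neighborhood in 1D). Peaks
    below ``min_peak_fraction`` of the global maximum are discarded, and
    maxima closer than ``min_separation`` (A) are merged keeping the denser
    one (residual sampling noise near a peak top otherwise splits it). The
    returned list is sorted by peak density (descending); labels S1, S2, ...
    are assigned in order of the mode's coordinate along component 1.
    """
    if pop_map.signed:
        raise ValueError("substate detection requires a population (unsigned) map")
    dens = pop_map.densities
    size = 3 if pop_map.dim == 1 else (3, 3)
    local_max = dens == ndimage.maximum_filter(dens, size=size, mode="constant", cval=-np.inf)
    local_max &= dens >= min_peak_fraction * dens.max()
    coords = np.argwhere(local_max)
    candidates = []
    for c in coords:
        loc = pop_map.grid_origin + pop_map.resolution * c
        candidates.append((float(dens[tuple(c)]), loc))
    candidates.sort(key=lambda p: -p[0])
    peaks = []
    for value, loc in candidates:
        if all(np.linalg.norm(loc - kept[1]) >= min_separation for kept in peaks):
            peaks.append((value, loc))
    # label along PC1 (first grid axis)
    order_pc1 = sorted(range(len(peaks)), key=lambda i: peaks[i][1][0])
    labels = {}
    for rank, i in enumerate(order_pc1):
        labels[i] = f"S{rank + 1}"
    return [
        Substate(label=labels[i], mode_location=peaks[i][1], peak_density=peaks[i][0])
        for i in range(len(peaks))
    ]


def substate_average_structure(
    frames: np.ndarray,
    projections: np.ndarray,
    substate: Substate,
    radius: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Average structure over frames whose projection lies within ``radius``
    (A, Euclidean in the map's PC subspace) of the substate mode.

    Returns (mean_frame, member_indices); the member list is also recorded
    on the substate. Raises if no frame qualifies.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    frames = np.asarray(frames, dtype=float)
    projections = np.asarray(projections, dtype=float)
    if projections.ndim == 1:
        projections = projections[:, None]
    d = len(substate.mode_location)
    dist = np.linalg.norm(projections[:, :d] - substate.mode_location, axis=1)
    members = np.where(dist <= radius)[0]
    if members.size == 0:
        raise ValueError(
            f"no conformer within {radius} A of substate {substate.label}; "
            "try a larger radius"
        )
    substate.member_frames = members
    return frames[members].mean(axis=0), members


def substate_populations(
    projections: np.ndarray,
    substates: list[Substate],
    weights: np.ndarray | None = None,
) -> dict:
    """Fraction of (optionally weighted) population assigned to each
    substate by nearest-mode partitioning of the PC subspace."""
    projections = np.asarray(projections, dtype=float)
    if projections.ndim == 1:
        projections = projections[:, None]
    if not substates:
        raise ValueError("no substates given")
    d = len(substates[0].mode_location)
    modes = np.stack([s.mode_location for s in substates])
    dist = np.linalg.norm(projections[:, None, :d] - modes[None, :, :], axis=2)
    assignment = np.argmin(dist, axis=1)
    if weights is None:
        weights = np.full(projections.shape[0], 1.0 / projections.shape[0])
    return {
        s.label: float(weights[assignment == i].sum()) for i, s in enumerate(substates)
    }


def write_map(pop_map: PopulationMap, path) -> None:
    """Serialize a map as TSV with a 3-line header (origin, resolution, dim)."""
    with open(path, "w") as fh:
        fh.write("# origin\t" + "\t".join(f"{v:.10g}" for v in pop_map.grid_origin) + "\n")
        fh.write(f"# resolution\t{pop_map.resolution:.10g}\n")
        fh.write(f"# dim\t{pop_map.dim}\tsigned\t{int(pop_map.signed)}\n")
        np.savetxt(fh, np.atleast_2d(pop_map.densities), delimiter="\t", fmt="%.12e")


def read_map(path) -> PopulationMap:
    """Read a map written by :func:`write_map`."""
    with open(path) as fh:
        origin = np.array([float(v) for v in fh.readline().split("\t")[1:]])
        resolution = float(fh.readline().split("\t")[1])
        parts = fh.readline().split("\t")
        dim = int(parts[1])
        signed = bool(int(parts[3]))
        dens = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if dim == 1:
        dens = dens.ravel()
    return PopulationMap(origin, resolution, dens, dim, signed=signed)
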