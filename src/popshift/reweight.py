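"""Ligand placement along an approach coordinate and Boltzmann reweighting
of snapshot populations.

Given a Boltzmann-sampled free-state ensemble of n snapshots (uniform prior
weights p_inf(j) = 1/n) and a rigid ligand translated to a series of
distances from its bound pose, each snapshot j is reweighted by the
inter-molecular energy change it experiences:

    p_dist(j) ∝ p_inf(j) * exp(-[E_dist(j) - E_inf(j)] / k_B T)

normalized to sum to 1. E_inf is evaluated with the ligand at a far
reference distance (1000 A) rather than set to zero, so any cutoff
artifacts cancel symmetrically. The reweighted ensemble is then summarised
as population maps in PC space, difference maps against the unperturbed
map, 1D projections along the first principal component, and
elec-only/vdw-only decomposition maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import kt
from .energy import EnergyModel, interaction_energy_batch
from .ensemble import ConformerEnsemble, Topology
from .pca import PopulationMap, difference_map, population_map
from .superpose import kabsch_superpose

__all__ = [
    "ApproachSpec",
    "ReweightResult",
    "interface_direction",
    "place_ligand",
    "weights_from_energy_diff",
    "boltzmann_reweight",
    "reweighted_population_analysis",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)

#: Default ligand-approach distances (A), the standard scan of the analysis.
DEFAULT_DISTANCES = (9.0, 12.0, 15.0, 18.0)

#: Far reference distance (A) approximating infinite separation.
REFERENCE_DISTANCE = 1000.0

#: Default contact cutoff (A) for interface detection.
DEFAULT_CONTACT_CUTOFF = 5.0


@dataclass
class ApproachSpec:
    """Ligand approach geometry: unit direction pointing away from the
    binding interface, scan distances, and the bound-pose coordinates at
    distance 0."""

    direction: np.ndarray
    distances: tuple
    bound_pose: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.bound_pose = np.asarray(self.bound_pose, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("approach direction must be a unit vector")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be non-negative")

    def rotated(self, angle_deg: float, axis: np.ndarray) -> "ApproachSpec":
        """Alternative approach direction: the interface normal rotated by
        ``angle_deg`` about ``axis`` (for direction-robustness scans)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        theta = np.deg2rad(angle_deg)
        k = axis
        v = self.direction
        rotated = (
            v * np.cos(theta)
            + np.cross(k, v) * np.sin(theta)
            + k * np.dot(k, v) * (1 - np.cos(theta))
        )
        return ApproachSpec(rotated / np.linalg.norm(rotated), self.distances, self.bound_pose)


@dataclass
class ReweightResult:
    """Per-snapshot Boltzmann weights and energies at one ligand distance."""

    distance: float
    weights: np.ndarray
    e_dist: np.ndarray
    e_inf: np.ndarray
    n: int
    temperature: float
    component_weights: dict = field(default_factory=dict)
    clash_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        if len(self.weights) != self.n:
            raise ValueError("weights length must equal snapshot count")

    @property
    def effective_sample_size(self) -> float:
        return effective_sample_size(self.weights)


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size 1 / sum(w^2) of a normalized weight
    vector; n for uniform weights, ~1 under severe degeneracy."""
    weights = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(weights**2))


def interface_direction(
    protein_coords: np.ndarray,
    ligand_coords: np.ndarray,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> np.ndarray:
    """Unit normal of the binding interface, oriented from the protein
    toward the ligand.

    Contacts are all protein-ligand atom pairs within ``contact_cutoff``;
    the direction is the normal of the least-squares plane through the
    contact midpoints, sign-fixed to point away from the protein's center
    of geometry.
    """
    protein_coords = np.asarray(protein_coords, dtype=float)
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    diff = protein_coords[:, None, :] - ligand_coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    pairs = np.argwhere(dist <= contact_cutoff)
    if pairs.shape[0] < 3:
        raise ValueError(
            f"only {pairs.shape[0]} contact pairs within {contact_cutoff} A; "
            "increase the contact cutoff"
        )
    midpoints = 0.5 * (protein_coords[pairs[:, 0]] + ligand_coords[pairs[:, 1]])
    centered = midpoints - midpoints.mean(axis=0)
    # plane normal = singular vector of least variance
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    outward = midpoints.mean(axis=0) - protein_coords.mean(axis=0)
    if np.dot(normal, outward) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def place_ligand(spec: ApproachSpec, distance: float) -> np.ndarray:
    """Rigidly translate the bound pose by ``distance`` along the approach
    direction; distance 0 returns the bound pose itself."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return spec.bound_pose + distance * spec.direction


def weights_from_energy_diff(delta_e: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized Boltzmann weights exp(-dE/kT)/Z from per-snapshot energy
    differences, overflow-guarded by subtracting the minimum difference."""
    delta_e = np.asarray(delta_e, dtype=float)
    beta_e = (delta_e - delta_e.min()) / kt(temperature)
    w = np.exp(-beta_e)
    return w / w.sum()


def boltzmann_reweight(
    ensemble: ConformerEnsemble,
    protein_top: Topology,
    ligand_top: Topology,
    spec: ApproachSpec,
    model: EnergyModel | None = None,
    temperature: float = 300.0,
    align_reference: np.ndarray | None = None,
    align_subset: np.ndarray | None = None,
    component_decomposition: bool = True,
) -> list[ReweightResult]:
    """Reweight snapshot populations for every distance of an approach scan.

    Each snapshot may first be superposed onto ``align_reference`` (the
    complex's protein frame, over ``align_subset`` core atoms) so the rigid
    ligand poses are meaningful for every snapshot; pass None when the
    ensemble is already in the complex frame. E_inf is evaluated with the
    ligand at the 1000 A reference position. With
    ``component_decomposition``, elec-only and vdw-only weight sets are
    attached for the energy-component analysis.
    """
    if ensemble.n_frames == 0:
        raise ValueError("ensemble is empty")
    model = model or EnergyModel()

    frames = ensemble.frames
    if align_reference is not None:
        aligned = np.empty_like(frames)
        for i in range(frames.shape[0]):
            _, aligned[i] = kabsch_superpose(frames[i], align_reference, align_subset)
        frames = aligned

    far_pose = place_ligand(spec, REFERENCE_DISTANCE)
    e_inf_elec, e_inf_vdw, e_inf_gb, _ = interaction_energy_batch(
        frames, protein_top, far_pose, ligand_top, model
    )
    enabled = model.components_enabled
    e_inf = e_inf_elec + e_inf_vdw + e_inf_gb

    results = []
    for distance in spec.distances:
        pose = place_ligand(spec, distance)
        elec, vdw, gb, clash = interaction_energy_batch(
            frames, protein_top, pose, ligand_top, model
        )
        e_dist = elec + vdw + gb
        weights = weights_from_energy_diff(e_dist - e_inf, temperature)
        component_weights = {}
        if component_decomposition:
            # polar (elec + gb screening) and apolar (vdw) contributions
            if "elec" in enabled:
                component_weights["elec"] = weights_from_energy_diff(
                    (elec + gb) - (e_inf_elec + e_inf_gb), temperature
                )
            if "vdw" in enabled:
                component_weights["vdw"] = weights_from_energy_diff(
                    vdw - e_inf_vdw, temperature
                )
        result = ReweightResult(
            distance=float(distance),
            weights=weights,
            e_dist=e_dist,
            e_inf=e_inf,
            n=ensemble.n_frames,
            temperature=temperature,
            component_weights=component_weights,
            clash_fraction=float(np.mean(clash)),
        )
        ess = result.effective_sample_size
        if ess < 0.01 * ensemble.n_frames:
            logger.warning(
                "severe weight degeneracy at %.1f A: effective sample size %.1f of %d",
                distance, ess, ensemble.n_frames,
            )
        results.append(result)
    return results


def reweighted_population_analysis(
    results: list[ReweightResult],
    projections: np.ndarray,
    resolution: float = 0.6,
    smoothing: bool = False,
) -> dict:
    """Population maps, difference maps and 1D projections per distance.

    For each :class:`ReweightResult` the snapshot projections (PC1, PC2)
    are rebinned with the reweighted weights on a common grid (default
    0.6 A cells), compared against the uniform-weight (free-state) map, and
    reduced to 1D along the first principal component. Component-restricted
    weight sets produce matching decomposition maps.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.ndim != 2 or projections.shape[1] < 2:
        raise ValueError("projections must be (n_snapshots, >=2)")
    n = projections.shape[0]
    for res in results:
        if res.n != n:
            raise ValueError("projections do not cover all snapshots")
    extent = tuple((projections[:, k].min(), projections[:, k].max()) for k in range(2))
    extent_1d = (extent[0],)
    free_map = population_map(projections, resolution, dim=2, smoothing=smoothing, extent=extent)
    free_1d = population_map(projections[:, 0], resolution, dim=1, smoothing=smoothing, extent=extent_1d)
    out = {
        "free_map": free_map,
        "free_1d": free_1d,
        "distances": {},
    }
    for res in results:
        wmap = population_map(
            projections, resolution, dim=2, weights=res.weights, smoothing=smoothing, extent=extent
        )
        w1d = population_map(
            projections[:, 0], resolution, dim=1, weights=res.weights,
            smoothing=smoothing, extent=extent_1d,
        )
        entry = {
            "map": wmap,
            "difference": difference_map(wmap, free_map),
            "projection_1d": w1d,
            "difference_1d": difference_map(w1d, free_1d),
            "effective_sample_size": res.effective_sample_size,
            "components": {},
        }
        for name, cw in res.component_weights.items():
            cmap = population_map(
                projections, resolution, dim=2, weights=cw, smoothing=smoothing, extent=extent
            )
            entry["components"][name] = {
                "map": cmap,
                "difference": difference_map(cmap, free_map),
            }
        out["distances"][res.distance] = entry
    return out
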