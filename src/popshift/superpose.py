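"""Rigid-body superposition and ensemble comparison statistics.

Implements Kabsch least-squares superposition and the statistics used to
compare a conformer ensemble against a set of target (e.g. crystal)
structures: overall Calpha RMSD, per-atom RMSF about the ensemble mean,
closest-conformer search, and the residue-wise RMSD profile

    rmsd_k = sqrt( (1/N) * sum_i d_{i,k}^2 )

where d_{i,k} is the Calpha-Calpha distance at residue k between target i
and its closest ensemble conformer, measured after the global superposition
that minimises the overall Calpha RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ConformerEnsemble

__all__ = [
    "RigidTransform",
    "ResidueRMSDProfile",
    "kabsch_superpose",
    "rmsd_ca",
    "rmsf",
    "closest_conformer",
    "residuewise_rmsd",
    "pool_residue_distances",
]


def pool_residue_distances(distances: np.ndarray) -> np.ndarray:
    """Pool per-target, per-residue distances d_{i,k} into the residue-wise
    RMSD profile: rmsd_k = sqrt( (1/N) sum_i d_{i,k}^2 ), averaging over the
    N target structures before the square root."""
    distances = np.asarray(distances, dtype=float)
    return np.sqrt(np.mean(distances**2, axis=0))


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal within 1e-9")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ResidueRMSDProfile:
    """Residue-wise RMSD between targets and their closest ensemble
    conformers, plus the closest-conformer bookkeeping."""

    res_id: np.ndarray
    rmsd: np.ndarray
    n_structures: int
    closest_indices: np.ndarray
    closest_rmsd: np.ndarray


def _check_subset(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 subset atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("subset atoms are collinear or degenerate")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal rotation is found over the ``subset`` atoms (all atoms when
    None) and applied to every atom of ``mobile``. Returns the transform and
    the transformed copy.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = slice(None) if subset is None else np.asarray(subset)
    m_sub, r_sub = mobile[idx], reference[idx]
    if m_sub.shape != r_sub.shape:
        raise ValueError("subset atom counts of mobile and reference differ")
    _check_subset(r_sub)
    m_cen = m_sub.mean(axis=0)
    r_cen = r_sub.mean(axis=0)
    h = (m_sub - m_cen).T @ (r_sub - r_cen)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = r_cen - rotation @ m_cen
    transform = RigidTransform(rotation, translation)
    return transform, transform.apply(mobile)


def rmsd_ca(
    a: np.ndarray,
    b: np.ndarray,
    subset: np.ndarray | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation between two frames over ``subset`` atoms,
    optionally after least-squares superposition of ``a`` onto ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    idx = slice(None) if subset is None else np.asarray(subset)
    if a[idx].shape != b[idx].shape:
        raise ValueError("subset atom counts differ between frames")
    if superpose:
        _, a = kabsch_superpose(a, b, subset)
    diff = a[idx] - b[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _superposed_frames(frames: np.ndarray, reference: np.ndarray, subset) -> np.ndarray:
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        _, out[i] = kabsch_superpose(frame, reference, subset)
    return out


def rmsf(
    ensemble: ConformerEnsemble | np.ndarray,
    subset: np.ndarray | None = None,
    align: bool = False,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble-mean
    position. With ``align=True`` frames are first superposed onto the mean
    structure (iterated once from the plain mean)."""
    frames = ensemble.frames if isinstance(ensemble, ConformerEnsemble) else np.asarray(ensemble)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if align:
        mean = frames.mean(axis=0)
        frames = _superposed_frames(frames, mean, subset)
        mean = frames.mean(axis=0)
        frames = _superposed_frames(frames, mean, subset)
    idx = slice(None) if subset is None else np.asarray(subset)
    sel = frames[:, idx, :]
    dev = sel - sel.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def closest_conformer(
    target: np.ndarray,
    ensemble: ConformerEnsemble | np.ndarray,
    subset: np.ndarray | None = None,
    stride: int = 1,
) -> tuple[int, float]:
    """Index and RMSD of the ensemble frame closest to ``target`` in
    superposed subset RMSD, scanning frames 0, stride, 2*stride, ...
    Ties break to the lowest frame index."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = ensemble.frames if isinstance(ensemble, ConformerEnsemble) else np.asarray(ensemble)
    best_idx, best_rmsd = -1, np.inf
    for i in range(0, frames.shape[0], stride):
        value = rmsd_ca(frames[i], target, subset, superpose=True)
        if value < best_rmsd - 1e-15:
            best_idx, best_rmsd = i, value
    return best_idx, best_rmsd


def residuewise_rmsd(
    targets: ConformerEnsemble,
    ensemble: ConformerEnsemble,
    stride: int = 1,
) -> ResidueRMSDProfile:
    """Residue-wise RMSD profile of targets against their closest ensemble
    conformers.

    Both inputs must carry one Calpha-like atom per residue; residues are
    matched by ``res_id`` and residues missing from either side are excluded
    from the profile. For each target the closest conformer is found by
    overall superposed RMSD over the shared residues; per-residue distances
    d_{i,k} are measured in that superposition and pooled as
    sqrt(mean_i d_{i,k}^2).
    """
    shared = np.intersect1d(targets.res_id, ensemble.res_id)
    if shared.size == 0:
        raise ValueError("targets and ensemble share no residues")
    t_idx = np.array([np.where(targets.res_id == r)[0][0] for r in shared])
    e_idx = np.array([np.where(ensemble.res_id == r)[0][0] for r in shared])

    n_targets = targets.n_frames
    d_sq = np.zeros((n_targets, shared.size))
    closest_idx = np.zeros(n_targets, dtype=int)
    closest_rmsd = np.zeros(n_targets)
    for i in range(n_targets):
        t_sub = targets.frames[i][t_idx]
        best, best_val = -1, np.inf
        for j in range(0, ensemble.n_frames, stride):
            value = rmsd_ca(ensemble.frames[j][e_idx], t_sub, superpose=True)
            if value < best_val - 1e-15:
                best, best_val = j, value
        closest_idx[i], closest_rmsd[i] = best, best_val
        _, aligned = kabsch_superpose(ensemble.frames[best][e_idx], t_sub)
        d_sq[i] = np.sum((aligned - t_sub) ** 2, axis=1)
    return ResidueRMSDProfile(
        res_id=shared,
        rmsd=pool_residue_distances(np.sqrt(d_sq)),
        n_structures=n_targets,
        closest_indices=closest_idx,
        closest_rmsd=closest_rmsd,
    )
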