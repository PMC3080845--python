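"""Residual dipolar coupling (RDC) back-calculation and Q-factor validation.

RDCs report the orientation of bond vectors relative to a molecular
alignment tensor. For an ensemble, the bond-vector second-order terms are
averaged over frames first (single tensor per alignment medium), then the
five independent tensor components are fitted by linear least squares
(the standard SVD procedure). Agreement is summarised by the Q-factor

    Q = rms(D_calc - D_exp) / rms(D_exp).

The convergence-vs-window analysis refits the tensor on contiguous frame
windows of growing size and averages Q per window size, tracing how the
apparent agreement improves as conformational averaging becomes complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble

__all__ = ["RDCDataset", "AlignmentFit", "order_matrix", "fit_alignment_tensor_svd", "convergence_curve"]

RDC_COLUMNS = ["res_id", "atom1", "atom2", "medium", "D_exp"]


@dataclass
class RDCDataset:
    """Table of measured couplings: one row per (residue, medium)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RDC_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"RDC table lacks columns: {missing}")
        dup = self.records.duplicated(subset=["res_id", "medium"])
        if dup.any():
            raise ValueError("duplicate (res_id, medium) pairs in RDC table")

    @property
    def media(self) -> list:
        return sorted(self.records["medium"].unique())

    def for_medium(self, medium) -> pd.DataFrame:
        return self.records[self.records["medium"] == medium]

    @classmethod
    def from_tsv(cls, path) -> "RDCDataset":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.records[RDC_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class AlignmentFit:
    """Fitted alignment tensor (5 independent components) for one medium."""

    medium: object
    tensor: np.ndarray
    d_calc: np.ndarray
    d_exp: np.ndarray
    q_value: float
    record_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _bond_vectors(ensemble: ConformerEnsemble, records: pd.DataFrame):
    """Per-frame bond vectors for each RDC record.

    The vector runs from ``atom1`` of ``res_id`` to ``atom2`` of the same
    residue, or of residue ``res_id + 1`` when the partner is not found in
    the residue itself (covers pseudo-bonds between consecutive Calpha
    atoms). Records with missing atoms are skipped with a warning.
    """
    key = {(int(r), str(n)): i for i, (r, n) in enumerate(zip(ensemble.res_id, ensemble.atom_name))}
    used, vec_idx = [], []
    for row_pos, row in enumerate(records.itertuples(index=False)):
        i = key.get((int(row.res_id), str(row.atom1)))
        j = key.get((int(row.res_id), str(row.atom2)))
        if j is None or j == i:
            j = key.get((int(row.res_id) + 1, str(row.atom2)))
        if i is None or j is None:
            warnings.warn(
                f"RDC record residue {row.res_id} ({row.atom1}-{row.atom2}): "
                "bond-partner atom missing, record skipped",
                stacklevel=2,
            )
            continue
        used.append(row_pos)
        vec_idx.append((i, j))
    if not vec_idx:
        raise ValueError("no RDC record matched the ensemble's atoms")
    idx = np.array(vec_idx)
    vectors = ensemble.frames[:, idx[:, 1], :] - ensemble.frames[:, idx[:, 0], :]
    return np.array(used, dtype=int), vectors  # (n_frames, n_records, 3)


def order_matrix(ensemble: ConformerEnsemble, records: pd.DataFrame):
    """Ensemble-averaged linear design matrix mapping the 5 tensor
    components to couplings.

    Rows follow the standard reduced basis over the unit bond vector u:
    [u_y^2 - u_x^2, u_z^2 - u_x^2, 2 u_x u_y, 2 u_x u_z, 2 u_y u_z],
    averaged over frames before fitting (one tensor per medium).
    """
    used, vectors = _bond_vectors(ensemble, records)
    norms = np.linalg.norm(vectors, axis=2, keepdims=True)
    u = vectors / norms
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    rows = np.stack(
        [uy**2 - ux**2, uz**2 - ux**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz], axis=-1
    )
    return used, rows.mean(axis=0)  # (n_records, 5)


def back_calculate(ensemble: ConformerEnsemble, records: pd.DataFrame, tensor: np.ndarray):
    """Ensemble-averaged couplings predicted by a given alignment tensor."""
    used, a = order_matrix(ensemble, records)
    return used, a @ np.asarray(tensor, dtype=float)


def fit_alignment_tensor_svd(
    ensemble: ConformerEnsemble | np.ndarray,
    rdc: RDCDataset,
    medium,
) -> AlignmentFit:
    """Least-squares (SVD) fit of the alignment tensor for one medium.

    Requires at least 5 usable records. Returns the fitted 5-component
    tensor, the back-calculated couplings and the Q-factor.
    """
    records = rdc.for_medium(medium)
    if len(records) < 5:
        raise ValueError(f"medium {medium!r} has {len(records)} records; need >= 5")
    used, a = order_matrix(ensemble, records)
    d_exp = records["D_exp"].to_numpy(dtype=float)[used]
    if a.shape[0] < 5:
        raise ValueError("fewer than 5 usable records after atom matching")
    rms_exp = np.sqrt(np.mean(d_exp**2))
    if rms_exp == 0:
        raise ValueError(f"all couplings are zero in medium {medium!r}: Q undefined (degenerate)")
    tensor, *_ = np.linalg.lstsq(a, d_exp, rcond=None)
    d_calc = a @ tensor
    q = float(np.sqrt(np.mean((d_calc - d_exp) ** 2)) / rms_exp)
    return AlignmentFit(
        medium=medium,
        tensor=tensor,
        d_calc=d_calc,
        d_exp=d_exp,
        q_value=q,
        record_index=used,
    )


def average_q(ensemble: ConformerEnsemble, rdc: RDCDataset) -> float:
    """Q averaged over all alignment media."""
    return float(
        np.mean([fit_alignment_tensor_svd(ensemble, rdc, m).q_value for m in rdc.media])
    )


def convergence_curve(
    ensemble: ConformerEnsemble,
    rdc: RDCDataset,
    window_sizes,
) -> pd.DataFrame:
    """Average Q as a function of the averaging-window length.

    For each window size w the ensemble is cut into contiguous
    non-overlapping windows of w frames; the tensor is refitted per window
    and per medium and the Q-values are averaged. A window spanning the full
    ensemble reproduces the global fit's Q.
    """
    rows = []
    for w in window_sizes:
        w = int(w)
        if w <= 0:
            raise ValueError("window sizes must be positive")
        if w > ensemble.n_frames:
            raise ValueError(f"window {w} exceeds ensemble length {ensemble.n_frames}")
        qs = []
        for start in range(0, ensemble.n_frames - w + 1, w):
            sub = ensemble.subset_frames(np.arange(start, start + w))
            for medium in rdc.media:
                qs.append(fit_alignment_tensor_svd(sub, rdc, medium).q_value)
        rows.append({"window": w, "q_av": float(np.mean(qs)), "n_windows": len(qs) // len(rdc.media)})
    return pd.DataFrame(rows)
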