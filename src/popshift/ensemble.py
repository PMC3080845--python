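"""Conformer-ensemble container and structural-ensemble I/O.

The :class:`ConformerEnsemble` is the central object of the package: an
ordered set of coordinate frames (snapshots) sharing one atom table. Frames
are stored as a dense ``(n_frames, n_atoms, 3)`` array in Angstrom. Ensembles
are exchanged on disk as multi-model PDB files (MODEL/ENDMDL records, PDB
v3.3 fixed width) via biotite; per-atom physical parameters travel in a
separate whitespace-delimited topology table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ConformerEnsemble",
    "Topology",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_topology_table",
    "write_topology_table",
    "select_atoms",
    "atom_mask",
]

#: Largest coordinate magnitude representable in the fixed-width PDB field.
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999

TOPOLOGY_COLUMNS = ["atom_id", "res_id", "name", "charge", "sigma", "epsilon", "born_radius"]


@dataclass
class Topology:
    """Per-atom physical parameters: charge (e), LJ sigma (A), LJ epsilon
    (kcal/mol) and effective Born radius (A), aligned with an ensemble's
    atom order."""

    charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    born_radius: np.ndarray

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.born_radius = np.asarray(self.born_radius, dtype=float)
        n = len(self.charge)
        for name in ("lj_sigma", "lj_epsilon", "born_radius"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match charge length {n}")
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be > 0 for every atom")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0 for every atom")
        if np.any(self.born_radius <= 0):
            raise ValueError("born_radius must be > 0 for every atom")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    @property
    def net_charge(self) -> float:
        return float(self.charge.sum())

    def subset(self, indices: np.ndarray) -> "Topology":
        return Topology(
            self.charge[indices],
            self.lj_sigma[indices],
            self.lj_epsilon[indices],
            self.born_radius[indices],
        )


@dataclass
class ConformerEnsemble:
    """Ordered coordinate frames with shared atom metadata.

    Parameters
    ----------
    atom_id, res_id : int arrays of length n_atoms
        PDB-convention identifiers; ``res_id`` is 1-based.
    atom_name, element : str arrays of length n_atoms
    frames : float array, shape (n_frames, n_atoms, 3), Angstrom
    frame_times : optional float array (ns), one entry per frame
    weights : optional per-frame probabilities (non-negative, sum to 1)
    meta : free-form provenance dictionary (seeds, acceptance rates, ...)
    """

    atom_id: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    frames: np.ndarray
    frame_times: np.ndarray | None = None
    weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_id = np.asarray(self.atom_id, dtype=int)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.frames.shape[1]
        for name in ("atom_id", "res_id", "atom_name", "element"):
            if len(getattr(self, name)) != n_atoms:
                raise ValueError(f"{name} length does not match atom count {n_atoms}")
        key = list(zip(self.res_id.tolist(), self.atom_name.tolist()))
        if len(set(key)) != len(key):
            raise ValueError("(res_id, atom_name) pairs must be unique within a frame")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != self.n_frames:
                raise ValueError("weights length must equal n_frames")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1 within 1e-9")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def subset_frames(self, indices) -> "ConformerEnsemble":
        indices = np.asarray(indices)
        return ConformerEnsemble(
            self.atom_id,
            self.res_id,
            self.atom_name,
            self.element,
            self.frames[indices],
            frame_times=None if self.frame_times is None else self.frame_times[indices],
            weights=None,
            meta=dict(self.meta),
        )

    def subset_atoms(self, indices) -> "ConformerEnsemble":
        indices = np.asarray(indices)
        return ConformerEnsemble(
            self.atom_id[indices],
            self.res_id[indices],
            self.atom_name[indices],
            self.element[indices],
            self.frames[:, indices, :],
            frame_times=self.frame_times,
            weights=self.weights,
            meta=dict(self.meta),
        )


def atom_mask(
    ensemble: ConformerEnsemble,
    res_range: tuple[int, int] | None = None,
    atom_names=None,
) -> np.ndarray:
    """Boolean mask over atoms matching an inclusive residue range and/or an
    atom-name filter (e.g. ``("CA",)``)."""
    mask = np.ones(ensemble.n_atoms, dtype=bool)
    if res_range is not None:
        lo, hi = res_range
        mask &= (ensemble.res_id >= lo) & (ensemble.res_id <= hi)
    if atom_names is not None:
        mask &= np.isin(ensemble.atom_name, list(atom_names))
    return mask


def select_atoms(
    ensemble: ConformerEnsemble,
    res_range: tuple[int, int] | None = None,
    atom_names=None,
) -> ConformerEnsemble:
    """Subset an ensemble by residue range (1-based, inclusive on both ends)
    and atom names, preserving frame order.

    Raises ``ValueError`` if nothing matches.
    """
    mask = atom_mask(ensemble, res_range, atom_names)
    if not mask.any():
        raise ValueError(
            f"selection matched no atoms (res_range={res_range}, atom_names={atom_names})"
        )
    return ensemble.subset_atoms(np.where(mask)[0])


def _model_atom_counts(path) -> list[int]:
    """Atom-record counts per MODEL block, for diagnostics on ragged files."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not counts and current:
        counts.append(current)
    elif in_model:
        counts.append(current)
    return counts


def read_multimodel_pdb(path) -> ConformerEnsemble:
    """Read a (multi-)model PDB file into a :class:`ConformerEnsemble`.

    Frame order follows MODEL order; a single-structure file yields one
    frame. Alternate locations other than 'A'/blank are dropped (logged via
    a warning by biotite's altloc handling). Files whose models disagree in
    atom count are rejected, naming the first offending model.
    """
    pdb_file = PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:
        counts = _model_atom_counts(path)
        if len(set(counts)) > 1:
            bad = next(i for i, c in enumerate(counts) if c != counts[0])
            raise ValueError(
                f"inconsistent atom count across models in {path}: model {bad + 1} "
                f"has {counts[bad]} atoms, model 1 has {counts[0]}"
            ) from exc
        raise
    if isinstance(stack, struc.AtomArray):  # defensive; model=None returns a stack
        stack = struc.stack([stack])
    return ConformerEnsemble(
        atom_id=np.arange(1, stack.array_length() + 1),
        res_id=stack.res_id,
        atom_name=stack.atom_name,
        element=stack.element,
        frames=stack.coord.astype(float),
    )


def write_multimodel_pdb(ensemble: ConformerEnsemble, path, single_model_records: bool = False) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks).

    A one-frame ensemble is written without MODEL records when
    ``single_model_records`` is False-compatible with either dialect on read.
    Coordinates outside the fixed-width PDB field raise ``ValueError``.
    """
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    coords = ensemble.frames
    if coords.max() > _PDB_COORD_MAX or coords.min() < _PDB_COORD_MIN:
        raise ValueError(
            "coordinates exceed the fixed-width PDB coordinate field "
            f"[{_PDB_COORD_MIN}, {_PDB_COORD_MAX}] A"
        )
    n = ensemble.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord[:] = coords
    stack.chain_id = np.full(n, "A")
    stack.res_id = ensemble.res_id
    stack.res_name = np.full(n, "GLY")
    stack.atom_name = ensemble.atom_name
    stack.element = np.where(ensemble.element == "", "C", ensemble.element)
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = PDBFile()
    if ensemble.n_frames == 1 and not single_model_records:
        pdb_file.set_structure(stack[0])
    else:
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_topology_table(path) -> Topology:
    """Read a whitespace-delimited per-atom parameter table.

    Expected header: ``atom_id res_id name charge sigma epsilon born_radius``.
    Invalid physical parameters are rejected naming the offending row
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"topology table {path} lacks columns: {missing}")
    for col, ok in (
        ("sigma", df["sigma"] > 0),
        ("epsilon", df["epsilon"] >= 0),
        ("born_radius", df["born_radius"] > 0),
    ):
        bad = np.where(~ok.to_numpy())[0]
        if bad.size:
            raise ValueError(f"invalid {col} in topology table row {bad[0] + 1}")
    return Topology(
        charge=df["charge"].to_numpy(),
        lj_sigma=df["sigma"].to_numpy(),
        lj_epsilon=df["epsilon"].to_numpy(),
        born_radius=df["born_radius"].to_numpy(),
    )


def write_topology_table(topology: Topology, path, ensemble: ConformerEnsemble | None = None) -> None:
    """Write a topology in the tabular on-disk format. Atom identifiers are
    taken from ``ensemble`` when given, else numbered 1..n."""
    n = topology.n_atoms
    if ensemble is not None:
        if ensemble.n_atoms != n:
            raise ValueError("ensemble atom count does not match topology")
        atom_id, res_id, name = ensemble.atom_id, ensemble.res_id, ensemble.atom_name
    else:
        atom_id = np.arange(1, n + 1)
        res_id = np.arange(1, n + 1)
        name = np.full(n, "CA")
    df = pd.DataFrame(
        {
            "atom_id": atom_id,
            "res_id": res_id,
            "name": name,
            "charge": topology.charge,
            "sigma": topology.lj_sigma,
            "epsilon": topology.lj_epsilon,
            "born_radius": topology.born_radius,
        }
    )
    df.to_csv(path, sep="\t", index=False)
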