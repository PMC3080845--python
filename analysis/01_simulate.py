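#!/usr/bin/env python
"""Generate the synthetic study inputs: a Boltzmann-sampled free-state
ensemble of the three-basin bead protein, its topology table, and the rigid
toy ligand.

The full ensemble (200k snapshots) is regenerated on the fly by later
stages; here a 500-frame thinned copy is written as a multi-model PDB for
inspection, together with the per-atom parameter table and the ligand.
"""

import argparse
from pathlib import Path

import numpy as np

from popshift.ensemble import write_multimodel_pdb, write_topology_table
from popshift.synthetic import make_toy_ligand, make_toy_system, sample_metropolis


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    system = make_toy_system(n_beads=5, temperature=300.0, seed=args.seed)
    print(f"system: {len(system.basins)} basins, {system.reference.shape[0]} beads, 300 K")

    ens = sample_metropolis(system, 200_000, step_size=0.25, seed=args.seed + 1)
    print(f"sampled 200000 snapshots, acceptance rate {ens.meta['acceptance_rate']:.3f}")

    thinned = ens.subset_frames(np.arange(0, ens.n_frames, 400))
    write_multimodel_pdb(thinned, args.out / "free_ensemble_thinned.pdb")
    write_topology_table(system.topology, args.out / "protein.top", ensemble=thinned)

    ligand_top, ligand_xyz = make_toy_ligand(3, net_charge=1.0, seed=args.seed + 2)
    np.savetxt(args.out / "ligand_xyz.tsv", ligand_xyz, delimiter="\t", fmt="%.6f")
    write_topology_table(ligand_top, args.out / "ligand.top")
    print(f"wrote thinned ensemble ({thinned.n_frames} frames), topology and ligand to {args.out}")


if __name__ == "__main__":
    main()
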