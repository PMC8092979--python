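#!/usr/bin/env python
"""Per-residue mobility and the side-chain network of the demo system.

Superposes every trailing frame of the synthetic coordinate trajectory
on the starting configuration, computes per-residue backbone RMSD,
applies the 10 Angstrom high-mobility filter, and builds the protein
side-chain network (20 Angstrom centroid cutoff) from the first frame.

Requires 02_simulate.py to have been run.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from allopath import build_pscn, high_mobility_residues, per_residue_rmsd
from allopath.structure_metrics import read_pdb_trajectory, write_edge_list

ROOT = os.path.join(os.path.dirname(__file__), "..")
SCRATCH = os.path.join(ROOT, "scratch", "demo")
OUT = os.path.join(ROOT, "results", "analysis")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    traj = read_pdb_trajectory(os.path.join(SCRATCH, "trajectory.pdb"))
    rmsd = per_residue_rmsd(traj)
    mobile = high_mobility_residues(rmsd, threshold=10.0)
    with open(os.path.join(OUT, "rmsd.tsv"), "w") as fh:
        fh.write("residue\trmsd\thigh_mobility\n")
        for rid in sorted(rmsd):
            fh.write(f"{rid}\t{rmsd[rid]:.3f}\t{int(rid in mobile)}\n")
    print(f"{len(rmsd)} residues; {len(mobile)} above 10 A: {mobile}")
    scaffold_max = max(v for r, v in rmsd.items() if r not in mobile)
    print(f"scaffold stays quiet (max {scaffold_max:.2f} A), so the filter "
          "isolates exactly the displaced loop")

    frame0 = traj.frames[0]
    graph = build_pscn(frame0, traj.atom_residue_ids, traj.atom_names, cutoff=20.0)
    write_edge_list(graph, os.path.join(OUT, "pscn_edges.tsv"))
    print(f"side-chain network at 20 A cutoff: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges "
          "(a 20 A cutoff is deliberately permissive; see docs/methods.md)")


if __name__ == "__main__":
    main()
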