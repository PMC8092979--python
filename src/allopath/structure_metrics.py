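"""Trajectory geometry: superposition, per-residue RMSD, side-chain network.

The high-mobility filter reproduces the standard steered-MD bookkeeping:
every frame is globally least-squares superposed on a reference frame
using the backbone atoms, per-residue backbone RMSD is averaged over a
trailing window of frames, and residues above a mobility threshold
(default 10 Angstrom) are flagged.

The protein side-chain network (PScN) treats residues as nodes and adds
an edge whenever the side-chain centroids of two residues lie within a
distance cutoff (default 20 Angstrom, configurable — far larger than a
typical contact cutoff, so treat the default as a deliberately permissive
neighbourhood graph rather than a contact map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ValidationError

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class CoordinateTrajectory:
    """Cartesian trajectory with per-atom residue assignment.

    Attributes
    ----------
    frames:
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atom_residue_ids:
        Author-numbered residue id per atom, shape ``(n_atoms,)``.
    atom_names:
        PDB atom names per atom (``CA``, ``N``...), shape ``(n_atoms,)``.
    """

    frames: np.ndarray
    atom_residue_ids: np.ndarray
    atom_names: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        rids = np.asarray(self.atom_residue_ids, dtype=int)
        names = np.asarray(self.atom_names, dtype=object)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.isfinite(frames).all():
            raise ValidationError("coordinates contain non-finite values")
        if rids.shape != (frames.shape[1],) or names.shape != (frames.shape[1],):
            raise ValidationError("atom metadata length must match atom count")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "atom_residue_ids", rids)
        object.__setattr__(self, "atom_names", names)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @property
    def backbone_mask(self) -> np.ndarray:
        return np.array([n in BACKBONE_ATOMS for n in self.atom_names], dtype=bool)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.atom_residue_ids)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    masked atoms.  The rotation is always proper (det +1).

    Raises
    ------
    GeometryError
        Fewer than 3 masked atoms, or the masked atoms are collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mob = mobile[mask]
    ref = reference[mask]
    if mob.shape != ref.shape:
        raise GeometryError("mobile and reference masked selections differ in size")
    if len(mob) < 3:
        raise GeometryError(f"need >=3 masked atoms for a rigid fit, got {len(mob)}")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    # Collinearity check: a line has rank-1 centred coordinates.
    sv = np.linalg.svd(mob0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise GeometryError("masked atoms are (near-)collinear; rotation is ill-determined")
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob0)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    rmsd = float(rssd / np.sqrt(len(mob)))
    return rmat, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rigid transform returned by :func:`superpose`."""
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def per_residue_rmsd(
    traj: CoordinateTrajectory,
    reference_frame_index: int = 0,
    window: int | None = None,
) -> dict[int, float]:
    """Backbone RMSD per residue after global superposition.

    Each frame in the trailing ``window`` (default: last 5% of frames,
    at least 1; ``window=1`` gives the final-frame reading) is superposed
    on the reference frame using all backbone atoms; the per-residue RMSD
    is the root of the mean squared deviation of that residue's backbone
    atoms pooled over the window frames.

    Residues with no backbone atoms are excluded with a logged warning.
    """
    n = traj.n_frames
    if window is None:
        window = max(1, round(0.05 * n))
    if not 1 <= window <= n - 1:
        raise ValueError(f"window must be in [1, {n - 1}], got {window}")
    bb = traj.backbone_mask
    if bb.sum() < 3:
        raise GeometryError("trajectory has fewer than 3 backbone atoms")
    ref = traj.frames[reference_frame_index]

    residue_ids = traj.residue_ids
    groups: dict[int, np.ndarray] = {}
    for rid in residue_ids:
        sel = (traj.atom_residue_ids == rid) & bb
        if not sel.any():
            logger.warning("residue %d has no backbone atoms; excluded from RMSD", rid)
            continue
        groups[int(rid)] = np.flatnonzero(sel)

    sq_sums = {rid: 0.0 for rid in groups}
    counts = {rid: 0 for rid in groups}
    for frame in traj.frames[n - window:]:
        rot, trans, _ = superpose(frame, ref, bb)
        fitted = apply_transform(frame, rot, trans)
        d2 = np.sum((fitted - ref) ** 2, axis=1)
        for rid, idx in groups.items():
            sq_sums[rid] += float(d2[idx].sum())
            counts[rid] += idx.size
    return {rid: float(np.sqrt(sq_sums[rid] / counts[rid])) for rid in groups}


def high_mobility_residues(
    rmsd_map: dict[int, float], threshold: float = 10.0
) -> list[int]:
    """Residues whose RMSD strictly exceeds ``threshold`` Angstrom, sorted."""
    return sorted(int(r) for r, v in rmsd_map.items() if v > threshold)


def side_chain_centroids(
    coords: np.ndarray,
    atom_residue_ids: np.ndarray,
    atom_names: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue side-chain centroid (mean of side-chain heavy atoms).

    Falls back to the C-alpha position for residues without side-chain
    atoms (glycine, or backbone-only models).  Hydrogens are excluded.
    Returns ``(residue_ids, centroids)``.
    """
    coords = np.asarray(coords, dtype=float)
    rids = np.asarray(atom_residue_ids, dtype=int)
    names = np.asarray(atom_names, dtype=object)
    residue_ids = np.unique(rids)
    centroids = np.empty((residue_ids.size, 3))
    for i, rid in enumerate(residue_ids):
        sel = rids == rid
        res_names = names[sel]
        res_xyz = coords[sel]
        heavy = np.array(
            [not str(n).startswith("H") for n in res_names], dtype=bool
        )
        side = heavy & np.array([n not in BACKBONE_ATOMS for n in res_names], dtype=bool)
        if side.any():
            centroids[i] = res_xyz[side].mean(axis=0)
        else:
            ca = np.array([n == "CA" for n in res_names], dtype=bool)
            pick = ca if ca.any() else heavy
            if not pick.any():
                pick = np.ones(res_xyz.shape[0], dtype=bool)
            centroids[i] = res_xyz[pick].mean(axis=0)
    return residue_ids, centroids


def build_pscn(
    coords: np.ndarray,
    atom_residue_ids: np.ndarray,
    atom_names: np.ndarray,
    cutoff: float = 20.0,
) -> nx.Graph:
    """Build the protein side-chain network from one coordinate frame.

    Nodes are residues; an edge (i, j), i != j, is added iff the distance
    between the side-chain centroids is <= ``cutoff`` (closed cutoff).
    Sequence-adjacent pairs are included like any other pair.  Each edge
    carries a ``distance`` attribute in Angstrom.
    """
    residue_ids, centroids = side_chain_centroids(coords, atom_residue_ids, atom_names)
    graph = nx.Graph()
    graph.add_nodes_from(int(r) for r in residue_ids)
    if residue_ids.size > 1:
        dmat = squareform(pdist(centroids))
        ii, jj = np.nonzero(np.triu(dmat <= cutoff, k=1))
        for i, j in zip(ii, jj):
            graph.add_edge(
                int(residue_ids[i]), int(residue_ids[j]), distance=float(dmat[i, j])
            )
    return graph


def write_edge_list(graph: nx.Graph, path, attribute: str = "distance") -> None:
    """Write a graph as a 3-column TSV: res_i, res_j, attribute value."""
    with open(path, "w") as fh:
        fh.write(f"res_i\tres_j\t{attribute}\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data[attribute]:.6g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    """Export a residue graph to GraphML (loadable by Cytoscape)."""
    nx.write_graphml(graph, path)


def read_pdb_trajectory(path) -> CoordinateTrajectory:
    """Read a multi-model PDB file (each MODEL = one snapshot)."""
    import biotite.structure.io.pdb as pdb

    stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
    return CoordinateTrajectory(
        frames=np.asarray(stack.coord, dtype=float),
        atom_residue_ids=np.asarray(stack.res_id, dtype=int),
        atom_names=np.asarray(stack.atom_name, dtype=object),
    )


def write_pdb_trajectory(traj: CoordinateTrajectory, path, residue_name: str = "ALA") -> None:
    """Write a trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = np.asarray(traj.frames, dtype=np.float32)
    stack.res_id = traj.atom_residue_ids
    stack.atom_name = traj.atom_names.astype(str)
    stack.res_name = np.full(n_atoms, residue_name)
    stack.chain_id = np.full(n_atoms, "A")
    stack.element = np.array(
        [str(n)[0] if str(n) else "C" for n in traj.atom_names], dtype="U2"
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
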