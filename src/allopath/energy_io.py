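"""Per-residue energy-decomposition tables: container, dialect, units.

The central object is :class:`EnergyTrajectory`: for every residue of a
protein, five force-field energy components (bond, angle, dihedral,
electrostatic, van der Waals) sampled at each snapshot of an MD
trajectory, in kJ/mol.  Everything downstream — energy-change
bookkeeping, correlation analysis, pathway inference — operates on this
container.

On disk the data live in a single long-format TSV dialect: one row per
(snapshot, residue) pair with the five component columns.  Long format
is robust to residue count and trivially streamable; exactly one dialect
avoids parser drift between stages.

Residue identifiers are author numbering from the source structure
(1-based, possibly gapped).  Dense 0-based indices are an internal
detail of the arrays and never appear in any output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError, FormatError, ValidationError

#: Canonical component order used everywhere in the package.
COMPONENT_TERMS: tuple[str, ...] = (
    "bond",
    "angle",
    "dihedral",
    "electrostatic",
    "vdw",
)

#: Composite terms derived from the five components.
DERIVED_TERM_NAMES: tuple[str, ...] = ("conformational", "nonbond", "total")

#: Thermochemical calorie; fixed so unit round trips are exact to 1e-9.
KCAL_TO_KJ: float = 4.184

_TABLE_COLUMNS = ("snapshot", "residue", *COMPONENT_TERMS)


def kcal_to_kj(x):
    """Convert kcal/mol values to kJ/mol."""
    return np.asarray(x, dtype=float) * KCAL_TO_KJ


def kj_to_kcal(x):
    """Convert kJ/mol values to kcal/mol."""
    return np.asarray(x, dtype=float) / KCAL_TO_KJ


@dataclass(frozen=True)
class EnergyTrajectory:
    """Five per-residue energy component series over trajectory snapshots.

    Parameters
    ----------
    residue_ids:
        Author-numbered residue identifiers, strictly increasing.
    components:
        Mapping term name -> array of shape ``(n_residues, n_snapshots)``
        in kJ/mol, with exactly the keys in :data:`COMPONENT_TERMS`.
    time_per_snapshot:
        Optional sampling interval in picoseconds (metadata only).
    """

    residue_ids: np.ndarray
    components: dict[str, np.ndarray]
    time_per_snapshot: float | None = None
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        rids = np.asarray(self.residue_ids, dtype=int)
        object.__setattr__(self, "residue_ids", rids)
        if rids.ndim != 1 or rids.size == 0:
            raise ValidationError("residue_ids must be a non-empty 1-D sequence")
        if not np.all(np.diff(rids) > 0):
            raise ValidationError("residue_ids must be unique and strictly increasing")
        if set(self.components) != set(COMPONENT_TERMS):
            missing = set(COMPONENT_TERMS) - set(self.components)
            extra = set(self.components) - set(COMPONENT_TERMS)
            raise ValidationError(
                f"components must have exactly {COMPONENT_TERMS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        shape = None
        comps: dict[str, np.ndarray] = {}
        for term in COMPONENT_TERMS:
            arr = np.asarray(self.components[term], dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"component {term!r} must be 2-D (residues x snapshots)")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValidationError(
                    f"component {term!r} has shape {arr.shape}, expected {shape}"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"component {term!r} contains non-finite values")
            comps[term] = arr
        assert shape is not None
        if shape[0] != rids.size:
            raise ValidationError(
                f"component rows ({shape[0]}) do not match residue count ({rids.size})"
            )
        if shape[1] < 2:
            raise ValidationError("need at least 2 snapshots")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "_index", {int(r): i for i, r in enumerate(rids)})

    @property
    def n_residues(self) -> int:
        return int(self.residue_ids.size)

    @property
    def n_snapshots(self) -> int:
        return int(self.components["bond"].shape[1])

    def index_of(self, residue_id: int) -> int:
        """Dense row index of an author-numbered residue."""
        try:
            return self._index[int(residue_id)]
        except KeyError:
            raise KeyError(f"residue {residue_id} not in trajectory") from None

    def term(self, name: str) -> np.ndarray:
        """Return the ``(R, N)`` series for a component or derived term."""
        if name in self.components:
            return self.components[name]
        if name in DERIVED_TERM_NAMES:
            d = derive_terms(self)
            return getattr(d, name)
        raise KeyError(f"unknown energy term {name!r}")

    def series(self, residue_id: int, term: str) -> np.ndarray:
        """Length-N series of one term for one residue."""
        return self.term(term)[self.index_of(residue_id)]


@dataclass(frozen=True)
class DerivedTerms:
    """Composite energy series: conformational, non-bond, total.

    Conformational energy is the covalent part (bond + angle + dihedral);
    non-bond energy is electrostatic + van der Waals; total is their sum.
    All arrays have shape ``(n_residues, n_snapshots)`` and the additivity
    holds exactly to accumulation tolerance (1e-9 kJ/mol).
    """

    conformational: np.ndarray
    nonbond: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        if not (self.conformational.shape == self.nonbond.shape == self.total.shape):
            raise ValidationError("derived term arrays must share one shape")
        if not np.allclose(
            self.total, self.conformational + self.nonbond, rtol=0.0, atol=1e-9
        ):
            raise ValidationError("total != conformational + nonbond beyond 1e-9")


def derive_terms(traj: EnergyTrajectory) -> DerivedTerms:
    """Compute the composite energy terms for every residue.

    conformational = bond + angle + dihedral
    nonbond        = electrostatic + vdw
    total          = conformational + nonbond
    """
    c = traj.components
    conf = c["bond"] + c["angle"] + c["dihedral"]
    nonb = c["electrostatic"] + c["vdw"]
    return DerivedTerms(conformational=conf, nonbond=nonb, total=conf + nonb)


def read_energy_table(path, units_in: str = "kJ") -> EnergyTrajectory:
    """Read an energy-decomposition TSV into an :class:`EnergyTrajectory`.

    The dialect is one header line ``snapshot  residue  bond  angle
    dihedral  electrostatic  vdw`` (tab-separated) followed by one data
    row per (snapshot, residue) cell; ``#`` starts a comment.  Rows may
    arrive in any order.  ``units_in`` is ``"kJ"`` (default) or
    ``"kcal"``; kcal inputs are converted with the factor 4.184.

    Raises
    ------
    FormatError
        Missing column (named in the message).
    DuplicateRecordError
        A (residue, snapshot) pair appears twice.
    ValidationError
        Non-finite value (with row number) or ragged series.
    """
    if units_in not in ("kJ", "kcal"):
        raise ValueError(f"units_in must be 'kJ' or 'kcal', got {units_in!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    df = df[list(_TABLE_COLUMNS)]

    bad = ~np.isfinite(df[list(COMPONENT_TERMS)].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-finite energy value at data row {row}")

    dup = df.duplicated(subset=["snapshot", "residue"])
    if dup.any():
        snap, res = df.loc[dup.idxmax(), ["snapshot", "residue"]]
        raise DuplicateRecordError(f"duplicate record for residue {res}, snapshot {snap}")

    df = df.sort_values(["residue", "snapshot"], kind="stable")
    residues = np.sort(df["residue"].unique())
    snapshots = np.sort(df["snapshot"].unique())
    n_res, n_snap = residues.size, snapshots.size
    if len(df) != n_res * n_snap:
        raise ValidationError(
            f"ragged series: expected {n_res * n_snap} rows "
            f"({n_res} residues x {n_snap} snapshots), found {len(df)}"
        )
    if not np.array_equal(np.sort(df["snapshot"].unique()), np.arange(n_snap)):
        raise ValidationError("snapshot indices must be 0-based and contiguous")

    scale = KCAL_TO_KJ if units_in == "kcal" else 1.0
    components = {
        term: df[term].to_numpy(dtype=float).reshape(n_res, n_snap) * scale
        for term in COMPONENT_TERMS
    }
    return EnergyTrajectory(residue_ids=residues, components=components)


def write_energy_table(traj: EnergyTrajectory, path) -> None:
    """Write an :class:`EnergyTrajectory` in the long-format TSV dialect.

    Values are written with ``repr``-exact float formatting so that
    ``read_energy_table(write_energy_table(t))`` is the identity on
    values to well below 1e-9 kJ/mol.
    """
    n_res, n_snap = traj.n_residues, traj.n_snapshots
    snap_idx = np.tile(np.arange(n_snap), n_res)
    res_idx = np.repeat(traj.residue_ids, n_snap)
    data = {"snapshot": snap_idx, "residue": res_idx}
    for term in COMPONENT_TERMS:
        data[term] = traj.components[term].reshape(-1)
    df = pd.DataFrame(data)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
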