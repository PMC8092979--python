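"""Energy-change bookkeeping and energy-term correlation analysis.

Covers the scalar statistics of the pipeline: start-vs-end energy-change
records per residue, component-sum totals, the threshold filters used to
flag energetically responsive residues, the Pearson product-moment
coefficient, and the 7x7 correlation matrix over energy terms (five
components plus the conformational and non-bond composites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_io import COMPONENT_TERMS, EnergyTrajectory, derive_terms
from .errors import ValidationError, ZeroVarianceError

#: Term order of the energy-term correlation matrix.
TERM_MATRIX_LABELS: tuple[str, ...] = (
    "bond",
    "angle",
    "dihedral",
    "conformational",
    "electrostatic",
    "vdw",
    "nonbond",
)

#: Agreement tolerance when validating totals printed at 3 decimal
#: places: each of the five addends carries up to 0.0005 rounding error.
PRINTED_TOTAL_TOLERANCE = 0.0015


def pearson(a, b) -> float:
    """Pearson product-moment correlation coefficient of two series.

    r = sum((a - <a>)(b - <b>)) / sqrt(sum((a - <a>)^2) sum((b - <b>)^2))

    Raises
    ------
    ZeroVarianceError
        If either series is constant, so an undefined coefficient can
        never masquerade as a numeric value.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(da @ da)
    ssb = float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise ZeroVarianceError("correlation undefined: constant input series")
    r = float(da @ db) / np.sqrt(ssa * ssb)
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of correlation coefficients with undefined flags.

    ``values[i, j]`` is NaN exactly where ``defined[i, j]`` is False
    (zero-variance inputs); undefined entries are flagged, never coerced
    to 0.  Labels may be energy-term names or residue ids.
    """

    labels: tuple
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        defined = np.asarray(self.defined, dtype=bool)
        k = len(self.labels)
        if values.shape != (k, k) or defined.shape != (k, k):
            raise ValidationError("matrix shape must be (len(labels), len(labels))")
        if not np.allclose(
            np.nan_to_num(values), np.nan_to_num(values).T, atol=1e-12
        ) or not np.array_equal(defined, defined.T):
            raise ValidationError("correlation matrix must be symmetric")
        fin = values[defined]
        if not np.isfinite(fin).all() or (np.abs(fin) > 1 + 1e-12).any():
            raise ValidationError("defined entries must be finite and within [-1, 1]")
        if np.isfinite(values[~defined]).any():
            raise ValidationError("undefined entries must be stored as NaN")
        diag_def = np.diag(defined)
        if not np.allclose(np.diag(values)[diag_def], 1.0, atol=1e-12):
            raise ValidationError("defined diagonal entries must equal 1")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "defined", defined)

    def index_of(self, label) -> int:
        return self.labels.index(label)

    def get(self, a, b) -> float:
        """Coefficient for a pair of labels; raises if undefined."""
        i, j = self.index_of(a), self.index_of(b)
        if not self.defined[i, j]:
            raise ZeroVarianceError(f"correlation ({a}, {b}) is undefined")
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())


def correlation_matrix_from_series(labels, series: list[np.ndarray]) -> CorrelationMatrix:
    """Build a flagged correlation matrix from equal-length 1-D series."""
    k = len(labels)
    mat = np.column_stack([np.asarray(s, dtype=float).ravel() for s in series])
    sd = mat.std(axis=0)
    ok = sd > 0
    values = np.full((k, k), np.nan)
    defined = np.zeros((k, k), dtype=bool)
    if ok.any():
        sub = np.corrcoef(mat[:, ok], rowvar=False)
        sub = np.clip(np.atleast_2d(sub), -1.0, 1.0)
        np.fill_diagonal(sub, 1.0)
        idx = np.flatnonzero(ok)
        values[np.ix_(idx, idx)] = sub
        defined[np.ix_(idx, idx)] = True
    return CorrelationMatrix(labels=tuple(labels), values=values, defined=defined)


@dataclass(frozen=True)
class EnergyChangeRecord:
    """Start-vs-end change of the five components for one residue (kJ/mol)."""

    residue_id: int
    d_bond: float
    d_angle: float
    d_dihedral: float
    d_electrostatic: float
    d_vdw: float
    d_total: float

    def __post_init__(self) -> None:
        if abs(self.d_total - self.component_sum()) > 1e-9:
            raise ValidationError(
                f"residue {self.residue_id}: d_total differs from component sum "
                "by more than 1e-9 kJ/mol"
            )

    def component_sum(self) -> float:
        return (
            self.d_bond
            + self.d_angle
            + self.d_dihedral
            + self.d_electrostatic
            + self.d_vdw
        )

    @classmethod
    def from_components(
        cls, residue_id: int, d_bond: float, d_angle: float, d_dihedral: float,
        d_electrostatic: float, d_vdw: float,
    ) -> "EnergyChangeRecord":
        total = d_bond + d_angle + d_dihedral + d_electrostatic + d_vdw
        return cls(residue_id, d_bond, d_angle, d_dihedral, d_electrostatic, d_vdw, total)

    def change(self, term: str) -> float:
        if term == "total":
            return self.d_total
        if term in COMPONENT_TERMS:
            return getattr(self, f"d_{term}")
        raise KeyError(f"unknown energy term {term!r}")


def component_sum(components) -> float:
    """Total energy change from the five component changes.

    Accepts a 5-sequence ``(bond, angle, dihedral, electrostatic, vdw)``.
    When validating totals printed at 3 dp, agreement within
    :data:`PRINTED_TOTAL_TOLERANCE` (0.0015 kJ/mol) is exact agreement.
    """
    components = tuple(float(x) for x in components)
    if len(components) != 5:
        raise ValueError(f"expected 5 components, got {len(components)}")
    return float(sum(components))


def energy_change(traj: EnergyTrajectory, window: int = 10) -> list[EnergyChangeRecord]:
    """Per-residue energy change between the start and end of a trajectory.

    For each component, the change is the mean over the last ``window``
    snapshots minus the mean over the first ``window`` snapshots.
    ``window=1`` reproduces the literal final-minus-first-frame reading;
    the default of 10 snapshots suppresses single-frame noise.
    """
    n = traj.n_snapshots
    if not 1 <= window <= n // 2:
        raise ValueError(f"window must be in [1, {n // 2}] for {n} snapshots, got {window}")
    deltas = {
        term: traj.components[term][:, n - window:].mean(axis=1)
        - traj.components[term][:, :window].mean(axis=1)
        for term in COMPONENT_TERMS
    }
    return [
        EnergyChangeRecord.from_components(
            int(rid),
            float(deltas["bond"][i]),
            float(deltas["angle"][i]),
            float(deltas["dihedral"][i]),
            float(deltas["electrostatic"][i]),
            float(deltas["vdw"][i]),
        )
        for i, rid in enumerate(traj.residue_ids)
    ]


def filter_by_change(
    records,
    term: str,
    threshold: float,
    mode: str = "abs_gt",
) -> list[int]:
    """Residues whose energy change strictly exceeds a threshold.

    ``mode="abs_gt"`` (default) compares |change| > threshold — the
    reported responsive-residue lists include negative changes;
    ``mode="signed_gt"`` compares the signed change.
    """
    if mode not in ("abs_gt", "signed_gt"):
        raise ValueError(f"mode must be 'abs_gt' or 'signed_gt', got {mode!r}")
    out = []
    for rec in records:
        value = rec.change(term)
        stat = abs(value) if mode == "abs_gt" else value
        if stat > threshold:
            out.append(rec.residue_id)
    return sorted(out)


def term_correlation_matrix(
    traj: EnergyTrajectory, mode: str = "pooled2d"
) -> CorrelationMatrix:
    """Correlation matrix over the 7 energy terms.

    ``pooled2d`` (default): for each pair of terms the full
    residue-by-snapshot matrices are flattened and correlated over all
    cells — the 2-D array-correlation reading.  ``system_sum``: each
    term is first summed over residues per snapshot and the two
    length-N system series are correlated.

    Zero-variance terms yield flagged undefined rows/columns.
    """
    if mode not in ("pooled2d", "system_sum"):
        raise ValueError(f"mode must be 'pooled2d' or 'system_sum', got {mode!r}")
    derived = derive_terms(traj)
    arrays = {
        "bond": traj.components["bond"],
        "angle": traj.components["angle"],
        "dihedral": traj.components["dihedral"],
        "conformational": derived.conformational,
        "electrostatic": traj.components["electrostatic"],
        "vdw": traj.components["vdw"],
        "nonbond": derived.nonbond,
    }
    if mode == "pooled2d":
        series = [arrays[t].ravel() for t in TERM_MATRIX_LABELS]
    else:
        series = [arrays[t].sum(axis=0) for t in TERM_MATRIX_LABELS]
    return correlation_matrix_from_series(TERM_MATRIX_LABELS, series)


def write_change_report(records, path) -> None:
    """Write energy-change records as a TSV with 3-dp fixed formatting."""
    with open(path, "w") as fh:
        fh.write("residue\tbond\tangle\tdihedral\telectrostatic\tvdw\ttotal\n")
        for rec in records:
            fh.write(
                f"{rec.residue_id}\t{rec.d_bond:.3f}\t{rec.d_angle:.3f}\t"
                f"{rec.d_dihedral:.3f}\t{rec.d_electrostatic:.3f}\t"
                f"{rec.d_vdw:.3f}\t{rec.d_total:.3f}\n"
            )


def write_correlation_matrix(matrix: CorrelationMatrix, path) -> None:
    """Write a labelled square correlation matrix as TSV (NaN = undefined)."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(str(l) for l in matrix.labels) + "\n")
        for i, label in enumerate(matrix.labels):
            row = "\t".join(
                f"{matrix.values[i, j]:.4f}" if matrix.defined[i, j] else "NA"
                for j in range(len(matrix.labels))
            )
            fh.write(f"{label}\t{row}\n")
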