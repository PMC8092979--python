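"""C-score pathway inference between binding-site endpoints.

A candidate energy-transduction pathway between a source residue A (in
the regulatory site) and a sink residue B (in the catalytic site) is
scored residue by residue with the C value

    C(X) = Cor(A, X) * Cor(X, B),

the product of residue X's energy correlations with both endpoints.
Only residues correlated with *both* ends score highly; membership uses
a strict threshold (default C > 0.3).  With 3 sources and 4 sinks this
yields a 12-pathway grid; residues shared across many pathways form the
conserved transduction backbone, characterised here by their mean
evolutionary conservation score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy_stats import CorrelationMatrix
from .errors import ValidationError, ZeroVarianceError

logger = logging.getLogger(__name__)

DEFAULT_C_THRESHOLD = 0.3


@dataclass(frozen=True)
class PathwaySpec:
    """A (source, sink) endpoint pair; both must differ."""

    source: int
    sink: int

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValidationError("pathway source and sink must differ")


@dataclass(frozen=True)
class PathwayResult:
    """C scores for one pathway and the above-threshold member set.

    ``c_scores`` maps every scored residue (all residues except the
    endpoints whose factor correlations are defined) to its C value;
    ``members`` lists residues with C strictly above ``threshold``,
    sorted by descending C.  ``n_undefined`` counts residues skipped
    because a factor correlation was undefined.
    """

    spec: PathwaySpec
    c_scores: dict[int, float]
    threshold: float
    n_undefined: int = 0
    members: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        members = sorted(
            (r for r, c in self.c_scores.items() if c > self.threshold),
            key=lambda r: (-self.c_scores[r], r),
        )
        object.__setattr__(self, "members", tuple(members))


@dataclass(frozen=True)
class ConservationTable:
    """Per-residue evolutionary rate scores, lower = more conserved.

    Follows the ConSurf/Rate4Site normalised-score convention: scores
    are protein-normalised and negative values mark conserved positions.
    """

    scores: dict[int, float]

    def __post_init__(self) -> None:
        clean = {}
        for rid, s in self.scores.items():
            s = float(s)
            if not np.isfinite(s):
                raise ValidationError(f"non-finite conservation score for residue {rid}")
            clean[int(rid)] = s
        if len(clean) != len(self.scores):
            raise ValidationError("duplicate residue ids in conservation table")
        object.__setattr__(self, "scores", clean)

    def __contains__(self, rid: int) -> bool:
        return int(rid) in self.scores

    def __getitem__(self, rid: int) -> float:
        return self.scores[int(rid)]


def read_conservation_table(path, polarity: str | None = None) -> ConservationTable:
    """Read a two-column TSV (``residue<TAB>score``, ``#`` comments).

    ``polarity`` must be stated explicitly: ``"lower_is_conserved"``
    (the ConSurf/Rate4Site convention, stored as-is) or
    ``"higher_is_conserved"`` (scores are negated on load).  A table of
    unknown polarity is refused rather than guessed at.
    """
    if polarity is None:
        raise ValidationError(
            "conservation score polarity must be stated: "
            "'lower_is_conserved' or 'higher_is_conserved'"
        )
    if polarity not in ("lower_is_conserved", "higher_is_conserved"):
        raise ValidationError(f"unknown conservation polarity {polarity!r}")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["residue", "score"])
    if df["residue"].duplicated().any():
        dup = int(df.loc[df["residue"].duplicated(), "residue"].iloc[0])
        raise ValidationError(f"duplicate conservation entry for residue {dup}")
    sign = -1.0 if polarity == "higher_is_conserved" else 1.0
    return ConservationTable(
        scores={int(r): sign * float(s) for r, s in zip(df["residue"], df["score"])}
    )


def c_score(matrix: CorrelationMatrix, a: int, x: int, b: int) -> float:
    """C value of residue ``x`` for the pathway ``a`` -> ``b``.

    The signed product Cor(a, x) * Cor(x, b), in [-1, 1].  Raises
    :class:`ZeroVarianceError` when either factor is undefined.
    """
    if len({a, x, b}) != 3:
        raise ValidationError("a, x, b must be three distinct residues")
    return matrix.get(a, x) * matrix.get(x, b)


def pathway_profile(
    matrix: CorrelationMatrix,
    spec: PathwaySpec,
    threshold: float = DEFAULT_C_THRESHOLD,
    use_abs: bool = False,
) -> PathwayResult:
    """Score every residue between one (source, sink) pair.

    Endpoints are excluded from scoring.  ``use_abs`` thresholds |C|
    instead of signed C (the default follows the signed reading).
    Residues with an undefined factor correlation are excluded and
    counted.
    """
    a, b = spec.source, spec.sink
    scores: dict[int, float] = {}
    n_undef = 0
    for x in matrix.labels:
        if x == a or x == b:
            continue
        try:
            c = c_score(matrix, a, x, b)
        except ZeroVarianceError:
            n_undef += 1
            continue
        scores[int(x)] = abs(c) if use_abs else c
    if n_undef:
        logger.warning(
            "pathway %d->%d: %d residues skipped (undefined correlations)",
            a, b, n_undef,
        )
    return PathwayResult(spec=spec, c_scores=scores, threshold=threshold, n_undefined=n_undef)


def all_pathways(
    matrix: CorrelationMatrix,
    sources,
    sinks,
    threshold: float = DEFAULT_C_THRESHOLD,
    use_abs: bool = False,
) -> list[PathwayResult]:
    """One :class:`PathwayResult` per (source, sink) pair, sources-major."""
    sources = [int(s) for s in sources]
    sinks = [int(s) for s in sinks]
    if not sources or not sinks:
        raise ValidationError("sources and sinks must be non-empty")
    if set(sources) & set(sinks):
        raise ValidationError("sources and sinks must be disjoint")
    return [
        pathway_profile(matrix, PathwaySpec(a, b), threshold=threshold, use_abs=use_abs)
        for a in sources
        for b in sinks
    ]


def shared_residues(results, min_pathways: int) -> list[int]:
    """Residues that are members of at least ``min_pathways`` pathways."""
    results = list(results)
    if not 1 <= min_pathways <= len(results):
        raise ValueError(
            f"min_pathways must be in [1, {len(results)}], got {min_pathways}"
        )
    counts: dict[int, int] = {}
    for res in results:
        for rid in res.members:
            counts[rid] = counts.get(rid, 0) + 1
    return sorted(r for r, n in counts.items() if n >= min_pathways)


def mean_conservation(residues, table: ConservationTable) -> float:
    """Arithmetic mean conservation score of a residue set.

    Raises on an empty set and on residues missing from the table (all
    missing ids are listed in the message).
    """
    residues = [int(r) for r in residues]
    if not residues:
        raise ValidationError("mean conservation of an empty residue set is undefined")
    missing = sorted(r for r in residues if r not in table)
    if missing:
        raise ValidationError(f"residues missing from conservation table: {missing}")
    return float(np.mean([table[r] for r in residues]))


def write_pathway_report(results, path) -> None:
    """TSV report: source, sink, residue, c_score, member flag."""
    with open(path, "w") as fh:
        fh.write("source\tsink\tresidue\tc_score\tmember\n")
        for res in results:
            member_set = set(res.members)
            for rid in sorted(res.c_scores):
                fh.write(
                    f"{res.spec.source}\t{res.spec.sink}\t{rid}\t"
                    f"{res.c_scores[rid]:.4f}\t{int(rid in member_set)}\n"
                )
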