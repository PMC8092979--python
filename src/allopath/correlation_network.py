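"""Residue-residue correlation networks for a chosen energy term.

Residues are nodes; an edge connects two residues whose energy-series
correlation satisfies a threshold predicate (for electrostatic energy,
the reported analysis uses > 0.5 for the coupled group and < -0.5 for
the compensating group).  Clusters are the connected components of the
thresholded graph: a negatively-thresholded group cannot be pairwise
transitive, so component membership is the operative notion of
"clustered together".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .energy_io import EnergyTrajectory
from .energy_stats import CorrelationMatrix
from .structure_metrics import write_edge_list, write_graphml  # re-export  # noqa: F401

logger = logging.getLogger(__name__)

_RULES = ("ge", "le", "abs_ge")


@dataclass(frozen=True)
class ResidueCorrelationNetwork:
    """Undirected residue graph with per-edge correlation coefficients.

    ``rule`` records the admitting predicate (e.g. ``"ge 0.5"``); every
    edge's ``coefficient`` attribute satisfies it.
    """

    graph: nx.Graph
    rule: str

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return sorted(
            (min(u, v), max(u, v), d["coefficient"])
            for u, v, d in self.graph.edges(data=True)
        )


def residue_pair_correlation(
    traj: EnergyTrajectory, term: str = "electrostatic"
) -> CorrelationMatrix:
    """R x R correlation matrix of one energy term across residues.

    Entry (s, t) is the Pearson coefficient between the term series of
    residues s and t over all snapshots.  Zero-variance residues yield
    flagged undefined rows/columns (counted in the log), never zeros.
    """
    series = traj.term(term)  # (R, N)
    sd = series.std(axis=1)
    ok = sd > 0
    r = traj.n_residues
    values = np.full((r, r), np.nan)
    defined = np.zeros((r, r), dtype=bool)
    if ok.any():
        sub = np.clip(np.atleast_2d(np.corrcoef(series[ok])), -1.0, 1.0)
        np.fill_diagonal(sub, 1.0)
        idx = np.flatnonzero(ok)
        values[np.ix_(idx, idx)] = sub
        defined[np.ix_(idx, idx)] = True
    n_flat = int((~ok).sum())
    if n_flat:
        logger.warning(
            "%d residues have zero %s variance; their correlations are undefined",
            n_flat, term,
        )
    labels = tuple(int(x) for x in traj.residue_ids)
    return CorrelationMatrix(labels=labels, values=values, defined=defined)


def threshold_network(
    matrix: CorrelationMatrix, rule: str, c: float
) -> ResidueCorrelationNetwork:
    """Admit residue pairs whose coefficient passes a strict threshold.

    ``rule`` is one of ``"ge"`` (coefficient > c), ``"le"``
    (coefficient < c, used with negative c for anticorrelated groups) or
    ``"abs_ge"`` (|coefficient| > c).  All comparisons are strict, and
    undefined entries never form edges.
    """
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}, got {rule!r}")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.labels)
    k = len(matrix.labels)
    for i in range(k):
        for j in range(i + 1, k):
            if not matrix.defined[i, j]:
                continue
            v = matrix.values[i, j]
            if (
                (rule == "ge" and v > c)
                or (rule == "le" and v < c)
                or (rule == "abs_ge" and abs(v) > c)
            ):
                graph.add_edge(matrix.labels[i], matrix.labels[j], coefficient=float(v))
    return ResidueCorrelationNetwork(graph=graph, rule=f"{rule} {c:g}")


def connected_clusters(net: ResidueCorrelationNetwork) -> list[list[int]]:
    """Connected components of the thresholded graph, largest first.

    Singletons (residues with no admitted edge) are omitted.  Each
    cluster is sorted by residue id; ties in size break on the smallest
    member for a deterministic ordering.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph) if len(c) > 1]
    return sorted(comps, key=lambda c: (-len(c), c))


def write_cluster_report(clusters, path) -> None:
    """One line per cluster, comma-separated residue ids."""
    with open(path, "w") as fh:
        for cluster in clusters:
            fh.write(",".join(str(r) for r in cluster) + "\n")
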