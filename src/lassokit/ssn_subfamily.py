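"""Sequence-similarity networks over precursor/core peptides.

Nodes are peptides, edges are pairwise global-alignment percent identities
at or above a threshold, and connected components approximate subfamilies.
The edge metric is end-gap-free global alignment (BLOSUM62, affine gaps,
same scoring scheme as the mining module); identity is identical columns
over aligned columns.  Components get deterministic labels — the
lexicographically smallest member id — so the graph is invariant to input
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SimilarityEdge",
    "SubfamilyGraph",
    "pairwise_identity",
    "build_ssn",
    "read_peptides_fasta",
    "write_graphml",
]

DEFAULT_PRECURSOR_THRESHOLD = 40.0
DEFAULT_CORE_THRESHOLD = 50.0


@dataclass(frozen=True)
class SimilarityEdge:
    nodes: tuple[str, str]  # ordered pair (lexicographic)
    percent_identity: float
    alignment_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


@dataclass(frozen=True)
class SubfamilyGraph:
    graph: nx.Graph
    threshold: float
    components: tuple[tuple[str, ...], ...]  # sorted member tuples
    labels: dict[str, str]  # node id -> component label (smallest member id)

    @property
    def n_components(self) -> int:
        return len(self.components)


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    # end-gap free: terminal overhangs are not penalized
    a.end_gap_score = 0.0
    return a


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and aligned length under end-gap-free global alignment.

    Identity counts identical columns over aligned columns (matches,
    mismatches and internal gaps; terminal overhangs excluded).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    if columns == 0:
        return 0.0, 0
    return 100.0 * counts.identities / columns, columns


def build_ssn(
    peptides: list[tuple[str, str]],
    threshold: float = DEFAULT_PRECURSOR_THRESHOLD,
) -> SubfamilyGraph:
    """All-vs-all identity network; components are subfamily calls.

    ``peptides`` is a list of (id, sequence).  Every pair at or above
    ``threshold`` percent identity contributes an edge; singleton components
    are kept.
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    ids = [pid for pid, _ in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peptide ids")
    g = nx.Graph(threshold=threshold)
    for pid, seq in sorted(peptides):
        g.add_node(pid, sequence=seq)
    ordered = sorted(peptides)
    for i, (id_a, seq_a) in enumerate(ordered):
        for id_b, seq_b in ordered[i + 1 :]:
            identity, length = pairwise_identity(seq_a, seq_b)
            if identity >= threshold:
                g.add_edge(
                    id_a, id_b, percent_identity=identity, alignment_length=length
                )
    components = tuple(
        tuple(sorted(c)) for c in sorted(nx.connected_components(g), key=min)
    )
    labels = {node: comp[0] for comp in components for node in comp}
    return SubfamilyGraph(g, threshold, components, labels)


def read_peptides_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_graphml(ssn: SubfamilyGraph, path: str | Path) -> None:
    """Write the network as GraphML, with component labels as node attributes."""
    g = ssn.graph.copy()
    for node, label in ssn.labels.items():
        g.nodes[node]["subfamily"] = label
    nx.write_graphml(g, str(path))
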