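"""The reverse-complement graph of the standard genetic code.

Pairing every codon with its reverse complement induces a graph on amino
acids: for each of the 32 unordered codon/reverse-complement-codon pairs, an
edge joins the amino acid encoded by one member to the amino acid encoded by
the other.  No codon is its own reverse complement (the middle base would
have to be self-complementary), so there are exactly 32 edges.  Stop codons
are kept as three distinct nodes (TAA, TAG, TGA) — merging them would
spuriously bridge otherwise separate clusters through a shared stop node.

Under the standard code the graph splits into three connected components:
8 amino acids + 1 stop codon, 5 amino acids + 2 stop codons, and 7 amino
acids with no stop codon.  Each component contains at least one aromatic,
one basic, one polar and one nonpolar residue (classification below).
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from Bio.Data import CodonTable

from .seqsym import reverse_complement

__all__ = ["CodeGraph", "ComponentSummary", "build_code_graph",
           "component_summary", "CHEMICAL_CLASSES", "standard_code"]

#: amino-acid chemical classification used for the coverage summary
#: (overlaps allowed: H is aromatic and basic, F/W/Y aromatic and nonpolar).
CHEMICAL_CLASSES: dict[str, frozenset[str]] = {
    "aromatic": frozenset("FWYH"),
    "basic": frozenset("KRH"),
    "polar": frozenset("STNQCYDE"),
    "nonpolar": frozenset("AVLIPMGFW"),
}

#: component shape labels by amino-acid count, following the conventional
#: drawn geometry of this graph (labels are annotations, not topology).
SHAPE_LABELS = {8: "pentagram", 5: "triangle", 7: "rhombus"}


def standard_code() -> dict[str, str]:
    """The standard genetic code as codon -> amino-acid letter ('*' stop)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def _node(codon: str, code: dict[str, str]) -> str:
    aa = code[codon]
    return f"stop:{codon}" if aa == "*" else aa


@dataclass(frozen=True)
class CodeGraph:
    """32-edge multigraph on 20 amino acids + 3 stop-codon nodes; each edge
    is annotated with its codon pair."""

    graph: nx.MultiGraph

    @property
    def edges(self) -> list[tuple[str, str, tuple[str, str]]]:
        return [(u, v, data["codons"])
                for u, v, data in self.graph.edges(data=True)]


def build_code_graph(translation_table: dict[str, str] | None = None
                     ) -> CodeGraph:
    """Build the codon <-> reverse-complement-codon graph.

    ``translation_table`` maps all 64 codons to amino-acid letters ('*' for
    stop); defaults to the standard code.  Unordered codon pairs are
    deduplicated, giving exactly 32 edges.
    """
    code = translation_table or standard_code()
    codons = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
    missing = [c for c in codons if c not in code]
    if missing:
        raise ValueError(f"translation table missing codons: {missing[:4]}...")
    graph = nx.MultiGraph()
    for codon in codons:
        graph.add_node(_node(codon, code))
    for codon in codons:
        rc = reverse_complement(codon)
        if codon < rc:
            graph.add_edge(_node(codon, code), _node(rc, code),
                           codons=(codon, rc))
    return CodeGraph(graph)


@dataclass(frozen=True)
class ComponentSummary:
    """One connected component: members, counts and chemical coverage."""

    component_id: int
    shape_label: str
    amino_acids: tuple[str, ...]
    stop_codons: tuple[str, ...]
    chemical_coverage: dict[str, bool]

    @property
    def n_amino_acids(self) -> int:
        return len(self.amino_acids)


def component_summary(code_graph: CodeGraph) -> list[ComponentSummary]:
    """Connected components ordered by descending amino-acid count."""
    components = []
    for nodes in nx.connected_components(code_graph.graph):
        aas = tuple(sorted(n for n in nodes if not n.startswith("stop:")))
        stops = tuple(sorted(n.split(":", 1)[1] for n in nodes
                             if n.startswith("stop:")))
        components.append((aas, stops))
    components.sort(key=lambda item: (-len(item[0]), item[0]))
    out = []
    for i, (aas, stops) in enumerate(components, start=1):
        coverage = {name: bool(set(aas) & members)
                    for name, members in CHEMICAL_CLASSES.items()}
        out.append(ComponentSummary(
            i, SHAPE_LABELS.get(len(aas), f"{len(aas)}-node"),
            aas, stops, coverage))
    return out
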