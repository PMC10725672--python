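"""The reverse-complement graph of the standard genetic code.

Pairs each of the 64 codons with its reverse complement (32 edges) and
joins the encoded amino acids; stop codons stay as three separate nodes.
The graph decomposes into three components — 8, 5 and 7 amino acids with
1, 2 and 0 stop codons — and every component carries at least one aromatic,
basic, polar and nonpolar residue.
"""
from csprkit import build_code_graph, component_summary

graph = build_code_graph()
print(f"{len(graph.edges)} codon/reverse-complement edges, e.g.:")
for u, v, (c, rc) in graph.edges[:4]:
    print(f"  {c} <-> {rc}   joins {u} and {v}")

print("\nconnected components:")
for s in component_summary(graph):
    stops = ", ".join(s.stop_codons) or "none"
    classes = ", ".join(k for k, v in s.chemical_coverage.items() if v)
    print(f"  {s.shape_label:9s} {s.n_amino_acids} amino acids "
          f"({''.join(s.amino_acids)}), stops: {stops}; covers {classes}")
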