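"""Classify aligned residue pairs by codon-level point mutations.

Positions are homologous (R, same residue), transition-type semihomologous
(#), transversion-type semihomologous ($), or separated by two or more point
mutations (-). The split between # and $ reflects how conservative the
underlying nucleotide change was.
"""

import geneimage as g

table = g.CodonTable.from_ncbi(1)  # the universal genetic code
for a, b in [("L", "L"), ("D", "N"), ("D", "E"), ("W", "C"), ("F", "K"), ("L", "F")]:
    dist = g.min_point_mutations(a, b, table)
    cls = g.classify_pair(a, b, table)
    print(f"{a} vs {b}: min point mutations = {dist}, class = {cls}")

seq_a = "MKLVWADHIRG"
seq_b = "MKLVWANHIRG"  # D -> N at position 7: a first-position transition
counts = g.count_positions(seq_a, seq_b, table)
print(f"\n{seq_a}\n{seq_b}\ncounts {counts.as_bracket()}  "
      "(R / # / $ / -; they always sum to the aligned length)")

# The vertebrate-mitochondrial code (table 2) can shift the #/$ split but
# never the R count:
counts2 = g.count_positions(seq_a, seq_b, g.CodonTable.from_ncbi(2))
print(f"same pair under the mitochondrial code: {counts2.as_bracket()}")
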