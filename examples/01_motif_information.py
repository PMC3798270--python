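"""Build an information weight matrix and score individual sites.

Constructs a 10-bp direct-repeat model from a small aligned half-site set,
reports its total information (the area of the sequence logo, corrected
for sample size), scores individual sequences in bits, and renders a
sequence walker.  A site's individual information Ri is the sum of the
positional weights Riw(b, l) = 2 + log2 f(b, l) - e(n); sites a protein
binds score well above 0 bits, and the alignment's mean Ri equals the
model's total information.
"""

from regulonscan import (
    SiteAlignment,
    build_matrix,
    individual_information,
    sequence_walker_report,
    total_information,
)

alignment = SiteAlignment(
    (
        "TGTTAATTAA", "TGTTAATTAA", "TGTTAATTAA", "TGTTAATTAA",
        "TGTTAATAAA", "TGTTAACTAA", "TGCTAATTAA", "AGTTAATTAA",
    )
)
matrix = build_matrix(alignment, pseudocount=0.25)

bits, sd = total_information(matrix)
print(f"total information: {bits:.2f} +- {sd:.2f} bits "
      f"(n = {matrix.n} sites, e(n) = {matrix.e_n:.3f} bits/column)")
print(f"consensus: {matrix.consensus} "
      f"(max attainable Ri = {matrix.max_score:.2f} bits)")

for seq in ("TGTTAATTAA", "TGTTAACTAA", "ACGGCCGGCA"):
    ri = individual_information(matrix, seq)
    print(f"Ri({seq}) = {ri:6.2f} bits")

print()
print(sequence_walker_report(matrix, "TGTTAACTAA"))
# The walker shows each base's bit contribution: the C at position 6
# appears with a reduced (or negative) letter, and the contributions sum
# to the sequence's Ri.
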