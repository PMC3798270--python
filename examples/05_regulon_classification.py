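"""Cross binding regions with expression into a direct/indirect regulon.

Builds a toy operon map, plants expression effects (up in the deletion
strain = repressed by the regulator), places binding regions upstream of
the direct targets only, and classifies every operon.  Directly regulated
operons are those both differentially expressed and bound; differentially
expressed operons without binding fall to the indirect regulon unless a
high-scoring site is still found upstream by the motif scan.
"""

from regulonscan import (
    OperonRecord,
    PeakRegion,
    assign_regions_to_operons,
    call_de_operons,
    classify_regulon,
)
from regulonscan.simulate import simulate_expression

operons = [
    OperonRecord(f"op{i}", (f"g{i}a", f"g{i}b"), "+", 2_000 + 3_000 * i,
                 chrom="chr")
    for i in range(10)
]
# ground truth: op0/op1 directly repressed, op2 directly activated,
# op3/op4 indirect, the rest unregulated
regulated = {"op0": +1, "op1": +1, "op2": -1, "op3": +1, "op4": -1}
direct = {"op0", "op1", "op2"}

expression, _ = simulate_expression(operons, regulated, seed=3)
verdicts, _ = call_de_operons(expression, operons,
                              fc_threshold=2.0, p_threshold=0.05)

regions = [
    PeakRegion("chr", op.anchor - 220, op.anchor - 60,
               op.anchor - 140, 2.5)
    for op in operons if op.operon_id in direct
]
region_map = assign_regions_to_operons(regions, operons, max_upstream_bp=500)

assignments, venn = classify_regulon(verdicts, region_map)
for a in assignments:
    if a.classification != "none":
        print(f"{a.operon_id}: DE={a.de_verdict:4s} -> {a.classification}")
print(f"\nVenn: {venn['direct']} direct "
      f"({venn['direct_repressed']} repressed / "
      f"{venn['direct_activated']} activated), "
      f"{venn['indirect']} indirect, {venn['bound_not_de']} bound-not-DE")
# Expect op0/op1 direct-repressed, op2 direct-activated, op3/op4 indirect;
# Venn counts 3 direct (2 repressed, 1 activated), 2 indirect.
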