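"""The two splicing pathways of a group I intron on a circular genome.

The giant intron spans >90% of the genome, so its natural primary transcript
is short and *permuted*: [intron 3' tail][exon 2][linker][exon 1][intron 5'
head].  The same two-step chemistry that cis-splices a conventional
precursor then ligates exon 1 to exon 2 across the transcript ends,
producing a covalently closed circular RNA — back-splicing."""

from mitosplice import (
    SimConfig,
    back_splice,
    build_permuted_precursor,
    enumerate_junctions,
    generate_genome,
    to_rna,
    validate_intron,
)

genome, features, introns = generate_genome(SimConfig(seed=1))
giant = introns[0]

print(f"{giant.id}: {giant.length(genome)} nt intron on a {genome.length} nt genome "
      f"({giant.length(genome) / genome.length:.0%} of the circle)")
for check in validate_intron(genome, giant):
    if check.status != "pass":
        print(f"  [{check.status}] {check.name}: {check.message}")

perm = build_permuted_precursor(
    genome, giant,
    tx_start=(giant.three_ss - 250) % genome.length,
    tx_end=(giant.five_ss + 250) % genome.length,
)
circ, seg3, seg5 = back_splice(perm, giant, genome)
print(f"permuted precursor: {len(perm)} nt (the full conventional precursor "
      f"would be {giant.length(genome) + 500} nt)")
print(f"back-splicing -> circular intermediate {len(circ)} nt "
      f"+ intron segments {len(seg3)} and {len(seg5)} nt (incl. exo-G)")
print(f"nucleotide conservation: {len(perm)} = {len(circ)} + {len(seg3)} "
      f"+ ({len(seg5)} - 1)")

e1e2 = next(j for j in enumerate_junctions(genome, giant, k=25)
            if j.category == "E1E2_LIGATION")
print(f"exon-ligation junction (RNA): ...{to_rna(e1e2.left_flank[-5:])}|"
      f"{to_rna(e1e2.right_flank[:6])}... — identical for cis- and "
      "back-splicing, which is why junction reads alone cannot tell the "
      "pathways apart")
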