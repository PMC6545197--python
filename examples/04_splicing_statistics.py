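"""Splicing statistics from published junction-spanning read counts.

Inputs are the read counts reported for the two mushroom-coral species:
ND5 splice-site flanks 18/12 with 6 ligated-exon reads (species 1), 9/13
with 4 (species 2), and COI ligated-exon reads 86 and 59."""

from mitosplice import compare_introns, reads_per_kb, splicing_efficiency

for species, (nd5_spliced, n5, n3, coi_spliced) in (
    ("species 1 (R. yuma-like counts)", (6, 18, 12, 86)),
    ("species 2 (A. fenestrafer-like counts)", (4, 9, 13, 59)),
):
    est = splicing_efficiency(nd5_spliced, n5, n3)
    ratio = compare_introns(coi_spliced, nd5_spliced)
    print(species)
    print(f"  ND5 unspliced fraction: {est.unspliced_fraction:.3f} "
          f"(>= 0.70: most ND5 precursors retain the giant intron)")
    print(f"  COI:ND5 ligated-read ratio: {ratio.ratio:.2f} "
          f"(95% CI {ratio.ci_low:.1f}-{ratio.ci_high:.1f}; > 10: the small "
          "intron splices far more efficiently)")

table = reads_per_kb({"LSU": 1200, "COI": 480, "ND6": 7},
                     {"LSU": 2300, "COI": 1550, "ND6": 1000})
print("\nabundance normalization (reads per kb of gene):")
print(table.to_string(index=False))
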