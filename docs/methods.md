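# Methods

## Coordinate model

All genome coordinates are 0-based, half-open and modular. A feature with
`end <= start` wraps through the origin; its length is `(end - start) mod L`.
`subsequence(a, a)` returns the full rotation starting at `a` — the natural
limit of the downstream walk on a circle. GFF3 output converts to 1-based
inclusive coordinates; an origin-spanning feature is written as two lines
sharing an `ID` attribute (the part ending at the last base and the part
starting at base 1) and re-joined on read, because GFF3 has no native
circular convention. The GFF3 reader/writer is deliberately small and
local: the split-join convention is specific to this package, so a generic
GFF library would not round-trip it.

## Splicing state machine

Group I introns excise by two transesterifications: an exogenous guanosine
(exo-G) attacks the 5' splice site and stays covalently attached to the
intron 5' end; the freed exon 1 3'-OH then attacks the 3' splice site,
ligating the exons. The model represents the exo-G as a literal non-encoded
`G` prepended to every excised 5'-intron-containing product, which makes
nucleotide conservation exact and explicit:

* cis-splicing: `len(precursor) = len(mRNA) + (len(intron product) - 1)`
* back-splicing: `len(precursor) = len(circle) + len(3' segment) +
  (len(5' segment) - 1)`

Back-splicing is the same chemistry applied to a permuted precursor
`[intron 3' tail][exon2][linker][exon1][intron 5' head]`; the ligation
closes exon2–linker–exon1 into a circular RNA, and the full-length intron is
never produced as one molecule. The linker (whatever genomic features lie
between exon 2 and exon 1 — a tRNA in the emulated architecture) is part of
the circle, matching the observed circular intermediate.

Intron circularization joins the terminal residue (ω) to the intron 5' end
(offset 0, full-length circle) or to an internal donor site (truncated
circle). It requires ωG; an ωA intron raises a chemistry error unless
forced. Back-splicing is *not* blocked by ωA because exon ligation uses the
3' splice site, not the intron terminus — this asymmetry (ωA intron that
splices but forms no circles, ωG intron with both full-length and truncated
circles) is a deliberate, tested property of the model.

Exact transcript termini of the permuted precursor are not knowable from
annotation alone; they are free parameters. `build_permuted_precursor`
defaults to 75 nt outside each splice site when none are given; the
synthetic study uses 250 nt (see below). Sequences are carried in the DNA
alphabet; `to_rna` converts for presentation only.

## Junction classification

Each diagnostic junction contributes a context of k nt on each side
(default k = 25): exon ligation (E1E2), unspliced 5'SS and 3'SS flanks, one
intron-circle junction per donor offset, and the permuted-genomic
contiguity (exon 2 3' end running into the linker). A read is ASSIGNED when
its best ungapped alignment — both orientations, every offset — crosses a
junction midpoint with at least m = 10 nt on both sides at a mismatch rate
of at most 4%; ties across junctions are AMBIGUOUS, never broken
arbitrarily, and duplicate contexts collapse into entries that can only be
AMBIGUOUS. The defaults operationalize "unambiguously flanking" for ~200 nt
single-end reads; m and the rate are exposed in the API and CLI.

Batch classification first dismisses reads that share no exact seed word
with any context. The seed length (12 under the defaults) is the
worst-case guaranteed exact run inside any *valid* candidate alignment —
`min over span s in [2m, 2k] of ceil((s - e)/(e + 1))` with `e = floor(rate*s)`
— so the prefilter can produce false positives (which are then scored and
rejected) but no false negatives. Alignment is substitution-only; indels,
the dominant Ion-Torrent homopolymer error mode, are not modelled — a
deliberate limitation matched by the read simulator (below).

Back-splicing support for a long sequence (amplicon, clone) requires *both*
hallmarks in one molecule: the exon-ligation context and the
permuted-genomic contiguity. Either alone is insufficient — the ligation
junction is equally produced by cis-splicing, and the contiguity alone is
present on the linear permuted precursor. Circular molecules are matched
through their doubled sequence, which makes every test rotation-invariant.

## Statistics

An unspliced precursor presents two countable junctions (5'SS and 3'SS
flanks); a spliced molecule presents one (the ligation junction). The
default unspliced summary is therefore the mean of the two flank counts,
`spliced = n_lig / (n_lig + (n5 + n3)/2)`; the `sum` variant is provided
because the original counting arithmetic behind published retention figures
is not fully specified, and both variants support the same qualitative
conclusions on the published counts. Intervals are Wilson score intervals
(statsmodels), chosen over Wald for small counts; the interval is computed
on the rounded implied totals. Intron-to-intron comparison reports the
ratio of ligated-read counts with a log-normal interval (variance
1/a + 1/b, treating counts as Poisson). Abundance is reads per kilobase of
feature length. No hypothesis tests are reported — the quantities of
interest are descriptive fractions and ratios.

## In-silico PCR

Primer sites require the 3'-terminal 5 nt to match exactly regardless of
the mismatch allowance (polymerase extension chemistry); circular templates
are searched on the doubled sequence with deduplication mod length.
Products run from the forward primer 5' end to the reverse primer 5' end
along the template; on a linear template a divergent pair has no rightward
path and yields nothing, while on a circular template the around-the-circle
product is reported (shortest product per site pair; rolling-circle
multimers are out of scope, matching single-band gel interpretation).
Circular prediction is property-tested against a brute-force oracle that
runs the linear predictor on every rotation and deduplicates.

## Synthetic study

`generate_genome` builds a 21 kb (configurable 19.7–25 kb) circle emulating
the corallimorpharian architecture: a giant ND5 intron covering 93% of the
circle (5'SS after 717 nt of exon 1; exon 2 upstream-adjacent across a
tRNA-bearing linker), the experimentally determined ligation flanks
(exon 1 ends AGGGT, exon 2 starts CCAACT in DNA space), exon 2 ending in a
stop codon and exon 1 starting with GTG so the circular intermediate
carries stop, start and ligation site in one continuous sequence; a
1.2 kb COI intron (insertion position 884) with an internal ORF and ωG; ωA
for the giant intron; an antisense 125-aa ORF planted on the minus strand
of one intergenic region; a 90 nt direct repeat planted in another; and 10
coding genes of which 4 initiate with GTG (the ~40% GTG fraction typical of
these genomes). Base composition is 62% AT. The gene plan is fixed;
sequence between stamps is seeded-random, and everything is byte-identical
given a seed (one root seed, per-stage child streams).

Transcription units are emitted with relative molar weights spanning three
orders of magnitude (rRNA units 5–20× a typical mRNA, floor 0.02). The
giant-intron unit transcribes the permuted precursor and back-splices with
probability `giant_spliced_fraction` (default 0.30); the COI unit
cis-splices with probability 0.98, and 20% of its excised introns
circularize at donor offsets {0, 57}. Transcript pads are 250 nt — at
least one read length beyond every diagnostic junction — so that junction
coverage is free of transcript-end effects.

`simulate_reads` samples a source molecule per read proportionally to
weight × length (fragment mass), then a start position uniform over *every*
position of the molecule: reads truncate at the 3' end of linear molecules
and wrap across the closure of circular ones. This fragmentation model
makes the expected junction-spanning read count proportional to molecule
abundance and independent of molecule length, so the splicing-efficiency
estimator is unbiased; restricting starts to full-length windows would
undercount junctions near transcript ends. Errors are i.i.d. substitutions
(default 1%/base); qualities are a constant placeholder and unused
downstream. Ground truth records, per read, the source species, any
junction spanned with ≥ m nt on both sides, and the error positions.

What passing tests on this generator do **not** show about real data:
homopolymer indel errors, coverage bias, partial processing of embedded
genes, degradation intermediates, and trans-splicing are all absent; the
generator's transcript termini are idealized; and "imperfect" repeat copies
are not emulated (the repeat finder reports exact maximal repeats only,
since imperfection would require an alignment model the analysis does not
otherwise need).

## Numerical and design choices

* IGRs are gaps between a *non-overlapping gene-level selection* of spans,
  strand-ignored; the antisense ORF is excluded by default (configurable)
  since it overlaps intergenic space on the opposite strand. Labels run
  IGR-1..n from the gap following the feature with the smallest start.
* ORF scanning reports, per in-frame stop, the longest ORF (earliest
  qualifying start after the previous stop), sorted by amino-acid length.
* Direct repeats: maximal exact pairs (extendable neither left nor right),
  length-descending, greedily filtered to non-overlapping occupancy;
  property-tested against a longest-common-extension brute-force oracle.
* Ambiguity codes other than N are rejected at genome input.
* Read classification ties: mismatches, then longest overlap, then
  AMBIGUOUS.
* The 100-seed recovery experiment asserts per-intron coverage (each
  intron's Wilson interval covers its configured truth in ≥ 90/100 seeds)
  at 50,000 reads per seed; problem sizes throughout (8k-read unit-test
  studies, 1000 toy genomes, 100 PCR templates ≤ 500 nt) were chosen as the
  smallest that exercise every code path with stable statistics.

## Limitations

Ungapped alignment only (no indels); no ribozyme folding, kinetics or
splice-site prediction from structure; no trans-splicing model; abundance
assignment is majority-overlap rather than probabilistic multi-mapping; the
in-silico PCR has no thermodynamics (no melting temperatures, no primer
dimers beyond the 3'-anchor rule).
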