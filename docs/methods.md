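# Methods

## The locus model

The toolkit models the 21-hydroxylase locus as a pair of homologous
references: a functional gene (`gene_ref`, standing in for CYP21A2 with
its downstream TNXB flank) and a pseudogene (`pseudo_ref`, CYP21A1P with
the TNXA flank). The real amplicons run tens of kilobases; the toy locus
compresses this to ~3.7 kb while preserving everything the method depends
on — distinguishable primer termini, a PSV-tiled gene body, junction bins,
and a coding map deep enough for every knowledge-base variant:

- 10 exons (146, 146, then 150-nt exons, final 158 nt; 1,500 coding nt)
  separated by 70-nt introns, starting at position 100; the 3' UTR extends
  past the last coding base at 2,229 into the downstream flank, so UTR
  names up to c.*1351 resolve on the reference.
- The pseudogene is the gene with a fixed edit script applied: 24 interior
  substitutions + 2 two-base insertions + 1 two-base deletion across the
  body, 9 substitutions in the flank, and 3 forced substitutions inside
  each terminal 20-mer so the paralog primers differ by ≥3 edits. Every
  edit is a paralog signature variant (PSV); `derive_signature_variants`
  re-derives the script from a global affine-gap alignment (match +2,
  mismatch −4, gap open −6, extend −1 — standard DNA scoring), and the
  build verifies the two routes agree.
- PSV density ≈ 1 per 110 nt in the body. The 27 interior body PSVs are
  split into nine equal-count junction bins CH-1…CH-9 (5'→3'); the flank
  PSVs form a single bin in the TNXA/TNXB namespace. Terminal primer PSVs
  belong to no bin, so simulated breakpoints can never truncate a primer.
  The bin table is configuration-overridable; the CH numbering itself is a
  naming convention without published coordinates, so bins are defined by
  PSV count rather than by genomic landmarks.
- Reference bases at knowledge-base variant positions are forced during
  construction (e.g. T at the c.518 coordinate), and indel-variant
  contexts are kept non-repetitive so left-normalization is stable.

Coordinates are 0-based half-open internally; variant names use 1-based
coding (HGVS-style) positions. The supported name grammar covers exonic
and intronic substitutions (`c.518T>A`, `c.293-13C>G`), single-base
duplications and deletions (`c.923dup`, `c.740del`), and 3'-UTR
substitutions (`c.*1316C>T`); unicode dashes and stray spaces, as they
appear in clinical tables, are normalized away.

## Simulator

Diplotypes are declared as two haplotype specs. A NORMAL haplotype yields
a functional-gene amplicon (with its variants applied right-to-left) and a
pseudogene amplicon. A deletion chimera yields a single fused amplicon —
pseudogene up to a breakpoint drawn uniformly inside the named bin, gene
after it — carrying the pseudo-forward/gene-reverse primer pair; a
TNX chimera places the breakpoint in the flank bin (the whole-gene
deletion). A conversion chimera keeps gene primers but substitutes pseudo
alleles at every interior PSV 5' of the breakpoint. A fusion duplication
adds the fused amplicon on top of one or more intact gene copies.

Reads are full-length amplicon copies (long-range PCR products sequenced
as single molecules; no fragmentation) flanked by a 10-nt barcode and its
reverse complement, with per-base errors at the default CCS-like rates of
0.3% substitution, 0.1% insertion, 0.1% deletion (total 0.5%, i.e. a bit
better than the Q20 accuracy floor of circular-consensus reads). Depth
allocation is deterministic — each amplicon of each haplotype is sampled
`depth//2` times — so small-depth tests are exact; alternate reads are
reverse-complemented. Fixtures default to 100× per sample (real per-case
depths vary over orders of magnitude; 100× is a conservative, fast choice
well above the caller's 30× floor).

What the simulator does **not** model: consensus formation from subreads,
PCR chimeric artifacts, barcode hopping, coverage imbalance between
amplicons, and mosaicism. Passing tests therefore demonstrate the
*analytical* pipeline's correctness on structurally faithful data, not
robustness to every artifact of a wet-lab run.

## Read classification

Demultiplexing matches the leading 10-mer barcode within one edit
(barcodes are pairwise Hamming ≥3, so one-edit assignment is unambiguous);
unmatched reads land in an `undetermined` bin and bin sizes always sum to
the input. Classification looks for a forward primer in the first
`primer_len + 5` bases and a reverse primer in the last, in both read
orientations: gene/gene → FUNCTIONAL, pseudo/pseudo → PSEUDO, pseudo/gene
→ deletion chimera. Primer matching is **edit** distance ≤1, not Hamming —
at CCS error rates a single indel inside a 20-mer is common and destroys
any fixed-offset comparison. One terminus may additionally be rescued at
two edits when its mate matched within one and the competing paralog
primer is strictly worse; without the rescue ~1% of reads would be
abstained on a single doubly-corrupted primer, and with it classification
agrees with simulation truth for ≥99.9% of reads while never assigning a
*wrong* category (ambiguous reads stay UNASSIGNED, never dropped).
Conversion chimeras carry plain gene primers, so their refinement is
deferred to the phaser; a dedicated conversion primer pair is accepted via
the primer-set configuration for assay designs that have one.

## Alignment and small-variant calling

Classified functional and chimeric reads are aligned to the functional
reference with a banded Gotoh affine-gap algorithm (glocal: reads align
end-to-end, reference flanks are free; same scoring as PSV derivation;
ties resolved toward leftmost gap placement, then indels left-normalized
to the VCF convention). Full-length amplicons stay near the main diagonal,
so a band of 80 columns (widened by any length difference) is exact in
practice; the test suite checks band-free scores against an independent
full-matrix DP oracle. Reads under 70% identity are flagged and excluded.

Variant calling is a count-based pileup over non-chimeric functional
reads: alleles at fraction ≥0.2 are emitted, ≥0.8 is homozygous, and
columns below the 30× depth floor are masked (BED) instead of called.
Base qualities are ignored — at ≥Q20 consensus accuracy, count-based
calling is adequate; this is a documented limitation, not an oversight.
Alleles matching a pseudogene PSV state are excluded from variant output:
they are paralog signal handled by the chimera machinery, not mutations.
Pseudogene-classified reads never contribute variant calls.

## Junctions and phasing

Each aligned read reduces to a PSV state vector (GENE / PSEUDO / MISSING;
discordant alleles at a PSV count as MISSING). Chimeras follow a
single-changepoint model: the junction is the leftmost cut minimizing
(#GENE states before) + (#PSEUDO states after), reported as the open
interval between the flanking informative PSVs and labeled with the bin
containing the interval midpoint (boundary-straddling junctions take the
left PSV's bin and are flagged ambiguous). Multi-switch reads are flagged,
not modeled. Junction calling is per read by default; groups are formed
per (region, bin) label and stray labels below 10% support are absorbed
into the nearest major bin.

Phasing exploits full-length reads — every read votes at every
heterozygous site — so a greedy two-seed clustering on allele vectors
(seeds = the two most frequent complete patterns, ties lexicographic;
reads conflicting with both consensi at >20% of sites set aside as noise)
recovers the partition essentially perfectly; an exact small-instance
oracle in the tests guards the greedy shortcut. Output is stable under
read order.

Diplotype slots are then filled: chimera groups first, conversion groups
(functional consensus with a contiguous PSEUDO prefix of ≥2 interior
PSVs) next, phased functional groups last. Two distinct functional
haplotypes *plus* a chimera group mean the chimera is a fusion duplication
riding on one haplotype: that haplotype keeps `intact_copy=True` and the
fused copy is supernumerary. The attachment to a specific functional
haplotype is arbitrary when no read links them (full-length amplicons
cannot span both copies), so it goes to the haplotype with fewer
pathogenic variants and is flagged ambiguous; the screening verdict is
invariant to the choice. A single functional group with a chimera group is
the classic heterozygous deletion; a single functional group alone is
reported homozygous.

## Interpretation

The knowledge base is a curated lookup (name → P/LP/VUS classification and
SW/SV/NC phenotype), packaging the study's 11 pathogenic entries (8
SNVs/indels, 3 deletion/chimera classes) plus the cohort's VUS/LP
annotations. ACMG evidence scoring itself is out of scope. The recessive
verdict counts pathogenic alleles: a haplotype contributes one if it
carries a P/LP variant on its functional copy, or if it is a
deletion/TNX chimera without an intact copy. LP counts toward pathogenic
alleles (screening convention); VUS never does, and adding a VUS can never
change a verdict. Phenotype prediction uses the standard 21-OHD convention
— the most severe variant dominates within an allele, the milder allele
sets the patient phenotype (SW > SV > NC) — and is labeled a prediction,
not a diagnosis.

## Screening statistics

Rates are percentages rounded half-up to two decimals; incidences are 1:N
with N rounded to the nearest integer (the initial-screen PPV denominator
is the 1,985 initial positives). Sensitivity and specificity are Beta
posteriors under the Jeffreys prior Beta(0.5, 0.5): x successes in n
trials give Beta(x+0.5, n−x+0.5) with mean (x+0.5)/(n+1). Credible
intervals are equal-tailed quantiles from regularized-incomplete-beta
inversion (verified in tests against an independent bisection to 1e−8;
equal-tailed, not HPD, because two-sided intervals are the reporting
convention). Frequentist coverage of the 95% interval is property-tested
at p=0.9, n=60.

## Problem sizes and numerical choices

Default test and acceptance runs use the 73-sample packaged cohort at
100× (≈200 reads/sample, ~3.7 kb each); the full screen takes about a
minute on one CPU. Alignment uses 64-bit integer scores (no overflow at
these scales); the changepoint search is exact, not heuristic; all
randomness flows through explicit seeds, and simulation fixtures are
byte-reproducible for a fixed seed. Degenerate inputs are handled
explicitly: empty read sets yield an empty diplotype with a warning,
samples below the depth floor call nothing and mask everything, junction
localization demands ≥2 informative PSV states, and sentinel (all-gene /
all-pseudo) vectors cannot be binned.

## Known limitations

Copy number is not inferred from read counts (per-amplicon depth is not
quantitative after PCR), so a fusion duplication is only recognized when
the two intact functional haplotypes are distinguishable by at least one
het site; identical intact copies alongside a chimera are reported as the
heterozygous-deletion configuration. Conversion tracts interior to a read
(not prefix-anchored) are flagged but not reconstructed. The toy locus
preserves category structure, not real coordinates: positions, bin
boundaries and PSV counts do not transfer to GRCh38.
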