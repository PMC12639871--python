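# cahlrs

Long-read amplicon screening toolkit for 21-hydroxylase-deficient
congenital adrenal hyperplasia (CAH), built around a desk-scale model of
the *CYP21A2*/*CYP21A1P* locus.

## The problem

More than 90% of CAH is caused by *CYP21A2* variants, but the gene sits
next to a ~98%-identical pseudogene, *CYP21A1P*, and most pathogenic
alleles arise by gene conversion or by 30-kb deletions that fuse the two
paralogs (including *TNXA*/*TNXB* chimeras that remove the whole gene).
Short reads cannot tell the paralogs apart; full-length single-molecule
amplicon reads can, because every read spans the entire gene and carries
the complete set of paralog signature variants (PSVs).

`cahlrs` implements the molecular half of such a screening assay as an
auditable, fully simulated toolkit:

- **locus model** — a ~3.7 kb toy functional-gene/pseudogene pair with
  primers, exon map, PSVs derived by affine-gap alignment, and labeled
  junction bins (CH-1…CH-9, plus a flank bin in the TNXA/TNXB namespace);
- **simulator** — renders diplotypes (SNVs/indels, deletion chimeras,
  conversion chimeras, fusion duplications) into barcoded CCS-like reads;
- **read classifier** — barcode demultiplexing and primer-pair category
  assignment (functional / pseudogene / deletion-chimera);
- **aligner + caller** — banded Gotoh affine-gap semi-global alignment and
  count-based SNV/indel calling with a 30× depth floor;
- **chimera phaser** — PSV state vectors, minimum-mismatch changepoint
  junction calling, bin labeling, and read-backed phasing (cis/trans);
- **interpreter** — knowledge-base annotation (P/LP/VUS; SW/SV/NC) and the
  recessive screening verdict AFFECTED / CARRIER / NEGATIVE, with fusion
  duplications correctly discounted when an intact gene copy remains;
- **screening statistics** — positivity/recall/PPV/incidence arithmetic
  and Jeffreys-prior Beta posteriors for sensitivity and specificity.

## Worked example

```bash
python examples/02_screen_one_case.py
```

simulates the five-variant compound-het case at 100× and prints:

```
read classes: {'FUNCTIONAL': 100, 'PSEUDO': 100}

sample: case01
status: AFFECTED  mode: CHet  predicted phenotype: SV
haplotype A: intact (50 reads)
  c.844G>T	P	NC [t]
  c.923dup	P	SW [t]
  c.955C>T	P	SW [t]
  c.1069C>T	P	SW [t]
haplotype B: intact (50 reads)
  c.518T>A	P	SV [t]
```

Five pathogenic variants were called and phased into two haplotypes:
c.518T>A is in trans with the other four (`[t]`), so the sample carries
two pathogenic alleles (compound heterozygous, AFFECTED). The predicted
phenotype follows the milder allele (SV) — the phase relationship a
short-read or Sanger workflow could only resolve with parental samples.

The other examples build the locus and simulate reads (`01`), localize
deletion-chimera junctions from PSV changepoints (`03`), and reproduce the
cohort screening statistics (`04`). A thin CLI wraps the same pipeline:

```bash
cahlrs simulate --out-dir fixtures --seed 1        # 73-sample cohort
cahlrs screen fixtures/case12.fastq --out-dir out  # VCF + report, exit 10
cahlrs cohort-stats                                # screening funnel
```

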