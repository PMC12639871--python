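"""Build the toy two-paralog locus and simulate reads for one diplotype.

The locus stands in for CYP21A2 (functional gene) and CYP21A1P (pseudogene):
two ~3.7 kb references that differ only at paralog signature variants (PSVs)
plus divergent primer-bearing termini.  We render a compound-heterozygous
diplotype into amplicons and sample CCS-like reads from it.
"""

from cahlrs import build_toy_locus
from cahlrs.simulate import (DiplotypeSpec, ErrorModel, HaplotypeSpec,
                             simulate_reads)

locus = build_toy_locus()
print(f"gene reference:   {len(locus.gene_ref)} nt")
print(f"pseudo reference: {len(locus.pseudo_ref)} nt")
print(f"signature variants (PSVs): {len(locus.psvs)}")
print(f"junction bins: {[b.label for b in locus.junction_bins]}"
      f" + flank {[b.label for b in locus.tnx_bins]}")

dip = DiplotypeSpec(
    sample_id="demo", barcode="ACGTACGTAC",
    hap_a=HaplotypeSpec("A", variants=("c.293-13C>G",)),
    hap_b=HaplotypeSpec("B", variants=("c.518T>A",)))

reads = simulate_reads(dip, locus, depth=40, error_model=ErrorModel(), seed=1)
print(f"\nsimulated {len(reads)} reads at depth 40 "
      f"(each amplicon sampled depth/2 = 20 times)")
print(f"first read: {len(reads[0].sequence)} nt, truth tag "
      f"{reads[0].truth_tag!r}")
# Each haplotype contributes a functional-gene amplicon and a pseudogene
# amplicon; the truth tag records which haplotype/amplicon produced the read.
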