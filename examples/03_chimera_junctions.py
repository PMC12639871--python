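"""Locate and bin a 30-kb-deletion chimera junction from PSV states.

A deletion chimera is pseudogene sequence 5' of its junction and functional
gene 3' of it.  Each read reduces to a vector of per-PSV states; the
junction is the minimum-mismatch single changepoint, labeled by the CH bin
holding its midpoint.
"""

import numpy as np

from cahlrs import build_toy_locus
from cahlrs.align import align_read
from cahlrs.phasing import bin_junction, locate_junction, psv_genotype_vector
from cahlrs.simulate import HaplotypeSpec, build_haplotype

locus = build_toy_locus()
rng = np.random.default_rng(3)

for bin_label, structure in (("CH-1", "DEL_CHIMERA"), ("CH-8", "DEL_CHIMERA"),
                             ("CH-1", "TNX_CHIMERA")):
    spec = HaplotypeSpec("A", structure=structure, bin_label=bin_label)
    amp = build_haplotype(spec, locus, rng)[0]
    aln = align_read("read", amp.sequence, locus.gene_ref)
    vec = psv_genotype_vector(aln, locus.psvs)
    j = locate_junction(vec)
    b = bin_junction(j, locus.psvs, locus.all_bins())
    name = ("CYP21A1P/CYP21A2" if b.region == "gene" else "TNXA/TNXB")
    print(f"simulated {structure}({bin_label}) breakpoint {amp.breakpoint}"
          f" -> junction between PSV {j.left_psv_index} and"
          f" {j.right_psv_index} (cost {j.cost}) -> {name}_{b.label}")
# cost 0 means every PSV state is consistent with a single changepoint; the
# recovered bin equals the simulated one, including the flank (TNXA/TNXB)
# junction that marks a whole-gene deletion.
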