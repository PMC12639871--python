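"""Diplotype interpretation: from per-haplotype calls to a screening verdict.

21-hydroxylase deficiency is recessive: a sample is AFFECTED when both
haplotypes carry a pathogenic lesion (small variant classified P/LP, or a
deletion/fusion chimera that removes the functional gene), CARRIER with one
pathogenic allele, NEGATIVE with none.  A fusion-duplication haplotype that
retains an intact functional copy contributes no pathogenic allele — the
chimeric copy is supernumerary.  The predicted phenotype follows standard
genotype–phenotype practice for this locus: within an allele the most
severe variant dominates; between the two alleles the milder one sets the
phenotype (severity order SW > SV > NC).  The prediction is a screening
annotation, not a diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .kb import VariantKB

SEVERITY = {"SW": 3, "SV": 2, "NC": 1}
REPORT_SCHEMA_VERSION = "1"

STRUCTURAL_PATHOGENIC = ("DEL_CHIMERA", "TNX_CHIMERA")


@dataclass
class HaplotypeCall:
    """One resolved haplotype: variant content plus structural class."""

    label: str
    variants: tuple = ()          # coding-style names
    structure: str = "NORMAL"     # NORMAL | DEL_CHIMERA | CONV_CHIMERA |
                                  # TNX_CHIMERA | DUP_FUSION
    bin_label: str | None = None
    supporting_reads: int = 0
    intact_copy: bool = False     # haplotype retains >= 1 intact gene copy
    ambiguous: bool = False

    @property
    def structure_name(self) -> str:
        """Knowledge-base name of the structural class, e.g.
        'CYP21A1P/CYP21A2_CH-1' or 'TNXA/TNXB_CH-1'."""
        if self.structure in ("DEL_CHIMERA", "DUP_FUSION"):
            return f"CYP21A1P/CYP21A2_{self.bin_label}"
        if self.structure == "TNX_CHIMERA":
            return f"TNXA/TNXB_{self.bin_label}"
        if self.structure == "CONV_CHIMERA":
            return f"CYP21A2/CYP21A1P_{self.bin_label}"
        return ""


@dataclass
class DiplotypeCall:
    sample_id: str
    hap_a: HaplotypeCall
    hap_b: HaplotypeCall
    status: str                   # AFFECTED | CARRIER | NEGATIVE
    pathogenic_alleles: int
    genotype_mode: str            # hom | CHet | het | none
    predicted_phenotype: str      # SW | SV | NC | NA
    annotations: dict = field(default_factory=dict)  # name -> classification
    trans_pairs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def annotate_variants(names, kb: VariantKB) -> dict:
    """name -> {classification, phenotype}; unknown variants never count."""
    out = {}
    for n in names:
        out[n] = {"classification": kb.classification(n),
                  "phenotype": kb.phenotype(n)}
    return out


def _pathogenic_content(hap: HaplotypeCall, kb: VariantKB):
    """(is_pathogenic_allele, lesion_names, severity) for one haplotype."""
    lesions = [n for n in hap.variants if kb.is_pathogenic(n)]
    # a structural lesion counts only when no intact functional copy remains
    # on the haplotype: a DUP_FUSION's chimeric copy is supernumerary, and
    # whatever the fused copy carries never reaches hap.variants
    if hap.structure in STRUCTURAL_PATHOGENIC and not hap.intact_copy:
        lesions.append(hap.structure_name)
    severities = [SEVERITY.get(kb.phenotype(n), 0) for n in lesions]
    severity = max(severities) if severities else 0
    return bool(lesions), lesions, severity


def call_diplotype(hap_a: HaplotypeCall, hap_b: HaplotypeCall,
                   kb: VariantKB, sample_id: str = "") -> DiplotypeCall:
    """Combine two haplotype calls into the per-sample screening verdict."""
    path_a, lesions_a, sev_a = _pathogenic_content(hap_a, kb)
    path_b, lesions_b, sev_b = _pathogenic_content(hap_b, kb)
    n_path = int(path_a) + int(path_b)
    status = {2: "AFFECTED", 1: "CARRIER", 0: "NEGATIVE"}[n_path]

    if n_path == 0:
        mode = "none"
    elif n_path == 1:
        mode = "het"
    elif sorted(lesions_a) == sorted(lesions_b) and len(set(lesions_a)) == 1:
        mode = "hom"
    else:
        mode = "CHet"

    if n_path == 2:
        milder = min(sev_a, sev_b)
        pheno = {3: "SW", 2: "SV", 1: "NC"}.get(milder, "NA")
    else:
        pheno = "NA"

    names = set(hap_a.variants) | set(hap_b.variants)
    for h in (hap_a, hap_b):
        if h.structure_name:
            names.add(h.structure_name)
    annotations = annotate_variants(sorted(names), kb)

    # cis/trans: pathogenic lesions on opposite haplotypes are in trans
    trans = []
    for la in (lesions_a or []):
        for lb in (lesions_b or []):
            if la != lb:
                trans.append((la, lb))
    warnings = []
    if hap_a.ambiguous or hap_b.ambiguous:
        warnings.append("haplotype assignment ambiguous")
    return DiplotypeCall(sample_id=sample_id, hap_a=hap_a, hap_b=hap_b,
                         status=status, pathogenic_alleles=n_path,
                         genotype_mode=mode, predicted_phenotype=pheno,
                         annotations=annotations, trans_pairs=trans,
                         warnings=warnings)


def render_report(call: DiplotypeCall, fmt: str = "json") -> str:
    """Serialize a diplotype call; JSON is canonical, text mirrors the
    per-case genotype table layout (variant, classification, phase)."""
    if fmt == "json":
        doc = asdict(call)
        doc["schema_version"] = REPORT_SCHEMA_VERSION
        return json.dumps(doc, indent=1, sort_keys=True)
    if fmt == "text":
        lines = [f"sample: {call.sample_id or '-'}",
                 f"status: {call.status}  mode: {call.genotype_mode}  "
                 f"predicted phenotype: {call.predicted_phenotype}"]
        trans_names = {n for pair in call.trans_pairs for n in pair}
        for hap in (call.hap_a, call.hap_b):
            desc = hap.structure_name or "intact"
            lines.append(f"haplotype {hap.label}: {desc} "
                         f"({hap.supporting_reads} reads)")
            for v in hap.variants:
                ann = call.annotations.get(v, {})
                mark = " [t]" if v in trans_names else ""
                lines.append(f"  {v}\t{ann.get('classification', '?')}\t"
                             f"{ann.get('phenotype', '?')}{mark}")
        if not call.hap_a.variants and not call.hap_b.variants \
                and call.status == "NEGATIVE":
            lines.append("no variants detected")
        for w in call.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def load_report(text: str) -> dict:
    return json.loads(text)


EXIT_NEGATIVE = 0
EXIT_AFFECTED = 10


def exit_code_for(call: DiplotypeCall) -> int:
    return EXIT_AFFECTED if call.status == "AFFECTED" else EXIT_NEGATIVE
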