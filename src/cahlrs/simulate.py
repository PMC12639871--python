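"""Diplotype construction and CCS-like amplicon read simulation.

Haplotypes are described declaratively (variant names plus a structural
class) and rendered into full-length amplicon sequences; reads are exact
amplicon copies with independent per-base substitution/indel errors at
rates emulating >=Q20 circular-consensus accuracy.  Depth allocation is a
deterministic per-amplicon count (depth//2 reads per amplicon) so that
small-depth tests are exact; reads carry truth tags for end-to-end checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .locus import LocusModel, revcomp
from .nomenclature import parse_coding_name

STRUCTURES = ("NORMAL", "DEL_CHIMERA", "CONV_CHIMERA", "TNX_CHIMERA",
              "DUP_FUSION")

# amplicon kinds: which primer pair the molecule carries
AMP_GENE = "gene"
AMP_PSEUDO = "pseudo"
AMP_FUSED = "fused"       # pseudo-forward + gene-reverse (deletion/fusion)
AMP_CONV = "conv"         # gene primers, pseudo-converted 5' tract


@dataclass(frozen=True)
class HaplotypeSpec:
    label: str
    variants: tuple = ()
    structure: str = "NORMAL"
    bin_label: str | None = None        # CH bin for chimeric structures
    fused_variants: tuple = ()          # variants on the fused copy (DUP_FUSION)
    copies: int = 1                     # intact functional copies (DUP_FUSION)

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure}")
        if self.structure != "NORMAL" and not self.bin_label:
            raise ValueError(f"{self.structure} requires a junction bin")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class DiplotypeSpec:
    sample_id: str
    barcode: str
    hap_a: HaplotypeSpec
    hap_b: HaplotypeSpec
    expected_status: str = ""  # truth annotation for fixtures


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.003
    ins_rate: float = 0.001
    del_rate: float = 0.001

    def __post_init__(self):
        for r in (self.substitution_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.05:
                raise ValueError("error rates must lie in [0, 0.05]")

    @property
    def total(self):
        return self.substitution_rate + self.ins_rate + self.del_rate


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass
class ReadRecord:
    id: str
    barcode: str
    sequence: str
    qualities: str
    truth_tag: str = ""

    def __post_init__(self):
        if not self.sequence or len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


@dataclass(frozen=True)
class Amplicon:
    kind: str
    sequence: str
    breakpoint: int | None = None  # gene_ref coordinate for chimeric kinds


class StructureConflictError(ValueError):
    """A requested variant's coordinate is removed by the structure."""


def _variant_edits(names, locus: LocusModel):
    edits = []
    for name in names:
        gv = parse_coding_name(name, locus.cds_map, locus.gene_ref)
        edits.append(gv)
    return edits


def _apply_edits(seq: str, edits) -> str:
    """Apply GenomicVariant edits right-to-left so coordinates stay valid."""
    out = list(seq)
    for gv in sorted(edits, key=lambda g: g.gene_pos, reverse=True):
        if gv.kind == "SNV":
            out[gv.gene_pos] = gv.alt
        elif gv.kind == "dup":
            out[gv.gene_pos + 1:gv.gene_pos + 1] = [gv.ref]
        elif gv.kind == "del":
            if gv.alt == "":  # plain single-base deletion at gene_pos
                del out[gv.gene_pos]
            else:             # anchored multi-base deletion after gene_pos
                del out[gv.gene_pos + 1:gv.gene_pos + len(gv.ref)]
        else:  # generic anchored insertion
            out[gv.gene_pos + 1:gv.gene_pos + 1] = list(gv.alt[len(gv.ref):])
    return "".join(out)


def _find_bin(locus: LocusModel, label: str, region: str):
    pool = locus.junction_bins if region == "gene" else locus.tnx_bins
    for b in pool:
        if b.label == label:
            return b
    raise ValueError(f"no junction bin {label!r} in region {region!r}")


def _breakpoint_in_bin(locus: LocusModel, b, rng) -> int:
    """Uniform breakpoint strictly between the bin's outermost PSVs, kept
    clear of PSV sites and indel footprints so the junction bins cleanly."""
    psvs = [p for p in locus.psvs if b.start <= p.gene_pos < b.end]
    lo, hi = psvs[0].gene_pos, psvs[-1].gene_pos
    blocked = set()
    for p in locus.psvs:
        span = len(p.gene_allele) + 2
        blocked.update(range(p.gene_pos - 1, p.gene_pos + span))
    candidates = [x for x in range(lo + 1, hi) if x not in blocked]
    if not candidates:
        raise ValueError(f"bin {b.label} has no usable breakpoint")
    return int(candidates[rng.integers(0, len(candidates))])


def _fused_sequence(locus: LocusModel, bp_gene: int, gene_side: str) -> str:
    bp_pseudo = int(locus.g2p[bp_gene])
    return locus.pseudo_ref[:bp_pseudo] + gene_side[bp_gene:]


def build_haplotype(spec: HaplotypeSpec, locus: LocusModel,
                    rng=None) -> list[Amplicon]:
    """Render a haplotype spec into its amplicon molecules."""
    rng = rng if rng is not None else np.random.default_rng(0)
    edits = _variant_edits(spec.variants, locus)

    if spec.structure == "NORMAL":
        gene = _apply_edits(locus.gene_ref, edits)
        return [Amplicon(AMP_GENE, gene), Amplicon(AMP_PSEUDO, locus.pseudo_ref)]

    if spec.structure in ("DEL_CHIMERA", "TNX_CHIMERA"):
        region = "gene" if spec.structure == "DEL_CHIMERA" else "tnx"
        b = _find_bin(locus, spec.bin_label, region)
        bp = _breakpoint_in_bin(locus, b, rng)
        for gv in edits:
            if gv.gene_pos < bp:
                raise StructureConflictError(
                    f"{gv.name} lies in the pseudogene-derived segment")
        gene_side = _apply_edits(locus.gene_ref, edits)
        return [Amplicon(AMP_FUSED, _fused_sequence(locus, bp, gene_side), bp)]

    if spec.structure == "CONV_CHIMERA":
        b = _find_bin(locus, spec.bin_label, "gene")
        bp = _breakpoint_in_bin(locus, b, rng)
        conv = _conversion_edits(locus, bp)
        for gv in edits:
            if any(c.gene_pos == gv.gene_pos for c in conv):
                raise StructureConflictError(
                    f"{gv.name} collides with a converted signature site")
        gene = _apply_edits(locus.gene_ref, list(conv) + list(edits))
        return [Amplicon(AMP_CONV, gene, bp),
                Amplicon(AMP_PSEUDO, locus.pseudo_ref)]

    # DUP_FUSION: fused pathogenic copy + `copies` intact functional copies
    b = _find_bin(locus, spec.bin_label, "gene")
    bp = _breakpoint_in_bin(locus, b, rng)
    fused_edits = _variant_edits(spec.fused_variants, locus)
    for gv in fused_edits:
        if gv.gene_pos < bp:
            raise StructureConflictError(
                f"{gv.name} lies in the pseudogene-derived segment")
    fused = _fused_sequence(locus, bp, _apply_edits(locus.gene_ref, fused_edits))
    gene = _apply_edits(locus.gene_ref, edits)
    amps = [Amplicon(AMP_FUSED, fused, bp)]
    amps += [Amplicon(AMP_GENE, gene)] * spec.copies
    amps.append(Amplicon(AMP_PSEUDO, locus.pseudo_ref))
    return amps


def _conversion_edits(locus: LocusModel, bp: int):
    """Pseudo alleles at every interior PSV 5' of the breakpoint."""
    from .nomenclature import GenomicVariant
    edits = []
    for p in locus.interior_psvs:
        if p.gene_pos >= bp:
            break
        if p.kind == "SNV":
            edits.append(GenomicVariant("", p.gene_pos, p.gene_allele,
                                        p.pseudo_allele, "SNV"))
        elif p.kind == "ins":
            edits.append(GenomicVariant("", p.gene_pos, p.gene_allele,
                                        p.pseudo_allele, "ins"))
        else:
            edits.append(GenomicVariant("", p.gene_pos, p.gene_allele,
                                        p.pseudo_allele, "del"))
    return edits


def mutate_sequence(seq: str, em: ErrorModel, rng) -> str:
    """Inject independent per-base substitution / insertion / deletion errors."""
    if em.total == 0:
        return seq
    n = len(seq)
    r = rng.random(n)
    s_cut = em.substitution_rate
    i_cut = s_cut + em.ins_rate
    d_cut = i_cut + em.del_rate
    hit = np.nonzero(r < d_cut)[0]
    if hit.size == 0:
        return seq
    bases = "ACGT"
    parts = []
    prev = 0
    for pos in hit:
        parts.append(seq[prev:pos])
        x = r[pos]
        if x < s_cut:
            parts.append(bases[(bases.index(seq[pos]) + 1 + rng.integers(0, 3)) % 4])
            prev = pos + 1
        elif x < i_cut:
            parts.append(seq[pos])
            parts.append(bases[rng.integers(0, 4)])
            prev = pos + 1
        else:  # deletion
            prev = pos + 1
    parts.append(seq[prev:])
    return "".join(parts)


def simulate_reads(dip: DiplotypeSpec, locus: LocusModel, depth: int,
                   error_model: ErrorModel = ErrorModel(),
                   seed: int | np.random.Generator = 0,
                   orient_mix: bool = True) -> list[ReadRecord]:
    """Barcoded full-length amplicon reads for one diplotype.

    Each amplicon of each haplotype is sampled depth//2 times; half the
    reads (deterministically interleaved) are emitted reverse-complemented.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    per_amp = depth // 2
    reads = []
    k = 0
    qchar = chr(33 + 30)
    for hap in (dip.hap_a, dip.hap_b):
        for a_idx, amp in enumerate(build_haplotype(hap, locus, rng)):
            for _ in range(per_amp):
                seq = dip.barcode + amp.sequence + revcomp(dip.barcode)
                seq = mutate_sequence(seq, error_model, rng)
                if orient_mix and k % 2 == 1:
                    seq = revcomp(seq)
                reads.append(ReadRecord(
                    id=f"{dip.sample_id}/{k}", barcode=dip.barcode,
                    sequence=seq, qualities=qchar * len(seq),
                    truth_tag=f"{hap.label}|{amp.kind}|{a_idx}"))
                k += 1
    return reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description=r.truth_tag)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33
                                                   for c in r.qualities]
        recs.append(rec)
    SeqIO.write(recs, path, "fastq")


def read_fastq(path) -> list[ReadRecord]:
    from Bio import SeqIO
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        q = "".join(chr(33 + v) for v in rec.letter_annotations["phred_quality"])
        tag = rec.description.split(" ", 1)[1] if " " in rec.description else ""
        reads.append(ReadRecord(id=rec.id, barcode="", sequence=str(rec.seq),
                                qualities=q, truth_tag=tag))
    return reads


def write_cohort_fixture(specs: list[DiplotypeSpec], locus: LocusModel,
                         out_dir, depth: int = 100,
                         error_model: ErrorModel = ErrorModel(),
                         seed: int = 0, overwrite: bool = False) -> dict:
    """One FASTQ per case plus a truth manifest; byte-reproducible per seed."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "depth": depth, "cases": []}
    for idx, dip in enumerate(specs):
        rng = np.random.default_rng([seed, idx])
        reads = simulate_reads(dip, locus, depth, error_model, rng)
        fq = out / f"{dip.sample_id}.fastq"
        write_fastq(reads, fq)
        manifest["cases"].append({
            "sample_id": dip.sample_id, "barcode": dip.barcode,
            "fastq": fq.name, "n_reads": len(reads),
            "expected_status": dip.expected_status,
            "hap_a": _spec_dict(dip.hap_a), "hap_b": _spec_dict(dip.hap_b)})
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _spec_dict(h: HaplotypeSpec) -> dict:
    return {"label": h.label, "variants": list(h.variants),
            "structure": h.structure, "bin": h.bin_label,
            "fused_variants": list(h.fused_variants), "copies": h.copies}


# ---------------------------------------------------------------------------
# packaged cohort: 12 confirmed cases + 4 carriers + 57 variant-free samples


def generate_barcodes(count: int, length: int = 10, min_dist: int = 3,
                      seed: int = 7) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    out: list[str] = []
    while len(out) < count:
        cand = "".join(bases[b] for b in rng.integers(0, 4, length))
        if all(sum(a != b for a, b in zip(cand, o)) >= min_dist for o in out):
            out.append(cand)
    return out


def load_cohort_yaml(path_or_handle) -> list[DiplotypeSpec]:
    """Cohort spec YAML -> diplotype specs (explicit cases + negatives count)."""
    if hasattr(path_or_handle, "read"):
        doc = yaml.safe_load(path_or_handle)
    else:
        with open(path_or_handle) as fh:
            doc = yaml.safe_load(fh)
    n_explicit = len(doc.get("cases", []))
    n_negative = int(doc.get("negatives", 0))
    barcodes = generate_barcodes(n_explicit + n_negative,
                                 seed=int(doc.get("barcode_seed", 7)))
    specs = []
    for i, case in enumerate(doc.get("cases", [])):
        hap_a = _hap_from_dict(case["hap_a"], "A")
        hap_b = _hap_from_dict(case["hap_b"], "B")
        specs.append(DiplotypeSpec(case["id"], barcodes[i], hap_a, hap_b,
                                   case.get("status", "")))
    for j in range(n_negative):
        lab = f"neg{j + 1:02d}"
        specs.append(DiplotypeSpec(
            lab, barcodes[n_explicit + j],
            HaplotypeSpec("A"), HaplotypeSpec("B"), "NEGATIVE"))
    return specs


def _hap_from_dict(d: dict, label: str) -> HaplotypeSpec:
    return HaplotypeSpec(
        label=d.get("label", label), variants=tuple(d.get("variants", [])),
        structure=d.get("structure", "NORMAL"), bin_label=d.get("bin"),
        fused_variants=tuple(d.get("fused_variants", [])),
        copies=int(d.get("copies", 1)))


def _packaged_cohort() -> list[DiplotypeSpec]:
    from importlib import resources
    with resources.files("cahlrs.data").joinpath("cohort.yaml").open() as fh:
        return load_cohort_yaml(fh)


def table1_specs() -> list[DiplotypeSpec]:
    """The 12 confirmed-case diplotypes."""
    return [d for d in _packaged_cohort() if d.expected_status == "AFFECTED"]


def cohort73_specs() -> list[DiplotypeSpec]:
    """Full retrospective cohort: 12 affected, 4 carriers, 57 variant-free."""
    return _packaged_cohort()
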