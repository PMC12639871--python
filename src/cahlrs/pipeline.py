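"""End-to-end per-sample screening: classify -> align -> call -> phase ->
interpret, plus cohort-level runners and the confusion matrix.

Haplotype slot assembly
-----------------------
A diploid sample offers two haplotype slots.  Chimera-classified read
groups (keyed by refined class and junction bin) claim slots first; groups
of conversion-carrying functional reads claim slots next; phased groups of
ordinary functional reads fill the rest.  Two distinct functional groups
alongside a chimera group mean the chimera cannot occupy a slot of its own —
it is a fusion duplication riding on one haplotype, which therefore keeps an
intact functional copy and contributes no pathogenic allele.  With a single
functional group and a chimera group, the chimera *is* the second haplotype
(the classic heterozygous 30-kb deletion).  A single functional group alone
is reported homozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import align as al
from . import phasing as ph
from .classify import ReadClass, classify_read, demultiplex
from .interpret import DiplotypeCall, HaplotypeCall, call_diplotype
from .kb import VariantKB, default_kb
from .locus import LocusModel, revcomp

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunables of a screening run; defaults mirror the study settings."""

    seed: int = 0
    depth: int = 100
    min_depth: int = 30
    het_low: float = 0.2
    het_high: float = 0.8
    hap_min_depth: int = 5
    hap_min_frac: float = 0.5
    band: int = 80
    min_identity: float = 0.70
    conv_min_psvs: int = 2
    chimera_min_frac: float = 0.10
    substitution_rate: float = 0.003
    ins_rate: float = 0.001
    del_rate: float = 0.001

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        unknown = set(doc) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class SampleResult:
    sample_id: str
    class_counts: dict
    calls: list                    # sample-level VariantCall list
    nocall_mask: list
    diplotype: DiplotypeCall
    n_reads: int = 0
    n_aligned: int = 0
    warnings: list = field(default_factory=list)


def _orient_for_alignment(seq: str, locus: LocusModel) -> str:
    """Reads may arrive reverse-complemented; pick the orientation whose
    start matches a forward primer."""
    import edlib
    gene_f = locus.primer_set["functional"][0]
    pseudo_f = locus.primer_set["pseudo"][0]
    w = locus.primer_len + 6
    best = None
    for s in (seq, revcomp(seq)):
        head = s[:w]
        for p in (gene_f, pseudo_f):
            res = edlib.align(p, head, mode="HW", task="distance", k=3)
            d = res["editDistance"]
            if d != -1 and (best is None or d < best[0]):
                best = (d, s)
    return best[1] if best else seq


def screen_sample(reads, locus: LocusModel, kb: VariantKB | None = None,
                  config: RunConfig | None = None,
                  sample_id: str = "sample") -> SampleResult:
    """Run the full screening pipeline on one sample's (demultiplexed,
    barcode-trimmed) reads."""
    cfg = config or RunConfig()
    kb = kb or default_kb()
    counts = {c.value: 0 for c in ReadClass}
    buckets: dict[ReadClass, list] = {c: [] for c in ReadClass}
    for r in reads:
        cls = classify_read(r, locus.primer_set)
        counts[cls.value] += 1
        buckets[cls].append(r)

    to_align = (buckets[ReadClass.FUNCTIONAL] + buckets[ReadClass.DEL_CHIMERA]
                + buckets[ReadClass.CONV_CHIMERA] + buckets[ReadClass.TNX_CHIMERA])
    alignments = {}
    vectors = {}
    for r in to_align:
        seq = _orient_for_alignment(r.sequence, locus)
        aln = al.align_read(r.id, seq, locus.gene_ref, band=cfg.band,
                            min_identity=cfg.min_identity)
        if aln is None:
            log.info("read %s below identity floor; excluded", r.id)
            continue
        alignments[r.id] = aln
        vectors[r.id] = ph.psv_genotype_vector(aln, locus.psvs)

    func_ids = [r.id for r in buckets[ReadClass.FUNCTIONAL]
                if r.id in alignments]
    chim_ids = [r.id for r in
                buckets[ReadClass.DEL_CHIMERA] + buckets[ReadClass.TNX_CHIMERA]
                if r.id in alignments]
    conv_ids = [r.id for r in buckets[ReadClass.CONV_CHIMERA]
                if r.id in alignments]

    interior_index = [i for i, p in enumerate(locus.psvs) if not p.in_primer]

    # conversion refinement: functional reads with a contiguous pseudo prefix
    for rid in list(func_ids):
        if ph.conversion_prefix(vectors[rid], interior_index,
                                cfg.conv_min_psvs):
            conv_ids.append(rid)
            func_ids.remove(rid)

    # chimera groups keyed by (region, bin label)
    chim_groups = _junction_groups(chim_ids, vectors, locus,
                                   cfg.chimera_min_frac)
    conv_groups = _junction_groups(conv_ids, vectors, locus,
                                   cfg.chimera_min_frac)

    # sample-level small-variant calls from ordinary functional reads
    psv_keys = locus.psv_exclusion_keys()
    func_alns = [alignments[i] for i in func_ids]
    calls, mask = [], [(0, len(locus.gene_ref))]
    if func_alns:
        calls, mask = al.call_small_variants(
            func_alns, locus.gene_ref, cds_map=locus.cds_map,
            min_depth=cfg.min_depth, het_band=(cfg.het_low, cfg.het_high),
            exclude=psv_keys)

    # phase functional reads over het sites
    het_calls = [c for c in calls if c.zygosity == "HET"]
    read_alleles = {rid: _allele_vector(alignments[rid], het_calls)
                    for rid in func_ids}
    phase = ph.phase_reads(read_alleles) if func_ids else ph.PhaseResult([], [], [])

    hap_a, hap_b, warnings = _assemble_diplotype(
        phase, chim_groups, conv_groups, alignments, locus, kb, cfg)
    dip = call_diplotype(hap_a, hap_b, kb, sample_id=sample_id)
    dip.warnings.extend(warnings)
    return SampleResult(sample_id=sample_id, class_counts=counts, calls=calls,
                        nocall_mask=mask, diplotype=dip, n_reads=len(list(reads)),
                        n_aligned=len(alignments), warnings=warnings)


def _allele_vector(aln, het_calls):
    v = []
    for c in het_calls:
        if not aln.covers(c.gene_pos):
            v.append(None)
        elif c.key in _aln_keys(aln):
            v.append(1)
        else:
            v.append(0)
    return tuple(v)


def _aln_keys(aln):
    keys = getattr(aln, "_keys_cache", None)
    if keys is None:
        keys = set()
        for pos, base in aln.mismatches.items():
            keys.add(("SNV", pos, base))
        for pos, seq in aln.insertions.items():
            keys.add(("ins", pos, seq))
        for pos, ln in aln.deletions.items():
            keys.add(("del", pos, ln))
        aln._keys_cache = keys
    return keys


def _junction_groups(read_ids, vectors, locus, min_frac):
    """Group chimeric reads by (region, bin) of their junction; minority
    labels (sequencing-error strays) are absorbed into the nearest major
    label of the same region."""
    labels = {}
    for rid in read_ids:
        try:
            j = ph.locate_junction(vectors[rid])
        except ValueError:
            continue
        if j.is_sentinel:
            continue
        try:
            b = ph.bin_junction(j, locus.psvs, locus.all_bins())
        except ValueError:
            continue
        labels[rid] = (b.region, b.label)
    if not labels:
        return {}
    total = len(labels)
    tally: dict[tuple, list] = {}
    for rid, key in labels.items():
        tally.setdefault(key, []).append(rid)
    major = {k: v for k, v in tally.items()
             if len(v) >= max(2, min_frac * total)}
    if not major:
        biggest = max(tally, key=lambda k: len(tally[k]))
        major = {biggest: tally[biggest]}
    for k, v in tally.items():
        if k in major:
            continue
        target = min(major, key=lambda mk: (mk[0] != k[0],
                                            abs(_bin_ord(mk[1]) - _bin_ord(k[1]))))
        major[target].extend(v)
    return {k: sorted(v) for k, v in major.items()}


def _bin_ord(label: str) -> int:
    try:
        return int(label.rsplit("-", 1)[1])
    except (IndexError, ValueError):
        return 0


def _hap_variants(read_ids, alignments, locus, kb, cfg, after_pos=None):
    """Per-haplotype variant set: majority events over the group's reads."""
    alns = [alignments[i] for i in read_ids]
    if not alns:
        return ()
    depth, events = al.pileup(alns, len(locus.gene_ref))
    psv_keys = locus.psv_exclusion_keys()
    names = []
    for (kind, pos, payload), count in sorted(events.items(),
                                              key=lambda kv: (kv[0][1], kv[0][0])):
        if (kind, pos, payload) in psv_keys:
            continue
        if after_pos is not None and pos < after_pos:
            continue
        d = int(depth[pos])
        if d < cfg.hap_min_depth or count / d < cfg.hap_min_frac:
            continue
        if kind == "SNV":
            ref_a, alt_a = locus.gene_ref[pos], payload
        elif kind == "ins":
            ref_a, alt_a = locus.gene_ref[pos], locus.gene_ref[pos] + payload
        else:
            ref_a, alt_a = locus.gene_ref[pos - 1:pos + payload], \
                locus.gene_ref[pos - 1]
        from .nomenclature import format_coding_name
        names.append(format_coding_name(kind, pos, ref_a, alt_a,
                                        locus.cds_map, locus.gene_ref))
    return tuple(names)


def _junction_start(read_ids, vectors, locus):
    """Median gene-side junction coordinate of a chimera group."""
    starts = []
    for rid in read_ids:
        try:
            j = ph.locate_junction(vectors[rid])
        except ValueError:
            continue
        if not j.is_sentinel:
            starts.append(locus.psvs[j.right_psv_index].gene_pos)
    return int(np.median(starts)) if starts else 0


def _assemble_diplotype(phase, chim_groups, conv_groups, alignments,
                        locus, kb, cfg):
    """Fill the two haplotype slots from chimera, conversion and functional
    read groups (see module docstring for the assignment rules)."""
    warnings = []
    slots: list[HaplotypeCall] = []
    vectors = {rid: ph.psv_genotype_vector(alignments[rid], locus.psvs)
               for g in list(chim_groups.values()) + list(conv_groups.values())
               for rid in g}

    n_func = len(phase.groups)
    struct_items = ([("chimera", k, v) for k, v in sorted(chim_groups.items())]
                    + [("conversion", k, v) for k, v in sorted(conv_groups.items())])

    dup_mode = n_func >= 2 and struct_items
    if dup_mode:
        warnings.append("two intact functional haplotypes plus a chimera: "
                        "fusion duplication; chimeric copy is supernumerary")

    for kind, (region, label), rids in struct_items:
        if kind == "chimera":
            structure = "TNX_CHIMERA" if region == "tnx" else "DEL_CHIMERA"
        else:
            structure = "CONV_CHIMERA"
        jstart = _junction_start(rids, vectors, locus)
        variants = _hap_variants(rids, alignments, locus, kb, cfg,
                                 after_pos=jstart if kind == "chimera" else None)
        slots.append(HaplotypeCall(
            label="?", variants=variants, structure=structure, bin_label=label,
            supporting_reads=len(rids), intact_copy=False))

    func_haps = []
    for g_idx, rids in enumerate(phase.groups):
        variants = _hap_variants(rids, alignments, locus, kb, cfg)
        func_haps.append(HaplotypeCall(
            label="?", variants=variants, structure="NORMAL",
            supporting_reads=len(rids), intact_copy=True))

    if dup_mode:
        # chimera rides on one haplotype as a fusion duplication: attach to
        # the functional haplotype with fewer pathogenic variants
        chim = slots[0]
        if len(slots) > 1:
            warnings.append("multiple chimera groups with a duplication; "
                            "keeping the best-supported")
        host = min(range(len(func_haps)),
                   key=lambda i: (sum(kb.is_pathogenic(v)
                                      for v in func_haps[i].variants), i))
        h = func_haps[host]
        func_haps[host] = HaplotypeCall(
            label=h.label, variants=h.variants, structure="DUP_FUSION",
            bin_label=chim.bin_label,
            supporting_reads=h.supporting_reads + chim.supporting_reads,
            intact_copy=True, ambiguous=True)
        slots = func_haps[:2]
    else:
        slots = slots + func_haps
        if len(slots) == 0:
            slots = [HaplotypeCall("A"), HaplotypeCall("B")]
            warnings.append("no usable reads; empty diplotype")
        elif len(slots) == 1:
            only = slots[0]
            if only.structure == "NORMAL":
                # single functional group: homozygous diplotype
                slots = [only, HaplotypeCall(
                    "?", variants=only.variants, structure="NORMAL",
                    supporting_reads=only.supporting_reads, intact_copy=True)]
            else:
                # chimera with no functional reads at all: homozygous chimera
                slots = [only, only]
                warnings.append("no functional reads; chimera appears homozygous")
        elif len(slots) > 2:
            warnings.append(f"{len(slots)} haplotype groups for two slots; "
                            "keeping the best-supported two")
            slots = sorted(slots, key=lambda h: -h.supporting_reads)[:2]

    a, b = slots[0], slots[1]
    a.label, b.label = "A", "B"
    return a, b, warnings


# ---------------------------------------------------------------------------
# cohort-level runners


def screen_fastq(fastq_path, locus, kb=None, config=None, sample_id=None):
    """Screen one FASTQ; reads still carrying barcodes are primer-trimmed."""
    from dataclasses import replace

    from .classify import trim_to_amplicon
    from .simulate import read_fastq
    reads = read_fastq(fastq_path)
    if not reads:
        raise ValueError(f"no reads in {fastq_path}")
    trimmed = []
    for r in reads:
        seq = trim_to_amplicon(r.sequence, locus.primer_set)
        trimmed.append(replace(r, sequence=seq, qualities=r.qualities[:len(seq)]))
    sid = sample_id or str(fastq_path)
    return screen_sample(trimmed, locus, kb, config, sample_id=sid)


def run_cohort(specs, locus, kb=None, config=None, seed: int = 0,
               depth: int | None = None, error_model=None,
               progress: bool = False):
    """Simulate and screen every diplotype spec; returns SampleResults."""
    from .simulate import ErrorModel, simulate_reads
    cfg = config or RunConfig(seed=seed)
    kb = kb or default_kb()
    em = error_model or ErrorModel(cfg.substitution_rate, cfg.ins_rate,
                                   cfg.del_rate)
    depth = depth or cfg.depth
    results = []
    for idx, dip in enumerate(specs):
        rng = np.random.default_rng([seed, idx])
        reads = simulate_reads(dip, locus, depth, em, rng)
        blen = len(dip.barcode)
        demux = demultiplex(reads, {dip.sample_id: dip.barcode})
        sample_reads = demux[dip.sample_id]
        res = screen_sample(sample_reads, locus, kb, cfg,
                            sample_id=dip.sample_id)
        results.append(res)
        if progress:
            log.info("%s -> %s", dip.sample_id, res.diplotype.status)
    return results


def confusion_matrix(results, truth_status: dict):
    """Screening confusion counts: disease-positive means AFFECTED; CARRIER
    and NEGATIVE are screening-negative."""
    tp = fp = tn = fn = 0
    for res in results:
        called_pos = res.diplotype.status == "AFFECTED"
        true_pos = truth_status[res.sample_id] == "AFFECTED"
        if called_pos and true_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
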