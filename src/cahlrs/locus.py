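"""Toy two-paralog locus: functional gene + pseudogene with flanking segments.

The model stands in for the CYP21A2/CYP21A1P pair on 6p21.3: a ~2.1 kb gene
body (10 exons), a 3' untranslated stretch, and a downstream flank standing
in for TNXB (functional side) / TNXA (pseudogene side).  The pseudogene is
the gene with a fixed edit script applied — substitutions plus small indels
— and those edits are exactly the paralog signature variants (PSVs) that let
a read segment be attributed to one paralog or the other.

Scale rationale: the real amplicons run ~30 kb; a ~3.7 kb toy preserves the
category structure (primer-distinguishable termini, PSV-tiled body, labeled
junction bins, coding map deep enough for every knowledge-base variant)
while keeping alignment desk-sized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .align import (OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH, align_pair,
                    left_normalize_deletion, left_normalize_insertion)
from .nomenclature import CdsMap, Exon, parse_coding_name

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SignatureVariant:
    """One paralog-differentiating site, reported on gene_ref coordinates.

    SNV: gene_allele/pseudo_allele are single bases at gene_pos.
    ins: the pseudogene carries extra bases after gene_pos;
         gene_allele = anchor base, pseudo_allele = anchor + inserted.
    del: the pseudogene lacks gene bases;
         gene_allele = gene_ref[gene_pos : gene_pos+1+L], pseudo_allele = anchor.
    """

    gene_pos: int
    kind: str  # "SNV" | "ins" | "del"
    gene_allele: str
    pseudo_allele: str
    in_primer: bool = False


@dataclass(frozen=True)
class JunctionBin:
    label: str
    start: int  # gene_ref coords, half-open
    end: int
    region: str  # "gene" (CYP21A1P/CYP21A2 classes) or "tnx" (TNXA/TNXB)


@dataclass
class LocusConfig:
    """Parameters of the toy locus build (defaults define the study locus)."""

    seed: int = 1021
    leader_len: int = 100          # 5' segment before exon 1
    exon_sizes: tuple = (146, 146, 150, 150, 150, 150, 150, 150, 150, 158)
    intron_len: int = 70
    total_len: int = 3700
    flank_start: int = 3100        # TNX stand-in begins here
    primer_len: int = 20
    # edit script sizes (all edits are PSVs)
    n_body_sub: int = 24
    n_body_ins: int = 2
    n_body_del: int = 1
    indel_len: int = 2
    n_flank_sub: int = 9
    n_terminal_sub: int = 3        # forced per terminus, inside the primers
    body_psv_start: int = 40
    body_psv_end: int = 3080
    flank_psv_start: int = 3110
    flank_psv_end: int = 3675
    n_gene_bins: int = 9
    min_psv_gap: int = 8
    # knowledge-base variants whose reference alleles the build guarantees
    required_variants: tuple = (
        "c.92C>T", "c.293-13C>G", "c.518T>A", "c.740del", "c.844G>T",
        "c.923dup", "c.955C>T", "c.1069C>T", "c.*1215C>T", "c.*1316C>T",
        "c.*1351G>C",
    )


@dataclass
class LocusModel:
    gene_ref: str
    pseudo_ref: str
    primer_set: dict          # category -> (forward, reverse) primer pair
    cds_map: CdsMap
    psvs: list                # list[SignatureVariant], sorted by gene_pos
    junction_bins: list       # gene-body bins CH-1..CH-k
    tnx_bins: list            # flank bins (TNXA/TNXB namespace)
    primer_len: int = 20
    config: LocusConfig | None = None
    g2p: np.ndarray = field(default=None, repr=False)  # gene->pseudo coords

    @property
    def interior_psvs(self):
        return [p for p in self.psvs if not p.in_primer]

    def all_bins(self):
        return list(self.junction_bins) + list(self.tnx_bins)

    def psv_exclusion_keys(self) -> set:
        """Pileup keys of pseudo alleles at PSV sites (paralog signal, not
        mutations), in the caller's left-normalized convention."""
        keys = set()
        for p in self.psvs:
            if p.kind == "SNV":
                keys.add(("SNV", p.gene_pos, p.pseudo_allele))
            elif p.kind == "ins":
                anchor, seq = left_normalize_insertion(
                    self.gene_ref, p.gene_pos, p.pseudo_allele[1:])
                keys.add(("ins", anchor, seq))
            else:
                ln = len(p.gene_allele) - 1
                pos = left_normalize_deletion(self.gene_ref, p.gene_pos + 1, ln)
                keys.add(("del", pos, ln))
        return keys

    # -- serialization -----------------------------------------------------
    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        recs = [SeqRecord(Seq(self.gene_ref), id="CYP21A2_TNXB_toy",
                          description="functional gene + downstream flank"),
                SeqRecord(Seq(self.pseudo_ref), id="CYP21A1P_TNXA_toy",
                          description="pseudogene + downstream flank")]
        SeqIO.write(recs, path, "fasta")

    def write_metadata(self, path) -> None:
        doc = {
            "primer_set": {k: list(v) for k, v in self.primer_set.items()},
            "primer_len": self.primer_len,
            "cds_map": self.cds_map.to_dict(),
            "psvs": [asdict(p) for p in self.psvs],
            "junction_bins": [asdict(b) for b in self.junction_bins],
            "tnx_bins": [asdict(b) for b in self.tnx_bins],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


class LocusBuildError(ValueError):
    pass


def _alignment_events(gene: str, pseudo: str, band: int = 120):
    """Run-length events of the pseudo-vs-gene alignment on gene coords."""
    score, ref_start, ops = align_pair(pseudo, gene, band=band)
    events = []
    i = 0  # pseudo cursor
    j = ref_start
    for op, ln in ops:
        if op == OP_MATCH:
            i += ln
            j += ln
        elif op == OP_MISMATCH:
            for t in range(ln):
                events.append(("SNV", j + t, pseudo[i + t]))
            i += ln
            j += ln
        elif op == OP_INS:  # pseudo has extra bases
            events.append(("ins", j - 1, pseudo[i:i + ln]))
            i += ln
        else:  # pseudo lacks gene bases
            events.append(("del", j, ln))
            j += ln
    ncols = sum(ln for _, ln in ops)
    nmatch = sum(ln for op, ln in ops if op == OP_MATCH)
    return events, (nmatch / ncols if ncols else 0.0), (ref_start, j)


def derive_signature_variants(gene_ref: str, pseudo_ref: str,
                              primer_len: int = 20) -> list:
    """PSVs from a global affine-gap alignment of the two references.

    Every mismatch column becomes one SNV PSV; every gap run one indel PSV.
    Positions are on gene_ref, sorted ascending.
    """
    if not gene_ref or not pseudo_ref:
        raise ValueError("empty reference")
    if set(gene_ref) - set(BASES) or set(pseudo_ref) - set(BASES):
        raise ValueError("alphabet must be ACGT")
    events, identity, _span = _alignment_events(gene_ref, pseudo_ref)
    if identity < 0.5:
        raise LocusBuildError(
            f"references align at {identity:.0%} identity; not homologous")
    psvs = []
    n = len(gene_ref)
    for kind, pos, payload in events:
        in_primer = pos < primer_len + 5 or pos >= n - primer_len - 5
        if kind == "SNV":
            psvs.append(SignatureVariant(pos, "SNV", gene_ref[pos], payload,
                                         in_primer))
        elif kind == "ins":
            anchor, seq = left_normalize_insertion(gene_ref, pos, payload)
            psvs.append(SignatureVariant(anchor, "ins", gene_ref[anchor],
                                         gene_ref[anchor] + seq, in_primer))
        else:
            p = left_normalize_deletion(gene_ref, pos, payload)
            psvs.append(SignatureVariant(p - 1, "del",
                                         gene_ref[p - 1:p + payload],
                                         gene_ref[p - 1], in_primer))
    psvs.sort(key=lambda p: p.gene_pos)
    return psvs


def _build_cds_map(cfg: LocusConfig) -> CdsMap:
    exons = []
    pos = cfg.leader_len
    cds = 1
    for size in cfg.exon_sizes:
        exons.append(Exon(pos, pos + size, cds))
        cds += size
        pos += size + cfg.intron_len
    return CdsMap(exons)


def _spread_positions(rng, start, end, count, forbidden, min_gap):
    """Deterministic near-uniform positions avoiding forbidden sites."""
    grid = np.linspace(start, end - 1, count)
    jitter = 4 * min_gap
    out = []
    for g in grid:
        for _ in range(500):
            pos = int(round(g + rng.integers(-jitter, jitter + 1)))
            pos = max(start, min(end - 1, pos))
            if all(abs(pos - f) >= min_gap for f in forbidden) and \
               all(abs(pos - o) >= min_gap for o in out):
                out.append(pos)
                break
        else:  # pragma: no cover - config error
            raise LocusBuildError("could not place PSVs; relax config")
    return sorted(out)


def _other_base(rng, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


def build_toy_locus(config: LocusConfig | None = None) -> LocusModel:
    """Deterministically build the paired references and all locus metadata.

    Raises LocusBuildError for configurations whose primers would occur in
    both references (reads could not be classified unambiguously).
    """
    cfg = config or LocusConfig()
    n_edits = (cfg.n_body_sub + cfg.n_body_ins + cfg.n_body_del
               + cfg.n_flank_sub + 2 * cfg.n_terminal_sub)
    if cfg.total_len < 1500:
        raise ValueError("total_len must be >= 1500")
    if not 0 < n_edits / cfg.total_len <= 0.1:
        raise ValueError("divergence must lie in (0, 0.1]")
    rng = np.random.default_rng(cfg.seed)
    cds_map = _build_cds_map(cfg)
    if cds_map.last_coding_pos >= cfg.flank_start:
        raise LocusBuildError("CDS extends into the flank")

    gene = rng.integers(0, 4, cfg.total_len)
    gene_ref = list("".join(BASES[b] for b in gene))

    # force knowledge-base reference alleles and indel-stable contexts
    kb_positions = []
    for name in cfg.required_variants:
        from .nomenclature import _INDEL_RE, _SUB_RE, _normalize
        norm = _normalize(name)
        m = _SUB_RE.match(norm)
        if m:
            n = int(m.group("n"))
            pos = (cds_map.utr3_to_genomic(n) if m.group("star")
                   else cds_map.coding_to_genomic(n)
                   + (int(m.group("off")) if m.group("off") else 0))
            gene_ref[pos] = m.group("ref")
        else:
            m = _INDEL_RE.match(norm)
            pos = cds_map.coding_to_genomic(int(m.group("n")))
            # non-repetitive context keeps left-normalization at pos
            while gene_ref[pos] in (gene_ref[pos - 1], gene_ref[pos + 1]):
                gene_ref[pos] = _other_base(rng, gene_ref[pos])
        kb_positions.append(pos)
    gene_ref = "".join(gene_ref)

    forbidden = set()
    for p in kb_positions:
        forbidden.update(range(p - 3, p + 4))

    body_sites = _spread_positions(rng, cfg.body_psv_start, cfg.body_psv_end,
                                   cfg.n_body_sub + cfg.n_body_ins + cfg.n_body_del,
                                   forbidden, cfg.min_psv_gap)
    # indels placed away from bin edges: take evenly spaced interior picks
    idx = rng.choice(np.arange(2, len(body_sites) - 2),
                     size=cfg.n_body_ins + cfg.n_body_del, replace=False)
    indel_sites = sorted(int(body_sites[i]) for i in idx)
    flank_sites = _spread_positions(rng, cfg.flank_psv_start, cfg.flank_psv_end,
                                    cfg.n_flank_sub, forbidden, cfg.min_psv_gap)
    pl = cfg.primer_len
    term5 = sorted(rng.choice(np.arange(2, pl - 2), cfg.n_terminal_sub,
                              replace=False).tolist())
    term3 = sorted((cfg.total_len - pl + 2
                    + rng.choice(np.arange(0, pl - 4), cfg.n_terminal_sub,
                                 replace=False)).tolist())

    # edit script on gene coordinates (applied right-to-left)
    script = []  # (pos, kind, payload)
    for pos in term5 + body_sites + flank_sites + term3:
        if pos in indel_sites:
            continue
        script.append((pos, "SNV", _other_base(rng, gene_ref[pos])))
    for k, pos in enumerate(indel_sites):
        if k < cfg.n_body_ins:
            ins = "".join(BASES[rng.integers(0, 4)] for _ in range(cfg.indel_len))
            # avoid repeat context so the event left-normalizes to its anchor
            while ins[-1] == gene_ref[pos] or ins[0] == gene_ref[pos + 1]:
                ins = "".join(BASES[rng.integers(0, 4)]
                              for _ in range(cfg.indel_len))
            script.append((pos, "ins", ins))
        else:
            script.append((pos, "del", cfg.indel_len))
    script.sort()

    pseudo = list(gene_ref)
    for pos, kind, payload in reversed(script):
        if kind == "SNV":
            pseudo[pos] = payload
        elif kind == "ins":
            pseudo[pos + 1:pos + 1] = list(payload)
        else:
            del pseudo[pos + 1:pos + 1 + payload]
    pseudo_ref = "".join(pseudo)

    psvs = derive_signature_variants(gene_ref, pseudo_ref, cfg.primer_len)

    # primers: the four category-defining pairs (forward, reverse)
    gene_f, gene_r = gene_ref[:pl], revcomp(gene_ref[-pl:])
    pseudo_f, pseudo_r = pseudo_ref[:pl], revcomp(pseudo_ref[-pl:])
    primer_set = {
        "functional": (gene_f, gene_r),
        "pseudo": (pseudo_f, pseudo_r),
        "del_chimera": (pseudo_f, gene_r),
        "conv_chimera": (gene_f, gene_r),
    }
    _check_primers(gene_ref, pseudo_ref, gene_f, gene_r, pseudo_f, pseudo_r)

    interior = [p for p in psvs
                if cfg.body_psv_start <= p.gene_pos < cfg.body_psv_end]
    gene_bins = _make_bins(interior, cfg.n_gene_bins, "gene", "CH-")
    flank_psvs = [p for p in psvs
                  if cfg.flank_psv_start - 5 <= p.gene_pos < cfg.flank_psv_end + 5
                  and not p.in_primer]
    tnx_bins = _make_bins(flank_psvs, 1, "tnx", "CH-")

    g2p = _coordinate_map(gene_ref, script)
    return LocusModel(gene_ref=gene_ref, pseudo_ref=pseudo_ref,
                      primer_set=primer_set, cds_map=cds_map, psvs=psvs,
                      junction_bins=gene_bins, tnx_bins=tnx_bins,
                      primer_len=pl, config=cfg, g2p=g2p)


def _check_primers(gene_ref, pseudo_ref, gene_f, gene_r, pseudo_f, pseudo_r):
    import edlib

    def hits(primer, ref, k=1):
        res = edlib.align(primer, ref, mode="HW", task="locations", k=k)
        return 0 if res["editDistance"] == -1 else len(res["locations"])

    for primer, home, away in ((gene_f, gene_ref, pseudo_ref),
                               (revcomp(gene_r), gene_ref, pseudo_ref),
                               (pseudo_f, pseudo_ref, gene_ref),
                               (revcomp(pseudo_r), pseudo_ref, gene_ref)):
        if hits(primer, home, k=0) != 1:
            raise LocusBuildError("primer not unique in its own reference")
        if hits(primer, away, k=1) != 0:
            raise LocusBuildError(
                "primer occurs in both references; classification ambiguous")


def _make_bins(psvs, k, region, prefix):
    if len(psvs) < k:
        raise LocusBuildError("not enough PSVs for the requested bins")
    pos = [p.gene_pos for p in psvs]
    per = len(pos) / k
    edges = [pos[0]]
    for i in range(1, k):
        a = pos[int(round(i * per)) - 1]
        b = pos[int(round(i * per))]
        edges.append((a + b + 1) // 2)
    edges.append(pos[-1] + 1)
    return [JunctionBin(f"{prefix}{i + 1}", edges[i], edges[i + 1], region)
            for i in range(k)]


def _coordinate_map(gene_ref: str, script) -> np.ndarray:
    """g2p[i] = pseudo coordinate of gene position i (gene bases deleted in
    the pseudogene map to the next existing pseudo base)."""
    n = len(gene_ref)
    events = {pos: (kind, payload) for pos, kind, payload in script
              if kind in ("ins", "del")}
    g2p = np.zeros(n + 1, dtype=np.int64)
    p = 0
    i = 0
    while i < n:
        g2p[i] = p
        p += 1
        if i in events:
            kind, payload = events[i]
            if kind == "ins":
                p += len(payload)
                i += 1
            else:
                for t in range(1, payload + 1):
                    if i + t <= n:
                        g2p[i + t] = p
                i += payload + 1
        else:
            i += 1
    g2p[n] = p
    return g2p


def parse_required_variant(name: str, locus: LocusModel):
    return parse_coding_name(name, locus.cds_map, locus.gene_ref)
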