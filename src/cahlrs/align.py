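"""Affine-gap semi-global alignment and pileup-based small-variant calling.

Classified amplicon reads are aligned to the functional-gene reference with
a banded Gotoh algorithm (glocal: the read must be aligned end to end, the
reference may contribute unaligned flanks).  Full-length amplicon reads stay
close to the main diagonal, so a band of a few tens of columns is exact in
practice; tests compare against an unbanded full-matrix oracle.

Variant calling is a straight count-based pileup: circular-consensus reads
at >=Q20 make base qualities nearly uninformative, so genotypes are decided
from allele fractions alone with a hard minimum-depth floor (30x by
default).  Indels are left-normalized to the VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

NEG_INF = np.int64(-(10**9))

# op codes used in traceback results
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # base present in read, absent from reference
OP_DEL = 3  # reference base absent from read


@dataclass(frozen=True)
class Scoring:
    """Affine-gap DNA scoring. A gap of length L costs open + extend*L."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """Semi-global alignment of one read against the gene reference."""

    read_id: str
    ref_start: int
    ref_end: int
    score: int
    ops: list  # [(op_code, length), ...] along the alignment
    identity: float
    # variant-style decompositions (left-normalized)
    mismatches: dict = field(default_factory=dict)  # ref_pos -> read base
    insertions: dict = field(default_factory=dict)  # anchor pos -> inserted seq
    deletions: dict = field(default_factory=dict)  # first deleted pos -> length

    def deleted_intervals(self):
        return [(p, p + ln) for p, ln in self.deletions.items()]

    def covers(self, pos: int) -> bool:
        return self.ref_start <= pos < self.ref_end


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@njit(cache=True)
def _gotoh_banded(q, r, lo, hi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    width = hi - lo + 1
    H = np.full((m + 1, width), NEG_INF, dtype=np.int64)
    E = np.full((m + 1, width), NEG_INF, dtype=np.int64)  # gap in read (del)
    F = np.full((m + 1, width), NEG_INF, dtype=np.int64)  # gap in ref (ins)
    ptrH = np.zeros((m + 1, width), dtype=np.uint8)  # 0 diag, 1 from E, 2 from F
    ptrE = np.zeros((m + 1, width), dtype=np.uint8)  # 0 open, 1 extend
    ptrF = np.zeros((m + 1, width), dtype=np.uint8)

    # row 0: free reference prefix
    j0 = 0 if lo < 0 else lo
    j1 = n if hi > n else hi
    for j in range(j0, j1 + 1):
        H[0, j - lo] = 0

    for i in range(1, m + 1):
        jlow = i + lo
        if jlow < 0:
            jlow = 0
        jhigh = i + hi
        if jhigh > n:
            jhigh = n
        if jlow > jhigh:
            continue
        for j in range(jlow, jhigh + 1):
            k = j - i - lo
            if j == 0:
                # leading read bases inserted before the reference
                F[i, k] = gap_open + gap_extend * i
                ptrF[i, k] = 1 if i > 1 else 0
                H[i, k] = F[i, k]
                ptrH[i, k] = 2
                continue
            # E: consume r[j-1] with a gap in the read
            km1 = k - 1  # (i, j-1)
            if km1 >= 0:
                e_open = H[i, km1] + gap_open + gap_extend
                e_ext = E[i, km1] + gap_extend
                if e_ext > e_open:
                    E[i, k] = e_ext
                    ptrE[i, k] = 1
                else:
                    E[i, k] = e_open
                    ptrE[i, k] = 0
            # F: consume q[i-1] with a gap in the reference; (i-1, j) is k+1
            kp1 = k + 1
            if kp1 < width:
                f_open = H[i - 1, kp1] + gap_open + gap_extend
                f_ext = F[i - 1, kp1] + gap_extend
                if f_ext > f_open:
                    F[i, k] = f_ext
                    ptrF[i, k] = 1
                else:
                    F[i, k] = f_open
                    ptrF[i, k] = 0
            # H: diagonal or close a gap
            s = match if q[i - 1] == r[j - 1] else mismatch
            best = H[i - 1, k] + s  # (i-1, j-1) shares k
            ptr = 0
            if E[i, k] > best:
                best = E[i, k]
                ptr = 1
            if F[i, k] > best:
                best = F[i, k]
                ptr = 2
            H[i, k] = best
            ptrH[i, k] = ptr

    # best end: free reference suffix on the last row
    best_score = NEG_INF
    best_j = -1
    jlow = m + lo
    if jlow < 0:
        jlow = 0
    jhigh = m + hi
    if jhigh > n:
        jhigh = n
    for j in range(jlow, jhigh + 1):
        k = j - m - lo
        if H[m, k] > best_score:
            best_score = H[m, k]
            best_j = j

    # traceback
    ops = np.empty(m + n + 2, dtype=np.uint8)
    nops = 0
    i = m
    j = best_j
    state = 0  # 0 H, 1 E, 2 F
    while i > 0:
        k = j - i - lo
        if state == 0:
            p = ptrH[i, k]
            if p == 0:
                if j == 0:
                    # j==0 H was set from F
                    state = 2
                    continue
                ops[nops] = OP_MATCH if q[i - 1] == r[j - 1] else OP_MISMATCH
                nops += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = OP_DEL
            nops += 1
            if ptrE[i, k] == 0:
                state = 0
            j -= 1
        else:
            ops[nops] = OP_INS
            nops += 1
            if ptrF[i, k] == 0:
                state = 0
            i -= 1
    ref_start = j
    return best_score, ref_start, ops[:nops][::-1].copy()


def band_limits(m: int, n: int, band: int) -> tuple[int, int]:
    """Diagonal window (on j - i) wide enough for drift plus `band` slack."""
    d = n - m
    return (min(0, d) - band, max(0, d) + band)


def align_pair(query: str, ref: str, scoring: Scoring = DEFAULT_SCORING,
               band: int | None = None) -> tuple[int, int, list]:
    """Align query to ref (glocal); returns (score, ref_start, run-length ops).

    band=None performs an exact (full-width) alignment.
    """
    if not query or not ref:
        raise ValueError("empty sequence")
    m, n = len(query), len(ref)
    if band is None:
        band = max(m, n)
    lo, hi = band_limits(m, n, band)
    score, ref_start, flat = _gotoh_banded(
        _encode(query), _encode(ref), lo, hi,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    ops: list[tuple[int, int]] = []
    for op in flat:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((int(op), 1))
    return int(score), int(ref_start), ops


def left_normalize_deletion(ref: str, pos: int, length: int, floor: int = 0) -> int:
    """Shift a deletion of ref[pos:pos+length] as far left as equivalent."""
    while pos > floor and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def left_normalize_insertion(ref: str, anchor: int, seq: str, floor: int = 0
                             ) -> tuple[int, str]:
    """Shift an insertion placed after ref[anchor] as far left as equivalent."""
    while anchor >= floor and anchor >= 0 and ref[anchor] == seq[-1]:
        seq = ref[anchor] + seq[:-1]
        anchor -= 1
    return anchor, seq


def align_read(read_id: str, seq: str, ref: str,
               scoring: Scoring = DEFAULT_SCORING, band: int = 80,
               min_identity: float = 0.70) -> Alignment | None:
    """Align one read; returns None when identity falls below min_identity.

    Flagged (None) reads are excluded from pileups.
    """
    eff_band = max(band, abs(len(seq) - len(ref)) + 10)
    score, ref_start, ops = align_pair(seq, ref, scoring, band=eff_band)
    ncols = sum(ln for _, ln in ops)
    nmatch = sum(ln for op, ln in ops if op == OP_MATCH)
    identity = nmatch / ncols if ncols else 0.0
    aln = Alignment(read_id=read_id, ref_start=ref_start, ref_end=ref_start,
                    score=score, ops=ops, identity=identity)
    if identity < min_identity:
        return None
    # decompose into variant events
    i = 0  # read cursor
    j = ref_start
    for op, ln in ops:
        if op == OP_MATCH:
            i += ln
            j += ln
        elif op == OP_MISMATCH:
            for t in range(ln):
                aln.mismatches[j + t] = seq[i + t]
            i += ln
            j += ln
        elif op == OP_INS:
            ins = seq[i:i + ln]
            anchor = j - 1
            anchor, ins = left_normalize_insertion(ref, anchor, ins, floor=ref_start)
            aln.insertions[anchor] = ins
            i += ln
        else:  # OP_DEL
            pos = left_normalize_deletion(ref, j, ln, floor=ref_start)
            aln.deletions[pos] = ln
            j += ln
    aln.ref_end = j
    return aln


# ---------------------------------------------------------------------------
# pileup & variant calling


@dataclass(frozen=True)
class VariantCall:
    gene_pos: int
    ref: str
    alt: str
    kind: str  # "SNV" | "ins" | "del"
    depth: int
    alt_count: int
    zygosity: str  # "HET" | "HOM"
    name: str = ""

    @property
    def key(self):
        return variant_key(self.kind, self.gene_pos, self.alt_payload)

    @property
    def alt_payload(self):
        if self.kind == "SNV":
            return self.alt
        if self.kind == "ins":
            return self.alt[1:]
        return len(self.ref) - 1


def variant_key(kind: str, pos: int, payload) -> tuple:
    """Canonical (kind, pos, payload) identity used across modules.

    payload: alt base for SNVs, inserted sequence for insertions, deleted
    length for deletions. Positions are the left-normalized 0-based anchors
    (first deleted base for deletions, base before the event for insertions).
    """
    return (kind, pos, payload)


def pileup(alignments: list[Alignment], ref_len: int):
    """Depth vector plus per-event alternate counts."""
    depth = np.zeros(ref_len, dtype=np.int64)
    events: dict[tuple, int] = {}
    for aln in alignments:
        depth[aln.ref_start:aln.ref_end] += 1
        for pos, base in aln.mismatches.items():
            key = variant_key("SNV", pos, base)
            events[key] = events.get(key, 0) + 1
        for anchor, seq in aln.insertions.items():
            key = variant_key("ins", anchor, seq)
            events[key] = events.get(key, 0) + 1
        for pos, ln in aln.deletions.items():
            key = variant_key("del", pos, ln)
            events[key] = events.get(key, 0) + 1
    return depth, events


def call_small_variants(alignments: list[Alignment], ref: str, cds_map=None,
                        min_depth: int = 30, het_band=(0.2, 0.8),
                        exclude: set | None = None):
    """Count-based diploid calls from a read pileup.

    Returns (calls, nocall_mask) where nocall_mask lists 0-based half-open
    intervals whose depth is below min_depth.  `exclude` suppresses known
    paralog-signature alleles so that pseudogene-derived segments are not
    reported as mutations.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    low, high = het_band
    depth, events = pileup(alignments, len(ref))
    calls = []
    for (kind, pos, payload), count in sorted(events.items()):
        if exclude and (kind, pos, payload) in exclude:
            continue
        d = int(depth[pos])
        if d < min_depth:
            continue
        frac = count / d
        if frac < low:
            continue
        zyg = "HOM" if frac >= high else "HET"
        if kind == "SNV":
            ref_a, alt_a = ref[pos], payload
        elif kind == "ins":
            ref_a, alt_a = ref[pos], ref[pos] + payload
        else:
            ref_a, alt_a = ref[pos - 1:pos + payload], ref[pos - 1]
        name = ""
        if cds_map is not None:
            from .nomenclature import format_coding_name
            name = format_coding_name(kind, pos, ref_a, alt_a, cds_map, ref)
        calls.append(VariantCall(gene_pos=pos, ref=ref_a, alt=alt_a, kind=kind,
                                 depth=d, alt_count=count, zygosity=zyg,
                                 name=name))
    # no-call mask
    mask = []
    in_low = False
    start = 0
    for i in range(len(ref) + 1):
        low_here = i < len(ref) and depth[i] < min_depth
        if low_here and not in_low:
            start, in_low = i, True
        elif not low_here and in_low:
            mask.append((start, i))
            in_low = False
    return calls, mask


def write_vcf(calls: list[VariantCall], contig: str, ref_len: int, path) -> None:
    """Minimal VCF 4.2 with GT:DP:AD, one sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={ref_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for c in calls:
            pos1 = c.gene_pos + 1 if c.kind != "del" else c.gene_pos  # anchored
            gt = "1/1" if c.zygosity == "HOM" else "0/1"
            ad = f"{c.depth - c.alt_count},{c.alt_count}"
            fh.write(f"{contig}\t{pos1}\t{c.name or '.'}\t{c.ref}\t{c.alt}\t.\t"
                     f"PASS\t.\tGT:DP:AD\t{gt}:{c.depth}:{ad}\n")


def write_bed_mask(mask, contig: str, path) -> None:
    with open(path, "w") as fh:
        for start, end in mask:
            fh.write(f"{contig}\t{start}\t{end}\tLOW_DEPTH\n")
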