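"""Barcode demultiplexing and primer-pair read classification.

A read is attributed to a sample when its leading barcode matches a table
entry within one edit, and to an amplicon category by the primer pair found
at its termini: (gene-F, gene-R) -> FUNCTIONAL, (pseudo-F, pseudo-R) ->
PSEUDO, (pseudo-F, gene-R) -> DEL_CHIMERA (refined to a TNXA/TNXB class
later from the junction position).  Primer matching tolerates one edit
(substitution or indel) — single errors in a 20-mer are common at CCS error
rates and an indel breaks any fixed-offset comparison.  Classification is
orientation-insensitive and never drops reads: unmatched ones are UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import edlib

from .locus import revcomp
from .simulate import ReadRecord


class ReadClass(str, Enum):
    FUNCTIONAL = "FUNCTIONAL"
    PSEUDO = "PSEUDO"
    DEL_CHIMERA = "DEL_CHIMERA"
    CONV_CHIMERA = "CONV_CHIMERA"
    TNX_CHIMERA = "TNX_CHIMERA"
    UNASSIGNED = "UNASSIGNED"


def _edit_distance(a: str, b: str, k: int) -> int:
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    return res["editDistance"]


def _find_in_window(primer: str, window: str, max_edits: int):
    """Best infix match of primer in window.

    Returns (distance, start, end_exclusive) or None.
    """
    res = edlib.align(primer, window, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def check_barcode_table(barcodes: dict[str, str], min_dist: int = 3) -> None:
    items = list(barcodes.items())
    for i, (sa, a) in enumerate(items):
        for sb, b in items[i + 1:]:
            if len(a) != len(b):
                raise ValueError("barcodes must share a length")
            d = sum(x != y for x, y in zip(a, b))
            if d < min_dist:
                raise ValueError(
                    f"barcodes {sa}/{sb} are only {d} mismatches apart "
                    f"(>= {min_dist} required)")


def demultiplex(reads: list[ReadRecord], barcodes: dict[str, str],
                max_edits: int = 1, trim: bool = True
                ) -> dict[str, list[ReadRecord]]:
    """Split reads by leading barcode; orientation-normalizes and trims.

    Returns sample -> reads, with unmatched reads under "undetermined".
    The bin sizes always sum to the input size.
    """
    check_barcode_table(barcodes)
    blen = len(next(iter(barcodes.values()))) if barcodes else 0
    out: dict[str, list[ReadRecord]] = {s: [] for s in barcodes}
    out["undetermined"] = []
    for read in reads:
        assigned = None
        for seq in (read.sequence, revcomp(read.sequence)):
            window = seq[:blen + max_edits + 1]
            best = None
            for sample, bc in barcodes.items():
                hit = _find_in_window(bc, window, max_edits)
                if hit and (best is None or hit[0] < best[0]):
                    best = (hit[0], hit[2], sample)
            if best:
                dist, end, sample = best
                new = seq[end:]
                if trim:
                    bc = barcodes[sample]
                    tail_w = new[-(blen + max_edits + 1):]
                    hit = _find_in_window(revcomp(bc), tail_w, max_edits)
                    if hit is not None:
                        cut = len(new) - len(tail_w) + hit[1]
                    else:
                        cut = max(0, len(new) - blen)
                    new = new[:cut]
                assigned = (sample, replace(
                    read, sequence=new, qualities=read.qualities[:len(new)]))
                break
        if assigned:
            out[assigned[0]].append(assigned[1])
        else:
            out["undetermined"].append(read)
    return out


def classify_read(read: ReadRecord | str, primer_set: dict,
                  primer_len: int | None = None, window_slack: int = 5,
                  max_edits: int = 1, rescue_edits: int = 2) -> ReadClass:
    """Assign one read to an amplicon category by its terminal primer pair.

    Both orientations are tried; the category is decided by which forward
    primer starts the read and which reverse primer ends it, each within
    max_edits.  One terminus may be rescued at up to rescue_edits when its
    mate matched within max_edits and the paralog assignment is unambiguous
    (strictly better than the competing primer) — without the rescue, a
    single doubly-corrupted 20-mer would discard the read even though the
    intact mate plus a clear best match leave no real ambiguity.
    """
    seq = read if isinstance(read, str) else read.sequence
    gene_f, gene_r = primer_set["functional"]
    pseudo_f, pseudo_r = primer_set["pseudo"]
    plen = primer_len or len(gene_f)
    w = plen + window_slack
    k = max(max_edits, rescue_edits)
    for s in (seq, revcomp(seq)):
        head, tail = s[:w], s[-w:]
        fwd = _pick(_find_in_window(gene_f, head, k),
                    _find_in_window(pseudo_f, head, k))
        rev = _pick(_find_in_window(revcomp(gene_r), tail, k),
                    _find_in_window(revcomp(pseudo_r), tail, k))
        if not (fwd and rev):
            continue
        d_f, d_r = fwd[0][0], rev[0][0]
        if not (max(d_f, d_r) <= max_edits
                or (min(d_f, d_r) <= max_edits
                    and max(d_f, d_r) <= rescue_edits)):
            continue
        if fwd[1] == "gene" and rev[1] == "gene":
            if "conv" in primer_set:  # dedicated conversion design
                conv_f = primer_set["conv"][0]
                if _find_in_window(conv_f, head, max_edits):
                    return ReadClass.CONV_CHIMERA
            return ReadClass.FUNCTIONAL
        if fwd[1] == "pseudo" and rev[1] == "pseudo":
            return ReadClass.PSEUDO
        if fwd[1] == "pseudo" and rev[1] == "gene":
            return ReadClass.DEL_CHIMERA
    return ReadClass.UNASSIGNED


def _pick(gene_hit, pseudo_hit):
    """Best paralog primer; ambiguous (equal-distance) hits are discarded."""
    if gene_hit and pseudo_hit and gene_hit[0] == pseudo_hit[0]:
        return None
    if gene_hit and (not pseudo_hit or gene_hit[0] < pseudo_hit[0]):
        return gene_hit, "gene"
    if pseudo_hit:
        return pseudo_hit, "pseudo"
    return None


def trim_to_amplicon(seq: str, primer_set: dict, max_lead: int = 30,
                     max_edits: int = 2) -> str:
    """Primer-anchored trimming for reads that still carry barcodes.

    Locates a forward primer near the 5' end and a reverse primer near the
    3' end (either paralog, either orientation) and cuts the read down to
    the primer-to-primer amplicon.  Already-trimmed reads pass unchanged;
    reads without locatable primers are returned as-is.
    """
    gene_f, gene_r = primer_set["functional"]
    pseudo_f, pseudo_r = primer_set["pseudo"]
    plen = len(gene_f)
    w = plen + max_lead
    for s in (seq, revcomp(seq)):
        head, tail = s[:w], s[-w:]
        start = None
        for p in (gene_f, pseudo_f):
            hit = _find_in_window(p, head, max_edits)
            if hit and (start is None or hit[0] < start[0]):
                start = (hit[0], hit[1])
        if start is None:
            continue
        end = None
        for p in (gene_r, pseudo_r):
            hit = _find_in_window(revcomp(p), tail, max_edits)
            if hit and (end is None or hit[0] < end[0]):
                end = (hit[0], hit[2])
        if end is None:
            continue
        return s[start[1]:len(s) - len(tail) + end[1]]
    return seq


def classify_reads(reads, primer_set, **kw):
    """Bulk classification preserving input order: [(read, ReadClass), ...]."""
    return [(r, classify_read(r, primer_set, **kw)) for r in reads]


def write_classification_report(rows, path) -> None:
    """TSV report: read_id, sample, class."""
    with open(path, "w") as fh:
        fh.write("read_id\tsample\tclass\n")
        for read_id, sample, cls in rows:
            fh.write(f"{read_id}\t{sample}\t{cls}\n")
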