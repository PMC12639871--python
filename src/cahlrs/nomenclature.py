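"""Coding-style (HGVS subset) variant names on the toy gene model.

Supported grammar, matching the notation used for CYP21A2 in the clinical
literature (spacing and unicode dashes are normalized away):

    c.N R>A          exonic substitution
    c.N-M R>A        intronic substitution, M bases 5' of the exon base N
    c.N+M R>A        intronic substitution, M bases 3' of the exon base N
    c.Ndup           single-base duplication
    c.Ndel           single-base deletion
    c.*N R>A         3'UTR substitution, N bases past the last coding base

Coding positions are 1-based per convention; genomic positions on the toy
reference are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class CodingNameError(ValueError):
    """The name does not match the supported grammar."""


class ReferenceMismatchError(ValueError):
    """The name parsed, but its reference allele contradicts gene_ref."""


@dataclass(frozen=True)
class Exon:
    start: int       # genomic, 0-based
    end: int         # genomic, half-open
    cds_start: int   # 1-based coding number of the exon's first base

    @property
    def cds_end(self) -> int:
        return self.cds_start + (self.end - self.start) - 1


@dataclass(frozen=True)
class GenomicVariant:
    name: str
    gene_pos: int
    ref: str
    alt: str
    kind: str  # "SNV" | "ins" | "del" | "dup"


class CdsMap:
    """Ordered exon intervals with coding coordinates (single + strand)."""

    def __init__(self, exons: list[Exon]):
        if not exons:
            raise ValueError("empty exon list")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end or b.cds_start != a.cds_end + 1:
                raise ValueError("exons must be ordered and contiguous in cds")
        self.exons = list(exons)

    @property
    def cds_len(self) -> int:
        return self.exons[-1].cds_end

    @property
    def last_coding_pos(self) -> int:
        return self.exons[-1].end - 1

    def coding_to_genomic(self, n: int) -> int:
        for ex in self.exons:
            if ex.cds_start <= n <= ex.cds_end:
                return ex.start + (n - ex.cds_start)
        raise CodingNameError(f"coding position {n} outside CDS (1..{self.cds_len})")

    def utr3_to_genomic(self, n: int) -> int:
        return self.last_coding_pos + n

    def genomic_to_coding(self, pos: int):
        """Returns (kind, n, offset): kind in {exon, intron, utr3, upstream}."""
        if pos > self.last_coding_pos:
            return ("utr3", pos - self.last_coding_pos, 0)
        if pos < self.exons[0].start:
            return ("upstream", self.exons[0].start - pos, 0)
        for i, ex in enumerate(self.exons):
            if ex.start <= pos < ex.end:
                return ("exon", ex.cds_start + (pos - ex.start), 0)
            if pos >= ex.end and pos < self.exons[i + 1].start:
                # intron between ex and the next exon: report nearest boundary
                d_left = pos - (ex.end - 1)       # bases past exon i's last base
                d_right = self.exons[i + 1].start - pos
                if d_left <= d_right:
                    return ("intron", ex.cds_end, d_left)
                return ("intron", self.exons[i + 1].cds_start, -d_right)
        raise ValueError(f"position {pos} not locatable")  # pragma: no cover

    def to_dict(self):
        return [{"start": e.start, "end": e.end, "cds_start": e.cds_start}
                for e in self.exons]

    @classmethod
    def from_dict(cls, items):
        return cls([Exon(**it) for it in items])


_DASHES = {"–": "-", "—": "-", "−": "-"}

_SUB_RE = re.compile(
    r"^c\.(?P<star>\*)?(?P<n>\d+)(?P<off>[+-]\d+)?(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_INDEL_RE = re.compile(r"^c\.(?P<n>\d+)(?P<op>dup|del)$")


def _normalize(name: str) -> str:
    for d, r in _DASHES.items():
        name = name.replace(d, r)
    return re.sub(r"\s+", "", name)


def parse_coding_name(name: str, cds_map: CdsMap, gene_ref: str) -> GenomicVariant:
    """Map a coding-style name to genomic coordinates, validating the ref allele."""
    norm = _normalize(name)
    m = _SUB_RE.match(norm)
    if m:
        n = int(m.group("n"))
        if m.group("star"):
            if m.group("off"):
                raise CodingNameError(f"unsupported grammar: {name}")
            pos = cds_map.utr3_to_genomic(n)
        else:
            pos = cds_map.coding_to_genomic(n)
            if m.group("off"):
                pos += int(m.group("off"))
        if pos < 0 or pos >= len(gene_ref):
            raise CodingNameError(f"{name}: position {pos} outside the reference")
        ref, alt = m.group("ref"), m.group("alt")
        if gene_ref[pos] != ref:
            raise ReferenceMismatchError(
                f"{name}: reference has {gene_ref[pos]} at {pos}, name says {ref}")
        canon = _format_sub(pos, ref, alt, cds_map)
        return GenomicVariant(canon, pos, ref, alt, "SNV")
    m = _INDEL_RE.match(norm)
    if m:
        n = int(m.group("n"))
        pos = cds_map.coding_to_genomic(n)
        base = gene_ref[pos]
        if m.group("op") == "dup":
            # duplication == insertion of base after pos
            return GenomicVariant(f"c.{n}dup", pos, base, base + base, "dup")
        return GenomicVariant(f"c.{n}del", pos, base, "", "del")
    raise CodingNameError(f"unsupported grammar: {name}")


def _format_sub(pos: int, ref: str, alt: str, cds_map: CdsMap) -> str:
    kind, n, off = cds_map.genomic_to_coding(pos)
    if kind == "exon":
        return f"c.{n}{ref}>{alt}"
    if kind == "utr3":
        return f"c.*{n}{ref}>{alt}"
    if kind == "intron":
        sign = f"+{off}" if off > 0 else f"{off}"
        return f"c.{n}{sign}{ref}>{alt}"
    return f"c.-{n}{ref}>{alt}"  # upstream; not produced by the toy KB


def format_coding_name(kind: str, pos: int, ref: str, alt: str,
                       cds_map: CdsMap, gene_ref: str) -> str:
    """Inverse of parse_coding_name for the supported event kinds.

    `pos`/`ref`/`alt` follow the caller's pileup conventions: SNV at pos;
    insertion anchored at pos with alt = ref_base + inserted; deletion with
    ref = anchor + deleted bases, alt = anchor.
    """
    if kind == "SNV":
        return _format_sub(pos, ref, alt, cds_map)
    if kind == "ins":
        inserted = alt[len(ref):]
        # a left-normalized single-base duplication of gene_ref[pos+1] sits
        # anchored one base upstream of the duplicated base
        if (len(inserted) == 1 and pos + 1 < len(gene_ref)
                and inserted == gene_ref[pos + 1]):
            k, n, off = cds_map.genomic_to_coding(pos + 1)
            if k == "exon":
                return f"c.{n}dup"
        k, n, off = cds_map.genomic_to_coding(pos)
        return f"g.{pos + 1}ins{inserted}" if k != "exon" else f"c.{n}ins{inserted}"
    if kind == "del":
        ndel = len(ref) - len(alt)
        k, n, off = cds_map.genomic_to_coding(pos)  # pos = first deleted base
        if k == "exon" and ndel == 1:
            return f"c.{n}del"
        return f"g.{pos + 1}del{ndel}"
    raise ValueError(f"unknown kind {kind}")


def format_genomic_variant(gv: GenomicVariant, cds_map: CdsMap) -> str:
    """Canonical name of a parsed variant (round-trip inverse of parsing)."""
    if gv.kind == "SNV":
        return _format_sub(gv.gene_pos, gv.ref, gv.alt, cds_map)
    k, n, _ = cds_map.genomic_to_coding(gv.gene_pos)
    if gv.kind == "dup":
        return f"c.{n}dup"
    if gv.kind == "del":
        return f"c.{n}del"
    raise ValueError(f"unknown kind {gv.kind}")
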