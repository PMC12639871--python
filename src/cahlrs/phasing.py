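"""PSV state vectors, chimera junction localization, and read-backed phasing.

Each aligned read is reduced to a vector of per-PSV states (GENE, PSEUDO or
MISSING).  Chimeric molecules follow a single-changepoint model — pseudogene
alleles 5' of the junction, functional-gene alleles 3' of it — and the
junction is placed at the cut minimizing the number of discordant states,
then labeled with the junction bin (CH-n) containing its midpoint.

Phasing exploits the fact that every read spans the entire amplicon: each
read votes at every heterozygous site, so greedy two-seed clustering on
allele vectors separates the haplotypes essentially perfectly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import Alignment

log = logging.getLogger(__name__)

GENE = 1
PSEUDO = 2
MISSING = 0


@dataclass
class PSVVector:
    read_id: str
    states: list  # per-PSV, aligned with locus.psvs

    @property
    def informative(self):
        return [(i, s) for i, s in enumerate(self.states) if s != MISSING]


@dataclass(frozen=True)
class JunctionInterval:
    """Junction between PSV indices (exclusive interval); sentinel kinds
    "all_gene" / "all_pseudo" flag non-chimeric vectors."""

    kind: str  # "junction" | "all_gene" | "all_pseudo"
    left_psv_index: int = -1
    right_psv_index: int = -1
    cost: int = 0

    @property
    def is_sentinel(self):
        return self.kind != "junction"


def psv_genotype_vector(aln: Alignment, psvs) -> PSVVector:
    """Score each covered PSV as GENE or PSEUDO from the read's alleles."""
    del_spans = aln.deleted_intervals()
    states = []
    for p in psvs:
        states.append(_psv_state(aln, p, del_spans))
    return PSVVector(aln.read_id, states)


def _in_deletion(pos, del_spans):
    return any(s <= pos < e for s, e in del_spans)


def _psv_state(aln, p, del_spans):
    if p.kind == "SNV":
        if not aln.covers(p.gene_pos) or _in_deletion(p.gene_pos, del_spans):
            return MISSING
        base = aln.mismatches.get(p.gene_pos)
        if base is None:
            return GENE
        return PSEUDO if base == p.pseudo_allele else MISSING
    if p.kind == "ins":
        if not (aln.covers(p.gene_pos) and aln.covers(p.gene_pos + 1)):
            return MISSING
        ins = aln.insertions.get(p.gene_pos)
        expected = p.pseudo_allele[1:]
        if ins == expected:
            return PSEUDO
        return GENE if ins is None else MISSING
    # deletion PSV: pseudogene lacks gene bases gene_pos+1 .. gene_pos+L
    ln = len(p.gene_allele) - 1
    first, last = p.gene_pos + 1, p.gene_pos + ln
    if not (aln.covers(p.gene_pos) and aln.covers(last + 1)):
        return MISSING
    d = aln.deletions.get(first)
    if d == ln:
        return PSEUDO
    if d is None and not any(_in_deletion(x, del_spans)
                             for x in range(first, last + 1)):
        return GENE
    return MISSING


def locate_junction(vector: PSVVector) -> JunctionInterval:
    """Minimum-mismatch single changepoint over the PSV state vector.

    Over cuts c in 0..n, cost(c) = #GENE states before c + #PSEUDO states
    after c (MISSING skipped); the leftmost minimal cut wins.  c == 0 means
    the read has no pseudogene segment; c == n no functional-gene segment.
    """
    info = vector.informative
    if len(info) < 2:
        raise ValueError("need >= 2 informative PSV states to place a junction")
    n = len(vector.states)
    # prefix counts of GENE, suffix counts of PSEUDO
    gene_before = [0] * (n + 1)
    for i in range(n):
        gene_before[i + 1] = gene_before[i] + (vector.states[i] == GENE)
    pseudo_after = [0] * (n + 2)
    for i in range(n - 1, -1, -1):
        pseudo_after[i] = pseudo_after[i + 1] + (vector.states[i] == PSEUDO)
    best_c, best_cost = 0, None
    for c in range(n + 1):
        cost = gene_before[c] + pseudo_after[c]
        if best_cost is None or cost < best_cost:
            best_c, best_cost = c, cost
    if best_c == 0:
        return JunctionInterval("all_gene", cost=best_cost)
    if best_c == n:
        return JunctionInterval("all_pseudo", cost=best_cost)
    # informative neighbors around the cut
    left = max((i for i, s in info if i < best_c), default=-1)
    right = min((i for i, s in info if i >= best_c), default=-1)
    if right == -1:
        return JunctionInterval("all_pseudo", cost=best_cost)
    if left == -1:
        return JunctionInterval("all_gene", cost=best_cost)
    return JunctionInterval("junction", left, right, best_cost)


@dataclass(frozen=True)
class BinnedJunction:
    label: str
    region: str  # "gene" | "tnx"
    ambiguous: bool = False


def bin_junction(junction: JunctionInterval, psvs, bins) -> BinnedJunction:
    """Label a junction with the bin containing its midpoint.

    An interval straddling a bin boundary takes the bin of its left
    informative PSV and is flagged ambiguous; a junction outside every bin
    is an error.
    """
    if junction.is_sentinel:
        raise ValueError("cannot bin a sentinel junction")
    pos_l = psvs[junction.left_psv_index].gene_pos
    pos_r = psvs[junction.right_psv_index].gene_pos
    mid = (pos_l + pos_r) // 2
    bin_l = _containing_bin(pos_l, bins)
    bin_r = _containing_bin(pos_r, bins)
    if bin_l is not None and bin_l is bin_r:
        return BinnedJunction(bin_l.label, bin_l.region)
    if bin_l is not None:
        return BinnedJunction(bin_l.label, bin_l.region, ambiguous=True)
    bin_m = _containing_bin(mid, bins)
    if bin_m is not None:
        return BinnedJunction(bin_m.label, bin_m.region, ambiguous=True)
    if bin_r is not None:  # junction walks in from outside the binned span
        return BinnedJunction(bin_r.label, bin_r.region, ambiguous=True)
    raise ValueError("junction lies outside all bins")


def _containing_bin(pos, bins):
    for b in bins:
        if b.start <= pos < b.end:
            return b
    return None


# ---------------------------------------------------------------------------
# read-backed phasing


@dataclass
class PhaseResult:
    groups: list          # up to two lists of read ids
    consensi: list        # per-group tuple of majority alleles (0 ref, 1 alt)
    noise: list           # read ids conflicting with both consensi
    multiallelic: bool = False


def phase_reads(read_alleles: dict, max_conflict: float = 0.2) -> PhaseResult:
    """Cluster reads into <= 2 haplotype groups from het-site allele vectors.

    read_alleles: read_id -> tuple over het sites with entries 0 (ref),
    1 (alt) or None (site not covered / ambiguous).  With no het sites all
    reads form a single group.  Output is stable under read order: seeds are
    the two most frequent complete allele patterns (ties broken
    lexicographically), assignment ties go to the first seed, and groups are
    reported with the larger one first (read ids sorted).
    """
    ids = sorted(read_alleles)
    if not ids:
        return PhaseResult([], [], [])
    nsites = len(next(iter(read_alleles.values())))
    if nsites == 0:
        return PhaseResult([list(ids)], [()], [])

    patterns: dict[tuple, int] = {}
    for rid in ids:
        v = read_alleles[rid]
        if None not in v:
            patterns[v] = patterns.get(v, 0) + 1
    ranked = sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked:  # every read partially missing: fall back to one group
        return PhaseResult([list(ids)], [(None,) * nsites], [])
    seeds = [ranked[0][0]]
    if len(ranked) > 1:
        seeds.append(ranked[1][0])
    n_total = len(ids)
    strong = [p for p, c in ranked if c >= 0.2 * n_total]
    multi = len(strong) > 2
    if multi:
        log.warning("more than two well-supported allele patterns "
                    "(%d); keeping the best two", len(strong))

    groups: list[list] = [[] for _ in seeds]
    noise = []
    for rid in ids:
        v = read_alleles[rid]
        dists = []
        for s in seeds:
            pairs = [(a, b) for a, b in zip(v, s) if a is not None]
            mism = sum(a != b for a, b in pairs)
            dists.append((mism, len(pairs)))
        best = min(range(len(seeds)), key=lambda k: dists[k][0])
        mism, npairs = dists[best]
        if npairs and mism / npairs > max_conflict:
            noise.append(rid)
        else:
            groups[best].append(rid)
    groups = [g for g in groups if g]
    # majority consensus per group
    consensi = []
    for g in groups:
        cons = []
        for s in range(nsites):
            votes = [read_alleles[r][s] for r in g
                     if read_alleles[r][s] is not None]
            cons.append(max((votes.count(a), a) for a in (0, 1))[1]
                        if votes else None)
        consensi.append(tuple(cons))
    order = sorted(range(len(groups)), key=lambda k: (-len(groups[k]),
                                                      str(consensi[k])))
    return PhaseResult([groups[k] for k in order],
                       [consensi[k] for k in order], noise, multi)


def conversion_prefix(vector: PSVVector, interior_index, min_psvs: int = 2):
    """Detect a contiguous PSEUDO prefix over interior PSVs (gene-primer
    reads whose 5' tract was overwritten by pseudogene alleles).

    interior_index: indices into the full PSV list that are interior (not in
    a primer).  Returns the count of leading PSEUDO states among informative
    interior sites if >= min_psvs and followed by GENE states, else 0.
    """
    states = [vector.states[i] for i in interior_index]
    informative = [s for s in states if s != MISSING]
    if not informative or informative[0] != PSEUDO:
        return 0
    k = 0
    for s in informative:
        if s == PSEUDO:
            k += 1
        else:
            break
    if k >= min_psvs and k < len(informative):
        return k
    return 0
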