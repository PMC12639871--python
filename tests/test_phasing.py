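"""PSV vectors, junction changepoint, binning, and read phasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cahlrs.align import align_read
from cahlrs.locus import JunctionBin, SignatureVariant
from cahlrs.phasing import (GENE, MISSING, PSEUDO, PSVVector, bin_junction,
                            conversion_prefix, locate_junction, phase_reads,
                            psv_genotype_vector)
from cahlrs.simulate import (DiplotypeSpec, HaplotypeSpec, build_haplotype,
                             simulate_reads)
from conftest import ERROR_FREE, brute_force_changepoint


def vec(states):
    return PSVVector("r", list(states))


P, G, M = PSEUDO, GENE, MISSING


class TestPSVGenotypeVector:
    def test_gene_reference_copy_scores_all_gene(self, locus):
        aln = align_read("r", locus.gene_ref, locus.gene_ref)
        v = psv_genotype_vector(aln, locus.psvs)
        assert all(s == GENE for s in v.states)

    def test_del_chimera_read_switches_inside_its_bin(self, locus, rng):
        spec = HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label="CH-3")
        amp = build_haplotype(spec, locus, rng)[0]
        aln = align_read("r", amp.sequence, locus.gene_ref)
        v = psv_genotype_vector(aln, locus.psvs)
        j = locate_junction(v)
        assert not j.is_sentinel and j.cost == 0
        b = bin_junction(j, locus.psvs, locus.all_bins())
        assert (b.label, b.region) == ("CH-3", "gene")
        # pseudo block strictly precedes the gene block
        informative = [s for s in v.states if s != MISSING]
        switch = informative.index(GENE)
        assert all(s == PSEUDO for s in informative[:switch])
        assert all(s == GENE for s in informative[switch:])

    def test_sequencing_error_at_psv_flips_or_masks_one_state(self, locus):
        base_aln = align_read("r", locus.gene_ref, locus.gene_ref)
        base = psv_genotype_vector(base_aln, locus.psvs)
        target = locus.psvs[10]
        assert target.kind == "SNV"
        seq = list(locus.gene_ref)
        seq[target.gene_pos] = target.pseudo_allele
        aln = align_read("e", "".join(seq), locus.gene_ref)
        v = psv_genotype_vector(aln, locus.psvs)
        diffs = [i for i, (a, b) in enumerate(zip(base.states, v.states))
                 if a != b]
        assert diffs == [10]
        assert v.states[10] in (PSEUDO, MISSING)


class TestLocateJunction:
    def test_clean_changepoint(self):
        j = locate_junction(vec([P, P, P, G, G]))
        assert (j.left_psv_index, j.right_psv_index, j.cost) == (2, 3, 0)

    def test_noisy_vector_leftmost_minimal_cut(self):
        # brute force over the 6 cuts: cuts 1 and 3 both cost 1 (one
        # discordant state either way); the leftmost minimal cut (c=1) wins
        j = locate_junction(vec([P, G, P, G, G]))
        c, cost = brute_force_changepoint([P, G, P, G, G])
        assert (c, cost) == (1, 1)
        assert j.cost == 1
        assert (j.left_psv_index, j.right_psv_index) == (0, 1)

    def test_all_gene_sentinel(self):
        assert locate_junction(vec([G, G, G, G])).kind == "all_gene"

    def test_all_pseudo_sentinel(self):
        assert locate_junction(vec([P, P, P])).kind == "all_pseudo"

    def test_fewer_than_two_informative_sites_is_error(self):
        with pytest.raises(ValueError):
            locate_junction(vec([M, M, P]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([G, P, M]), min_size=2, max_size=200))
    def test_matches_exhaustive_search_on_random_vectors(self, states):
        informative = [s for s in states if s != M]
        if len(informative) < 2:
            with pytest.raises(ValueError):
                locate_junction(vec(states))
            return
        c, cost = brute_force_changepoint(states)
        j = locate_junction(vec(states))
        assert j.cost == cost
        if j.kind == "junction":
            # the reported open interval brackets the leftmost-minimal cut
            assert j.left_psv_index < c <= j.right_psv_index
            assert states[j.left_psv_index] != M
            assert states[j.right_psv_index] != M

    def test_invariant_to_added_missing_states(self, locus, rng):
        states = [P] * 6 + [G] * 8
        j1 = locate_junction(vec(states))
        padded = states[:6] + [M, M] + states[6:]
        j2 = locate_junction(vec(padded))
        assert j1.cost == j2.cost == 0
        assert j1.left_psv_index == 5 and j2.left_psv_index == 5
        assert j2.right_psv_index == 8  # first informative gene-side PSV


class TestBinJunction:
    BINS = [JunctionBin("CH-1", 0, 100, "gene"),
            JunctionBin("CH-2", 100, 200, "gene")]

    def _psvs(self, positions):
        return [SignatureVariant(p, "SNV", "A", "C") for p in positions]

    def test_midpoint_bin(self):
        psvs = self._psvs([10, 40, 60, 90])
        j = locate_junction(vec([P, P, G, G]))
        b = bin_junction(j, psvs, self.BINS)
        assert b.label == "CH-1" and not b.ambiguous

    def test_boundary_straddle_takes_left_bin_with_flag(self):
        psvs = self._psvs([40, 90, 110, 150])
        j = locate_junction(vec([P, P, G, G]))  # junction between 90 and 110
        b = bin_junction(j, psvs, self.BINS)
        assert b.label == "CH-1" and b.ambiguous

    def test_sentinel_rejected(self):
        with pytest.raises(ValueError):
            bin_junction(locate_junction(vec([G, G])), self._psvs([1, 2]),
                         self.BINS)

    def test_junction_outside_all_bins_is_error(self):
        psvs = self._psvs([300, 320, 340, 360])
        j = locate_junction(vec([P, P, G, G]))
        with pytest.raises(ValueError):
            bin_junction(j, psvs, self.BINS)

    def test_simulated_breakpoints_recover_their_bin(self, locus, rng):
        for label in ("CH-1", "CH-5", "CH-8"):
            spec = HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label=label)
            amp = build_haplotype(spec, locus, rng)[0]
            aln = align_read("r", amp.sequence, locus.gene_ref)
            v = psv_genotype_vector(aln, locus.psvs)
            b = bin_junction(locate_junction(v), locus.psvs, locus.all_bins())
            assert b.label == label

    def test_tnx_breakpoint_lands_in_flank_namespace(self, locus, rng):
        spec = HaplotypeSpec("A", structure="TNX_CHIMERA", bin_label="CH-1")
        amp = build_haplotype(spec, locus, rng)[0]
        aln = align_read("r", amp.sequence, locus.gene_ref)
        b = bin_junction(locate_junction(psv_genotype_vector(aln, locus.psvs)),
                         locus.psvs, locus.all_bins())
        assert (b.label, b.region) == ("CH-1", "tnx")


class TestPhaseReads:
    def test_no_het_sites_single_group(self):
        res = phase_reads({f"r{i}": () for i in range(6)})
        assert len(res.groups) == 1
        assert sorted(res.groups[0]) == [f"r{i}" for i in range(6)]

    def test_single_het_site_perfect_partition(self):
        alleles = {f"a{i}": (0,) for i in range(5)}
        alleles.update({f"b{i}": (1,) for i in range(5)})
        res = phase_reads(alleles)
        assert len(res.groups) == 2
        assert {tuple(sorted(g)) for g in res.groups} == {
            tuple(f"a{i}" for i in range(5)), tuple(f"b{i}" for i in range(5))}
        assert set(res.consensi) == {(0,), (1,)}
        assert res.noise == []

    def test_conflicting_read_set_aside_as_noise(self):
        alleles = {f"a{i}": (0, 0, 0, 0, 0) for i in range(5)}
        alleles.update({f"b{i}": (1, 1, 1, 1, 1) for i in range(5)})
        alleles["x"] = (1, 0, 1, 0, 1)  # 40%+ conflict with both consensi
        res = phase_reads(alleles)
        assert res.noise == ["x"]

    def test_three_strong_patterns_warn_and_keep_two(self):
        alleles = {}
        for i in range(6):
            alleles[f"a{i}"] = (0, 0)
        for i in range(6):
            alleles[f"b{i}"] = (1, 1)
        for i in range(5):
            alleles[f"c{i}"] = (0, 1)
        res = phase_reads(alleles)
        assert res.multiallelic
        assert len(res.groups) == 2

    def test_stable_under_read_order(self):
        rng = np.random.default_rng(5)
        alleles = {}
        for i in range(20):
            alleles[f"r{i:02d}"] = (0, 1, 0) if i % 2 else (1, 0, 1)
        res1 = phase_reads(alleles)
        shuffled = {k: alleles[k] for k in
                    np.array(sorted(alleles))[rng.permutation(20)]}
        res2 = phase_reads(shuffled)
        assert res1.groups == res2.groups
        assert res1.consensi == res2.consensi

    @pytest.mark.parametrize("depth", [2, 4, 30])
    def test_error_free_partition_matches_truth_at_any_depth(
            self, locus, depth):
        """With no errors, phasing recovers the simulator's truth partition
        (up to label swap) from depth 2 upwards."""
        dip = DiplotypeSpec(
            "s", "ACGTACGTAC",
            HaplotypeSpec("A", variants=("c.293-13C>G",)),
            HaplotypeSpec("B", variants=("c.518T>A",)))
        reads = [r for r in simulate_reads(dip, locus, depth, ERROR_FREE,
                                           seed=1, orient_mix=False)
                 if "|gene|" in r.truth_tag]
        alns = {r.id: align_read(r.id, r.sequence[10:-10], locus.gene_ref)
                for r in reads}
        sites = sorted({827, 519})
        alleles = {}
        for r in reads:
            a = alns[r.id]
            alleles[r.id] = tuple(1 if p in a.mismatches else 0 for p in sites)
        res = phase_reads(alleles)
        truth = {r.id: r.truth_tag.split("|")[0] for r in reads}
        assert len(res.groups) == 2
        for g in res.groups:
            assert len({truth[r] for r in g}) == 1

    def test_partition_accuracy_with_default_errors(self, locus):
        """>= 99% of functional reads phased to their true haplotype at
        100x across repeated seeded simulations."""
        from cahlrs.simulate import ErrorModel
        dip = DiplotypeSpec(
            "s", "ACGTACGTAC",
            HaplotypeSpec("A", variants=("c.293-13C>G",)),
            HaplotypeSpec("B", variants=("c.518T>A",)))
        good = total = 0
        for seed in range(10):
            reads = [r for r in simulate_reads(dip, locus, 100, ErrorModel(),
                                               seed=seed, orient_mix=False)
                     if "|gene|" in r.truth_tag]
            alleles = {}
            alns = {}
            for r in reads:
                a = align_read(r.id, r.sequence[10:-10], locus.gene_ref)
                if a is None:
                    continue
                alns[r.id] = a
                alleles[r.id] = tuple(
                    (1 if p in a.mismatches else 0) if a.covers(p) else None
                    for p in (519, 827))
            res = phase_reads(alleles)
            truth = {r.id: r.truth_tag.split("|")[0] for r in reads}
            for g in res.groups:
                labels = [truth[r] for r in g]
                majority = max(set(labels), key=labels.count)
                good += labels.count(majority)
                total += len(labels)
        assert total >= 900
        assert good / total >= 0.99


class TestConversionPrefix:
    def test_detects_pseudo_prefix_on_functional_read(self, locus, rng):
        spec = HaplotypeSpec("A", structure="CONV_CHIMERA", bin_label="CH-2")
        amp = build_haplotype(spec, locus, rng)[0]
        aln = align_read("r", amp.sequence, locus.gene_ref)
        v = psv_genotype_vector(aln, locus.psvs)
        interior = [i for i, p in enumerate(locus.psvs) if not p.in_primer]
        assert conversion_prefix(v, interior, min_psvs=2) >= 2

    def test_plain_gene_read_has_no_prefix(self, locus):
        aln = align_read("r", locus.gene_ref, locus.gene_ref)
        v = psv_genotype_vector(aln, locus.psvs)
        interior = [i for i, p in enumerate(locus.psvs) if not p.in_primer]
        assert conversion_prefix(v, interior) == 0
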