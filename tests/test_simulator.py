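"""Haplotype rendering and CCS-like read simulation."""

import numpy as np
import pytest

from cahlrs.locus import revcomp
from cahlrs.nomenclature import parse_coding_name
from cahlrs.simulate import (AMP_FUSED, AMP_GENE, AMP_PSEUDO, DiplotypeSpec,
                             ErrorModel, HaplotypeSpec, build_haplotype,
                             mutate_sequence, simulate_reads,
                             write_cohort_fixture, StructureConflictError)
from conftest import ERROR_FREE


def edit_script_positions(a: str, b: str):
    """Columnwise diff oracle for equal-length sequences."""
    assert len(a) == len(b)
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


class TestBuildHaplotype:
    def test_normal_yields_gene_and_pseudo_amplicons(self, locus):
        amps = build_haplotype(HaplotypeSpec("A"), locus)
        kinds = [a.kind for a in amps]
        assert kinds == [AMP_GENE, AMP_PSEUDO]
        assert amps[0].sequence == locus.gene_ref
        assert amps[1].sequence == locus.pseudo_ref

    def test_homozygote_spec_renders_on_both_haplotypes(self, locus):
        # intron-2 splice homozygote
        spec = HaplotypeSpec("hap", variants=("c.293-13C>G",))
        gv = parse_coding_name("c.293-13C>G", locus.cds_map, locus.gene_ref)
        for label in ("A", "B"):
            seq = build_haplotype(spec, locus)[0].sequence
            assert seq[gv.gene_pos] == "G"
            assert edit_script_positions(locus.gene_ref, seq) == [gv.gene_pos]

    def test_five_variant_haplotype_edit_count(self, locus):
        """4 SNV + 1 dup differ from gene_ref at exactly 5 loci."""
        spec = HaplotypeSpec("B", variants=("c.844G>T", "c.923dup",
                                            "c.955C>T", "c.1069C>T"))
        seq = build_haplotype(spec, locus)[0].sequence
        assert len(seq) == len(locus.gene_ref) + 1  # the dup
        dup = parse_coding_name("c.923dup", locus.cds_map, locus.gene_ref)
        # remove the duplicated base to compare columnwise
        undup = seq[:dup.gene_pos + 1] + seq[dup.gene_pos + 2:]
        positions = edit_script_positions(locus.gene_ref, undup)
        expected = sorted(
            parse_coding_name(n, locus.cds_map, locus.gene_ref).gene_pos
            for n in ("c.844G>T", "c.955C>T", "c.1069C>T"))
        assert positions == expected
        assert seq[dup.gene_pos] == seq[dup.gene_pos + 1]

    def test_del_chimera_psv_states_switch_inside_bin(self, locus, rng):
        spec = HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label="CH-3")
        amps = build_haplotype(spec, locus, rng)
        assert [a.kind for a in amps] == [AMP_FUSED]
        bp = amps[0].breakpoint
        b = [x for x in locus.junction_bins if x.label == "CH-3"][0]
        assert b.start <= bp < b.end
        seq = amps[0].sequence
        # pseudo alleles before the breakpoint, gene alleles after
        for p in locus.psvs:
            if p.kind != "SNV":
                continue
            if p.gene_pos < bp:
                assert seq[int(locus.g2p[p.gene_pos])] == p.pseudo_allele
            else:
                offset = int(locus.g2p[bp]) - bp
                assert seq[p.gene_pos + offset] == p.gene_allele

    def test_fused_amplicon_has_pseudo_forward_gene_reverse_primers(
            self, locus, rng):
        spec = HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label="CH-5")
        seq = build_haplotype(spec, locus, rng)[0].sequence
        pf, _ = locus.primer_set["pseudo"]
        _, gr = locus.primer_set["functional"]
        assert seq.startswith(pf)
        assert seq.endswith(revcomp(gr))

    def test_conversion_keeps_gene_primers(self, locus, rng):
        spec = HaplotypeSpec("A", structure="CONV_CHIMERA", bin_label="CH-2")
        amps = build_haplotype(spec, locus, rng)
        gf, gr = locus.primer_set["functional"]
        assert amps[0].sequence.startswith(gf)
        assert amps[0].sequence.endswith(revcomp(gr))
        assert amps[1].kind == AMP_PSEUDO

    def test_dup_fusion_keeps_intact_copies(self, locus, rng):
        spec = HaplotypeSpec("B", structure="DUP_FUSION", bin_label="CH-1",
                             copies=1)
        amps = build_haplotype(spec, locus, rng)
        kinds = [a.kind for a in amps]
        assert kinds.count(AMP_FUSED) == 1
        assert kinds.count(AMP_GENE) == 1
        assert locus.gene_ref in [a.sequence for a in amps]

    def test_variant_deleted_by_structure_is_an_error(self, locus, rng):
        # c.92 sits far 5' of every CH-8 breakpoint
        spec = HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label="CH-8",
                             variants=("c.92C>T",))
        with pytest.raises(StructureConflictError):
            build_haplotype(spec, locus, rng)


class TestSimulateReads:
    def _dip(self, **kw):
        return DiplotypeSpec("s1", "ACGTACGTAC",
                             HaplotypeSpec("A", **kw), HaplotypeSpec("B"))

    def test_error_free_reads_are_exact_amplicon_copies(self, locus):
        dip = self._dip()
        reads = simulate_reads(dip, locus, depth=8, error_model=ERROR_FREE,
                               seed=1, orient_mix=False)
        amps = {locus.gene_ref, locus.pseudo_ref}
        for r in reads:
            core = r.sequence[10:-10]
            assert core in amps
            assert r.sequence.startswith(dip.barcode)

    def test_deterministic_depth_allocation(self, locus):
        """depth=60 with one amplicon per haplotype -> exactly 30/30."""
        dip = DiplotypeSpec(
            "s", "ACGTACGTAC",
            HaplotypeSpec("A", structure="DEL_CHIMERA", bin_label="CH-2"),
            HaplotypeSpec("B", structure="DEL_CHIMERA", bin_label="CH-7"))
        reads = simulate_reads(dip, locus, depth=60, error_model=ERROR_FREE,
                               seed=5)
        assert len(reads) == 60
        tags = [r.truth_tag.split("|")[0] for r in reads]
        assert tags.count("A") == 30
        assert tags.count("B") == 30

    def test_same_seed_reproduces_reads(self, locus):
        dip = self._dip(variants=("c.518T>A",))
        a = simulate_reads(dip, locus, 20, ErrorModel(), seed=9)
        b = simulate_reads(dip, locus, 20, ErrorModel(), seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        c = simulate_reads(dip, locus, 20, ErrorModel(), seed=10)
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_substitution_count_matches_binomial_expectation(self):
        """Mismatch count over ~10 kb within 3 sigma of Binomial(n, 0.01)."""
        rng = np.random.default_rng(42)
        em = ErrorModel(substitution_rate=0.01, ins_rate=0.0, del_rate=0.0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        mismatches = 0
        total = 0
        for _ in range(10):
            out = mutate_sequence(seq, em, rng)
            assert len(out) == len(seq)
            mismatches += sum(a != b for a, b in zip(seq, out))
            total += len(seq)
        mean = total * 0.01
        sigma = (total * 0.01 * 0.99) ** 0.5
        assert abs(mismatches - mean) <= 3 * sigma

    def test_indel_rates_change_length(self):
        rng = np.random.default_rng(3)
        em = ErrorModel(substitution_rate=0.0, ins_rate=0.02, del_rate=0.0)
        seq = "A" * 5000
        out = mutate_sequence(seq, em, rng)
        assert len(out) > len(seq)

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ErrorModel(substitution_rate=0.2)

    def test_depth_precondition(self, locus):
        with pytest.raises(ValueError):
            simulate_reads(self._dip(), locus, depth=0)


class TestCohortFixture:
    def test_twelve_case_fixture_roundtrip(self, tmp_path, locus, cases12):
        manifest = write_cohort_fixture(cases12, locus, tmp_path / "fx",
                                        depth=10, seed=3)
        assert len(manifest["cases"]) == 12
        fqs = sorted((tmp_path / "fx").glob("*.fastq"))
        assert len(fqs) == 12
        # byte-identical on re-run with the same seed
        first = {f.name: f.read_bytes() for f in fqs}
        write_cohort_fixture(cases12, locus, tmp_path / "fx2", depth=10,
                             seed=3)
        for f in sorted((tmp_path / "fx2").glob("*.fastq")):
            assert f.read_bytes() == first[f.name]

    def test_seed_changes_reads_but_not_truth(self, tmp_path, locus, cases12):
        m1 = write_cohort_fixture(cases12[:2], locus, tmp_path / "a",
                                  depth=10, seed=1)
        m2 = write_cohort_fixture(cases12[:2], locus, tmp_path / "b",
                                  depth=10, seed=2)
        a = (tmp_path / "a" / m1["cases"][0]["fastq"]).read_bytes()
        b = (tmp_path / "b" / m2["cases"][0]["fastq"]).read_bytes()
        assert a != b
        assert [c["hap_a"] for c in m1["cases"]] == \
            [c["hap_a"] for c in m2["cases"]]

    def test_refuses_to_clobber_nonempty_dir(self, tmp_path, locus, cases12):
        out = tmp_path / "fx"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_cohort_fixture(cases12[:1], locus, out, depth=4, seed=0)
        write_cohort_fixture(cases12[:1], locus, out, depth=4, seed=0,
                             overwrite=True)

    def test_empty_spec_list_gives_empty_manifest(self, tmp_path, locus):
        m = write_cohort_fixture([], locus, tmp_path / "e", depth=4, seed=0)
        assert m["cases"] == []
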