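"""Haplotype collapsing, variant classification, homopolymer context and the
species-level summary, including the designed-site round trip on the
packaged benchmark and the cryptic-species split."""

import numpy as np
import pytest

from ciliate_rdna.clone_align import CloneLibrary, star_align_sequences
from ciliate_rdna.io_formats import NamedSequence
from ciliate_rdna.polymorphism import (
    annotate_homopolymer,
    classify_variant,
    collapse_haplotypes,
    find_polymorphic_sites,
    most_common_haplotype,
    site_matrix,
    summarize_species,
)


def _library(seqs, species="sp", individual="ind1"):
    return CloneLibrary(
        species, individual, [NamedSequence(f"{individual}_c{i}", s) for i, s in enumerate(seqs)]
    )


class TestCollapseHaplotypes:
    def test_identical_clones_collapse_to_one(self):
        haps = collapse_haplotypes(_library(["ACGT"] * 30))
        assert len(haps) == 1
        assert haps[0].total_count == 30 and haps[0].haplotype_id == 1

    def test_ordering_by_count(self):
        haps = collapse_haplotypes(_library(["AAAA"] * 27 + ["AACA"] * 3))
        assert [(h.haplotype_id, h.sequence, h.total_count) for h in haps] == [
            (1, "AAAA", 27),
            (2, "AACA", 3),
        ]

    def test_counts_conserved_and_match_provenance(self, benchmark_libraries, benchmark):
        libs = benchmark_libraries["Trithigmostoma_sp"]
        haps = collapse_haplotypes(libs)
        assert sum(h.total_count for h in haps) == sum(len(l.clones) for l in libs)
        assert len(haps) == 4
        # provenance tally: clones per designed haplotype == collapsed counts
        prov_counts = {}
        for lib in libs:
            for p in lib.provenance.values():
                prov_counts[p.haplotype_id] = prov_counts.get(p.haplotype_id, 0) + 1
        assert sorted(prov_counts.values(), reverse=True) == [h.total_count for h in haps]

    def test_singleton_annotation_never_changes_counts(self):
        haps = collapse_haplotypes(_library(["AAAA"] * 9 + ["AACA"]))
        assert haps[1].singleton and not haps[0].singleton
        assert sum(h.total_count for h in haps) == 10


class TestMostCommonHaplotype:
    def test_single_haplotype_is_itself(self):
        haps = collapse_haplotypes(_library(["ACGT"] * 5))
        assert most_common_haplotype(haps) is haps[0]

    def test_tie_resolves_lexicographically(self):
        haps = collapse_haplotypes(_library(["TTTT"] * 15 + ["AAAA"] * 15))
        assert most_common_haplotype(haps).sequence == "AAAA"


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("C", "T", "transition"),
            ("A", "T", "transversion"),
            ("A", "C", "transversion"),
            ("G", "T", "transversion"),
            ("A", "-", "deletion"),
            ("-", "C", "insertion"),
        ],
    )
    def test_classification_table(self, ref, alt, expected):
        assert classify_variant(ref, alt) == expected

    def test_rejects_equal_states_and_double_gap(self):
        with pytest.raises(ValueError):
            classify_variant("A", "A")
        with pytest.raises(ValueError):
            classify_variant("-", "-")


class TestFindPolymorphicSites:
    def test_identical_alignment_has_no_sites(self):
        aln = star_align_sequences([NamedSequence(f"h{i}", "ACGTACGT") for i in range(3)])
        assert find_polymorphic_sites(aln) == []

    def test_single_transition_detected_with_position(self):
        ref = "C" * 16 + "A" + "C" * 3
        alt = "C" * 16 + "G" + "C" * 3
        aln = star_align_sequences(
            [NamedSequence("h1", ref), NamedSequence("h2", alt)], reference_seq=ref
        )
        sites = find_polymorphic_sites(aln)
        assert len(sites) == 1
        assert sites[0].position == 17 and sites[0].types == {"G": "transition"}

    def test_multiallelic_column_counts_once(self):
        seqs = ["CCACC", "CCGCC", "CCTCC"]
        aln = star_align_sequences(
            [NamedSequence(f"h{i}", s) for i, s in enumerate(seqs)], reference_seq=seqs[0]
        )
        sites = find_polymorphic_sites(aln)
        assert len(sites) == 1
        assert sites[0].alt_states == ("G", "T")


class TestAnnotateHomopolymer:
    def _site(self, ref, alt):
        aln = star_align_sequences(
            [NamedSequence("h1", ref), NamedSequence("h2", alt)], reference_seq=ref
        )
        (site,) = find_polymorphic_sites(aln)
        return aln, site

    def test_a_deletion_inside_tract_is_flagged(self):
        aln, site = self._site("CCAAAAAGG", "CCAAAAGG")
        out = annotate_homopolymer(aln, site, min_run=3)
        assert out.in_at_homopolymer and out.tract_base == "A" and out.tract_length == 5

    def test_substitution_in_gc_context_is_not_flagged(self):
        aln, site = self._site("GCGCGCGCG", "GCGTGCGCG")
        assert not annotate_homopolymer(aln, site, min_run=3).in_at_homopolymer

    def test_all_benchmark_indel_sites_are_in_tracts(self, benchmark_summaries):
        for summary in benchmark_summaries.values():
            for unit in summary.units:
                for site in unit.sites:
                    if {"deletion", "insertion"} & set(site.types.values()):
                        assert site.in_at_homopolymer or site.ref_state == "C", (
                            summary.species_id,
                            site,
                        )


class TestSummarizeSpecies:
    def test_zero_variation_species(self):
        s = summarize_species([_library(["ACGTAC"] * 30)])
        assert s.polymorphism_style == "No"
        assert s.n_polymorphic_sites == "0" and s.n_haplotypes == 1

    def test_biconditional_one_haplotype_iff_zero_sites(self):
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), 40))
        for n_variants in (0, 1, 2):
            seqs = [base] * 8
            for k in range(n_variants):
                pos = 5 + 10 * k
                seqs.append(base[:pos] + ("G" if base[pos] != "G" else "C") + base[pos + 1:])
            s = summarize_species([_library(seqs)])
            assert (s.total_sites == 0) == (s.n_haplotypes == 1)

    def test_site_count_invariant_under_clone_permutation(self, benchmark_libraries):
        libs = benchmark_libraries["Coleps_sp"]
        s1 = summarize_species(libs)
        rng = np.random.default_rng(3)
        shuffled = []
        for lib in libs:
            clones = list(lib.clones)
            rng.shuffle(clones)
            shuffled.append(CloneLibrary(lib.species_id, lib.individual_id, clones))
        s2 = summarize_species(shuffled)
        assert s1.n_polymorphic_sites == s2.n_polymorphic_sites

    def test_benchmark_designed_sites_and_styles_recovered(
        self, benchmark_summaries, benchmark
    ):
        for species, design in benchmark.designs.items():
            s = benchmark_summaries[species]
            assert tuple(u.n_sites for u in s.units) == design.expected_sites, species
            observed = {
                style for u in s.units for site in u.sites for style in site.types.values()
            }
            assert observed == set(design.expected_styles), species
            assert s.n_clones == design.total_clones
            assert tuple(int(x) for x in s.length.split("/")) == design.expected_lengths

    def test_cryptic_species_splits_into_reporting_units(self, benchmark_summaries):
        fav = benchmark_summaries["Favella_ehrenbergii"]
        assert len(fav.units) == 2
        assert fav.units[0].individual_ids == ["ind1", "ind2"]
        assert fav.units[1].individual_ids == ["ind3"]
        assert fav.n_polymorphic_sites == "2/1"

    def test_shared_dominant_haplotype_stays_one_unit(self, benchmark_summaries):
        assert len(benchmark_summaries["Trithigmostoma_sp"].units) == 1


class TestSiteMatrix:
    def test_dot_dash_convention(self):
        # hap1 dominant, hap2 carries one deletion inside the tract
        libs = [_library(["CCAAAAAGG"] * 8 + ["CCAAAAGG"] * 2)]
        s = summarize_species(libs)
        m = site_matrix(s.units[0])
        assert list(m["haplotype"]) == ["hap1", "hap2"]
        assert list(m["clones"]) == [8, 2]
        label = s.units[0].sites[0].label
        assert m.loc[0, label] == "A" and m.loc[1, label] == "-"
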