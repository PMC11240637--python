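"""Mapping, segregating sites and haplotype collapsing."""

import random

import pytest

from crhaplo import (AlignmentWindow, PrimerPair, SampleRecord, amplicon_span,
                     assign_haplotypes, call_segregating_sites,
                     haplotype_frequencies, map_to_reference)
from crhaplo.haplotyping import IndelUnsupportedError, UnmappableError
from crhaplo.registry import HaplotypeRegistry
from crhaplo.simulate import VARIABLE_SITES, WINDOW, build_registry


WIN = AlignmentWindow(*WINDOW)


class TestAmpliconSpan:
    def test_survey_primer_pair_spans_945(self):
        win = amplicon_span(PrimerPair("F15,386", "R16,330"))
        assert (win.start, win.end, win.L) == (15386, 16330, 945)

    def test_control_region_coordinates_span_747(self):
        assert amplicon_span(PrimerPair("F15,400", "R16,146")).L == 747

    def test_degenerate_order_rejected(self):
        with pytest.raises(ValueError):
            amplicon_span(PrimerPair("F10", "R10"))

    def test_unparseable_name_rejected(self):
        with pytest.raises(ValueError):
            amplicon_span(PrimerPair("X15,386", "R16,330"))


class TestMapToReference:
    def test_identity_placement(self, regional_bundle):
        ref = regional_bundle.reference
        p = map_to_reference(("s", ref.subsequence(*WINDOW)), ref, WIN)
        assert (p.start, p.end, p.mismatches) == (WINDOW[0], WINDOW[1], 0)

    def test_single_substitution_recorded(self, regional_bundle):
        ref = regional_bundle.reference
        seq = list(ref.subsequence(*WINDOW))
        seq[100] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[100]]
        p = map_to_reference(("s", "".join(seq)), ref, WIN)
        assert (p.start, p.mismatches) == (WINDOW[0], 1)

    def test_fragment_placed_at_correct_offset(self, regional_bundle):
        ref = regional_bundle.reference
        frag = ref.subsequence(WINDOW[0] + 200, WINDOW[0] + 649)
        p = map_to_reference(("frag", frag), ref, WIN)
        assert (p.start, p.end) == (WINDOW[0] + 200, WINDOW[0] + 649)
        assert p.end - p.start + 1 == 450

    def test_gap_raises_named_indel_error(self, regional_bundle):
        with pytest.raises(IndelUnsupportedError, match="offset 3"):
            map_to_reference(("s", "AC-GT"), regional_bundle.reference, WIN)

    def test_unrelated_sequence_unmappable(self, regional_bundle):
        rng = random.Random(1)
        junk = "".join(rng.choice("ACGT") for _ in range(300))
        with pytest.raises(UnmappableError):
            map_to_reference(("junk", junk), regional_bundle.reference, WIN)


class TestSegregatingSites:
    def test_global_fixture_has_six_sites(self, global_results):
        assert global_results.segregating_sites == list(VARIABLE_SITES)

    def test_nw_subset_has_one_site(self, regional_bundle):
        nw = [r for r in regional_bundle.records if r.sample_id.startswith("NW")]
        positioned = [map_to_reference(r, regional_bundle.reference, WIN)
                      for r in nw]
        assert len(call_segregating_sites(positioned, WIN)) == 1

    def test_identical_samples_have_none(self, regional_bundle):
        ref = regional_bundle.reference
        positioned = [map_to_reference((f"s{i}", ref.subsequence(*WINDOW)),
                                       ref, WIN) for i in range(3)]
        assert call_segregating_sites(positioned, WIN) == []

    def test_ambiguous_bases_give_no_evidence(self, regional_bundle):
        ref = regional_bundle.reference
        base = ref.subsequence(*WINDOW)
        variant = list(base)
        variant[50] = "N"
        positioned = [map_to_reference(("a", base), ref, WIN),
                      map_to_reference(("b", "".join(variant)), ref, WIN)]
        assert call_segregating_sites(positioned, WIN) == []

    def test_direct_scan_oracle(self, regional_results):
        """Every reported site has >= 2 distinct bases; every unreported
        covered position is monomorphic (checked by a naive per-position
        scan)."""
        reported = set(regional_results.segregating_sites)
        positioned = regional_results.positioned
        for pos in range(WINDOW[0], WINDOW[1] + 1, 13):  # strided full scan
            bases = {b for p in positioned
                     if (b := p.base_at(pos)) in set("ACGT")}
            assert (len(bases) >= 2) == (pos in reported)
        for pos in reported:
            bases = {b for p in positioned
                     if (b := p.base_at(pos)) in set("ACGT")}
            assert len(bases) >= 2


class TestAssignHaplotypes:
    def test_global_fixture_collapses_to_six_names(self, global_results):
        assert global_results.haplotype_names == [f"Hun{i}" for i in
                                                  range(1, 7)]

    def test_input_order_invariance(self, regional_bundle):
        ref = regional_bundle.reference
        registry = build_registry(ref)
        positioned = [map_to_reference(r, ref, WIN)
                      for r in regional_bundle.records[:40]]
        a1, _ = assign_haplotypes(list(positioned), build_registry(ref))
        shuffled = list(positioned)
        random.Random(4).shuffle(shuffled)
        a2, _ = assign_haplotypes(shuffled, registry)
        assert {x.sample_id: x.haplotype for x in a1} == \
               {x.sample_id: x.haplotype for x in a2}

    def test_idempotent_collapse(self, regional_bundle):
        ref = regional_bundle.reference
        positioned = [map_to_reference(r, ref, WIN)
                      for r in regional_bundle.records[:30]]
        reg = build_registry(ref)
        a1, reg = assign_haplotypes(positioned, reg)
        names_before = list(reg.names)
        a2, reg = assign_haplotypes(positioned, reg)
        assert reg.names == names_before
        assert [x.haplotype for x in a1] == [x.haplotype for x in a2]

    def test_novel_full_coverage_sequence_registers_next_name(self,
                                                              regional_bundle):
        ref = regional_bundle.reference
        reg = build_registry(ref)
        seq = list(reg.full_sequence("Hun2", *WINDOW))
        pos = 400  # a private substitution away from all variable sites
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        p = map_to_reference(("novel", "".join(seq)), ref, WIN)
        assignments, reg = assign_haplotypes([p], reg)
        assert assignments[0].haplotype == "Hun7"
        assert "Hun7" in reg.names and len(reg) == 7

    def test_allow_new_false_rejects_novelty(self, regional_bundle):
        ref = regional_bundle.reference
        reg = build_registry(ref)
        seq = list(reg.full_sequence("Hun1", *WINDOW))
        seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
        p = map_to_reference(("novel", "".join(seq)), ref, WIN)
        with pytest.raises(ValueError, match="registration disabled"):
            assign_haplotypes([p], reg, allow_new=False)

    def test_uninformative_fragment_consistent_with_all(self, regional_bundle):
        ref = regional_bundle.reference
        reg = build_registry(ref)
        # fragment upstream of every variable site
        frag = ref.subsequence(WINDOW[0], VARIABLE_SITES[0] - 10)
        p = map_to_reference(("frag", frag), ref, WIN)
        assignments, _ = assign_haplotypes([p], reg)
        a = assignments[0]
        assert not a.assigned
        assert set(a.consistency_set) == set(reg.names)
        assert a.missing_sites == VARIABLE_SITES

    def test_fragment_consistency_contains_source_haplotype(self,
                                                            regional_bundle):
        """Any contiguous fragment of a full-length sample remains consistent
        with that sample's haplotype."""
        from crhaplo import FragmentModel, fragment_samples
        ref = regional_bundle.reference
        reg = regional_bundle.registry
        full = [map_to_reference(r, ref, WIN)
                for r in regional_bundle.records[::17]]
        full_assign, reg = assign_haplotypes(full, reg)
        truth = {a.sample_id: a.haplotype for a in full_assign}
        frags = fragment_samples(regional_bundle.records[::17],
                                 FragmentModel(80, 400), seed=6)
        positioned = [map_to_reference(f, ref, WIN) for f in frags]
        frag_assign, _ = assign_haplotypes(positioned, reg)
        for a in frag_assign:
            members = (a.haplotype,) if a.assigned else a.consistency_set
            assert truth[a.sample_id] in members


class TestHaplotypeFrequencies:
    def test_global_counts_match_printed_inventory(self, global_results):
        pooled = global_results.population_table.pooled_counts()
        assert pooled == {"Hun1": 66, "Hun2": 108, "Hun3": 1, "Hun4": 1,
                          "Hun5": 9, "Hun6": 7}

    def test_row_sums_equal_region_sizes(self, regional_results):
        table = regional_results.population_table
        assert {r: table.n(r) for r in table.regions} == \
               {"NW": 34, "NM": 42, "NE": 41, "SW": 37, "SM": 31, "SE": 7}

    def test_proportions_simple_case(self):
        from crhaplo.diversity import PopulationTable
        t = PopulationTable.from_counts({"R": {"a": 3, "b": 1}})
        assert t.frequencies("R") == {"a": 0.75, "b": 0.25}

    def test_unlabelled_sample_is_error(self, regional_bundle):
        ref = regional_bundle.reference
        positioned = [map_to_reference(r, ref, WIN)
                      for r in regional_bundle.records[:3]]
        assignments, _ = assign_haplotypes(positioned,
                                           regional_bundle.registry)
        meta = regional_bundle.metadata[
            regional_bundle.metadata.sample_id != positioned[0].sample_id]
        with pytest.raises(KeyError, match="no region label"):
            haplotype_frequencies(assignments, meta)
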