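"""Classifier: element location, P-form calls, lineage/sub-lineage
assignment, haplotype calling and the in-silico DraI digest."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beemito import grammar
from beemito.mitotyping import (
    AmbiguousPForm,
    UnrecognizedAmplicon,
    assign_lineage,
    assign_sublineage,
    call_haplotype,
    insilico_dra1_digest,
    length_pattern,
    locate_elements,
    reverse_complement,
    type_sequence,
    type_sequences,
)
from beemito.refdata import Edit, build_catalog
from beemito.seqsim import ArchitectureSpec, add_noise, build_amplicon


def _sweep_specs():
    for p_form, n_q in itertools.product(grammar.P_FORMS, range(6)):
        if p_form == "P0":
            subs = ["none", "AI", "AII", "Z"]
        elif p_form == "P1":
            subs = ["none", "AIII"]
        else:
            subs = ["none"]
        for sub in subs:
            yield ArchitectureSpec(p_form, n_q, sub)


class TestLocateAndClassify:
    @pytest.mark.parametrize("spec", list(_sweep_specs()),
                             ids=lambda s: f"{s.p_form}-{s.n_q}q-{s.sublineage_template}")
    def test_classifier_inverts_generator(self, spec):
        """Noise-free generated amplicons are classified back to their true
        P form, Q count, pattern and sub-lineage for every architecture."""
        seq = build_amplicon(spec)
        emap = locate_elements(seq)
        assert emap.p_form == spec.p_form
        assert len(emap.q_spans) == spec.n_q
        want_pattern = (("" if spec.p_form == "absent" else spec.p_form)
                        + "Q" * spec.n_q)
        assert length_pattern(emap) == want_pattern
        got = assign_sublineage(emap.p_form, emap.dra1_sites, emap)
        if spec.p_form == "P1":
            # AIII is read from the P1 form alone
            assert got == "AIII"
        elif spec.p_form == "P0" and spec.n_q == 0 and \
                spec.sublineage_template != "none":
            # without a Q copy the Q-site diagnostics collapse; the tRNAleu
            # site alone is read as AI (the A65 configuration)
            assert got == "AI"
        else:
            assert got == spec.sublineage_template

    def test_c_architecture_has_no_p_span(self):
        emap = locate_elements(build_amplicon(ArchitectureSpec("absent", 1, "none")))
        assert emap.p_span is None
        assert len(emap.q_spans) == 1

    def test_q_less_architecture(self):
        emap = locate_elements(build_amplicon(ArchitectureSpec("P0", 0, "AI")))
        assert emap.q_spans == []
        assert emap.p_form == "P0"

    def test_short_sequence_rejected(self):
        with pytest.raises(UnrecognizedAmplicon):
            locate_elements("ACGT" * 10)

    def test_foreign_sequence_rejected(self):
        import numpy as np
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 700))
        with pytest.raises(UnrecognizedAmplicon):
            locate_elements(junk)

    def test_two_large_deletions_is_ambiguous(self):
        # a P element missing both the middle 13 bp and the 3' 15 bp
        p0 = grammar.TEMPLATES["p0"]
        p_broken = p0[:27] + p0[40:53]
        seq = (grammar.TEMPLATES["trnaleu"] + p_broken
               + grammar.TEMPLATES["q"] + grammar.TEMPLATES["cox2"])
        with pytest.raises(AmbiguousPForm):
            locate_elements(seq)

    def test_reverse_complement_auto_detected(self, catalog):
        seq = catalog.sequence("A4p")
        res = type_sequence(reverse_complement(seq), catalog)
        assert res.haplotype == "A4p"
        assert res.element_map.strand == "-"


class TestLineageRules:
    @pytest.mark.parametrize("p_form,lineage", [
        ("P0", "A"), ("P1", "A"), ("P", "M"), ("P2", "Y"), ("absent", "C")])
    def test_lineage_from_p_form(self, p_form, lineage):
        assert assign_lineage(p_form) == lineage

    def test_lineage_consistent_with_catalog_records(self, catalog):
        for rec in catalog.records:
            p_form = rec.pattern[:2] if rec.pattern[:2] in ("P0", "P1") else (
                "P" if rec.pattern.startswith("P") else "absent")
            assert assign_lineage(p_form) == rec.lineage


class TestHaplotypeCalling:
    def test_every_catalog_haplotype_called_by_name(self, catalog):
        for rec in catalog.records:
            res = type_sequence(catalog.sequence(rec.name), catalog)
            assert res.haplotype == rec.name
            assert not res.novel
            assert res.edits_vs_closest == ()
            assert res.sublineage == rec.sublineage

    def test_a1t_reconstructed_from_printed_edits(self, catalog):
        """A1 plus the three published edits (G99A, insertion A at 139,
        C646T) is called A1t."""
        row = catalog.family_base_row("A1")
        edited = grammar.apply_edits(row, (
            Edit(99, "G", "A"), Edit(139, "-", "A"), Edit(646, "C", "T")))
        res = type_sequence(grammar.degap(edited), catalog)
        assert res.haplotype == "A1t"
        assert not res.novel

    def test_novel_naming_on_reduced_catalog(self, catalog):
        reduced = build_catalog()
        reduced.records = [r for r in reduced.records if r.name != "A1t"]
        reduced.__post_init__()
        res = type_sequence(catalog.sequence("A1t"), reduced)
        assert res.novel
        assert res.closest_reference == "A1"          # ties break by order
        assert res.haplotype == "A1a"                 # first unused letter
        assert len(res.edits_vs_closest) == 3

    def test_novel_call_is_idempotent(self, catalog):
        """A never-seen variant gets the same coined name when its own
        sequence is re-typed."""
        seq = catalog.sequence("A4u")
        mutated = seq[:600] + ("A" if seq[600] != "A" else "G") + seq[601:]
        first = type_sequence(mutated, catalog)
        assert first.novel
        second = type_sequence(mutated, catalog)
        assert second.haplotype == first.haplotype
        assert second.edits_vs_closest == first.edits_vs_closest

    def test_pattern_without_catalog_members_flagged(self, catalog):
        seq = build_amplicon(ArchitectureSpec("P2", 1, "none"))
        res = type_sequence(seq, catalog)
        assert res.lineage == "Y"
        assert res.haplotype == "X1"
        assert any("curation" in n for n in res.notes)

    def test_full_survey_recovered_noise_free(self, catalog, survey):
        records, sheet, truth = survey
        results = type_sequences(records, catalog, sheet)
        truth_map = dict(zip(truth.sample_id,
                             zip(truth.haplotype, truth.lineage,
                                 truth.sublineage, truth.pattern)))
        hits = sum(
            (r.haplotype, r.lineage, r.sublineage, r.pattern)
            == truth_map[r.sample_id] for r in results)
        assert hits == len(records)

    def test_labels_robust_to_one_percent_noise(self, catalog, survey):
        records, sheet, truth = survey
        noisy, _ = add_noise(records[:150], 0.01, seed=13)
        truth_map = dict(zip(truth.sample_id,
                             zip(truth.lineage, truth.sublineage,
                                 truth.pattern)))
        results = type_sequences(noisy, catalog, sheet)
        hits = sum((r.lineage, r.sublineage, r.pattern)
                   == truth_map[r.sample_id] for r in results)
        assert hits / len(results) >= 0.99


class TestDigest:
    @pytest.mark.parametrize("seq,frags", [
        ("AAAA", [4]),
        ("CCTTTAAACC", [5, 5]),
        ("TTTAAA", [3, 3]),
        ("TTTAAATTTAAA", [3, 6, 3]),
    ])
    def test_examples(self, seq, frags):
        assert insilico_dra1_digest(seq) == frags

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_conservation(self, seq):
        frags = insilico_dra1_digest(seq)
        assert sum(frags) == len(seq)
        assert len(frags) == seq.count("TTTAAA") + 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            insilico_dra1_digest("")
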