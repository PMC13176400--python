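"""Cassette construction, Type IIS scanning, and sticky-end assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sybodykit.assembly import (
    ENZYMES,
    AssemblyError,
    CodonTable,
    Fragment,
    build_cassette,
    feature_table,
    reverse_translate,
    revcomp,
    scan_restriction_sites,
    simulate_assembly,
    translate,
    type_iis_digest,
    verify_cassette,
)
from sybodykit.design import AMINO_ACIDS

# printed primer sequences used for in-silico verification
FW2_R = "ATGCATGGTCTCACCCATTCGCGCTCCTTCCCTGGAGCTTGACGAAACC"
TOLA_R2 = "CAGCAGCTATAGCTCTTCAAAACC"
LINK1_F = "GAATGGGTGAGACCATGCATGAAGACCTTGGGTTGC"
FLANK_F = "CGAAATTAATACGACTCACTATAGGGAGAC"


def brute_force_hits(dna: str, site: str) -> set:
    """All-substring oracle for recognition-site scanning."""
    hits = set()
    rc = revcomp(site)
    for i in range(len(dna) - len(site) + 1):
        window = dna[i:i + len(site)]
        if window == site:
            hits.add((i, "+"))
        if window == rc:
            hits.add((i, "-"))
    return hits


class TestCodonTable:
    def test_default_table_round_trips_every_amino_acid(self, ecoli_table):
        for aa in AMINO_ACIDS:
            assert translate(ecoli_table.codon_of[aa]) == aa

    def test_incomplete_table_rejected(self):
        partial = {aa: CodonTable.ecoli().codon_of[aa] for aa in "ACD"}
        with pytest.raises(AssemblyError, match="missing"):
            CodonTable(partial)

    def test_wrong_codon_assignment_rejected(self):
        codons = dict(CodonTable.ecoli().codon_of)
        codons["A"] = "TTT"   # encodes F
        with pytest.raises(AssemblyError):
            CodonTable(codons)


class TestReverseTranslate:
    @pytest.mark.parametrize("peptide, nt_len", [
        ("SLEHHHHHH", 27),          # Legobody linker
        ("GLNDIFEAQKIEWHE", 45),    # Avi tag
        ("", 0),
    ])
    def test_known_peptides_round_trip(self, ecoli_table, peptide, nt_len):
        orf = reverse_translate(peptide, ecoli_table)
        assert len(orf.sequence) == nt_len
        assert translate(orf.sequence) == peptide

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60))
    def test_round_trip_is_identity(self, protein):
        orf = reverse_translate(protein, CodonTable.ecoli())
        assert translate(orf.sequence) == protein

    def test_design_slots_cover_allowed_letters(self, s10, ecoli_table):
        orf = reverse_translate(s10.scaffold, ecoli_table, s10)
        assert set(orf.slots) == set(s10.randomized_positions)
        for pos, alts in orf.slots.items():
            assert set(alts) == set(s10.composition_at(pos).weights)
            for aa, codon in alts.items():
                assert translate(codon) == aa

    def test_off_design_residue_rejected(self, s10, ecoli_table):
        pos = s10.randomized_positions[0]
        allowed = set(s10.composition_at(pos).weights)
        bad = next(a for a in AMINO_ACIDS if a not in allowed)
        mutated = (s10.scaffold[:pos] + bad + s10.scaffold[pos + 1:])
        with pytest.raises(AssemblyError, match="allowed set"):
            reverse_translate(mutated, ecoli_table, s10)


class TestRestrictionScan:
    def test_bsai_site_in_fw2r_primer(self):
        hits = scan_restriction_sites(FW2_R, ["BsaI"])
        assert [(h.start, h.strand) for h in hits] == [(6, "+")]

    def test_bspqi_site_in_tola_r2_primer(self):
        hits = scan_restriction_sites(TOLA_R2, ["BspQI"])
        assert [(h.start, h.strand) for h in hits] == [(11, "+")]

    def test_link1f_has_bbsi_plus_and_bsai_minus(self):
        bbsi = scan_restriction_sites(LINK1_F, ["BbsI"])
        assert [(h.start, h.strand) for h in bbsi] == [(20, "+")]
        bsai = scan_restriction_sites(LINK1_F, ["BsaI"])
        assert [(h.start, h.strand) for h in bsai] == [(8, "-")]

    def test_no_hits_gives_empty_list(self):
        assert scan_restriction_sites("ACGTACGTACGT", ["BsaI"]) == []

    def test_non_acgt_rejected(self):
        with pytest.raises(AssemblyError, match="non-ACGT"):
            scan_restriction_sites("ACGTN", ["BsaI"])

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=400),
           st.sampled_from(sorted(ENZYMES)))
    def test_scan_agrees_with_brute_force_oracle(self, dna, enzyme):
        hits = scan_restriction_sites(dna, [enzyme])
        got = {(h.start, h.strand) for h in hits}
        assert got == brute_force_hits(dna, ENZYMES[enzyme].site)

    def test_printed_primers_against_oracle(self):
        for primer in (FW2_R, TOLA_R2, LINK1_F, FLANK_F):
            for enzyme, enz in ENZYMES.items():
                got = {(h.start, h.strand)
                       for h in scan_restriction_sites(primer, [enzyme])}
                assert got == brute_force_hits(primer, enz.site)


def _three_fragments():
    """Synthetic fragment trio with unique 4-nt overhangs."""
    return [
        Fragment("left", "ATGGCTTTAGGCA", None, "GGCA"),
        Fragment("mid", "GGCATTCCGAACCT", "GGCA", "ACCT"),
        Fragment("right", "ACCTGGGTTTAA", "ACCT", None),
    ]


class TestAssembly:
    def test_three_fragments_join_once(self):
        t = simulate_assembly(_three_fragments())
        assert t.sequence == "ATGGCTTTAGGCATTCCGAACCTGGGTTTAA"
        assert [e.name for e in t.elements] == ["left", "mid", "right"]

    def test_joined_length_arithmetic(self):
        frags = _three_fragments()
        t = simulate_assembly(frags)
        overhang_total = 4 + 4   # one shared overhang per junction
        assert len(t.sequence) == sum(len(f.seq) for f in frags) - overhang_total

    def test_order_independent_and_deterministic(self):
        a = simulate_assembly(_three_fragments())
        b = simulate_assembly(list(reversed(_three_fragments())))
        assert a.sequence == b.sequence

    def test_identical_overhangs_are_ambiguous(self):
        frags = [
            Fragment("left", "ATGGCTGGCA", None, "GGCA"),
            Fragment("m1", "GGCATTCAAA", "GGCA", None),
            Fragment("m2", "GGCAGGGTTT", "GGCA", None),
        ]
        with pytest.raises(AssemblyError, match="ambiguous"):
            simulate_assembly(frags)

    def test_incompatible_overhang_names_junction(self):
        frags = [
            Fragment("left", "ATGGCTGGCA", None, "GGCA"),
            Fragment("right", "TTTTAAACCC", "TTTT", None),
        ]
        with pytest.raises(AssemblyError, match="GGCA"):
            simulate_assembly(frags)

    def test_overhang_must_match_fragment_sequence(self):
        with pytest.raises(AssemblyError, match="prefix"):
            Fragment("bad", "ATGC", "GGGG", None)

    def test_digest_then_religate_restores_sequence(self):
        # one BsaI site in the middle: GGTCTC N1 + 4-nt overhang
        dna = "AAATTTGGTCTCAGGCCTTTACGATCGATC"
        frags = type_iis_digest(dna, "BsaI")
        assert len(frags) == 2
        assert frags[1].left_overhang == frags[0].right_overhang
        t = simulate_assembly(frags)
        assert t.sequence == dna

    def test_frameshifted_join_fails_orf_verification(self, s10):
        # drop one base at a junction: translation oracle catches the shift
        good = build_cassette(s10)
        orf = good.segment("ORF")
        shifted = orf[:30] + orf[31:]
        assert len(shifted) % 3 != 0
        protein = translate(shifted[: 3 * (len(shifted) // 3)])
        assert "*" in protein or protein != translate(orf)


class TestVerifyCassette:
    def test_s10_cassette_passes_all_checks(self, s10_template):
        report = verify_cassette(s10_template)
        assert report.passed, report.checks
        assert report.warnings == ()

    def test_t7_core_is_inside_printed_flank_primer(self):
        hits = FLANK_F.find("TAATACGACTCACTATAG")
        assert hits != -1

    def test_deleting_promoter_fails_promoter_check(self, s10):
        from sybodykit.assembly import ConstructTemplate, Element
        t = build_cassette(s10)
        prom = t.element("promoter")
        seq = t.sequence[prom.end:]
        shift = prom.end
        elements = tuple(
            Element(e.name, e.start - shift, e.end - shift)
            for e in t.elements if e.name != "promoter"
        )
        broken = ConstructTemplate(seq, elements)
        report = verify_cassette(broken)
        assert not report.checks["promoter"]
        assert not report.passed

    def test_internal_stop_is_flagged(self, s10):
        from sybodykit.assembly import ConstructTemplate
        t = build_cassette(s10)
        orf = t.element("ORF")
        # mutate a codon to TAA in frame
        i = orf.start + 33
        seq = t.sequence[:i] + "TAA" + t.sequence[i + 3:]
        broken = ConstructTemplate(seq, t.elements)
        report = verify_cassette(broken)
        assert not report.checks["no_internal_stop"]
        assert any("stop" in w for w in report.warnings)

    def test_feature_table_lists_all_elements(self, s10_template):
        text = feature_table(s10_template)
        for name in ("promoter", "RBS", "ORF", "linker", "spacer"):
            assert name in text

    def test_rt_primer_site_embedded_in_spacer(self, s10_template):
        from sybodykit.assembly import RT_PRIMER
        assert revcomp(RT_PRIMER) in s10_template.segment("spacer")
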