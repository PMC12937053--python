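"""Peptide mass arithmetic, labels, fragments, digestion, variant panels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from pairdia.chem import (
    HEAVY_E_SHIFT,
    HEAVY_K_SHIFT,
    PROTON_MASS,
    IsotopePair,
    LabeledPeptide,
    LabelKind,
    Variant,
    classify_pair_fragments,
    digest,
    fragment_series,
    get_protease,
    make_pair,
    peptide_monoisotopic_mass,
    precursor_ion,
    precursor_mz,
    variant_panel,
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=25)


class TestMass:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ITDFGRAK", 906.4923), ("G", 75.0320), ("ELREATSPK", 1029.5455)],
    )
    def test_monoisotopic_mass_matches_frozen_values(self, seq, expected):
        assert peptide_monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-4)

    @given(sequences)
    @settings(deadline=None, max_examples=50)
    def test_mass_agrees_with_elemental_composition_oracle(self, seq):
        # independent route: pyteomics sums elemental compositions
        assert peptide_monoisotopic_mass(seq) == pytest.approx(
            pmass.calculate_mass(sequence=seq), abs=1e-4
        )

    def test_label_shift_is_additive(self):
        light = LabeledPeptide("ITDFGRAK")
        heavy = light.with_label(LabelKind.HEAVY_K)
        assert peptide_monoisotopic_mass(heavy) == pytest.approx(
            peptide_monoisotopic_mass(light) + 8.0142, abs=1e-3
        )
        assert HEAVY_K_SHIFT == pytest.approx(8.0142, abs=1e-3)
        assert HEAVY_E_SHIFT == pytest.approx(6.0138, abs=1e-3)

    def test_non_canonical_residue_named_in_error(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            LabeledPeptide("AABAA")

    def test_label_residue_mismatch_rejected(self):
        with pytest.raises(ValueError, match="C-terminal"):
            LabeledPeptide("PEPTIDER").with_label(LabelKind.HEAVY_K)


class TestPrecursor:
    @pytest.mark.parametrize(
        "seq, kind, expected",
        [
            ("ITDFGRAK", LabelKind.NONE, 454.25),
            ("ITDFGRAK", LabelKind.HEAVY_K, 458.26),
            ("ELREATSPK", LabelKind.NONE, 515.78),
            ("ELREATSPK", LabelKind.HEAVY_K, 519.79),
        ],
    )
    def test_2plus_mz_matches_reported_values(self, seq, kind, expected):
        pep = LabeledPeptide(seq)
        if kind is not LabelKind.NONE:
            pep = pep.with_label(kind)
        assert round(precursor_mz(pep, 2), 2) == expected

    def test_charge_below_one_rejected(self):
        with pytest.raises(ValueError, match="charge"):
            precursor_mz("PEPTIDE", 0)

    @given(sequences, st.integers(1, 4))
    @settings(deadline=None, max_examples=50)
    def test_charge_relation(self, seq, z):
        mz = precursor_mz(seq, z)
        assert mz * z - z * PROTON_MASS == pytest.approx(
            peptide_monoisotopic_mass(seq), abs=1e-4
        )

    def test_pair_spacing_is_shift_over_charge(self, l858r_pair):
        assert l858r_pair.mz_spacing == pytest.approx(HEAVY_K_SHIFT / 2, abs=1e-4)
        z3 = make_pair("ITDFGRAK", 3)
        assert z3.mz_spacing == pytest.approx(HEAVY_K_SHIFT / 3, abs=1e-4)

    def test_pair_requires_matching_sequence_and_charge(self):
        light = precursor_ion("ITDFGRAK", 2)
        other = precursor_ion(
            LabeledPeptide("ELREATSPK").with_label(LabelKind.HEAVY_K), 2
        )
        with pytest.raises(ValueError, match="sequence"):
            IsotopePair(light, other)


class TestFragments:
    def test_y4_of_elre_peptide(self):
        frags = {f.name: f for f in fragment_series("ELREATSPK")}
        assert frags["y4"].mz == pytest.approx(432.245, abs=1e-3)

    def test_heavy_y_ions_shifted_by_full_label(self):
        light = {f.name: f.mz for f in fragment_series("ELREATSPK")}
        heavy = {
            f.name: f.mz
            for f in fragment_series(
                LabeledPeptide("ELREATSPK").with_label(LabelKind.HEAVY_K)
            )
        }
        for j in range(1, 9):
            assert heavy[f"y{j}"] - light[f"y{j}"] == pytest.approx(8.0142, abs=1e-3)
            assert heavy.get(f"b{j}") == light.get(f"b{j}")

    def test_c_terminal_label_marks_exactly_the_y_series(self):
        frags = fragment_series(LabeledPeptide("ELREATSPK").with_label(LabelKind.HEAVY_K))
        for f in frags:
            assert f.carries_label == (f.series == "y")

    @given(sequences)
    @settings(deadline=None, max_examples=50)
    def test_by_complementarity(self, seq):
        n = len(seq)
        neutral = peptide_monoisotopic_mass(seq)
        frags = {f.name: f.mz for f in fragment_series(seq)}
        for i in range(1, n):
            total = frags[f"b{i}"] + frags[f"y{n - i}"]
            assert total == pytest.approx(neutral + 2 * PROTON_MASS, abs=1e-3)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fragment_series("G")


class TestClassify:
    def test_coisolation_shares_b_and_separates_y(self, elre_pair):
        part = classify_pair_fragments(elre_pair, coisolated=True)
        assert sorted(f.name for f in part.shared) == [f"b{i}" for i in range(1, 9)]
        assert sorted(f.name for f in part.unique_light) == [
            f"y{i}" for i in range(1, 9)
        ]
        assert len(part.unique_heavy) == 8
        assert part.quantifiable_count_light == 8

    def test_separated_observed_set_counts_ten_quantifiable_ions(self, elre_pair):
        observed = {"b3", "b4", "b5", "b6", "b7", "y3", "y4", "y5", "y6", "y8"}
        part = classify_pair_fragments(elre_pair, coisolated=False, observed=observed)
        assert part.quantifiable_count_light == 10
        # the same observed set under coisolation keeps only the y ions
        co = classify_pair_fragments(elre_pair, coisolated=True, observed=observed)
        assert co.quantifiable_count_light == 5

    def test_unlabeled_pair_is_fully_shared(self):
        # a "pair" of identical species shares every fragment
        light = precursor_ion("SAMPLEK", 2)
        heavy = precursor_ion(
            LabeledPeptide("SAMPLEK").with_label(LabelKind.HEAVY_K), 2
        )
        pair = IsotopePair(light, heavy)
        unlabeled = IsotopePair(light, heavy)
        part = classify_pair_fragments(pair, coisolated=True, mz_tolerance=100.0)
        assert not part.unique_light and len(part.shared) == 12

    @given(st.text(alphabet="ACDEFGHILMNPQRSTVWY", min_size=2, max_size=20))
    @settings(deadline=None, max_examples=40)
    def test_mz_partition_agrees_with_label_span_oracle(self, body):
        """Brute-force oracle: unique iff the fragment span carries the label."""
        pair = make_pair(body + "K", 2)
        part = classify_pair_fragments(pair, coisolated=True, mz_tolerance=0.01)
        by_label = {f.name for f in fragment_series(pair.heavy.peptide) if f.carries_label}
        assert {f.name for f in part.unique_light} == by_label
        assert {f.name for f in part.shared} == {
            f.name for f in fragment_series(body + "K")
        } - by_label


class TestDigest:
    def test_lysc_cleaves_after_every_k(self):
        peps = digest("AKELREATSPKG", "lysc", 0)
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("AK", 1, 2),
            ("ELREATSPK", 3, 11),
            ("G", 12, 12),
        ]

    def test_gluc_cleaves_after_every_e(self):
        peps = digest("AEKVE", "gluc", 0)
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("AE", 1, 2),
            ("KVE", 3, 5),
        ]

    def test_missed_cleavages_emit_adjacent_concatenations(self):
        got = {
            (p.sequence, p.start, p.end) for p in digest("AKELREATSPKG", "lysc", 1)
        }
        assert ("AKELREATSPK", 1, 11) in got
        assert ("ELREATSPKG", 3, 12) in got

    def test_trypsin_p_vs_classical_before_proline(self):
        assert [p.sequence for p in digest("AKPGR", "trypsin_p", 0)] == ["AK", "PGR"]
        assert [p.sequence for p in digest("AKPGR", "trypsin", 0)] == ["AKPGR"]

    def test_unknown_protease_rejected(self):
        with pytest.raises(ValueError, match="unknown protease"):
            digest("PEPTIDEK", "chymotrypsin", 0)
        with pytest.raises(ValueError, match="unknown protease"):
            get_protease("nope")

    @given(sequences)
    @settings(deadline=None, max_examples=50)
    def test_zero_missed_cleavage_digest_partitions_protein(self, protein):
        peps = digest(protein, "trypsin_p", 0)
        assert "".join(p.sequence for p in peps) == protein
        cursor = 1
        for p in peps:
            assert p.start == cursor
            cursor = p.end + 1


# Synthetic context around the receptor kinase-domain motif: the real
# numbering places the mutated leucine at 858 inside the tryptic peptide
# spanning 853-860; the padding residues are synthetic.
_KINASE_CONTEXT = "A" * 851 + "K" + "ITDFGLAK" + "LVGAEE" + "K" + "AAAAAAA"


class TestVariantPanel:
    def test_only_peptides_spanning_the_site_are_returned(self):
        result = variant_panel(
            "MKAAGKLLRKE",
            Variant("sub", 4, ref="A", alt="V"),
            ["lysc"],
            length_range=(2, 52),
            scan_range=(50.0, 2000.0),
        )
        for cand in result.candidates:
            assert cand.peptide.start <= 4 <= cand.peptide.end
        assert any(c.peptide.sequence == "AVGK" for c in result.candidates)

    def test_kinase_domain_point_mutation_yields_reported_peptide(self):
        result = variant_panel(
            _KINASE_CONTEXT,
            Variant("sub", 858, ref="L", alt="R"),
            ["lysc"],
            protein_id="EGFR",
        )
        mut = [c for c in result.candidates if c.peptide.sequence == "ITDFGRAK"]
        assert mut, "variant peptide missing from panel"
        cand = mut[0]
        assert (cand.peptide.start, cand.peptide.end) == (853, 860)
        assert cand.role == "mutant"
        assert cand.heavy.label.kind is LabelKind.HEAVY_K
        assert (round(cand.light_mz, 2), round(cand.heavy_mz, 2)) == (454.25, 458.26)
        wt = [c for c in result.candidates if c.peptide.sequence == "ITDFGLAK"]
        assert wt and wt[0].role == "wild_type"

    def test_length_bounds_exclude_6_and_53_residue_candidates(self):
        short = variant_panel(
            "MKAAGKLLRKE",
            Variant("sub", 4, ref="A", alt="V"),
            ["lysc"],
            max_missed_cleavages=0,
        )
        # AVGK (length 4) fails the 7-52 rule and is recorded as excluded
        assert not any(c.peptide.sequence == "AVGK" for c in short.candidates)
        assert any(
            seq == "AVGK" and "length" in reason for seq, reason in short.excluded
        )
        long_prot = "MK" + "A" * 20 + "S" + "A" * 31 + "K"
        long = variant_panel(
            long_prot,
            Variant("sub", 23, ref="S", alt="T"),
            ["lysc"],
            max_missed_cleavages=0,
        )
        assert not long.candidates
        assert any("length 53" in reason for _, reason in long.excluded)

    def test_deletion_keeps_junction_spanning_peptides(self):
        # deleting 5 residues: remaining peptides must straddle the junction
        protein = "MKAAAVVVVVSSSKGGGK"
        result = variant_panel(
            protein,
            Variant("del", 6, end=10),
            ["lysc"],
            length_range=(2, 52),
            scan_range=(50.0, 2000.0),
            max_missed_cleavages=0,
        )
        mutant_seq = protein[:5] + protein[10:]
        for c in result.candidates:
            if c.role == "mutant":
                assert c.peptide.start <= 5 and c.peptide.end >= 6
                assert c.peptide.sequence in mutant_seq

    def test_variant_outside_protein_rejected(self):
        with pytest.raises(ValueError, match="outside protein"):
            variant_panel("MKAAGK", Variant("sub", 99, ref="A", alt="V"), ["lysc"])
        with pytest.raises(ValueError, match="reference mismatch"):
            variant_panel("MKAAGK", Variant("sub", 2, ref="A", alt="V"), ["lysc"])
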