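"""Precursor maturation: signal removal, cleavage, trimming, amidation."""

import pytest
from hypothesis import given, settings, strategies as st

from neuromine.maturation import (
    DIBASIC_GRAMMAR,
    DegenerateSegmentError,
    SignalPrediction,
    find_cleavage_sites,
    predict_signal_peptide,
    process_precursor,
    segment_propeptide,
    trim_and_modify,
)
from neuromine.synthetic_data import PrecursorSpec, build_precursor_protein, synthetic_signal


class TestSignalHeuristic:
    def test_constructed_signal_recovered_exactly(self):
        # Met + Leu h-region + A-F-A peptidase box; only one point qualifies
        for length in (9, 15, 27, 33, 45):
            protein = synthetic_signal(length) + "HNNYAFGLGKRTPDYAFGLGKR"
            pred = predict_signal_peptide(protein)
            assert pred.length_aa == length
            assert pred.source == "heuristic"

    def test_no_hydrophobic_core_means_no_signal(self):
        assert predict_signal_peptide("G" * 60).length_aa == 0

    def test_short_protein_gets_zero_with_zero_score(self):
        pred = predict_signal_peptide("MKTLLVALSA")
        assert (pred.length_aa, pred.score) == (0, 0.0)

    def test_external_annotation_overrides_heuristic(self):
        protein = synthetic_signal(20) + "HNNYAFGLGKR"
        external = SignalPrediction(18, "external", 1.0)
        model, _ = process_precursor(protein, signal=external)
        assert model.signal.source == "external"
        assert model.propeptide == protein[18:]


class TestCleavageScan:
    def test_single_dibasic_site(self):
        (site,) = find_cleavage_sites("AAKRGG")
        assert (site.motif, site.pos_aa, site.kind) == ("KR", 4, "dibasic")

    def test_orcokinin_internal_basics_are_not_sites(self):
        # two printed orcokinin segments joined: only KR@13 and terminal KK
        prop = "FDAFTTGFGHSKR" + "NFDEIDRSGFAFAKK"
        sites = find_cleavage_sites(prop)
        assert [(s.motif, s.pos_aa) for s in sites] == [("KR", 13), ("KK", 28)]

    def test_overlapping_basics_resolve_leftmost(self):
        sites = find_cleavage_sites("GKRR")
        assert [(s.motif, s.pos_aa) for s in sites] == [("KR", 3)]

    def test_overlap_rule_matches_brute_force_enumeration(self):
        # oracle: simulate the scan by explicit enumeration of placements
        for prop in ("KRRK", "AKKRRA", "RRRR", "KRKKRR"):
            expected = []
            i = 0
            while i < len(prop) - 1:
                pair = prop[i : i + 2]
                if pair in DIBASIC_GRAMMAR:
                    expected.append((pair, i + 2))
                    i += 2
                else:
                    i += 1
            got = [(s.motif, s.pos_aa) for s in find_cleavage_sites(prop)]
            assert got == expected, prop

    def test_monobasic_r_is_opt_in(self):
        assert find_cleavage_sites("AARAA") == []
        (site,) = find_cleavage_sites("AARAA", monobasic_r=True)
        assert (site.motif, site.kind) == ("R", "monobasic")


class TestSegmentation:
    def test_cut_after_motif(self):
        prop = "AKRB".replace("B", "W")
        segs = segment_propeptide(prop, find_cleavage_sites(prop))
        assert [s for s, _ in segs] == ["AKR", "W"]

    def test_no_sites_is_identity(self):
        segs = segment_propeptide("ALGEW", [])
        assert segs == [("ALGEW", 1)]

    def test_concatenation_reconstructs_propeptide(self, peptides_by_family):
        prop = "".join(p for p, _ in peptides_by_family["Orcokinin"])
        segs = segment_propeptide(prop, find_cleavage_sites(prop))
        assert "".join(s for s, _ in segs) == prop
        assert len(segs) == 11

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_segments_conserve_sequence(self, prop):
        segs = segment_propeptide(prop, find_cleavage_sites(prop))
        assert "".join(s for s, _ in segs) == prop


class TestTrimAndModify:
    @pytest.mark.parametrize(
        "segment,motif,sequence,amidated",
        [
            ("HNNYAFGLGKR", "KR", "HNNYAFGL", True),
            ("APSGFLGMRGKR", "KR", "APSGFLGMR", True),  # peptide keeps its own R
            ("EDSPASDAYTLKR", "KR", "EDSPASDAYTL", False),
            ("SGGEYDDYGHLRFG", "", "SGGEYDDYGHLRF", True),  # terminal segment
        ],
    )
    def test_printed_peptides(self, segment, motif, sequence, amidated):
        pep = trim_and_modify(segment, motif)
        assert (pep.sequence, pep.amidated) == (sequence, amidated)

    def test_pyroglutamate_flagged_not_edited(self):
        pep = trim_and_modify("QTFQYSRGWTNGKR", "KR")
        assert pep.sequence == "QTFQYSRGWTN"
        assert pep.amidated and pep.pyroglutamate

    def test_trimming_to_nothing_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            trim_and_modify("KR", "KR")


class TestProcessPrecursor:
    def _run(self, family, signal_len, peptides_by_family, repeat=None):
        peps = peptides_by_family[family]
        if repeat:
            peps = peps * repeat
        spec = PrecursorSpec(family=family, peptides=tuple(peps), signal_length=signal_len)
        protein, truth = build_precursor_protein(spec)
        model, mature = process_precursor(
            protein, SignalPrediction(signal_len, "external", 1.0)
        )
        return peps, truth, mature

    def test_a_type_allatostatin_releases_22_peptides(self, peptides_by_family):
        peps, truth, mature = self._run("Allatostatin A", 27, peptides_by_family)
        assert len(mature) == 22
        assert [(m.sequence, m.amidated) for m in mature] == peps

    def test_internal_single_basics_never_split(self, peptides_by_family):
        _, _, mature = self._run("Allatostatin A", 27, peptides_by_family)
        by_seq = {m.sequence for m in mature}
        assert "NRQYSFGL" in by_seq  # internal R retained
        assert "SDLYDNDLGRSYDFGL" in by_seq  # internal GR retained

    def test_sulfakinin_lengths_10_and_13(self, peptides_by_family):
        _, _, mature = self._run("Sulfakinin", 27, peptides_by_family)
        assert sorted(len(m.sequence) for m in mature) == [10, 13]
        assert all(m.amidated for m in mature)

    def test_tachykinin_seven_identical_9mers(self, peptides_by_family):
        _, _, mature = self._run("Tachykinin", 22, peptides_by_family, repeat=7)
        assert len(mature) == 7
        assert {m.sequence for m in mature} == {"APSGFLGMR"}
        assert all(m.amidated and len(m.sequence) == 9 for m in mature)

    def test_degenerate_terminal_peptide(self):
        protein = synthetic_signal(15) + "AG"
        model, mature = process_precursor(protein, SignalPrediction(15, "external"))
        (pep,) = mature
        assert pep.sequence == "A" and pep.amidated

    def test_coordinates_map_back_to_full_protein(self, peptides_by_family):
        peps = peptides_by_family["Allatostatin C"]
        spec = PrecursorSpec(family="C", peptides=tuple(peps), signal_length=22)
        protein, truth = build_precursor_protein(spec)
        _, mature = process_precursor(protein, SignalPrediction(22, "external"))
        for expected, got in zip(truth, mature):
            assert (got.start_aa, got.end_aa) == (expected["start_aa"], expected["end_aa"])
            assert protein[got.start_aa - 1 : got.end_aa] == got.sequence

    def test_raw_segments_join_to_propeptide(self, peptides_by_family):
        peps = peptides_by_family["Allatostatin B"]
        spec = PrecursorSpec(family="B", peptides=tuple(peps), signal_length=33)
        protein, _ = build_precursor_protein(spec)
        model, mature = process_precursor(protein, SignalPrediction(33, "external"))
        assert "".join(m.raw_segment for m in mature) == model.propeptide
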