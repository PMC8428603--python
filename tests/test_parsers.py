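"""Format readers: RR contacts/distograms, ss2, disorder, topology, grades, custom tracks."""

import numpy as np
import pytest

from cmapviz.errors import ParserError, ValidationError
from cmapviz.parsers import (
    conservation_palette,
    instructions_to_track,
    parse_consurf,
    parse_custom_track,
    parse_fasta,
    parse_iupred,
    parse_psipred_ss2,
    parse_rr_contacts,
    parse_rr_distogram,
    parse_topcons,
    write_rr,
)
from conftest import random_contact_map


class TestRRContacts:
    def test_five_column_dialect(self):
        cmap = parse_rr_contacts("1 9 0 8 0.95\n2 11 0 8 0.80\n")
        assert len(cmap) == 2
        assert cmap.score(1, 9) == pytest.approx(0.95)
        assert cmap.score(2, 11) == pytest.approx(0.80)

    def test_three_column_dialect_with_headers(self):
        cmap = parse_rr_contacts("PFRMAT RR\nMODEL 1\n1 9 0.95\nEND\n")
        assert len(cmap) == 1 and cmap.score(1, 9) == pytest.approx(0.95)

    def test_mixed_dialects_in_one_file(self):
        cmap = parse_rr_contacts("1 9 0.95\n2 11 0 8 0.80\n")
        assert len(cmap) == 2

    def test_sequence_line_sets_length(self):
        cmap = parse_rr_contacts("PFRMAT RR\nMALWMRLLPLLALLALWGPDPAAA\n1 9 0.9\nEND\n")
        assert cmap.seq_length == 24
        assert cmap.sequence.startswith("MALW")

    def test_malformed_data_line_names_line_number(self):
        with pytest.raises(ParserError, match="line 1"):
            parse_rr_contacts("1 9 x\n")

    def test_headers_only_is_an_error(self):
        with pytest.raises(ParserError, match="no contacts"):
            parse_rr_contacts("PFRMAT RR\nEND\n")

    def test_index_beyond_supplied_length_rejected(self):
        with pytest.raises(ValidationError, match="9"):
            parse_rr_contacts("1 9 0.5\n", seq_length=8)

    def test_roundtrip_both_dialects(self, rng):
        for _ in range(20):
            cmap = random_contact_map(rng, int(rng.integers(10, 60)))
            if len(cmap) == 0:
                continue
            for dialect in ("3col", "5col"):
                assert parse_rr_contacts(write_rr(cmap, dialect)) == cmap

    def test_no_silent_line_drops(self):
        text = "PFRMAT RR\nMALW\n1 3 0.5\n\nEND\n"
        lines = [ln for ln in text.splitlines() if ln.strip()]
        headers = sum(1 for ln in lines if ln.split()[0] in ("PFRMAT", "END"))
        seqs = sum(1 for ln in lines if ln.replace(" ", "").isalpha() and ln.split()[0] not in ("PFRMAT", "END"))
        data = len(parse_rr_contacts(text))
        assert headers + seqs + data == len(lines)


class TestRRDistogram:
    header = "PFRMAT RR\nRMODE 2\nMODEL 1\n"

    def test_one_hot_vector_lands_in_first_bin(self):
        text = self.header + "1 9 1 0 0 0 0 0 0 0 0 0\nEND\n"
        d = parse_rr_distogram(text)
        assert d.entries[(1, 9)][0] == pytest.approx(1.0)

    def test_small_sum_deviation_renormalized(self):
        vec = "0.505 0.5 0 0 0 0 0 0 0 0"  # sums to 1.005
        d = parse_rr_distogram(self.header + f"1 9 {vec}\nEND\n")
        assert d.entries[(1, 9)].sum() == pytest.approx(1.0, abs=1e-9)

    def test_large_sum_deviation_rejected(self):
        vec = "0.55 0.5 0 0 0 0 0 0 0 0"  # sums to 1.05
        with pytest.raises(ParserError, match="sums to"):
            parse_rr_distogram(self.header + f"1 9 {vec}\nEND\n")

    def test_wrong_probability_count_rejected(self):
        vec = " ".join(["0.111"] * 9)
        with pytest.raises(ParserError, match="expected 10 probabilities"):
            parse_rr_distogram(self.header + f"1 9 {vec}\nEND\n")

    def test_missing_rmode_header_requires_forcing(self):
        body = "1 9 1 0 0 0 0 0 0 0 0 0\n"
        with pytest.raises(ParserError, match="RMODE"):
            parse_rr_distogram(body)
        d = parse_rr_distogram(body, require_rmode=False)
        assert (1, 9) in d.entries


class TestPsipredSS2:
    body = (
        "# PSIPRED VFORMAT\n\n"
        "1 M C  0.9 0.1 0.0\n"
        "2 A H  0.1 0.8 0.1\n"
        "3 L H  0.1 0.9 0.0\n"
    )

    def test_states_and_called_probabilities(self):
        track = parse_psipred_ss2(self.body)
        assert track.states == ["C", "H", "H"]
        assert track.values == pytest.approx([0.9, 0.8, 0.9])

    def test_default_palette_covers_states(self):
        track = parse_psipred_ss2(self.body)
        assert track.palette["H"] == "red" and track.palette["C"] == "green"

    def test_empty_body_is_an_error(self):
        with pytest.raises(ParserError, match="no residues"):
            parse_psipred_ss2("# PSIPRED VFORMAT\n\n")

    def test_unknown_state_names_line(self):
        with pytest.raises(ParserError, match="line 2"):
            parse_psipred_ss2("1 M C 0.9 0.1 0.0\n2 A X 0.1 0.8 0.1\n")

    def test_numbering_gap_rejected(self):
        with pytest.raises(ParserError, match="gap"):
            parse_psipred_ss2("1 M C 0.9 0.1 0.0\n3 A H 0.1 0.8 0.1\n")


class TestIupred:
    def test_threshold_splits_ordered_disordered(self):
        track = parse_iupred("1 M 0.2\n2 A 0.7\n")
        assert track.states == ["ordered", "disordered"]

    def test_boundary_counts_as_disordered(self):
        assert parse_iupred("1 M 0.5\n").states == ["disordered"]

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ParserError, match="outside"):
            parse_iupred("1 M 1.3\n")


class TestTopcons:
    def test_maps_characters_to_topology_states(self):
        track = parse_topcons("ooMMMiii")
        assert track.seq_length == 8
        assert track.states[:2] == ["outside", "outside"]
        assert track.states[2:5] == ["membrane"] * 3
        assert track.states[5:] == ["inside"] * 3

    def test_wrapped_lines_concatenated(self):
        assert parse_topcons("ooM\nMMi\nii\n").seq_length == 8

    def test_empty_topology_rejected(self):
        with pytest.raises(ParserError, match="empty topology"):
            parse_topcons("")

    def test_bad_character_reports_position(self):
        with pytest.raises(ParserError, match="position 3"):
            parse_topcons("ooXii")

    def test_full_results_file_uses_consensus_block(self):
        text = (
            "TOPCONS result file\n"
            "TOPCONS predicted topology:\n"
            "ooMMMiii\n"
            "\n"
            "OCTOPUS predicted topology:\n"
            "iiMMMooo\n"
        )
        assert parse_topcons(text).states[0] == "outside"


class TestConsurf:
    def test_gradient_endpoints_lightest_to_darkest(self):
        track = parse_consurf("1 M 1\n2 A 9\n")
        palette = conservation_palette()
        assert track.palette["1"] == palette["1"]
        # darker blue means more conserved: grade 9 has the lower luminance
        from matplotlib import colors as mcolors

        l1 = sum(mcolors.to_rgb(track.palette["1"]))
        l9 = sum(mcolors.to_rgb(track.palette["9"]))
        assert l9 < l1

    def test_grade_zero_rejected(self):
        with pytest.raises(ParserError, match="outside 1-9"):
            parse_consurf("1 M 0\n")

    def test_row_count_sets_track_length(self):
        track = parse_consurf("\n".join(f"{r} A {1 + r % 9}" for r in range(1, 6)))
        assert track.seq_length == 5


class TestCustomTrack:
    def test_two_purple_loop_instructions(self):
        ins = parse_custom_track("16 42 purple loop1\n105 131 purple loop2\n")
        assert [(c.start, c.end, c.colour) for c in ins] == [
            (16, 42, "purple"),
            (105, 131, "purple"),
        ]
        assert ins[0].label == "loop1"

    def test_start_after_end_rejected(self):
        with pytest.raises(ParserError, match="start after end"):
            parse_custom_track("5 3 red\n")

    def test_comment_only_input_gives_empty_list(self):
        assert parse_custom_track("# comment only\n") == []

    def test_slot_hint_parsed_from_trailing_integer(self):
        ins = parse_custom_track("1 10 #ff00ff binding_site 3\n")
        assert ins[0].slot_hint == 3 and ins[0].label == "binding_site"

    def test_unparseable_colour_rejected(self):
        with pytest.raises(ParserError, match="colour"):
            parse_custom_track("1 10 notacolour\n")

    def test_later_instruction_wins_on_overlap(self):
        ins = parse_custom_track("1 10 red a\n5 10 blue b\n")
        track = instructions_to_track(ins, 12)
        assert track.states[3] == "a" and track.states[4] == "b"
        assert track.states[10] == "none"


class TestFasta:
    def test_single_record(self):
        rec = parse_fasta(">x\nMALW\n")
        assert rec.id == "x" and rec.sequence == "MALW" and len(rec) == 4

    def test_multi_record_rejected(self):
        with pytest.raises(ParserError, match="single"):
            parse_fasta(">a\nM\n>b\nA\n")

    def test_whitespace_stripped_and_uppercased(self):
        assert parse_fasta(">x\nma lw\n").sequence == "MALW"

    def test_odd_characters_kept_with_warning(self):
        with pytest.warns(UserWarning, match="non-amino-acid"):
            rec = parse_fasta(">x\nMA1W\n")
        assert rec.sequence == "MA1W"


class TestWriteRR:
    def test_unknown_dialect_rejected(self, rng):
        cmap = random_contact_map(rng, 20)
        with pytest.raises(ValidationError, match="dialect"):
            write_rr(cmap, dialect="7col")
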