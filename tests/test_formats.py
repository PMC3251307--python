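"""Unit and property tests for the track-file grammars."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomap import formats
from genomap.errors import FormatError
from genomap.formats import (BlastHit, GradientSpec, Track,
                             assign_gradient_colour, parse_blast,
                             parse_chromosomes, parse_colors, parse_expr,
                             parse_freq, parse_genes, parse_gradient_header,
                             parse_graph, parse_posn, parse_track,
                             track_to_text)

FIG_GRADIENT_HEADER = (
    "# clBeige\t1\tclKhaki\t2\tclGold\t3\tclGoldenRod\t4\tclTomato\t8"
    "\tclCrimson"
)


# ---------------------------------------------------------------------------
# chromosomes table
# ---------------------------------------------------------------------------


class TestParseChromosomes:
    def test_documented_first_line(self):
        chroms = parse_chromosomes("1 = 11723881\n")
        assert chroms.entries == (("1", 11723881),)

    def test_whitespace_and_comments_tolerated(self):
        text = "# genome\n\n  chrA   =  500 \nchrB=250\n"
        chroms = parse_chromosomes(text)
        assert chroms.entries == (("chrA", 500), ("chrB", 250))

    def test_order_preserved_from_file(self):
        # chromosome numbering may follow the genetic map, not size order
        text = "2 = 100\n1 = 900\n"
        assert parse_chromosomes(text).ids == ("2", "1")

    @pytest.mark.parametrize("text,match", [
        ("", "no chromosomes"),
        ("1 = 100\n1 = 200\n", "duplicate"),
        ("1 = ten\n", "not an integer"),
        ("1 = 0\n", "non-positive"),
        ("1 = -5\n", "non-positive"),
        ("just a line\n", "id = length"),
    ])
    def test_grammar_errors(self, text, match):
        with pytest.raises(FormatError, match=match):
            parse_chromosomes(text)

    def test_cap_of_one_thousand(self):
        ok = "".join(f"c{i} = 100\n" for i in range(1000))
        assert len(parse_chromosomes(ok)) == 1000
        over = ok + "c1000 = 100\n"
        with pytest.raises(FormatError, match="cap exceeded"):
            parse_chromosomes(over)


# ---------------------------------------------------------------------------
# colors table
# ---------------------------------------------------------------------------


class TestParseColors:
    def test_missing_file_gives_the_16_builtins(self):
        table = parse_colors(None)
        assert len(table) == 16
        assert table["clBlack"] == (0, 0, 0)
        assert table["clWhite"] == (255, 255, 255)

    def test_hex_read_in_rgb_order(self):
        table = parse_colors("clPureRed = $FF0000\nclX = $123456\n")
        assert table["clPureRed"] == (255, 0, 0)
        assert table["clX"] == (0x12, 0x34, 0x56)

    def test_file_entries_overlay_builtins(self):
        table = parse_colors("clRed = $800080\n")
        assert table["clRed"] == (128, 0, 128)

    def test_malformed_hex_rejected(self):
        with pytest.raises(FormatError, match="malformed"):
            parse_colors("clBad = $12345\n")

    def test_name_without_cl_prefix_kept_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="genomap"):
            table = parse_colors("weird = $010203\n")
        assert table["weird"] == (1, 2, 3)
        assert any("prefix" in r.message for r in caplog.records)

    def test_unknown_name_resolves_to_fallback_grey(self):
        table = parse_colors(None)
        assert table.resolve("clNotAColour") == table["clGray"]


# ---------------------------------------------------------------------------
# genes table
# ---------------------------------------------------------------------------


class TestParseGenes:
    def test_five_fields_plus_annotation(self):
        genes = parse_genes("2\t100\t500\t+\tgeneA\tdesc\n")
        (g,) = genes
        assert (g.chrom_id, g.first_nt, g.last_nt) == ("2", 100, 500)
        assert (g.strand, g.feature_id, g.extras) == ("+", "geneA", ("desc",))

    def test_comments_and_blanks_ignored(self):
        assert parse_genes("# header\n\n") == []

    def test_reversed_coordinates_swapped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="genomap"):
            (g,) = parse_genes("2\t500\t100\t-\tg\n")
        assert (g.first_nt, g.last_nt) == (100, 500)
        assert any("swapped" in r.message for r in caplog.records)

    def test_short_line_reports_line_number(self):
        with pytest.raises(FormatError, match="line 3"):
            parse_genes("# c\n1\t1\t2\t+\tok\n1\t10\t20\n")

    def test_non_integer_coordinates_rejected(self):
        with pytest.raises(FormatError, match="not an integer"):
            parse_genes("1\tten\t20\t+\tg\n")

    def test_extras_preserved_verbatim(self):
        odd = "  spaced , punct;\"quoted\"  "
        (g,) = parse_genes(f"1\t1\t2\t+\tg\t{odd}\tmore\n")
        assert g.extras == (odd, "more")


# ---------------------------------------------------------------------------
# posn
# ---------------------------------------------------------------------------


class TestParsePosn:
    def test_colour_header_and_record(self):
        t = parse_posn("# clBlue\n1\t100\t500\t+\tgeneA\n", "TRI_genes")
        assert (t.kind, t.colour, len(t)) == ("posn", "clBlue", 1)

    def test_header_only_is_a_valid_empty_track(self):
        t = parse_posn("# clBlue\n", "empty")
        assert t.colour == "clBlue" and len(t) == 0

    def test_data_before_header_is_an_error(self):
        with pytest.raises(FormatError, match="colour header"):
            parse_posn("1\t1\t2\t+\tg\n# clBlue\n", "bad")


# ---------------------------------------------------------------------------
# blast
# ---------------------------------------------------------------------------


def _blast_text(cutoff, rows):
    lines = ["# clRed", f"# {cutoff}"]
    for chrom, first, last, pairs in rows:
        fields = [chrom, str(first), str(last), "+", "seq"]
        for q, e in pairs:
            fields += [q, str(e)]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


class TestParseBlast:
    def test_first_e_at_or_below_cutoff_retained(self):
        t = parse_blast(_blast_text("1e-10", [
            ("1", 10, 20, [("q1", "1e-20")]),
        ]), "hits")
        assert len(t) == 1 and t.records[0].best_e == 1e-20

    def test_first_e_above_cutoff_dropped(self):
        t = parse_blast(_blast_text("1e-10", [
            ("1", 10, 20, [("q1", "1e-5")]),
        ]), "hits")
        assert len(t) == 0

    def test_unsorted_pairs_resorted_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="genomap"):
            t = parse_blast(_blast_text("1", [
                ("1", 10, 20, [("a", "1e-3"), ("b", "1e-9")]),
            ]), "hits")
        assert t.records[0].pairs == (("b", 1e-9), ("a", 1e-3))
        assert any("re-sorted" in r.message for r in caplog.records)

    def test_missing_cutoff_line_is_an_error(self):
        with pytest.raises(FormatError, match="cut-off"):
            parse_blast("# clRed\n1\t1\t2\t+\tseq\tq\t1e-5\n", "bad")

    def test_line_without_pair_is_an_error(self):
        with pytest.raises(FormatError, match="pair"):
            parse_blast("# clRed\n# 1e-5\n1\t1\t2\t+\tseq\n", "bad")

    def test_retention_matches_brute_force_filter(self):
        """Parser retention == first_E <= cutoff over all generated lines."""
        rng = random.Random(99)
        for _ in range(50):
            cutoff = 10.0 ** rng.uniform(-15, 0)
            rows, expected = [], 0
            for i in range(rng.randint(0, 30)):
                e1 = 10.0 ** rng.uniform(-30, 2)
                if e1 <= cutoff:
                    expected += 1
                rows.append(("1", 10 * i + 1, 10 * i + 5, [("q", repr(e1))]))
            t = parse_blast(_blast_text(repr(cutoff), rows), "fuzz")
            assert len(t) == expected


# ---------------------------------------------------------------------------
# expr
# ---------------------------------------------------------------------------


class TestParseExpr:
    def test_last_field_is_the_row_colour(self):
        t = parse_expr("# ignored\n1\t5\t9\t+\tg1\tclRed\n", "e")
        assert t.records[0].colour == "clRed"

    def test_zero_rows_is_a_valid_track(self):
        assert len(parse_expr("# any\n# lines\n", "e")) == 0

    def test_unknown_colour_warned_when_table_supplied(self, caplog):
        table = parse_colors(None)
        with caplog.at_level("WARNING", logger="genomap"):
            t = parse_expr("1\t5\t9\t+\tg\tclNotAColour\n", "e",
                           colours=table)
        assert t.records[0].colour == "clNotAColour"
        assert any("clNotAColour" in r.message for r in caplog.records)
        assert table.resolve("clNotAColour") == table["clGray"]


# ---------------------------------------------------------------------------
# freq + gradient
# ---------------------------------------------------------------------------


class TestParseFreq:
    def test_six_colour_recombination_header(self):
        t = parse_freq(FIG_GRADIENT_HEADER + "\n1\t1\t27000\t.\tw\t0.5\n",
                       "recomb")
        assert t.gradient.colours == ("clBeige", "clKhaki", "clGold",
                                      "clGoldenRod", "clTomato", "clCrimson")
        assert t.gradient.boundaries == (1.0, 2.0, 3.0, 4.0, 8.0)
        assert t.records[0].value == 0.5

    def test_space_separated_header_accepted(self):
        g = parse_gradient_header("clA 1 clB 2 clC")
        assert g.colours == ("clA", "clB", "clC")

    def test_single_colour_no_boundary(self):
        g = parse_gradient_header("clOnly")
        assert g.boundaries == ()
        assert assign_gradient_colour(-1e9, g) == "clOnly"
        assert assign_gradient_colour(1e9, g) == "clOnly"

    @staticmethod
    def _header_with(k: int) -> str:
        tokens = []
        for i in range(k):
            if i:
                tokens.append(str(i))
            tokens.append(f"clC{i}")
        return "\t".join(tokens)

    def test_twenty_colours_allowed_twenty_one_exceed_cap(self):
        assert len(parse_gradient_header(self._header_with(20)).colours) == 20
        with pytest.raises(FormatError, match="cap exceeded"):
            parse_gradient_header(self._header_with(21))

    def test_non_increasing_boundaries_rejected(self):
        with pytest.raises(FormatError, match="increasing"):
            parse_gradient_header("clA\t5\tclB\t5\tclC")

    def test_header_must_end_with_a_colour(self):
        with pytest.raises(FormatError, match="boundary"):
            parse_gradient_header("clA\t5")

    def test_missing_header_is_an_error(self):
        with pytest.raises(FormatError, match="gradient header"):
            parse_freq("1\t1\t2\t.\tw\t1\n", "bad")


FIG_GRADIENT = GradientSpec(
    ("clBeige", "clKhaki", "clGold", "clGoldenRod", "clTomato", "clCrimson"),
    (1.0, 2.0, 3.0, 4.0, 8.0))


class TestAssignGradientColour:
    @pytest.mark.parametrize("value,expected", [
        (0.5, "clBeige"),          # below the first boundary
        (1.0, "clKhaki"),          # boundary belongs to the upper bin
        (2.5, "clGold"),
        (7.999, "clTomato"),
        (8.0, "clCrimson"),
        (100.0, "clCrimson"),      # above the last boundary
    ])
    def test_half_open_bins(self, value, expected):
        assert assign_gradient_colour(value, FIG_GRADIENT) == expected

    def test_agrees_with_linear_scan_oracle(self):
        def oracle(v, g):
            i = sum(1 for b in g.boundaries if b <= v)
            return g.colours[i]

        rng = random.Random(5)
        for _ in range(500):
            v = rng.uniform(-5, 15)
            assert assign_gradient_colour(v, FIG_GRADIENT) == \
                oracle(v, FIG_GRADIENT)

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False),
           st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_value(self, a, b):
        lo, hi = sorted((a, b))
        idx = FIG_GRADIENT.colours.index
        assert idx(assign_gradient_colour(lo, FIG_GRADIENT)) <= \
            idx(assign_gradient_colour(hi, FIG_GRADIENT))

    def test_non_finite_value_rejected(self):
        with pytest.raises(FormatError, match="non-finite"):
            assign_gradient_colour(float("nan"), FIG_GRADIENT)


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


class TestParseGraph:
    def test_last_field_is_the_y_value(self):
        t = parse_graph("1\t1\t50000\t.\tw1\t12\n", "snp")
        assert t.records[0].value == 12.0

    def test_negative_and_zero_values_accepted(self):
        t = parse_graph("1\t1\t10\t.\tw\t-3.5\n1\t11\t20\t.\tw\t0\n", "g")
        assert [r.value for r in t.records] == [-3.5, 0.0]

    def test_non_numeric_value_rejected(self):
        with pytest.raises(FormatError, match="not a number"):
            parse_graph("1\t1\t10\t.\tw\thigh\n", "g")

    def test_optional_colour_directive(self):
        assert parse_graph("# clNavy\n", "g").colour == "clNavy"


# ---------------------------------------------------------------------------
# round-trip
# ---------------------------------------------------------------------------


def payload_key(track: Track):
    return (track.kind, track.colour, track.cutoff, track.gradient)


def records_key(track: Track):
    return sorted(tuple(formats._record_fields(r)) for r in track.records)


class TestRoundTrip:
    @pytest.mark.parametrize("kind", formats.TRACK_KINDS)
    def test_write_then_parse_is_identity(self, kind, track_fuzzer, tmp_path):
        rng = random.Random(hash(kind) % 2**31)
        for i in range(25):
            track = track_fuzzer(rng, kind)
            path = tmp_path / f"{kind}_{i}.{kind}"
            formats.write_track(track, path)
            back = parse_track(path.read_text(encoding="utf-8"),
                               track.name, kind)
            assert payload_key(back) == payload_key(track)
            assert records_key(back) == records_key(track)

    def test_data_lines_written_sorted(self, track_fuzzer):
        rng = random.Random(3)
        track = track_fuzzer(rng, "posn", n_max=30)
        text = track_to_text(track)
        data = [line.split("\t") for line in text.splitlines()
                if line and not line.startswith("#")]
        keys = [(f[0], int(f[1])) for f in data]
        assert keys == sorted(keys)

    def test_empty_track_round_trips(self, tmp_path):
        track = Track(name="e", kind="posn", colour="clBlue", records=[])
        path = tmp_path / "e.posn"
        formats.write_track(track, path)
        back = parse_posn(path.read_text(encoding="utf-8"), "e")
        assert back.colour == "clBlue" and len(back) == 0

    def test_crlf_input_accepted(self):
        t = parse_posn("# clBlue\r\n1\t1\t2\t+\tg\r\n", "p")
        assert len(t) == 1 and t.records[0].feature_id == "g"

    def test_blast_pairs_survive_round_trip(self):
        hit = BlastHit(chrom_id="1", first_nt=5, last_nt=50, strand=".",
                       feature_id="seq",
                       pairs=(("qA", 1e-30), ("qB", 2.5e-12)))
        track = Track(name="b", kind="blast", colour="clRed", cutoff=1e-10,
                      records=[hit])
        back = parse_blast(track_to_text(track), "b")
        assert back.records[0].pairs == hit.pairs
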