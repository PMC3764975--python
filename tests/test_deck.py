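"""Input-deck embedding: byte-faithful round trips, the streaming write
quintet, DOM and streaming extraction."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from cmlcompchem.core import CmlParseError, CmlStructureError, parse_document, serialize_document
from cmlcompchem.deck import (
    InputDeck,
    InputFile,
    add_input_deck_line,
    dump_input_deck,
    end_input_deck_file,
    end_input_deck_list,
    extract_input_deck,
    extract_input_deck_streaming,
    reconstruct_file,
    start_input_deck_file,
    start_input_deck_list,
    write_input_deck,
)
from cmlcompchem.writer import WriterError, begin_document

from conftest import perturbations

ascii_line = st.text(
    alphabet=st.characters(min_codepoint=32, max_codepoint=126), max_size=60
) | st.sampled_from(["", "\tindented", "trailing  ", "  leading", "a\tb  c"])


def dump_lines(lines, tmp_path, name="file.nw"):
    path = tmp_path / name
    path.write_bytes("".join(line + "\n" for line in lines).encode("ascii"))
    session = begin_document("deck test")
    dump_input_deck(session, [path])
    return path, session.finish()


class TestDump:
    def test_lines_become_scalars_in_order(self, tmp_path):
        lines = ["geometry", "  H 0 0 0", "", "end"]
        _, doc = dump_lines(lines, tmp_path, "h2.nw")
        scalars = [n for n in doc.iter() if n.local_name == "scalar"]
        assert [s.text for s in scalars] == lines
        assert scalars[2].text == ""  # empty line -> empty scalar

    def test_tab_preserved(self, tmp_path):
        _, doc = dump_lines(["\tbasis sto-3g"], tmp_path)
        scalar = next(n for n in doc.iter() if n.local_name == "scalar")
        assert scalar.text == "\tbasis sto-3g"

    def test_file_name_recorded_as_metadata(self, tmp_path):
        _, doc = dump_lines(["x"], tmp_path, "prop_h2o.nw")
        meta = next(
            n
            for n in doc.iter()
            if n.local_name == "metadata"
            and n.get("name") == "compchem:inputFileName"
        )
        assert meta.get("content") == "prop_h2o.nw"

    def test_zero_files_allowed_with_empty_list_module(self):
        session = begin_document("t")
        dump_input_deck(session, [])
        doc = session.finish()
        (module,) = [n for n in doc.iter() if n.local_name == "module"]
        assert module.children == []

    def test_non_ascii_byte_reported_with_offset(self, tmp_path):
        path = tmp_path / "bad.nw"
        path.write_bytes(b"ok\n\xc3\xa9\n")
        session = begin_document("t")
        with pytest.raises(CmlStructureError, match="offset 3"):
            dump_input_deck(session, [path])

    def test_unreadable_path_is_an_error(self, tmp_path):
        session = begin_document("t")
        with pytest.raises(CmlStructureError):
            dump_input_deck(session, [tmp_path / "absent.nw"])


class TestStreamingQuintet:
    def test_equivalent_to_dump(self, tmp_path):
        path = tmp_path / "a.nw"
        path.write_bytes(b"x\n")
        s1 = begin_document("t")
        dump_input_deck(s1, [path])
        s2 = begin_document("t")
        start_input_deck_list(s2)
        start_input_deck_file(s2, "a.nw")
        add_input_deck_line(s2, "x")
        end_input_deck_file(s2)
        end_input_deck_list(s2)
        from cmlcompchem.core import semantically_equal

        assert semantically_equal(s1.finish(), s2.finish())

    def test_line_before_file_is_a_state_error(self):
        s = begin_document("t")
        start_input_deck_list(s)
        with pytest.raises(WriterError):
            add_input_deck_line(s, "x")

    def test_file_outside_list_is_a_state_error(self):
        s = begin_document("t")
        with pytest.raises(WriterError):
            start_input_deck_file(s, "a.nw")

    def test_end_list_with_open_file_is_a_state_error(self):
        s = begin_document("t")
        start_input_deck_list(s)
        start_input_deck_file(s, "a.nw")
        with pytest.raises(WriterError):
            end_input_deck_list(s)

    def test_nameless_file_omits_metadata(self):
        # Data read from standard input has no file name.
        s = begin_document("t")
        start_input_deck_list(s)
        start_input_deck_file(s, None)
        add_input_deck_line(s, "from stdin")
        end_input_deck_file(s)
        end_input_deck_list(s)
        doc = s.finish()
        assert not [n for n in doc.iter() if n.local_name == "metadata"]
        deck = extract_input_deck(doc)
        assert deck.files[0].file_name is None
        assert deck.files[0].lines == ["from stdin"]

    @pytest.mark.parametrize("bad", ["a\nb", "a\rb"])
    def test_line_ending_characters_rejected(self, bad):
        s = begin_document("t")
        start_input_deck_list(s)
        start_input_deck_file(s, "a.nw")
        with pytest.raises(CmlStructureError):
            add_input_deck_line(s, bad)


class TestExtract:
    def test_extraction_survives_every_perturbation(self, tmp_path):
        lines = ["geometry", "  H  0 0 0", "\t tab", "", "end  "]
        _, doc = dump_lines(lines, tmp_path)
        reference = extract_input_deck(doc)
        assert [f.lines for f in reference.files] == [lines]
        for label, perturbed in perturbations(doc):
            deck = extract_input_deck(perturbed)
            assert [f.lines for f in deck.files] == [lines], label
            assert deck.files[0].file_name == "file.nw", label

    def test_document_without_deck_is_empty(self):
        doc = begin_document("t").finish()
        assert extract_input_deck(doc).files == []

    def test_wrong_datatype_scalar_still_contributes_text(self, tmp_path, caplog):
        _, doc = dump_lines(["42"], tmp_path)
        scalar = next(n for n in doc.iter() if n.local_name == "scalar")
        scalar.attributes["dataType"] = "xsd:integer"
        scalar.attributes["units"] = "units:none"
        with caplog.at_level("WARNING"):
            deck = extract_input_deck(doc)
        assert deck.files[0].lines == ["42"]
        assert any("dataType" in r.message for r in caplog.records)


class TestStreamingExtract:
    def test_agrees_with_dom_on_fixture_corpus(self, calc_docs):
        for seed, doc in calc_docs.items():
            xml = serialize_document(doc)
            dom = extract_input_deck(doc)
            streamed = extract_input_deck_streaming(xml)
            assert [(f.file_name, f.lines) for f in streamed.files] == [
                (f.file_name, f.lines) for f in dom.files
            ], seed

    def test_reads_from_file_like_source(self, tmp_path):
        _, doc = dump_lines(["alpha", "beta"], tmp_path)
        stream = io.BytesIO(serialize_document(doc))
        deck = extract_input_deck_streaming(stream)
        assert deck.files[0].lines == ["alpha", "beta"]

    def test_truncated_stream_raises_and_discards(self, tmp_path):
        _, doc = dump_lines(["alpha"], tmp_path)
        xml = serialize_document(doc)
        with pytest.raises(CmlParseError):
            extract_input_deck_streaming(xml[: len(xml) // 2])


class TestReconstruct:
    def test_definition(self):
        f = InputFile(lines=["a", "", "b"])
        assert reconstruct_file(f, "\n") == b"a\n\nb\n"
        assert reconstruct_file(f, "\r\n") == b"a\r\n\r\nb\r\n"

    def test_empty_file_yields_empty_bytes(self):
        assert reconstruct_file(InputFile(lines=[])) == b""

    def test_unsupported_ending_rejected(self):
        with pytest.raises(CmlStructureError):
            reconstruct_file(InputFile(lines=["a"]), "\r")

    def test_end_to_end_bytes_identical(self, tmp_path):
        original = b"geometry\n  H 0 0 0\n\tH 0 0 0.74\n\nend\n"
        path = tmp_path / "h2.nw"
        path.write_bytes(original)
        session = begin_document("t")
        dump_input_deck(session, [path])
        doc = parse_document(serialize_document(session.finish()))
        (f,) = extract_input_deck(doc).files
        assert reconstruct_file(f) == original

    def test_missing_final_newline_is_recorded(self, tmp_path):
        path = tmp_path / "nofinal.nw"
        path.write_bytes(b"line1\nline2")
        session = begin_document("t")
        dump_input_deck(session, [path])
        doc = parse_document(serialize_document(session.finish()))
        (f,) = extract_input_deck(doc).files
        assert f.had_final_newline is False
        assert f.lines == ["line1", "line2"]
        (g,) = extract_input_deck_streaming(serialize_document(doc)).files
        assert g.had_final_newline is False


@given(files=st.lists(st.lists(ascii_line, max_size=12), min_size=1, max_size=3))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_round_trip_property(files):
    """Any ASCII deck survives write -> serialize -> parse -> extract,
    by both extractors."""
    deck = InputDeck(
        files=[InputFile(file_name=f"f{i}.nw", lines=lines) for i, lines in enumerate(files)]
    )
    session = begin_document("prop")
    write_input_deck(session, deck)
    xml = serialize_document(session.finish())
    for extracted in (
        extract_input_deck(parse_document(xml)),
        extract_input_deck_streaming(xml),
    ):
        assert [f.lines for f in extracted.files] == files
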