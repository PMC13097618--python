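"""Serialization/parsing: delimiters, envelope arithmetic, round trips, CSVs."""

import random
from decimal import Decimal
from pathlib import Path

import pytest

from claimforge import (
    DelimiterSet,
    GeneratorConfig,
    detect_delimiters,
    generate_batch,
    generate_envelope,
    parse_interchange,
    serialize_interchange,
    worked_example_claim,
    write_csv_outputs,
)
from claimforge.exceptions import SerializationError, X12ParseError

ALT_DELIMS = DelimiterSet(element_sep="|", component_sep=">", repetition_sep="^",
                          segment_term="~")


def segment_count_oracle(text: str, element_sep: str = "*", term: str = "~") -> list[int]:
    """Count ST..SE segments per transaction by raw text scanning (codec-independent)."""
    counts, current = [], None
    for chunk in text.split(term):
        chunk = chunk.strip()
        if not chunk:
            continue
        tag = chunk.split(element_sep)[0]
        if tag == "ST":
            current = 1
        elif current is not None:
            current += 1
            if tag == "SE":
                counts.append(current)
                current = None
    return counts


def claim_signature(claim):
    return (
        claim.claim_id,
        claim.provider.npi,
        [(d.qualifier, d.code, d.ordinal) for d in claim.diagnoses],
        [(l.line_number, l.procedure_code, l.charge, l.diagnosis_pointers,
          l.service_date.strftime("%Y%m%d")) for l in claim.service_lines],
    )


def parsed_signature(parsed_claim):
    return (
        parsed_claim.claim_id,
        parsed_claim.provider_npi,
        [(d.qualifier, d.code, d.ordinal) for d in parsed_claim.diagnoses],
        [(l.line_number, l.procedure_code.split(":", 1)[1], l.charge,
          l.diagnosis_pointers, l.service_date) for l in parsed_claim.service_lines],
    )


class TestDetectDelimiters:
    def test_round_trip_through_serializer(self, worked_claim):
        text = serialize_interchange([worked_claim])
        d = detect_delimiters(text)
        assert (d.element_sep, d.component_sep, d.repetition_sep, d.segment_term) == \
            ("*", ":", "^", "~")

    def test_alternate_set_detected(self, worked_claim):
        text = serialize_interchange([worked_claim], delimiters=ALT_DELIMS)
        assert detect_delimiters(text) == ALT_DELIMS

    def test_non_isa_start_rejected(self):
        with pytest.raises(X12ParseError):
            detect_delimiters("GS*HC*A*B~")

    def test_short_file_rejected(self):
        with pytest.raises(X12ParseError):
            detect_delimiters("ISA*00*x~")

    def test_colliding_delimiters_rejected(self, worked_claim):
        text = serialize_interchange([worked_claim])
        mutated = text[:104] + "*" + text[105:]  # ISA16 equals the element separator
        with pytest.raises(X12ParseError):
            detect_delimiters(mutated)


class TestSerializeInterchange:
    def test_envelope_bracketing(self, worked_text):
        assert worked_text.startswith("ISA")
        segments = [s.strip() for s in worked_text.split("~") if s.strip()]
        assert segments[-1].startswith("IEA")
        assert segments[1].startswith("GS")

    def test_one_transaction_per_claim(self, bundle):
        cfg = GeneratorConfig(n_claims=5, line_max=3, seed=2)
        text = serialize_interchange(generate_batch(cfg, bundle))
        assert text.count("ST*837*") == 5
        assert sum(1 for l in text.splitlines() if l.startswith("SE*")) == 5

    def test_se01_matches_independent_count(self, worked_text):
        (count,) = segment_count_oracle(worked_text)
        se_line = next(s for s in worked_text.splitlines() if s.startswith("SE*"))
        assert se_line.split("*")[1] == str(count)

    def test_isa_is_fixed_width_106(self, worked_text):
        first_line = worked_text.splitlines()[0]
        assert len(first_line) == 106

    def test_empty_batch_rejected(self):
        with pytest.raises(SerializationError):
            serialize_interchange([])

    def test_invalid_claim_rejected_with_named_violation(self, worked_claim):
        from dataclasses import replace
        bad = replace(worked_claim, total_charge=Decimal(999))
        with pytest.raises(SerializationError, match="total charge"):
            serialize_interchange([bad])

    def test_duplicate_control_numbers_rejected(self, worked_claim):
        with pytest.raises(SerializationError, match="control numbers"):
            serialize_interchange([worked_claim, worked_claim])

    def test_streaming_mode_has_no_newlines(self, worked_claim):
        text = serialize_interchange([worked_claim], newline=False)
        assert "\n" not in text
        assert parse_interchange(text).claims[0].claim_id == "4742333269"


class TestParseInterchange:
    def test_round_trip_count(self, bundle):
        cfg = GeneratorConfig(n_claims=5, line_max=4, seed=0)
        parsed = parse_interchange(serialize_interchange(generate_batch(cfg, bundle)))
        assert len(parsed.header_rows) == 5

    def test_truncated_file_is_unterminated(self, worked_text):
        truncated = worked_text[: worked_text.rindex("IEA")]
        with pytest.raises(X12ParseError, match="unterminated interchange"):
            parse_interchange(truncated)

    def test_se_count_mismatch_is_a_parse_error(self, worked_text):
        mutated = worked_text.replace("SE*28*", "SE*29*")
        with pytest.raises(X12ParseError, match="SE01"):
            parse_interchange(mutated)

    def test_control_number_disagreement_is_a_parse_error(self, worked_text):
        mutated = worked_text.replace("IEA*1*000000001", "IEA*1*000000002")
        with pytest.raises(X12ParseError, match="control numbers disagree"):
            parse_interchange(mutated)

    @pytest.mark.parametrize("n_claims,seed", [(10, 0), (10, 7), (5, 101)])
    def test_round_trip_preserves_claim_content(self, bundle, n_claims, seed):
        cfg = GeneratorConfig(n_claims=n_claims, seed=seed)
        claims = generate_batch(cfg, bundle)
        parsed = parse_interchange(serialize_interchange(claims, generate_envelope(cfg)))
        assert [parsed_signature(p) for p in parsed.claims] == \
            [claim_signature(c) for c in claims]

    def test_round_trip_under_alternate_delimiters(self, bundle):
        cfg = GeneratorConfig(n_claims=8, seed=3)
        claims = generate_batch(cfg, bundle)
        text = serialize_interchange(claims, delimiters=ALT_DELIMS)
        parsed = parse_interchange(text)
        assert [parsed_signature(p) for p in parsed.claims] == \
            [claim_signature(c) for c in claims]

    def test_unknown_segments_are_preserved_but_ignored(self, worked_text):
        # inject a PER contact segment; tables must be unaffected
        mutated = worked_text.replace("REF*EI", "PER*IC*HELPDESK~\nREF*EI")
        mutated = mutated.replace("SE*28*", "SE*29*")
        parsed = parse_interchange(mutated)
        assert len(parsed.claims) == 1
        assert len(parsed.diagnosis_rows) == 6


class TestWorkedExampleTables:
    """Re-parsing the serialized reference claim reproduces its printed tables."""

    def test_header_row(self, worked_text):
        (row,) = parse_interchange(worked_text).header_rows
        assert row["transaction_set_id"] == "837"
        assert row["control_number"] == "44146"
        assert row["billing_provider"] == "HSA GLENWOOD, LLC"
        assert row["provider_npi"] == "1548083421"
        assert row["provider_city"] == "GLENDALE"
        assert row["provider_state"] == "CA"
        assert row["subscriber_name"] == "Jonathan Mendez"
        assert row["subscriber_id"] == "3191511"

    def test_diagnosis_rows(self, worked_text):
        rows = parse_interchange(worked_text).diagnosis_rows
        assert [(r["claim_id"], r["diagnosis_type"], r["diagnosis_code"], r["pointer"])
                for r in rows] == [
            ("4742333269", "ABK", "T82330A", "1"),
            ("4742333269", "ABK", "S62665A", "2"),
            ("4742333269", "ABK", "Z13811", "3"),
            ("4742333269", "ABK", "S72141Q", "4"),
            ("4742333269", "ABK", "S61431A", "5"),
            ("4742333269", "ABK", "H61301", "6"),
        ]

    def test_service_line_rows(self, worked_text):
        rows = parse_interchange(worked_text).service_line_rows
        assert [(r["claim_id"], r["line_number"], r["procedure_code"], r["charge"],
                 r["unit"], r["qty"], r["diagnosis_pointers"], r["service_date"])
                for r in rows] == [
            ("4742333269", "1", "HC:97605", "76", "UN", "1", "[1]", "20180428"),
            ("4742333269", "2", "HC:67228", "33", "UN", "1", "[2, 4, 6]", "20180428"),
            ("4742333269", "3", "HC:92316", "107", "UN", "1", "[6]", "20180428"),
        ]


class TestCsvOutputs:
    def test_three_files_with_expected_rows(self, worked_text, tmp_path):
        parsed = parse_interchange(worked_text)
        header, dx, lines = write_csv_outputs(parsed, tmp_path)
        assert header.name == "header.csv" and dx.name == "diagnoses.csv"
        line_rows = lines.read_text().splitlines()
        assert line_rows[0].startswith("claim_id,line_number,procedure_code")
        assert line_rows[1] == '4742333269,1,HC:97605,76,UN,1,"[1]",20180428'
        assert line_rows[2] == '4742333269,2,HC:67228,33,UN,1,"[2, 4, 6]",20180428'
        header_rows = header.read_text().splitlines()
        assert '"HSA GLENWOOD, LLC"' in header_rows[1]  # RFC-4180 quoting of the comma
        assert "Jonathan Mendez" in header_rows[1]

    def test_row_counts_are_relational(self, bundle, tmp_path):
        cfg = GeneratorConfig(n_claims=4, dx_min=2, dx_max=2, line_min=3, line_max=3, seed=5)
        parsed = parse_interchange(serialize_interchange(generate_batch(cfg, bundle)))
        header, dx, lines = write_csv_outputs(parsed, tmp_path)
        assert len(header.read_text().splitlines()) == 1 + 4
        assert len(dx.read_text().splitlines()) == 1 + 4 * 2
        assert len(lines.read_text().splitlines()) == 1 + 4 * 3
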