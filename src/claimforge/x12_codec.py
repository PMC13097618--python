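"""X12 5010 837i serialization and parsing.

Serialization emits one interchange: a fixed-width 106-character ISA header,
one GS functional group, one ST..SE transaction per claim, then GE and IEA
trailers with matching control numbers and counts. Within a transaction the
segment order is::

    ST, BHT,
    NM1*41 (submitter), NM1*40 (receiver),            # 1000A / 1000B
    HL*1**20*1, NM1*85, N3, N4, REF*EI,               # 2000A billing provider
    HL*2*1*22*0, SBR, NM1*IL, DMG, NM1*PR,            # 2000B subscriber
    CLM, DTP*434, HI (principal), [HI (others)],      # 2300 claim
    per line: LX, SV2, DTP*472,                       # 2400 service lines
    SE

Dialect notes (documented deviations from the bare implementation guide):

* Standard SV2 carries no diagnosis pointers; to preserve the per-line
  pointer links the parser reports, the serializer writes them as a composite
  (values joined by the component separator) in SV2 element 7, and the parser
  reads the same position.
* REF*EI carries a synthetic employer identifier derived from the billing
  NPI's first nine digits — purely structural filler, never a real tax ID.
* The principal diagnosis occupies its own HI segment; remaining diagnoses
  share a second HI (up to 11 composites). Each composite is
  ``qualifier:code:::::::poa`` with the present-on-admission flag in the
  ninth component.
* Dates are CCYYMMDD (DTP format D8); by default each segment terminator is
  followed by a newline for readability, with ``newline=False`` for
  single-line streaming output.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Optional, Sequence

from .claim_model import (
    DelimiterSet,
    EnvelopeMeta,
    InstitutionalClaim,
    validate_claim,
)
from .exceptions import SerializationError, X12ParseError

ISA_LENGTH = 106
VERSION_CODE = "005010X223A2"  # HIPAA institutional-claim implementation guide
TRANSACTION_SET = "837"

#: SBR09 claim-filing indicator by payer market segment
CLAIM_FILING_CODES = {"MEDICARE": "MB", "MEDICAID": "MC", "COMMERCIAL": "CI"}

HEADER_COLUMNS = (
    "transaction_set_id", "control_number", "isa_sender", "isa_receiver",
    "gs_control_number", "bht_reference", "billing_provider", "provider_npi",
    "provider_city", "provider_state", "subscriber_name", "subscriber_id",
)
DIAGNOSIS_COLUMNS = ("claim_id", "diagnosis_type", "diagnosis_code", "pointer")
SERVICE_LINE_COLUMNS = (
    "claim_id", "line_number", "procedure_code", "charge", "unit", "qty",
    "diagnosis_pointers", "service_date",
)


@dataclass(frozen=True)
class Segment:
    """One X12 segment: tag, raw elements, and 1-based position in the file."""

    tag: str
    elements: tuple[str, ...]
    index: int

    def element(self, i: int) -> str:
        """1-based element access ('' when absent)."""
        return self.elements[i - 1] if i <= len(self.elements) else ""


@dataclass(frozen=True)
class ParsedDiagnosis:
    qualifier: str
    code: str
    poa: str
    ordinal: int


@dataclass(frozen=True)
class ParsedServiceLine:
    line_number: int
    procedure_code: str  # qualifier-prefixed, e.g. "HC:97605"
    charge: Decimal
    unit: str
    quantity: int
    diagnosis_pointers: tuple[int, ...]
    service_date: str  # CCYYMMDD as carried in the file
    revenue_code: str


@dataclass(frozen=True)
class ParsedClaim:
    """One claim as read back from an 837i transaction."""

    claim_id: str
    transaction_control_number: str
    bht_reference: str
    provider_name: str
    provider_npi: str
    provider_street: str
    provider_city: str
    provider_state: str
    provider_zip: str
    subscriber_first: str
    subscriber_last: str
    subscriber_id: str
    subscriber_birth_date: str
    subscriber_gender: str
    payer_name: str
    payer_id: str
    total_charge: Decimal
    facility_type_code: str
    claim_frequency_code: str
    diagnoses: tuple[ParsedDiagnosis, ...]
    service_lines: tuple[ParsedServiceLine, ...]

    @property
    def subscriber_name(self) -> str:
        return f"{self.subscriber_first} {self.subscriber_last}".strip()


@dataclass(frozen=True)
class ParsedInterchange:
    """Structured result of parsing one interchange."""

    delimiters: DelimiterSet
    envelope: EnvelopeMeta
    claims: tuple[ParsedClaim, ...]
    segments: tuple[Segment, ...] = field(repr=False, default=())
    gs_control_number: str = ""

    @property
    def header_rows(self) -> list[dict[str, str]]:
        rows = []
        for c in self.claims:
            rows.append({
                "transaction_set_id": TRANSACTION_SET,
                "control_number": c.transaction_control_number,
                "isa_sender": self.envelope.sender_id,
                "isa_receiver": self.envelope.receiver_id,
                "gs_control_number": self.gs_control_number,
                "bht_reference": c.bht_reference,
                "billing_provider": c.provider_name,
                "provider_npi": c.provider_npi,
                "provider_city": c.provider_city,
                "provider_state": c.provider_state,
                "subscriber_name": c.subscriber_name,
                "subscriber_id": c.subscriber_id,
            })
        return rows

    @property
    def diagnosis_rows(self) -> list[dict[str, str]]:
        return [
            {"claim_id": c.claim_id, "diagnosis_type": d.qualifier,
             "diagnosis_code": d.code, "pointer": str(d.ordinal)}
            for c in self.claims for d in c.diagnoses
        ]

    @property
    def service_line_rows(self) -> list[dict[str, str]]:
        return [
            {"claim_id": c.claim_id, "line_number": str(l.line_number),
             "procedure_code": l.procedure_code, "charge": format_amount(l.charge),
             "unit": l.unit, "qty": str(l.quantity),
             "diagnosis_pointers": render_pointers(l.diagnosis_pointers),
             "service_date": l.service_date}
            for c in self.claims for l in c.service_lines
        ]


def format_amount(amount: Decimal) -> str:
    """Render a monetary amount, dropping the fraction when integral (76, not 76.00)."""
    if amount == amount.to_integral_value():
        return str(int(amount))
    return str(amount.quantize(Decimal("0.01")).normalize())


def render_pointers(pointers: Sequence[int]) -> str:
    """Bracketed pointer-list rendering used in the service-lines CSV: ``[2, 4, 6]``."""
    return "[" + ", ".join(str(p) for p in pointers) + "]"


def _ccyymmdd(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _isa_segment(env: EnvelopeMeta, d: DelimiterSet) -> str:
    e = d.element_sep
    fields = [
        "ISA", "00", " " * 10, "00", " " * 10,
        "ZZ", env.sender_id.ljust(15), "ZZ", env.receiver_id.ljust(15),
        env.interchange_date.strftime("%y%m%d"), env.interchange_time.strftime("%H%M"),
        d.repetition_sep, "00501", env.interchange_control_number, "0",
        env.usage_indicator, d.component_sep,
    ]
    seg = e.join(fields)
    assert len(seg) + 1 == ISA_LENGTH, f"ISA is {len(seg) + 1} chars, want {ISA_LENGTH}"
    return seg


def _claim_segments(claim: InstitutionalClaim, env: EnvelopeMeta, d: DelimiterSet) -> list[list[str]]:
    """All segments of one ST..SE transaction, as element lists (tag first)."""
    comp = d.component_sep
    sub = claim.subscriber
    prov = claim.provider
    segs: list[list[str]] = []

    segs.append(["ST", TRANSACTION_SET, claim.transaction_control_number, VERSION_CODE])
    segs.append(["BHT", "0019", "00", claim.claim_id,
                 _ccyymmdd(env.interchange_date), env.interchange_time.strftime("%H%M"), "CH"])
    segs.append(["NM1", "41", "2", env.sender_id, "", "", "", "", "46", env.sender_id])
    segs.append(["NM1", "40", "2", env.receiver_id, "", "", "", "", "46", env.receiver_id])

    # 2000A billing provider
    segs.append(["HL", "1", "", "20", "1"])
    segs.append(["NM1", "85", "2", prov.org_name, "", "", "", "", "XX", prov.npi])
    segs.append(["N3", prov.street])
    segs.append(["N4", prov.city, prov.state, prov.zip])
    segs.append(["REF", "EI", prov.npi[:9]])

    # 2000B subscriber
    segs.append(["HL", "2", "1", "22", "0"])
    filing = CLAIM_FILING_CODES.get(sub.payer.payer_type, "CI")
    segs.append(["SBR", "P", "18", "", "", "", "", "", "", filing])
    segs.append(["NM1", "IL", "1", sub.last_name, sub.first_name, "", "", "", "MI", sub.member_id])
    segs.append(["DMG", "D8", _ccyymmdd(sub.birth_date), sub.gender])
    segs.append(["NM1", "PR", "2", sub.payer.product_name, "", "", "", "", "PI", sub.payer.hios_id])

    # 2300 claim
    facility = comp.join([claim.facility_type_code, "A", claim.claim_frequency_code])
    segs.append(["CLM", claim.claim_id, format_amount(claim.total_charge), "", "",
                 facility, "Y", "A", "Y", "Y"])
    segs.append(["DTP", "434", "D8", _ccyymmdd(claim.service_lines[0].service_date)])

    def hi_composite(dx) -> str:
        return comp.join([dx.qualifier, dx.code, "", "", "", "", "", "", dx.poa])

    segs.append(["HI", hi_composite(claim.diagnoses[0])])
    if len(claim.diagnoses) > 1:
        segs.append(["HI", *[hi_composite(dx) for dx in claim.diagnoses[1:]]])

    # 2400 service lines
    for line in claim.service_lines:
        segs.append(["LX", str(line.line_number)])
        segs.append(["SV2", line.revenue_code,
                     comp.join([line.procedure_qualifier, line.procedure_code]),
                     format_amount(line.charge), line.unit, str(line.quantity), "",
                     comp.join(str(p) for p in line.diagnosis_pointers)])
        segs.append(["DTP", "472", "D8", _ccyymmdd(line.service_date)])

    segs.append(["SE", str(len(segs) + 1), claim.transaction_control_number])
    return segs


def serialize_interchange(
    claims: Sequence[InstitutionalClaim],
    envelope: Optional[EnvelopeMeta] = None,
    delimiters: Optional[DelimiterSet] = None,
    *,
    newline: bool = True,
) -> str:
    """Serialize claims into one X12 837i interchange.

    Raises :class:`SerializationError` for an empty batch, a claim failing
    :func:`validate_claim`, or duplicate transaction control numbers.
    """
    if not claims:
        raise SerializationError("cannot serialize an empty claim list")
    env = envelope or EnvelopeMeta()
    d = delimiters or DelimiterSet()

    tcns = [c.transaction_control_number for c in claims]
    if len(set(tcns)) != len(tcns):
        raise SerializationError("transaction control numbers must be unique within a group")
    for claim in claims:
        violations = validate_claim(claim)
        if violations:
            raise SerializationError(
                f"claim {claim.claim_id} is invalid: {violations[0]}"
            )

    e = d.element_sep
    sep = d.segment_term + ("\n" if newline else "")
    out: list[str] = [_isa_segment(env, d)]
    out.append(e.join(["GS", "HC", env.sender_id, env.receiver_id,
                       _ccyymmdd(env.interchange_date), env.interchange_time.strftime("%H%M"),
                       str(env.group_control_number), "X", VERSION_CODE]))
    for claim in claims:
        for seg in _claim_segments(claim, env, d):
            out.append(e.join(seg))
    out.append(e.join(["GE", str(len(claims)), str(env.group_control_number)]))
    out.append(e.join(["IEA", "1", env.interchange_control_number]))
    return sep.join(out) + sep


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def detect_delimiters(text: str) -> DelimiterSet:
    """Read the delimiter set off the fixed-width ISA header.

    ISA is positional: the element separator sits at offset 3, the repetition
    separator at offset 82 (ISA11), the component separator at offset 104
    (ISA16), and the segment terminator at offset 105.
    """
    if not text.startswith("ISA"):
        raise X12ParseError("file does not begin with an ISA header", segment_index=1)
    if len(text) < ISA_LENGTH:
        raise X12ParseError(
            f"ISA header must be {ISA_LENGTH} characters, file has {len(text)}",
            segment_index=1,
        )
    try:
        return DelimiterSet(
            element_sep=text[3],
            repetition_sep=text[82],
            component_sep=text[104],
            segment_term=text[105],
        )
    except ValueError as exc:
        raise X12ParseError(f"bad delimiter set in ISA header: {exc}", segment_index=1)


def split_segments(text: str, delimiters: Optional[DelimiterSet] = None) -> list[Segment]:
    """Tokenize X12 text into segments (newlines after terminators are cosmetic)."""
    d = delimiters or detect_delimiters(text)
    segments: list[Segment] = []
    index = 0
    for chunk in text.split(d.segment_term):
        chunk = chunk.strip("\r\n ")
        if not chunk:
            continue
        index += 1
        parts = chunk.split(d.element_sep)
        segments.append(Segment(tag=parts[0], elements=tuple(parts[1:]), index=index))
    return segments


def _parse_transaction(
    segs: list[Segment], comp: str, gs_control_number: str
) -> ParsedClaim:
    """Build one ParsedClaim from the segments of an ST..SE transaction."""
    st = segs[0]
    fields: dict[str, str] = {
        "transaction_control_number": st.element(2), "bht_reference": "",
        "claim_id": "", "provider_name": "", "provider_npi": "",
        "provider_street": "", "provider_city": "", "provider_state": "",
        "provider_zip": "", "subscriber_first": "", "subscriber_last": "",
        "subscriber_id": "", "subscriber_birth_date": "", "subscriber_gender": "",
        "payer_name": "", "payer_id": "",
        "facility_type_code": "", "claim_frequency_code": "",
    }
    total = Decimal(0)
    diagnoses: list[ParsedDiagnosis] = []
    lines: list[ParsedServiceLine] = []
    current_lx: Optional[int] = None
    pending: dict[str, str] = {}

    def flush_line(seg_index: int) -> None:
        nonlocal current_lx, pending
        if current_lx is None:
            return
        if "sv2" not in pending:
            raise X12ParseError(f"LX {current_lx} has no SV2 segment", segment_index=seg_index)
        sv2 = pending["_sv2_seg"]
        proc = sv2[1].replace(comp, ":")
        ptr_text = sv2[6] if len(sv2) > 6 else ""
        pointers = tuple(int(p) for p in ptr_text.split(comp) if p)
        try:
            charge = Decimal(sv2[2])
        except InvalidOperation:
            raise X12ParseError(f"bad charge {sv2[2]!r} on line {current_lx}",
                                segment_index=seg_index)
        lines.append(ParsedServiceLine(
            line_number=current_lx, procedure_code=proc, charge=charge,
            unit=sv2[3] if len(sv2) > 3 else "", quantity=int(sv2[4] or 1),
            diagnosis_pointers=pointers, service_date=pending.get("date", ""),
            revenue_code=sv2[0],
        ))
        current_lx, pending = None, {}

    for seg in segs:
        tag = seg.tag
        if tag == "BHT":
            fields["bht_reference"] = seg.element(3)
        elif tag == "NM1":
            kind = seg.element(1)
            if kind == "85":
                fields["provider_name"] = seg.element(3)
                fields["provider_npi"] = seg.element(9)
            elif kind == "IL":
                fields["subscriber_last"] = seg.element(3)
                fields["subscriber_first"] = seg.element(4)
                fields["subscriber_id"] = seg.element(9)
            elif kind == "PR":
                fields["payer_name"] = seg.element(3)
                fields["payer_id"] = seg.element(9)
        elif tag == "N3":
            fields["provider_street"] = seg.element(1)
        elif tag == "N4":
            fields["provider_city"] = seg.element(1)
            fields["provider_state"] = seg.element(2)
            fields["provider_zip"] = seg.element(3)
        elif tag == "DMG":
            fields["subscriber_birth_date"] = seg.element(2)
            fields["subscriber_gender"] = seg.element(3)
        elif tag == "CLM":
            fields["claim_id"] = seg.element(1)
            try:
                total = Decimal(seg.element(2))
            except InvalidOperation:
                raise X12ParseError(f"bad claim total {seg.element(2)!r}",
                                    segment_index=seg.index)
            facility = seg.element(5).split(comp)
            fields["facility_type_code"] = facility[0] if facility else ""
            fields["claim_frequency_code"] = facility[2] if len(facility) > 2 else ""
        elif tag == "HI":
            for composite in seg.elements:
                parts = composite.split(comp)
                if len(parts) < 2:
                    raise X12ParseError(f"malformed HI composite {composite!r}",
                                        segment_index=seg.index)
                diagnoses.append(ParsedDiagnosis(
                    qualifier=parts[0], code=parts[1],
                    poa=parts[8] if len(parts) > 8 else "",
                    ordinal=len(diagnoses) + 1,
                ))
        elif tag == "LX":
            flush_line(seg.index)
            try:
                current_lx = int(seg.element(1))
            except ValueError:
                raise X12ParseError(f"non-numeric LX number {seg.element(1)!r}",
                                    segment_index=seg.index)
        elif tag == "SV2":
            if current_lx is None:
                raise X12ParseError("SV2 outside a service-line loop", segment_index=seg.index)
            pending["sv2"] = "1"
            pending["_sv2_seg"] = seg.elements  # type: ignore[assignment]
        elif tag == "DTP" and seg.element(1) == "472" and current_lx is not None:
            pending["date"] = seg.element(3)
        # other segments (HL, REF, SBR, DTP*434, ...) are structural; tables ignore them
    flush_line(segs[-1].index)

    return ParsedClaim(total_charge=total, diagnoses=tuple(diagnoses),
                       service_lines=tuple(lines), **fields)


def parse_interchange(text: str) -> ParsedInterchange:
    """Parse 837i text into envelope metadata plus per-claim records.

    Permissive on unknown segments, strict on envelope arithmetic: unbalanced
    ISA/GS/ST nesting, control-number disagreement, or an SE01 segment count
    that does not match the transaction all raise :class:`X12ParseError` with
    the offending segment index.
    """
    delimiters = detect_delimiters(text)
    segments = split_segments(text, delimiters)
    if not segments or segments[0].tag != "ISA":
        raise X12ParseError("interchange must begin with ISA", segment_index=1)
    isa = segments[0]
    if segments[-1].tag != "IEA":
        raise X12ParseError("unterminated interchange (missing IEA trailer)",
                            segment_index=segments[-1].index)
    iea = segments[-1]
    if iea.element(2) != isa.element(13):
        raise X12ParseError(
            f"interchange control numbers disagree: ISA13={isa.element(13)!r} "
            f"IEA02={iea.element(2)!r}", segment_index=iea.index)

    yy = isa.element(9)
    envelope = EnvelopeMeta(
        sender_id=isa.element(6).strip(),
        receiver_id=isa.element(8).strip(),
        interchange_control_number=isa.element(13),
        group_control_number=1,
        interchange_date=dt.date(2000 + int(yy[0:2]), int(yy[2:4]), int(yy[4:6])),
        interchange_time=dt.time(int(isa.element(10)[0:2]), int(isa.element(10)[2:4])),
        usage_indicator=isa.element(15) or "T",
    )

    claims: list[ParsedClaim] = []
    gs_control = ""
    group_count = 0
    in_group = False
    current_tx: Optional[list[Segment]] = None
    tx_count_in_group = 0

    for seg in segments[1:-1]:
        if seg.tag == "GS":
            if in_group:
                raise X12ParseError("nested GS group", segment_index=seg.index)
            in_group = True
            group_count += 1
            gs_control = seg.element(6)
            envelope = EnvelopeMeta(
                sender_id=envelope.sender_id, receiver_id=envelope.receiver_id,
                interchange_control_number=envelope.interchange_control_number,
                group_control_number=int(gs_control) if gs_control.isdigit() else 1,
                interchange_date=envelope.interchange_date,
                interchange_time=envelope.interchange_time,
                usage_indicator=envelope.usage_indicator,
            )
            tx_count_in_group = 0
        elif seg.tag == "GE":
            if not in_group:
                raise X12ParseError("GE without GS", segment_index=seg.index)
            if current_tx is not None:
                raise X12ParseError("GE inside an open transaction", segment_index=seg.index)
            if seg.element(2) != gs_control:
                raise X12ParseError(
                    f"group control numbers disagree: GS06={gs_control!r} "
                    f"GE02={seg.element(2)!r}", segment_index=seg.index)
            if seg.element(1) != str(tx_count_in_group):
                raise X12ParseError(
                    f"GE01 transaction count {seg.element(1)!r} != {tx_count_in_group} found",
                    segment_index=seg.index)
            in_group = False
        elif seg.tag == "ST":
            if not in_group:
                raise X12ParseError("ST outside a functional group", segment_index=seg.index)
            if current_tx is not None:
                raise X12ParseError("nested ST transaction", segment_index=seg.index)
            current_tx = [seg]
        elif seg.tag == "SE":
            if current_tx is None:
                raise X12ParseError("SE without ST", segment_index=seg.index)
            current_tx.append(seg)
            st = current_tx[0]
            if seg.element(2) != st.element(2):
                raise X12ParseError(
                    f"transaction control numbers disagree: ST02={st.element(2)!r} "
                    f"SE02={seg.element(2)!r}", segment_index=seg.index)
            if seg.element(1) != str(len(current_tx)):
                raise X12ParseError(
                    f"SE01 segment count mismatch: expected {len(current_tx)}, "
                    f"found {seg.element(1)!r}", segment_index=seg.index)
            claims.append(_parse_transaction(current_tx, delimiters.component_sep, gs_control))
            tx_count_in_group += 1
            current_tx = None
        elif current_tx is not None:
            current_tx.append(seg)
        # segments between envelopes outside any transaction are ignored
    if current_tx is not None:
        raise X12ParseError("unterminated transaction (missing SE)",
                            segment_index=current_tx[-1].index)
    if in_group:
        raise X12ParseError("unterminated functional group (missing GE)",
                            segment_index=segments[-1].index)
    if iea.element(1) != str(group_count):
        raise X12ParseError(
            f"IEA01 group count {iea.element(1)!r} != {group_count} found",
            segment_index=iea.index)

    return ParsedInterchange(
        delimiters=delimiters, envelope=envelope, claims=tuple(claims),
        segments=tuple(segments), gs_control_number=gs_control,
    )


# ---------------------------------------------------------------------------
# CSV outputs
# ---------------------------------------------------------------------------

def _csv_field(value: str) -> str:
    if any(c in value for c in ',"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value


def write_csv_outputs(parsed: ParsedInterchange, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write header.csv, diagnoses.csv and service_lines.csv under ``outdir``.

    The three tables share ``claim_id`` as the join key: one header row per
    claim, one diagnosis row per (claim, diagnosis), one service-line row per
    (claim, line). Pointer lists are rendered bracketed (``"[2, 4, 6]"``) and
    always quoted; procedure codes keep their qualifier prefix (``HC:97605``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header_path = outdir / "header.csv"
    dx_path = outdir / "diagnoses.csv"
    lines_path = outdir / "service_lines.csv"

    with open(header_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=HEADER_COLUMNS, lineterminator="\n")
        w.writeheader()
        w.writerows(parsed.header_rows)

    with open(dx_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=DIAGNOSIS_COLUMNS, lineterminator="\n")
        w.writeheader()
        w.writerows(parsed.diagnosis_rows)

    # hand-rolled so the pointer list is always quoted, matching the reference
    # rendering: 4742333269,1,HC:97605,76,UN,1,"[1]",20180428
    with open(lines_path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(SERVICE_LINE_COLUMNS) + "\n")
        for row in parsed.service_line_rows:
            cells = [_csv_field(row[c]) for c in SERVICE_LINE_COLUMNS
                     if c != "diagnosis_pointers"]
            cells.insert(6, '"' + row["diagnosis_pointers"].replace('"', '""') + '"')
            fh.write(",".join(cells) + "\n")

    return header_path, dx_path, lines_path
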