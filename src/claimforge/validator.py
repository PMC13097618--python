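"""Structural validation of 837i text against a documented rule catalog.

The validator is collect-all, never fail-fast: it scans the whole file and
returns every finding it can establish, sorted by segment index, so a report
lists all defects of a hand-edited classroom file at once. Rules fall into
five families:

* ``DEL`` — delimiter hygiene: fixed-width ISA, pairwise-distinct separators;
* ``ENV`` — envelope arithmetic: ISA/IEA, GS/GE, ST/SE pairing, control-number
  agreement, SE01 segment counts, GE01/IEA01 tallies;
* ``SEQ`` — segment sequencing inside a transaction (ST < BHT < 1000A/B <
  2000A < 2000B < 2300 < 2400 < SE) and consecutive LX numbering;
* ``LOOP`` — required-segment presence per loop (NM1*85 with N3/N4, SBR with
  NM1*IL, CLM before HI, every LX followed by its SV2);
* ``PTR`` — diagnosis-pointer soundness: every service-line pointer must
  reference an existing diagnosis ordinal.

Unknown segment tags produce a WARNING, not an error: classroom files may be
hand-edited, and an unrecognized segment is suspicious but not structurally
fatal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .exceptions import X12ParseError
from .x12_codec import ISA_LENGTH, Segment, detect_delimiters, split_segments

#: the complete rule catalog; every Finding.rule_code is one of these
RULES: dict[str, str] = {
    "DEL-001": "file must begin with a fixed-width 106-character ISA header",
    "DEL-002": "element/component/repetition separators and segment terminator must be distinct",
    "ENV-001": "ISA interchange must be terminated by an IEA trailer",
    "ENV-002": "IEA02 must equal the ISA13 interchange control number",
    "ENV-003": "GS functional group must be terminated by a GE trailer",
    "ENV-004": "GE02 must equal the GS06 group control number",
    "ENV-005": "GE01 must equal the number of transactions in the group",
    "ENV-006": "every ST must have a matching SE (and SE an ST)",
    "ENV-007": "SE02 must equal the ST02 transaction control number",
    "ENV-008": "SE01 must equal the segment count from ST through SE inclusive",
    "ENV-009": "IEA01 must equal the number of functional groups",
    "SEQ-001": "segment out of order within the transaction loop hierarchy",
    "SEQ-002": "LX service-line numbers must be consecutive from 1",
    "LOOP-001": "billing-provider loop requires NM1*85 with N3 and N4",
    "LOOP-002": "subscriber loop requires SBR with NM1*IL",
    "LOOP-003": "HI diagnosis segments require a preceding CLM",
    "LOOP-004": "every LX must be followed by an SV2 service line",
    "PTR-001": "service-line diagnosis pointer must reference an existing diagnosis ordinal",
    "OTH-001": "unrecognized segment tag (ignored for tables)",
}

_KNOWN_TAGS = {"ISA", "GS", "ST", "BHT", "NM1", "HL", "N3", "N4", "REF", "PER",
               "PRV", "SBR", "DMG", "CLM", "DTP", "HI", "CL1", "LX", "SV2",
               "SE", "GE", "IEA"}

# loop phase ranks for SEQ-001 (monotone non-decreasing within a transaction)
_PHASE_HEADER, _PHASE_BHT, _PHASE_SUBMITTER = 0, 1, 2
_PHASE_2000A, _PHASE_2000B, _PHASE_2300, _PHASE_2400, _PHASE_TRAILER = 3, 4, 5, 6, 7


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``segment_index`` 0 marks a file-level problem."""

    segment_index: int
    rule_code: str
    severity: str  # ERROR or WARNING
    message: str

    def __post_init__(self) -> None:
        assert self.rule_code in RULES, f"undocumented rule {self.rule_code}"
        assert self.severity in ("ERROR", "WARNING")


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def error_count(self) -> int:
        return sum(1 for f in self.findings if f.severity == "ERROR")

    @property
    def warning_count(self) -> int:
        return sum(1 for f in self.findings if f.severity == "WARNING")

    @property
    def is_valid(self) -> bool:
        return self.error_count == 0

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["segment_index", "rule_code", "severity", "message"])
            for f in self.findings:
                w.writerow([f.segment_index, f.rule_code, f.severity, f.message])
        return path

    def pretty(self) -> str:
        lines = [f"{self.error_count} error(s), {self.warning_count} warning(s)"]
        for f in self.findings:
            where = f"segment {f.segment_index}" if f.segment_index else "file"
            lines.append(f"  [{f.severity}] {f.rule_code} at {where}: {f.message}")
        return "\n".join(lines)


def _segment_phase(seg: Segment, current: int) -> Optional[int]:
    """Loop rank of a segment, or None when the tag carries no ordering constraint."""
    tag = seg.tag
    if tag == "ST":
        return _PHASE_HEADER
    if tag == "BHT":
        return _PHASE_BHT
    if tag == "NM1":
        return {"41": _PHASE_SUBMITTER, "40": _PHASE_SUBMITTER,
                "85": _PHASE_2000A, "IL": _PHASE_2000B,
                "PR": _PHASE_2000B}.get(seg.element(1))
    if tag == "HL":
        return {"20": _PHASE_2000A, "22": _PHASE_2000B}.get(seg.element(3))
    if tag in ("N3", "N4", "REF", "PRV", "PER"):
        return _PHASE_2000A
    if tag in ("SBR", "DMG"):
        return _PHASE_2000B
    if tag in ("CLM", "HI", "CL1"):
        return _PHASE_2300
    if tag == "DTP":
        return current if current in (_PHASE_2300, _PHASE_2400) else _PHASE_2300
    if tag in ("LX", "SV2"):
        return _PHASE_2400
    if tag == "SE":
        return _PHASE_TRAILER
    return None


def _validate_transaction(segs: list[Segment], comp: str, out: list[Finding]) -> None:
    """SEQ / LOOP / PTR checks over one ST..SE segment run."""
    err = lambda idx, code, msg: out.append(Finding(idx, code, "ERROR", msg))

    # sequencing: phases must never decrease
    phase = _PHASE_HEADER
    for seg in segs:
        p = _segment_phase(seg, phase)
        if p is None:
            continue
        if p < phase:
            err(seg.index, "SEQ-001",
                f"{seg.tag} appears after the "
                f"{'2400' if phase == _PHASE_2400 else '2300' if phase == _PHASE_2300 else 'later'}"
                f" loop has started")
        else:
            phase = p

    tags = [s.tag for s in segs]

    # 2000A: billing provider name + address
    nm185 = [s for s in segs if s.tag == "NM1" and s.element(1) == "85"]
    if not nm185:
        err(segs[0].index, "LOOP-001", "missing NM1*85 billing-provider segment")
    else:
        if "N3" not in tags:
            err(nm185[0].index, "LOOP-001", "billing-provider loop lacks an N3 address")
        if "N4" not in tags:
            err(nm185[0].index, "LOOP-001", "billing-provider loop lacks an N4 city/state/zip")

    # 2000B: subscriber
    sbr = [s for s in segs if s.tag == "SBR"]
    nm1il = [s for s in segs if s.tag == "NM1" and s.element(1) == "IL"]
    if not sbr:
        err(segs[0].index, "LOOP-002", "missing SBR subscriber segment")
    elif not nm1il:
        err(sbr[0].index, "LOOP-002", "SBR present without an NM1*IL subscriber name")

    # 2300: CLM before HI
    clm_idx = next((i for i, s in enumerate(segs) if s.tag == "CLM"), None)
    n_dx = 0
    for i, seg in enumerate(segs):
        if seg.tag == "HI":
            n_dx += len([e for e in seg.elements if e])
            if clm_idx is None or i < clm_idx:
                err(seg.index, "LOOP-003", "HI diagnosis segment without a preceding CLM")
    if clm_idx is None:
        err(segs[0].index, "LOOP-003", "transaction carries no CLM claim segment")

    # 2400: LX/SV2 pairing + numbering; PTR soundness
    lx_numbers: list[str] = []
    open_lx: Optional[Segment] = None
    for seg in segs:
        if seg.tag == "LX":
            if open_lx is not None:
                err(open_lx.index, "LOOP-004",
                    f"LX {open_lx.element(1)} is not followed by an SV2")
            open_lx = seg
            lx_numbers.append(seg.element(1))
        elif seg.tag == "SV2":
            if open_lx is None:
                err(seg.index, "LOOP-004", "SV2 service line outside any LX loop")
            else:
                open_lx = None
            ptr_text = seg.element(7)
            for token in (p for p in ptr_text.split(comp) if p):
                try:
                    ptr = int(token)
                except ValueError:
                    err(seg.index, "PTR-001", f"non-numeric diagnosis pointer {token!r}")
                    continue
                if not 1 <= ptr <= n_dx:
                    err(seg.index, "PTR-001",
                        f"diagnosis pointer {ptr} outside [1, {n_dx}]")
    if open_lx is not None:
        err(open_lx.index, "LOOP-004",
            f"LX {open_lx.element(1)} is not followed by an SV2")
    expected = [str(i + 1) for i in range(len(lx_numbers))]
    if lx_numbers != expected:
        first_bad = next(i for i, (a, b) in enumerate(zip(lx_numbers, expected)) if a != b)
        bad_seg = [s for s in segs if s.tag == "LX"][first_bad]
        err(bad_seg.index, "SEQ-002",
            f"LX numbering {lx_numbers} is not consecutive from 1")


def validate_structure(text: str) -> ValidationReport:
    """Apply the full rule catalog to raw 837i text; never raises."""
    findings: list[Finding] = []
    err = lambda idx, code, msg: findings.append(Finding(idx, code, "ERROR", msg))

    try:
        delimiters = detect_delimiters(text)
    except X12ParseError as exc:
        code = "DEL-002" if "delimiter" in str(exc) else "DEL-001"
        findings.append(Finding(0, code, "ERROR", str(exc)))
        return ValidationReport(findings=tuple(findings))

    segments = split_segments(text, delimiters)
    comp = delimiters.component_sep

    for seg in segments:
        if seg.tag not in _KNOWN_TAGS:
            findings.append(Finding(seg.index, "OTH-001", "WARNING",
                                    f"unrecognized segment tag {seg.tag!r}"))

    isa = segments[0]
    iea = [s for s in segments if s.tag == "IEA"]
    if not iea:
        err(segments[-1].index, "ENV-001", "missing IEA interchange trailer")
    else:
        if iea[0].element(2) != isa.element(13):
            err(iea[0].index, "ENV-002",
                f"IEA02 {iea[0].element(2)!r} != ISA13 {isa.element(13)!r}")
        n_groups = sum(1 for s in segments if s.tag == "GS")
        if iea[0].element(1) != str(n_groups):
            err(iea[0].index, "ENV-009",
                f"IEA01 {iea[0].element(1)!r} != {n_groups} functional group(s) found")

    # functional groups
    gs_stack: list[Segment] = []
    tx_in_group = 0
    saw_group = False
    for seg in segments:
        if seg.tag == "GS":
            saw_group = True
            gs_stack.append(seg)
            tx_in_group = 0
        elif seg.tag == "ST":
            tx_in_group += 1
        elif seg.tag == "GE":
            if not gs_stack:
                err(seg.index, "ENV-003", "GE without a matching GS")
                continue
            gs = gs_stack.pop()
            if seg.element(2) != gs.element(6):
                err(seg.index, "ENV-004",
                    f"GE02 {seg.element(2)!r} != GS06 {gs.element(6)!r}")
            if seg.element(1) != str(tx_in_group):
                err(seg.index, "ENV-005",
                    f"GE01 {seg.element(1)!r} != {tx_in_group} transaction(s) found")
    for gs in gs_stack:
        err(gs.index, "ENV-003", "GS group is never closed by GE")
    if not saw_group:
        err(isa.index, "ENV-003", "interchange contains no GS functional group")

    # transactions
    current: Optional[list[Segment]] = None
    for seg in segments:
        if seg.tag == "ST":
            if current is not None:
                err(current[0].index, "ENV-006", "ST transaction is never closed by SE")
                _validate_transaction(current, comp, findings)
            current = [seg]
        elif seg.tag == "SE":
            if current is None:
                err(seg.index, "ENV-006", "SE without a matching ST")
                continue
            current.append(seg)
            st = current[0]
            if seg.element(2) != st.element(2):
                err(seg.index, "ENV-007",
                    f"SE02 {seg.element(2)!r} != ST02 {st.element(2)!r}")
            if seg.element(1) != str(len(current)):
                err(seg.index, "ENV-008",
                    f"SE01 expected {len(current)} segments, found {seg.element(1)!r}")
            _validate_transaction(current, comp, findings)
            current = None
        elif current is not None:
            current.append(seg)
    if current is not None:
        err(current[0].index, "ENV-006", "ST transaction is never closed by SE")
        _validate_transaction(current, comp, findings)

    findings.sort(key=lambda f: f.segment_index)
    return ValidationReport(findings=tuple(findings))
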