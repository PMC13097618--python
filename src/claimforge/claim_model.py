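"""Domain model for institutional (837i) claims.

Pure data: the claim, its subscriber, diagnosis and service-line entries, the
EDI delimiter set and interchange envelope metadata, and the generator
configuration. Serialization lives in :mod:`claimforge.x12_codec`.

An institutional claim carries 1–12 ordered diagnoses (the first is the
principal diagnosis) and 1–50 service lines. Each line holds 1–4 diagnosis
pointers — integers referencing diagnosis ordinals — which is how the 837
transaction justifies a billed procedure by one or more diagnoses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import Decimal

from .exceptions import ConfigError
from .reference_data import ICD10CM_RE, HCPCS_RE, PayerRecord, ProviderRecord

DIAGNOSIS_QUALIFIERS = ("ABK", "ABF")  # principal / other diagnosis (ICD-10-CM)
POA_VALUES = ("Y", "N", "U", "W", "1")
GENDERS = ("M", "F", "U")
MAX_DIAGNOSES = 12
MAX_SERVICE_LINES = 50
MAX_POINTERS_PER_LINE = 4


@dataclass(frozen=True)
class DelimiterSet:
    """The four characters governing X12 serialization and parsing."""

    element_sep: str = "*"
    component_sep: str = ":"
    repetition_sep: str = "^"
    segment_term: str = "~"

    def __post_init__(self) -> None:
        chars = (self.element_sep, self.component_sep, self.repetition_sep, self.segment_term)
        for c in chars:
            if len(c) != 1:
                raise ValueError(f"delimiter must be a single character, got {c!r}")
            if c.isdigit() or (c.isalpha() and c.isupper()):
                raise ValueError(f"delimiter may not be a digit or uppercase letter: {c!r}")
        if len(set(chars)) != 4:
            raise ValueError(f"delimiters must be pairwise distinct: {chars}")


@dataclass(frozen=True)
class EnvelopeMeta:
    """ISA/GS envelope metadata; transaction control numbers live on each claim."""

    sender_id: str = "CLAIMFORGE"
    receiver_id: str = "RECEIVER"
    interchange_control_number: str = "000000001"
    group_control_number: int = 1
    interchange_date: dt.date = dt.date(2024, 1, 15)
    interchange_time: dt.time = dt.time(12, 0)
    usage_indicator: str = "T"

    def __post_init__(self) -> None:
        if len(self.sender_id) > 15 or len(self.receiver_id) > 15:
            raise ValueError("sender/receiver IDs are limited to 15 characters")
        icn = self.interchange_control_number
        if len(icn) != 9 or not icn.isdigit():
            raise ValueError(f"interchange control number must be 9 digits, got {icn!r}")
        if self.group_control_number < 1:
            raise ValueError("group control number must be positive")
        if self.usage_indicator not in ("T", "P"):
            raise ValueError("usage indicator must be T (test) or P (production)")


@dataclass(frozen=True)
class Subscriber:
    first_name: str
    last_name: str
    member_id: str
    payer: PayerRecord
    birth_date: dt.date
    gender: str


@dataclass(frozen=True)
class DiagnosisEntry:
    """One diagnosis on a claim: qualifier, ICD-10-CM code, POA flag, ordinal 1–12."""

    qualifier: str
    code: str
    poa: str
    ordinal: int


@dataclass(frozen=True)
class ServiceLine:
    """One 2400-loop service line with its diagnosis-pointer links."""

    line_number: int
    procedure_code: str
    charge: Decimal
    quantity: int
    diagnosis_pointers: tuple[int, ...]
    service_date: dt.date
    revenue_code: str
    procedure_qualifier: str = "HC"
    unit: str = "UN"


@dataclass(frozen=True)
class InstitutionalClaim:
    claim_id: str
    transaction_control_number: str
    provider: ProviderRecord
    subscriber: Subscriber
    diagnoses: tuple[DiagnosisEntry, ...]
    service_lines: tuple[ServiceLine, ...]
    total_charge: Decimal
    facility_type_code: str = "11"
    claim_frequency_code: str = "1"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the claim generator; all randomness flows from ``seed``.

    Diagnosis counts are drawn uniformly in [dx_min, dx_max] (hard-limited to
    1–12) and line counts in [line_min, line_max] (1–50), matching the
    configurable-complexity bounds of institutional claims. ID widths default
    to a 10-digit claim ID and 7-digit member ID.
    """

    n_claims: int = 1
    dx_min: int = 1
    dx_max: int = 12
    line_min: int = 1
    line_max: int = 50
    max_pointers_per_line: int = 4
    seed: int = 0
    service_year_range: tuple[int, int] = (2018, 2024)
    claim_id_digits: int = 10
    member_id_digits: int = 7
    per_line_service_dates: bool = False
    facility_type_code: str = "11"
    claim_frequency_code: str = "1"

    def validate(self) -> None:
        if self.n_claims < 1:
            raise ConfigError(f"n_claims must be positive, got {self.n_claims}")
        if not (1 <= self.dx_min <= self.dx_max <= MAX_DIAGNOSES):
            raise ConfigError(
                f"diagnosis range must satisfy 1 <= dx_min <= dx_max <= {MAX_DIAGNOSES}, "
                f"got [{self.dx_min}, {self.dx_max}]"
            )
        if not (1 <= self.line_min <= self.line_max <= MAX_SERVICE_LINES):
            raise ConfigError(
                f"service-line range must satisfy 1 <= line_min <= line_max <= "
                f"{MAX_SERVICE_LINES}, got [{self.line_min}, {self.line_max}]"
            )
        if not (1 <= self.max_pointers_per_line <= MAX_POINTERS_PER_LINE):
            raise ConfigError(
                f"max_pointers_per_line must be in [1, {MAX_POINTERS_PER_LINE}], "
                f"got {self.max_pointers_per_line}"
            )
        y0, y1 = self.service_year_range
        if y0 > y1:
            raise ConfigError(f"service_year_range out of order: {self.service_year_range}")
        if not (5 <= self.member_id_digits <= 9):
            raise ConfigError("member_id_digits must be in [5, 9]")
        if self.claim_id_digits < 1:
            raise ConfigError("claim_id_digits must be positive")


def validate_claim(claim: InstitutionalClaim) -> list[str]:
    """Check every claim invariant; returns violation messages (empty list = valid).

    Violations are returned rather than raised so callers can collect complete
    reports over a batch.
    """
    v: list[str] = []

    if not (claim.claim_id.isdigit() and claim.claim_id):
        v.append(f"claim_id must be a digit string, got {claim.claim_id!r}")
    if not claim.transaction_control_number.isdigit():
        v.append("transaction control number must be numeric")

    n_dx = len(claim.diagnoses)
    if not 1 <= n_dx <= MAX_DIAGNOSES:
        v.append(f"claim must carry 1-{MAX_DIAGNOSES} diagnoses, found {n_dx}")
    for i, dx in enumerate(claim.diagnoses):
        if dx.ordinal != i + 1:
            v.append(f"diagnosis ordinals must be consecutive from 1; position {i + 1} "
                     f"has ordinal {dx.ordinal}")
        if dx.qualifier not in DIAGNOSIS_QUALIFIERS:
            v.append(f"diagnosis {dx.ordinal}: unknown qualifier {dx.qualifier!r}")
        if dx.poa not in POA_VALUES:
            v.append(f"diagnosis {dx.ordinal}: bad POA indicator {dx.poa!r}")
        if not ICD10CM_RE.match(dx.code):
            v.append(f"diagnosis {dx.ordinal}: malformed ICD-10-CM code {dx.code!r}")
    codes = [dx.code for dx in claim.diagnoses]
    if len(set(codes)) != len(codes):
        v.append("diagnosis codes must be distinct within a claim")

    n_lines = len(claim.service_lines)
    if not 1 <= n_lines <= MAX_SERVICE_LINES:
        v.append(f"claim must carry 1-{MAX_SERVICE_LINES} service lines, found {n_lines}")
    for i, line in enumerate(claim.service_lines):
        tag = f"service line {line.line_number}"
        if line.line_number != i + 1:
            v.append(f"line numbers must be consecutive from 1; position {i + 1} "
                     f"is numbered {line.line_number}")
        if not HCPCS_RE.match(line.procedure_code):
            v.append(f"{tag}: malformed HCPCS code {line.procedure_code!r}")
        if line.charge < 0:
            v.append(f"{tag}: negative charge {line.charge}")
        if line.charge != line.charge.quantize(Decimal("0.01")):
            v.append(f"{tag}: charge {line.charge} has more than 2 decimal places")
        if line.quantity < 1:
            v.append(f"{tag}: quantity must be positive, got {line.quantity}")
        ptrs = line.diagnosis_pointers
        if not 1 <= len(ptrs) <= MAX_POINTERS_PER_LINE:
            v.append(f"{tag}: must carry 1-{MAX_POINTERS_PER_LINE} diagnosis pointers")
        if len(set(ptrs)) != len(ptrs):
            v.append(f"{tag}: duplicate diagnosis pointers {list(ptrs)}")
        if list(ptrs) != sorted(ptrs):
            v.append(f"{tag}: diagnosis pointers must be sorted ascending, got {list(ptrs)}")
        for p in ptrs:
            if not 1 <= p <= n_dx:
                v.append(f"{tag}: pointer {p} does not reference a diagnosis "
                         f"ordinal in [1, {n_dx}]")
        if len(line.revenue_code) != 4 or not line.revenue_code.isdigit():
            v.append(f"{tag}: revenue code must be 4 digits, got {line.revenue_code!r}")

    line_total = sum((l.charge for l in claim.service_lines), Decimal(0))
    if claim.service_lines and claim.total_charge != line_total:
        v.append(f"total charge {claim.total_charge} != sum of line charges {line_total}")

    sub = claim.subscriber
    if not (sub.member_id.isdigit() and 5 <= len(sub.member_id) <= 9):
        v.append(f"member ID must be 5-9 digits, got {sub.member_id!r}")
    if not sub.first_name or not sub.last_name:
        v.append("subscriber names must be nonempty")
    if sub.gender not in GENDERS:
        v.append(f"subscriber gender must be one of {GENDERS}, got {sub.gender!r}")

    if len(claim.facility_type_code) != 2 or not claim.facility_type_code.isdigit():
        v.append(f"facility type code must be 2 digits, got {claim.facility_type_code!r}")
    if len(claim.claim_frequency_code) != 1 or not claim.claim_frequency_code.isdigit():
        v.append(f"claim frequency code must be 1 digit, got {claim.claim_frequency_code!r}")

    return v


_WORKED_EXAMPLE_PROVIDER = ProviderRecord(
    npi="1548083421",
    org_name="HSA GLENWOOD, LLC",
    taxonomy="282N00000X",
    street="1200 N BRAND BLVD",
    city="GLENDALE",
    state="CA",
    zip="91203",
)

_WORKED_EXAMPLE_PAYER = PayerRecord(
    hios_id="18581", product_name="Anchor Blue Select PPO", payer_type="COMMERCIAL"
)

# (qualifier, code) rows for the reference claim; the file carries ABK on every
# row and the parser reproduces qualifiers verbatim
_WORKED_EXAMPLE_DIAGNOSES = (
    ("ABK", "T82330A"),
    ("ABK", "S62665A"),
    ("ABK", "Z13811"),
    ("ABK", "S72141Q"),
    ("ABK", "S61431A"),
    ("ABK", "H61301"),
)

_WORKED_EXAMPLE_LINES = (
    # (procedure, charge, pointers)
    ("97605", 76, (1,)),
    ("67228", 33, (2, 4, 6)),
    ("92316", 107, (6,)),
)


def worked_example_claim() -> InstitutionalClaim:
    """The reference claim used throughout the docs and tests.

    Claim 4742333269 for subscriber Jonathan Mendez (member ID 3191511), billed
    by HSA GLENWOOD, LLC (NPI 1548083421) under transaction control number
    44146: six diagnoses and three service lines (charges 76 / 33 / 107 on
    2018-04-28, pointers [1], [2, 4, 6] and [6]).
    """
    service_date = dt.date(2018, 4, 28)
    diagnoses = tuple(
        DiagnosisEntry(qualifier=q, code=c, poa="Y", ordinal=i + 1)
        for i, (q, c) in enumerate(_WORKED_EXAMPLE_DIAGNOSES)
    )
    lines = tuple(
        ServiceLine(
            line_number=i + 1,
            procedure_code=code,
            charge=Decimal(charge),
            quantity=1,
            diagnosis_pointers=ptrs,
            service_date=service_date,
            revenue_code="0510",
        )
        for i, (code, charge, ptrs) in enumerate(_WORKED_EXAMPLE_LINES)
    )
    return InstitutionalClaim(
        claim_id="4742333269",
        transaction_control_number="44146",
        provider=_WORKED_EXAMPLE_PROVIDER,
        subscriber=Subscriber(
            first_name="Jonathan",
            last_name="Mendez",
            member_id="3191511",
            payer=_WORKED_EXAMPLE_PAYER,
            birth_date=dt.date(1985, 3, 14),
            gender="M",
        ),
        diagnoses=diagnoses,
        service_lines=lines,
        total_charge=sum((l.charge for l in lines), Decimal(0)),
    )
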