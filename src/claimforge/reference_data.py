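"""Loading and sampling of the packaged synthetic reference tables.

The generator never ingests patient-level data: the bundle holds only
nonidentifiable code sets (ICD-10-CM diagnoses, HCPCS procedures), an
organizational provider directory with NPIs and practice addresses, payer
products with HIOS issuer IDs, and institutional revenue codes. The packaged
tables are a small curated synthetic stand-in for the public CMS / NPPES /
Healthcare.gov extracts a production deployment would use; ``load_reference_bundle``
accepts a directory of user-supplied full-size tables with the same columns.

Provider NPIs in the packaged bundle are synthetic but carry a correct Luhn
check digit, so the NPI validity invariant is real and testable.
"""

from __future__ import annotations

import csv
import random
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .exceptions import BundleIntegrityError, BundleLoadError, ConfigError

ICD10CM_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{1,5}$")
HCPCS_RE = re.compile(r"^[0-9A-Z]{5}$")
REVENUE_CODE_RE = re.compile(r"^[0-9]{4}$")

#: table name -> required header columns; person-level fields never appear here
BUNDLE_SCHEMA = {
    "diagnoses": ("code", "description"),
    "procedures": ("code", "description"),
    "providers": ("npi", "org_name", "taxonomy", "street", "city", "state", "zip"),
    "payers": ("hios_id", "product_name", "payer_type"),
    "revenue_codes": ("code",),
}

PAYER_TYPES = frozenset({"MEDICARE", "MEDICAID", "COMMERCIAL"})


@dataclass(frozen=True)
class CodeEntry:
    """One diagnosis or procedure code with its free-text description."""

    code: str
    description: str
    system: str  # "ICD10CM" or "HCPCS"


@dataclass(frozen=True)
class ProviderRecord:
    """One billing-provider organization: NPI, taxonomy, and practice address."""

    npi: str
    org_name: str
    taxonomy: str
    street: str
    city: str
    state: str
    zip: str


@dataclass(frozen=True)
class PayerRecord:
    """One insurance product: HIOS issuer ID, product name, and market segment."""

    hios_id: str
    product_name: str
    payer_type: str


@dataclass(frozen=True)
class ReferenceBundle:
    """The five lookup tables the claim generator samples from."""

    diagnoses: Sequence[CodeEntry]
    procedures: Sequence[CodeEntry]
    providers: Sequence[ProviderRecord]
    payers: Sequence[PayerRecord]
    revenue_codes: Sequence[str] = field(default_factory=tuple)


def npi_check_digit(base9: str) -> str:
    """Luhn check digit for a 9-digit NPI base, computed over ``"80840" + base9``.

    The 80840 prefix is the ISO health-industry issuer identifier that the
    NPI enumerator prepends before applying the standard Luhn mod-10 scheme.
    """
    if len(base9) != 9 or not base9.isdigit():
        raise ValueError(f"NPI base must be 9 digits, got {base9!r}")
    payload = "80840" + base9
    total = 0
    # with the check digit appended, base digits at odd positions from the
    # right are doubled; rightmost payload digit is one of them
    for i, ch in enumerate(reversed(payload)):
        d = int(ch)
        if i % 2 == 0:
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return str((10 - total % 10) % 10)


def npi_is_valid(npi: str) -> bool:
    """True iff ``npi`` is 10 digits whose last digit is the correct Luhn check digit."""
    if not isinstance(npi, str) or len(npi) != 10 or not npi.isdigit():
        raise ValueError(f"NPI must be exactly 10 decimal digits, got {npi!r}")
    return npi_check_digit(npi[:9]) == npi[9]


def _read_table(name: str, directory: Optional[Path]) -> list[dict[str, str]]:
    filename = f"{name}.csv"
    if directory is not None:
        path = Path(directory) / filename
        if not path.is_file():
            raise BundleLoadError(f"missing reference table {name!r} ({path})")
        text = path.read_text(encoding="utf-8")
    else:
        ref = resources.files(__package__) / "data" / filename
        try:
            text = ref.read_text(encoding="utf-8")
        except FileNotFoundError:  # pragma: no cover - packaging defect
            raise BundleLoadError(f"missing packaged reference table {name!r}")
    rows = list(csv.DictReader(text.splitlines()))
    if not rows:
        raise BundleLoadError(f"reference table {name!r} is empty")
    required = BUNDLE_SCHEMA[name]
    have = set(rows[0].keys())
    missing = [c for c in required if c not in have]
    if missing:
        raise BundleLoadError(f"reference table {name!r} lacks columns {missing}")
    extra_person_fields = have - set(required)
    if extra_person_fields:
        # privacy contract: the schema is closed, nothing person-level can ride along
        raise BundleIntegrityError(
            f"reference table {name!r} has unexpected columns {sorted(extra_person_fields)}"
        )
    return rows


def _check_unique(kind: str, values: Iterator[str]) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise BundleIntegrityError(f"duplicate {kind}: {v}")
        seen.add(v)


def load_reference_bundle(path: Optional[str | Path] = None) -> ReferenceBundle:
    """Load the packaged bundle, or the five CSV tables found in ``path``.

    Raises :class:`BundleLoadError` when a table is missing or empty and
    :class:`BundleIntegrityError` when a loaded table violates an invariant
    (duplicate NPI, malformed code, Luhn-invalid NPI, unknown payer type).
    """
    directory = Path(path) if path is not None else None

    diagnoses = []
    for row in _read_table("diagnoses", directory):
        code = row["code"].strip()
        if not ICD10CM_RE.match(code) or "." in code:
            raise BundleIntegrityError(f"malformed ICD-10-CM code: {code!r}")
        diagnoses.append(CodeEntry(code, row["description"], "ICD10CM"))
    _check_unique("ICD10CM code", (e.code for e in diagnoses))

    procedures = []
    for row in _read_table("procedures", directory):
        code = row["code"].strip()
        if not HCPCS_RE.match(code):
            raise BundleIntegrityError(f"malformed HCPCS code: {code!r}")
        procedures.append(CodeEntry(code, row["description"], "HCPCS"))
    _check_unique("HCPCS code", (e.code for e in procedures))

    providers = []
    for row in _read_table("providers", directory):
        rec = ProviderRecord(
            npi=row["npi"].strip(),
            org_name=row["org_name"],
            taxonomy=row["taxonomy"],
            street=row["street"],
            city=row["city"],
            state=row["state"],
            zip=row["zip"],
        )
        if not npi_is_valid(rec.npi):
            raise BundleIntegrityError(f"NPI fails Luhn check: {rec.npi}")
        if len(rec.state) != 2 or not rec.state.isalpha() or not rec.state.isupper():
            raise BundleIntegrityError(f"bad state code {rec.state!r} for NPI {rec.npi}")
        providers.append(rec)
    _check_unique("NPI", (p.npi for p in providers))

    payers = []
    for row in _read_table("payers", directory):
        rec = PayerRecord(row["hios_id"].strip(), row["product_name"], row["payer_type"].strip())
        if len(rec.hios_id) != 5 or not rec.hios_id.isdigit():
            raise BundleIntegrityError(f"HIOS ID must be 5 digits: {rec.hios_id!r}")
        if not rec.product_name:
            raise BundleIntegrityError("empty payer product name")
        if rec.payer_type not in PAYER_TYPES:
            raise BundleIntegrityError(f"unknown payer type {rec.payer_type!r}")
        payers.append(rec)
    _check_unique("HIOS ID", (p.hios_id for p in payers))

    revenue_codes = []
    for row in _read_table("revenue_codes", directory):
        code = row["code"].strip()
        if not REVENUE_CODE_RE.match(code):
            raise BundleIntegrityError(f"revenue code must be 4 digits: {code!r}")
        revenue_codes.append(code)
    _check_unique("revenue code", iter(revenue_codes))

    return ReferenceBundle(
        diagnoses=tuple(diagnoses),
        procedures=tuple(procedures),
        providers=tuple(providers),
        payers=tuple(payers),
        revenue_codes=tuple(revenue_codes),
    )


def load_name_lists() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Packaged (first_names, last_names) used to synthesize subscriber identities."""
    data = resources.files(__package__) / "data"
    first = tuple((data / "first_names.txt").read_text(encoding="utf-8").split())
    last = tuple((data / "last_names.txt").read_text(encoding="utf-8").split())
    return first, last


def sample_provider(bundle: ReferenceBundle, rng: random.Random) -> ProviderRecord:
    """Uniform draw of one provider; deterministic for a given rng state."""
    if not bundle.providers:
        raise BundleIntegrityError("provider table is empty")
    return rng.choice(list(bundle.providers))


def sample_payer(bundle: ReferenceBundle, rng: random.Random) -> PayerRecord:
    """Uniform draw of one payer product."""
    if not bundle.payers:
        raise BundleIntegrityError("payer table is empty")
    return rng.choice(list(bundle.payers))


def sample_procedure(bundle: ReferenceBundle, rng: random.Random) -> CodeEntry:
    """Uniform draw of one HCPCS procedure code."""
    if not bundle.procedures:
        raise BundleIntegrityError("procedure table is empty")
    return rng.choice(list(bundle.procedures))


def sample_revenue_code(bundle: ReferenceBundle, rng: random.Random) -> str:
    """Uniform draw of one institutional revenue code."""
    if not bundle.revenue_codes:
        raise BundleIntegrityError("revenue code table is empty")
    return rng.choice(list(bundle.revenue_codes))


def sample_diagnosis_set(bundle: ReferenceBundle, rng: random.Random, k: int) -> list[CodeEntry]:
    """Draw ``k`` distinct diagnosis codes; the first is the principal diagnosis.

    ``k`` is capped at 12, the institutional-claim diagnosis limit.
    """
    if not 1 <= k <= 12:
        raise ConfigError(f"diagnosis count must be in [1, 12], got {k}")
    pool = list(bundle.diagnoses)
    if k > len(pool):
        raise BundleIntegrityError(
            f"requested {k} distinct diagnoses but bundle holds only {len(pool)}"
        )
    return rng.sample(pool, k)
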