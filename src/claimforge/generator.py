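"""Seed-deterministic generation of random institutional claims.

Every transactional attribute — subscriber identity, member and claim IDs,
service dates, charges — is synthesized de novo from one seeded random stream;
only nonidentifiable reference data (codes, provider directory, payer catalog)
is sampled from the bundle, so generated files contain no protected health
information by construction.

Defaults: line charges are drawn log-uniformly in [10, 5000] dollars and
rounded to whole dollars; quantity is 1; all lines of a claim share one
service date (per-line dates are a config toggle); line 1 always points at
the principal diagnosis.
"""

from __future__ import annotations

import datetime as dt
import math
import random
from decimal import Decimal

from .claim_model import (
    DiagnosisEntry,
    EnvelopeMeta,
    GeneratorConfig,
    InstitutionalClaim,
    ServiceLine,
    Subscriber,
)
from .exceptions import ConfigError
from .reference_data import (
    ReferenceBundle,
    load_name_lists,
    sample_diagnosis_set,
    sample_payer,
    sample_procedure,
    sample_provider,
    sample_revenue_code,
)

CHARGE_RANGE_DOLLARS = (10, 5000)


def assign_diagnosis_pointers(
    rng: random.Random, n_dx: int, max_per_line: int = 4, *, force_principal: bool = False
) -> tuple[int, ...]:
    """Draw a sorted set of 1–``max_per_line`` distinct pointers in [1, n_dx].

    ``force_principal`` guarantees pointer 1 (the principal diagnosis) is
    among them, used for the first service line of each claim.
    """
    if not 1 <= n_dx <= 12:
        raise ConfigError(f"diagnosis count must be in [1, 12], got {n_dx}")
    if not 1 <= max_per_line <= 4:
        raise ConfigError(f"max pointers per line must be in [1, 4], got {max_per_line}")
    k = rng.randint(1, min(max_per_line, n_dx))
    if force_principal:
        rest = rng.sample(range(2, n_dx + 1), k - 1)
        chosen = [1, *rest]
    else:
        chosen = rng.sample(range(1, n_dx + 1), k)
    return tuple(sorted(chosen))


def _random_digits(rng: random.Random, n: int) -> str:
    """n-digit string with a nonzero leading digit."""
    return str(rng.randrange(10 ** (n - 1), 10**n))


def _random_date(rng: random.Random, lo: dt.date, hi: dt.date) -> dt.date:
    return dt.date.fromordinal(rng.randint(lo.toordinal(), hi.toordinal()))


def _random_charge(rng: random.Random) -> Decimal:
    lo, hi = CHARGE_RANGE_DOLLARS
    dollars = round(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    return Decimal(dollars)


def _random_subscriber(
    rng: random.Random, bundle: ReferenceBundle, member_id_digits: int
) -> Subscriber:
    first_names, last_names = load_name_lists()
    gender = rng.choices(["M", "F", "U"], weights=[49, 49, 2])[0]
    return Subscriber(
        first_name=rng.choice(first_names),
        last_name=rng.choice(last_names),
        member_id=_random_digits(rng, member_id_digits),
        payer=sample_payer(bundle, rng),
        birth_date=_random_date(rng, dt.date(1930, 1, 1), dt.date(2005, 12, 31)),
        gender=gender,
    )


def generate_claim(
    config: GeneratorConfig,
    bundle: ReferenceBundle,
    rng: random.Random,
    *,
    transaction_control_number: str | None = None,
) -> InstitutionalClaim:
    """Generate one claim under ``config``, drawing from ``rng`` only."""
    config.validate()

    n_dx = rng.randint(config.dx_min, config.dx_max)
    n_lines = rng.randint(config.line_min, config.line_max)

    diagnosis_codes = sample_diagnosis_set(bundle, rng, n_dx)
    diagnoses = tuple(
        DiagnosisEntry(
            qualifier="ABK" if i == 0 else "ABF",
            code=entry.code,
            poa=rng.choices(["Y", "N", "U", "W", "1"], weights=[70, 15, 8, 2, 5])[0],
            ordinal=i + 1,
        )
        for i, entry in enumerate(diagnosis_codes)
    )

    y0, y1 = config.service_year_range
    claim_date = _random_date(rng, dt.date(y0, 1, 1), dt.date(y1, 12, 31))

    lines = []
    for i in range(n_lines):
        pointers = assign_diagnosis_pointers(
            rng, n_dx, config.max_pointers_per_line, force_principal=(i == 0)
        )
        date = (
            _random_date(rng, dt.date(y0, 1, 1), dt.date(y1, 12, 31))
            if config.per_line_service_dates
            else claim_date
        )
        lines.append(
            ServiceLine(
                line_number=i + 1,
                procedure_code=sample_procedure(bundle, rng).code,
                charge=_random_charge(rng),
                quantity=1,
                diagnosis_pointers=pointers,
                service_date=date,
                revenue_code=sample_revenue_code(bundle, rng),
            )
        )
    lines = tuple(lines)

    tcn = transaction_control_number or _random_digits(rng, 5)
    return InstitutionalClaim(
        claim_id=_random_digits(rng, config.claim_id_digits),
        transaction_control_number=tcn,
        provider=sample_provider(bundle, rng),
        subscriber=_random_subscriber(rng, bundle, config.member_id_digits),
        diagnoses=diagnoses,
        service_lines=lines,
        total_charge=sum((l.charge for l in lines), Decimal(0)),
        facility_type_code=config.facility_type_code,
        claim_frequency_code=config.claim_frequency_code,
    )


def generate_batch(config: GeneratorConfig, bundle: ReferenceBundle) -> list[InstitutionalClaim]:
    """Generate ``config.n_claims`` claims, reproducible from ``config.seed``.

    Claim IDs are unique within the batch; transaction control numbers are a
    consecutive block starting at a seeded base so every ST02 in one
    functional group is distinct.
    """
    config.validate()
    rng = random.Random(config.seed)
    tcn_base = rng.randrange(10_000, 100_000_000)
    claims: list[InstitutionalClaim] = []
    seen_ids: set[str] = set()
    for i in range(config.n_claims):
        claim = generate_claim(
            config, bundle, rng, transaction_control_number=str(tcn_base + i)
        )
        while claim.claim_id in seen_ids:  # rare collision: redraw the ID only
            claim = InstitutionalClaim(
                claim_id=_random_digits(rng, config.claim_id_digits),
                transaction_control_number=claim.transaction_control_number,
                provider=claim.provider,
                subscriber=claim.subscriber,
                diagnoses=claim.diagnoses,
                service_lines=claim.service_lines,
                total_charge=claim.total_charge,
                facility_type_code=claim.facility_type_code,
                claim_frequency_code=claim.claim_frequency_code,
            )
        seen_ids.add(claim.claim_id)
        claims.append(claim)
    return claims


def generate_envelope(config: GeneratorConfig) -> EnvelopeMeta:
    """Seeded envelope metadata to pair with :func:`generate_batch` output.

    Uses an independent stream (seed offset) so envelope fields do not perturb
    claim content.
    """
    rng = random.Random((config.seed << 1) ^ 0x5A17)
    y0, y1 = config.service_year_range
    date = _random_date(rng, dt.date(y0, 1, 1), dt.date(y1, 12, 31))
    return EnvelopeMeta(
        sender_id="CLAIMFORGE",
        receiver_id="RECEIVER",
        interchange_control_number=f"{rng.randrange(1, 10**9):09d}",
        group_control_number=rng.randrange(1, 10**6),
        interchange_date=date,
        interchange_time=dt.time(rng.randrange(0, 24), rng.randrange(0, 60)),
        usage_indicator="T",
    )
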