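"""Reference bundle loading, NPI check-digit logic, and seeded sampling."""

import csv
import random
import re
from dataclasses import replace
from pathlib import Path

import pytest

from claimforge import (
    BundleIntegrityError,
    BundleLoadError,
    ConfigError,
    load_reference_bundle,
    npi_is_valid,
    sample_diagnosis_set,
    sample_provider,
)
from claimforge.reference_data import BUNDLE_SCHEMA, HCPCS_RE, ICD10CM_RE


def luhn_oracle(number: str) -> bool:
    """Textbook Luhn mod-10 validity check, independent of the package's code."""
    total = 0
    for i, ch in enumerate(reversed(number)):
        d = int(ch)
        if i % 2 == 1:
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return total % 10 == 0


def brute_force_npi_check_digit(base9: str) -> str:
    """Try all ten candidate check digits against the Luhn oracle."""
    hits = [d for d in "0123456789" if luhn_oracle("80840" + base9 + d)]
    assert len(hits) == 1
    return hits[0]


class TestNpiValidity:
    @pytest.mark.parametrize(
        "npi,expected",
        [
            ("1548083421", True),   # reference-claim billing provider
            ("1548083420", False),  # same base, perturbed check digit
            ("0000000006", True),   # all-zero base has check digit 6
        ],
    )
    def test_known_values_match_brute_force_oracle(self, npi, expected):
        assert npi_is_valid(npi) is expected
        assert (brute_force_npi_check_digit(npi[:9]) == npi[9]) is expected

    @pytest.mark.parametrize("bad", ["12345", "12345678901", "154808342X", ""])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(ValueError):
            npi_is_valid(bad)

    def test_agrees_with_oracle_over_random_bases(self):
        rng = random.Random(99)
        for _ in range(200):
            base = f"{rng.randrange(10**9):09d}"
            check = brute_force_npi_check_digit(base)
            assert npi_is_valid(base + check)
            assert not npi_is_valid(base + str((int(check) + 1) % 10))


class TestBundleLoading:
    def test_packaged_bundle_meets_size_contract(self, bundle):
        assert len(bundle.diagnoses) >= 50
        assert len(bundle.procedures) >= 20
        assert len(bundle.providers) >= 20
        assert len(bundle.payers) >= 5
        assert bundle.revenue_codes

    def test_code_shapes_and_uniqueness(self, bundle):
        dx_codes = [e.code for e in bundle.diagnoses]
        px_codes = [e.code for e in bundle.procedures]
        assert all(ICD10CM_RE.match(c) and "." not in c for c in dx_codes)
        assert all(HCPCS_RE.match(c) for c in px_codes)
        assert len(set(dx_codes)) == len(dx_codes)
        assert len(set(px_codes)) == len(px_codes)
        assert all(re.fullmatch(r"\d{4}", c) for c in bundle.revenue_codes)

    def test_every_packaged_npi_is_luhn_valid(self, bundle):
        npis = [p.npi for p in bundle.providers]
        assert len(set(npis)) == len(npis)
        assert all(npi_is_valid(n) for n in npis)
        assert all(luhn_oracle("80840" + n) for n in npis)

    def test_schema_carries_no_person_level_fields(self):
        forbidden = {"member_id", "patient_name", "first_name", "last_name",
                     "ssn", "dob", "birth_date", "subscriber_id"}
        for table, columns in BUNDLE_SCHEMA.items():
            assert not forbidden & set(columns), table

    def test_missing_table_names_it(self, tmp_path):
        with pytest.raises(BundleLoadError, match="diagnoses"):
            load_reference_bundle(tmp_path)

    def _write_minimal_tables(self, d: Path, providers_rows):
        tables = {
            "diagnoses.csv": [["code", "description"], ["I10", "Hypertension"]],
            "procedures.csv": [["code", "description"], ["99213", "Office visit"]],
            "payers.csv": [["hios_id", "product_name", "payer_type"],
                           ["12345", "Plan A", "COMMERCIAL"]],
            "revenue_codes.csv": [["code"], ["0450"]],
            "providers.csv": providers_rows,
        }
        for name, rows in tables.items():
            with open(d / name, "w", newline="") as fh:
                csv.writer(fh).writerows(rows)

    def test_duplicate_npi_is_an_integrity_error(self, tmp_path):
        row = ["1548083421", "ORG A", "282N00000X", "1 MAIN ST", "GLENDALE", "CA", "91203"]
        self._write_minimal_tables(
            tmp_path,
            [["npi", "org_name", "taxonomy", "street", "city", "state", "zip"], row, row],
        )
        with pytest.raises(BundleIntegrityError, match="duplicate NPI"):
            load_reference_bundle(tmp_path)

    def test_luhn_invalid_npi_is_an_integrity_error(self, tmp_path):
        self._write_minimal_tables(
            tmp_path,
            [["npi", "org_name", "taxonomy", "street", "city", "state", "zip"],
             ["1548083420", "ORG A", "282N00000X", "1 MAIN ST", "GLENDALE", "CA", "91203"]],
        )
        with pytest.raises(BundleIntegrityError, match="Luhn"):
            load_reference_bundle(tmp_path)

    def test_user_supplied_directory_round_trips(self, tmp_path):
        self._write_minimal_tables(
            tmp_path,
            [["npi", "org_name", "taxonomy", "street", "city", "state", "zip"],
             ["1548083421", "ORG A", "282N00000X", "1 MAIN ST", "GLENDALE", "CA", "91203"]],
        )
        b = load_reference_bundle(tmp_path)
        assert [p.npi for p in b.providers] == ["1548083421"]


class TestSampling:
    def test_identical_seeds_give_identical_draws(self, bundle):
        a = sample_provider(bundle, random.Random(7))
        b = sample_provider(bundle, random.Random(7))
        assert a == b

    def test_single_provider_bundle_returns_it(self, bundle):
        small = replace(bundle, providers=bundle.providers[:1])
        assert sample_provider(small, random.Random(0)) == bundle.providers[0]

    def test_coupon_collector_coverage(self, bundle):
        # 1,000 uniform draws from 20 providers miss one with prob < 20*(19/20)^1000 ~ 1e-21
        small = replace(bundle, providers=bundle.providers[:20])
        rng = random.Random(123)
        drawn = {sample_provider(small, rng).npi for _ in range(1000)}
        assert drawn == {p.npi for p in small.providers}

    @pytest.mark.parametrize("k", [1, 5, 12])
    def test_diagnosis_set_is_k_distinct_codes(self, bundle, k):
        codes = [e.code for e in sample_diagnosis_set(bundle, random.Random(1), k)]
        assert len(codes) == k == len(set(codes))

    def test_exhaustive_draw_from_exact_size_pool(self, bundle):
        small = replace(bundle, diagnoses=bundle.diagnoses[:12])
        codes = {e.code for e in sample_diagnosis_set(small, random.Random(3), 12)}
        assert codes == {e.code for e in small.diagnoses}

    @pytest.mark.parametrize("k", [0, 13, -1])
    def test_out_of_range_k_is_a_config_error(self, bundle, k):
        with pytest.raises(ConfigError):
            sample_diagnosis_set(bundle, random.Random(0), k)

    def test_k_beyond_pool_size_errors(self, bundle):
        small = replace(bundle, diagnoses=bundle.diagnoses[:3])
        with pytest.raises(BundleIntegrityError):
            sample_diagnosis_set(small, random.Random(0), 5)
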