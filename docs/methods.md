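# Methods

## Scope and model

claimforge models one artifact: the institutional health-care claim as carried
by the ASC X12 005010X223A2 (837i) transaction set. A claim is a billing
provider (organizational NPI, taxonomy, practice address), a subscriber
(synthetic identity plus a payer product), an ordered list of 1–12 diagnoses,
and 1–50 numbered service lines. Structure, not adjudication, is the point:
the package makes no claim about medical necessity, pricing, or payer rules,
and performs no clinical pairing of diagnosis and procedure codes — sampling
is uniform and independent, because any category-aware pairing scheme would be
a guess presented as realism.

Three invariant families define a well-formed claim and are enforced at every
boundary (generation, serialization, parsing, validation):

1. **Ordering** — diagnosis ordinals and line numbers are consecutive from 1;
   exactly one principal diagnosis (ordinal 1).
2. **Linkage** — every service line carries 1–4 distinct ascending diagnosis
   pointers, each referencing an existing diagnosis ordinal. This is the
   relational heart of the format: procedures are justified by diagnoses.
3. **Arithmetic** — the claim total equals the sum of line charges; after
   serialization, SE01 equals the ST..SE segment count, GE01 the transaction
   count, IEA01 the group count, and paired control numbers agree
   (ISA13/IEA02, GS06/GE02, ST02/SE02).

## Reference data and privacy

The packaged bundle holds five tables: 200 ICD-10-CM diagnosis codes, 52
HCPCS procedure codes, 50 provider organizations, 10 payer products, and 10
institutional revenue codes. It is a deliberately small curated stand-in for
the public full-size sources (CMS code releases, the NPPES provider registry,
the Healthcare.gov plan catalog); `load_reference_bundle(path)` accepts a
directory of user-supplied tables with the same columns for full-scale use.
Two properties are load-time invariants rather than conventions:

- every provider NPI must pass the Luhn check (check digit over
  `"80840" + first nine digits`) — the packaged NPIs are synthetic but valid,
  so the validity property is real and testable without shipping registry
  extracts;
- the table schemas are closed: an unexpected column is an integrity error,
  which is how the no-person-level-data contract is mechanically enforced.

Subscriber identities come from packaged first/last-name lists (98 and 100
entries) drawn through the seeded stream; no external name service is used.

## Generator defaults

All randomness flows through one `random.Random(seed)` stream per batch, so a
batch is reproducible down to serialized bytes. Defaults, chosen once and
documented rather than tuned:

| Parameter | Default | Rationale |
|---|---|---|
| diagnoses per claim | uniform on [dx_min, dx_max] ⊆ [1, 12] | the 837i HI segment pair carries at most 12 |
| lines per claim | uniform on [line_min, line_max] ⊆ [1, 50] | configurable-complexity bound |
| pointers per line | uniform 1–4, distinct, sorted | 4 is the per-line pointer maximum |
| line 1 pointers | always include 1 | the principal diagnosis justifies the first line |
| line charge | log-uniform on [$10, $5000], whole dollars | spans office visit to minor procedure; integer rendering matches the reference claim |
| quantity | 1 | unit-service lines; a field, not a distribution |
| service date | uniform within `service_year_range` (2018–2024); one date shared by all lines of a claim | institutional statements typically bill one date of service; per-line dates are a toggle |
| POA indicator | Y/N/U/W/1 at 70/15/8/2/5 % | Y dominates on admission-coded diagnoses |
| IDs | claim 10 digits, member 7 digits, nonzero leading digit | widths configurable |
| qualifiers | ABK for ordinal 1, ABF otherwise | principal vs other diagnosis convention |

What the generator does **not** emulate: real-world payer mix, charge
distributions calibrated to any fee schedule, clinically coherent
code co-occurrence, or data-entry errors. Passing tests therefore demonstrate
structural fidelity and pipeline correctness, not statistical realism of any
production claims feed.

## Serialization dialect

Fixed constants: 106-character fixed-width ISA; qualifiers `ZZ`; version
`00501`/`005010X223A2`; GS01 `HC`; ST01 `837`; BHT01 `0019`; dates CCYYMMDD
under DTP format D8. Default delimiters `*` `:` `^` `~`, with one segment per
line for classroom readability (`newline=False` emits a single stream);
delimiters are fully parametric and re-detected positionally on parse (offsets
3, 82, 104, 105 of the ISA).

Per-transaction segment order: ST, BHT, NM1\*41/NM1\*40, HL (billing,
level 20), NM1\*85, N3, N4, REF\*EI, HL (subscriber, level 22), SBR, NM1\*IL,
DMG, NM1\*PR, CLM, DTP\*434, HI (principal), HI (others, up to 11 composites),
then LX / SV2 / DTP\*472 per line, SE. Each HI composite is
`qualifier:code:::::::poa` — POA in the ninth component.

Two deliberate deviations, both load-bearing for the relational outputs:

1. **SV2 pointers.** The standard institutional SV2 has no diagnosis-pointer
   element, but per-line pointer links are exactly what the parsed
   service-lines table teaches. The serializer therefore writes the pointers
   as a composite (joined by the component separator) in SV2 element 7, and
   the parser reads the same position. Files remain parseable by tolerant
   X12 readers; the element is documented here rather than hidden.
2. **REF\*EI filler.** The billing-provider loop carries a REF segment whose
   value is the first nine digits of the NPI — structural filler standing in
   for an employer identification number the model deliberately does not
   carry (a real EIN would be fabricated PII-adjacent data with no
   educational value). The parser ignores it.

The parser is permissive on unknown segments (they are kept in the segment
stream, skipped for the tables) but strict on envelope arithmetic: any
control-number disagreement or SE01/GE01/IEA01 miscount raises a parse error
with the offending 1-based segment index. The rationale is asymmetric risk:
hand-edited classroom files legitimately contain extra segments, but broken
envelope arithmetic means the file's structure cannot be trusted.

## Validator

`validate_structure` never raises and never stops early: it tokenizes the
whole file and returns every finding, sorted by segment index, so a student's
report lists all defects at once. The catalog (`claimforge.validator.RULES`)
has five families — DEL (delimiter hygiene), ENV (envelope pairing and
arithmetic), SEQ (loop-phase ordering ST < BHT < 1000A/B < 2000A < 2000B <
2300 < 2400 < SE, plus consecutive LX numbering), LOOP (required segments per
loop), PTR (pointer range soundness). Pointer faults are classified ERROR,
not WARNING, because pointer linkage is core claim logic rather than styling.
Unknown segment tags are WARNINGs. Two findings are file-level (index 0): a
missing/short ISA and a delimiter collision, both of which make further
tokenization meaningless, so validation stops after reporting them.

Sequencing uses a monotone phase rank per segment; segments whose loop is
ambiguous from the tag alone (DTP) inherit the current phase. A transaction
missing its SE is both an ENV-006 finding and still validated for its inner
structure.

## Numerical and encoding choices

- Charges are `decimal.Decimal` end to end (2 dp max), rendered without a
  fractional part when integral (`76`, not `76.00`), so amounts survive round
  trips exactly and match the integer rendering of the reference tables.
- CSV outputs are UTF-8 with a header row and RFC-4180 quoting; the
  diagnosis-pointer cell is always quoted (`"[1]"`) for a stable, readable
  rendering even without embedded commas.
- Batch claim IDs are redrawn on collision (uniqueness within a batch);
  transaction control numbers are a consecutive block from a seeded base so
  every ST02 in a functional group is distinct.
- The worked-example fixture stores qualifier ABK on all six of its diagnosis
  rows, exactly as its reference tables print them, while generated claims
  follow the ABK/ABF convention; the codec carries whatever qualifier an
  entry holds, and the parser reproduces the file verbatim — the fixture and
  the convention are both first-class, deliberately distinct cases.

## Problem sizes used in the checks

The self-verification pipeline (`scripts/acceptance.py` and the test suite)
uses 1,000 generated claims for the zero-structural-error sweep (four
configurations covering the full 1–12 × 1–50 complexity envelope), 500 claims
for round-trip exactness and SE01 oracle agreement, ten documented
single-defect mutations for validator sensitivity, and byte-identity of a
repeated 500-claim batch for determinism. These sizes exercise every loop
shape the format admits while keeping the whole pipeline around a second of
runtime; the library itself has no batch-size ceiling.

## Known limitations

- 837p (professional), 835 (remittance), error-injection modes, and
  longitudinal patient journeys are out of scope.
- Validation is structural (SNIP-1-like plus pointer linkage); code-set
  membership against a specific annual ICD-10-CM/HCPCS release, payer
  companion guides, and semantic edits are not checked.
- The SV2 pointer composite is a documented dialect extension; third-party
  strict validators may flag that element even though the file's envelope and
  loop structure conform.
- Equivalence with any commercial EDI validator's proprietary rule inventory
  is not claimed.
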