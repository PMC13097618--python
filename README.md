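# claimforge

Synthetic **X12 5010 837i** institutional health-care claims for education and
analytics training: a seed-deterministic claim **generator**, an EDI→relational
**parser**, and a structural **validator**, as one library with a thin CLI.

Privacy regulations keep real claim files out of classrooms, so students of
health information management rarely touch the raw X12 format that carries
institutional billing — the nested ISA/GS/ST envelopes, the
2000A (billing provider) / 2000B (subscriber) / 2300 (claim) / 2400 (service
line) loop hierarchy, and the diagnosis pointers that tie each billed
procedure back to the diagnoses justifying it. claimforge produces
structurally authentic 837i files containing **zero protected health
information**: only nonidentifiable reference data (ICD-10-CM and HCPCS code
sets, an organizational provider directory with Luhn-valid NPIs, a payer
product catalog) is sampled, while every patient-level attribute — names,
member IDs, claim numbers, dates, charges — is synthesized de novo from a
single seeded random stream.

The three capabilities:

- **generate** — random claims with configurable complexity: 1–12 ordered
  diagnoses (the first is the principal, qualifier `ABK`; POA indicators on
  each) and 1–50 service lines, each linking 1–4 diagnosis pointers. Same
  seed, same bytes.
- **parse** — any 837i text file into three analytics-ready CSV tables joined
  by claim ID: `header.csv` (transaction metadata + provider + subscriber),
  `diagnoses.csv` (one row per diagnosis), `service_lines.csv` (one row per
  line, pointers rendered `"[2, 4, 6]"`).
- **validate** — a collect-all structural validator with a documented rule
  catalog (`DEL`/`ENV`/`SEQ`/`LOOP`/`PTR` families): envelope control-number
  arithmetic, SE01 segment counts, loop sequencing, LX numbering, required
  segments per loop, and pointer soundness. Generator output always validates
  with zero errors.

The NPI check is the standard one: the 10th digit of an NPI is the Luhn mod-10
check digit of `80840` + the first nine digits.

## Worked example

```bash
$ claimforge generate --count 2 --dx-range 2-4 --line-range 1-3 --seed 42 --out claims.txt
generated 2 claim(s) | seed=42 dx=[2,4] lines=[1,3] profile=batch
  wrote claims.txt

$ claimforge parse claims.txt --outdir tables
parsed 2 claim(s): 2 header, 4 diagnosis, 3 service-line row(s)
  wrote tables/header.csv
  wrote tables/diagnoses.csv
  wrote tables/service_lines.csv

$ claimforge validate claims.txt
0 error(s), 0 warning(s)

$ head -3 tables/diagnoses.csv
claim_id,diagnosis_type,diagnosis_code,pointer
1402418010,ABK,S81801S,1
1402418010,ABF,K219,2

$ head -3 tables/service_lines.csv
claim_id,line_number,procedure_code,charge,unit,qty,diagnosis_pointers,service_date
1402418010,1,HC:88305,138,UN,1,"[1]",20190224
7887950851,1,HC:47562,26,UN,1,"[1, 2]",20191016
```

Reading the output: claim `1402418010` carries principal diagnosis `S81801S`
(`ABK`) and secondary `K219` (`ABF`); its single service line bills surgical
pathology `HC:88305` for $138 on 2019-02-24, justified by diagnosis 1. The
second claim's line points at both of its diagnoses (`[1, 2]`). The `pointer`
column in `diagnoses.csv` is the diagnosis ordinal the service-line pointers
refer to — join the two tables on `claim_id` to check that every procedure is
linked to existing diagnoses.

The same pipeline is available as a library:

```python
from claimforge import (GeneratorConfig, generate_batch, load_reference_bundle,
                        serialize_interchange, parse_interchange, validate_structure)

bundle = load_reference_bundle()            # or load_reference_bundle("my_tables/")
cfg = GeneratorConfig(n_claims=100, dx_min=1, dx_max=12, seed=7)
text = serialize_interchange(generate_batch(cfg, bundle))
assert validate_structure(text).error_count == 0
tables = parse_interchange(text)            # .header_rows / .diagnosis_rows / ...
```

`claimforge.worked_example_claim()` returns the fixed reference claim
(claim 4742333269, NPI 1548083421, subscriber Jonathan Mendez) used throughout
the test suite; serializing and re-parsing it reproduces its header, diagnosis
and service-line tables cell for cell.

The CLI's `--profile web` preset caps a single invocation at 25 claims,
mirroring a per-session limit appropriate for hosted classroom use;
`--profile batch` (the default) has no cap.

## Notes on the dialect

The serialized segment inventory and two documented deviations from the bare
implementation guide (per-line diagnosis pointers carried in SV2 element 7;
a synthetic REF*EI filler identifier) are described in
[docs/methods.md](docs/methods.md), together with the generator's statistical
defaults and the validator's complete rule catalog.
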