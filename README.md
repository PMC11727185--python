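# vetregqa

Quality assessment of fish-vaccine data in a national veterinary
prescription register, for veterinary epidemiologists and register
custodians who need to know whether dispensing records are fit for
monitoring vaccine usage in salmonid aquaculture.

Pharmacies report fish-vaccine dispensings in a mix of quantity units —
doses ("stk"), millilitres, and occasionally grams or kilograms — and the
records carry an animal count that, for injectable vaccines given as one
dose per fish, should equal the number of doses. `vetregqa` implements the
three-attribute quality framework for such a register:

- **Validity.** A unit-harmonization cascade brings every record to a
  canonical volume: routine dose→ml conversion via the product's per-dose
  volume (`n_doses = volume_ml / dose_ml`), reinterpretation of g/kg
  records as ml/L when the implied dose count matches the animal count
  exactly, exclusion of bath-vaccine records reported in doses (immersion
  products have no fixed per-fish dose), and detection of ml↔dose label
  swaps via exact animal-count matches. Record-level checks flag animal
  count consistency, species, owner location against a hatchery register,
  and product authorization years. The association between multi-vaccine
  prescriptions and inconsistent animal counts is estimated as an odds
  ratio OR = ad/bc with a Woolf 95% CI,
  exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), and a Fisher exact p.
- **Completeness.** Coverage = 100 × use / sales in ml against wholesaler
  statistics (sales volume = pack size × packs sold), per product ID and
  per vaccine name, yearly and pooled — name-level and total-period
  coverage are pooled ratios, never means of ratios.
- **Timeliness.** Reporting delay (registration − delivery, whole days),
  summarized by inverse-ECDF quantiles (the smallest observed day count d
  with ECDF(d) ≥ q) per year, per pharmacy, and jointly.

Because real register extracts are access-restricted, the package ships a
product-metadata registry (23 national product IDs, 18 vaccine names) and
a seeded synthetic-data generator that plants every defect class with
exact bookkeeping, including a replication profile that encodes the
published 2016–2022 cleansing census.

## Worked example

```sh
vetregqa simulate --profile table3 --seed 20160101 --out data/
vetregqa run --records data/records.csv --sales data/sales.csv --out out/ --seed 20160101
```

The run prints the quality summary; the cleansing ledger is the census of
the harmonization cascade (abridged):

```
 year  total  practitioner_removed  bath_dose_excluded  uncorrectable_excluded  corrected_g_to_ml  corrected_kg_to_l  corrected_ml_to_stk  corrected_stk_to_ml_swap  converted_stk_to_ml  final
 2016    715                     3                   7                       0                  0                  0                    5                         0                  327    705
 2017    939                     0                  79                       0                  0                  0                    9                         0                  398    860
 ...
total   7443                    12                 684                       3                  2                  3                   32                         3                 3129   6744
```

Reading the total row: of 7,443 in-scope records, 12 practitioner-use
notifications were removed as duplicates of pharmacy dispensings; 684
bath-vaccine records in doses and 3 uncorrectable mass-unit records were
excluded; 5 mass-unit records and 35 label swaps were corrected; 3,129
dose-unit records were routinely converted to ml; 6,744 records (22
product IDs) entered the completeness comparison. Because the profile
emits sales equal to true use, every defined coverage cell prints 100.00;
the validity section reports the planted 31.0% animal-count inconsistency
share and a multi-vaccine odds ratio above 1, and the timeliness table
shows the two dominant pharmacies' delay quantiles (medians ~10 and ~3
days). `vetregqa check --out out/` re-verifies that the written ledger
reconciles (input = survivors + exclusions, per year and in total).

## Layout

- `src/vetregqa/model.py` — domain types, packaged product/location registries
- `src/vetregqa/ingest.py` — readers/writers, scope filter, duplicate removal
- `src/vetregqa/validity.py` — harmonization cascade, flags, odds ratio
- `src/vetregqa/completeness.py` — sales expansion and coverage tables
- `src/vetregqa/timeliness.py` — delays, quantiles, ECDF curves
- `src/vetregqa/synthetic.py` — planted-defect generator and profiles
- `src/vetregqa/pipeline.py`, `cli.py` — orchestration, outputs, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
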