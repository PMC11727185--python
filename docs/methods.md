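# Methods

## Setting and data model

Norwegian farmed salmonids (Atlantic salmon, rainbow trout) are vaccinated
as juveniles at hatcheries; pharmacies report each dispensing of a fish
vaccine to a national prescription register, and wholesalers report yearly
sales of the same products to a public-health institute. The two streams
are joinable through the six-character national product ID and the ATC
code (QI10A/QI10B for salmonid vaccines). Product IDs are handled as
zero-padded strings throughout: integer coercion silently destroys leading
zeros and breaks the join.

A dispensing record carries a report ID (one prescription may span several
rows), registration and delivery dates, product identifiers, a quantity
with a unit, the species, the number of animals, an owner location, and
the reporting pharmacy. The record's year is defined by the delivery date.
The fish-weight column is carried but never used: the register does not
state its unit, so a single "weight present but unitless" count is the
only thing derived from it.

## Validity: the harmonization cascade

Injectable vaccines are administered as exactly one dose per fish, and the
per-dose volume (0.025–0.1 ml) is fixed per product by its Summary of
Product Characteristics; this is what makes the animal count usable as an
internal reference. The cascade, in fixed order after practitioner-
notification removal:

1. **Mass-unit inference (g/kg).** Mass units are invalid for a liquid
   vaccine; the plausible explanations are a volume mislabel (g↔ml,
   kg↔L) or a dose-count mislabel. The volume assumption is tested
   first: if assumed-volume / dose volume equals the number of animals
   exactly, the unit is corrected (`g_to_ml` / `kg_to_l`). Otherwise the
   dose-count assumption is tested (`mass_to_stk`). Records matching
   neither, or without an animal count, are excluded as uncorrectable.
   For bath products the animal cross-check is undefined, so the volume
   assumption is accepted only when the assumed volume is an exact
   positive integer multiple of the pack size — the only internal
   evidence available; this branch is separately flagged and can be
   disabled (`bath_pack_multiple_inference`).
2. **Bath-dose exclusion.** The number of fish treated per volume of an
   immersion vaccine varies, so dose counts cannot be converted to ml;
   bath records in "stk" are excluded (`bath_dose_unit`).
3. **Routine dose→ml conversion.** Injectable records in "stk" convert as
   volume = quantity × dose volume (`stk_to_ml`).
4. **Swap detection.** For injectable records with an animal count: a
   record in ml whose quantity *read as doses* equals the animal count,
   while the volume reading does not, was doses miscoded as ml
   (`ml_to_stk`); symmetrically for stk records whose quantity/dose
   volume matches (`stk_to_ml_swap`). Swap corrections are kept distinct
   from the routine conversion in the ledger because they represent
   manual-edit classes, not unit algebra.
5. **Consistency flagging.** A record is consistent iff its dose count
   equals the animal count exactly; records without an animal count, bath
   records, and excluded records are `not_evaluable` — absence of
   evidence is never counted as inconsistency.

A record receives at most one correction; corrections and exclusions are
mutually exclusive; and kept + corrected + excluded equals the input count
for every batch — the ledger reconciliation the `check` command re-verifies.

**Exactness.** "Exact match" means integer equality after rounding the
computed count to the nearest integer with absolute tolerance 1e-6. The
tolerance only absorbs binary floating-point noise from dose volumes like
0.05 ml; it is far below one animal, so it can never turn a genuine
mismatch into a match.

Other record-level checks: species against a configurable target set
(default the three salmonids), with non-target species at ≥ 100,000
animals flagged as probable entry errors rather than off-label use (a
dispensing of half a million doses against ornamental fish is a coding
slip); owner location against a five-digit hatchery site list; delivery
year against the product's authorization interval (outside is a flag, not
an exclusion — special-license imports are legal).

**Multi-vaccine odds ratio.** Exposure is a report ID shared by ≥ 2
distinct products; outcome is the inconsistency flag; non-evaluable
records stay out of the 2×2 table. OR = ad/bc with a Haldane–Anscombe 0.5
added to all cells when any cell is zero; 95% CI by Woolf's log-normal
interval; two-sided p by Fisher's exact test (chi-square switchable).
These method choices are configuration, not claims: the CI/p methods for
this statistic are not standardized in the source setting.

## Completeness

Coverage = 100 × use / sales in ml. Sales volume is pack size × packs
sold, summed per product and year; register use is the harmonized volume
of non-excluded records (bath records that arrived in ml are included —
their volume is sound even though their dose count is not). Name-level
cells pool numerators and denominators across the vaccine's product IDs
before dividing, and the "total" row pools across years; a pooled ratio
always lies within the member coverages' range, a mean of ratios does not.
Degenerate cells carry a status instead of a number: `not_in_sales`
(use without sales), `not_in_use` (sales without use, coverage 0),
`absent`. Values are kept at full precision; rounding to two decimals is
presentation-only. The register side is attributed by delivery year and
the sales side by reported sales year; the known one-year billing lag
between the streams is surfaced, not adjusted.

## Timeliness

Delay = registration − delivery in whole days. Negative delays are data
errors and are diverted to an invalid list (counted in the validity
summary, excluded from quantiles). Quantiles are inverse-ECDF with no
interpolation — the smallest observed d with ECDF(d) ≥ q — so "75% of
records within 25 days" always names an observed day count. Summaries are
stratified by year, by pharmacy, and jointly, because reporting delay is
overwhelmingly a property of the reporter.

## The synthetic generator

The generator draws clean records first — consistent dispensings where the
dose count equals the animal count exactly, with plausible product mixes
per year, target species, valid hatchery locations, and per-pharmacy
geometric reporting delays — then plants each defect class by transforming
clean records. Ground truth is the pre-corruption state, so each defect is
detectable by exactly its intended rule and the per-class totals are exact
counts, not expectations. One root seed is split into independent
substreams (records, defects, dates/delays, sales) so adding a defect
class does not perturb unrelated draws; output files are byte-stable per
seed.

Defaults that matter:

- Clean animal counts are uniform on 2,000–90,000 fish per record — large
  enough to be hatchery-scale, below the 100,000 entry-error threshold so
  species plants land where intended.
- Two dominant pharmacies carry ~53% and ~46% of records with geometric
  delay medians ~10 and ~3 days (p = 0.065 and 0.20); two minor reporters
  carry the remainder. This echoes the observed two-pharmacy asymmetry of
  the real register without claiming its values.
- A quarter of clean records are paired into two-product prescriptions,
  and planted inconsistency is weighted ~2.2:1 onto paired records, so the
  multi-vaccine odds ratio has signal without a pinned value.
- Sales policies: `equal_to_use` emits sales exactly equal to true use
  (every defined coverage cell is 100% by construction), `scaled(f)` emits
  f × use (coverage 100/f %), `independent` draws Poisson pack counts at
  the registry pack size. The first two use a single sales row whose pack
  size equals the (scaled) use so the identity is exact with integer pack
  counts. A decoy sales row for a miscoded foreign-ATC product exercises
  the wholesale exclusion list.

**Replication profile.** `table3_profile()` encodes the published
2016–2022 cleansing census of the register as per-year planted counts:
yearly totals 715/939/1,060/1,010/1,172/1,283/1,264 (7,443 in scope);
practitioner notifications 3/0/1/2/0/2/4 (12); bath-dose exclusions
7/79/144/257/114/33/50 (684); uncorrectable mass units 0/0/0/0/0/1/2 (3);
g→ml corrections in 2019 and 2022 (2); kg→L corrections in 2019 (3);
ml→stk swaps 5/9/3/10/0/3/2 (32); stk→ml swaps in 2019–2021 (3); 6,744
survivors over 22 product IDs (17 vaccine names, the kept bath product
reported in ml from 2020). The 3,129 routine dose→ml conversions are
allocated across years by largest remainder in proportion to clean-record
counts, and the 31% animal-count inconsistency is planted per year on the
same basis. The per-year split of the census columns is fully determined
by row conservation (total = practitioner + bath + uncorrectable + final)
together with the published percentages and aggregate counts. Twenty
out-of-scope records (10 foreign-ATC, 10 delivered the year before the
window) exercise the scope filter without entering the census. All of
these counts are design constants of the profile — the seed varies record
content, dates, delays and pairings, never the census.

What the generator does **not** emulate: the real joint distribution of
products × pharmacies × years beyond the per-year availability table, true
coverage levels (sales are tied to use by policy, so real over-/under-
reporting patterns are out of reach by design), seasonal vaccination
peaks, autogenous vaccines (absent from the register by construction),
and free-text species/name noise beyond the alias table. Passing the
planted-recovery suites therefore demonstrates that the cleansing rules
detect exactly what they claim to detect — not that real extracts contain
defects at these rates.

## Problem sizes

The replication fixture is 7,463 records; the planted-recovery suite runs
twenty 5,000-record configurations; the odds-ratio null simulation uses
500 multinomial replicates of n = 20,000; the timeliness oracle checks
1,000 random delay vectors. These sizes make every check exact or tightly
concentrated while keeping the full suite around a minute on one core.

## Known limitations

- The mass-unit inference needs an animal count; g/kg records without one
  are always excluded, even if a human could have resolved them.
- Swap detection cannot fire when an entry error corrupts both the unit
  and the animal count; such records surface as inconsistent instead.
- The bath pack-multiple rule can mistake a genuine mass that happens to
  be an exact pack multiple for a volume; it is flagged distinctly and
  can be disabled.
- Coverage interprets wholesaler data as the reference standard; cells
  above 100% may equally reflect incomplete sales reporting.
- The location check validates membership only; it cannot detect a valid
  but wrong site number.
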