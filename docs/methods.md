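# Methods

This note documents the semantics the package implements, the design
decisions taken where the underlying conventions are genuinely open, the
synthetic data it is validated against, and the known limitations.

## Typed parsing

A VCF header declares, per INFO/FORMAT key, a `Number` (0, 1, n, `A`, `R`,
`G`, or `.`) and a `Type` (`Integer`, `Float`, `Flag`, `String`,
`Character`).  `vcfstack` parses these into `FieldDef` objects and coerces
every body value accordingly: `Number` 0/1 fields become scalars, anything
else a list (one element per declared value, `.` → `None` elementwise);
flags become `True`; a missing scalar (`.`) becomes `None`.

Three robustness rules keep real-world files usable:

* **Undeclared keys** are auto-registered as `String` with `Number='.'`
  and logged once per key, rather than rejected — under-declared VCFs are
  ubiquitous and a mining tool must accept any structurally valid file.
* **Coercion failures** (e.g. text under a `Float` declaration) warn and
  keep the raw string; the record is never dropped.  Degraded values fail
  numeric comparisons rather than raising at query time.
* **Line endings**: LF and CRLF are both accepted; output is always LF.
  Gzip input is detected by magic bytes, so a gzipped file with a `.vcf`
  name parses identically to its uncompressed bytes.

Parse depth is selectable.  L0 retains the fixed columns plus typed INFO;
L1 adds the FORMAT key list; L2 adds typed per-sample values.  FILTER is
retained at every level, because the single most common first query on a
callset — keep PASS variants — runs on it; a depth level that cannot
answer it would be useless.  The L0 projection of an L2 parse equals the
L0 parse of the same file (tested), so deeper parses only add information.

Trailing FORMAT fields dropped from a sample column (allowed by the
format) are stored as explicit missing values, which makes the
write-then-reparse round trip an identity on typed content.  Round-trip
identity is field-for-field on typed values, not byte-for-byte: `QUAL 50`
and `QUAL 50.0` serialize identically because they are the same number.

## The filter stack

Filters are typed predicates constructed against the header, so operand
errors surface at build time, not during evaluation.  The operator set per
field follows its declared type:

| field type          | operators                                          |
|---------------------|----------------------------------------------------|
| Integer / Float     | `>` `<` `>=` `<=` `==` `!=` `is_missing` `not_missing` |
| Flag                | `present` `absent`                                 |
| String / Character  | `==` `!=` `in_set` `is_missing` `not_missing`      |
| FORMAT `GT`         | `is_hom_ref` `is_het` `is_hom_alt` `is_hemi` `is_missing` `has_alt` |

Evaluation rules, chosen for predictable survivor counts:

* **ANY over multi-valued fields** (`Number=A/R/.`): a record passes a
  numeric test if any element passes, which keeps multi-allelic records
  discoverable when one allele qualifies.  An `all_` operator prefix
  switches a single filter to ALL semantics.
* **Missing fails everything** except the explicit `is_missing`.  A
  "predicate or missing" workflow is expressible by comparing two stacks;
  OR composition inside one stack is deliberately out of scope — the
  stack is a conjunction.
* **FILTER** is matched per semicolon-separated member; `PASS` matches
  only the literal `PASS`.
* **GT is a genotype-class field**, not a string: `0/1`, `1/0`, and `1|0`
  all classify as `het`, so phased and unphased encodings filter
  identically.  `1/2`-style genotypes classify as `multi_alt_het`, which
  `has_alt` counts but `is_het` does not.
* **Format filters** evaluate per sample; every sample in the filter's
  scope must satisfy the predicate (AND within one filter), and an empty
  scope means all samples.  One filter scoped `{a, b}` therefore equals
  two stacked filters scoped `{a}` and `{b}` (tested as a law).
* **CHROM** comparisons are normalized: a leading `chr`/`Chr` is stripped
  and case folded for matching, while original spellings are preserved on
  output.

The stack itself is immutable: `push` computes the new survivor set from
the previous top, `pop` re-exposes the exact prior set.  Survivor sets are
strictly nested, and the final set of any stack equals the brute-force
conjunction of its filters evaluated independently per record — hence the
final set is invariant to filter order even though intermediate counts are
not.  These three laws (nesting, LIFO restoration, conjunction
equivalence) are enforced by randomized property tests against the
brute-force oracle.

Each filter has a canonical string form — `category:field op operand
[@sample1,sample2]`, e.g. `info:AF_1KG < 0.01` or `format:GT is_het
@FATHER,MOTHER` — used in CLI flags and written as provenance lines into
exported VCFs; parsing this form is the exact inverse of rendering
(property-tested over generated filters, including quoted operands).

## Store and indexes

The store is an in-memory ordered collection with dense 0-based record
ids; an engine-agnostic contract, not a database.  The default index set
is the composite `CHROM+POS`, `ID`, the composite `REF+ALT`, `QUAL`, and
`FILTER`; any fixed column or INFO key can be indexed on demand.  Indexes
are sorted value → ascending-id maps used for equality, flag presence, set
membership, and numeric range queries; every other operator falls back to
a scan, and indexed results are required (and property-tested) to equal
the scan results exactly.  Region queries are 1-based and inclusive on
both ends.  A store persists to a single versioned JSON file (gzip when
named `.gz`) so a CLI session loads once and filters many times.

## Annotation transfer and screening

Matching is exact on the normalized `(chrom, pos, ref, alt)` of each
alternate allele.  Normalization trims the longest shared ref/alt suffix,
then the shared prefix (advancing `pos` one base per trimmed prefix base),
keeping both alleles non-empty; it is idempotent (property-tested).  This
deliberately stops short of reference-genome left-alignment, which would
require a FASTA; representation differences that only left-alignment can
reconcile (e.g. indels in homopolymer runs placed at different anchors)
will not match — a documented limitation.  Position-only or rsID matching
is deliberately not offered: both silently conflate alleles, which is
unacceptable for whitelist/blacklist screening.

Keyed transfer copies only the user-selected INFO keys, namespaced
`sourcename_key` so in-house annotations are never clobbered, stored as
per-allele lists aligned with the target's ALT (`Number=A`).  Multi-allelic
source records are decomposed per allele with `Number=A` values
distributed positionally.  `Number=G` (genotype-shaped) fields are never
transferred: their values depend on the source file's samples.  Collisions
with an existing, differently-defined INFO key abort before any mutation.
List mode (whitelists/blacklists) stores a presence flag only; screening
is then an ordinary `present`/`absent` filter, and the two partition the
store.  BED intervals (0-based half-open) set flags by position: a record
at 1-based `pos` is inside `[start, end)` iff `start <= pos-1 < end`.

## Trio inheritance filters

Patterns are defined on genotype classes with missing genotypes excluded
by default (conservative screening; `include_missing=True` relaxes every
member check to "missing counts as compatible"):

* **recessive**: father het, mother het, child homozygous for the
  alternate allele, all three involving the *same* alternate allele index.
  The shared-allele requirement matters at multi-allelic sites: parents
  het for different alternate alleles is not a recessive transmission.
  "Child homozygous" is interpreted as hom-alt — a hom-ref child cannot
  carry a recessive condition.
* **de novo**: both parents hom-ref, child carries ≥1 alternate allele.
* **X-linked recessive**: normalized chromosome `X`, mother het, child
  hemizygous- or homozygous-alt, father carrying no alternate allele
  (hemi-ref or hom-ref).  The father criterion is the natural choice for a
  rare-disease screen and can be relaxed (`require_father_ref=False`).
* **compound heterozygous**: within each value of a string-typed gene
  field, pairs of child-het sites in trans configuration inferred from
  parental genotypes — one site with the father carrying an alt while the
  mother is hom-ref, one with the roles swapped.  Read-based phasing is
  not used (a VCF at L2 has only genotypes).

On fully called trios, recessive and de novo are provably disjoint
(parents cannot be het and hom-ref at once); this is asserted on the
synthetic data.  Every filter accepts a survivor-id subset, so the
diagnostic cascade — rarity, function class, then inheritance — composes
with the filter stack and its counts are non-increasing end to end.

## Synthetic data and what passing tests show

The generator (`FixtureSpec`/`generate`) builds a three-sample trio VCF
over chromosomes 1–22 and X with strictly increasing positions per
chromosome, typed INFO fields (three `Number=A` float allele-frequency
fields emulating population panels, a function-class string, a gene
symbol, a depth integer, a membership flag), per-sample GT/DP/GQ, ~3%
multi-allelic sites, ~1% missing genotypes and QUALs, and hemizygous
father/son calls on X.

Controlled quantities are exact by construction, not sampled: the PASS
count is exactly `round(n × pass_fraction)`; the whitelist shares exactly
`whitelist_overlap` normalized allele keys with the trio (half of them
written in a suffix-padded representation to exercise normalization);
planted inheritance patterns occupy exactly the requested records.
Background trio genotypes are drawn only from combinations that satisfy no
pattern, so each inheritance filter recovers exactly its planted set — an
exact assertion, not a statistical one.  Planted recessive sites are
forced below 0.01 on all three frequency fields and to a missense/nonsense
function class, making the cascade's final set equal the planted recessive
truth; background frequencies are uniform on [0, 0.5].

Defaults: 10,000 variants; 12 recessive, 5 de novo, 3 compound-het genes
(sample sizes chosen to represent a desk-scale exome screen while keeping
the full suite under a minute); `pass_fraction` 0.7; whitelist overlap 37;
seed 42.  One seeded generator drives everything and gzip timestamps are
pinned, so identical specs produce byte-identical files.

What the fixture does **not** emulate: linkage/haplotype structure,
realistic site-frequency spectra, sequencing-error or genotyping-error
models, structural variants, and pedigrees beyond a trio.  Passing tests
therefore demonstrate the correctness of the parsing, storage, filtering,
matching, and inheritance logic under well-formed inputs — not calibration
of any biological quantity against real cohorts.

## Numerical and formatting choices

Floats serialize via Python's shortest round-trip repr (integral floats as
integers), so parse → write → parse is value-exact.  Survivor output is
ordered by (normalized chromosome, position, ref, alt) with lexicographic
chromosome order — reproducible without a contig dictionary.  CSV export
uses RFC-4180-style quoting; TSV replaces embedded tabs with spaces under
a warning.  CLI exports are written to a temporary file and atomically
renamed, so no error path leaves a partial file.

## Known limitations

* No BCF, no tabix/bgzf virtual offsets; symbolic/breakend ALTs pass
  through as strings and are never normalized.
* Allele normalization without a reference genome cannot left-align
  repeat-region indels (see above).
* The filter stack is purely conjunctive; OR/NOT trees and two-field
  predicates are out of scope.
* Compound-het detection requires an observed trans configuration in the
  parents; it cannot call a pair when both parents carry both alleles.
* The store targets desk-scale files (exome-sized, a few million records
  at L0); it holds records in memory and has no concurrent-writer story.
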