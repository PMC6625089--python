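# vcfstack

Headless VCF mining for clinical and research variant analysis: typed,
metadata-driven VCF parsing at selectable depth, an indexed in-memory
variant store, a LIFO filter-stack query engine with sample-scoped genotype
filters, allele-keyed annotation transfer (including whitelist/blacklist
screening), trio inheritance-pattern filters, and VCF/CSV/TSV exporters.

## The problem

Variants called from next-generation sequencing land in VCF files: a header
of `##INFO`/`##FORMAT` metadata declaring, for every annotation, its
cardinality (`Number`) and value type (`Integer`, `Float`, `Flag`,
`String`), followed by one record per site with fixed columns (CHROM, POS,
ID, REF, ALT, QUAL, FILTER), free-form INFO annotations, and per-sample
FORMAT values such as the genotype GT.  Mining such a file — "keep PASS
variants rarer than 1% that are missense or nonsense, then keep those
compatible with recessive inheritance in this trio" — is a sequence of
typed predicates over heterogeneous fields, and getting it right means
getting the metadata semantics right: `Number=A` values are per alternate
allele, flags are presence/absence, `.` is missing, and `0/1` and `1|0`
are the same genotype.

`vcfstack` implements that workflow as a library plus a small CLI:

* **Parsing** is driven by the header metadata.  Values are coerced to
  their declared types; undeclared keys are auto-registered as free-text
  rather than rejected; a value that contradicts its type is kept as text
  with a warning, never silently dropped.  Parse depth is selectable —
  L0 (fixed columns + INFO), L1 (+ FORMAT keys), L2 (+ typed sample
  values) — and FILTER is retained at every depth.  Plain and gzip input
  are detected by magic bytes, not file extension.
* **Filters** come in three categories (basic columns, INFO, FORMAT), with
  the operator set derived from each field's declared type: relational
  operators for numerics, presence/absence for flags, equality and set
  membership for strings, genotype-class operators for GT.  Filters live on
  a last-in-first-out stack: each new filter applies to the survivors of
  all previous ones, and popping restores the exact prior survivor set.
  The final survivor set always equals the brute-force conjunction of the
  filters, so it is independent of filter order.
* **Annotation transfer** matches variants by the normalized
  `(chrom, pos, ref, alt)` of each alternate allele (shared suffix then
  prefix trimmed, position advanced), copies only user-selected keys from a
  source VCF under a namespaced `sourcename_key`, and supports
  whitelist/blacklist VCFs as presence flags plus BED intervals as region
  flags.
* **Trio filters** select autosomal-recessive, de novo, X-linked recessive,
  and compound-heterozygous candidates from the genotype classes of a
  father/mother/child trio, and compose with the filter stack's survivors.

Because the package is built for exact, reproducible testing, it ships a
deterministic synthetic-trio generator that plants known inheritance
patterns and whitelist overlaps and emits the ground truth beside the VCF.

## Worked example

Generate a 1,000-variant synthetic trio (12 recessive, 5 de novo, 3
compound-het genes planted; 700 PASS records; a whitelist sharing 37 allele
keys), load it, screen it against the whitelist, and run the diagnostic
cascade — rarity on three frequency fields, function class, then recessive
inheritance:

```console
$ vcfstack fixtures --spec spec.json --outdir fx
$ vcfstack load fx/trio.vcf.gz --level L2 --out trio.store.json
records: 1000
samples: 3 (FATHER, MOTHER, CHILD)
info fields: 7
sample fields retained: 3

$ vcfstack annotate trio.store.json --list fx/whitelist.vcf --name WL
annotated 37 records

$ vcfstack filter trio.store.json \
    -f "info:AF_1KG < 0.01" -f "info:AF_EXAC < 0.01" \
    -f "info:AF_ESP < 0.01" \
    -f "info:FUNC in_set {missense,nonsense}" --export candidates.vcf
info:AF_1KG < 0.01      36
info:AF_EXAC < 0.01     12
info:AF_ESP < 0.01      12
info:FUNC in_set {missense,nonsense}    12
exported 12 records -> candidates.vcf

$ vcfstack trio trio.store.json --father FATHER --mother MOTHER \
    --child CHILD --pattern recessive
recessive: 12 records
```

Each `filter` line prints the survivor count after that filter is pushed:
36 variants are rare in the first population panel, 12 are rare in all
three, all 12 are already missense/nonsense, and all 12 are exactly the
planted recessive sites — the cascade narrows monotonically and ends on
the known truth.  The exported `candidates.vcf` carries each applied
filter verbatim as `##vcfstack_filter=` provenance lines.

`vcfstack describe` lists every field with its type-derived operators and,
for string fields, the observed value domain:

```console
$ vcfstack describe trio.store.json | head -5
basic:CHROM   type=String   number=1  operators=!=,==,in_set,is_missing,not_missing  values={1,10,...,X}
basic:POS     type=Integer  number=1  operators=!=,<,<=,==,>,>=,is_missing,not_missing
basic:ID      type=String   number=1  operators=!=,==,in_set,is_missing,not_missing
basic:QUAL    type=Float    number=1  operators=!=,<,<=,==,>,>=,is_missing,not_missing
basic:FILTER  type=String   number=.  operators=!=,==,in_set,is_missing,not_missing  values={PASS,lowDP,q10,s50}
```

The same workflow is available as a library — `read_vcf`, `VariantStore`,
`FilterStack`, `make_filter`, `build_source`/`annotate_store`,
`recessive_filter`/`denovo_filter`/`xlinked_recessive_filter`/
`compound_het`, and `FixtureSpec`/`generate` — see `docs/methods.md`.

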