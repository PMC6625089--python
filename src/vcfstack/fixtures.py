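"""Deterministic synthetic trio VCFs with planted truth.

No public trio callset accompanies the workflows this package implements, so
every module is exercised against generated data: a multi-sample VCF with
typed INFO fields (three allele-frequency-like floats, a function-class
string, a gene symbol, a depth integer, a membership flag), controlled
FILTER composition, and trio genotype patterns planted at known records.
Companion outputs carry the ground truth (planted record ids per pattern,
whitelist overlap keys), so recovery assertions are exact rather than
statistical.

Counts controlled by the spec are enforced by construction, not sampled:
``pass_fraction=0.7`` over 1,000 records yields exactly 700 ``FILTER=PASS``
lines, and a requested whitelist overlap of 37 shares exactly 37 normalized
allele keys with the trio.  Background genotypes are drawn only from trio
combinations that can satisfy no inheritance pattern, so each pattern filter
recovers exactly its planted set.

What this emulates — and what it does not: typed annotations, multi-allelic
sites, missing values, hemizygous chrX calls, and representation-shifted
whitelist entries are all present; linkage structure, sequencing-error
models, and realistic site-frequency spectra are not.  Passing tests
therefore demonstrate the correctness of parsing, filtering, matching, and
inheritance logic, not calibration against real cohorts.

Determinism: one seeded ``random.Random`` drives everything, and gzip
output pins mtime, so the same spec and seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
import os
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import random

from .errors import ScenarioError, SpecError
from .filters import FilterStack, make_filter, record_passes
from .inheritance import TrioSpec, recessive_filter
from .store import VariantStore
from .vcfio import (
    FieldDef,
    HeaderMeta,
    ParseLevel,
    VariantRecord,
    read_vcf,
    render_record,
    write_vcf,
)

DEFAULT_SEED = 42

AF_FIELDS = ("AF_1KG", "AF_EXAC", "AF_ESP")
FUNC_FIELD = "FUNC"
GENE_FIELD = "GENE"

FUNCTIONAL_CLASSES = ("missense", "nonsense")
BACKGROUND_CLASSES = ("missense", "nonsense", "synonymous", "intronic",
                      "utr5", "intergenic")

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMS = AUTOSOMES + ("X",)

# Trio genotype combinations (father, mother, child) that satisfy no
# inheritance pattern, on autosomes and (with hemizygous father/son) on X.
SAFE_AUTOSOMAL = (
    ("0/0", "0/0", "0/0"),
    ("0/1", "0/1", "0/1"),
    ("0/1", "0/0", "0/0"),
    ("0/0", "0/1", "0/0"),
    ("1/1", "0/1", "0/1"),
    ("1/1", "1/1", "1/1"),
    ("0/1", "0/1", "0/0"),
)
SAFE_AUTOSOMAL_MISSING = (
    ("./.", "0/1", "0/0"),
    ("0/1", "./.", "0/1"),
    ("0/0", "0/0", "./."),
)
SAFE_X = (
    ("0", "0/0", "0"),
    ("0", "0/1", "0"),
    ("1", "0/1", "0"),
    ("1", "1/1", "1"),
)

PATTERN_GENOTYPES = {
    "recessive": ("0/1", "0/1", "1/1"),
    "denovo": ("0/0", "0/0", "0/1"),
    "comphet_paternal": ("0/1", "0/0", "0/1"),
    "comphet_maternal": ("0/0", "0/1", "0/1"),
    "xlinked": ("0", "0/1", "1"),
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic trio dataset.

    ``planted`` maps pattern names to counts; ``comphet_genes`` counts genes
    (two variants each).  ``whitelist_overlap`` is the exact number of trio
    allele keys shared with the generated whitelist VCF.
    """

    n_variants: int = 10_000
    samples: tuple = ("FATHER", "MOTHER", "CHILD")
    seed: int = DEFAULT_SEED
    pass_fraction: float = 0.7
    planted: dict = dc_field(default_factory=lambda: {
        "recessive": 12, "denovo": 5, "comphet_genes": 3, "xlinked": 0})
    whitelist_overlap: int = 37
    whitelist_extra: int = 15
    gene_count: int = 120
    ann_overlap: int = 300
    ann_extra: int = 40
    missing_gt_fraction: float = 0.01
    multiallelic_fraction: float = 0.03

    def planted_count(self, name: str) -> int:
        return int(self.planted.get(name, 0))

    def validate(self) -> None:
        slots = (self.planted_count("recessive") + self.planted_count("denovo")
                 + 2 * self.planted_count("comphet_genes")
                 + self.planted_count("xlinked"))
        if slots > self.n_variants:
            raise SpecError(
                f"planted counts need {slots} records but n_variants="
                f"{self.n_variants}")
        if len(self.samples) != 3:
            raise SpecError("fixture trios need exactly three samples")
        if not 0 <= self.pass_fraction <= 1:
            raise SpecError("pass_fraction must be in [0, 1]")
        if self.whitelist_overlap > self.n_variants:
            raise SpecError("whitelist_overlap exceeds n_variants")
        if self.ann_overlap > self.n_variants:
            raise SpecError("ann_overlap exceeds n_variants")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        data = json.loads(text)
        if "samples" in data:
            data["samples"] = tuple(data["samples"])
        return cls(**data)

    @property
    def trio(self) -> TrioSpec:
        return TrioSpec(*self.samples)


# ---------------------------------------------------------------------------
# header / record construction

def _fixture_header(samples: Sequence[str]) -> HeaderMeta:
    info = {}
    for af in AF_FIELDS:
        info[af] = FieldDef(af, "INFO", "A", "Float",
                            f"Population allele frequency ({af})")
    info[FUNC_FIELD] = FieldDef(FUNC_FIELD, "INFO", 1, "String",
                                "Predicted functional class")
    info[GENE_FIELD] = FieldDef(GENE_FIELD, "INFO", 1, "String", "Gene symbol")
    info["DP"] = FieldDef("DP", "INFO", 1, "Integer", "Total depth")
    info["DB"] = FieldDef("DB", "INFO", 0, "Flag", "Known-variant membership")
    fmt = {
        "GT": FieldDef("GT", "FORMAT", 1, "String", "Genotype"),
        "DP": FieldDef("DP", "FORMAT", 1, "Integer", "Read depth"),
        "GQ": FieldDef("GQ", "FORMAT", 1, "Integer", "Genotype quality"),
    }
    other = [f"##contig=<ID={c}>" for c in CHROMS]
    other.append('##FILTER=<ID=q10,Description="Quality below 10">')
    other.append('##FILTER=<ID=s50,Description="Low sample coverage">')
    other.append('##FILTER=<ID=lowDP,Description="Low depth">')
    return HeaderMeta("VCFv4.2", info, fmt, list(samples), other)


_BASE_CHOICES = ("A", "C", "G", "T")


def _draw_alleles(rng: random.Random) -> Tuple[str, List[str]]:
    if rng.random() < 0.02:  # small deletion
        ref = rng.choice(_BASE_CHOICES) + rng.choice(_BASE_CHOICES)
        return ref, [ref[0]]
    ref = rng.choice(_BASE_CHOICES)
    alt = rng.choice([b for b in _BASE_CHOICES if b != ref])
    return ref, [alt]


@dataclass
class _Plan:
    """Where each planted pattern lives, decided before records are built."""

    pattern_of: Dict[int, str]
    comphet_gene_of: Dict[int, str]
    recessive: List[int]
    denovo: List[int]
    xlinked: List[int]
    comphet: Dict[str, Tuple[int, int]]


def _assign_genes(chrom_of: List[str], gene_count: int) -> List[str]:
    """Contiguous same-chromosome gene blocks over the record order."""
    n = len(chrom_of)
    block = max(1, n // max(1, gene_count))
    genes, gi, start = [], 0, 0
    for i in range(n):
        if i > start and (i - start >= block or chrom_of[i] != chrom_of[i - 1]):
            gi, start = gi + 1, i
        genes.append(f"GENE{gi:04d}")
    return genes


def _plan_patterns(spec: FixtureSpec, chrom_of: List[str], genes: List[str],
                   rng: random.Random) -> _Plan:
    n = len(chrom_of)
    auto_ids = [i for i in range(n) if chrom_of[i] != "X"]
    x_ids = [i for i in range(n) if chrom_of[i] == "X"]
    n_x = spec.planted_count("xlinked")
    if n_x > len(x_ids):
        raise SpecError(f"cannot plant {n_x} X-linked records: only "
                        f"{len(x_ids)} chrX records")
    taken: set = set()
    pattern_of: Dict[int, str] = {}
    comphet_gene_of: Dict[int, str] = {}

    def take(pool: List[int], k: int) -> List[int]:
        avail = [i for i in pool if i not in taken]
        if len(avail) < k:
            raise SpecError("not enough records to plant the requested patterns")
        picked = rng.sample(avail, k)
        taken.update(picked)
        return sorted(picked)

    recessive = take(auto_ids, spec.planted_count("recessive"))
    denovo = take(auto_ids, spec.planted_count("denovo"))
    xlinked = take(x_ids, n_x)
    for i in recessive:
        pattern_of[i] = "recessive"
    for i in denovo:
        pattern_of[i] = "denovo"
    for i in xlinked:
        pattern_of[i] = "xlinked"

    # compound-het pairs need two free records in one autosomal gene block
    by_gene: Dict[str, List[int]] = {}
    for i in auto_ids:
        if i not in taken:
            by_gene.setdefault(genes[i], []).append(i)
    candidates = sorted(g for g, ids in by_gene.items() if len(ids) >= 2)
    k_genes = spec.planted_count("comphet_genes")
    if len(candidates) < k_genes:
        raise SpecError("not enough multi-record genes for compound-het planting")
    comphet: Dict[str, Tuple[int, int]] = {}
    for gene in rng.sample(candidates, k_genes):
        v1, v2 = sorted(rng.sample(by_gene[gene], 2))
        taken.update((v1, v2))
        pattern_of[v1] = "comphet_paternal"
        pattern_of[v2] = "comphet_maternal"
        comphet_gene_of[v1] = comphet_gene_of[v2] = gene
        comphet[gene] = (v1, v2)
    return _Plan(pattern_of, comphet_gene_of, recessive, denovo, xlinked, comphet)


def build_records(spec: FixtureSpec
                  ) -> Tuple[HeaderMeta, List[VariantRecord], dict]:
    """Build the trio header, records, and truth tables in memory.

    The truth dict maps ``"recessive"``/``"denovo"``/``"xlinked"`` to sorted
    planted record-id lists and ``"comphet"`` to ``{gene: (id1, id2)}``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    header = _fixture_header(spec.samples)

    # chromosome layout: ~5% chrX (at least the planted X count), rest even
    n = spec.n_variants
    n_x = max(spec.planted_count("xlinked"), round(n * 0.05))
    n_x = min(n_x, n)
    per_auto, extra = divmod(n - n_x, len(AUTOSOMES))
    chrom_of: List[str] = []
    for ci, chrom in enumerate(AUTOSOMES):
        chrom_of.extend([chrom] * (per_auto + (1 if ci < extra else 0)))
    chrom_of.extend(["X"] * n_x)

    positions: List[int] = []
    pos = 0
    last_chrom = None
    for chrom in chrom_of:
        if chrom != last_chrom:
            pos = rng.randint(10_000, 20_000)
            last_chrom = chrom
        else:
            pos += rng.randint(50, 2_000)
        positions.append(pos)

    genes = _assign_genes(chrom_of, spec.gene_count)
    plan = _plan_patterns(spec, chrom_of, genes, rng)

    pass_count = round(n * spec.pass_fraction)
    pass_ids = set(rng.sample(range(n), pass_count))

    gene_of_record = list(genes)
    for i, gene in plan.comphet_gene_of.items():
        gene_of_record[i] = gene

    records: List[VariantRecord] = []
    for i in range(n):
        chrom = chrom_of[i]
        pattern = plan.pattern_of.get(i)
        planted = pattern is not None

        ref, alt = _draw_alleles(rng)
        if not planted and chrom != "X" and rng.random() < spec.multiallelic_fraction:
            second = rng.choice([b for b in _BASE_CHOICES
                                 if b != ref[0] and b != alt[0]])
            if len(ref) == 1 and second not in alt:
                alt = alt + [second]
        if planted:  # planted sites stay biallelic SNVs for unambiguous truth
            ref = rng.choice(_BASE_CHOICES)
            alt = [rng.choice([b for b in _BASE_CHOICES if b != ref])]

        info: dict = {}
        rare = pattern == "recessive"
        for af in AF_FIELDS:
            if rare:
                vals = [round(rng.uniform(0.0001, 0.009), 4) for _ in alt]
            else:
                vals = [round(rng.uniform(0.0, 0.5), 4) for _ in alt]
            info[af] = vals
        if rare:
            info[FUNC_FIELD] = rng.choice(FUNCTIONAL_CLASSES)
        else:
            info[FUNC_FIELD] = rng.choice(BACKGROUND_CLASSES)
        info[GENE_FIELD] = gene_of_record[i]
        info["DP"] = rng.randint(20, 400)
        if rng.random() < 0.2:
            info["DB"] = True

        if planted:
            gts = PATTERN_GENOTYPES[pattern]
        elif chrom == "X":
            gts = rng.choice(SAFE_X)
        elif rng.random() < spec.missing_gt_fraction:
            gts = rng.choice(SAFE_AUTOSOMAL_MISSING)
        else:
            gts = rng.choice(SAFE_AUTOSOMAL)

        samples = {}
        for name, gt in zip(spec.samples, gts):
            samples[name] = {
                "GT": None if gt in (".", "./.") else gt,
                "DP": rng.randint(10, 120),
                "GQ": rng.randint(20, 99),
            }
            if gt == "./.":
                samples[name]["GT"] = "./."  # called-missing, not absent

        qual = None if rng.random() < 0.01 else round(rng.uniform(20, 100), 1)
        rec_id = f"rs{rng.randint(10**6, 10**8)}" if rng.random() < 0.3 else None
        filt = ["PASS"] if i in pass_ids else [rng.choice(
            ["q10", "s50", "lowDP", "q10;s50"])]
        if filt != ["PASS"] and ";" in filt[0]:
            filt = filt[0].split(";")

        records.append(VariantRecord(
            chrom, positions[i], rec_id, ref, alt, qual, filt, info,
            ["GT", "DP", "GQ"], samples))

    truth = {
        "recessive": plan.recessive,
        "denovo": plan.denovo,
        "xlinked": plan.xlinked,
        "comphet": plan.comphet,
    }
    return header, records, truth


# ---------------------------------------------------------------------------
# companion files

def _write_gz_text(path, text: str) -> None:
    with open(path, "wb") as raw:
        with io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="wb", mtime=0),
                              encoding="utf-8") as out:
            out.write(text)


def _used_keys(records: List[VariantRecord]):
    from .annotate import normalize_allele
    used = set()
    for rec in records:
        for alt in rec.alt:
            used.add(normalize_allele(rec.chrom, rec.pos, rec.ref, alt))
    return used


def _site_header(info_defs: Dict[str, FieldDef], source: str) -> HeaderMeta:
    other = [f"##contig=<ID={c}>" for c in CHROMS]
    other.append(f"##source={source}")
    return HeaderMeta("VCFv4.2", dict(info_defs), {}, [], other)


def _build_whitelist(spec: FixtureSpec, records: List[VariantRecord],
                     rng: random.Random):
    """Whitelist VCF sharing exactly ``whitelist_overlap`` allele keys."""
    overlap_ids = sorted(rng.sample(range(len(records)), spec.whitelist_overlap))
    wl_records: List[VariantRecord] = []
    for j, i in enumerate(overlap_ids):
        rec = records[i]
        ref, alt, pos = rec.ref, rec.alt[0], rec.pos
        if j % 2 == 1 and len(ref) == 1 and len(alt) == 1:
            pad = rng.choice(_BASE_CHOICES)  # shifted representation
            ref, alt = ref + pad, alt + pad
        wl_records.append(VariantRecord(
            rec.chrom, pos, None, ref, [alt], None, None, {}, [], {}))
    used = _used_keys(records)
    from .annotate import normalize_allele
    extras = 0
    guard = 0
    while extras < spec.whitelist_extra and guard < 10_000:
        guard += 1
        chrom = rng.choice(CHROMS)
        pos = rng.randint(1_000_000, 5_000_000)
        ref = rng.choice(_BASE_CHOICES)
        alt = rng.choice([b for b in _BASE_CHOICES if b != ref])
        if normalize_allele(chrom, pos, ref, alt) in used:
            continue
        wl_records.append(VariantRecord(
            chrom, pos, None, ref, [alt], None, None, {}, [], {}))
        extras += 1
    wl_records.sort(key=VariantRecord.sort_key)
    return wl_records, overlap_ids


def _build_ann_source(spec: FixtureSpec, records: List[VariantRecord],
                      rng: random.Random):
    """Keyed annotation source covering ``ann_overlap`` trio records."""
    defs = {
        "POP_AF": FieldDef("POP_AF", "INFO", "A", "Float",
                           "Population allele frequency"),
        "SIFT_SCORE": FieldDef("SIFT_SCORE", "INFO", 1, "Float",
                               "Deleteriousness score"),
        "PRED": FieldDef("PRED", "INFO", 1, "String", "Categorical prediction"),
        "GLS": FieldDef("GLS", "INFO", "G", "Float",
                        "Genotype-shaped likelihoods (never transferable)"),
    }
    overlap_ids = sorted(rng.sample(range(len(records)), spec.ann_overlap))
    src_records: List[VariantRecord] = []
    for i in overlap_ids:
        rec = records[i]
        info = {
            "POP_AF": [round(rng.uniform(0.0, 0.3), 4) for _ in rec.alt],
            "SIFT_SCORE": round(rng.uniform(0.0, 1.0), 3),
            "PRED": rng.choice(["tolerated", "damaging"]),
            "GLS": [round(rng.uniform(-10, 0), 2) for _ in range(3)],
        }
        src_records.append(VariantRecord(
            rec.chrom, rec.pos, None, rec.ref, list(rec.alt), None, None,
            info, [], {}))
    used = _used_keys(records)
    from .annotate import normalize_allele
    extras = 0
    guard = 0
    while extras < spec.ann_extra and guard < 10_000:
        guard += 1
        chrom = rng.choice(CHROMS)
        pos = rng.randint(6_000_000, 9_000_000)
        ref = rng.choice(_BASE_CHOICES)
        alts = [rng.choice([b for b in _BASE_CHOICES if b != ref])]
        if rng.random() < 0.3:
            second = [b for b in _BASE_CHOICES if b != ref and b not in alts]
            alts.append(rng.choice(second))
        if any(normalize_allele(chrom, pos, ref, a) in used for a in alts):
            continue
        info = {
            "POP_AF": [round(rng.uniform(0.0, 0.3), 4) for _ in alts],
            "SIFT_SCORE": round(rng.uniform(0.0, 1.0), 3),
            "PRED": rng.choice(["tolerated", "damaging"]),
        }
        src_records.append(VariantRecord(
            chrom, pos, None, ref, alts, None, None, info, [], {}))
        extras += 1
    src_records.sort(key=VariantRecord.sort_key)
    return defs, src_records, overlap_ids


def _build_bed(records: List[VariantRecord], rng: random.Random) -> List[str]:
    """A few intervals per chromosome, each covering some record positions."""
    lines = []
    by_chrom: Dict[str, List[int]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec.pos)
    for chrom in CHROMS:
        poss = by_chrom.get(chrom)
        if not poss:
            continue
        anchor = rng.choice(poss)
        lines.append(f"{chrom}\t{anchor - 1}\t{anchor - 1 + rng.randint(1, 5000)}")
    return lines


def generate(spec: FixtureSpec, outdir) -> Dict[str, str]:
    """Generate the full fixture set under ``outdir``; returns file paths.

    Outputs: ``trio.vcf.gz`` (the multi-sample VCF), ``truth.tsv`` (planted
    record ids per pattern), ``whitelist.vcf`` + ``whitelist_truth.tsv``,
    ``ann_source.vcf`` (keyed annotation source), ``regions.bed``, and
    ``spec.json`` (the recipe itself).
    """
    os.makedirs(outdir, exist_ok=True)
    header, records, truth = build_records(spec)
    rng = random.Random(spec.seed + 1)  # companion-file stream

    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "trio": "trio.vcf.gz",
        "truth": "truth.tsv",
        "whitelist": "whitelist.vcf",
        "whitelist_truth": "whitelist_truth.tsv",
        "ann_source": "ann_source.vcf",
        "bed": "regions.bed",
        "spec": "spec.json",
    }.items()}

    body = "\n".join(header.render_lines()) + "\n" + "".join(
        render_record(rec, header) + "\n" for rec in records)
    _write_gz_text(paths["trio"], body)

    rows = [f"# fixture truth, seed={spec.seed}",
            "record_id\tpattern\tgene\tchrom\tpos\tref\talt"]

    def row(i: int, pattern: str, gene: str = ".") -> str:
        rec = records[i]
        return (f"{i}\t{pattern}\t{gene}\t{rec.chrom}\t{rec.pos}\t{rec.ref}"
                f"\t{','.join(rec.alt)}")

    for i in truth["recessive"]:
        rows.append(row(i, "recessive"))
    for i in truth["denovo"]:
        rows.append(row(i, "denovo"))
    for i in truth["xlinked"]:
        rows.append(row(i, "xlinked"))
    for gene, (v1, v2) in sorted(truth["comphet"].items()):
        rows.append(row(v1, "comphet", gene))
        rows.append(row(v2, "comphet", gene))
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(rows) + "\n")

    wl_records, wl_ids = _build_whitelist(spec, records, rng)
    wl_header = _site_header({}, "vcfstack-fixtures whitelist")
    write_vcf(wl_header, wl_records, paths["whitelist"])
    with open(paths["whitelist_truth"], "w", encoding="utf-8") as fh:
        fh.write(f"# whitelist overlap, seed={spec.seed}\n")
        fh.write("record_id\tchrom\tpos\tref\talt\n")
        for i in wl_ids:
            rec = records[i]
            fh.write(f"{i}\t{rec.chrom}\t{rec.pos}\t{rec.ref}"
                     f"\t{','.join(rec.alt)}\n")

    ann_defs, ann_records, _ = _build_ann_source(spec, records, rng)
    ann_header = _site_header(ann_defs, "vcfstack-fixtures annotation source")
    write_vcf(ann_header, ann_records, paths["ann_source"])

    with open(paths["bed"], "w", encoding="utf-8") as fh:
        for line in _build_bed(records, rng):
            fh.write(line + "\n")

    with open(paths["spec"], "w", encoding="utf-8") as fh:
        fh.write(spec.to_json() + "\n")
    return paths


def read_truth(path) -> dict:
    """Parse truth.tsv back into the in-memory truth structure."""
    truth: dict = {"recessive": [], "denovo": [], "xlinked": [], "comphet": {}}
    pairs: Dict[str, List[int]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("record_id"):
                continue
            cols = line.rstrip("\n").split("\t")
            rid, pattern, gene = int(cols[0]), cols[1], cols[2]
            if pattern == "comphet":
                pairs.setdefault(gene, []).append(rid)
            else:
                truth[pattern].append(rid)
    for gene, ids in pairs.items():
        truth["comphet"][gene] = tuple(sorted(ids))
    return truth


# ---------------------------------------------------------------------------
# the diagnostic cascade scenario

def cascade_filters(header: HeaderMeta) -> list:
    """The ordered rarity → function filter stack of the diagnostic cascade."""
    filters = [make_filter(header, "info", af, "<", 0.01) for af in AF_FIELDS]
    filters.append(make_filter(header, "info", FUNC_FIELD, "in_set",
                               set(FUNCTIONAL_CLASSES)))
    return filters


def scenario_trio_cascade(fixture_dir, spec: Optional[FixtureSpec] = None) -> dict:
    """Run the trio diagnostic cascade on a generated fixture and verify it.

    Pushes the three rarity filters (< 0.01 on each frequency-like field) and
    the function-class filter, then applies the trio recessive filter to the
    survivors.  Checks that counts are non-increasing and that the final set
    equals the planted-recessive ∩ rare ∩ functional truth, computed by
    independent per-record predicate evaluation.  Raises
    :class:`~vcfstack.errors.ScenarioError` on any violation; returns a
    summary dict with the per-level counts and final ids.
    """
    if spec is None:
        spec_path = os.path.join(fixture_dir, "spec.json")
        with open(spec_path, encoding="utf-8") as fh:
            spec = FixtureSpec.from_json(fh.read())
    header, stream = read_vcf(os.path.join(fixture_dir, "trio.vcf.gz"),
                              ParseLevel.L2)
    store = VariantStore.load(header, stream)
    truth = read_truth(os.path.join(fixture_dir, "truth.tsv"))

    stack = FilterStack(store)
    counts = [len(store.records)]
    for filt in cascade_filters(header):
        stack = stack.push(filt)
        counts.append(len(stack.survivor_ids))
    final_ids = sorted(recessive_filter(store, spec.trio,
                                        ids=stack.survivor_ids))
    counts.append(len(final_ids))

    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ScenarioError(f"cascade counts increased: {counts}")

    # independent oracle: evaluate every predicate on every record
    filters = cascade_filters(header)
    rare_functional = {
        i for i, rec in enumerate(store.records)
        if all(record_passes(rec, f, header) for f in filters)}
    expected = sorted(set(truth["recessive"]) & rare_functional)
    if final_ids != expected:
        raise ScenarioError(
            f"cascade final set {final_ids} != expected {expected}")
    return {
        "counts": counts,
        "final_ids": final_ids,
        "expected_ids": expected,
        "n_variants": len(store.records),
    }
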