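"""Variant-keyed annotation transfer, whitelist/blacklist flags, BED flags.

Annotation sources are themselves VCF files.  Matching is exact on the
normalized ``(chrom, pos, ref, alt)`` of each alternate allele — never on
position alone and never on rsID, because screening against curated variant
lists is allele-level by nature and anything looser silently conflates
alleles.

Normalization trims the longest shared suffix of ref/alt, then the shared
prefix (advancing the position), always keeping both alleles non-empty.
This makes ``CA>CT`` at 100 equal to ``A>T`` at 101 without requiring a
reference genome for full left-alignment; symbolic (non-ACGTN) alleles pass
through untouched.

Two transfer modes:

* **keyed** — copy a user-selected subset of the source's INFO keys into the
  target, namespaced ``sourcename_key`` so in-house annotations are never
  clobbered, with per-allele (``Number=A``) alignment to the target's ALT
  list.  Genotype-shaped fields (``Number=G``) are never copied: their
  values are sample-dependent and meaningless across files.
* **list** — whitelist/blacklist screening: set a single flag on every
  record whose allele key appears in the source; the flag can then drive an
  ordinary present/absent filter.

A third, interval-based path flags records falling inside BED regions
(0-based half-open), covering region-type annotations such as target
panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Union

from intervaltree import IntervalTree

from .errors import AnnotationError, CollisionError, InputError
from .vcfio import FieldDef, ParseLevel, normalize_chrom, read_vcf

_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class AlleleKey:
    """Normalized (chrom, pos, ref, alt) identity of one alternate allele."""

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_allele(chrom: str, pos: int, ref: str, alt: str) -> AlleleKey:
    """Reduce one ref/alt pair to normal form.

    Trims the longest common suffix, then the common prefix (advancing
    ``pos`` per base trimmed), keeping both alleles non-empty throughout.
    Idempotent.  Symbolic or non-ACGTN alleles are passed through with a
    warning, unmodified except for chromosome normalization.
    """
    nchrom = normalize_chrom(chrom)
    r, a = ref.upper(), alt.upper()
    if not (set(r) <= _BASES and set(a) <= _BASES) or not r or not a:
        warnings.warn(
            f"allele {ref!r}>{alt!r} at {chrom}:{pos} contains non-ACGTN "
            "characters; not normalized", UserWarning, stacklevel=2)
        return AlleleKey(nchrom, pos, ref, alt)
    while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    return AlleleKey(nchrom, pos, r, a)


@dataclass
class AnnotationSource:
    """Allele-keyed lookup built from an annotation VCF."""

    name: str
    mode: str  # keyed | list
    selected_keys: list
    lookup: dict  # AlleleKey -> {key: value} (keyed) or True (list)
    defs: dict = dc_field(default_factory=dict)  # key -> FieldDef of source


def _allele_slice(value, number: Union[int, str], alt_index: int):
    """Pick the per-allele element of a source INFO value for one alt."""
    if number == "A":
        if isinstance(value, list):
            return value[alt_index] if alt_index < len(value) else None
        return value if alt_index == 0 else None
    if number == "R":
        if isinstance(value, list):
            return value[alt_index + 1] if alt_index + 1 < len(value) else None
        return None
    if isinstance(value, list):  # Number='.' or fixed >1: not allele-shaped
        return "|".join("." if v is None else str(v) for v in value)
    return value


def build_source(ann_vcf, selected_keys: Optional[Sequence[str]] = None,
                 mode: str = "keyed", name: Optional[str] = None
                 ) -> AnnotationSource:
    """Build an :class:`AnnotationSource` from an annotation VCF.

    ``selected_keys=None`` in keyed mode selects every transferable INFO key
    of the source (everything except ``Number=G`` fields).  Multi-allelic
    source records are decomposed per alternate allele, with ``Number=A``
    values distributed positionally.
    """
    if mode not in ("keyed", "list"):
        raise AnnotationError(f"mode must be 'keyed' or 'list', got {mode!r}")
    header, records = read_vcf(ann_vcf, ParseLevel.L0)
    src_name = name or "ann"
    if mode == "list":
        keys: list = []
    else:
        transferable = [k for k, d in header.info_defs.items()
                        if d.number != "G"]
        if selected_keys is None:
            keys = transferable
        else:
            keys = list(selected_keys)
            unknown = [k for k in keys if k not in header.info_defs]
            if unknown:
                raise AnnotationError(
                    f"keys {unknown} absent from {ann_vcf}; available: "
                    f"{sorted(header.info_defs)}")
            shaped = [k for k in keys if header.info_defs[k].number == "G"]
            if shaped:
                raise AnnotationError(
                    f"keys {shaped} have Number=G (genotype-shaped) and are "
                    "never transferred across files")
        if not keys:
            raise AnnotationError(f"no transferable INFO keys in {ann_vcf}")

    lookup: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # symbolic-allele noise
        for rec in records:
            for ai, alt in enumerate(rec.alt):
                key = normalize_allele(rec.chrom, rec.pos, rec.ref, alt)
                if mode == "list":
                    lookup[key] = True
                    continue
                values = {}
                for k in keys:
                    v = rec.info.get(k)
                    if v is None:
                        continue
                    picked = _allele_slice(v, header.info_defs[k].number, ai)
                    if picked is not None:
                        values[k] = picked
                lookup[key] = values
    defs = {k: header.info_defs[k] for k in keys}
    return AnnotationSource(src_name, mode, keys, lookup, defs)


def _install_def(header, fdef: FieldDef) -> None:
    existing = header.info_defs.get(fdef.id)
    if existing is None:
        header.info_defs[fdef.id] = fdef
    elif existing != fdef:
        raise CollisionError(
            f"INFO key {fdef.id!r} already declared with a different "
            "definition; refusing to overwrite")


def _new_defs(store, source: AnnotationSource) -> List[FieldDef]:
    """The FieldDefs annotation would add; collision-checked before mutation."""
    if source.mode == "list":
        return [FieldDef(source.name, "INFO", 0, "Flag",
                         f"Variant present in list {source.name}")]
    defs = []
    for k in source.selected_keys:
        src = source.defs[k]
        if src.type == "Flag":
            elem_type = "Integer"
        elif src.number not in (0, 1, "A", "R"):
            elem_type = "String"  # joined multi-values travel as text
        else:
            elem_type = src.type
        defs.append(FieldDef(
            f"{source.name}_{k}", "INFO", "A", elem_type,
            f"{src.description} [transferred from {source.name}]".strip()))
    return defs


def annotate_store(store, source: AnnotationSource) -> int:
    """Transfer annotations onto every matching record; returns records hit.

    Keyed mode copies the selected keys into INFO under ``name_key`` as
    per-allele lists aligned with the record's ALT; list mode sets the flag
    ``name``.  Header declarations are added exactly once; re-annotating
    with the same source is idempotent.  Records' fixed columns are never
    modified and the record count is invariant.
    """
    new_defs = _new_defs(store, source)
    for fdef in new_defs:  # validate all before mutating anything
        existing = store.header.info_defs.get(fdef.id)
        if existing is not None and existing != fdef:
            raise CollisionError(
                f"INFO key {fdef.id!r} already declared with a different "
                "definition; pick another source name")
    for fdef in new_defs:
        _install_def(store.header, fdef)

    count = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for rec in store.records:
            hit = False
            for ai, alt in enumerate(rec.alt):
                key = normalize_allele(rec.chrom, rec.pos, rec.ref, alt)
                found = source.lookup.get(key)
                if found is None:
                    continue
                hit = True
                if source.mode == "list":
                    rec.info[source.name] = True
                    continue
                for k, v in found.items():
                    target = f"{source.name}_{k}"
                    values = rec.info.get(target)
                    if not isinstance(values, list) or len(values) != len(rec.alt):
                        values = [None] * len(rec.alt)
                        rec.info[target] = values
                    values[ai] = v
            if hit:
                count += 1
    return count


def read_bed(path) -> Dict[str, IntervalTree]:
    """Parse a BED3+ file into per-chromosome interval trees.

    Coordinates are 0-based half-open; chromosome names are normalized.
    """
    trees: Dict[str, IntervalTree] = {}
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise InputError(f"cannot read BED {path}: {exc}")
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise InputError(
                f"{path} line {lineno}: BED needs >=3 columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise InputError(
                f"{path} line {lineno}: non-integer BED coordinates")
        if start > end:
            raise InputError(
                f"{path} line {lineno}: start {start} > end {end}")
        if start == end:
            continue  # empty interval contains no base
        trees.setdefault(normalize_chrom(cols[0]), IntervalTree()).addi(start, end)
    return trees


def annotate_intervals(store, bed, flag_name: str) -> int:
    """Flag every record whose base falls in a BED interval; returns count.

    A record at 1-based position ``pos`` is flagged iff ``pos - 1`` lies in
    ``[start, end)`` of some interval on its (normalized) chromosome.
    """
    trees = read_bed(bed)
    _install_def(store.header, FieldDef(
        flag_name, "INFO", 0, "Flag", f"Position overlaps intervals in {bed}"))
    count = 0
    for rec in store.records:
        tree = trees.get(normalize_chrom(rec.chrom))
        if tree is not None and tree.overlaps_point(rec.pos - 1):
            rec.info[flag_name] = True
            count += 1
    return count
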