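"""Trio inheritance-pattern filters.

In the diagnostic setting a trio (father, mother, affected child) is
sequenced jointly and the candidate disease variants are screened by
genotype pattern:

* **autosomal recessive** — both parents heterozygous carriers, the child
  homozygous for the same alternate allele;
* **de novo** — both parents homozygous reference, the child carries an
  alternate allele absent from either parent;
* **X-linked recessive** — on chromosome X, the mother a heterozygous
  carrier, the child hemizygous or homozygous for the alternate allele, and
  the father carrying no alternate allele;
* **compound heterozygous** — two different heterozygous variants in the
  same gene in the child, one inherited from each parent (trans
  configuration inferred from parental genotypes, not read-based phasing).

All filters work on genotype classes, not raw GT strings, so phased (``1|0``)
and unphased (``0/1``) encodings compare equal.  Records with a missing trio
genotype are excluded by default (conservative screening); pass
``include_missing=True`` to let a missing member count as compatible.

Every filter accepts an optional ``ids`` subset so it can be composed with a
filter stack's survivors: frequency and function filters first, inheritance
last, with non-increasing counts down the cascade.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import TrioSpecError, WrongTypeError
from .vcfio import HeaderMeta, VariantRecord, normalize_chrom

_GT_SEP = re.compile(r"[/|]")

MISSING_GENOTYPE = None  # sentinel for an absent GT value


@dataclass(frozen=True)
class Genotype:
    """Parsed GT value: allele indices (None = missing allele) and phasing."""

    alleles: tuple
    phased: bool = False

    @property
    def ploidy(self) -> int:
        return len(self.alleles)


def parse_genotype(raw: Optional[str]) -> Optional[Genotype]:
    """Parse a GT string; returns None for an entirely absent value."""
    if raw is None or raw == "":
        return None
    phased = "|" in raw
    alleles = tuple(None if tok in (".", "") else int(tok)
                    for tok in _GT_SEP.split(raw))
    return Genotype(alleles, phased)


def gt_class(g: Optional[Genotype]) -> str:
    """Classify a genotype.

    Returns one of ``hom_ref``, ``het``, ``hom_alt``, ``hemi_ref``,
    ``hemi_alt``, ``missing``, ``multi_alt_het``.  Any missing allele makes
    the whole genotype ``missing``; ``1/2``-style genotypes (two distinct
    non-reference alleles) are ``multi_alt_het``, which deliberately does not
    count as ``het`` for inheritance patterns (ambiguous transmission).
    """
    if g is None or any(a is None for a in g.alleles):
        return "missing"
    if g.ploidy == 1:
        return "hemi_alt" if g.alleles[0] != 0 else "hemi_ref"
    distinct = set(g.alleles)
    if distinct == {0}:
        return "hom_ref"
    if len(distinct) == 1:
        return "hom_alt"
    if 0 in distinct and len(distinct) == 2:
        return "het"
    return "multi_alt_het"


def has_alt(g: Optional[Genotype]) -> bool:
    """True when the genotype carries at least one called alternate allele."""
    return g is not None and any(a not in (0, None) for a in g.alleles)


def _alt_index(g: Genotype) -> Optional[int]:
    """The single non-reference allele index of a het/hom_alt/hemi_alt call."""
    alts = {a for a in g.alleles if a not in (0, None)}
    return alts.pop() if len(alts) == 1 else None


@dataclass(frozen=True)
class TrioSpec:
    """Sample-role assignment for a father/mother/child trio."""

    father: str
    mother: str
    child: str

    def validate(self, header: HeaderMeta) -> None:
        names = (self.father, self.mother, self.child)
        if len(set(names)) != 3:
            raise TrioSpecError(f"trio samples must be distinct, got {names}")
        missing = [n for n in names if n not in header.sample_names]
        if missing:
            raise TrioSpecError(
                f"samples {missing} not in header sample names "
                f"{header.sample_names}")


def _trio_genotypes(rec: VariantRecord, trio: TrioSpec
                    ) -> Tuple[Optional[Genotype], ...]:
    return tuple(
        parse_genotype(rec.samples.get(name, {}).get("GT"))
        for name in (trio.father, trio.mother, trio.child))


def _ids(store, ids: Optional[Iterable[int]]) -> Iterable[int]:
    return range(len(store.records)) if ids is None else sorted(ids)


def recessive_filter(store, trio: TrioSpec, ids: Optional[Iterable[int]] = None,
                     include_missing: bool = False) -> List[int]:
    """Autosomal-recessive pattern: parents het, child hom-alt, shared allele.

    The child must be homozygous for the *alternate* allele (a hom-ref child
    cannot carry a recessive condition), and all three members must involve
    the same alternate allele index — parents het for different alt alleles
    is not a recessive transmission.
    """
    trio.validate(store.header)
    kept = []
    for i in _ids(store, ids):
        f, m, c = _trio_genotypes(store.records[i], trio)
        classes = [gt_class(g) for g in (f, m, c)]
        if "missing" in classes:
            if not include_missing:
                continue
            ok = all(cls == "missing" or
                     (cls == "het" if j < 2 else cls == "hom_alt")
                     for j, cls in enumerate(classes))
            if ok:
                kept.append(i)
            continue
        if classes != ["het", "het", "hom_alt"]:
            continue
        shared = {_alt_index(g) for g in (f, m, c)}
        if len(shared) == 1 and None not in shared:
            kept.append(i)
    return kept


def denovo_filter(store, trio: TrioSpec, ids: Optional[Iterable[int]] = None,
                  include_missing: bool = False) -> List[int]:
    """De novo pattern: both parents hom-ref, child carries >=1 alt allele."""
    trio.validate(store.header)
    kept = []
    for i in _ids(store, ids):
        f, m, c = _trio_genotypes(store.records[i], trio)
        classes = [gt_class(g) for g in (f, m, c)]
        if "missing" in classes and not include_missing:
            continue
        parents_ok = all(cls == "hom_ref" or (include_missing and cls == "missing")
                         for cls in classes[:2])
        child_ok = has_alt(c) or (include_missing and classes[2] == "missing")
        if parents_ok and child_ok and (classes[2] != "missing" or include_missing):
            kept.append(i)
    return kept


def xlinked_recessive_filter(store, trio: TrioSpec,
                             ids: Optional[Iterable[int]] = None,
                             include_missing: bool = False,
                             require_father_ref: bool = True) -> List[int]:
    """X-linked recessive: chrX, mother het, child hemi/hom-alt, father no alt.

    The father criterion (no alternate allele, i.e. hemi-ref or hom-ref) can
    be relaxed with ``require_father_ref=False``.
    """
    trio.validate(store.header)
    kept = []
    for i in _ids(store, ids):
        rec = store.records[i]
        if normalize_chrom(rec.chrom) != "X":
            continue
        f, m, c = _trio_genotypes(rec, trio)
        fc, mc, cc = (gt_class(g) for g in (f, m, c))
        if "missing" in (fc, mc, cc) and not include_missing:
            continue
        mother_ok = mc == "het" or (include_missing and mc == "missing")
        child_ok = cc in ("hemi_alt", "hom_alt") or (
            include_missing and cc == "missing")
        father_ok = (not require_father_ref
                     or fc in ("hemi_ref", "hom_ref")
                     or (include_missing and fc == "missing"))
        if mother_ok and child_ok and father_ok:
            kept.append(i)
    return kept


def compound_het(store, trio: TrioSpec, gene_field: str,
                 ids: Optional[Iterable[int]] = None
                 ) -> Dict[str, List[Tuple[int, int]]]:
    """Compound-heterozygote candidate pairs per gene.

    Within each value of ``gene_field``, pairs ``(v1, v2)`` with ``v1 < v2``
    by record id where the child is het at both sites and the two alternate
    alleles come from different parents: at one site the father carries an
    alt allele while the mother is hom-ref, at the other the roles swap.
    Records lacking the gene field are skipped.
    """
    trio.validate(store.header)
    fdef = store.header.info_defs.get(gene_field)
    if fdef is None:
        raise WrongTypeError(f"gene field {gene_field!r} not declared in header")
    if fdef.type not in ("String", "Character"):
        raise WrongTypeError(
            f"gene field {gene_field!r} must be String/Character, "
            f"is {fdef.type}")
    paternal: Dict[str, list] = {}
    maternal: Dict[str, list] = {}
    for i in _ids(store, ids):
        rec = store.records[i]
        gval = rec.info.get(gene_field)
        if gval is None:
            continue
        genes = [g for g in (gval if isinstance(gval, list) else [gval])
                 if g is not None]
        f, m, c = _trio_genotypes(rec, trio)
        if gt_class(c) != "het":
            continue
        fc, mc = gt_class(f), gt_class(m)
        is_paternal = has_alt(f) and mc == "hom_ref"
        is_maternal = has_alt(m) and fc == "hom_ref"
        for gene in genes:
            if is_paternal:
                paternal.setdefault(gene, []).append(i)
            if is_maternal:
                maternal.setdefault(gene, []).append(i)
    result: Dict[str, List[Tuple[int, int]]] = {}
    for gene in sorted(set(paternal) & set(maternal)):
        pairs = sorted({(min(p, q), max(p, q))
                        for p in paternal[gene] for q in maternal[gene]
                        if p != q})
        if pairs:
            result[gene] = pairs
    return result
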