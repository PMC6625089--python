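"""Typed LIFO filter-stack query engine.

Filters fall into three categories mirroring the columns of a VCF:

* **basic** — the fixed columns CHROM, POS, ID, QUAL, FILTER (REF and ALT
  are deliberately not filterable);
* **info** — any declared or auto-registered INFO key;
* **format** — per-sample FORMAT keys, optionally restricted to a sample
  scope (an empty scope means all samples; within one filter every scoped
  sample must satisfy the predicate).

The operator set for a field is derived from its declared type: numeric
fields get relational operators, flags get presence/absence, strings get
equality and set membership, and GT gets genotype-class operators so that
``0/1`` and ``1|0`` compare equal.

Filters live on a stack with last-in-first-out semantics: each pushed filter
applies only to the survivors of all previous filters, and popping restores
the exact previous survivor set.  The final survivor set of any stack equals
the brute-force conjunction of its filters, so it is invariant to filter
order even though the intermediate counts are not.

Evaluation rules that keep survivor counts predictable:

* a multi-valued field passes a test if ANY element passes (an ``all_``
  operator prefix switches a filter to ALL semantics);
* a missing value fails every operator except the explicit ``is_missing``;
* FILTER matches per semicolon-separated member, and ``PASS`` only matches
  the literal ``PASS``.

Each filter has a canonical string form ``category:field op operand
[@sample1,sample2]`` used in CLI flags, logs, and export provenance;
:func:`parse_filter_string` is the exact inverse of :func:`render_filter`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import FrozenSet, List, Optional, Sequence, Tuple, Union

from .errors import (
    FilterConstructionError,
    StackEmptyError,
    UnknownFieldError,
    WrongTypeError,
)
from .inheritance import gt_class, has_alt, parse_genotype
from .vcfio import FieldDef, HeaderMeta, VariantRecord, normalize_chrom

NUMERIC_OPS = frozenset({">", "<", ">=", "<=", "==", "!=",
                         "is_missing", "not_missing"})
FLAG_OPS = frozenset({"present", "absent"})
STRING_OPS = frozenset({"==", "!=", "in_set", "is_missing", "not_missing"})
GT_OPS = frozenset({"is_hom_ref", "is_het", "is_hom_alt", "is_hemi",
                    "is_missing", "has_alt"})

_NO_OPERAND_OPS = frozenset({"is_missing", "not_missing", "present",
                             "absent"}) | GT_OPS

BASIC_FIELD_DEFS = {
    "CHROM": FieldDef("CHROM", "BASIC", 1, "String", "Chromosome"),
    "POS": FieldDef("POS", "BASIC", 1, "Integer", "1-based position"),
    "ID": FieldDef("ID", "BASIC", 1, "String", "Variant identifier"),
    "QUAL": FieldDef("QUAL", "BASIC", 1, "Float", "Call quality"),
    "FILTER": FieldDef("FILTER", "BASIC", ".", "String", "Filter status"),
}

CATEGORIES = ("basic", "info", "format")


def operators_for(fdef: FieldDef) -> FrozenSet[str]:
    """The applicable operator symbols for a field, from its declared type."""
    if fdef.source == "FORMAT" and fdef.id == "GT":
        return GT_OPS
    if fdef.type == "Flag":
        return FLAG_OPS
    if fdef.is_numeric:
        return NUMERIC_OPS
    return STRING_OPS


def field_def_for(header: HeaderMeta, category: str, field: str) -> FieldDef:
    if category == "basic":
        fdef = BASIC_FIELD_DEFS.get(field)
        if fdef is None:
            raise FilterConstructionError(
                f"basic filters apply to {sorted(BASIC_FIELD_DEFS)}, "
                f"not {field!r} (REF/ALT are not filterable)")
        return fdef
    if category == "info":
        fdef = header.info_defs.get(field)
        if fdef is None:
            raise UnknownFieldError(
                f"unknown INFO field {field!r}; known: "
                f"{sorted(header.info_defs)}")
        return fdef
    if category == "format":
        fdef = header.format_defs.get(field)
        if fdef is None:
            raise UnknownFieldError(
                f"unknown FORMAT field {field!r}; known: "
                f"{sorted(header.format_defs)}")
        return fdef
    raise FilterConstructionError(
        f"category must be one of {CATEGORIES}, got {category!r}")


@dataclass(frozen=True)
class Filter:
    """One typed predicate; build through :func:`make_filter`."""

    category: str
    field: str
    op: str
    operand: object = None
    sample_scope: tuple = ()
    elementwise: str = "any"  # multi-valued fields: any|all element passes


def make_filter(header: HeaderMeta, category: str, field: str, op: str,
                operand=None, sample_scope: Sequence[str] = (),
                elementwise: str = "any") -> Filter:
    """Validate and construct a :class:`Filter` (errors at make-time, not eval)."""
    fdef = field_def_for(header, category, field)
    ops = operators_for(fdef)
    if op not in ops:
        raise FilterConstructionError(
            f"operator {op!r} not applicable to {category}:{field} "
            f"({fdef.type}); applicable: {sorted(ops)}")
    if elementwise not in ("any", "all"):
        raise FilterConstructionError(
            f"elementwise must be 'any' or 'all', got {elementwise!r}")
    if op in _NO_OPERAND_OPS:
        if operand is not None:
            raise FilterConstructionError(f"operator {op!r} takes no operand")
    elif op == "in_set":
        if operand is None or isinstance(operand, str) or not hasattr(
                operand, "__iter__"):
            raise FilterConstructionError("in_set needs a collection of strings")
        operand = frozenset(str(v) for v in operand)
        if not operand:
            raise FilterConstructionError("in_set needs a non-empty value set")
    elif fdef.is_numeric:
        if isinstance(operand, bool) or not isinstance(operand, (int, float)):
            raise FilterConstructionError(
                f"{category}:{field} is {fdef.type}; operand {operand!r} "
                "must be numeric")
    else:
        if not isinstance(operand, str):
            raise FilterConstructionError(
                f"{category}:{field} is {fdef.type}; operand {operand!r} "
                "must be a string")
        if field == "CHROM":
            operand = normalize_chrom(operand)
    if sample_scope:
        if category != "format":
            raise FilterConstructionError(
                "sample scope is only valid on format filters")
        unknown = [s for s in sample_scope if s not in header.sample_names]
        if unknown:
            raise FilterConstructionError(
                f"unknown samples in scope: {unknown}; header samples: "
                f"{header.sample_names}")
    if isinstance(operand, frozenset) and field == "CHROM":
        operand = frozenset(normalize_chrom(v) for v in operand)
    return Filter(category, field, op, operand, tuple(sample_scope), elementwise)


# ---------------------------------------------------------------------------
# evaluation

def _scalar_passes(value, op: str, operand, fdef: FieldDef) -> bool:
    """Evaluate one non-missing scalar; degraded strings fail numeric tests."""
    if fdef.is_numeric and op in (">", "<", ">=", "<=", "==", "!="):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return False  # coercion-degraded value: not comparable
        if op == ">":
            return value > operand
        if op == "<":
            return value < operand
        if op == ">=":
            return value >= operand
        if op == "<=":
            return value <= operand
        if op == "==":
            return value == operand
        return value != operand
    text = str(value)
    if op == "==":
        return text == operand
    if op == "!=":
        return text != operand
    if op == "in_set":
        return text in operand
    raise FilterConstructionError(f"operator {op!r} unusable here")  # pragma: no cover


def _value_passes(value, filt: Filter, fdef: FieldDef) -> bool:
    missing = value is None or (
        isinstance(value, list) and all(v is None for v in value))
    if filt.op == "is_missing":
        return missing
    if filt.op == "not_missing":
        return not missing
    if filt.op == "present":
        return value is True
    if filt.op == "absent":
        return value is not True
    if missing:
        return False
    elements = value if isinstance(value, list) else [value]
    elements = [v for v in elements if v is not None]
    if not elements:
        return False
    if filt.elementwise == "all":
        return all(_scalar_passes(v, filt.op, filt.operand, fdef)
                   for v in elements)
    return any(_scalar_passes(v, filt.op, filt.operand, fdef)
               for v in elements)


def _gt_passes(raw_gt: Optional[str], op: str) -> bool:
    cls = gt_class(parse_genotype(raw_gt))
    if op == "is_missing":
        return cls == "missing"
    if cls == "missing":
        return False
    if op == "is_hom_ref":
        return cls == "hom_ref"
    if op == "is_het":
        return cls == "het"
    if op == "is_hom_alt":
        return cls == "hom_alt"
    if op == "is_hemi":
        return cls in ("hemi_ref", "hemi_alt")
    return has_alt(parse_genotype(raw_gt))  # has_alt


def _basic_value(rec: VariantRecord, field: str):
    if field == "CHROM":
        return normalize_chrom(rec.chrom)
    if field == "POS":
        return rec.pos
    if field == "ID":
        return rec.id
    if field == "QUAL":
        return rec.qual
    return list(rec.filter) if rec.filter else None  # FILTER members


def record_passes(rec: VariantRecord, filt: Filter, header: HeaderMeta) -> bool:
    """Evaluate one filter on one record."""
    fdef = field_def_for(header, filt.category, filt.field)
    if filt.category == "format":
        scope = filt.sample_scope or tuple(header.sample_names)
        for sample in scope:
            value = rec.samples.get(sample, {}).get(filt.field)
            if filt.field == "GT":
                ok = _gt_passes(value, filt.op)
            else:
                ok = _value_passes(value, filt, fdef)
            if not ok:
                return False
        return True
    if filt.category == "basic":
        value = _basic_value(rec, filt.field)
    else:
        value = rec.info.get(filt.field)
    return _value_passes(value, filt, fdef)


def value_domain(store, field: str) -> List[str]:
    """Distinct observed values of a string-typed field (for select boxes).

    Multi-valued entries contribute their members: FILTER is split on
    semicolons, list-valued INFO fields per element.  CHROM values are
    normalized.
    """
    if field in BASIC_FIELD_DEFS:
        fdef = BASIC_FIELD_DEFS[field]
    elif field in store.header.info_defs:
        fdef = store.header.info_defs[field]
    elif field in store.header.format_defs:
        fdef = store.header.format_defs[field]
    else:
        raise UnknownFieldError(f"unknown field {field!r}")
    if fdef.type not in ("String", "Character"):
        raise WrongTypeError(
            f"value_domain is for string fields; {field!r} is {fdef.type}")
    seen = set()
    for rec in store.records:
        if fdef.source == "BASIC":
            value = _basic_value(rec, field)
        elif fdef.source == "INFO":
            value = rec.info.get(field)
        else:
            value = [s.get(field) for s in rec.samples.values()]
        if value is None:
            continue
        for v in (value if isinstance(value, list) else [value]):
            if v is not None and v is not True:
                seen.add(str(v))
    return sorted(seen)


# ---------------------------------------------------------------------------
# the stack

@dataclass(frozen=True)
class FilterStack:
    """Immutable LIFO stack of filters with survivor sets per level.

    ``push`` narrows the current survivor set; ``pop`` returns the stack as
    it was before the last push.  Survivor sets are strictly nested down the
    stack.
    """

    store: object
    levels: tuple = ()  # tuple of (Filter, frozenset of record ids)

    @property
    def base_ids(self) -> frozenset:
        return frozenset(range(len(self.store.records)))

    @property
    def survivor_ids(self) -> frozenset:
        return self.levels[-1][1] if self.levels else self.base_ids

    @property
    def filters(self) -> Tuple[Filter, ...]:
        return tuple(f for f, _ in self.levels)

    @property
    def counts(self) -> List[int]:
        return [len(ids) for _, ids in self.levels]

    def push(self, filt: Filter) -> "FilterStack":
        header = self.store.header
        survivors = frozenset(
            i for i in self.survivor_ids
            if record_passes(self.store.records[i], filt, header))
        return FilterStack(self.store, self.levels + ((filt, survivors),))

    def pop(self) -> "FilterStack":
        if not self.levels:
            raise StackEmptyError("pop on empty filter stack")
        return FilterStack(self.store, self.levels[:-1])

    def survivors(self) -> List[VariantRecord]:
        """Surviving records in genomic order (normalized chrom, pos, ref, alt)."""
        recs = self.store.records
        order = sorted(self.survivor_ids,
                       key=lambda i: recs[i].sort_key() + (i,))
        return [recs[i] for i in order]

    def survivor_id_order(self) -> List[int]:
        recs = self.store.records
        return sorted(self.survivor_ids,
                      key=lambda i: recs[i].sort_key() + (i,))


def push_filter(stack: FilterStack, filt: Filter) -> Tuple[FilterStack, int]:
    """Push a filter; returns the new stack and the survivor count."""
    new = stack.push(filt)
    return new, len(new.survivor_ids)


def pop_filter(stack: FilterStack) -> FilterStack:
    return stack.pop()


def survivors(stack: FilterStack) -> List[VariantRecord]:
    return stack.survivors()


# ---------------------------------------------------------------------------
# canonical string form

_BARE_TOKEN = re.compile(r"^[A-Za-z0-9_.+\-]+$")
_SPEC_RE = re.compile(
    r"^(?P<cat>basic|info|format):(?P<field>\S+)\s+(?P<op>\S+)"
    r"(?:\s+(?P<rest>.*?))?\s*$")


def _render_operand(operand) -> str:
    if isinstance(operand, frozenset):
        return "{" + ",".join(_render_operand(v) for v in sorted(operand)) + "}"
    if isinstance(operand, bool):
        raise FilterConstructionError("boolean operands are not serializable")
    if isinstance(operand, (int, float)):
        return repr(operand)
    text = str(operand)
    if _BARE_TOKEN.match(text):
        return text
    escaped = text.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def render_filter(filt: Filter) -> str:
    """Canonical single-line form, e.g. ``info:AF < 0.01`` or
    ``format:GT is_het @FATHER,MOTHER``."""
    op = filt.op if filt.elementwise == "any" else "all_" + filt.op
    parts = [f"{filt.category}:{filt.field}", op]
    if filt.operand is not None:
        parts.append(_render_operand(filt.operand))
    if filt.sample_scope:
        parts.append("@" + ",".join(filt.sample_scope))
    return " ".join(parts)


def _parse_operand_token(token: str, fdef: FieldDef):
    if token.startswith("{") and token.endswith("}"):
        return frozenset(_parse_string_token(t)
                         for t in _split_set_members(token[1:-1]))
    if fdef.is_numeric:
        try:
            return int(token)
        except ValueError:
            try:
                return float(token)
            except ValueError:
                raise FilterConstructionError(
                    f"numeric operand expected, got {token!r}")
    return _parse_string_token(token)


def _parse_string_token(token: str) -> str:
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        body, out, i = token[1:-1], [], 0
        while i < len(body):
            if body[i] == "\\" and i + 1 < len(body):
                out.append(body[i + 1])
                i += 2
            else:
                out.append(body[i])
                i += 1
        return "".join(out)
    return token


def _split_set_members(body: str) -> List[str]:
    members, buf, in_quote, i = [], [], False, 0
    while i < len(body):
        ch = body[i]
        if in_quote:
            buf.append(ch)
            if ch == "\\" and i + 1 < len(body):
                buf.append(body[i + 1])
                i += 1
            elif ch == '"':
                in_quote = False
        elif ch == '"':
            buf.append(ch)
            in_quote = True
        elif ch == ",":
            members.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
        i += 1
    if buf:
        members.append("".join(buf))
    return members


def _scope_split_point(text: str) -> Optional[int]:
    """Index of the ``@`` starting a sample scope, ignoring quoted/braced text."""
    in_quote = False
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if in_quote:
            if ch == "\\":
                i += 1
            elif ch == '"':
                in_quote = False
        elif ch == '"':
            in_quote = True
        elif ch == "{":
            depth += 1
        elif ch == "}":
            depth = max(0, depth - 1)
        elif ch == "@" and depth == 0 and (i == 0 or text[i - 1] == " "):
            return i
        i += 1
    return None


def parse_filter_string(text: str, header: HeaderMeta) -> Filter:
    """Parse the canonical filter string form; exact inverse of rendering."""
    m = _SPEC_RE.match(text.strip())
    if m is None:
        raise FilterConstructionError(
            f"cannot parse filter {text!r}; expected "
            "'category:field op [operand] [@sample1,sample2]'")
    category, field, op = m.group("cat"), m.group("field"), m.group("op")
    elementwise = "any"
    if op.startswith("all_"):
        elementwise, op = "all", op[4:]
    rest = m.group("rest") or ""
    scope: tuple = ()
    operand_text = rest.strip()
    at = _scope_split_point(operand_text)
    if at is not None:
        scope = tuple(s for s in operand_text[at + 1:].split(",") if s)
        operand_text = operand_text[:at].strip()
    operand = None
    if operand_text:
        fdef = field_def_for(header, category, field)
        operand = _parse_operand_token(operand_text, fdef)
    return make_filter(header, category, field, op, operand, scope, elementwise)
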