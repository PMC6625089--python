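"""Reading and writing VCF at selectable parse depth.

The VCF header declares, for every INFO and FORMAT key, a cardinality
(``Number``) and a value type (``Integer``/``Float``/``Flag``/``String``/
``Character``).  This module parses those declarations into :class:`FieldDef`
objects and uses them to coerce body values to typed Python objects, so that
downstream filtering can offer the right operators for each field.

Parsing depth is selectable:

* ``L0`` — fixed columns (CHROM, POS, ID, REF, ALT, QUAL, FILTER) plus typed
  INFO; sample columns are skipped entirely.
* ``L1`` — additionally the FORMAT key list.
* ``L2`` — additionally every per-sample value, typed via the FORMAT
  declarations.

FILTER is retained at every level: the single most common query on a fresh
callset ("keep PASS variants") needs it, and dropping it at L0 would make the
cheapest parse unable to answer it.

Missing values ("."), per the format, map to ``None``; flags map to ``True``.
A value that contradicts its declared type (e.g. text under ``Float``) is kept
as the raw string and reported through :class:`~vcfstack.errors.CoercionWarning`
— a miner must never silently drop variants.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import os
import warnings
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

from .errors import (
    CoercionWarning,
    ConsistencyError,
    DuplicateDefinitionError,
    InputError,
    MalformedHeaderError,
    MalformedRecordError,
    UnknownColumnError,
)

logger = logging.getLogger(__name__)

FIXED_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER")

_VALID_TYPES = {"Integer", "Float", "Flag", "String", "Character"}
_VALID_SOURCES = {"INFO", "FORMAT", "BASIC"}


class ParseLevel(str, Enum):
    """How much of each VCF body line is retained."""

    L0 = "L0"
    L1 = "L1"
    L2 = "L2"

    @property
    def rank(self) -> int:
        return {"L0": 0, "L1": 1, "L2": 2}[self.value]

    @classmethod
    def coerce(cls, value: "Union[str, ParseLevel]") -> "ParseLevel":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix and uppercase, for matching.

    Original spellings are always preserved on output; normalization is only
    used when comparing chromosomes across files or against user input.
    """
    c = chrom
    if c[:3].lower() == "chr":
        c = c[3:]
    return c.upper()


@dataclass(frozen=True)
class FieldDef:
    """One ``##INFO``/``##FORMAT`` declaration (or a synthetic basic-column def)."""

    id: str
    source: str  # INFO | FORMAT | BASIC
    number: Union[int, str]  # n>=0, or 'A', 'R', 'G', '.'
    type: str  # Integer | Float | Flag | String | Character
    description: str = ""

    def __post_init__(self) -> None:
        if self.source not in _VALID_SOURCES:
            raise MalformedHeaderError(f"invalid field source {self.source!r}")
        if self.type not in _VALID_TYPES:
            raise MalformedHeaderError(
                f"field {self.id!r}: invalid Type {self.type!r}"
            )
        if isinstance(self.number, int) and self.number < 0:
            raise MalformedHeaderError(f"field {self.id!r}: negative Number")
        if isinstance(self.number, str) and self.number not in {"A", "R", "G", "."}:
            raise MalformedHeaderError(
                f"field {self.id!r}: invalid Number {self.number!r}"
            )
        if self.type == "Flag" and (self.number != 0 or self.source != "INFO"):
            raise MalformedHeaderError(
                f"field {self.id!r}: Flag requires Number=0 and source INFO"
            )

    @property
    def is_scalar(self) -> bool:
        return self.number in (0, 1)

    @property
    def is_numeric(self) -> bool:
        return self.type in ("Integer", "Float")


@dataclass
class HeaderMeta:
    """Parsed VCF header: field declarations, sample names, and raw meta lines."""

    fileformat: str
    info_defs: dict
    format_defs: dict
    sample_names: list
    other_lines: list
    auto_registered: set = dc_field(default_factory=set)

    def get_def(self, source: str, field_id: str) -> Optional[FieldDef]:
        table = self.info_defs if source == "INFO" else self.format_defs
        return table.get(field_id)

    def auto_register(self, source: str, field_id: str) -> FieldDef:
        """Register an undeclared key as free-text (String, Number='.')."""
        table = self.info_defs if source == "INFO" else self.format_defs
        fdef = table.get(field_id)
        if fdef is None:
            fdef = FieldDef(field_id, source, ".", "String",
                            "Auto-registered (undeclared in header)")
            table[field_id] = fdef
            self.auto_registered.add((source, field_id))
        return fdef

    def render_lines(self, provenance: Sequence[str] = ()) -> List[str]:
        """Serialize back to ``##`` meta lines plus the ``#CHROM`` line."""
        lines = [f"##fileformat={self.fileformat}"]
        lines.extend(self.other_lines)
        for fdef in self.info_defs.values():
            lines.append(_render_def(fdef, "INFO"))
        for fdef in self.format_defs.values():
            lines.append(_render_def(fdef, "FORMAT"))
        lines.extend(provenance)
        cols = list(FIXED_COLUMNS) + ["INFO"]
        if self.sample_names:
            cols += ["FORMAT"] + list(self.sample_names)
        lines.append("#" + "\t".join(cols))
        return lines


@dataclass
class VariantRecord:
    """One VCF body line with typed INFO and (at L2) typed sample values."""

    chrom: str
    pos: int
    id: Optional[str]
    ref: str
    alt: list
    qual: Optional[float]
    filter: Optional[list]
    info: dict
    format_keys: list = dc_field(default_factory=list)
    samples: dict = dc_field(default_factory=dict)

    def sort_key(self) -> tuple:
        return (normalize_chrom(self.chrom), self.pos, self.ref, ",".join(self.alt))


# ---------------------------------------------------------------------------
# header parsing

def _split_structured(inner: str) -> List[Tuple[str, str]]:
    """Split ``ID=AF,Number=A,...,Description="a, b"`` respecting quotes."""
    pairs, key, buf, in_quote = [], None, [], False
    i = 0
    while i < len(inner):
        ch = inner[i]
        if in_quote:
            if ch == '\\' and i + 1 < len(inner):
                buf.append(inner[i + 1])
                i += 2
                continue
            if ch == '"':
                in_quote = False
            else:
                buf.append(ch)
        elif ch == '"':
            in_quote = True
        elif ch == "=" and key is None:
            key = "".join(buf)
            buf = []
        elif ch == ",":
            pairs.append((key or "", "".join(buf)))
            key, buf = None, []
        else:
            buf.append(ch)
        i += 1
    if key is not None or buf:
        pairs.append((key or "", "".join(buf)))
    return pairs


def _parse_number(raw: str) -> Union[int, str]:
    if raw in {"A", "R", "G", "."}:
        return raw
    try:
        return int(raw)
    except ValueError:
        raise MalformedHeaderError(f"invalid Number={raw!r} in header line")


def _parse_def_line(line: str, source: str) -> FieldDef:
    lt, gt = line.find("<"), line.rfind(">")
    if lt < 0 or gt < lt:
        raise MalformedHeaderError(f"malformed ##{source} line: {line!r}")
    attrs = dict(_split_structured(line[lt + 1:gt]))
    try:
        return FieldDef(
            id=attrs["ID"],
            source=source,
            number=_parse_number(attrs.get("Number", ".")),
            type=attrs.get("Type", "String"),
            description=attrs.get("Description", ""),
        )
    except KeyError as exc:
        raise MalformedHeaderError(f"##{source} line missing {exc}: {line!r}")


def _render_def(fdef: FieldDef, source: str) -> str:
    desc = fdef.description.replace("\\", "\\\\").replace('"', '\\"')
    return (f"##{source}=<ID={fdef.id},Number={fdef.number},"
            f'Type={fdef.type},Description="{desc}">')


def parse_header(lines: Sequence[str]) -> HeaderMeta:
    """Parse the ``##`` meta lines and the ``#CHROM`` column line.

    Unrecognized ``##`` lines (contigs, FILTER definitions, provenance) are
    preserved verbatim, in order, in ``other_lines``.
    """
    lines = [ln.rstrip("\r\n") for ln in lines]
    if not lines or not lines[0].startswith("##fileformat"):
        raise MalformedHeaderError("header must start with a ##fileformat line")
    fileformat = lines[0].split("=", 1)[1] if "=" in lines[0] else ""
    chrom_lines = [ln for ln in lines if ln.startswith("#CHROM")]
    if not chrom_lines:
        raise MalformedHeaderError("header has no #CHROM column line")
    if len(chrom_lines) > 1:
        raise MalformedHeaderError("header has multiple #CHROM lines")

    info_defs: dict = {}
    format_defs: dict = {}
    other: list = []
    for ln in lines[1:]:
        if ln.startswith("##INFO="):
            fdef = _parse_def_line(ln, "INFO")
            if fdef.id in info_defs:
                raise DuplicateDefinitionError(f"duplicate INFO definition {fdef.id!r}")
            info_defs[fdef.id] = fdef
        elif ln.startswith("##FORMAT="):
            fdef = _parse_def_line(ln, "FORMAT")
            if fdef.id in format_defs:
                raise DuplicateDefinitionError(
                    f"duplicate FORMAT definition {fdef.id!r}")
            format_defs[fdef.id] = fdef
        elif ln.startswith("##"):
            other.append(ln)
        elif ln.startswith("#CHROM"):
            cols = ln.split("\t")
            sample_names = cols[9:] if len(cols) >= 10 else []

    return HeaderMeta(fileformat, info_defs, format_defs, list(sample_names), other)


# ---------------------------------------------------------------------------
# value coercion and record parsing

def coerce_value(raw: str, fdef: FieldDef):
    """Coerce the text after ``KEY=`` according to the field declaration.

    Returns a scalar for Number 0/1 fields, a list otherwise; ``.`` maps to
    ``None`` (elementwise inside lists); a Flag maps to ``True``.  Failures
    under a numeric type warn and keep the raw string.
    """
    if fdef.type == "Flag":
        return True
    if raw == "." or raw == "":
        return None

    def one(tok: str):
        if tok == ".":
            return None
        if fdef.type == "Integer":
            try:
                return int(tok)
            except ValueError:
                pass
        elif fdef.type == "Float":
            try:
                return float(tok)
            except ValueError:
                pass
        else:
            return tok
        warnings.warn(
            f"field {fdef.id!r}: cannot coerce {tok!r} to {fdef.type}; "
            "kept as text", CoercionWarning, stacklevel=3)
        return tok

    if fdef.is_scalar:
        return one(raw)
    return [one(t) for t in raw.split(",")]


def parse_record(line: str, header: HeaderMeta,
                 level: ParseLevel = ParseLevel.L2,
                 lineno: Optional[int] = None) -> VariantRecord:
    """Parse one body line at the given depth, coercing via the header."""
    level = ParseLevel.coerce(level)
    where = f"line {lineno}" if lineno is not None else "record"
    cols = line.rstrip("\r\n").split("\t")
    if len(cols) < 8:
        raise MalformedRecordError(
            f"{where}: expected >=8 tab-separated columns, got {len(cols)}")
    try:
        pos = int(cols[1])
    except ValueError:
        raise MalformedRecordError(f"{where}: POS {cols[1]!r} is not an integer")
    if pos < 1:
        raise MalformedRecordError(f"{where}: POS must be >= 1, got {pos}")

    rec_id = None if cols[2] == "." else cols[2]
    try:
        qual = None if cols[5] == "." else float(cols[5])
    except ValueError:
        raise MalformedRecordError(f"{where}: QUAL {cols[5]!r} is not numeric")
    filt = None if cols[6] == "." else cols[6].split(";")

    info: dict = {}
    if cols[7] != ".":
        for tok in cols[7].split(";"):
            if not tok:
                continue
            if "=" in tok:
                key, val = tok.split("=", 1)
            else:
                key, val = tok, None
            fdef = header.info_defs.get(key)
            if fdef is None:
                fdef = header.auto_register("INFO", key)
            if val is None or fdef.type == "Flag":
                info[key] = True
            else:
                info[key] = coerce_value(val, fdef)

    format_keys: list = []
    samples: dict = {}
    if level.rank >= 1 and len(cols) >= 9 and cols[8] != ".":
        format_keys = cols[8].split(":")
    if level.rank >= 2 and len(cols) >= 10:
        sample_cols = cols[9:]
        if len(sample_cols) > len(header.sample_names):
            raise MalformedRecordError(
                f"{where}: {len(sample_cols)} sample columns but header "
                f"declares {len(header.sample_names)} samples")
        for name, col in zip(header.sample_names, sample_cols):
            values = col.split(":")
            data: dict = {}
            for i, key in enumerate(format_keys):
                fdef = header.format_defs.get(key)
                if fdef is None:
                    fdef = header.auto_register("FORMAT", key)
                if i >= len(values):  # trailing fields may be dropped
                    data[key] = None
                elif key == "GT":
                    data[key] = None if values[i] in (".", "") else values[i]
                else:
                    data[key] = coerce_value(values[i], fdef)
            samples[name] = data

    return VariantRecord(cols[0], pos, rec_id, cols[3], cols[4].split(","),
                         qual, filt, info, format_keys, samples)


# ---------------------------------------------------------------------------
# file reading

def _open_text(path) -> IO[str]:
    """Open plain or gzip text; gzip is detected by magic bytes, not extension."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def read_vcf(path, level: Union[str, ParseLevel] = ParseLevel.L2
             ) -> Tuple[HeaderMeta, Iterator[VariantRecord]]:
    """Read a VCF (plain or gzip), returning the header and a record stream.

    The header is parsed eagerly; records stream lazily in file order.  Each
    undeclared INFO/FORMAT key is auto-registered and logged once.
    """
    level = ParseLevel.coerce(level)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        fh = _open_text(path)
        header_lines: list = []
        for line in fh:
            header_lines.append(line)
            if line.startswith("#CHROM"):
                break
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}")
    if not header_lines:
        raise InputError(f"empty file: {path}")
    header = parse_header(header_lines)

    def stream() -> Iterator[VariantRecord]:
        seen = set(header.auto_registered)
        lineno = len(header_lines)
        try:
            for raw_line in fh:
                lineno += 1
                if not raw_line.strip():
                    continue
                rec = parse_record(raw_line, header, level, lineno)
                for key in header.auto_registered - seen:
                    logger.info("auto-registered undeclared %s key %r as "
                                "String (Number='.')", key[0], key[1])
                    seen.add(key)
                yield rec
        finally:
            fh.close()

    return header, stream()


# ---------------------------------------------------------------------------
# serialization

def format_scalar(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value) if value != int(value) else f"{value:g}"
    return str(value)


def _format_info_value(value) -> str:
    if isinstance(value, (list, tuple)):
        return ",".join(format_scalar(v) for v in value)
    return format_scalar(value)


def _format_qual(qual: Optional[float]) -> str:
    if qual is None:
        return "."
    if qual == int(qual):
        return f"{qual:g}"
    return repr(qual)


def render_record(rec: VariantRecord, header: HeaderMeta) -> str:
    """Serialize one record back to a VCF body line."""
    info_parts = []
    for key, value in rec.info.items():
        if value is True:  # flag / bare-key presence marker
            info_parts.append(key)
        else:
            info_parts.append(f"{key}={_format_info_value(value)}")
    cols = [
        rec.chrom,
        str(rec.pos),
        rec.id if rec.id is not None else ".",
        rec.ref,
        ",".join(rec.alt),
        _format_qual(rec.qual),
        ";".join(rec.filter) if rec.filter else ".",
        ";".join(info_parts) if info_parts else ".",
    ]
    if rec.format_keys:
        cols.append(":".join(rec.format_keys))
        for name in header.sample_names:
            data = rec.samples.get(name)
            if data is None:
                cols.append(".")
                continue
            vals = []
            for key in rec.format_keys:
                v = data.get(key)
                vals.append(_format_info_value(v) if v is not None else ".")
            cols.append(":".join(vals))
    return "\t".join(cols)


def write_vcf(header: HeaderMeta, records: Iterable[VariantRecord], path,
              provenance: Sequence[str] = ()) -> int:
    """Write a VCF (gzip when the path ends in .gz); returns records written.

    ``provenance`` strings are emitted verbatim as ``##`` lines just before
    the ``#CHROM`` line.  Output is deterministic (gzip mtime pinned to 0).
    """
    known = set(header.sample_names)
    out: IO[str]
    if str(path).endswith(".gz"):
        raw = open(path, "wb")
        out = io.TextIOWrapper(
            gzip.GzipFile(fileobj=raw, mode="wb", mtime=0), encoding="utf-8")
    else:
        out = open(path, "w", encoding="utf-8", newline="\n")
    count = 0
    with out:
        for line in header.render_lines(provenance):
            out.write(line + "\n")
        for rec in records:
            extra = set(rec.samples) - known
            if extra:
                raise ConsistencyError(
                    f"record {rec.chrom}:{rec.pos} references samples absent "
                    f"from header: {sorted(extra)}")
            out.write(render_record(rec, header) + "\n")
            count += 1
    return count


# ---------------------------------------------------------------------------
# tabular export

def _column_getter(spec: str, header: HeaderMeta):
    if spec in FIXED_COLUMNS:
        def fixed(rec, s=spec):
            if s == "CHROM":
                return rec.chrom
            if s == "POS":
                return rec.pos
            if s == "ID":
                return rec.id
            if s == "REF":
                return rec.ref
            if s == "ALT":
                return ",".join(rec.alt)
            if s == "QUAL":
                return rec.qual
            return ";".join(rec.filter) if rec.filter else None
        return fixed
    if spec in header.info_defs:
        return lambda rec, s=spec: rec.info.get(s)
    if "." in spec:
        sample, key = spec.split(".", 1)
        if sample in header.sample_names and key in header.format_defs:
            return lambda rec, s=sample, k=key: rec.samples.get(s, {}).get(k)
    valid = (list(FIXED_COLUMNS) + sorted(header.info_defs)
             + [f"<SAMPLE>.{k}" for k in sorted(header.format_defs)])
    raise UnknownColumnError(
        f"unknown column {spec!r}; valid columns: {', '.join(valid)}")


def _cell(value) -> str:
    if value is None:
        return "."
    if value is True:
        return "1"
    if isinstance(value, (list, tuple)):
        return ",".join(format_scalar(v) for v in value)
    return format_scalar(value)


def write_table(header: HeaderMeta, records: Iterable[VariantRecord],
                columns: Sequence[str], path, dialect: str = "CSV") -> int:
    """Export records to CSV (RFC-4180 quoting) or TSV; returns data rows written.

    Column specs name a fixed column, an INFO key, or ``SAMPLE.FORMATKEY``.
    List values are joined with commas; missing renders as ``.``.  In TSV a
    literal tab inside a value is replaced with a space (with a warning).
    """
    dialect = dialect.upper()
    if dialect not in ("CSV", "TSV"):
        raise InputError(f"unknown table dialect {dialect!r}")
    getters = [(spec, _column_getter(spec, header)) for spec in columns]
    rows = 0
    with open(path, "w", encoding="utf-8", newline="") as out:
        if dialect == "CSV":
            writer = csv.writer(out, lineterminator="\n")
            writer.writerow([spec for spec, _ in getters])
            for rec in records:
                writer.writerow([_cell(g(rec)) for _, g in getters])
                rows += 1
        else:
            def tsv_safe(text: str) -> str:
                if "\t" in text:
                    warnings.warn("tab inside TSV value replaced with space",
                                  UserWarning, stacklevel=2)
                    return text.replace("\t", " ")
                return text
            out.write("\t".join(spec for spec, _ in getters) + "\n")
            for rec in records:
                out.write("\t".join(tsv_safe(_cell(g(rec)))
                                    for _, g in getters) + "\n")
                rows += 1
    return rows
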