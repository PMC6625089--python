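"""In-memory variant store with optional per-field indexes and persistence.

The store is a contract, not a database: records keep dense 0-based ids in
insertion order, and any query answered through an index must equal the same
query by full scan.  The default index set covers the fields most queries
touch on a fresh callset: the CHROM+POS composite, ID, the REF+ALT
composite, QUAL, and FILTER; any fixed column or declared INFO key can be
indexed on demand.

The engine has no query planner beyond "use an index if present, else
scan".  A store can be persisted to a single versioned JSON file (gzip when
the path ends in .gz) so a CLI session can load once and filter many times.
"""

from __future__ import annotations

import bisect
import gzip
import json
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .errors import InputError, UnknownFieldError
from .filters import Filter, make_filter, record_passes
from .vcfio import (
    FIXED_COLUMNS,
    FieldDef,
    HeaderMeta,
    VariantRecord,
    normalize_chrom,
)

STORE_FORMAT_VERSION = 1

DEFAULT_INDEX_FIELDS = ("CHROM+POS", "ID", "REF+ALT", "QUAL", "FILTER")

_COMPOSITES = {"CHROM+POS", "REF+ALT"}

FLAG_PRESENT = "present"  # index key used for flag-typed fields


@dataclass
class Index:
    """Sorted value -> ascending record-id lists for one field (or composite)."""

    field_spec: str
    entries: Dict[object, List[int]] = dc_field(default_factory=dict)

    def sorted_keys(self) -> list:
        return sorted(self.entries)

    def ids_for(self, key) -> List[int]:
        return self.entries.get(key, [])

    def ids_in_key_range(self, lo, hi, lo_incl=True, hi_incl=True) -> List[int]:
        """Union of id lists over keys in [lo, hi]; keys must be orderable."""
        keys = self.sorted_keys()
        left = bisect.bisect_left(keys, lo) if lo_incl else bisect.bisect_right(keys, lo)
        right = bisect.bisect_right(keys, hi) if hi_incl else bisect.bisect_left(keys, hi)
        out: set = set()
        for k in keys[left:right]:
            out.update(self.entries[k])
        return sorted(out)


class VariantStore:
    """Ordered record collection with stable integer ids and optional indexes."""

    def __init__(self, header: HeaderMeta, records: Iterable[VariantRecord]):
        self.header = header
        self.records: List[VariantRecord] = list(records)
        self.indexes: Dict[str, Index] = {}

    @classmethod
    def load(cls, header: HeaderMeta,
             records: Iterable[VariantRecord]) -> "VariantStore":
        return cls(header, records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # -- indexing -----------------------------------------------------------

    def _index_keys(self, rec: VariantRecord, field: str) -> list:
        if field == "CHROM+POS":
            return [(normalize_chrom(rec.chrom), rec.pos)]
        if field == "REF+ALT":
            return [(rec.ref, ",".join(rec.alt))]
        if field == "CHROM":
            return [normalize_chrom(rec.chrom)]
        if field == "POS":
            return [rec.pos]
        if field == "ID":
            return [] if rec.id is None else [rec.id]
        if field == "QUAL":
            return [] if rec.qual is None else [rec.qual]
        if field == "FILTER":
            return list(rec.filter) if rec.filter else []
        value = rec.info.get(field)
        if value is None:
            return []
        if value is True:
            return [FLAG_PRESENT]
        if isinstance(value, list):
            return [v for v in value if v is not None]
        return [value]

    def build_index(self, field: str) -> Index:
        """Build (or rebuild) an index on a fixed column, composite, or INFO key."""
        if field not in _COMPOSITES and field not in FIXED_COLUMNS \
                and field not in self.header.info_defs:
            known = sorted(_COMPOSITES) + list(FIXED_COLUMNS) \
                + sorted(self.header.info_defs)
            raise UnknownFieldError(
                f"cannot index unknown field {field!r}; known fields: "
                f"{', '.join(known)}")
        idx = Index(field)
        for i, rec in enumerate(self.records):
            for key in self._index_keys(rec, field):
                idx.entries.setdefault(key, []).append(i)
        self.indexes[field] = idx
        return idx

    def build_default_indexes(self) -> "VariantStore":
        """Build the five default indexes (idempotent)."""
        for field in DEFAULT_INDEX_FIELDS:
            self.build_index(field)
        return self

    # -- queries ------------------------------------------------------------

    def query(self, category: str, field: str, op: str, operand=None,
              **kwargs) -> List[int]:
        """Record ids satisfying one predicate; uses an index when it can.

        Results are always identical to a full scan; the index is a pure
        speedup for equality, numeric ranges and flag presence.
        """
        filt = make_filter(self.header, category, field, op, operand, **kwargs)
        idx = self.indexes.get(field)
        ids = self._query_via_index(idx, filt) if idx is not None else None
        if ids is None:
            ids = [i for i, rec in enumerate(self.records)
                   if record_passes(rec, filt, self.header)]
        return ids

    def _query_via_index(self, idx: Index, filt: Filter) -> Optional[List[int]]:
        if filt.category == "format" or filt.elementwise != "any":
            return None
        op, operand = filt.op, filt.operand
        if op == "present":
            return list(idx.ids_for(FLAG_PRESENT))
        if op == "==" and not isinstance(operand, frozenset):
            return list(idx.ids_for(operand))
        if op == "in_set" and isinstance(operand, frozenset):
            out: set = set()
            for member in operand:
                out.update(idx.ids_for(member))
            return sorted(out)
        if op in (">", ">=", "<", "<=") and isinstance(operand, (int, float)):
            numeric = [k for k in idx.entries
                       if isinstance(k, (int, float)) and not isinstance(k, bool)]
            if len(numeric) != len(idx.entries):
                return None  # degraded values present; fall back to scan
            if op in (">", ">="):
                lo, hi = operand, float("inf")
                return idx.ids_in_key_range(lo, hi, lo_incl=(op == ">="))
            lo, hi = float("-inf"), operand
            return idx.ids_in_key_range(lo, hi, hi_incl=(op == "<="))
        return None  # absent/!=/missing-ops need the missing records: scan

    def query_region(self, chrom: str, start: int, end: int) -> List[int]:
        """Ids of records with ``start <= pos <= end`` on a chromosome.

        Coordinates are 1-based and inclusive on both ends; chromosome
        matching is normalized (``chr1`` matches ``1``).
        """
        if start > end:
            raise ValueError(f"query_region: start {start} > end {end}")
        target = normalize_chrom(chrom)
        idx = self.indexes.get("CHROM+POS")
        if idx is not None:
            return idx.ids_in_key_range((target, start), (target, end))
        return [i for i, rec in enumerate(self.records)
                if normalize_chrom(rec.chrom) == target
                and start <= rec.pos <= end]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist header + records (not indexes) to a versioned JSON file."""
        payload = {
            "format": "vcfstack-store",
            "version": STORE_FORMAT_VERSION,
            "header": _header_to_dict(self.header),
            "records": [_record_to_dict(r) for r in self.records],
        }
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_file(cls, path) -> "VariantStore":
        opener = gzip.open if str(path).endswith(".gz") else open
        try:
            with opener(path, "rt", encoding="utf-8") as fh:
                payload = json.load(fh)
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read store file {path}: {exc}")
        if payload.get("format") != "vcfstack-store":
            raise InputError(f"{path} is not a vcfstack store file")
        header = _header_from_dict(payload["header"])
        records = [_record_from_dict(d) for d in payload["records"]]
        return cls(header, records)


# ---------------------------------------------------------------------------
# JSON (de)serialization helpers

def _def_to_dict(fdef: FieldDef) -> dict:
    return {"id": fdef.id, "source": fdef.source, "number": fdef.number,
            "type": fdef.type, "description": fdef.description}


def _def_from_dict(d: dict) -> FieldDef:
    return FieldDef(d["id"], d["source"], d["number"], d["type"],
                    d.get("description", ""))


def _header_to_dict(header: HeaderMeta) -> dict:
    return {
        "fileformat": header.fileformat,
        "info_defs": [_def_to_dict(f) for f in header.info_defs.values()],
        "format_defs": [_def_to_dict(f) for f in header.format_defs.values()],
        "sample_names": list(header.sample_names),
        "other_lines": list(header.other_lines),
        "auto_registered": sorted(list(t) for t in header.auto_registered),
    }


def _header_from_dict(d: dict) -> HeaderMeta:
    return HeaderMeta(
        fileformat=d["fileformat"],
        info_defs={f["id"]: _def_from_dict(f) for f in d["info_defs"]},
        format_defs={f["id"]: _def_from_dict(f) for f in d["format_defs"]},
        sample_names=list(d["sample_names"]),
        other_lines=list(d["other_lines"]),
        auto_registered={tuple(t) for t in d.get("auto_registered", [])},
    )


def _record_to_dict(rec: VariantRecord) -> dict:
    return {
        "chrom": rec.chrom, "pos": rec.pos, "id": rec.id, "ref": rec.ref,
        "alt": rec.alt, "qual": rec.qual, "filter": rec.filter,
        "info": rec.info, "format_keys": rec.format_keys,
        "samples": rec.samples,
    }


def _record_from_dict(d: dict) -> VariantRecord:
    return VariantRecord(
        d["chrom"], d["pos"], d["id"], d["ref"], list(d["alt"]), d["qual"],
        d["filter"], d["info"], d.get("format_keys", []), d.get("samples", {}))
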