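"""Reading, writing and validation of curated AOP tables.

The canonical schema is one KER per row per AOP:

    aop_id, upstream_title, upstream_type, downstream_title,
    downstream_type, adjacency, woe

with optional columns ``aop_title``, ``oecd_status``, ``upstream_wiki_id``
and ``downstream_wiki_id``. Other layouts are supported through a
column-mapping dict (canonical name -> actual column name). Both CSV
(UTF-8, comma, header row) and XLSX (first worksheet by default) dialects
are read with pandas.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    AOPCollection,
    AOPRecord,
    HarmonisationError,
    HarmonisationMap,
    KeyEvent,
    KeyEventRelationship,
    Role,
    SchemaError,
    ValidationError,
    merge_role,
    normalise_title,
    parse_adjacency,
    parse_role,
    parse_woe,
)

MANDATORY_COLUMNS: tuple[str, ...] = (
    "aop_id",
    "upstream_title",
    "upstream_type",
    "downstream_title",
    "downstream_type",
    "adjacency",
    "woe",
)

OPTIONAL_COLUMNS: tuple[str, ...] = (
    "aop_title",
    "oecd_status",
    "upstream_wiki_id",
    "downstream_wiki_id",
)


def _load_frame(path: str | Path, dialect: str | None, sheet: int | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if dialect == "xlsx":
        frame = pd.read_excel(path, sheet_name=sheet, dtype=str, keep_default_na=False)
    elif dialect == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        raise SchemaError(f"unknown dialect {dialect!r} (expected 'csv' or 'xlsx')")
    return frame


def read_aop_tables(
    path: str | Path,
    dialect: str | None = None,
    sheet: int | str = 0,
    column_map: Mapping[str, str] | None = None,
) -> AOPCollection:
    """Read a curated KER table into an :class:`AOPCollection`.

    Parameters
    ----------
    path:
        CSV or XLSX file in the canonical schema (or mappable onto it).
    dialect:
        ``"csv"`` or ``"xlsx"``; inferred from the suffix when omitted.
    sheet:
        Worksheet index or name for the XLSX dialect.
    column_map:
        Mapping from canonical column names to the file's actual column
        names, for tables using a different header vocabulary.

    Row order within an AOP is preserved as the KER order of its record.
    Blank WoE cells become ``unspecified``. Duplicate rows for the same
    (AOP, upstream, downstream) triple are rejected when they disagree on
    adjacency; otherwise the first row wins.
    """
    frame = _load_frame(path, dialect, sheet)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    frame = frame.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: dict[int, AOPRecord] = {}
    key_events: dict[str, KeyEvent] = {}
    seen_pairs: dict[tuple[int, str, str], tuple[int, KeyEventRelationship]] = {}
    conflicts: list[str] = []

    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based with header row
        raw_id = str(row["aop_id"]).strip()
        try:
            aop_id = int(float(raw_id))
        except ValueError:
            raise SchemaError(f"row {rownum}: aop_id {raw_id!r} is not an integer") from None

        up = normalise_title(row["upstream_title"])
        down = normalise_title(row["downstream_title"])
        if not up or not down:
            raise SchemaError(f"row {rownum}: blank KE title")
        up_role = parse_role(row["upstream_type"])
        down_role = parse_role(row["downstream_type"])
        adjacency = parse_adjacency(row["adjacency"])
        woe = parse_woe(row["woe"])

        record = records.get(aop_id)
        if record is None:
            record = AOPRecord(aop_id=aop_id)
            records[aop_id] = record
        if "aop_title" in frame.columns and not record.title:
            record.title = str(row["aop_title"]).strip()
        if "oecd_status" in frame.columns and not record.oecd_status:
            record.oecd_status = str(row["oecd_status"]).strip()

        key = (aop_id, up, down)
        prev = seen_pairs.get(key)
        if prev is not None:
            prev_row, prev_ker = prev
            if prev_ker.adjacency != adjacency:
                conflicts.append(
                    f"AOP {aop_id}: rows {prev_row} and {rownum} report "
                    f"{up!r} -> {down!r} with contradictory adjacency"
                )
            continue  # duplicate report of the same pair: first row wins

        ker = KeyEventRelationship(
            upstream=up,
            downstream=down,
            adjacency=adjacency,
            woe=woe,
            aop_ids=frozenset({aop_id}),
        )
        seen_pairs[key] = (rownum, ker)
        record.kers.append(ker)

        for title, role, id_col in (
            (up, up_role, "upstream_wiki_id"),
            (down, down_role, "downstream_wiki_id"),
        ):
            ke = key_events.get(title)
            if ke is None:
                ke = KeyEvent(canonical_title=title)
                key_events[title] = ke
            ke.type_profile[aop_id] = merge_role(ke.type_profile.get(aop_id), role)
            if id_col in frame.columns:
                raw_wiki = str(row[id_col]).strip()
                if raw_wiki:
                    try:
                        ke.wiki_ids.add(int(float(raw_wiki)))
                    except ValueError:
                        raise SchemaError(
                            f"row {rownum}: {id_col} {raw_wiki!r} is not an integer"
                        ) from None

    if conflicts:
        raise ValidationError("contradictory duplicate KER rows:\n" + "\n".join(conflicts))
    if not records:
        raise ValidationError(f"no KER rows found in {path}")

    for record in records.values():
        for ker in record.kers:
            for title in ker.pair:
                role = key_events[title].type_profile[record.aop_id]
                if role is Role.MIE:
                    record.mies.add(title)
                elif role is Role.AO:
                    record.aos.add(title)

    ordered = [records[i] for i in sorted(records)]
    return AOPCollection(records=ordered, key_events=key_events)


def write_aop_tables(collection: AOPCollection, path: str | Path) -> None:
    """Write a collection in the canonical CSV schema (round-trip safe)."""
    path = Path(path)
    columns = list(MANDATORY_COLUMNS) + ["aop_title", "oecd_status"]
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for record in collection.records:
            for ker in record.kers:
                up_role = collection.key_events[ker.upstream].type_profile[record.aop_id]
                down_role = collection.key_events[ker.downstream].type_profile[record.aop_id]
                writer.writerow(
                    [
                        record.aop_id,
                        ker.upstream,
                        up_role.value,
                        ker.downstream,
                        down_role.value,
                        ker.adjacency.value,
                        ker.woe.value,
                        record.title,
                        record.oecd_status,
                    ]
                )


def read_harmonisation_map(path: str | Path) -> HarmonisationMap:
    """Read a two-column CSV (raw_title, canonical_title)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError("harmonisation map needs two columns: raw_title, canonical_title")
    raw_col, canon_col = frame.columns[:2]
    entries = {
        normalise_title(r): normalise_title(c)
        for r, c in zip(frame[raw_col], frame[canon_col])
        if normalise_title(r)
    }
    return HarmonisationMap(entries=entries)


def apply_harmonisation(
    collection: AOPCollection, hmap: HarmonisationMap
) -> AOPCollection:
    """Rewrite all KE references to canonical titles, pooling merged events.

    The multiset of (AOP, upstream, downstream) triples is preserved up to
    title rewriting: no KER is created or lost. Pooled key events union
    their aliases, wiki ids and per-AOP roles. Applying the same map twice
    is a no-op the second time.
    """
    new_records: list[AOPRecord] = []
    new_events: dict[str, KeyEvent] = {}

    for record in collection.records:
        new_kers: list[KeyEventRelationship] = []
        for ker in record.kers:
            up = hmap.resolve(ker.upstream)
            down = hmap.resolve(ker.downstream)
            if up == down:
                raise HarmonisationError(
                    f"AOP {record.aop_id}: harmonising KER "
                    f"{ker.upstream!r} -> {ker.downstream!r} collapses both endpoints "
                    f"into {up!r} (would create a self-loop)"
                )
            new_kers.append(
                KeyEventRelationship(
                    upstream=up,
                    downstream=down,
                    adjacency=ker.adjacency,
                    woe=ker.woe,
                    aop_ids=ker.aop_ids,
                )
            )
        new_records.append(
            AOPRecord(
                aop_id=record.aop_id,
                title=record.title,
                kers=new_kers,
                mies={hmap.resolve(t) for t in record.mies},
                aos={hmap.resolve(t) for t in record.aos},
                oecd_status=record.oecd_status,
            )
        )

    for title, ke in collection.key_events.items():
        canonical = hmap.resolve(title)
        pooled = new_events.get(canonical)
        if pooled is None:
            pooled = KeyEvent(canonical_title=canonical)
            new_events[canonical] = pooled
        pooled.aliases |= ke.aliases | {title}
        pooled.wiki_ids |= ke.wiki_ids
        for aop_id, role in ke.type_profile.items():
            pooled.type_profile[aop_id] = merge_role(pooled.type_profile.get(aop_id), role)

    return AOPCollection(records=new_records, key_events=new_events)


@dataclass
class Finding:
    code: str
    message: str

    def as_dict(self) -> dict[str, str]:
        return {"code": self.code, "message": self.message}


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_collection`; empty iff build-ready."""

    findings: list[Finding] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.findings

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def to_text(self) -> str:
        if self.is_empty:
            return "collection is build-ready: no findings\n"
        lines = [f"{f.code}: {f.message}" for f in self.findings]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({"findings": [f.as_dict() for f in self.findings]}, indent=2)


def validate_collection(
    collection: AOPCollection,
    hmap: HarmonisationMap | None = None,
) -> ValidationReport:
    """Structural audit of a collection prior to network construction.

    Reported findings: dangling KE references, AOPs lacking an MIE or AO,
    contradictory duplicate KERs, self-loop KERs, and (when a map is
    supplied) harmonisation keys that matched nothing.
    """
    findings: list[Finding] = []
    known = set(collection.key_events)

    for record in collection.records:
        for title in sorted(record.titles - known):
            findings.append(
                Finding(
                    "dangling_reference",
                    f"AOP {record.aop_id} references unknown KE {title!r}",
                )
            )
        if not record.mies:
            findings.append(Finding("aop_without_mie", f"AOP {record.aop_id} has no MIE"))
        if not record.aos:
            findings.append(Finding("aop_without_ao", f"AOP {record.aop_id} has no AO"))
        seen: dict[tuple[str, str], KeyEventRelationship] = {}
        for ker in record.kers:
            if ker.upstream == ker.downstream:
                findings.append(
                    Finding(
                        "self_loop",
                        f"AOP {record.aop_id} reports self-loop KER on {ker.upstream!r}",
                    )
                )
            prev = seen.get(ker.pair)
            if prev is not None and prev.adjacency != ker.adjacency:
                findings.append(
                    Finding(
                        "contradictory_duplicate",
                        f"AOP {record.aop_id} reports {ker.upstream!r} -> "
                        f"{ker.downstream!r} with contradictory adjacency",
                    )
                )
            seen.setdefault(ker.pair, ker)

    if hmap is not None:
        all_titles: set[str] = set()
        for ke in collection.key_events.values():
            all_titles |= ke.aliases
            all_titles.add(ke.canonical_title)
        for record in collection.records:
            all_titles |= record.titles
        for raw, canonical in sorted(hmap.entries.items()):
            if raw != canonical and raw not in all_titles:
                findings.append(
                    Finding(
                        "unused_harmonisation_key",
                        f"harmonisation key {raw!r} matched no title in the collection",
                    )
                )

    return ValidationReport(findings=findings)
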