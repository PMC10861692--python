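"""Domain model for adverse outcome pathway (AOP) collections.

An AOP is a linear chain of causally linked biological events: a molecular
initiating event (MIE) followed by intermediate key events (KEs) and a
terminal adverse outcome (AO). Directed links between events are key event
relationships (KERs), annotated with adjacency (direct vs indirect) and a
qualitative weight of evidence (WoE). Collections of curated AOPs are the
input to network derivation; nodes are identified solely by their canonical
title after harmonisation.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class AopnetError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(AopnetError):
    """Input table does not conform to the expected column schema."""


class ValidationError(AopnetError):
    """A collection violates a structural constraint."""


class HarmonisationError(AopnetError):
    """A harmonisation map is ill-formed or its application is unsafe."""


class BuildError(AopnetError):
    """Network construction cannot proceed."""


class GenerationError(AopnetError):
    """A synthetic-collection configuration is infeasible."""


class PathExplosionError(AopnetError):
    """Simple-path enumeration exceeded the configured guard."""


class Role(str, Enum):
    """Role of a key event within one AOP."""

    MIE = "MIE"
    KE = "KE"
    AO = "AO"


class Adjacency(str, Enum):
    """Whether a KER links directly (adjacent) or indirectly (nonadjacent)."""

    ADJACENT = "adjacent"
    NONADJACENT = "nonadjacent"


class Woe(str, Enum):
    """Developer-assigned qualitative weight of evidence for a KER."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    UNSPECIFIED = "unspecified"


#: Evidence ordering used when collapsing parallel KER reports onto one edge.
WOE_RANK: dict[Woe, int] = {
    Woe.HIGH: 3,
    Woe.MEDIUM: 2,
    Woe.LOW: 1,
    Woe.UNSPECIFIED: 0,
}

_WOE_ALIASES = {
    "h": Woe.HIGH,
    "high": Woe.HIGH,
    "m": Woe.MEDIUM,
    "medium": Woe.MEDIUM,
    "moderate": Woe.MEDIUM,
    "l": Woe.LOW,
    "low": Woe.LOW,
    "": Woe.UNSPECIFIED,
    "unspecified": Woe.UNSPECIFIED,
    "n/a": Woe.UNSPECIFIED,
    "na": Woe.UNSPECIFIED,
}

_ROLE_ALIASES = {
    "mie": Role.MIE,
    "ke": Role.KE,
    "ao": Role.AO,
}

_ADJ_ALIASES = {
    "adjacent": Adjacency.ADJACENT,
    "direct": Adjacency.ADJACENT,
    "nonadjacent": Adjacency.NONADJACENT,
    "non-adjacent": Adjacency.NONADJACENT,
    "indirect": Adjacency.NONADJACENT,
}


def normalise_title(raw: str) -> str:
    """Canonicalise a KE title: Unicode NFC plus leading/trailing trim.

    Matching is exact-string after this normalisation; no fuzzy pooling is
    ever attempted (synonym pooling is the curator's job, expressed through
    an explicit harmonisation map).
    """
    return unicodedata.normalize("NFC", str(raw)).strip()


def parse_woe(raw: object) -> Woe:
    """Parse a WoE cell; both letters (H/M/L) and words are accepted.

    Blank cells mean the developer left the field unfilled and map to
    ``unspecified``.
    """
    if raw is None:
        return Woe.UNSPECIFIED
    key = str(raw).strip().lower()
    if key in ("nan", "none"):
        return Woe.UNSPECIFIED
    try:
        return _WOE_ALIASES[key]
    except KeyError:
        raise SchemaError(f"unrecognised weight-of-evidence value: {raw!r}") from None


def parse_role(raw: object) -> Role:
    key = str(raw).strip().lower()
    try:
        return _ROLE_ALIASES[key]
    except KeyError:
        raise SchemaError(f"unrecognised KE type: {raw!r} (expected MIE, KE or AO)") from None


def parse_adjacency(raw: object) -> Adjacency:
    key = str(raw).strip().lower()
    try:
        return _ADJ_ALIASES[key]
    except KeyError:
        raise SchemaError(
            f"unrecognised adjacency value: {raw!r} (expected adjacent or nonadjacent)"
        ) from None


@dataclass
class KeyEvent:
    """A harmonised network node.

    The canonical title is the sole node identity. Wiki ids are retained as
    metadata only; the curation workflow may pool several wiki entries into
    one event, so ids can never serve as merge keys. A key event may hold
    different roles in different AOPs (e.g. an MIE in one pathway and an
    interior KE in another), hence the per-AOP ``type_profile``.
    """

    canonical_title: str
    aliases: set[str] = field(default_factory=set)
    wiki_ids: set[int] = field(default_factory=set)
    type_profile: dict[int, Role] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.canonical_title:
            raise ValidationError("key event with empty canonical title")
        self.aliases.add(self.canonical_title)

    @property
    def aop_ids(self) -> set[int]:
        return set(self.type_profile)

    @property
    def roles(self) -> set[Role]:
        return set(self.type_profile.values())


@dataclass
class KeyEventRelationship:
    """A directed causal link upstream -> downstream, with its annotations."""

    upstream: str
    downstream: str
    adjacency: Adjacency = Adjacency.ADJACENT
    woe: Woe = Woe.UNSPECIFIED
    aop_ids: frozenset[int] = frozenset()

    @property
    def pair(self) -> tuple[str, str]:
        return (self.upstream, self.downstream)


@dataclass
class AOPRecord:
    """One curated linear pathway: its ordered KERs and designated endpoints."""

    aop_id: int
    title: str = ""
    kers: list[KeyEventRelationship] = field(default_factory=list)
    mies: set[str] = field(default_factory=set)
    aos: set[str] = field(default_factory=set)
    oecd_status: str = ""

    @property
    def titles(self) -> set[str]:
        out = set(self.mies) | set(self.aos)
        for ker in self.kers:
            out.add(ker.upstream)
            out.add(ker.downstream)
        return out


@dataclass
class AOPCollection:
    """A set of AOP records plus the pooled key-event table they reference."""

    records: list[AOPRecord] = field(default_factory=list)
    key_events: dict[str, KeyEvent] = field(default_factory=dict)

    @property
    def aop_ids(self) -> set[int]:
        return {r.aop_id for r in self.records}

    def record(self, aop_id: int) -> AOPRecord:
        for r in self.records:
            if r.aop_id == aop_id:
                return r
        raise LookupError(f"no AOP with id {aop_id} in collection")


@dataclass(frozen=True)
class HarmonisationMap:
    """Explicit raw-title -> canonical-title pooling map.

    The map must be idempotent: canonical titles map to themselves (or do
    not appear as keys), and no key's target is itself remapped. Chains such
    as a -> b, b -> c are rejected because applying them once vs twice would
    give different collections.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        entries = {normalise_title(k): normalise_title(v) for k, v in self.entries.items()}
        object.__setattr__(self, "entries", entries)
        for raw, canonical in entries.items():
            if not raw or not canonical:
                raise HarmonisationError("harmonisation entries must be non-empty titles")
            target = entries.get(canonical, canonical)
            if target != canonical:
                raise HarmonisationError(
                    f"harmonisation chain: {raw!r} -> {canonical!r} -> {target!r}"
                )

    def resolve(self, title: str) -> str:
        title = normalise_title(title)
        return self.entries.get(title, title)

    @classmethod
    def identity(cls) -> "HarmonisationMap":
        return cls(entries={})


def merge_role(existing: Role | None, new: Role) -> Role:
    """Resolve the role of a pooled node within a single AOP.

    When harmonisation pools two events that held different roles in the
    same pathway, the endpoint roles win over the interior role (an event
    that is anywhere recorded as the pathway's MIE or AO keeps that status).
    """
    if existing is None or existing == new:
        return new
    priority = {Role.MIE: 2, Role.AO: 1, Role.KE: 0}
    return existing if priority[existing] >= priority[new] else new
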