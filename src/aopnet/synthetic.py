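"""Seeded generation of synthetic AOP collections, plus packaged fixtures.

The generator emulates the structure of curated nephrotoxicity pathway
collections: a modest number of mostly-linear AOPs (3-8 events each), a
minority of key events shared across pathways, occasional whole-KER
sharing, sporadic feedback loops, mixed weight-of-evidence labels and a
small fraction of nonadjacent relationships. It makes no attempt to model
dose-response or chemistry; it exists so that every pipeline stage is
exercisable without any download.

Two fixtures package real curated endpoints from the public AOP-Wiki
(snapshot of 1 May 2023): the 13 nephrotoxicity AOPs with their initiating
events and adverse outcomes, and the reference convergent/divergent
classification of the merged network. Interior key events of the fixture
pathways are deliberately namespaced placeholders — the intermediate
events are not part of the packaged summary data, and inventing realistic-
looking titles for them would fabricate curation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .model import (
    Adjacency,
    AOPCollection,
    AOPRecord,
    GenerationError,
    KeyEvent,
    KeyEventRelationship,
    Role,
    Woe,
)

#: Default WoE mix: roughly a quarter of curated KERs carry high evidence,
#: an eighth medium, and about two thirds are left unspecified by their
#: developers; explicitly low labels are rare.
DEFAULT_WOE_WEIGHTS: dict[Woe, float] = {
    Woe.HIGH: 0.23,
    Woe.MEDIUM: 0.13,
    Woe.LOW: 0.0,
    Woe.UNSPECIFIED: 0.64,
}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic collection generator.

    Defaults mirror the regime of the curated nephrotoxicity collection:
    13 pathways of 3-8 events, about a quarter of new events reusing an
    existing one, occasional shared KERs, sporadic feedback, ~7% of KERs
    flagged nonadjacent.
    """

    n_aops: int = Field(default=13, gt=0)
    chain_length_min: int = Field(default=3, ge=3)
    chain_length_max: int = Field(default=8, ge=3)
    p_share_ke: float = Field(default=0.25, ge=0.0, le=1.0)
    p_share_ker: float = Field(default=0.10, ge=0.0, le=1.0)
    p_feedback: float = Field(default=0.15, ge=0.0, le=1.0)
    p_nonadjacent: float = Field(default=0.07, ge=0.0, le=1.0)
    woe_weights: dict[Woe, float] = Field(
        default_factory=lambda: dict(DEFAULT_WOE_WEIGHTS)
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.chain_length_max < self.chain_length_min:
            raise ValueError("chain_length_max must be >= chain_length_min")
        total = sum(self.woe_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"woe_weights must sum to 1 (got {total})")
        if any(w < 0 for w in self.woe_weights.values()):
            raise ValueError("woe_weights must be non-negative")
        return self


def _aop_rng(seed: int, aop_id: int) -> random.Random:
    # independent substream per AOP: adding a pathway never reshuffles the
    # draws of the others (string seeding is stable across processes)
    return random.Random(f"aopnet:{seed}:{aop_id}")


def _draw_woe(rng: random.Random, weights: dict[Woe, float]) -> Woe:
    levels = list(weights)
    return rng.choices(levels, weights=[weights[w] for w in levels], k=1)[0]


def _draw_adjacency(rng: random.Random, p_nonadjacent: float) -> Adjacency:
    return (
        Adjacency.NONADJACENT
        if rng.random() < p_nonadjacent
        else Adjacency.ADJACENT
    )


def generate_collection(config: GeneratorConfig) -> AOPCollection:
    """Generate a reproducible synthetic AOP collection.

    Each pathway is a simple chain MIE -> KE* -> AO. At every position the
    next event is, in order of precedence: an existing KER followed from
    the current tail (probability ``p_share_ker``, only possible when an
    earlier pathway already leaves the tail), an existing event reused as a
    new relationship (``p_share_ke``), or a fresh event. An optional
    back-edge per pathway (``p_feedback``) creates a feedback loop; it
    never runs AO -> MIE of its own chain, so every pathway keeps at least
    one MIE-to-AO path. Generated collections always pass validation.
    """
    pool: list[str] = []  # creation order, across AOPs
    outgoing: dict[str, list[str]] = {}  # KERs of earlier AOPs, for reuse
    counter = 0
    records: list[AOPRecord] = []

    for index in range(config.n_aops):
        aop_id = index + 1
        rng = _aop_rng(config.seed, aop_id)
        length = rng.randint(config.chain_length_min, config.chain_length_max)
        chain: list[str] = []

        for position in range(length):
            tail = chain[-1] if chain else None
            node: str | None = None
            if tail is not None and rng.random() < config.p_share_ker:
                candidates = [
                    v for v in outgoing.get(tail, []) if v not in chain
                ]
                if candidates:
                    node = rng.choice(sorted(candidates))
            if node is None and rng.random() < config.p_share_ke:
                candidates = [t for t in pool if t not in chain]
                if candidates:
                    node = rng.choice(candidates)
                elif config.p_share_ke >= 1.0:
                    raise GenerationError(
                        "p_share_ke=1 requires an existing event to reuse, "
                        "but none is available"
                    )
            if node is None:
                counter += 1
                node = f"synKE-{counter:04d}"
                pool.append(node)
            chain.append(node)

        kers = [
            KeyEventRelationship(
                upstream=chain[i],
                downstream=chain[i + 1],
                adjacency=_draw_adjacency(rng, config.p_nonadjacent),
                woe=_draw_woe(rng, config.woe_weights),
                aop_ids=frozenset({aop_id}),
            )
            for i in range(length - 1)
        ]

        if rng.random() < config.p_feedback:
            pairs = [
                (i, j)
                for i in range(length)
                for j in range(i + 1, length)
                if not (i == 0 and j == length - 1)  # keep an MIE->AO path
            ]
            i, j = rng.choice(pairs)
            kers.append(
                KeyEventRelationship(
                    upstream=chain[j],
                    downstream=chain[i],
                    adjacency=_draw_adjacency(rng, config.p_nonadjacent),
                    woe=_draw_woe(rng, config.woe_weights),
                    aop_ids=frozenset({aop_id}),
                )
            )

        for i in range(length - 1):
            outgoing.setdefault(chain[i], []).append(chain[i + 1])

        records.append(
            AOPRecord(
                aop_id=aop_id,
                title=f"Synthetic AOP {aop_id}",
                kers=kers,
                mies={chain[0]},
                aos={chain[-1]},
            )
        )

    key_events: dict[str, KeyEvent] = {}
    for record in records:
        chain_roles: dict[str, Role] = {}
        for title in record.titles:
            chain_roles[title] = Role.KE
        for title in record.mies:
            chain_roles[title] = Role.MIE
        for title in record.aos:
            chain_roles[title] = Role.AO
        for title, role in chain_roles.items():
            ke = key_events.get(title)
            if ke is None:
                ke = KeyEvent(canonical_title=title)
                key_events[title] = ke
            ke.type_profile[record.aop_id] = role

    return AOPCollection(records=records, key_events=key_events)


# ---------------------------------------------------------------------------
# packaged fixtures

@dataclass
class Fixture:
    """A packaged input with the externally known values it should yield."""

    name: str
    collection: AOPCollection
    expected: dict[str, object] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)


_DATA = files("aopnet").joinpath("data")
_SNAPSHOT = "AOP-Wiki (aopwiki.org), snapshot of 2023-05-01"


def nephrotoxicity_aops_fixture(n_interior: int = 2) -> Fixture:
    """The 13 curated nephrotoxicity AOPs, endpoints only.

    Each pathway is shipped as MIE -> placeholder interior KEs -> AO; the
    placeholders are namespaced (``placeholder:AOP105:KE1``) because the
    packaged summary covers endpoints only and fabricated interior titles
    would masquerade as curation. Metrics on this fixture therefore
    characterise the endpoint skeleton, not the full curated network.
    """
    with _DATA.joinpath("nephrotoxicity_aops.csv").open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, dtype=str, keep_default_na=False)

    records: list[AOPRecord] = []
    key_events: dict[str, KeyEvent] = {}

    def _event(title: str, aop_id: int, role: Role) -> None:
        ke = key_events.setdefault(title, KeyEvent(canonical_title=title))
        ke.type_profile[aop_id] = role

    for _, row in table.iterrows():
        aop_id = int(row["aop_id"])
        mie, ao = row["mie_title"], row["ao_title"]
        chain = (
            [mie]
            + [f"placeholder:AOP{aop_id}:KE{i + 1}" for i in range(n_interior)]
            + [ao]
        )
        kers = [
            KeyEventRelationship(
                upstream=chain[i],
                downstream=chain[i + 1],
                aop_ids=frozenset({aop_id}),
            )
            for i in range(len(chain) - 1)
        ]
        _event(mie, aop_id, Role.MIE)
        for interior in chain[1:-1]:
            _event(interior, aop_id, Role.KE)
        _event(ao, aop_id, Role.AO)
        records.append(
            AOPRecord(
                aop_id=aop_id,
                title=row["title"],
                kers=kers,
                mies={mie},
                aos={ao},
                oecd_status=row["oecd_status"],
            )
        )

    collection = AOPCollection(records=records, key_events=key_events)
    shared_mie = "Inhibition, mitochondrial electron transport chain complexes"
    return Fixture(
        name="nephrotoxicity_aops",
        collection=collection,
        expected={
            "n_aops": 13,
            "aop_ids": sorted(r.aop_id for r in records),
            "shared_mie_title": shared_mie,
            "shared_mie_aop_ids": [437, 447],
            "placeholder_mie_title": "Unknown, MIE",
        },
        provenance={
            "n_aops": _SNAPSHOT,
            "aop_ids": _SNAPSHOT,
            "shared_mie_title": f"{_SNAPSHOT}; the only MIE shared by multiple AOPs",
            "shared_mie_aop_ids": _SNAPSHOT,
            "placeholder_mie_title": f"{_SNAPSHOT}; AOP 186 has an uncharacterised MIE",
        },
    )


def nephrotoxicity_classification_fixture() -> Fixture:
    """Reference convergent/divergent key-event lists of the merged network.

    Carries no records: it is the expected output side of the degree-based
    classification, usable as a cross-check once the full curated KER table
    is available as input.
    """
    with _DATA.joinpath("nephrotoxicity_classification.json").open(
        "r", encoding="utf-8"
    ) as fh:
        data = json.load(fh)
    convergent = [e["title"] for e in data["convergent"]]
    divergent = [e["title"] for e in data["divergent"]]
    return Fixture(
        name="nephrotoxicity_classification",
        collection=AOPCollection(),
        expected={
            "convergent": convergent,
            "divergent": divergent,
            "n_convergent": len(convergent),
            "n_divergent": len(divergent),
        },
        provenance={k: _SNAPSHOT for k in ("convergent", "divergent", "n_convergent", "n_divergent")},
    )
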