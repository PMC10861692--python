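# Methods

## The network model

A curated AOP collection is a set of linear pathways over a shared
vocabulary of key events. Each pathway record carries an ordered list of
key event relationships (KERs), each KER annotated with adjacency
(`adjacent` = direct causal step, `nonadjacent` = indirect link) and a
qualitative weight of evidence (`high` / `medium` / `low`, or
`unspecified` when the developer left the field blank — both H/M/L
letters and words are accepted on read). Node identity is the
**canonical title** and nothing else: AOP-Wiki numeric KE ids are kept
as metadata but never used as merge keys, because curation routinely
pools several wiki entries (distinct ids) into one biological event.

Harmonisation is an explicit raw-title → canonical-title map supplied by
the curator. The map must be idempotent (no chains a→b→c); applying it
rewrites every KE reference, unions the alias sets, wiki ids and per-AOP
role profiles of pooled events, and preserves the multiset of
(AOP, upstream, downstream) triples. Title matching is exact-string
after Unicode NFC normalisation and whitespace trimming; fuzzy or
ontology-based matching is deliberately out of scope — silent automatic
pooling would fabricate curation decisions.

The merged network is a **simple directed graph**: at most one edge per
ordered node pair, no self-loops. Design choices at the merge step:

- **Edge collapse.** Parallel reports of the same pair collapse onto
  one edge whose `aop_ids` provenance is the union of contributors. The
  collapsed WoE is the *highest* evidence level among contributors
  (rank high > medium > low > unspecified); the full per-AOP WoE and
  adjacency labels are kept on the edge (`woe_by_aop`,
  `adjacency_by_aop`), so no information is lost and any alternative
  merge rule can be recomputed from the stored network.
- **Nonadjacency reconciliation.** Default policy `reconcile`: an edge
  is adjacent if any contributor reports it adjacent — an indirect link
  in one pathway that another pathway describes directly is considered
  bridged. `keep_flagged` (nonadjacent wins) and `exclude` (nonadjacent
  reports discarded before collapsing) are provided for sensitivity
  analysis, since including or excluding indirect links shifts degree,
  eccentricity and path-occurrence values.
- **Node drops.** After construction, titles in `drop_titles` (default:
  the `"Unknown, MIE"` placeholder used by pathways whose initiating
  event is uncharacterised) are removed with their incident edges.
  Nodes left isolated by a drop are *retained* (they still count in
  sharing statistics, with degree 0) and logged.
- **Determinism.** Nodes and edges are inserted in sorted order and all
  ranked outputs carry explicit tie-breaks, so identical inputs produce
  identical networks and serialisations regardless of input row order.

Metrics run on the collapsed simple graph, not a multigraph: shared
KERs are single arrows, and per-AOP multiplicity lives in provenance.

## Node statistics

- **Degree triple** — in-degree, out-degree, total, over collapsed
  edges; isolated nodes report zeros.
- **Convergence class** — convergent iff in > out, divergent iff
  out > in, balanced otherwise (including isolated nodes); the three
  classes partition the node set.
- **Directed eccentricity** — with the default `incoming` orientation,
  ecc(v) is the maximum shortest-path hop count from any ancestor of v;
  nodes with no ancestors (typically MIEs) score 0, terminal outcomes
  score high. Unreachable pairs are ignored (maximum over finite
  distances only), so disconnected networks remain well-defined. The
  `outgoing` orientation (distance to descendants) is offered for
  sensitivity. Banding: upstream (ecc < 3), middle (3 ≤ ecc ≤ 6),
  downstream (ecc > 6). The incoming default is what makes low scores
  mean "net upstream": it is an inference from that banding semantics,
  not a convention every directed-network tool states explicitly.
- **Betweenness** — standard directed shortest-path betweenness,
  endpoints excluded, normalised by (n−1)(n−2).
- **Simple path occurrence (normalised)** — enumerate *all* simple
  directed paths from any annotated MIE to any annotated AO; a node's
  score is the fraction of those paths containing it (endpoints count).
  Choices that matter:
  - Endpoint sets are **annotation-driven** (per-AOP roles), never
    inferred from degree. An MIE with incoming edges (cytotoxicity in
    the nephrotoxicity network) is a valid path start while remaining
    interior to other paths; likewise an AO with outgoing edges.
  - Normalisation is by total path count — the reading under which
    scores live in [0, 1] and a node on every path scores exactly 1.
  - A node that is both MIE and AO contributes **no zero-length path**:
    a path with no relationship carries no information and would only
    inflate that node's own score.
  - Cycles are safe because simple paths forbid node revisits; the
    worst case is still exponential, so enumeration carries a
    `max_paths` guard (default 1 000 000, far above the ~10² paths of a
    45-node curated network) and fails loudly with advice rather than
    hanging.
- **Sharing and distributions** — per-node AOP membership count with
  histogram; in/out-degree histograms; WoE percentage distribution over
  collapsed edges.

**Percentage rounding** is half-away-from-zero to integer percent
(26/45 → 58%, 11/45 → 24%, 7/45 → 16%, 27/45 → 60% — mutually
consistent at n = 45). Because independent roundings need not sum to
100, the summary always carries the raw fractions and flags non-100
sums instead of re-normalising. Degree-histogram percentages are
emitted under **both** denominators (all nodes, and nodes with the
respective degree ≥ 1), since either is a defensible population for
"x% of in-degree KEs". Ranked tables order by (path occurrence desc,
degree desc, title asc); the CLI serialises occurrence and betweenness
at 3 decimals, full precision in JSON.

## Synthetic collections

The generator emulates the structural regime of curated nephrotoxicity
collections; its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
| --- | --- | --- |
| `n_aops` | 13 | pathways per collection |
| `chain_length_min/max` | 3 / 8 | events per pathway (MIE, ≥1 KE, AO) |
| `p_share_ke` | 0.25 | a new event reuses an existing one |
| `p_share_ker` | 0.10 | an existing KER is followed from the chain tail |
| `p_feedback` | 0.15 | one back-edge injected per pathway |
| `p_nonadjacent` | 0.07 | a KER is flagged nonadjacent (≈ 4 per ~60 KERs) |
| `woe_weights` | .23/.13/.00/.64 | high/medium/low/unspecified mix |

Each pathway is a simple chain; at each position the next event is, in
precedence order, an existing KER followed from the current tail
(possible only when an earlier pathway leaves that tail — so with
`p_share_ke = 0` collections are node-disjoint), a reused existing
event, or a fresh one. Back-edges never run AO → MIE of their own
chain, preserving at least one MIE→AO path per pathway. The WoE mix
reflects the curated regime in which roughly a quarter of KERs carry
high evidence, an eighth medium, explicit lows are rare, and about two
thirds are unfilled (the printed curated percentages 23/13/65 sum to
101 after rounding; the defaults .23/.13/.00/.64 sum to 1). Seeding:
one root seed, with a deterministic substream per pathway, so adding a
pathway never reshuffles the draws of the others.

What the generator does *not* emulate: biologically meaningful titles,
dose–response, chemistry, realistic WoE–topology correlation, or the
heavy-tailed sharing of real collections (reuse is uniform over the
existing pool). Passing tests on synthetic collections therefore
demonstrate algorithmic correctness and pipeline robustness, not
biological validity of any conclusion drawn from a real table.

Two packaged fixtures carry real curated content (AOP-Wiki snapshot of
2023-05-01): the 13 nephrotoxicity AOPs with their MIE/AO endpoints,
and the reference convergent/divergent classification (11 and 13 key
events) of the merged network. Interior events of the endpoint fixture
are namespaced placeholders (`placeholder:AOP105:KE1`): the packaged
summary covers endpoints only, and realistic-looking invented interiors
would masquerade as curation. Consequently the full curated network's
statistics are only reproducible when a user supplies the complete
curated KER table; the corresponding acceptance test states exactly
where to place it and fails otherwise.

## Verification strategy and problem sizes

The algorithmic core is checked against independent brute-force oracles
written as plain recursive DFS over successor lists (no shared code
with the implementation path, which delegates traversal to networkx):
path enumeration and betweenness agree exhaustively on **every**
labelled simple digraph with up to 4 nodes (4 165 graphs) and on seeded
random samples of 5- and 6-node digraphs across densities; betweenness
agrees to 1e−12 on random DAGs up to 10 nodes. Termination and score
bounds are stress-checked on 200 seeded collections with a forced
feedback loop in every pathway. Structural invariants (class partition,
degree-sum conservation, harmonisation idempotence, rounding pins,
round-trip identity of CSV/GraphML/JSON serialisations) run on
generated collections with fixed seeds; property-based tests are
derandomised for reproducibility. Problem sizes were chosen so the
whole suite runs in seconds on one CPU while the exhaustive tier stays
genuinely exhaustive at its stated size.

## Known limitations

- Harmonisation quality is the curator's responsibility; the package
  validates map shape (idempotence, no chains, no KER collapse) but
  cannot judge biological synonymy.
- Eccentricity banding thresholds (3 and 6 hops) are taken as given for
  comparability across networks of this scale; they are not adaptive to
  network diameter.
- Simple-path occurrence weights all MIE→AO routes equally; it does not
  discount long or low-evidence paths.
- The `exclude` nonadjacency policy can disconnect pathways whose only
  record of a step is indirect; its output is for sensitivity analysis,
  not a replacement for the reconciled network.
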