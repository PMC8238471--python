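# Methods

## Data model

The pipeline's single in-memory currency is a labeled property graph: nodes
carry exactly one non-empty label (an entity category) and a property map;
edges are directed, labeled, and parallel edges with identical endpoints and
label are allowed (required downstream, where multiple sources asserting the
same relationship must remain distinguishable). Property values are
restricted to the set that survives GraphML serialization: booleans,
integers, floats, strings, and homogeneous non-empty lists thereof. A
single-label node model was chosen as the simplest one consistent with the
warehouse's per-source schemas; a source needing multi-category nodes can
express the secondary category as a property or an extra node.

Internal numeric ids are deliberately not stable across a write/read
boundary — they are regenerated in document order on read. Any stage that
must track elements across files stores an explicit id property instead
(the merger writes `__source_id`). This mirrors the intermediate-file
workflow, where files may be regenerated between runs.

## GraphML dialect

GraphML attributes are declared per (element kind, property key) with a type
inferred from the first occurrence; a key used with two different types in
one graph is rejected at write time rather than silently coerced. GraphML
has no list type, so lists are encoded as `|`-delimited strings with
backslash escaping and an `attr.list="true"` marker on the key declaration;
the delimiter is documented in a header comment of every file. Node labels
live under the reserved attribute `labels`, edge labels under `label`, which
keeps the files importable by common graph tooling. Empty lists are rejected
at insertion (their element type would be unrecoverable); the empty string
scalar and empty-string list items round-trip fine. Floats are written with
`repr`, which round-trips exactly.

Nodes and edges are serialized in insertion order and keys in
first-occurrence order, so writing is deterministic: write → read → write is
byte-identical, and unchanged pipeline runs reproduce identical artifacts.
The test suite and the acceptance script both verify this fixed point.

## Workspace life cycle

A workspace is a directory with `config.json` at the root and a `sources/`
folder holding one folder per data source (metadata file, `source/` raw-file
folder, `intermediate.graphml`, `meta-graph-statistics.txt`) plus the
warehouse-level `merged.graphml` and `mapped.graphml`. The JSON field names
are this implementation's dialect; unknown keys are preserved on rewrite so
that foreign or future fields survive. The workspace format version is 1;
opening a newer version fails with an explicit upgrade-required error.

Source versions are opaque strings compared by equality only — version
schemes across real sources are too heterogeneous for a semantic ordering,
and up-to-dateness only needs equality. Timestamps are ISO-8601 with UTC
timezone.

Each source run executes update → parse → export. The three outcome flags
are monotone (export ⇒ parse ⇒ update); a failing step clears downstream
flags and records the error message, and normalization re-enforces the chain
whenever metadata is saved or loaded. When the probed newest version equals
the stored one and a successful export exists, the whole run is skipped
(unless forced); when the version probe itself fails, the source degrades to
"newest unknown, not updated" instead of aborting — existing raw files are
still parsed and exported if needed.

## Merge

Merging is a disjoint union with zero entity resolution by construction:
deduplication is exclusively the mapper's concern, which keeps the merge
trivially non-destructive and order-invariant up to isomorphism. Node labels
are namespaced as `<source_id>_<label>` to keep same-named labels from
different sources separable; edge labels are left readable and
disambiguated by the `__datasource` provenance property instead, which every
merged element carries. Module exporters are forbidden from writing
`__`-prefixed keys (checked at export time) so the reserved namespace cannot
be spoofed.

## Mapping layer

Node mapping collects, per source and describable label, a
(node, entity label, identifier set) description. Within each entity label
the descriptions are partitioned by transitive identifier overlap using a
union–find keyed on first identifier occurrence (linear in total identifier
count, versus the quadratic pairwise-intersection oracle used in tests). One
mapping node per partition class is created, labeled
`MAPPED_<entity label>`, holding the sorted union of its members'
identifiers in the `ids` property and marked `__mapped`; member links
(`MAPPED_TO` edges) connect each source node to its mapping node.

Design choices that the underlying idea leaves open, fixed here:

- **Collapse scope is per entity label.** A Drug and a Chemical sharing an
  identifier value are not merged; identifier values are only meaningful
  within a type system, and cross-category collapse on coincidental values
  would be semantically wrong.
- **Paths are matched in stored edge direction only**, and they are simple
  (no node revisited). A source wanting reverse traversal declares the
  reversed path. This keeps matching deterministic and prevents degenerate
  cycles from inflating the layer.
- **Paths never mix sources**: every element of a concrete path must carry
  the declaring source's provenance. Cross-source relationships emerge in
  the meta-layer through collapsed endpoints, not through cross-source
  traversal.
- **Mapping-edge deduplication is per (from, to, label, source).** Distinct
  concrete paths from one source between the same mapping nodes collapse to
  one edge; distinct sources keep parallel edges. The layer thus counts
  *sources* asserting a relationship, not paths, which is the meaningful
  consensus unit.
- **A configurable maximum path length (default 10 labels)** guards against
  pathological declarations; matching cost grows with path length.

Path matching is a straightforward DFS from all nodes matching the first
label, following insertion order at every step, which makes the match list —
and hence the whole mapped artifact — deterministic. Describer exceptions
are isolated per node/per path: one faulty description never poisons the
rest of the layer.

Non-destructiveness is structural: the mapper only calls `add_node` /
`add_edge`, and the tests additionally verify element-for-element equality
of the merged subgraph inside the mapped graph across the serialization
boundary.

## Meta graphs

A meta graph counts nodes per label and edges per (from-label, edge-label,
to-label) triple; the sums equal the graph's totals and the meta graph of a
disjoint union is the entrywise sum of the parts. The plain-text report
(`meta-graph-statistics.txt` per source, `merged-`/`mapped-` variants at the
workspace level) is fixed-width with lexicographic line order, so
regeneration is byte-identical; the exact layout is this implementation's
dialect.

## Synthetic sources

Real source modules download from the network; the bundled fixtures emulate
their *shapes* offline so every stage is testable. Heterogeneity is
deliberate — one TSV table source, one JSON source, one multi-file source —
to exercise the parser contract. Identifiers and names are synthetic tokens;
no biological realism is attempted or needed, since the pipeline's
correctness depends on structure (identifier overlap, label paths), not
content. Consequences for interpretation: passing tests demonstrate correct
integration, collapse and projection mechanics, but say nothing about the
quality of real sources' describers or about identifier noise (typos,
retired accessions, coarse identifier types) that real data would bring.

The parameterized generator (`OverlapSpec`) fabricates workspaces with
controlled structure. Parameters and defaults: 3 sources; 20 drugs and 20
diseases per source; overlap fraction 0.5 (the fraction of each source's
entities drawn from a pool shared by *all* sources — shared entities keep
identical identifier sets everywhere, so expected co-mapping groups are
known by construction); relationship density 1.5 relations per entity;
annotation-path fraction 0.3 (relations expressed through an intermediate
annotation node rather than a direct edge, exercising two-edge path
mapping); about half the drugs carry a second identifier namespace. The
defaults are small enough to run hundreds of end-to-end pipelines in
seconds yet large enough that every mapping mechanism (singletons, full
cross-source groups, direct and annotated relations, per-source
deduplication) occurs.

The ground truth returned by the generator is computed from the
construction itself — which world entity went to which source, which
relation was sampled — never by running the mapper, so the end-to-end
comparison in the tests and the acceptance script is a genuinely independent
check. The generator returns the workspace handle and a registry of the
generated modules alongside the ground truth, because the caller needs the
modules to run the pipeline.

## Numerical and degenerate cases

Empty workspaces merge to a valid empty GraphML; unknown labels in a path
pattern yield an empty match set, not an error; a source with zero
describable nodes contributes nothing to the layer; an unresolvable
configured source is reported and skipped, and the warehouse is still built
from the remaining sources (a warehouse of k−1 sources beats none, with the
failure visible in metadata flags and the exit code). Problem sizes used by
the test suite and acceptance script — up to 200 collapse candidates with a
50-value identifier alphabet, 100-node graphs with 7-label paths, dozens of
generated workspaces per run — were chosen so the oracle comparisons
(quadratic pairwise overlap, exhaustive path enumeration) stay exact and the
whole suite runs in seconds.

## Known limitations

- No on-disk graph engine: graphs live in memory, which caps warehouse size
  well below what the real databases emulated here would produce.
- No fuzzy or probabilistic record linkage; mapping is exact identifier
  equality only, and there is no user-level control to exclude coarse
  identifier types from collapse.
- Single label per node and directed edges only; undirected relationships
  must be modeled as two declarations.
- Workspace upgrade is detected but not performed.
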