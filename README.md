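# graphdwh

A graph-based data warehouse and mapping tool for heterogeneous biomedical
data sources.

Research projects in pharmacogenomics and related fields routinely need
several databases at once — a gene nomenclature, a drug vocabulary, a
drug–disease relation source — each with its own formats, update cadence
and identifier systems. `graphdwh` integrates such sources into a single
labeled property graph inside a self-contained **workspace**: each source is
updated, parsed and exported to its own graph; the per-source graphs are
merged into one warehouse graph; and a **non-destructive mapping layer** is
added on top that interconnects entities across sources without altering any
source data. All intermediate and final graphs are plain GraphML, so they
can be loaded into standard graph tooling.

## The mapping model

Two mechanisms build the meta-layer on the merged graph:

**Node mapping by identifier overlap.** Each data source ships a
*mapping describer* that assigns describable nodes a canonical entity label
(`Drug`, `Gene`, `Disease`, ...) and a set of namespaced global identifiers
(`UNII:…`, `HGNC_SYMBOL:…`). For every described node a mapping node is
created, and mapping nodes of the same entity label with overlapping
identifier sets are collapsed. The collapsed partition is the set of
connected components of the graph whose vertices are the described nodes and
whose links join nodes sharing at least one identifier — computed with a
union–find over identifier occurrences, so transitive chains
{x}, {x,y}, {y,z} collapse into one entity known as {x,y,z}. Identifier
matching is exact (namespace + value, whitespace-trimmed); collapse never
crosses entity labels.

**Path mapping.** Relationships worth lifting into the meta-layer are
declared as *label paths* — alternating node/edge label lists such as
`[Drug, INDUCES, Disease]` (one edge) or
`[Variant, ASSOCIATED_WITH, VariantDrugAnnotation, ASSOCIATED_WITH,
Chemical]` (two edges through an annotation node). Concrete simple paths
matching a declared pattern, with all elements from the declaring source,
are projected onto one mapping edge between the terminal nodes' mapping
nodes, labeled with a global relationship name (`INDUCES`, `TARGETS`,
`ASSOCIATED_WITH`, ...) and annotated with the source id. When several
sources assert the same relationship, the layer keeps one parallel edge per
source — a simple consensus signal.

The layer only ever adds elements: every node, edge and property of the
merged graph is preserved byte-for-byte in the mapped graph.

## Worked example

The package bundles three fixture data sources that emulate real module
shapes offline: a gene-nomenclature TSV table, a drug-vocabulary JSON source
with gene targets, and a multi-file relation source with drug–disease
relations and a variant–annotation–chemical motif.

```
$ graphdwh generate-fixtures demo
Created fixture workspace at demo with sources: ToyGenes, ToyDrugs, ToyRelations
$ graphdwh update demo
Merged graph: demo/sources/merged.graphml
Mapped graph: demo/sources/mapped.graphml
$ graphdwh status demo
Workspace format version: 1
Data source   Up-to-date  Version  Newest version  Last update
------------  ----------  -------  --------------  -------------------------
ToyGenes      yes         2024.1   2024.1          2026-09-19T23:44:18+00:00
ToyDrugs      yes         7.4      7.4             2026-09-19T23:44:18+00:00
ToyRelations  yes         2023-10  2023-10         2026-09-19T23:44:18+00:00
```

The mapped graph's statistics (`demo/sources/mapped-meta-graph-statistics.txt`)
begin:

```
Node labels: 14 (39 nodes total)
  MAPPED_Chemical    2
  MAPPED_Disease     3
  MAPPED_Drug        3
  MAPPED_Gene        4
  MAPPED_Variant     2
  ToyDrugs_Disease   2
  ...
```

Reading: the 25 source nodes (labels prefixed with their source id) are
untouched, and 14 mapping nodes were added. The four `MAPPED_Gene` nodes are
*collapsed* entities — both `ToyGenes` and `ToyDrugs` export the same four
genes under shared `HGNC_SYMBOL` identifiers, so each pair of source nodes
shares one mapping node. Likewise the three `MAPPED_Drug` nodes join
`ToyDrugs` and `ToyRelations` records sharing `UNII` ingredient identifiers.
Among the 11 projected mapping edges are 4 `TARGETS` edges (trivial one-edge
projection), 2 `ASSOCIATED_WITH` edges (two-edge annotation paths collapsed
to direct variant→chemical edges), and 5 `INDUCES` edges of which two
drug–disease pairs are asserted by *both* relation-bearing sources and
therefore appear as parallel edges with distinct source annotations.

The same can be done in code:

```python
from graphdwh import OverlapSpec, generate_fixture_workspace, update_workspace

result = generate_fixture_workspace(OverlapSpec(n_sources=3, overlap_fraction=0.5, seed=0), "ws")
update = update_workspace(result.workspace, result.registry)
print(update.mapped_path)   # ws/sources/mapped.graphml
```

`generate_fixture_workspace` also returns a constructively computed ground
truth (which entities must co-map, which mapping edges must exist), which
the test suite compares against the pipeline's actual output.

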