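# Methods

This note documents the models, conventions and deliberate design choices
behind phenomatrix, in the spirit of a software-methods appendix.

## The annotation model

A study document is an ordered list of taxa, an ordered list of characters
(each with ≥ 1 uniquely-symbolled states), a sparse cell map
`(taxon, character) → set of state symbols`, and free-form document
metadata. Cells hold *sets* so polymorphic scores are first-class; an absent
cell means "not scored", and the symbol `?` is reserved for missing data and
can never carry annotations.

EQ annotations attach to character **states**, not cells: the phenotype
described by a state description is a property of the state, and a
taxon-level assertion arises by joining a cell's symbols to the state's
annotations. An annotation must carry at least one of entity/quality (a
fully empty annotation is rejected at construction); the stronger
completeness requirements are the checker's job, not the constructor's, so
partially built annotations can be represented, saved, and flagged.

Term references are opaque id strings plus an optional cached display
label. CURIEs and full URIs are both accepted and compared by exact string
equality; no expansion happens inside the reasoning layer.

## Ontology graphs and reasoning

The OBO parser handles a documented subset (`format-version` header;
`[Term]` stanzas with `id`, `name`, `def`, `synonym`, `is_a`,
`is_obsolete`, `replaced_by`, `namespace`); unknown tags and non-Term
stanzas are skipped with a logged notice, malformed lines fail with a line
number, and duplicate ids fail naming the id. The graph is held as a
`networkx` DiGraph of child→parent `is_a` edges and must be acyclic
(checked at parse and merge time).

Numerical/semantic choices:

* **Dangling parents** (an `is_a` target never declared) become placeholder
  terms flagged as such rather than errors, because curators routinely load
  ontology slices; placeholders are reported, count as "unknown" for the
  checker, and are not serialized back out.
* **Obsolete terms are excluded from subsumption**: they never appear in
  `descendants()` results and their outgoing edges do not transmit
  reachability, so rules cannot fire on (or through) retired branches.
* **`replaced_by` resolution** follows chains transitively to a terminal
  id, detects cycles, and by default errors on a target missing from the
  graph. The broker's migration resolver passes `allow_dangling=True`: a
  permanent id may legitimately name a term in an ontology that is not
  loaded, and it is then treated as terminal. When a term lists several
  replacements the first is followed with a warning — the request workflow
  mints exactly one permanent id per provisional term, so multiplicity is
  an out-of-band ontology event the curator should see.
* Provisional terms merged into a session are ordinary nodes: a pending
  request's suggested superclass (when loaded) becomes a real `is_a` edge,
  so provisional terms participate in rule subsumption like any other term.

## NeXML mapping

The annotation vocabulary (`pa:` prefix, documented in `nexml_io`) is this
package's own, declared contract: taxonomy links as ResourceMeta on `otu`
elements, each EQ annotation as one `pa:phenotype` ResourceMeta container on
a `state` with nested entity/quality/related-entity ResourceMeta and
comment/label LiteralMeta children. Polymorphic cells use NeXML
`polymorphic_state_set` members. Generated ids are deterministic
(`t{i}`, `c{i}`, `s{i}_{symbol}`, `meta{n}`), element order is canonical,
and dictionaries are serialized sorted, so equal documents produce
byte-identical files — which is what makes content-hash change detection
and write-determinism checks possible.

Term ids are written as full URIs; CURIEs expand through a configurable
prefix map defaulting to the OBO library PURL pattern
(`PREFIX:NUM → http://purl.obolibrary.org/obo/PREFIX_NUM`) and are
contracted back on read. Consequently a document that stores a raw
obolibrary URI reads back as the equivalent CURIE — a deliberate
normalization; round-trip identity holds for CURIE-based and
non-obolibrary-URI references, which covers ontology terms and provisional
ids alike.

Unrecognized document-level metadata is preserved opaquely: on read each
foreign element is re-serialized *as it will appear inside this package's
output tree* (namespace prefixes reconciled against the writer's map) and
stored as an opaque string; on write it is re-emitted verbatim. After the
first write the representation is a fixed point, so repeated read/write
cycles are byte-stable and nothing foreign is dropped.

Schema conformance is enforced structurally (root element and version, id
uniqueness, referential integrity of otus/char/state/member references)
by `validate_nexml`; the checks mirror the constraints of the NeXML schema
that matter for character matrices.

## The request broker

The store contract is exactly three capabilities: mint a fresh unique id,
list a submitter's requests, and set a pending request's permanent id (all
other fields immutable; re-resolution rejected). The default backend is a
local JSON-lines file — append for create, atomic rewrite for update,
re-read on every operation so sessions sharing the file see each other's
requests. A REST backend would map these to POST / filtered GET / PATCH;
no network client is included. Provisional ids are
`<namespace>/<UUID4>` with a configurable namespace
(default `http://example.org/provisional/`), optionally minted from a
seeded RNG for reproducible runs. `created` timestamps are ISO-8601 UTC and
are forced strictly increasing within a store so listing by
`(created, id)` reproduces creation order even under sub-microsecond
bursts. Duplicate labels are allowed with a warning: avoiding duplicates is
a social convention of a shared submitter id, not an invariant.

`sync_and_migrate` composes the pieces: merge all of the submitter's
requests into the ontology session, then rewrite every term reference in
the document to its terminal replacement. After a sync nothing in the
document resolves further, and a second sync is a no-op. Resolved but
unmigrated references simply persist in saved files until a sync runs.

## Consistency rules

Severities follow the rule-id prefix: `E_*` error, `W_*` warning, `N_*`
note. Rules are independent and may stack on one annotation, with two
deliberate exceptions that prevent double-reporting a single mistake:
the process rule requires a present, resolvable quality (a missing quality
is already `E_MISSING_QUALITY`), and unknown terms get `W_UNKNOWN_TERM`
instead of participating in subsumption tests.

`relational_quality_root` has no built-in default because no single
canonical ontology id denotes "relational quality"; configuration must
supply it (the fixture bundles do), and an enabled rule whose root is
missing from the loaded graph is a configuration error, distinct from data
errors in the exit-code contract (2 vs 1).

The incomplete-character census counts a character once when ≥ 1 state is
annotated and ≥ 1 non-missing state is not; untouched characters produce
nothing, and `?` states are excluded.

## Editing sessions

Undo/redo stores explicit forward/inverse transformation pairs; the
provided edit factories capture the prior value at construction so
`inverse∘forward` is exact. A failed edit leaves the session untouched.
Autosave (off by default) saves after every edit, undo and redo — no
debounce, by design: the cost of a save is one serialization, and the
guarantee "the bound file always parses to the in-memory document" is what
makes shared-folder collaboration safe. Saves are atomic
(temp file + rename) so a sync service never observes a torn file.

Change monitoring is content-hash based, not mtime based: sync services
rewrite identical bytes and clocks skew across machines. The session
remembers the hash of its own last write; the first observation of those
bytes classifies as `SELF_SAVE`, later observations as `UNCHANGED`, any
other content as `EXTERNAL_CHANGE` (with a deletion flag when the file is
gone). The monitor is a polling generator (CLI `watch`); the truth table,
not a thread model, is the contract. `reload` refuses to discard unsaved
edits unless forced — a situation autosave makes unreachable.

## Synthetic fixtures and what they do (not) show

The fixture generator emulates the *structure* of real curation data —
rooted anatomy/quality/process/taxonomy DAGs containing the rule roots
(including real ids `GO:0008150` and `PATO:0001236` so default
configuration resolves), matrices with sparse and polymorphic cells,
taxonomy links, stacked annotations — but not its *content*: labels are
synthetic, branch sizes are small (≈ 20-term anatomy, ≈ 5-term branches),
and ids outside the two real roots use clearly synthetic ranges. Default
bundle dimensions are 8 taxa × 10 binary characters with 80 % of
characters annotated, a size typical of a small published matrix and large
enough for every injectable rule to have room.

Ground truth is recorded from the injection *plan*, never by running the
checker — generator and checker are independent routes to the same counts,
and their exact agreement is the acceptance property. Two constructions
make exactness achievable: the annotated fraction selects whole characters
(every state annotated) so incomplete characters arise only from explicit
injection, and each planted violation is built to break exactly one rule
(e.g. process-rule violations use a plain quality, which is not under
'process quality', and a non-root process entity). Passing these tests
shows the rules are implemented as specified; it does not show how often
real curation data violates them, nor exercise the scale or vocabulary of
production ontologies.

Problem sizes throughout the automated checks (≤ 50-node DAGs, 20 fixture
seeds, 50 random documents, ≤ 30-edit sessions, 1000 broker requests) were
chosen as the smallest sizes that still exercise every code path and
boundary; all are parameters, not limits.

## Known limitations

* Only `is_a` is reasoned over; other OBO relationship types, OWL, and
  cross-ontology imports are out of scope.
* NeXML trees blocks, continuous characters, and NEXUS/phylip interchange
  are not supported.
* The checker has no taxonomic-applicability rule (flagging a term used in
  a clade where it cannot occur); that requires curated applicability data
  the tool does not model.
* Concurrent-edit *merging* is out of scope: the session detects and
  reports external changes but does not reconcile them.
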