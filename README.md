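# phenomatrix

Entity–Quality semantic annotation of phenotypic character matrices, as a
Python library and command-line tool.

Comparative morphologists publish their observations as character matrices:
taxa × characters tables in which each cell scores a taxon for a discrete
character state ("dorsal fin: present/absent"). To make those free-text
descriptions computable, curators annotate each character state with
ontology terms using the **Entity–Quality (EQ) model**: an anatomical or
process *entity* term (e.g. `UBERON:femur`, `GO:0008150` descendants) paired
with a *quality* term from the Phenotype and Trait Ontology (PATO)
(e.g. *curved*), optionally with a *related entity* when the quality is
relational (e.g. *fused with*). Taxa are annotated with identifiers from a
taxonomy ontology. The annotated matrix is stored as
[NeXML](http://www.nexml.org/), which allows metadata on any data element.

phenomatrix is aimed at the curation teams doing this work. It addresses the
three practical bottlenecks of large-scale phenotype curation:

1. **Missing ontology terms.** An *Ontology Request Broker* (ORB) lets a
   curator mint a globally unique *provisional term* URI on the spot and use
   it in annotations immediately, instead of pausing to shepherd a term
   request through community review. Once an ontology editor records a
   permanent identifier for the request, a sync marks the provisional term
   obsolete with a `replaced_by` pointer and rewrites every annotation to the
   permanent id — following `replaced_by` chains transitively, whether they
   arise from provisional resolutions or ordinary ontology obsolescence.
2. **Annotation quality control.** An ontology-aware consistency checker
   enforces the EQ guidelines: every annotation needs both an entity and a
   quality; relational qualities require a related entity (and
   non-relational ones must not carry one); entities under
   'biological process' (`GO:0008150`) may only pair with descendants of
   'process quality' (`PATO:0001236`); obsolete or unknown terms are flagged;
   characters with some but not all states annotated are noted as incomplete.
3. **Collaborative editing.** Teams share files through folder-sync
   services. Editing sessions provide exact undo/redo, optional autosave
   after every change (atomic writes), and content-hash file monitoring that
   distinguishes a session's own saves from a collaborator's changes and
   refuses to discard unsaved work on reload.

Ontologies are loaded from a documented OBO flat-file subset (`[Term]`
stanzas with `id`, `name`, `def`, `synonym`, `is_a`, `is_obsolete`,
`replaced_by`, `namespace`); reasoning is transitive `is_a` closure with
obsolete terms excluded.

## Worked example

Generate a synthetic fixture bundle (four mini-ontologies plus an annotated
matrix with known planted violations), then run the consistency checker:

```
$ phenomatrix fixtures --seed 11 --out bundle
$ phenomatrix --config bundle/config.json check bundle/matrix.xml --out report.tsv
[ERROR] E_MISSING_QUALITY at character 0, state '0', annotation 1: annotation has no quality term
[ERROR] E_RELATIONAL_NEEDS_RELATED at character 0, state '0', annotation 2: relational quality PATO:9000001 requires a related entity
[NOTE] N_INCOMPLETE_CHARACTER at character 3: character 'Character 4' has unannotated state(s) 1
[ERROR] E_PROCESS_NEEDS_PROCESS_QUALITY at character 4, state '1', annotation 1: process entity GO:9000102 must be qualified by a descendant of PATO:0001236
...
$ echo $?
1
```

The seed-11 bundle plants exactly 3 missing-quality, 2 relational, 1
process-rule violation and 2 incomplete characters, and the report contains
exactly those eight findings — the checker and the generator are independent
implementations of the same rules, and their agreement is asserted by the
test suite. Exit code 1 signals findings of error severity (0 = clean,
2 = configuration problem).

The provisional-term lifecycle, end to end:

```
$ phenomatrix request "basipterygium" --definition "paired-fin support element" \
      --store orb.jsonl --submitter team
http://example.org/provisional/52e359cd-8012-4b46-a606-d8d0bf43332b
# ... the URI is used in 3 annotations; later an editor records the permanent id:
$ phenomatrix resolve http://example.org/provisional/52e359cd-... \
      http://purl.obolibrary.org/obo/UBERON_2000623 --store orb.jsonl
$ phenomatrix sync bundle/matrix.xml --store orb.jsonl --submitter team \
      --ontology bundle/anatomy.obo
http://example.org/provisional/52e359cd-... -> http://purl.obolibrary.org/obo/UBERON_2000623 (3 reference(s) rewritten)
```

A second `sync` reports `no migrations needed` — migration is idempotent.
Other subcommands: `validate` (structural NeXML check), `list-requests
[--pending|--resolved]`, `watch` (prints `SELF_SAVE` / `EXTERNAL_CHANGE` /
`DELETED` events for a matrix file being edited elsewhere).

The same operations are available as library functions
(`phenomatrix.request_term`, `check_document`, `sync_and_migrate`,
`EditSession`, …); the CLI is a thin binding over them.

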