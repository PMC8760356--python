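# Methods

## Scope and architecture

evilake re-creates the service patterns of a provenance-aware
computational data commons — registration, identifier minting and
resolution, object retrieval, computation, search, evidence-graph
extraction and visualization export, and object deletion — as a single
in-process library over a directory. The storage backends of a deployed
commons (an S3-compatible object store, a document database, a graph
database) are replaced by a filesystem object store and an append-only
JSON-lines registry with an in-memory `networkx` edge index; cluster
engines are replaced by a local executor contract. The service *semantics*
are kept: everything observable through the API (identifier behaviour,
provenance capture, closure extraction, challenge propagation, deletion
permanence) is specified independently of the backends.

## Identifiers

PIDs are ARKs, `ark:{naan}/{shoulder}{blade}`. The NAAN must be five
decimal digits (default `59852`, configurable; no external NAAN registry
is contacted). Blades are 8 characters drawn from the betanumeric alphabet
(digits plus consonants), following common ARK practice to avoid
accidental words; at 29⁸ ≈ 5·10¹¹ possible blades, collision probability
at desk scale is negligible, and the registry re-mints on the rare
collision so minting is injective within a registry by construction.
Parsing accepts the legacy `ark:/naan/name` spelling and normalizes to the
slashless form; the shoulder is recovered with the first-digit convention
(the shoulder ends at the first digit of the name). The shoulder
convention and blade length are declared package defaults, not values
inherited from any deployment. Alternative PIDs for one object are alias
records: they resolve to the canonical record but never appear as evidence
graph nodes, and edges referencing an alias are indexed against the
canonical PID.

## Records and serialization

Five record types exist: `Dataset`, `Software`, `Computation`, `Image`,
and `Challenge`. Structural rules enforced on every write:

- a `Computation` has ≥ 1 `usedSoftware` (every computation is launched
  from a registered script) and ≥ 0 `usedDataset` (a pure generator is
  legal); it never carries `generatedBy`;
- only `Dataset` and `Image` may carry `generatedBy`, and its target must
  be a `Computation`;
- every referenced PID must resolve at write time (no dangling edges), and
  the implied edge relation must remain acyclic;
- challenges reference their target but contribute no support edges.

Records serialize to flat JSON-LD 1.1 documents (`@id` = the ARK, `@type`
= the EVI term, provenance under `usedDataset` / `usedSoftware` /
`generatedBy` / `parameters`, checksum as `sha256:<hex>`). Null fields are
omitted; unknown keys round-trip through an `extras` bag, so serialization
is lossless in both directions over the supported vocabulary. The
`@context` maps terms to the `https://w3id.org/EVI#` namespace and is
bundled statically (also as `data/evi-context.jsonld`, which carries the
PROV subclass alignment), so no document ever requires a network fetch.
Authors are kept as literals, not Agent nodes; evidence graphs therefore
contain only the four result-graph types.

## Registry

A single-writer, multi-reader store: records in insertion order, an alias
map, challenges, full version history (updates bump `version` and keep the
prior record in an audit trail), and a `networkx.MultiDiGraph` edge index
keyed by predicate. Two invariants are maintained and tested: the index
always equals the index rebuilt from the records alone, and the relation
is acyclic after every accepted operation. A `create` cannot introduce a
cycle (a fresh PID has no incoming references, because dangling references
are rejected), so the expensive check runs only on edge-changing updates,
where a trial copy of the graph is checked with `networkx.find_cycle`
before committing; rejected updates leave the state untouched.

Persistence is an append-only JSON-lines event log (`create`, `update`,
`alias`, `challenge`, `tombstone`), replayed on open. Timestamps are a
deterministic logical clock — a fixed epoch plus one second per event —
rather than wall-clock time, so two registries built by the same seeded
operation sequence are bit-identical on disk. This is a deliberate trade:
the registry records *order*, not physical time.

## Object store and transfer

Objects are files under a root directory, addressed by sanitized relative
locations (`{ark-name}/{filename}`). Writes stream through SHA-256 in
1 MiB chunks (memory independent of object size) into a temporary file
renamed into place; if the computed digest differs from the claimed one
the temporary file is removed and nothing persists. Reads recompute the
digest against the store manifest and fail with both digests named on any
drift. Registration is atomic end-to-end: metadata is validated before any
bytes are written, and a failure at any stage leaves registry and store
byte-identical to their prior state. Metadata-only registration (no
payload) is allowed so externally archived objects remain citable.

## Compute

`submit` resolves every input PID first, then mints the `Computation`
record *before* execution — so failed runs remain auditable — with
`usedDataset`/`usedSoftware` set and, when runtime parameters are given,
a separate parameters record linked via `parameters`. Parameters stay out
of evidence graphs by default; `include_parameters=True` re-includes them
at extraction time.

Execution is synchronous, with the job lifecycle
(`queued → running → completed | failed`) retained for interface fidelity.
Executors receive only dereferenced local paths: inputs staged under
`data/`, outputs collected from `outputs/`. Engines:

- `local` — the registered software payload is run as a Python script,
  `python script.py <data_dir> <out_dir>`, in a scratch directory;
- `noop` — a caller-supplied in-process callable, used by the fixtures and
  for provenance-only runs;
- `spark` and `nipype` are recognized engine names that raise a clear
  configuration error: they are part of the interface, not of this build.

On success every output file is registered through the normal transfer
path with `generatedBy` = the computation, typed `Image` for raster
extensions (`.png .jpg .jpeg .gif .bmp .tif .tiff .svg`) and `Dataset`
otherwise — a declared package rule, since output typing must be decided
somewhere. On executor failure nothing is registered, the computation
record is annotated `status=failed`, and the scratch area is cleaned
either way.

## Evidence graphs and challenges

`extract(root)` computes the closure by breadth-first traversal — from
each entity its `generatedBy` computation, from each computation its
inputs and software — at unbounded depth (termination is guaranteed by
registry acyclicity). Node order is BFS level by level with lexicographic
PID order within a level; edges are sorted by (subject, predicate,
object); all exports (JSON-LD `@graph`, Cytoscape JSON, Graphviz DOT) are
therefore deterministic. Only the backward support closure is traversed:
registering a new computation that *consumes* a node never changes that
node's evidence graph.

Challenge semantics are simple reverse reachability: `undermined(e)`
returns exactly the challenges whose target lies in `extract(e)`'s node
set, each with one (shortest) support path from `e` to the challenged
node. Richer argumentation semantics — defeat, reinstatement, acceptance —
are intentionally out of scope; a challenge here is a flag with
provenance, not a defeasible argument.

## Search

Case-sensitive contiguous substring match over each record's literal
fields (name, description, author, string-valued extras), returning PIDs
in insertion order with the matching field names. No stemming, no ranking.
Tombstoned records keep their literals and remain findable.

## Deletion

`delete_object` removes bytes and nulls `content_location` in place —
version and every other field intact — recording a tombstone with the
prior location and digest (so a re-deposit can be verified as the same
bytes; a differing re-deposit is treated as a fresh version). Evidence
graphs and search results are provably unchanged by deleting any or all
payloads.

## The demonstration generators

`generate_hctsa(n_patients, seed, root)` emulates a cohort analysis over
neonatal-ICU vital-sign monitoring: per patient, a unique raw time-series
dataset (eight 10-minute samples of heart rate ~ N(140, 8²) bpm and SpO2 ~
N(97, 1.5²) %, seeded noise, < 1 KB), a per-patient analysis computation
(column means via the noop executor), and a processed feature set; shared
across the cohort, the analysis script, the clustering script, one
clustering computation consuming *all* processed sets, and one generated
heatmap PNG (8×8 grayscale). Everything flows through the public
`register`/`submit`/`run_job` paths — no store backdoors — so the closure
law |nodes(heatmap)| = 3·N + 4 certifies the whole pipeline: 7 nodes at
N = 1, 17,995 at N = 5997 with census {Image 1, Software 2, Computation
5998, Dataset 11994}. `generate_nested_workflow(depth, seed, root)` builds
a linear chain (seed dataset, then per step a script, a computation, an
output), giving 1 + 3·depth nodes — the deep, workflow-style graph.

What the generators do *not* emulate: real vital-sign dynamics, the actual
time-series feature battery (payloads are synthetic stand-ins; the
per-patient sub-steps live inside the analysis script and are not
separately registered), heatmap content, or any neuroimaging workflow.
Passing tests certify the provenance framework — identifier conservation,
closure structure, integrity, permanence, determinism — not any scientific
claim about the analyses themselves.

## Problem sizes and numerical choices

The test suite exercises cohorts of 1–10 patients for the closure law,
200 randomized DAG registries of ≤ 50 nodes for oracle equivalence
(extraction vs brute-force reachability, undermined vs the definitional
set), payload sizes 0 B–10 MB for integrity, and the full 5997-patient
cohort (≈ 18,000 records, ≈ 24,000 edges) end-to-end, which builds in
about 15 s on one CPU. Ties and orderings are all resolved
lexicographically on the rendered ARK; degenerate inputs (empty payloads,
single-node graphs, zero-dataset computations) are covered explicitly.

## Known limitations

Single-writer concurrency only; no SPARQL endpoint or OWL reasoning; no
authentication or multi-tenancy; no global ARK resolution (`n2t.net`
redirect rules are a deployment concern); no container execution; version
history is retained but prior versions are not resolvable by PID; the DOT
export targets rendering, not graph round-tripping.
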