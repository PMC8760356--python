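# evilake

A provenance-aware data commons in a directory: persistent identifiers,
hash-verified object storage, provenance-capturing computation, and
**evidence graphs** — the complete support DAG behind every computed
result — for research groups that need their computational results to be
transparent, citable, and challengeable without running a cluster, a
message broker, or an external database.

## The model

Every object — dataset, software, computation, image — is registered under
an ARK persistent identifier (`ark:NAAN/name`) with JSON-LD metadata in a
vocabulary extending W3C PROV (`Dataset`, `Software`, `Image` ⊑
`prov:Entity`; `Computation` ⊑ `prov:Activity`). Provenance is carried by
three typed, directed support relations:

```
entity       --generatedBy-->   computation
computation  --usedDataset-->   input dataset
computation  --usedSoftware-->  script / software
```

The registry keeps this edge relation acyclic at all times, so the
**evidence graph** of any PID — the exact reachability closure along those
edges — is a finite support DAG: all the data, code, and computations that
transitively support the result, and nothing else. Runtime parameters get
their own PID, linked via `parameters`, but stay out of evidence graphs
unless explicitly requested.

A **challenge** is a first-class assertion that some node is disputed
(retraction, algorithmic error, contaminated input, …). A result is
*undermined* iff a challenged node lies in its support closure — so a
single challenge deep in a graph propagates to everything built on it.

Object bytes are verified with SHA-256 on every write (claimed vs
recomputed digest; mismatches persist nothing) and re-verified on every
read. Deleting an object removes bytes only: metadata, provenance edges,
and search visibility are permanent, keeping deleted objects citable.

## Worked example

Build the bundled neonatal-ICU demonstration cohort (per patient: a raw
vital-sign dataset, an analysis computation, a processed feature set; the
analysis script, clustering script, clustering computation, and cluster
heatmap shared by all patients):

```sh
$ evilake --root lake demo hctsa --patients 1 --seed 7
raw analysis script: ark:59852/fk4b4dp12wk
clustering script:   ark:59852/fk43cm1j612
heatmap:             ark:59852/fk4kwq53mmp
evidence graph of heatmap: 7 nodes, 6 edges
```

The heatmap's evidence graph is the 7-node chain raw dataset → analysis
computation (+ script) → processed dataset → clustering computation
(+ script) → heatmap. Challenge the analysis script and the heatmap is
undermined, with the support path as evidence:

```sh
$ evilake --root lake challenge ark:59852/fk4b4dp12wk \
      --category error-in-algorithm --description "windowing bug"
ark:59852/fk4xdtzf18j
$ evilake --root lake undermined ark:59852/fk4kwq53mmp
ark:59852/fk4xdtzf18j  error-in-algorithm  ark:59852/fk4kwq53mmp -> ark:59852/fk449f4k3m9 -> ark:59852/fk4mmd171kx -> ark:59852/fk4wm37ppm1 -> ark:59852/fk4b4dp12wk
```

The same operations are available as a library:

```python
from evilake import Commons, Draft, EviType, sha256_hex

commons = Commons("lake", seed=1)
data = open("UVA_7219_HR.csv", "rb").read()
raw = commons.register(
    Draft(EviType.DATASET, "Raw Time Series Feature Set"),
    payload=data, sha256=sha256_hex(data), filename="UVA_7219_HR.csv",
)
job = commons.run_job(commons.submit([raw.pid], script_pid, engine="local"))
graph = commons.evidence_graph(job.output_pids[0])   # the full support DAG
```

Evidence graphs export as JSON-LD (`@graph` node array), Cytoscape JSON,
or Graphviz DOT via `evilake evidence-graph ARK --format jsonld|cytoscape|dot`.

## Layout

| module | role |
| --- | --- |
| `evilake.identifiers` | mint/parse/render ARK PIDs (betanumeric blades) |
| `evilake.model` | EVI record types, JSON-LD (de)serialization, validation |
| `evilake.registry` | durable JSON-lines metadata store + acyclic edge index |
| `evilake.store` | SHA-256-verified filesystem object store |
| `evilake.transfer` | atomic registration (mint + metadata + payload) |
| `evilake.compute` | provenance-capturing job execution (local / noop engines) |
| `evilake.graph` | evidence-graph extraction, challenges, exports |
| `evilake.search` | exact-substring search over metadata literals |
| `evilake.deletion` | delete bytes, keep metadata (tombstones) |
| `evilake.fixtures` | deterministic demonstration registries |
| `evilake.commons` | the `Commons` facade wiring everything together |
| `evilake.cli` | the `evilake` command |
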