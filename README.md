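# minkit

Analysis of molecular interaction networks (MINs): undirected graphs of
cellular components whose edges may carry confidence scores in [0, 1].
Every analysis operation runs on a vertex-centric, bulk-synchronous
superstep engine with a serial reference executor and a partitioned
multi-worker executor that are guaranteed to produce identical results.

## Features

- **Graph model** (`minkit.model`) — validated simple graphs; duplicate
  interaction records collapse to the maximum score, self-loops are
  dropped, graphs are homogeneously weighted or unweighted; edges are
  hashed into stable partitions.
- **I/O** (`minkit.io`) — PSI-MI TAB (MITAB) reading with configurable
  confidence keys (`intact-miscore` first by default), plain edge-list
  reading (with STRING-style score rescaling) and byte-reproducible
  sorted edge-list writing.
- **Engine** (`minkit.engine`) — Pregel-style superstep execution of
  user programs (vertex update / send message / merge message), with
  commutativity checking of the merge function.
- **Statistics** (`minkit.stats`) — counts, density, degree tables with
  deterministic top-k, harmonic closeness (unreachable vertices
  contribute 0).
- **Neighborhoods** (`minkit.neighborhood`) — k-hop neighborhoods of a
  source set and max-path-product threshold neighborhoods of a single
  source, plus their induced subgraphs.
- **Components** (`minkit.components`) — connected components by
  min-label propagation, closest-component and per-component
  intersection queries.
- **Dispersion** (`minkit.dispersion`) — Kleinberg dispersion K(u, v)
  over common-neighbor pairs.
- **Synthetic data** (`minkit.synth`) — seeded preferential-attachment
  generator and independent brute-force oracles (path enumeration, BFS,
  union-find, pairwise connectivity) used as ground truth in tests.

## CLI

Every subcommand reads `--input` in `--format edgelist` (default) or
`mitab`, accepts `--workers N` and `--partitions N` (results are
byte-identical for any setting), and writes tab-separated text to stdout
or `--output`. Exit codes: 0 success, 1 invalid input/parameters, 2 I/O
failure.

```sh
minkit generate --n 1000 --attach 2 --weights uniform --seed 7 --out net.tsv
minkit stats --input net.tsv --weight-col 2
minkit degrees --input net.tsv --weight-col 2 --top 20
minkit closeness --input net.tsv --weight-col 2 --node p000001
minkit xneighbors --input net.tsv --weight-col 2 --nodes p000001,p000002 --x 2
minkit xwneighbors --input net.tsv --weight-col 2 --node p000001 --x 0.45
minkit components --input net.tsv --weight-col 2
minkit closest-component --input net.tsv --weight-col 2 --set p000001,p000009
minkit intersect-components --input net.tsv --weight-col 2 --set p000001
minkit dispersion --input net.tsv --weight-col 2 --u p000001 --v p000002
minkit convert --input interactions.mitab --format mitab --output net.tsv
```

Add `--subgraph` to `xneighbors`/`xwneighbors` to emit the induced
subgraph as an edge list instead of the member table.

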