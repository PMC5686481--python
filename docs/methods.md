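# Methods

## The problem and the data model

`randnet` builds null models for simple undirected networks and compares
numeric node attributes of a real network against those of a random
ensemble. The core type is a validated simple graph: string node ids, an
unordered edge set, no self-loops, no parallel edges. Graphs are immutable
and compare equal independently of insertion order; every generator output
satisfies the handshake lemma (asserted in the tests). Node attributes —
typically centralities computed by an external tool — live in a separate
table mapping node id → attribute name → value. Attribute names are
case-sensitive throughout: `Degree` and `degree` are different attributes,
and the comparison module only offers attributes shared by *all* selected
networks.

## Random network models

All generators are deterministic under a fixed seed; generated node ids are
`n0, n1, …` (lattices use 0-based coordinates joined with `_`).

* **Erdős–Rényi.** `G(n, M)` draws exactly M distinct non-loop pairs
  uniformly; `G(n, p)` includes each of the C(n, 2) pairs independently
  with probability p. Backed by networkx's generators.
* **Watts–Strogatz.** Ring lattice of n nodes, each wired to its k nearest
  neighbours (k even, 0 < k < n); each edge's far endpoint is rewired with
  probability β to a uniform node, rejecting loops and duplicates — the
  canonical small-world procedure (networkx). β = 0 leaves the pure ring
  lattice, whose average clustering has the closed form 3(k−2)/(4(k−1));
  rewiring conserves the nk/2 edge count.
* **Barabási–Albert.** Authored in-package to pin the seed-graph
  convention: m isolated seed nodes; each arriving node connects to m
  distinct existing nodes sampled proportionally to degree (the first
  arrival necessarily takes all m zero-degree seeds), giving exactly
  (n − m)·m edges and a right-skewed, power-law-tailed degree distribution.
  m = 1 yields trees.
* **Lattice.** One node per coordinate tuple of the requested box; edges
  join tuples differing by 1 in exactly one coordinate. The torus option
  wraps every dimension (no end nodes) and requires every dimension ≥ 3 so
  wrap-around edges stay simple. A 1-D lattice is a path; a 1-D torus a
  cycle.
* **Community Affiliation Graph Model.** Input rows of (edge probability,
  member names). Every member pair of every community receives an
  independent Bernoulli trial; a pair sharing several communities is
  connected if any trial succeeds (union semantics — the standard reading;
  the per-community trials are independent). No edge can appear between
  nodes sharing no community.

## Randomisation of an existing network

* **Simple shuffle** keeps the node set and edge count and resamples the
  edge set uniformly (without replacement) from all C(n, 2) pairs: the
  output is uniform among simple graphs with that node set and edge count.
* **Degree-preserving shuffle** applies double-edge swaps
  (a,b),(c,d) → (a,d),(c,b), rejecting any swap that would create a loop or
  duplicate. The swap budget defaults to 10 × |edges|, a common mixing
  heuristic for double-edge-swap Markov chains; rejected attempts count
  toward the budget so runtime is deterministic. Graphs with fewer than two
  edges are returned unchanged with a warning. Connectivity is *not*
  preserved.

Both shuffles are pure: the input graph is never mutated and a fixed seed
reproduces the output exactly.

## Multiplication model

Simulates a set of weighted experiments on a fixed topology. From a value
file (one number per row; the row count is expected, but not required, to
match the node count — a mismatch warns and proceeds) the range
[min, max] is extracted, and each node receives an integer weight drawn
uniformly from {max(1, ⌊min⌋), …, ⌊max⌋}. Weights are integral because the
graphical output materialises them as node copies; the uniform-integer
choice reproduces the worst case of max·n total nodes (a 10-node network
with values in [0, 100] can reach 1000 nodes) and the boundary behaviour
that a file of only zeros and ones never multiplies (all weights 1).

The default output is the unchanged topology plus a `weight` attribute.
The graphical output adds, for each node v of weight w_v, the copies
`v__copy1 … v__copy{w_v−1}`; each copy connects to every *original*
neighbour of v, and {v} ∪ copies(v) forms a clique, so the node count is
exactly Σ w_v and the restriction to original nodes equals the input graph.
Copies of adjacent multiplied nodes are deliberately **not** interconnected:
a copy inherits the original's neighbours, which are original nodes. The
graphical network is for visualisation; no analytics should be run on it.

## Two-sample Kolmogorov–Smirnov comparison

The distance between two attribute samples is the maximum absolute gap
between their ECDFs. The ECDFs are never materialised: both samples are
sorted and traversed in one merged pass, accumulating normalised step
heights and keeping the largest gap. Ties across the two samples are
resolved by advancing both accumulators over *all* elements equal to the
current value before measuring — the two-sided convention, which makes
replicated samples (e.g. [1,2,3] vs [1,1,2,2,3,3]) exactly distance 0.

Numerical choices: in the default count normalisation (each observation
contributes 1/sample-size) the accumulators are integer tie counts and the
gap is the cross-multiplied |i·n_b − j·n_a| / (n_a·n_b), so replicated
samples give *exactly* 0 and disjoint ordered supports *exactly* 1, with no
floating-point drift. An alternative `value_sum` normalisation (each
observation contributes value/sum-of-sample) is exposed as a non-default
option; it requires strictly positive sample sums and is not
replication-invariant in general, which is why count normalisation — the
standard ECDF — is the default. No p-value is computed: the distance is
reported and interpreted qualitatively (0 = identical up to replication,
near 1 = strong separation). Nodes lacking a selected attribute are skipped
with a warning rather than imputed as 0, which would distort the ECDF.

## Reports

Reports are text files of fields: a `>`-prefixed explanation line followed
by CSV rows; the first fields name the real and random networks. With one
real network the fields are the per-random average distance across
attributes, the most similar random network per attribute, and the full
attribute-by-random matrix; with several real networks, the per-real
distance to its most similar random network, the most similar random
network per (real, attribute), and the real-by-random matrix of
attribute-averaged distances. Averages are exactly the means (or row
minima) of the corresponding matrix field, a consistency the tests recheck
after a write→parse round trip. Numbers are printed with 6 significant
digits and `.` as the decimal separator; the format round-trips through the
bundled parser.

## File formats

Edge-list (two whitespace-separated tokens per row) and SIF
(`source interaction target`; the interaction type is discarded — this is a
topology-only tool). A one-token row declares an isolated node, so the
write→read round trip is exact for any graph. Duplicate rows collapse;
self-loop rows are dropped with a warning. Attribute tables are CSV with an
id column; value files hold one number per row with `.` as decimal
separator; community files hold `p member member …` per row (member names
cannot contain whitespace — no quoting rule is defined, so such names are
rejected rather than guessed at). The GUI-style row-count confirmation for
value files becomes a non-interactive logged warning, preserving the check
without blocking batch runs.

## CLI and reproducibility

Subcommands `generate`, `randomize`, `multiply`, `compare`; replicate i of
a run with seed s uses seed s + i, so runs are byte-reproducible while
replicates differ. `--replicates` defaults to 1 (one network per selected
model). Selecting both shuffle modes in one `randomize` run emits one
output per mode. Each subcommand accepts a YAML `--config` whose entries
act as defaults for flags not given explicitly.

## What the tests do and do not show

The suite exercises desk-scale problems: graphs of tens to a few thousand
nodes, attribute samples of 1–200 values, ensembles of ≤ 100 seeds. The
statistical checks (e.g. the G(n, p) mean edge count over 500 seeds within
3 standard deviations; the Barabási–Albert tail versus a matched G(n, M))
validate the generators' moments and qualitative shape, not their full
distributions. The streaming K–S implementation is checked against an
independent brute-force ECDF oracle (1000 random sample pairs, agreement
within 1e−12) and against `scipy.stats.ks_2samp`; scipy is a test-only
dependency, never the implementation. Synthetic fixtures are toy graphs
with known structure — they do not emulate the degree heterogeneity, noise
or missingness of real interactomes, so passing tests certify the
algorithms' contracts, not biological conclusions.

## Known limitations

Directed and edge-weighted graphs are out of scope; the degree-preserving
shuffle may change connectivity; with a low swap budget it mixes
incompletely (the default 10 × |edges| is a heuristic, not a mixing-time
guarantee); the multiplication model's uniform-integer weights are one
defensible reading of "random weights in the range"; and the K–S distance
carries no significance level — judging what distance matters is left to
the analyst.
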