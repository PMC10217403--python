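# Methods

## Scope and model

`rettnet` implements a seed-gene interactome analysis: given a curated
catalog of disease genes in two classes — RTT (classical + atypical Rett
syndrome genes) and RTT-L (Rett-syndrome-like genes from a sequenced cohort
and from literature curation) — it builds the first-order protein–protein
interaction network around them, measures topology, restricts the network
to a tissue, and tests the seed list for annotation-term over-representation.
The analysis is deterministic end to end: identical inputs give
byte-identical reports.

## Seed catalogs

Gene symbols are normalized by uppercasing, trimming and deleting internal
whitespace; no alias or HGNC resolution is attempted, because the curated
lists are already symbol-level and alias mapping would silently import an
external database. A symbol may belong to several classes: MECP2 is both a
classical and an atypical RTT gene (counted once in the distinct RTT
count), and six cohort genes (GABRG2, GRIN1, GRIN2A, KCNB1, KCNQ2, TCF4)
also appear in the literature list, so the RTT-L union has 60 distinct
symbols while the literature list alone has 58. Both views are exposed;
the pipeline's `rttl_choice` option (`union`, default, or `literature`)
makes the selection explicit rather than baking one in.

The cohort phenotype table carries twelve Y/N phenotype columns per
patient. Of the five main diagnostic criteria (regression, loss of hand
skills, loss of spoken language, gait abnormalities, hand stereotypies)
only three have matching columns; the default criteria map covers exactly
those three and the mapping is configuration, not code — we do not invent
phenotype data for the missing columns. CADD scores are stored as data and
never computed.

## Network construction

The first-order network retains exactly the interactions with at least one
seed endpoint whose evidence class passes the filter (default:
`experimental` only, matching the practice of building physical PPINs from
experimentally validated interactions). The graph is simple and
undirected: duplicate rows merge (unioning source and tissue annotations),
self-loops are excluded from the edge set but counted, and seeds left
without any retained interaction are listed as *isolated* rather than
dropped — losing a seed is a scientifically meaningful outcome (CDKL5-like
behaviour under tissue filtering) and must stay visible. Node classes are
RTT_SEED > RTTL_SEED > INTERACTOR, RTT taking precedence for dual-listed
symbols because it is the stricter diagnostic class.

## Topology

Centralities follow the conventions of Cytoscape's NetworkAnalyzer for
simple undirected graphs:

- **degree** — incident edge count;
- **betweenness** — Brandes' algorithm (networkx), counting each unordered
  pair of distinct endpoints once and excluding the endpoints; the raw pair
  count is reported alongside the normalized value raw·2/((N−1)(N−2));
- **closeness** — the Wasserman–Faust component-scaled form
  ((n_c−1)/Σd)·((n_c−1)/(N−1)), chosen because the analysis network is
  disconnected by construction (some seeds form small islands); isolated
  nodes score 0.

Group summaries use linear-interpolation (type-7) quartiles. Hub ranking
sorts descending by the chosen metric with ties broken by ascending symbol,
making top-k lists deterministic and prefix-consistent. Dense-cluster
inspection is realized as hub ranking plus sub-network extraction around
the top-k hubs rather than a menu of proprietary cluster scores.

Tests verify betweenness and closeness against an independent brute-force
oracle (all-pairs BFS distances and path counts, exact rational
arithmetic) on hundreds of random graphs up to 50 nodes, at 1e-9 absolute.

## Tissue restriction

Expression calls use the four-level ordinal atlas scale {not_detected,
low, medium, high}; duplicates for a (protein, tissue) aggregate by
maximum. A protein is expressed iff its call is anything other than
*not detected*; a protein with **no** call for the tissue is treated as not
expressed and removed. This default reproduces the observed behaviour of
seeds that drop out of a brain-specific network purely for lack of
protein-level data; `keep_uncovered=True` inverts it. Filtering keeps a
node iff expressed and an edge iff both endpoints survive, so it is
idempotent and monotone in the expression table — both are tested. Edge
tissue flags from the interaction table are retained and can serve as an
alternative edge-level filter, but node-expression filtering is the
default semantics.

Partner sets exclude seeds: `rtt_partners` / `rttl_partners` are
INTERACTOR nodes adjacent to at least one seed of the class, and the
common interactors are their intersection. Whether one *should* count a
seed adjacent to the other class as a "partner" is genuinely ambiguous;
excluding seeds keeps the common-interactor set a set of third-party
bridges, and the report documents the convention so external counts are
compared like for like.

## Sub-networks

A seed-mediated sub-network is, by default, the induced subgraph on the
anchors plus their first-order neighbors. Induction (keeping
neighbor–neighbor edges) is the default because it preserves the local
interaction density around the anchors; `induced=False` restricts to
anchor-incident edges. Missing anchors are reported and tolerated; only
losing all anchors is an error.

## Enrichment

The raw statistic is the hypergeometric upper tail P(X ≥ k) for overlap k
between a query of size n and a term of size K in a universe of N genes.
Sums are taken over log-pmf values with `logsumexp`, so deep tails remain
accurate far below the underflow range of direct products. A two-sided
minimum-likelihood mode (sum of all outcome probabilities ≤ that of the
observed k, with 1e-9 log-slack for floating-point ties) is provided;
upper-tail is the default because over-representation is the question
being asked. Correction is Bonferroni with scope per source by default
(each annotation database corrected by its own term count, the behaviour
of common ORA web services), with a global option. Terms with zero overlap
count toward m but are not reported. The default universe is the union of
the source's member symbols; alternatives are the network's node set or a
user list — the choice materially changes p-values and is therefore
explicit configuration. Exactness is tested against exhaustive rational
enumeration for every admissible (N ≤ 12, K, n, k) at 1e-12 relative, and
tail monotonicity in k is property-tested.

## Synthetic data

The generator emulates the features the analysis relies on, not any
database's content:

- **Backbone**: Barabási–Albert preferential attachment (default
  n_nodes = 2250, m = 2), giving the heavy-tailed degree distribution that
  makes hub analysis meaningful; an Erdős–Rényi mode exists for statistical
  tests. The backbone is connected before planting.
- **Seeds**: 4 RTT + 58 RTT-L symbols sampled uniformly, mirroring the
  study's seed-list sizes.
- **Planted common interactors** (default 63): accidental cross-class
  partners are first unwired (their edges to RTT seeds removed), then
  exactly k nodes are wired to ≥ 1 seed of each class. Planting adds edges
  rather than rewiring, so planted nodes' degrees can rise slightly above
  the backbone distribution — accepted to keep the rest of the backbone
  intact.
- **Expression** (default p_uncovered = 0.05, p_not_detected = 0.15):
  independent per protein — no record at all with p_uncovered, a
  *not detected* call with p_not_detected, otherwise low/medium/high
  uniformly; a named seed can be forced uncovered to reproduce the
  data-gap dropout scenario.
- **Gene sets**: one planted term with an exact (K, k) overlap against a
  designated query (default K = 20, k = 15) among uniformly drawn terms.

What the generator does **not** emulate: the true size and density of a
real interactome snapshot (the synthetic first-order network is smaller
and sparser than a real database yield), correlated expression across
tissues, annotation-term overlap structure, and study-bias in which
proteins are well covered. Passing tests therefore demonstrate the
pipeline's correctness and its contracts (exact planted-count recovery,
filter idempotence/monotonicity, enrichment power at the planted effect
size), not numerical agreement with any particular database release —
counts from real snapshots depend on the snapshot and are expected to
differ.

## Numerical and degenerate-input choices

- Betweenness/closeness tolerances: oracle agreement at 1e-9 absolute;
  graphs with N ≤ 2 have normalized betweenness defined as 0.
- Hypergeometric bounds are validated; out-of-support overlaps raise.
- Tie-breaks everywhere are lexicographic on symbol; all outputs are
  written in sorted order so files and reports are reproducible.
- Empty inputs: an empty expression table yields an empty filtered network
  (with a warning); an empty network exports a header-only file; an empty
  seed catalog is an error.
- All randomness flows from a single integer seed per generator call;
  replicate seeds are derived additively and kept below 2^31.

## Problem sizes used in validation

The packaged validation suite runs the centrality oracle on 200 random
graphs (n ≤ 50), the hypergeometric enumeration exhaustively to N = 12,
planted-term recovery over 100 replicates at universe 1000, and pipeline
determinism on a few-hundred-node synthetic study; the acceptance script
uses the full-scale generator defaults (2250 nodes) for planted-structure
recovery. These sizes exercise every code path while keeping the suite
fast enough to run routinely.

## Known limitations

- Symbol-level identity only: no mapping between gene symbols, UniProt
  accessions or Ensembl IDs; inputs must agree on nomenclature.
- Flat gene sets: no ontology-graph propagation for GO terms; terms are
  used exactly as given in the GMT.
- No confidence weighting of interactions; evidence classes are a filter,
  not a score.
- The expression rule is binary (detected vs not); quantitative thresholds
  (TPM cutoffs) are out of scope.
- Real-database headline counts (network size, partner counts, enrichment
  p-values) are snapshot-dependent and not reproducible from the package
  alone; the package instead guarantees the procedure and its contracts.
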