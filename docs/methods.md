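# Methods

This note documents the models implemented in `biblionet`, the numerical
choices behind them, what the synthetic benchmarks do and do not show,
and the known limitations.

## Corpus ingestion and term extraction

MEDLINE flat files are parsed with Biopython's Medline reader; the DP
field is reduced to (year, month), accepting month names and numerals
and mapping seasons/quarters to a missing month. Records without a PMID
are skipped and counted; for duplicate PMIDs the first occurrence wins.

Published bibliometric studies rarely state their text cleaning in
reproducible detail, so the pipeline fixes one explicit recipe: lowercase
tokens, the scikit-learn English stopword list, suffix-rule plural
folding ("genes"→"gene", "pathologies"→"pathology"; -ss/-us/-is words
untouched; the rules are idempotent by construction), and word n-grams up
to length 3 that never span punctuation. Terms below a document-frequency
floor (`min_df`, default 5) are dropped. Affiliation strings resolve to
an institution via an alias table, else the first comma-separated segment
containing an institutional keyword (University, College, Hospital,
Institute, Academy, Center/Centre); the country is the last gazetteer
match in the string. This is a documented stand-in, not a reconstruction
of any particular study's disambiguation.

All rankings break ties lexicographically so outputs are deterministic.

## Co-occurrence networks

Node frequency F(i) and edge co-frequency CF(i,j) are document counts.
Collaboration (institution) networks are Jaccard-normalized —
CF/(F(i)+F(j)−CF), the overlap of the two document sets — which corrects
for institution size; term networks keep raw CF by default, with
normalization behind a flag. Communities come from networkx's Louvain
implementation (greedy local moving on modularity) with a resolution
parameter and a seed; labels are relabeled to contiguous integers ordered
by community size so runs are comparable. A configurable minimum
community size (default 1 = disabled) merges smaller groups into their
strongest-connected neighbor. Exact reproduction of any specific
VOSViewer clustering is out of scope: its quality function and parameters
differ slightly, so community counts on real corpora are qualitative.

## Streaming topic evolution (SEP)

Documents become term-frequency vectors over the extracted vocabulary,
L2-normalized. Normalization makes the two metrics in play consistent:
for unit vectors E² = 2 − 2·cos, so the cosine-nearest candidate topic
is also the Euclidean-nearest, and the drift ratio (E − r)/r is evaluated
against the candidate that cosine similarity selects.

Slices are calendar months (or years). The first non-empty slice seeds a
single topic; slice-1 documents are tested against it alone, later
slices against all existing topics. Classification uses the topic state
frozen at slice start; assigned documents are folded in (centroid,
radius, label recomputed over the full membership) and drifted documents
clustered once at slice end, so document order within a slice cannot
change the result. Lineage edges run from each topic that rejected
documents into the descendant that absorbed them.

Numerical choices:

* **σ = 0.1** is the default drift threshold; raising it makes topics
  more absorbent, and topic counts are non-increasing in σ on a fixed
  stream (checked empirically in the suite).
* **Zero-radius topics** (singletons, identical members) make the ratio
  undefined; any distance above 1e-9 counts as drift there, since any
  measurable departure from a degenerate topic is novel.
* **K selection** for descendant clustering scans K = 2..min(k_max, n−1)
  with K-means (K-means++ init, 10 restarts, seeded) and keeps the best
  mean silhouette, falling back to K = 1 when n < 3 or no K reaches a
  silhouette of 0.25. The floor matters: a single noisy document cloud
  scores weakly positive (~0.1) silhouettes at any K, and splitting on
  those shatters coherent topics; 0.25 is the conventional boundary
  below which cluster structure is considered weak.
* Topic labels are the most document-frequent member term, ties
  lexicographic.

## Heterogeneous bio-entity network

PubTator annotations map onto four categories (Disease, Chemical, Gene;
Mutation/SNP/DNAMutation/ProteinMutation → variant); other types are
dropped with a count. Cleaning keeps diseases/chemicals that resolve in
the MeSH dictionary, genes present in the human gene dictionary, and
variants that map to an rsID, merging mutation-notation aliases with
explicit SNP mentions under one variant node. Everything unresolved is
tallied, never fatal. The shipped dictionaries are small hand-built
fixtures (35 MeSH descriptors, 30 human + 2 murine genes, 20 rsIDs) that
make reports read naturally; full MeSH/NCBI/dbSNP tables can be swapped
in as TSVs of the same shape.

Edge weight is the number of co-mentioning documents; intra- and
inter-category edges both count, and the 4×4 category tally counts each
unordered edge exactly once, so the table total equals the edge count.

Centralities are computed on the unweighted skeleton — the distances are
topological hop counts — with weights reserved for edge existence and
the intersection ratio. Degree centrality is neighbors/(|V|−1);
betweenness is shortest-path betweenness normalized by (|V|−1)(|V|−2)/2;
closeness uses the Wasserman–Faust correction
(reachable/(|V|−1))·(reachable/Σd), which equals the classical
(|V|−1)/Σd on connected networks and degrades gracefully on the
disconnected ones real corpora produce. All three are validated against
an independent brute-force oracle (plain BFS plus exhaustive
shortest-path enumeration) to 1e-9 in the test suite.

### Entropy-weight combination

Each centrality's value set is min-max normalized, and its Shannon
entropy decides its weight: w = (1 − H)/(3 − ΣH). A centrality whose
distribution barely discriminates between nodes (H near 1) earns little
weight. The default mode converts normalized values to proportions
p_i = n_i/Σn before the entropy, the standard entropy-weight
construction that keeps H ∈ [0, 1]; a `literal` mode evaluates the
entropy on the min-max values directly, which can push H above 1 and
1 − H negative, and is retained only for comparison with the published
form of the formula. A constant centrality is degenerate (min-max
undefined): it receives weight 0 and the remaining weights renormalize,
with a log message.

### Intersection ratio and the emerging-gene map

IR(v) = w(v, target disease)/Σ_d w(v, disease d) ∈ [0, 1]; genes with no
disease edges are reported as IR 0 with an explicit flag rather than a
silent zero. For the map, IR (x-axis) and the centrality combination
(y-axis) are min-max normalized over the genes and split at configurable
thresholds (default 0.5/0.5). Quadrant I (high on both) minus the top-k
genes by combined centrality — the established, "frequently highlighted"
players, k = 4 by default — is the emerging list, ranked by normalized
IR then combined centrality. Raw entity frequency counts mentions by
default (documents behind a flag).

## Synthetic benchmarks: what they emulate

* **Topic stream**: four topics with disjoint 12-term vocabulary blocks,
  born at slices 0/2/3/4 over six monthly slices, 80 documents per
  active topic per slice (≈1,200 documents), each document drawing 12
  tokens from its block with 10% off-block noise. This is the study
  condition for topic recovery: the default run recovers the planted
  count within ±1 with document-lineage ARI ≥ 0.8 in ≥ 8/10 seeds.
* **Collaboration corpus**: a planted partition over 30 institutions in
  3 communities; each document anchors one institution and recruits
  others with probability p_in = 0.9 inside, p_out = 0.05 across.
  Louvain on the Jaccard-normalized network recovers the plant at
  ARI ≥ 0.9.
* **Bio-entity corpus**: 300 PubTator-format documents in three recipes.
  Hub-gene documents give ACE2 the broadest co-mentions (highest
  expected degree and closeness). Specific-gene documents pair ISG15
  with the target disease only — never a distractor disease, so IR = 1
  by construction — while drawing chemicals and variants from the whole
  pools, including peripherals no other recipe touches, so the specific
  gene is their only bridge into the network and keeps a high combined
  centrality: the profile of an emerging gene, broadly discussed but
  only in the target-disease context. Because this world plants exactly
  one established hub, analyses of it use a highlighted set of size 1;
  the package default of 4 reflects the multi-hub structure of real
  corpora.

Generators are pure functions of (parameters, seed); identical inputs
give byte-identical corpora.

What passing these benchmarks does **not** show: real literature has
overlapping topic vocabularies, drifting term usage, noisy NER output,
skewed entity frequencies and institutional name variants far messier
than the alias-table model. Recovery on planted orthogonal structure is
a correctness check of the machinery, not a performance claim on PubMed.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
≈1,200-document streams, 30-institution collaboration corpora,
300-document bio-entity corpora, brute-force network oracles at n ≤ 30.
These sizes make planted structure unambiguous while keeping a full run
in seconds; all of them scale up through ordinary parameters.

## Known limitations

* Term/affiliation cleaning is a fixed, documented recipe, not a learned
  disambiguator; institutions that never mention a keyword and have no
  alias entry are unresolved (and logged).
* SEP never merges topics, and a document, once assigned, is never
  reassigned; both mirror the streaming design but can fragment
  long-lived themes on noisy corpora.
* The silhouette-based K selection is the weakest link of descendant
  spawning: simultaneous unrelated drifts in one slice are clustered
  jointly and may land in one descendant if their separation is weak.
* Force-directed layouts and interactive visualization are out of scope;
  the exports (GraphML, Pajek, CSV) target external tools.
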