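# Methods

This note records the models, conventions and numerical choices behind
`phononet`, in enough detail to reproduce or challenge any of them.

## The network model

Nodes are word forms (or lemmas); an undirected edge links two words whose
phoneme sequences are at token-level Levenshtein distance exactly 1 —
one substitution, addition, or deletion of a single phoneme, with unit costs
and no transposition. The graph is simple: homophones (identical
transcriptions, distinct spellings) are distinct nodes at distance 0 and are
never linked, though they share all neighbors. Words with no neighbors
("hermits") remain in the network as isolates.

### Phoneme segmentation

Transcriptions arrive as IPA strings and are segmented by greedy longest
match against a phoneme inventory. The shipped default is a General-American
inventory: 24 consonants (affricates tʃ dʒ as single tokens), the usual
monophthongs, the diphthongs aɪ aʊ ɔɪ eɪ oʊ and the rhotic vowels ɝ ɚ as
single tokens; stress marks (ˈ ˌ), length (ː) and syllable dots are stripped
before matching. Treating diphthongs and affricates as one phoneme matches
the granularity of the CMU pronouncing dictionary, the usual source of North
American English transcriptions, and therefore determines what "one phoneme
edit" means. Segmentation conventions are not universal; the inventory is a
configurable object precisely because a different convention (e.g. diphthongs
as two units) changes the edge set. Greedy longest match is deterministic and
independent of the order the inventory happens to list its tokens.

### Construction

Edges are found with a deletion-key index: every sequence is bucketed under
its exact key and each of its delete-one-position keys. Any distance-1 pair
must share a bucket (deletion/addition pairs share exact-vs-deleted keys;
substitution pairs share the key with the differing position deleted), and
bucket co-members are verified by an exact distance-1 check, so the index is
provably edge-equivalent to the brute-force all-pairs scan — and the test
suite asserts exactly that equivalence on 50 seeded lexicons, plus agreement
with an independent alignment library (edlib) on the pair predicate.
Expected cost is near-linear in the lexicon for realistic word lengths,
against quadratic for the scan.

### Inflection filter

Phonological similarity networks are blind to morphology, so word-form
networks link bases to their inflected variants (cat–cats). The filter
removes every edge whose endpoints carry the same lemma annotation (a node
without one counts as its own lemma); no nodes are removed and the operation
is idempotent. "Same stem differing only in inflection" is not computable
without a morphological analyzer, so equality of lemma annotations is the
operationalization; a custom predicate can replace it.

## Frequency thresholding

Smaller lexicons are simulated by removing low-frequency words: entries at
or above the median frequency (ties count as above) are always kept when
they fit the target size; the rest of the quota is filled from below-median
entries by weighted sampling without replacement with probability
proportional to frequency (an exponential-race draw, so the sample is exact
and seeded). A deterministic `top-n` frequency-cutoff mode is available.
Ladders of sizes are built top-down so each smaller sample nests inside the
next larger one, making networks along a ladder directly comparable; nesting
is this package's choice, not a universal convention.

## Measures

* **Components.** Giant component = largest connected component (ties broken
  by smallest node key); islands = other components of ≥ 2 nodes; hermits =
  isolates. An edgeless network has *no* giant component (giant count 0):
  a lone node is a hermit, not a giant.
* **Density** 2E/N(N−1); **mean degree** 2E/N, with giant-component degree
  statistics (mean, max, population SD) reported for the GC scope.
* **Assortativity**: Pearson correlation of degrees over symmetrized edge
  endpoints (Newman's r); undefined and signalled as such when all endpoint
  degrees are equal.
* **Heterogeneity**: the Estrada index, Σ_edges (k_i^(−1/2) − k_j^(−1/2))²
  normalized by N − 2√(N−1) — 0 for regular graphs, 1 for stars. Chosen
  because it is the standard normalized [0,1] heterogeneity measure and
  reproduces the low, size-shrinking values phonological networks show; the
  ratio ⟨k²⟩/⟨k⟩² is a different quantity and is not what is reported here.
* **Closeness** is component-scaled: ((n_r−1)/Σd)·((n_r−1)/(N−1)) with n_r
  the reachable set — words in small islands get values near 0, isolates
  exactly 0, which is what makes before/after backbone comparisons of
  disconnected networks meaningful.
* **Group comparisons** use Welch's unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom (a pooled test would be wrong for
  the very unequal class sizes backbone analysis produces). Both groups
  having zero variance and equal means is reported as undefined rather than
  t = 0.

## Small-world analysis

L (ASPL) and C (mean local clustering) are computed on the giant component;
the reference ensemble is G(n, m) matched to the GC's node and edge counts,
10 replicates by default, and S = (C/C_ER)/(L/L_ER) with S > 3 the
conventional small-world threshold. Random graphs this sparse are usually
disconnected, so ensemble ASPL is computed on each replicate's largest
component; clustering is averaged over all n nodes. All-pairs distances run
as chunked breadth-first searches through scipy's csgraph so the full
distance matrix is never materialized.

## Degree-distribution fitting

Degrees are integers, so candidate families are *discrete* distributions on
k ∈ {1, 2, ...}: exponential, power law (α > 1), truncated power law, and
log-normal. No lower-cutoff (xmin) optimization is performed — the whole
observed range is modelled, k_min = 1 — which deliberately diverges from
power-law-toolkit default behaviour; a different k_min can be passed.
Normalization is by direct summation to max(10·max degree, 10⁵); every
family's tail beyond that bound is negligible at the 1e−9 tolerance the
tests assert for PMF normalization. MLE uses bounded scalar optimization for
the 1-parameter families and L-BFGS-B on sufficient statistics for the
2-parameter ones. Goodness of fit is the KS distance between fitted and
empirical CDFs at the observed degrees; ranking is ascending KS with a
parsimony tie-break: fits within 2e−3 of their group's best KS are ordered
by parameter count, because the truncated power law nests both the pure
power law (λ→0) and the exponential (α→0) and optimizer noise would
otherwise decide nested ties arbitrarily.

## Robustness

Nodes are removed up to a fraction grid (default 0–0.95 by 0.05), either
uniformly at random (averaged over seeded replicates) or by descending
*initial* degree with ties broken by node key — simultaneous ranking, since
adaptive re-ranking is a different experiment (available behind a flag).
The outcome is |largest remaining component| / original N, so curves start
at the intact giant share and end at 0. The divergence point is the first
grid fraction where |attack − failure| exceeds 0.05. A caution from the
synthetic experiments: on the giant component of a strongly assortative
network, early targeted attacks can be marginally *less* fragmenting than
random failures, because the high-degree core is densely interlinked and
redundant; the familiar attack-is-worse ordering holds once removal reaches
the collapse regime, and at every fraction on the full network, where random
removals also land on hermits and islands.

## L-Spar backbone

Each node of degree d marks its ⌈d^s⌉ incident edges of highest endpoint
Jaccard similarity (open neighborhoods, exact computation — the minhash
approximation of the original algorithm is unnecessary at these sizes); the
backbone is the union of marked edges over the unchanged node set. Hence:
backbone edges ⊆ original, isolate count preserved, s = 1 is the identity,
and s = 0 still leaves every non-isolated node one edge. Ties in similarity
are broken by lexicographic neighbor key so extraction is reproducible.
s = 0.5 is the default. Community counts and modularity Q come from a
seeded Louvain partition; the algorithm choice is the package's own (Q is
partition-dependent, so values are comparable only qualitatively across
implementations). In the paired report, the "connected components" row
counts islands only — components of ≥ 2 nodes excluding the giant — and the
component size range likewise excludes the giant; isolates are their own
row. Word-class comparisons take degree, clustering and closeness from the
*original* network and compare original-GC words retained in the backbone
GC against those removed, with Welch tests per measure.

## Synthetic lexicons

The generator emulates the structure the pipeline assumes, in the tradition
of pseudo-lexicon studies that draw segments at random from a fixed sound
inventory:

* **Inventory**: 19 consonants + 10 vowels from the default IPA set.
* **Length**: categorical on 2–8 phonemes, {0.10, 0.26, 0.26, 0.18, 0.11,
  0.06, 0.03}, peaked at 3–4 segments — an English-like profile; short words
  are what give these networks their dense, clustered, assortative core.
* **Phonotactics**: none — segments are uniform per position. (A bigram
  mode is a possible extension; its absence means generated "words" are
  less clustered than real ones at equal length.)
* **Frequencies**: Zipfian with exponent 1.0 over ranks that are biased
  toward shorter words (rank = order of word length plus Gumbel noise of
  scale 2.0). This implements Zipf's law of abbreviation; without the
  length–frequency correlation, frequency-thresholded subsamples behave
  like uniform node samples and density would not fall along a size ladder
  the way it does in real lexicons.
* **Inflection**: each base spawns a variant with suffix /z/ with
  probability 0.35 and /d/ with probability 0.20, sharing its lemma — about
  1.55 word forms per lemma, enough for the inflection filter and lemma
  collapse to be exercised.

At the medium benchmark size (16,384 words) the generated networks show the
qualitative regularities real phonological networks show — giant component
around 45–50% of nodes, positive assortativity ≈ 0.69, Estrada
heterogeneity ≈ 0.05, small-world-ness far above 3, exponential/log-normal
degree distributions fitting far better than power laws, and
failure/attack robustness curves diverging near 40% removal. What passing
these tests does *not* show: anything about orthography, phonotactic
legality, part-of-speech structure, or the exact numeric values of any real
corpus — those require supplying the corpus as input.

## Problem sizes and determinism

The shipped benchmark fixtures are tiny (10 words, hand-checkable), small
(1,000) and medium (16,384 — the 2^14 rung of the published ladders); these
sizes exercise every code path while keeping the full suite and the
acceptance script at the scale of a coffee break. Every stochastic step
(sampling, ensembles, removal replicates, community detection) takes an
explicit seed; the pipeline derives per-stage seeds from one root seed via
`numpy.random.SeedSequence` and records them in its manifest, so reruns are
byte-identical.

## Known limitations

* The default inventory is General-American; other dialects or languages
  need their own inventory object.
* Lemma networks depend entirely on the lemma annotations supplied;
  no lemmatizer is included.
* Modularity values depend on the (seeded) partition found; only the
  direction of original-vs-backbone changes is meaningful.
* The degree-fit truncation bound makes extremely heavy-tailed fits
  (α ≤ 1 power laws) representable only as truncated variants.
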