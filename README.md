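# phononet

Tools for building and analyzing **phonological similarity networks**: graphs
over a transcribed lexicon in which two words are linked when their phoneme
sequences differ by exactly one substitution, addition, or deletion of a
single phoneme. These networks are a standard object in psycholinguistics —
a word's degree is its *phonological neighborhood density*, and global
properties (giant-component structure, small-world-ness, degree
distributions, robustness, backbone structure) characterize the mental
lexicon as a whole.

`phononet` is for researchers who have a lexicon table (orthography, IPA
transcription, corpus frequency, optionally lemma annotations) and want the
full analysis pipeline without external services:

* **Construction** — edit-distance-1 networks over word forms or lemmas,
  built with a deletion-key index that is provably equivalent to the
  brute-force all-pairs scan; an inflection filter removes edges between
  words sharing a lemma (cat–cats) that conflate morphological and
  phonological relatedness.
* **Size ladders** — frequency-thresholded subsampling simulates smaller
  lexicons (entries below the median frequency are removed with probability
  proportional to frequency), nested across sizes.
* **Descriptives** — giant component / lexical islands / hermits, density,
  degree statistics, assortativity, Estrada heterogeneity, clustering,
  component-scaled closeness, Welch group comparisons.
* **Small-world analysis** — Humphries–Gurney S = (C/C_ER)/(L/L_ER) against
  matched Erdős–Rényi G(n, m) ensembles (10 replicates), computed on the
  giant component; S > 3 is the conventional small-world threshold.
* **Degree-distribution fitting** — discrete maximum-likelihood fits of
  exponential, power-law, truncated power-law and log-normal families,
  ranked by Kolmogorov–Smirnov distance.
* **Robustness** — random-failure vs degree-targeted-attack node removal,
  tracking giant-component survival.
* **Backbone extraction** — L-Spar local sparsification: each node of degree
  d keeps its ⌈d^s⌉ highest-Jaccard edges; plus Louvain communities,
  modularity, and retained-vs-removed word-class comparisons.
* **Synthetic lexicons** — a seeded generator (random phoneme strings,
  Zipfian frequencies obeying the law of abbreviation, inflectional
  families) so every stage is testable without downloading a corpus.

I/O is plain text: TSV lexicons, whitespace-separated adjacency lists
(networkx-compatible), and CMU-dictionary-style ARPABET files (converted to
IPA by a fixed table).

## Worked example

Generate a 1,000-word synthetic lexicon, build the word-form network with
the inflection filter, and analyze it:

```sh
$ phononet synth --n-lemmas 650 --seed 7 --out lexicon.tsv
998 entries -> lexicon.tsv
$ phononet build --lexicon lexicon.tsv --inflection-filter --out net.adjlist
inflection filter removed 391 edges
998 nodes, 290 edges -> net.adjlist
$ phononet stats net.adjlist
size  nodes  links  density   giant        islands_nodes  hermits      islands ...
net…  998    290    0.000583  151 (15.13)  78 (7.82)      769 (77.05)  33      ...
$ phononet smallworld net.adjlist --reps 10 --seed 7
network      aspl    aspl_er  cc      cc_er   s
net.adjlist  5.6453  4.2455   0.2363  0.0182  9.77
$ phononet degreefit net.adjlist
network      family               ks_distance  params
net.adjlist  lognormal            0.0279       mu=0.9306 sigma=0.7185
net.adjlist  exponential          0.0698       lam=0.3684
net.adjlist  truncated_powerlaw   0.0698       alpha=0.0000 lam=0.3684
net.adjlist  powerlaw             0.2545       alpha=1.7129
```

Reading the output: of 998 words, 151 (15.1%) form the giant component, 769
are hermits with no neighbors, and the remaining 78 sit in 33 small islands
— at a thousand words the network is sparse (density 5.8·10⁻⁴). The giant
component is nonetheless small-world: its clustering (0.236) is 13× the
matched random ensemble's (0.018) while path lengths are comparable
(5.65 vs 4.25), giving S = 9.77 ≫ 3. Its degree distribution is best fit by
a log-normal (KS 0.028); a pure power law fits poorly (KS 0.255) — note the
truncated power law collapses onto the exponential (α → 0), which is why
ranking breaks near-ties by parameter count. Larger lexicons sharpen all of
these patterns.

The same analyses are available as library functions:

```python
from phononet import read_lexicon, build_network, decompose, small_world_analysis

lexicon, report = read_lexicon("lexicon.tsv")
net = build_network(lexicon)
print(decompose(net))
print(small_world_analysis(net, reps=10, seed=7))
```

`phononet run --lexicon lexicon.tsv --sizes 2^9,2^10 --seed 1 --out-dir out/`
executes the whole pipeline over a nested size ladder and writes adjacency
lists, report tables and a manifest of every derived seed.

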