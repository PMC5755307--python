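# Methods

## Problem and scope

`forumscope` analyses a hidden population active in an online discussion
forum through the traces it leaves: who replies to whom, what topics each
user writes about, and the emotional tone of their posts.  The package
reconstructs the analysis as a reusable pipeline: build a directed weighted
interaction network from reply/comment records, partition users into
communities (once by text similarity, once by graph topology), measure each
community's content coherence and structural compactness, and test whether
the two co-vary.  Because real crawls of this kind are rarely
redistributable, a synthetic forum generator with planted ground truth is a
first-class component: every downstream stage is validated against
structure the generator planted.

## The interaction network

Users are nodes.  An arc `u -> v` records that `u` commented in a thread
opened by `v`, or replied addressing `v`; its integer weight counts such
acts.  Self-interactions are dropped.  Three structural statistics are
computed per community on the induced subgraph:

* **Network efficiency** `E(G) = 2/(n(n-1)) * sum_{i<j} 1/d(i,j)`, where
  `d(i,j)` is the unweighted shortest-path length.  Distances are taken on
  the undirected projection and unreachable pairs contribute 0 (the
  standard efficiency convention).  `E` is 1 for a complete graph and 0 for
  an edgeless one.  Whether distances should respect arc direction is
  genuinely open; the undirected choice is consistent with the companion
  use of *weakly* connected components and is the one implemented.
* **Density**: distinct arcs divided by `n(n-1)` (directed convention).
* **Largest weakly connected component (Gcc)** with a deterministic
  tie-break (largest size, then lexicographically smallest member).

Arc weights are kept for community detection but deliberately ignored by
`E` and density, whose formulas are purely topological.

## Community detection

The quality function is directed weighted modularity with an
in-/out-strength null model:

    Q = sum_c [ w_cc/W - S_out(c) S_in(c) / W^2 ].

Optimisation is a seeded multi-level greedy: local single-node moves (with
an "isolate into a fresh community" move so splits are reachable), graph
aggregation, repetition until no level merges, then a community-merge sweep
and one single-node refinement pass on the original graph.  Several
restarts with shuffled node orders are run and the best partition kept;
half the restarts start from a random coarse assignment rather than
singletons, which empirically escapes the rare local optima that node-move
dynamics cannot leave.  Restarts are nearly free on small graphs, so the
default budget is 64 restarts up to 50 nodes and 8 beyond.  Everything is
deterministic given the seed.  An exhaustive search over all set
partitions (refusing `n > 8`) provides the small-`n` oracle used in tests.

The method deliberately lives behind a small `Partition` contract: any
other optimiser of a directed weighted quality (e.g. a map-equation tool)
can be swapped in without touching the analysis.

Communities with fewer than 2 nodes or no internal edge are filtered out
before per-community statistics ("meaningful" communities), and the
fraction of communities forming a single weakly connected piece is
reported.

## Text route: embedding, k selection, topics

Documents are per-user concatenations (in time order) of the user's
writing.  `assemble_user_documents` includes replies alongside thread
comments by default, but the *pipeline's* clustering/topic corpus uses
opened-thread content only (`include_replies=False`): reply text volume
scales with a user's interaction degree, and letting document length track
degree couples topic-mixture estimation noise to network density — members
of denser communities would look more topically similar purely because
their mixtures are better estimated.  The flag restores the all-text
reading.  The activity filter
keeps users with strictly more than `min_posts` (default 3) opened
threads.  Preprocessing strips URLs and markup, lower-cases, segments
(default: whole Latin words and contiguous CJK runs — Chinese input is
assumed pre-segmented; a dictionary segmenter can be plugged in) and
removes stop-words from a user-supplied list.

The default embedding is deliberately deterministic: a document-term count
matrix reduced by truncated SVD at a fixed random state.  k-means is plain
Lloyd iteration from a seeded k-means++ start, tracking
`SSE = sum_i sum_{x in C_i} ||x - u_i||^2` after every step (the recorded
path is non-increasing by construction).  Because SSE is monotone
non-increasing in `k`, minimising it literally is degenerate; `select_k`
therefore returns the knee of the curve — the interior `k` maximising the
second difference `SSE(k-1) - 2 SSE(k) + SSE(k+1)` over best-of-restarts
curves — while also reporting the raw minimiser.  Flat or too-narrow
curves fall back to the raw minimum with a flag.

Topics are fitted with latent Dirichlet allocation (batch variational EM).
The topic count is chosen automatically: candidates on a small grid are
fitted on an 80% split and scored by held-out perplexity, and the smallest
count within 1% of the grid minimum wins — larger counts must earn their
complexity.  Per-user mixtures `theta` are the normalised posterior means.
A corpus with fewer than two distinct words degenerates to a flagged
single-topic model.

**Topic similarity** `s(i,j)` is the cosine of the two mixture vectors
(bounded in [0,1] on the simplex); the community average is
`S(C) = 2/(n(n-1)) * sum_{i<j} s(i,j)`.  The functional form of `s` is not
canonical; cosine is the package default and 1 − Jensen–Shannon could be
substituted behind the same contract.

**Keywords**: each community's member documents are pooled into one
community document; a word's score is its raw in-community count times
`ln(N/df)` over the `N` community documents, after stop-word removal, with
lexicographic tie-breaks and the top 100 kept.  Overlap between keyword
tables is |intersection| / |union| of the keyword sets.

## Sentiment

Scoring is dictionary-based: lexicon words carry signed intensities
(+1..+5 positive, −1..−5 negative), a document's positive/negative sums are
intensity-weighted occurrence counts, and the document is positive exactly
when the positive sum strictly exceeds the negative sum.  A document with
no sentiment words is *neutral* — a third class introduced because binary
percentages are silent about evidence-free users; neutral users are
excluded from community positive/negative proportions and counted
separately.  A nonzero tie maps to negative, consistent with the strict
positivity rule.  No negation or degree-adverb handling is applied in the
default scorer.  Per-class precision/recall against reference labels are
standard confusion-table ratios with degenerate cells flagged as `None`.

## Synthetic forum generator

The generator emulates the statistical structure of a real forum dump at a
size where every property is testable:

* `K` communities (default 30) with sizes drawn uniformly from 20–60;
* per-community topic profile `m_k` over `T = 8` topics; per-user mixture
  `theta ~ Dirichlet(alpha_k * m_k)`, with `alpha_k` geometrically spaced
  over [0.5, 50] so communities range from topically diffuse to coherent;
* within-community arcs drawn with probability
  `p_intra * ((1-gamma) + gamma * cos(theta_u, theta_v))` (`p_intra`
  default 0.25, homophily weight `gamma` default 1), cross-community arcs
  with `p_inter = 5e-4`; each arc is realised as one or more reply or
  comment records (weights 1 + Poisson(0.3), comment share 0.3);
* bag-of-words documents over a 400-word vocabulary with block-structured
  topic-word distributions (85% of a topic's mass on its own block), 25
  words per post and 8 per interaction record;
* planted polarity: ~60% of users negative; each post receives injected
  lexicon words and a final top-up guarantees the planted sign is *strict*
  over the user's full corpus, so dictionary scoring is exact by
  construction;
* timestamps drawn from an evening-peaked hourly profile (peak 22:00,
  trough 03:00–05:00);
* every user opens at least 4 threads, because the generator models the
  *active* sub-population the pipeline analyses after its activity filter.

One master seed drives per-stage spawned streams, so identical
configuration and seed give byte-identical tables, and adding a stage never
perturbs earlier draws.  The mechanism under test is: dispersed-`alpha`
communities discuss diverse topics, and under homophily (`gamma = 1`) their
members interact less, so per-community `S` and `E` co-vary; with
`gamma = 0` and a shared `alpha` the association vanishes.  Note the
direction of the `gamma` effect: since `cos <= 1`, raising `gamma` can only
*reduce* within-community arc counts when mixtures are dispersed.

What the generator does **not** emulate: realistic vocabulary size or
Zipfian word frequencies, thread conversation dynamics, user churn over
the crawl window, correlation between sentiment and topics, or fitted
matches to any real corpus's statistics beyond qualitative shapes.
Passing tests therefore demonstrate that the pipeline recovers structure
of this planted kind; they say nothing about segmentation quality or
lexicon coverage on real Chinese text.

## Correlation analysis

Per-community rows (size, `S`, `E`, density, Gcc size, `S_gcc`, sentiment
proportions) feed sample Pearson correlations with two-sided p-values from
the t transform.  Correlations run on untransformed values; communities
where a quantity is undefined (fewer than two members with mixtures) are
excluded and the exclusion count logged.  The handful of reported
correlations carry raw p-values; no multiple-testing correction is
applied, by design.  The `S_gcc` comparison reports `S_gcc - S` per
community and the fraction of communities where restricting to the largest
component raises similarity.

## Problem sizes and numerical choices

Default study design: 30 communities, ~1100 users, ~10k comments, ~7k
replies; a full pipeline run takes tens of seconds.  Statistical
acceptance checks use 20 seeds; oracle checks use 100 random graphs
(`n <= 30` for efficiency against brute-force BFS, `n <= 7` against the
exhaustive partition oracle).  Floating-point tolerances: efficiency
agrees with the oracle to 1e-12; simplex normalisation to 1e-9; greedy
modularity improvements require a 1e-12 margin, with lowest-label
tie-breaks everywhere for determinism.

## Known limitations

* The community detector optimises directed modularity, not the map
  equation; equivalence with flow-based tools is not claimed.
* Held-out-perplexity topic-count selection is conservative by design (the
  1% rule); corpora with weak topic separation may select fewer topics
  than a nonparametric model would.
* The default tokenizer assumes pre-segmented CJK text.
* `E` and density ignore arc multiplicity; weighted variants would need a
  different distance definition.
* The sentiment scorer has no negation handling; on real text its accuracy
  is bounded by lexicon coverage, unlike the exact-by-construction
  synthetic setting.
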