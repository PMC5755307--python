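# forumscope

Interaction-network and text analysis of hidden populations in online
forums.

Some populations — for instance users of disease-related discussion
boards — have no sampling frame and strong reasons not to disclose
membership, which makes them nearly invisible to surveys.  The traces they
leave in a forum are analysable, though: who replies to whom, what each
user writes about, and the emotional tone of their posts.  `forumscope`
turns a three-table forum dump (users, comments, replies) into a directed
weighted **interaction network**, partitions users into communities by
text similarity and by graph topology, and tests whether content coherence
and structural compactness go together.

For each community *C* with *n* members it computes

* average topic similarity
  `S(C) = 2/(n(n-1)) * Σ_{i<j} s(i,j)`, with `s(i,j)` the cosine of the
  users' topic-mixture vectors from a latent topic model;
* network efficiency
  `E(G) = 2/(n(n-1)) * Σ_{i<j} 1/d(i,j)`, with `d(i,j)` the shortest-path
  length on the community's induced subgraph;
* density, the largest weakly connected component and its similarity
  `S_Gcc`, TF-IDF keyword tables, and lexicon-based sentiment proportions
  (positive words score +1..+5, negative −1..−5; a user is positive when
  the positive sum strictly exceeds the negative sum);

and then the Pearson correlations between `S` and the structural
quantities across communities.

Because crawls of this kind are rarely redistributable, the package ships
a synthetic forum generator with planted community labels, Dirichlet topic
mixtures, homophilous arc formation (arc probability
`p_intra*((1-γ) + γ·cos(θ_u, θ_v))` within communities), planted sentiment
polarity and diurnal timestamps — so every pipeline stage can be validated
against known ground truth.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from forumscope import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_communities=8, size_range=(15, 30), seed=42),
    seed=42,
)
rep = run_pipeline(cfg)
c = rep.correlations["topology"]["S_vs_E"]
print(f"active users:        {rep.n_active}")
print(f"interaction arcs:    {rep.graph_summary['n_arcs']}")
print(f"communities found:   {rep.n_topology_communities} ({rep.n_meaningful} meaningful)")
print(f"S-E correlation:     r={c.r:.3f}, p={c.p:.1e} (n={c.n_points})")
print(f"negative users:      {rep.sentiment_summary['negative_fraction']:.1%}")
```

prints

```
active users:        190
interaction arcs:    736
communities found:   8 (8 meaningful)
S-E correlation:     r=0.952, p=2.6e-04 (n=8)
negative users:      60.5%
```

The generator planted 8 communities whose topic concentrations span two
orders of magnitude under full homophily; the pipeline detects the
communities from the interaction graph alone, re-estimates each user's
topic mixture from raw text alone, and recovers the planted coupling:
topically coherent communities are structurally compact (r = 0.95 here),
and the planted ~60% negative-user share is reproduced exactly because the
synthetic lexicon coverage is complete.

The same pipeline runs on real dumps via
`PipelineConfig(table_paths=(users, comments, replies), ...)`, with
user-supplied stop-word and sentiment-lexicon files.

## Command line

```sh
forumscope simulate --seed 7 --out data/          # synthetic dump + truth files
forumscope network  --in data/ --out edges.txt    # build the interaction graph
forumscope cluster  --in data/ --out part.txt     # communities (topology or text)
forumscope topics   --in data/ --out theta.tsv    # per-user topic mixtures
forumscope sentiment --in data/ --out sent.tsv    # lexicon scoring
forumscope report   --in data/ --out report.json  # full pipeline
```

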