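# Methods

## The problem

A transcription-factor (TF) knockout experiment in mouse yields a list of
differentially expressed genes (DEGs) that is typically far too large and
too noisy to interpret: it mixes genuine downstream effects of the knockout
with genes altered by genetic background differences between animals and
with threshold artifacts of the DEG caller. `knockrank` narrows that list to
candidates that are mechanistically attributable to the knockout, then
orders the survivors by how relevant they are to the researcher's stated
hypothesis ("context") and to the knockout gene itself.

## Pipeline

### Selection

**TF-network filter.** The knockout gene is the root of a directed
regulatory graph (TF → target edges). A DEG is a plausible knockout effect
only if a directed regulatory path connects the knockout to it. Three
interpretations of the selection rule are exposed as `tf_mode`:

- `reachable` (default): keep DEG *g* iff *g* is reachable from the
  knockout by a directed path. Terminal targets of the cascade are
  biologically valid candidates, so this is the default.
- `strict`: additionally require that *g* has an outgoing regulatory edge
  to another DEG — the literal conjunction of "affected by the knockout"
  and "affects another DEG". Note that only genes in the TF list can carry
  outgoing edges, so strict mode restricts candidates to TFs.
- `regulator`: the union reading — reachable from the knockout *or*
  regulating another DEG.

`max_depth` caps the path length (default unlimited; `1` gives the
direct-targets-only reading). Reachability excludes the root itself unless
it lies on a regulatory cycle.

**SNV filter.** Inbred mice still differ genetically, and with the small
sample sizes typical of RNA-seq knockout designs those differences can
masquerade as knockout effects. Candidates whose variant rate in the
knockout samples exceeds `max_snv_rate` (variants per kilobase of the gene
model; default 3.0/kb, always logged) are discarded. Rates come either from
a precomputed per-gene table or from a VCF plus BED gene intervals, counted
with the standard conventions (BED 0-based half-open; VCF POS 1-based,
converted at the boundary; overlapping intervals merged before the length
is taken). Genes absent from the profile pass the filter: absence of
evidence of genetic difference is not evidence of contamination.

### Prioritization

**Literature relevance.** Each surviving candidate is scored against (a)
the user's context keywords and (b) the knockout gene, over a local corpus
of titles+abstracts with a gene-synonym lexicon; the **maximum** of the two
scores represents the candidate. The default scorer is cosine document
co-occurrence,

    score(q, g) = |D(q) ∩ D(g)| / sqrt(|D(q)| · |D(g)|),

where D(·) is the set of documents mentioning the entity (case-insensitive
whole-phrase match at word boundaries, so `Il2` never matches `Il24`), and
the score is 0 when either set is empty. The scorer is bounded, symmetric,
and hand-checkable; a raw co-mention `count` mode exists for corpora too
small for the normalization to matter. Multiple context keywords are scored
separately and the per-gene context score is their maximum; multi-word
phrases match as whole phrases, never as bags of words. The max is taken
after scoring, and every threshold is echoed into the run log.

Candidates whose combined score is 0 are **rejected**, not ranked last:
with no literature tying a gene to either the context or the knockout there
is no basis for prioritizing it, and the prediction denominator therefore
shrinks with the corpus coverage of the chosen context. `--keep-zero`
disables rejection.

**PPI path ranking.** Survivors are ranked by the unweighted hop count of
the shortest path to the knockout gene on the score-thresholded PPI graph
(STRING-convention integer scores 0–1000; default cutoff 400, medium
confidence). Hop count, not edge-weighted cost, is deliberate: on a dense
interactome shortest-hop distances are small integers and produce massive
rank ties, which is the empirically observed behavior of path-based
prioritization and is handled, not avoided. Candidates unreachable on the
thresholded graph are kept and share the last rank block (logged
distinctly).

**Borda fusion.** The relevance ranking and the path ranking are combined
by unweighted Borda count: in a list of N genes, competition rank r earns
N − r + 1 points; tied genes receive the full points of their shared rank;
the two criteria weigh equally; final order is by summed points, again with
competition ranks. The point scheme is isolated in `borda_points`, so
alternatives (e.g. averaging points across a tie span) are one-line
variants. All tie-breaks by gene symbol are cosmetic presentation order
only — tied genes keep equal rank values, and evaluation never depends on
the cosmetic order.

Competition ranking throughout: tied entries share the smallest rank of
their block, and the next distinct rank is 1 + the number of strictly
better entries.

### Evaluation

Against a validated gene set: precision = tp/|ranked list|, recall =
tp/|validated|, F = harmonic mean (0 when both are 0), and top-k hits =
validated genes with rank ≤ k (default 10; everything tied at the boundary
counts). The prediction denominator is the post-rejection ranked list, not
the input DEG list. Printed-value comparisons in the tests use
round-half-even at the printed precision.

## Synthetic benchmark

`knockrank.simulate` builds a coherent bundle with planted truth. Defaults:
300 genes, 40 TFs in a random out-tree of depth ≤ 3 and fan-out ≤ 6 rooted
at the knockout, 15 true targets, 30 decoys, 60 noise DEGs, 10%
SNV-contamination among downstream candidates, 3 planted co-mention
abstracts per true target plus 60 background documents, a
preferential-attachment PPI backbone (m = 2), seed 7. These sizes keep a
full 20-replicate recovery experiment under a few seconds while leaving
each filter with real work to do.

The construction is adversarial by wiring, not by chance: noise DEGs are
regulatorily disconnected (the TF filter must remove them), contaminated
genes carry ≈10 variants/kb (the SNV filter must remove them), decoys
survive both filters and are separated from true targets only by the
literature criterion (no planted co-mentions) and by PPI geometry (anchored
≥ 3 hops from the knockout, true targets ≤ 2). Everything derives from one
seeded `numpy` generator, so equal configs give byte-identical output
files.

What the simulator does **not** emulate: expression-level realism (read
counts, DE posterior probabilities — only DEG labels are generated),
synonym ambiguity and NER noise in real abstracts, literature-volume skew
between well- and poorly-studied genes, and false edges in real regulatory
or interaction networks. Passing the recovery tests therefore demonstrates
the machinery is correct and the criteria compose as designed, not that
real knockout studies will reach comparable precision.

## Numerical and degenerate-input choices

- Gene identity is case-insensitive; symbols normalize to mouse-style
  capitalization at load.
- Duplicate PPI pairs collapse to the maximum score (conservative merge);
  self-loops drop with a warning; duplicate DEG rows keep first occurrence.
- Unreachable distances are `inf` end to end; an empty candidate set after
  any stage returns an empty ranking with the stage named in diagnostics
  rather than an error.
- A validated set disjoint from the ranking gives P = R = F = 0; an empty
  validated set is a configuration error.
- Two runs with identical inputs and config are byte-identical; the only
  randomness anywhere is the simulator's seed.

## Known limitations

- The cosine co-occurrence scorer is a transparent stand-in for full
  literature-relevance systems (named-entity recognition, citation
  weighting, recency); scores are corpus-dependent and the scorer is
  pluggable for that reason.
- Strict mode can only return TFs (see above) — a structural consequence of
  edge lists whose sources are restricted to a TF list.
- The SNV threshold ("a certain rate") has no canonical published value;
  3.0/kb is a configurable default, and conclusions should be checked for
  sensitivity to it.
- Borda fusion with two criteria cannot break ties the criteria agree on;
  large tie blocks propagate to the final list by design.
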