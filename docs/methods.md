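# Methods

This note records the modelling decisions, default parameters, and
numerical choices behind `oligomine`, and what its synthetic benchmark
does and does not emulate.

## Disorder annotation and IDR extraction

Input is one per-residue disorder score track per protein (IUPred-style
TSV: position, residue, score; 1-based consecutive positions; a fourth
column, if present, is ignored). A residue belongs to an IDR when its
score is **strictly greater** than the threshold (default 0.5); a score of
exactly 0.5 is excluded. Maximal such runs of length ≥ `idr_min_length`
(default 3) become IDR segments. Segments never span proteins, so N-gram
windows never cross protein boundaries.

The seed residues for generation are the `seeds_k` = 10 most frequent
residues in the pooled IDR segments; frequency ties are broken
alphabetically so the seed set is deterministic.

## Neural N-gram conditional model

The model estimates p(ω_k | ω_{k−n+1} … ω_{k−1}) over the 20 canonical
amino acids (`ACDEFGHIKLMNPQRSTVWY`, output indices 0–19).

Architecture: each context position is embedded in R^m; the n−1
embeddings are concatenated, mapped through one tanh hidden layer, and a
softmax over the 20 residues gives the conditional. Contexts shorter than
n−1 (the first residues of a segment) are left-padded with a PAD symbol
that has its own embedding row (index 20) but is never a prediction
target, so the output simplex always has 20 bins.

Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| order `n` | 4 | 3-residue context: long enough to capture short linear motifs, short enough that contexts are well observed in corpora of a few hundred proteins |
| embedding `m` | 16 | small; 21×16 embedding table is far below the data size |
| `hidden_units` | 128 | fixed structural choice of the screen |
| `epochs` | 200 | with early stopping (Δloss < 1e−5 for 10 epochs) |
| `learning_rate` | 1e−3 | Adam default scale |
| `batch_size` | 256 | minibatch SGD; per-epoch reshuffle |

Training minimises cross-entropy over every window of every segment with
minibatch Adam, implemented directly in NumPy (forward, backprop and the
embedding scatter-add via `np.add.at`). Initial weights are uniform
(−0.1, 0.1) from `np.random.default_rng(seed)`. Softmax subtracts the row
maximum before exponentiation for numerical stability. Given the same
corpus and seed, training is bit-reproducible.

The model satisfies the scikit-learn estimator contract
(`get_params`/`set_params`/`clone`; fitted attributes carry trailing
underscores). `count_oracle` provides an independent brute-force
frequency estimate per observed context, used by the tests to bound the
trained model's total-variation error.

Persistence is a zip of `meta.json` plus one `.npy` per parameter array;
loading verifies the format version and (optionally) the expected order,
and raises a typed `ModelError` on corrupt or truncated files.

## Monte Carlo generation and scoring

Each of the 10 seed residues is extended one residue at a time. At each
cycle, every frontier sequence draws `draws_per_step` = 200 next residues
by inverse-CDF sampling of the model's conditional (duplicate draws are
collapsed), until the length cap `max_length` = 10.

A candidate's score is the product of its step probabilities
Π p(ω_k | context), stored as a log-sum; a bare seed is the empty product,
1. A candidate is **admissible** only when every step probability is
strictly greater than chance (1/20); a step of exactly 1/20 fails. Since
any extension of an inadmissible prefix is itself inadmissible, such
prefixes are pruned from the frontier — this pruning is exact with
respect to the admissible set. As a safety valve against combinatorial
growth the frontier is additionally capped at `max_frontier` = 2000
best-scoring sequences (ties broken lexicographically); in practice the
admissibility pruning keeps frontiers far below the cap. Candidates of
length ≥ `min_emit_length` = 3 are emitted; the admissible pool is ranked
by (−log score, sequence) and truncated to `keep_top` = 100.

## Clustering and selection

Candidates are clustered **within a length** only: across lengths the
edit distance is dominated by the arbitrary overhang of the longer
sequence. The metric is unit-cost Levenshtein distance (two-row dynamic
program, hand-written so that the core operation is explicit; the test
suite checks it against `edlib` and exhaustive oracles).

Agglomeration is complete linkage (scipy `linkage` on the condensed
matrix; average/single also available). The k-subgroup cut uses scipy
`cut_tree`, which removes exactly the k−1 last merges even when the top
merge heights are tied — `fcluster(criterion="maxclust")` can return
fewer groups in that case. Subgroup ids are renumbered by smallest leaf
index so assignments are stable. Per subgroup, the `per_group` = 3
top-scoring candidates are selected (ties lexicographic); groups smaller
than `per_group` contribute all members. The default k = 2 reflects the
typical split of disordered composition into a serine/glutamate-rich and
a glycine/proline/alanine-rich class.

Dendrograms are serialised to Newick with ultrametric branch lengths:
reading merge heights as cophenetic distances, a branch spans half the
height gap between child and parent merges (a pair merged at height 2
becomes `(A:1,B:1);`).

## Synthetic benchmark

`simulate_corpus` emulates a disorder-annotated corpus at the scale of a
real screen: by default 171 proteins of 150–400 residues with one
contiguous disordered block per protein covering 40% of its length.
Scores are clipped Gaussians (mean 0.8 inside the block, 0.2 outside,
σ = 0.1) kept strictly on the correct side of 0.5, so extraction recall
is measurable but the track still looks noisy. A pentapeptide motif
(`ESSES`) is planted inside the blocks at rate 0.3 per fill step (~68% of
disordered residues lie in motif copies at the default rate); the
remaining residues are uniform over the 20 amino acids.

What this does *not* emulate: realistic background composition of
disordered sequence (a biased background generator is provided
separately), multiple IDRs per protein, disorder-score autocorrelation
beyond the block structure, and any structure in the ordered regions.
The benchmark validates the machinery — extraction accuracy, enrichment
detection, motif recovery, subgroup separation — not biological realism.

Problem sizes in the tests and the acceptance script (tens to a couple
hundred proteins, shortened 30–40 epoch schedules) are the package's own
choices to keep runs within minutes; the defaults of the library itself
are the full-scale ones above.

## Reproducibility

`PipelineConfig(seed=s)` derives stage seeds `(s·1000003 + 1) mod 2^31`
for training and `(s·1000003 + 2) mod 2^31` for generation, so one
integer pins the whole run; `manifest.json` records the resolved
configuration and package version. A full run on the checked-in reference
fixture reproduces `tests/data/reference_candidates_top.tsv` byte for
byte (regenerate the snapshot whenever model, generator, or table-format
numerics change).

## Limitations

- Likelihood under a local N-gram model rewards repetitive,
  high-frequency composition; it ranks "most IDR-like" peptides, not
  peptides optimised for a specific function or binding target.
- The strict >1/20 admissibility rule and the top-100 truncation are
  screening heuristics, not statistical tests; scores are comparable
  within a run, not across corpora.
- Monte Carlo extension with finite `draws_per_step` can miss admissible
  low-probability candidates; coverage improves with more draws at
  linear cost.
- Complete-linkage subgroups at k = 2 are a fixed structural choice; for
  corpora without a bimodal composition the two subgroups may be
  arbitrary splits of one cluster.
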