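# oligomine

Generation of candidate functional oligopeptides from the intrinsically
disordered regions (IDRs) of a protein corpus, by unsupervised language
modelling of disordered sequence.

Intrinsically disordered regions are protein segments without a stable
tertiary structure. They are compositionally biased (enriched in serine,
glutamate, proline and glycine, depleted in bulky hydrophobics) and often
carry short linear motifs that do the functional work — for example the
acidic serine-rich stretches of biomineralization proteins. `oligomine`
learns the local sequence statistics of the disordered proteome of interest
and uses that model to propose short peptides (3–10 residues) that look like
concentrated fragments of disordered sequence, ranked by model likelihood
and organised into composition subgroups for experimental follow-up.

## Method

1. **IDR extraction** (`oligomine.corpus`). Each protein comes with a
   per-residue disorder score track (IUPred-style, one score per residue).
   Maximal runs of residues with score strictly greater than 0.5 and length
   ≥ 3 are kept as IDR segments.
2. **Seed residues.** The residue-frequency profile of the pooled IDR
   segments is computed and the 10 most frequent residues become the seeds
   of generation.
3. **Neural N-gram model** (`oligomine.ngram`). A conditional model
   p(ω<sub>k</sub> | ω<sub>k−n+1</sub> … ω<sub>k−1</sub>) over the 20
   amino acids: each context residue is mapped to an m-dimensional
   embedding (default m = 16), the n − 1 context embeddings (default
   n = 4) are concatenated, passed through a tanh hidden layer of 128
   units, and a softmax gives the next-residue distribution. Contexts
   shorter than n − 1 (segment starts) are left-padded with a dedicated
   PAD symbol, which is never a prediction target. Training is
   minibatch Adam on the cross-entropy of every window in the IDR corpus,
   implemented directly in NumPy.
4. **Monte Carlo extension** (`oligomine.generate`). Each seed residue is
   grown one residue at a time by inverse-CDF sampling from the model's
   conditional, up to length 10. A candidate ω<sub>1</sub>…ω<sub>L</sub>
   is scored by the product of its step probabilities,
   Π<sub>k=2..L</sub> p(ω<sub>k</sub> | context), kept in log space. A
   candidate is *admissible* only if every step probability is strictly
   greater than chance, 1/20; inadmissible prefixes are pruned from the
   search frontier (any extension of an inadmissible prefix is itself
   inadmissible). Admissible candidates are ranked by score and the top
   100 form the candidate pool.
5. **Clustering and selection** (`oligomine.cluster`). Within each length,
   pairwise Levenshtein (unit-cost edit) distances are computed and the
   candidates are agglomerated with complete linkage. Cutting the highest
   merge yields k = 2 subgroups — typically a serine/glutamate-rich and a
   glycine/proline/alanine-rich group — and the 3 top-scoring candidates
   per subgroup are selected. Dendrograms are written as Newick trees.

A synthetic-corpus generator (`oligomine.simulate`) produces annotated
proteins with one disordered block per protein (noisy scores around 0.8
inside, 0.2 outside) and a pentapeptide motif (`ESSES` by default) planted
in the disordered blocks at a configurable rate, together with the ground
truth needed to validate every stage.

## Worked example

Simulate a 40-protein annotated corpus and run the full pipeline:

```sh
$ oligomine simulate --out demo/corpus --n-proteins 40 --seed 7
wrote 40 proteins to demo/corpus (empirical motif insertion rate 0.278)

$ oligomine run-all --tracks demo/corpus/tracks --out demo/results --seed 7
... IDR segments: 40; seed residues: SECHRQGFDY
... trained model: 4447 windows, final loss 1.2960
... pool 110646, admissible 24659, top 100
pipeline complete: 100 top candidates in demo/results
```

The ranked pool (`demo/results/candidates_top.tsv`) starts:

```text
rank  sequence  length  seed  score     log_score  step_probs
1     ESS       3       E     0.795508  -0.228775  0.824657;0.964653
2     ESSE      4       E     0.763781  -0.269474  0.824657;0.964653;0.960118
3     ESSES     5       E     0.754319  -0.28194   0.824657;0.964653;0.960118;0.987611
4     SES       3       S     0.376649  -0.976442  0.407383;0.924557
5     RES       3       R     0.372092  -0.988615  0.442018;0.841801
```

The planted motif `ESSES` is the top length-5 candidate. The per-length
selection (`selected_candidates.tsv`) shows the two composition subgroups at
length 5 — an ES-rich subgroup 0 and a G/D-rich subgroup 1:

```text
sequence  length  subgroup  score      rank
ESSES     5       0         0.754319   1
RESSE     5       0         0.350435   2
CESSE     5       0         0.340541   3
GGHES     5       1         0.0109596  4
DGGES     5       1         0.00682292 5
DGVES     5       1         0.00637461 6
```

Other artifacts per run: `idr_segments.tsv/.fasta`, `seed_residues.txt`,
the persisted model `ngram_model.zip`, per-length candidate tables,
Newick dendrograms `tree_len{L}.nwk`, and `manifest.json` recording the
full configuration and seed. The same pipeline is available stage by stage
(`extract-idr`, `train`, `generate`, `cluster`, `select`) and from Python
via `oligomine.pipeline.run_pipeline`. Runs are byte-reproducible given the
`--seed`.

## Testing

```sh
python -m pytest -q tests/
```

The suite covers unit behaviour of every module, property-based checks
(hypothesis) of the metric and the model's distributions, independent
oracles (count-based N-gram frequencies, `edlib` edit distances, exhaustive
dynamic programs), statistical checks (chi-square sampling fidelity,
total-variation convergence bounds), and `tests/test_acceptance.py` with
end-to-end structural, statistical, recovery, and byte-level regression
tests against a checked-in reference run.

See `docs/methods.md` for the modelling details, parameter rationale, and
limitations.
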