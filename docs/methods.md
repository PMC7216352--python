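# Methods

## Model

`cluscore` treats gene–disease association prediction as link prediction on
an unweighted bipartite graph *G(X, Y, L)*: genes on one side, diseases on
the other, edges the known associations. Nodes exist only through edges
(degree ≥ 1 by construction), identifiers are matched exactly after
whitespace stripping with no case folding or ontology mapping, and duplicate
associations from multiple sources collapse to a single edge — the scores
count edges, not report multiplicities.

For a pair *(g, d)* the cluster association score
`C_score(g, d) = |L(N(g), N(d))|` counts edges between the disease cluster
of *g* and the gene cluster of *d*; the association score
`DG_score(g, d) = (1/deg(g) + 1/deg(d)) · C_score(g, d)` damps the advantage
of high-degree nodes. In matrix form the full score table is `A·Aᵀ·A` for
biadjacency matrix A, which is how candidate tables are computed; single
pairs use adjacency-set intersections, and the two routes are tested against
each other and against a brute-force double loop over edges.

When a scored pair is itself a known edge, its own edge lies between the two
clusters and is counted by default (`exclude_direct_edge=False`); the flag
matters only for the known-edge validation analyses, where both settings are
available. Prediction candidates are non-edges, ranked by DG_score with
deterministic tie-breaks (C_score descending, then gene id, then disease id)
so outputs are bit-reproducible; top-fraction selection keeps
`ceil(fraction·n)` pairs, default fraction 0.01.

## Evaluation protocols

**LOOCV.** Each test edge is removed in turn and rescored on the reduced
network (both endpoint degrees drop by one). Negatives are the candidate
non-edges of the full network, scored once; a per-removal rescoring variant
exists for sensitivity analysis. Degree-one nodes are removed first
(single-pass by default — an iterated variant is available, cascades are
possible), because a positive whose removal isolates an endpoint cannot be
ranked. The AUC is the tie-handled Mann–Whitney statistic
(P(pos > neg) + ½·P(pos = neg)), computed from midranks; ROC points come
from sweeping the rank threshold, so their trapezoidal area equals the AUC
exactly. **k-fold CV** removes a seeded uniform partition fold by fold
(fold sizes within one of each other, no stratification); a fold removal
that isolates a positive's endpoint scores that positive 0 and is logged.

**Robustness.** The top-fraction predictions of the intact network form the
verification set. Per repetition, `round(deletion_fraction·|L|)` edges are
deleted uniformly, the top-fraction list is recomputed over the remaining
network's non-edges, and each verification pair found in it counts as
recovered. "Recovered" therefore means re-entering the same top fraction —
the reading consistent with counting how often a prediction survives 1000
perturbation experiments. One master seed spawns per-repetition substreams,
so runs are reproducible and order-independent. The structural baseline
rewires the network by bipartite double-edge swaps
((g1,d1),(g2,d2) → (g1,d2),(g2,d1)), rejecting duplicate-creating swaps,
with a default target of 10·|L| accepted swaps (a standard mixing
heuristic); degrees are preserved exactly, and a graph with no legal swap
(e.g. complete bipartite) is returned unchanged with a warning.

**Cluster significance.** Given an externally supplied similarity matrix
(symmetric within 1e-9, values in [0,1], diagonal ignored — the package
deliberately does not compute semantic or functional similarity), each real
cluster's mean pairwise similarity is compared with `n_random` size-matched
clusters drawn uniformly without replacement from the whole part (default
10,000 draws). Empirical p-values use the add-one convention
`(1 + #{null ≥ obs}) / (1 + n_random)`, so they are never 0; the pooled
real-vs-random comparison is a one-sided Mann–Whitney test. The analogous
C_score null draws random gene and disease clusters of the observed sizes
(default 1,000 draws per edge); its analytic mean is `a·b·density` for
cluster sizes a, b, which serves as a cross-check.

## Synthetic study conditions

The planted-block generator encodes the method's assumption as a generative
model: aligned gene/disease blocks, edge probability `p_in` within a block
and `p_out` across. The benchmark conditions used throughout the tests and
the acceptance script are 4 blocks of 20 genes × 20 diseases with
`p_in = 0.5`, `p_out = 0.01` and a 10% holdout of realized within-block
edges (recoverable by construction); smaller variants (2–3 blocks of 10–15
per side) are used where many replicates are needed, and `p_in = p_out`
gives the no-signal control. Similarity matrices assign 0.8 within blocks
and 0.1 across, plus truncated Gaussian noise (default SD 0.05). Optional
log-normal per-node activity multipliers add degree heterogeneity to
exercise the degree correction. The generator does not imitate real
degree distributions, identifier vocabularies or the biased way curated
databases sample biology, so green tests demonstrate correctness of the
machinery and recoverability of planted structure, not real-world accuracy.

Under these conditions the pipeline yields holdout ranking AUC ≈ 0.93,
LOOCV AUC ≈ 0.89–0.90 and 5-fold AUC ≈ 0.83–0.84 (a fold removes ~20% of
edges at once, which costs a few AUC points relative to LOOCV), and recovery
accuracy decreases strictly across 10/20/30% deletion.

## Numerical and design choices

- AUC ties contribute ½; score comparisons in the oracles use exact float
  equality on integer-valued scores.
- Fractions select `ceil(fraction·n)`; ranks are 1-based.
- Random draws always flow from an explicit seed through
  `numpy.random.default_rng`; repetition substreams come from
  `SeedSequence.spawn`.
- Degree-one filtering defaults to a single pass; emptied networks raise
  rather than silently returning nothing.
- The negative set is scored once on the full network by default: it is the
  common convention and far cheaper; the per-removal variant is available.

## Known limitations

- LOOCV is slightly conservative: a positive is scored after losing one
  degree at each endpoint while negatives keep theirs. On Poisson-like
  (Erdős–Rényi) null networks the size-biased degree of an edge endpoint
  exceeds the population mean by Var(k)/E(k) = 1, which cancels the lost
  degree exactly, and the measured null AUC is 0.5 within Monte-Carlo error.
  Degree-preserving rewiring of planted-block networks, however, preserves
  their *underdispersed* (binomial, Var < mean) degree sequence, the
  compensation is only ≈ 0.5 of a degree, and the null LOOCV AUC sits
  measurably below chance (≈ 0.46–0.47). The bias is in the conservative
  direction — the method never gains spurious signal from rewired networks —
  but "rewired null AUC = 0.5" is only exact for Poisson-like degrees. Real
  curated networks are overdispersed, where the same mechanism would, if
  anything, push the null slightly above 0.5.
- The C_score of a *known* edge always contains the edge's own star
  (deg(g) + deg(d) − 1 incident edges lie between its clusters by
  construction), so known-edge scores exceed the size-matched random-cluster
  null even in structureless networks; enrichment beyond
  `star + (a−1)(b−1)·density` is what indicates genuine cluster structure.
- Exact reproduction of cross-validation AUCs published for curated datasets
  depends on conventions those publications leave open (negative rescoring,
  tie handling, candidate sets), and the original association tables must be
  supplied by the user (see README); checks against them use a ±0.03 band.
- The two-sample comparisons reported for robustness and cluster-validity
  are Mann–Whitney tests, an explicit choice where the original analyses do
  not name a test.
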