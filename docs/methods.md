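# Methods

## Problem

Experimentally confirming an association between a long non-coding RNA
(lncRNA) and a disease is slow and expensive, while databases of confirmed
lncRNA–disease, lncRNA–miRNA and miRNA–disease associations keep growing.
`lmdlink` treats the prediction of unobserved lncRNA–disease associations as
supervised link prediction on this tripartite evidence: each candidate pair
is represented by a feature vector combining a *linear* view of the
association matrix with a *nonlinear* view of the surrounding heterogeneous
network, and a binary classifier scores the pair.

## Model

### Association matrix and linear features

Let R be the M×N binary matrix with R(i,j) = 1 iff lncRNA i has a recorded
association with disease j. A zero in R means "unconfirmed", not "absent",
so before factorization every 0 is replaced by a small ε (default 1e-6; any
positive value is accepted). The filled matrix is decomposed

    R ≈ U · Σ · Vᵀ,

and with the spectrum truncated to the leading k singular values, row i of
U_{M×k} is the linear feature LL_i of lncRNA i and column j of Vᵀ_{k×N} is
the linear feature LD_j of disease j. No Σ weighting is applied to the
vectors.

Rank selection. The singular spectrum of a sparse binary association matrix
after ε-filling collapses abruptly at the numerical rank (on real data of
this kind the drop spans many orders of magnitude, e.g. 1e-1 → 1e-14 at one
dimension). `select_rank` therefore places k at the largest ratio of
consecutive singular values, accepted only if that ratio reaches
`gap_floor` (default 1e6); otherwise the full spectrum is kept. A `fixed`
method overrides the heuristic (the reference configuration fixes k = 173).
Ratios with an exactly zero denominator count as infinite, so the gap just
before the first exact zero always qualifies.

Sign convention. Singular vectors are sign-ambiguous; we flip each U column
(and the matching Vᵀ row) so its largest-magnitude entry is positive, making
features bit-identical across runs. The decomposition is the full LAPACK
SVD: at the intended scale (≲10³×10³) exactness is cheaper than an iterative
solver.

### Heterogeneous network and nonlinear features

The lncRNA–miRNA–disease network (LMDN) is the undirected, unweighted union
of the three association tables. Node ids are namespaced by class
(`l:`, `m:`, `d:`) so a symbol naming two different molecule classes cannot
collapse into one node. Only cross-class edges exist by construction.

Nonlinear features are node2vec embeddings of the LMDN, implemented from
scratch. A second-order walk at node v that arrived from t chooses the next
node x ∝ α_pq(t,x)·w_vx with w ≡ 1 and

    α_pq = 1/p if d(t,x) = 0,  1 if d(t,x) = 1,  1/q if d(t,x) = 2,

where d is shortest-path distance. Because x is a neighbor of v, d(t,x) is
0 iff x = t and 1 iff x is adjacent to t, else 2 — no search needed. Each
per-edge categorical distribution is compiled into an alias table
(O(deg) build, O(1) draws); at p = q = 1 the walk is exactly the uniform
DeepWalk walk, which the tests assert. The first step of a walk, where no
previous node exists, is uniform over neighbors, matching reference
implementations.

The walk corpus is embedded by skip-gram with negative sampling. Since no
word2vec library is part of the dependency set, the trainer is implemented
here: unigram^(3/4) noise distribution, per-position reduced window, linear
learning-rate decay from 0.025, and a sequential single-threaded SGD inner
loop compiled with numba. Sequential updates (rather than large vectorized
minibatches) matter on graphs: hub nodes occur so often that batch-summed
stale gradients diverge, and batch-averaged ones oversmooth the embedding
toward community centroids. All sampling is driven by one seeded generator,
so the embedding is a bit-identical function of (corpus, config, seed).

Walk and trainer defaults — p = 1, q = 1, 10 walks of length 80 per node,
window 10, 5 negative samples, 5 epochs — are the standard node2vec/word2vec
settings; the embedding dimension d defaults to 16, the size that combines
best with the linear features in the reference configuration (16–128 are
all supported).

### Integration and classification

Integrated features are concatenations, linear part first:
FL_i = [LL_i ; NL_i], FD_j = [LD_j ; ND_j], each of length k + d; a
classification sample for (i,j) is [FL_i ; FD_j], length 2(k + d). Entities
present in only one feature source are dropped with a warning. No scaling
is applied by default (a z-scoring switch exists for experimentation).

Training data are all known associations (label 1) plus an equal number of
distinct unannotated pairs drawn uniformly without replacement (label 0) —
the usual closed-world negative-sampling assumption; negatives are fixed
once per experiment seed, not resampled per fold. Five classifiers are
supported with library defaults and only the seed fixed: logistic
regression ("LR"), Gaussian naive Bayes, random forest, AdaBoost, and
XGBoost (the default, the configuration that performed best in the
reference setting). Tree ensembles additionally run single-threaded so
reports are byte-reproducible.

### Evaluation

Stratified tenfold cross-validation. Per fold: Acc, Sen, Spec, Prec and MCC
at the 0.5 threshold, trapezoidal ROC AUC (equal to the normalized
Mann–Whitney statistic, ties ½) and step-rule (average-precision) AUPR.
Degenerate denominators are reported as 0 with an explicit `undefined`
flag. Curves are kept per fold; AUC/AUPR are macro-averaged.

Two evaluation modes exist because association-prediction studies commonly
compute features once on the full data before splitting, which leaks
held-out edges into the features. The default mode reproduces that protocol
(features once, only labeled pairs are split); `leak_free=True` rebuilds the
SVD and the embeddings per fold with the test-fold positives removed from
the matrix and network. The leak-free mode expects a fixed rank k so fold
features keep a constant dimension.

### Candidate ranking

Case-study mode trains on all labeled data and scores every lncRNA with no
recorded association to the queried disease; the top-N (default 10) by
descending score are reported, ties broken by name so output is
deterministic.

## Synthetic data

The generator is a cross-class stochastic block model: each entity gets one
of `n_blocks` communities uniformly at random, and a cross-class pair is an
edge with probability `within_density` (same block) or `between_density`
(different blocks). One block assignment drives all three tables, so the
association matrix is approximately rank-`n_blocks` (exercising the SVD
stage) and the LMDN has matching community structure (exercising the
node2vec stage), with a single ground truth for oracle tests. The
lncRNA–disease table then passes through the same min-degree filter as real
preprocessing.

Defaults (120 lncRNAs, 60 miRNAs, 60 diseases, 3 blocks, 0.30/0.02
densities, min_assoc 2) are a scaled-down stand-in for the real data shape
(a sparse 861×253 lncRNA–disease matrix with denser lncRNA–miRNA and
miRNA–disease satellites): small enough that the full pipeline
cross-validates in well under a minute, dense enough that the planted
signal is clearly recoverable. What the generator does *not* emulate:
scale-free degree distributions, correlated annotation bias (well-studied
diseases have more edges), name vocabularies, and the overlap structure of
multiple source databases. Passing tests on this generator therefore
demonstrate that the machinery recovers planted low-rank/community signal,
not that real-data headline numbers are reproduced.

## Numerical and design choices

- ε-fill default 1e-6; `epsilon ≤ 0` rejected.
- `gap_floor` 1e6 (the observed spectral collapse is many orders larger);
  zero singular values treated as infinite-ratio gaps.
- Alias construction is the standard two-stack method; reconstruction of
  the encoded distribution is exact to 1e-12 and asserted analytically.
- Transition distributions sum to 1 within 1e-12 by construction
  (normalization happens in exact arithmetic relative to the weights).
- Degenerate metrics: 0 + flag, never NaN.
- One global seed expands into per-stage seeds by fixed offsets
  (walks +1, embedding +2, negatives +3, shuffle +4, classifier +5,
  CV splits +6, modulo 2³¹), so stages can be rerun independently.
- Min-degree filtering is single-pass by default (one removal step), with
  an opt-in iterate-to-fixed-point mode.
- Name matching is exact after whitespace trimming; an optional casefold
  mode lowercases before matching. Ontology normalization of disease names
  is out of scope and assumed done upstream.
- The miRNA–disease input is assumed pre-filtered to causal records; a
  tag-column option keeps rows whose annotation column equals a given tag.

## Problem sizes used in validation

The planted-signal experiment (also what `scripts/acceptance.py` runs) uses
the generator defaults above: ~780 positive pairs after filtering, ~1550
labeled samples, a ~240-node LMDN, k = 8 linear + d = 16 nonlinear
dimensions, XGBoost, tenfold CV, plus linear-only / nonlinear-only
ablations and a label-shuffled control. Determinism is verified end-to-end
at 60/30/30; the k = 173 feature-shape contract at 200 lncRNAs × 180
diseases. These sizes were chosen so the complete suite runs comfortably on
one CPU.

## Known limitations

- The closed-world negative assumption mislabels any true-but-unconfirmed
  association drawn as a negative.
- Embeddings ignore node classes during training (no metapath constraints
  or type-aware objectives).
- The default evaluation protocol shares features across folds (see
  leak-free mode above); leak-free AUCs are systematically lower and are
  the more honest generalization estimate.
- Entities absent from the network (or isolated after filtering) receive no
  nonlinear features and are dropped from integrated-feature analyses.
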