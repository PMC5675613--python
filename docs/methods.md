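# Methods

## Model

The scorer treats the known miRNA–disease association network as a
bipartite graph and ranks unobserved pairs by a two-step resource
diffusion. The core assumption is that miRNAs with similar expression
distributions across tissues participate in similar diseases, so the
binary network is first re-weighted by two similarity structures — one
on the disease side (`A_d = A·SM_disease`), one on the miRNA side
(`A_m = SM_miRNA·A`) — and resource flows through the *shares* each
edge holds of its column or row mass. Because shares are ratios, the
final scores are invariant to any positive rescaling of either
similarity matrix; what matters is relative similarity, not its scale.
The diffusion is deliberately not iterated to convergence: it is
exactly one resource step plus one feedback step, followed by averaging
the miRNA-side and disease-side feedback. Scores are affine in each
damping coefficient at fixed value of the other, which makes the
convex-combination structure of the two weighted streams directly
testable.

A matrix-orientation note: the association matrix is fixed repo-wide as
rows = miRNAs, columns = diseases, and the two weightings are the
unique assignment (`A·SM_disease` and `SM_miRNA·A`) that is
dimensionally consistent with the column/row share normalizers. Column
or row sums of zero (a node isolated by cross-validation removal)
produce zero shares rather than errors — zero flow is the natural
limit, and leave-one-out routinely creates such nodes.

## Similarities

**miRNA side.** Pearson correlation of tissue expression profiles.
Pair correlations are computed by a scalar centered-dot-product routine
applied to each pair (cross-checked against an independent statistical
implementation in the tests) rather than a one-shot correlation-matrix
call; this keeps the missing-profile imputation bit-reproducible: every
pair touching an unprofiled miRNA receives the arithmetic mean of all
computable off-diagonal pair values — a single shared number, computed
over unordered pairs with the diagonal excluded (self-similarities
would inflate the mean) — and the imputed entries are flagged in a
mask. Zero-variance profiles are rejected by default, naming the
offending miRNA; `treat_constant_as_missing` downgrades them to the
missing-profile path. Negative correlations are kept by default;
`clip_negative_similarity` zeroes them *before* the imputation mean so
the stored matrix stays internally consistent. Negative weights make
the diffusion shares sign-mixed, which is mathematically fine but can
produce negative scores; both behaviors are exposed because neither is
canonically right.

**Disease side.** Each disease's DAG contains its descriptor term plus
all ancestors. Contributions are `Δ^k` with `k` the minimum descending
distance to the disease term, computed by breadth-first search up the
child→parent edges (the dynamic-programming form of "max over children
of Δ times the child's contribution"); the test suite keeps an
exhaustive path-enumeration oracle. Similarity is shared contribution
mass over total mass, with the disease's own term included in its term
set — required for self-similarity exactly 1. Diseases without a DAG
(MeSH coverage of real association databases is incomplete) mirror the
miRNA rule: they receive the mean of all computable off-diagonal
disease-pair similarities, flagged in a mask. Two disease ids may share
one descriptor term, in which case their DAGs are identical and their
similarity is 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha`, `beta` | 0.5 | convex weights of the disease- vs miRNA-weighted stream on the miRNA / disease side; 0.5 weights both streams equally and no data-driven tuning is attempted |
| `delta` | 0.5 | semantic decay per DAG level; the standard choice in disease-semantic-similarity work |
| `clip_negative_similarity` | false | zero negative expression correlations before diffusion |
| `lambda_neighbor` | 0.5 | user- vs item-based mix of the neighbor CF baseline |
| `katz_beta`, `katz_max_length` | 0.01, 4 | walk damping and length cap of the Katz baseline; no authoritative values exist for this task, these are conventional link-prediction settings (a warning is logged if `katz_beta` reaches 1/spectral radius) |
| `katz_include_direct` | true | add the length-1 term `β·A`; known edges are excluded from evaluation anyway, so both settings are defensible |
| `cv_folds`, `cv_repetitions` | 5, 20 | repeated k-fold protocol |

## Evaluation conventions

Held-out pairs compete only against the pairs unknown in the *full*
association matrix, never against other training positives. A round's
AUC is the Mann–Whitney concordance of the held-out score(s) against
the candidate scores, ties counting 0.5; the overall AUC averages
rounds. This rank-averaged concordance is the limit of a threshold
sweep over TPR/FPR while remaining exactly testable against an O(n²)
oracle. k-fold with k equal to the number of known pairs reproduces
leave-one-out up to floating-point summation order (the per-round
concordances are bit-identical; the means may differ at ~1e-16 because
fold order is shuffled). Repetition seeds are `seed + repetition
index`; the spread across repetitions is reported as the sample
standard deviation (n−1). The pooled ROC curve returned by `loocv`
aggregates every round's held-out and candidate scores; its trapezoidal
area is a pooled summary and can differ slightly from the
mean-over-rounds AUC, which is the headline number.

## Baselines

The collaborative filters and the Katz index are reconstructions from
standard definitions, not reproductions of any reference code: user-
based CF averages other miRNAs' associations weighted by miRNA
similarity (self excluded, absolute-value normalizer), item-based CF is
its disease-side mirror, neighbor-based CF is their convex blend, and
Katz sums damped walk weights of length 2..L on the symmetric block
network `[[SM_mir, A], [Aᵀ, SM_dis]]`, taking the miRNA×disease block.
Latent-factor and SVD baselines are out of scope.

## Synthetic benchmark

The generator emulates the structural assumption the scorer exploits:
60 miRNAs in 6 clusters share Gaussian expression templates over 40
tissues (per-miRNA noise sd 0.5, so within-cluster correlation ≈ 0.8
and between-cluster ≈ 0); 30 diseases anchor at the non-root nodes of a
binary term tree of depth 4, in depth-first preorder, and are split
into 6 contiguous blocks of that order (hence unions of adjacent
subtrees); each miRNA links to 3 distinct diseases of its cluster's
block; 10% of associations are replaced by uniform random pairs; 10% of
miRNAs lose their expression rows. All randomness derives from one
seed; identical seeds give byte-identical files. These sizes keep a
full leave-one-out sweep (178 rounds) plus 20×5-fold cross-validation
in a few seconds while leaving enough candidates (~1600) for stable
AUCs.

What the benchmark does *not* emulate: the heavy-tailed intensity
distribution of real expression data (Pearson similarity is
location/scale-free, so only the correlation structure matters), the
scale and extreme sparsity of curated association databases, their
block-free overlapping disease structure, and literature biases. In
particular, relative method ordering on this benchmark does not
transfer to real data — its planted block structure favors direct
similarity averaging, and the CF baselines indeed outscore the
diffusion scorer here, whereas on curated data the opposite has been
reported. Passing tests demonstrate correctness of the computations
and recovery of planted structure, not real-data performance.

## Numerical choices and degenerate inputs

0/0 shares are 0; ranking ties break by input order (stable sort);
Pearson values are clipped into [−1, 1] against rounding; id orderings
follow first appearance in the input file, making runs bit-reproducible
for identical inputs; all writers emit 17-significant-digit TSV so
read(write(x)) round-trips to full double precision. Empty association
files, single-class label vectors, zero-variance profiles, cyclic or
disconnected DAGs, duplicate DAGs, and infeasible generator
specifications all raise with messages naming the offender.

## Known limitations

A disease with no known associated miRNA (empty column) receives only
zero flow on its own column in training — the method cannot score
genuinely new diseases. The imputation rules tie all profile-less
miRNAs (and DAG-less diseases) together with one shared value, which
flattens their ranking among themselves. Damping coefficients are not
learned; 0.5 is a neutral choice, not an optimum.
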