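# Methods

This note records the mathematical and design choices behind
`phenofactor`, in the order data flows through the pipeline.

## 1. Term-by-encounter matrix

Each hospital encounter is tokenized into **field-qualified terms**: one
term per ICD-9-CM code per coded field (`adm:` admitting diagnosis,
`prin:` principal diagnosis, `sec:` secondary diagnosis, `pproc:`/`sproc:`
principal/secondary procedure), one `gender:` and one `disch:` term, one
binned `age:` term (half-open bins of width 0.5 years by default), and
stop-word-filtered, lower-cased `txt:` tokens from any free text.
Qualifying terms by field preserves the clinical role of a code: the same
diagnosis means different things as an admitting complaint versus a
principal diagnosis.  Missing or `N/A` fields emit nothing, and encounters
with no tokens are dropped with a warning (or kept as zero columns when
projecting test data).

The matrix `X` is terms × encounters with entries

* `binary` — 1 if the term occurs;
* `tf` — the raw count;
* `tfidf` (default) — count × `ln(N / df)`, with `df` the number of
  encounters containing the term.

**Why tf-idf is the factorization default.**  The l1 factorization seeds
its components with the max-l1-norm column/row selection rule.  Under
binary weighting, ubiquitous demographic rows (discharged home, gender)
carry the largest norms, so the selection rule seeds components on shared
demographics instead of diagnostic profiles; this was verified to miss one
or two of four planted phenotypes on mixed cohorts.  tf-idf sends a term
shared by all encounters to weight zero, which is exactly the
downweighting the selection criterion needs.

When projecting test encounters through a training vocabulary, unseen
terms are discarded and the *training* idf weights are reused, so test
columns live exactly in the training row space and no test-set statistics
leak into the features.

## 2. l1 low-rank matrix decomposition (LRMD)

LRMD fits `X ≈ Σᵢ σᵢ uᵢ vᵢᵀ` by minimizing the **entry-wise l1 norm** of
the residual.  The l1 criterion is robust to gross entry-wise outliers
(coding errors): a few corrupted entries move a weighted median far less
than they move a least-squares fit.

### Rank-one subproblem

With `u` fixed, each column `j` decouples:
`min_v ‖x_j − v·u‖₁ = min_v Σᵢ |uᵢ|·|x_ij/uᵢ − v| + const`,
whose exact minimizer is the **weighted median** of the ratios `x_ij/uᵢ`
with weights `|uᵢ|` (left endpoint when the optimal set is an interval).
With `v` fixed, the transposed criterion updates `u` the same way.  Each
half-step is an exact block minimization, so the objective sequence is
non-increasing and bounded below — the iteration always makes monotone
progress.  Iteration stops when two successive reconstructions differ by
less than `ε = 10⁻⁷` in Frobenius norm, or at `max_iter = 500`.

**Initialization.**  The classical selection rule picks the column or row
of largest l1 norm (ties: columns first, then lowest index).  A single
such start can be trapped by a dominant shared row or a noisy high-idf
column, so the driver races the top-3 columns *and* top-3 rows and keeps
the fixed point with the lowest objective.  The selection ranking is
unchanged; only its worse local minima are discarded.

### Rank-k

* `strategy="deflate"` (default): fit a rank-one term, subtract it, repeat
  on the residual `k` times.  Greedy deflation alone is not a stationary
  point of the joint rank-k objective, so by default it is followed by up
  to 10 **joint refinement sweeps**: alternating full least-absolute-
  deviations (LAD) matrix solves for `V` given `U` and for `U` given `V`,
  started from the deflation result.  On planted noise-free rank-≤3
  matrices this drives the relative l1 residual to machine precision.
* `strategy="joint"`: initialize `U` with the k largest-l1-norm columns
  (or rows) and run the alternating LAD matrix solves directly.

The k-dimensional LAD column subproblems are solved by iteratively
reweighted least squares (residual smoothing 10⁻⁸) followed by an exact
linear-programming polish (HiGHS via `scipy.optimize.linprog`); the
better objective wins, certifying optimality to 10⁻⁹.

Factors are returned in normalized form: `‖uᵢ‖₁ = ‖vᵢ‖₁ = 1`, `σᵢ > 0`,
and each `uᵢ` has a nonnegative entry sum (the sign indeterminacy of a
rank-one term is resolved by flipping both vectors).  The l2 baseline
(`svd_truncate`) uses l2 normalization, mirroring its fit norm.

### Baselines

* `svd_truncate` — best rank-k approximation in the Frobenius norm via
  LAPACK SVD, with numerically zero singular values dropped.
* `nmf_decompose` — non-negative matrix factorization by Lee–Seung
  multiplicative updates on the Frobenius objective, hand-written so the
  per-iteration objective trace and nonnegativity are observable; it
  agrees with scikit-learn's NMF objective on test problems.

## 3. Similarity-cutoff classifier

Given k term-space feature vectors extracted from training encounters, a
test encounter `x` is scored by its best cosine similarity to any feature,
clipped to `[0, 1]` (1 = perfect correlation, 0 = none); it is called
positive when the score **strictly exceeds** the cutoff.  The default
cutoff grid is `{0.65, 0.75, 0.85, 0.90}`.

Cross-validation uses a seeded shuffle + round-robin fold assignment
(sizes differ by at most one).  Per fold, the vocabulary, idf weights, and
features come from training folds only.  Two defaults deserve note:

* **Training on positives** (`train_on="positives"`): features are
  extracted from the positive-class training encounters, mirroring a
  detector trained on the phenotype of interest.  With max-over-features
  scoring, features extracted from a mixed cohort would let every
  background encounter match its own background feature, destroying the
  classifier; `train_on="all"` remains available.
* **Binary weighting for scoring** (`weighting="binary"` in
  `cross_validate` only): cosine similarity between presence/absence
  vectors lives on the scale the cutoff grid presumes (a positive-class
  median score ≈ 0.7), whereas tf-idf compresses scores toward zero and
  makes the printed cutoffs degenerate.  AUC is high under either
  weighting; tf-idf remains the default wherever features are being
  *discovered* rather than scored.

Confusion counts are pooled (micro-averaged) across folds for the cutoff
table and the ROC curve (one vertex per distinct score, trapezoidal AUC);
per-fold reports are kept alongside.

## 4. Synthetic cohort generator

Four latent phenotype profiles model a pediatric respiratory cohort:
asthma (APR-DRG 141, prevalence 0.5; wheezing on admission, asthma with
acute exacerbation as principal diagnosis, family history of asthma, ages
4–8, discharged home) and three background groups (144 respiratory signs,
131 cystic fibrosis, 132 BPD/chronic respiratory; prevalences
0.2/0.15/0.15) with majority-disjoint code sets.  Admitting/principal
diagnoses and the principal procedure are categorical draws; each
secondary code is an independent Bernoulli emission (0–3 secondaries per
record); ages are uniform in the profile range.  Conditional independence
makes the expected term matrix exactly rank-4 — one rank-one term per
profile — so `planted_feature_vectors` provides an exact ground truth for
recovery tests.  Profiles emit their defining codes with high probability
(0.65–0.9): a term must occur in more than half of a cluster to enter a
weighted-median feature at all, so lower emission rates would make a
profile invisible to *any* l1 factorization, not just this one.

With `noise_rate > 0`, each diagnosis slot is replaced with probability
`noise_rate` by a uniform draw from the pooled code list.  All randomness
flows from one seeded generator; identical arguments reproduce the cohort
byte-identically.

**A caution on noise and AUC.**  Pipeline AUC degrades with noise over
`{0.1, 0.3, 0.5}` but is *not* monotone from 0: at noise exactly 0 the
positives-only training matrix is so clean that the factorization splits
the asthma cluster into sparse sub-features that background encounters
partially match, and pooled AUC sits measurably below its noise-0.1 value.
The regression test asserts the monotone degradation on the noisy range
and that heavy noise is worse than none.

## 5. Reproducibility

Every CLI command funnels all randomness through one `--seed` and writes a
JSON manifest (full configuration, package version, SHA-256 checksums of
the inputs) into its output directory; rerunning a command with identical
inputs and seed reproduces its artifacts byte-for-byte.
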