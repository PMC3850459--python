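# phenofactor

Robust **l1-norm low-rank matrix decomposition** (LRMD) for clinical
phenotyping of hospital encounters, with the full surrounding pipeline:
term-by-encounter matrix construction from coded encounter records,
rank-k phenotype feature extraction, similarity-cutoff classification with
cross-validated sensitivity/specificity and ROC curves, SVD and NMF
baselines, and a seeded synthetic cohort generator so everything is
testable without access to protected health data.

## The science in brief

Hospital encounters can be represented as a weighted term-by-encounter
matrix `X`: rows are field-qualified clinical terms (`adm:786.07` wheezing
on admission, `prin:493.92` asthma with acute exacerbation, `sec:v175`
family history of asthma, gender, discharge status, binned age), columns
are encounters.  A low-rank factorization `X ≈ Σᵢ σᵢ uᵢ vᵢᵀ` compresses
the cohort into a few **phenotype features** `uᵢ` — term profiles that
co-occur — and encounters can then be classified by their cosine
similarity to those features.

Real coded data contain gross entry-wise errors, and least-squares
factorizations (truncated SVD) bend toward them.  LRMD instead minimizes
the **entry-wise l1 norm** of the residual by alternating optimization:
with `u` fixed, every column's optimal coefficient is an independent
least-absolute-deviations problem solved *exactly* by a weighted median;
with `v` fixed, the transposed criterion updates `u`.  Each half-step is
an exact block minimization, so the error sequence is monotone
non-increasing.  Rank-k factors come from greedy rank-one deflation
followed by joint alternating refinement (or a purely joint strategy).
See [docs/methods.md](docs/methods.md) for the complete methodology and
the reasoning behind every default.

## Worked example

```python
import numpy as np
from phenofactor import (build_matrix, cross_validate, default_profiles,
                         dominant_terms_report, extract_features,
                         generate_cohort)

# 1. a seeded synthetic cohort: 50% asthma (APR-DRG 141) against three
#    background respiratory phenotypes, with 10% code noise
cohort = generate_cohort(default_profiles(), n=1200, noise_rate=0.1, seed=0)

# 2. tf-idf term-by-encounter matrix and rank-4 l1 factorization
tm = build_matrix(cohort.records)
features = extract_features(tm, k=4)            # method="lrmd"
print(dominant_terms_report(features, top_m=3)) # Table-style feature view

# 3. 4-fold cross-validated similarity-cutoff classifier
report = cross_validate(cohort.records, cohort.labels, k=4, seed=0)
print(report.cutoff_table())                    # sens/spec at 0.65..0.90
print(f"pooled AUC = {report.auc:.3f}")         # ~0.99 on this cohort
```

The same pipeline through the CLI:

```bash
phenofactor simulate --n 1200 --noise-rate 0.1 --seed 0 --out out/cohort
phenofactor build-matrix --encounters out/cohort/encounters.csv --out out/matrix
phenofactor decompose --matrix out/matrix/matrix.txt --k 4 --out out/factors
phenofactor cross-validate --encounters out/cohort/encounters.csv \
    --labels out/cohort/labels.csv --k 4 --seed 0 --out out/cv
phenofactor report --encounters out/cohort/encounters.csv --k 4 --out out/report
```

Every command writes a JSON manifest (configuration, seed, package
version, input checksums); rerunning with identical inputs reproduces the
artifacts byte-for-byte.

The [examples/](examples/) directory contains one narrative script per
capability: robust factorization versus SVD under outliers, term-matrix
construction, planted-phenotype recovery, the cutoff classifier, and the
CLI pipeline.

## Repository layout

```
src/phenofactor/
  factorization.py   l1 LRMD, LAD solvers, SVD and NMF baselines
  features.py        tokenization, vocabulary, weighted term matrix
  evaluate.py        scoring, cutoff tables, ROC/AUC, cross-validation
  simulate.py        seeded planted-phenotype cohort generator
  io.py, cli.py      plain-text formats, manifests, CLI front end
docs/methods.md      methodology note
examples/            one narrative script per capability
scripts/acceptance.py  headline-quantity computation
tests/               unit, property-based and acceptance tests
```
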