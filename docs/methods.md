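# Methods

## Model and procedure

`phenofuse` scores the association of a candidate gene *g* with a query
disease *d* separately under each genomic data source, then fuses the
per-source evidence.

**Similarity construction.** Each source is reduced to a symmetric
gene–gene similarity matrix with entries in [0, 1]. Profile-based sources
use cosine similarity (counts, information contents, binary memberships)
or the absolute Pearson correlation (expression vectors, length ≥ 3);
network-based sources (sequence-similarity graphs thresholded at e-value
< 1e−4, interaction graphs) use `ω = 1 − δ/δ_max` with δ the shortest-path
distance and δ_max the largest finite distance. Raw scores are sharpened
by `φ = exp(−((1 − ω)/σ)²)`. σ defaults to the *population* standard
deviation of the strictly-upper-triangle raw scores: self-pairs are not
pairs, so the diagonal is excluded, and missing entries (zero-norm or
zero-variance profiles, disconnected network pairs) are excluded as
carrying no information. Disconnected pairs are assigned ω = 0 — the
lowest-similarity semantics — but flagged in a missing mask so downstream
sums can skip them; δ_max is taken over the whole network, not per
component. The transform is strictly increasing in ω and fixes φ(1) = 1,
so it never reorders similarities; with a typically small σ it pushes weak
raw scores to essentially zero, which is the intended noise suppression.

**Regression scoring.** With reference diseases = all annotated diseases
in the phenotype matrix except the query, the phenotype similarities
`Y_i` are regressed on genotype similarities `x_i = Σ_{k∈I_i} φ(g, k)` and
H₀: β = 0 is tested one-sided against β > 0 with the exact t_{n−2}
statistic from closed-form OLS. The candidate is treated as the sole gene
of the query, so the query's own annotations are never used; this makes
leave-one-out validation masking inherent rather than a switch — there is
no separate "masking" flag because removing the query's annotations would
change nothing in the protocol. Degenerate predictors (zero variance in x)
raise an error in the scalar path and yield a missing score in the batch
path; a perfect fit (S² = 0, β̂ > 0) underflows the p-value to the clip
floor rather than zero.

**Empirical calibration.** Because phenotype similarities are bounded and
not exactly Gaussian in real data, raw p-values are calibrated against the
empirical distribution of raw p-values over a seeded sample of
non-associated (disease, gene) pairs. The calibrated value is the add-one
smoothed rank `(#{null ≤ p} + 1)/(M + 1)` — a deliberate deviation from
the plain proportion, so that calibrated p-values are strictly positive
and safe under the `−2 ln p` transform. The default grid size is
M = 2,000 pairs in the pipeline object (10,000 in the low-level builder;
full enumeration is available for small instances). One grid is shared by
all sources: it provides the per-source null distributions *and* the
sample on which the cross-source correlation is estimated, so calibration
and dependence correction refer to the same background.

**Fusion.** Available per-source calibrated p-values are combined with
`X = Σ −2 ln p_i`; missing sources are dropped and k reduced. Under
dependence X is approximated by `r·χ²_v` with
`r̂ = (1/4k)ΣΣ cov(V_i, V_j)`, `v̂ = 2k/r̂`, `cov(V_i, V_i) = 4`, and cross
covariances from the quartic polynomial
`a₁ρ̃ + a₂ρ̃² + a₃ρ̃³ + a₄ρ̃⁴` with a₁ = 3.263119, a₂ = 0.709866,
a₃ = 0.026589, a₄ = −0.709866/n. ρ̃ is the bias-corrected correlation
`ρ̂(1 + (1 − ρ̂²)/(2(n − 1)))` of the probit scores `Z = Φ⁻¹(1 − p)`
estimated pairwise-complete over the background grid; source pairs with
fewer than 30 complete observations fall back to independence with a
warning, and a non-positive r̂ (never observed for |ρ̃| ≤ 1 with these
coefficients, but guarded) also falls back to independence. n is the
minimum pairwise-complete count. p-values are clipped to
[1e−300, 1 − 1e−16] before probit and log transforms. Combined p-values
become Storey q-values with π̂₀ estimated at a single fixed λ = 0.5
(`π̂₀ = #{p > λ}/((1 − λ)m)`, clipped into [1/m, 1] for determinism — no
spline smoothing); with π̂₀ = 1 they reduce exactly to Benjamini–Hochberg.
Ranked output orders by (q, p, gene id), a deterministic total order.

## Validation harness

Leave-one-out cross-validation hides one annotated association per run and
ranks the hidden gene against m = 99 controls — either the m genes nearest
on the same chromosome (absolute coordinate distance; ties by smaller
coordinate, then gene id) or a uniform seeded draw from the genome.
Controls always exclude the test gene and every gene annotated to the
query. Metrics: mean rank ratio (mean of rank/(m+1); ≈ 50.5% for a random
ranker at m = 99), the rank-ROC AUC from sweeping a rank-ratio threshold
(sensitivity = fraction of test genes at or below the threshold,
specificity = fraction of control ranks above it, trapezoid integration
over all observed thresholds plus the endpoints), and top-k counts with
`n_runs · k / list_size` as the random-guess reference. The binned
correlation analysis buckets all C(n, 2) pairs of annotated diseases into
10 equal-width phenotype-similarity bins on [0, 1] (last bin closed,
empty bins dropped with a warning) and reports Pearson's r over the
per-bin means of phenotype and genotype similarity. Candidate-list
enrichment against a functional gene subset uses the one-sided
hypergeometric tail (Fisher's exact test).

## Synthetic worlds

The generator emulates the structural assumption the method exploits:
genes belong to functional modules, diseases are driven by modules, and
sharing a module raises both phenotype similarity (by `effect_b`) and
per-source gene similarity (by `sim_boost × reliability`). A latent noise
component shared between sources with weight `cross_source_rho` induces
correlated per-source scores. All noise is Gaussian, symmetrized, and
clipped to [0, 1] after addition (a simple, documented boundary bias —
negligible at the default scales where the clip point is ≥ 4 sd away).
Randomness flows from one root `SeedSequence` through five named children
(module assignment, phenotype, shared noise, locations, per-source noise),
so identical configs give byte-identical worlds and components can be
regenerated independently.

Defaults (the study conditions for every test and the acceptance script):
100 diseases, 200 genes, 50 modules of 4 genes, `genes_per_disease = 4`
(each disease annotated with its whole module, so two diseases per module
share their full gene family and *every* non-annotated pair is a genuine
null — the generator plants no partially-annotated modules),
`effect_b = 0.3`, `noise_sd = 0.05`, phenotype baseline 0.2, three sources
at reliability 1.0, `cross_source_rho = 0.2`, raw-similarity baseline 0.1,
boost 0.6, noise 0.05, five chromosomes.

What the worlds do *not* emulate: free-text-derived phenotype vectors and
their heavy-tailed cosine distributions, scale-free interaction networks,
annotation incompleteness bias toward well-studied genes, and
per-source gene-coverage gaps (all genes are present in all sources by
default). Passing tests therefore demonstrate the statistical machinery —
calibration, dependence correction, ranking — not performance on any real
corpus.

Two consequences of the defaults are worth knowing. First, with the
exponential transform's small σ, between-module similarities collapse
toward zero while the diagonal stays 1, so genotype vectors behave like
annotation indicators that are *identical across sources*; the estimated
cross-source correlation then saturates near 1 and the Brown-style
correction collapses k sources to effectively one test — the regime the
correction exists for, and the null-world combined p-values stay uniform.
The generative `cross_source_rho` becomes visible in the estimated
correlation only in a noise-dominated regime (high `sim_baseline`, large
`sim_noise_sd`, reliability 0), which is how the monotonicity property is
tested. Second, p-values of genes scored against the same query share that
query's phenotype vector and are positively dependent; uniformity checks
that compare a KS statistic to its iid critical value are therefore run on
a 400-disease null world, where at most a handful of sampled pairs share a
disease. This choice makes the KS reference distribution applicable; it
does not alter any threshold.

## Numerical choices and problem sizes

- Symmetry tolerance for matrix validation: 1e−10 relative; entries
  clipped into [0, 1] after validation.
- p-value clip bounds [1e−300, 1 − 1e−16]; combined p floored at 1e−300,
  never 0.
- The null grid in tests and the acceptance script uses 1,000–2,500 pairs;
  LOOCV experiments run all 400 planted associations at m = 99. These
  sizes give Monte-Carlo noise well inside the asserted margins while the
  whole suite completes in well under a minute of compute.
- e-value network edges use a strict `<` threshold comparison.
- Rank ties cannot occur in the output (total order by (q, p, gene id));
  in the LOOCV harness this amounts to competition ranking with a
  deterministic gene-id tie-break.

## Known limitations

- The scaled chi-squared is a two-moment approximation; its far tail is
  not exact under strong dependence, though the empirical size at
  α = 0.05 is correct within Monte-Carlo error (copula check, ρ = 0.5,
  k = 4).
- Calibrated p-values are discrete at resolution 1/(M + 1); very small
  combined p-values among candidates are floor-limited by the null grid
  size, which matters only for separating genes that are all already at
  the top.
- Sources are unweighted in the combination; weighting is deliberately
  out of scope.
- The probit-correlation estimate assumes the background pairs are
  representative of candidate pairs; a query-specific correction is not
  attempted.
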