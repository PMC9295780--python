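# Methods

## The model

The package targets regression problems where the mean response is a sparse
sum of Boolean threshold interactions — the *locally spiky sparse* (LSS)
family:

    E[Y | X] = β₀ + Σⱼ βⱼ Πₖ∈Sⱼ 1(X_k ⋚ γ_k),      X ∈ [0,1]^p,

with the inequality direction per feature encoded as a sign (−1 for "≤",
+1 for ">").  Each (feature, sign) pair is a *signed feature*; each term's
signed set S⁻ⱼ is a *basic signed interaction*.  This form captures switch-like
behaviour of biomolecules (gene-regulatory thresholds, kinase activation,
small-RNA repression) that smooth additive models cannot.  Reference
constraints: features uniform (hence independent) on [0,1]^p, bounded
response, non-overlapping interaction supports, and s = Σ|Sⱼ| bounded.  The
mean function depends on features only through their ranks, so uniformity is
equivalent to any independent continuous marginals.

*Union signed interactions* are unions of basic signed interactions, where a
single-feature interaction may enter with either sign (a lone indicator's
direction is not identified, since 1(x≤g) = 1 − 1(x>g)).

## Depth-weighted prevalence

For a CART tree with variance impurity, choose a random root-to-leaf path by
a fair coin at every internal node; a path of depth D has probability 2^(−D).
The path's thresholded signed-feature set F^ε collects (feature, branch sign)
at nodes whose impurity decrease ΔI = I(t) − Σ_children (N_c/N_t) I(c)
strictly exceeds ε, first occurrence per feature.  The DWP of a signed set S
is P(S ⊆ F^ε) over path and tree randomness.

Two facts drive selection: DWP(S) ≤ 2^(−|S|) for *any* ensemble and data
(each member of S forces one specific coin flip), and under the LSS model the
bound is attained asymptotically exactly when S is a union signed
interaction.  The selection rule keeps S with 2^|S|·DWP(S) ≥ 1 − η among
candidates of size ≤ smax found above the pruning support (1−η)·2^(−smax);
the maximal selected sets (not strictly contained in another selected set)
estimate the basic signed interactions.

DWP is estimated by *enumerating* every leaf path with its exact 2^(−depth)
weight rather than sampling paths: the path-randomness expectation is then
computed in closed form per tree and only tree randomness is approximated (by
`n_trees`, default 100).  Candidate mining is a weighted FP-growth over path
transactions; weighted support equals the DWP estimate exactly, and
anti-monotonicity of support makes the pruning sound.

## Forest fitting

Trees are grown greedily on the full dataset — no bootstrap or row
subsampling — with `mtry` features drawn uniformly without replacement at
every node.  Numerical conventions:

- candidate thresholds are midpoints between consecutive distinct sorted
  values; samples equal to the threshold go left ("≤" branch);
- ties in impurity decrease go to the smaller feature index, then the smaller
  threshold, making fits bit-reproducible given a seed;
- node impurity is the population variance (ddof = 0) of the node's
  responses; a node is a leaf when its impurity is ≤ 1e−15 or no split leaves
  ≥ `min_child` (default 1) samples on each side.  This matches the common
  library behaviour (grow to purity, minimum leaf size 1): in particular two
  samples with distinct responses are split once.

The node table (split feature, threshold, children, per-node count, impurity,
mean) is backend-neutral; ensembles fitted by scikit-learn can be imported
via `from_sklearn` / `import_forest` and mined identically — this serves as
an independent cross-check of the native fit in the test suite.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| ε (impurity threshold) | 0.01 | minimum ΔI for a split to enter F^ε; filters noise splits |
| η (prevalence slack) | 0.01 | relative margin below the 2^(−|S|) ceiling |
| smax | L+1 in presets | largest candidate size; one above the expected order so pruning is not overly restrictive |
| n_trees | 100 | trees used to average out tree randomness |
| mtry (selection) | p − 2 | see below |
| mtry (plain forest fit) | ⌈p/2⌉ | neutral default near the theory's optimum for p ≫ s |
| min_child | 1 | minimum samples per leaf |

**Why mtry = p − 2 for selection.**  The strict rule leaves interactions a
relative margin of only η below the ceiling 2^(−|S|); at n = 1000 this margin
is consumed unless signal splits are nearly deterministic, which requires
mtry close to p.  Conversely, if every node sees all features (mtry = p, no
row resampling), all trees coincide and the sign-flipped singleton of a
strong feature sits exactly on the 2^(−1) ceiling — a guaranteed false
positive.  Excluding a small fixed number of features per node (two) keeps
sign-flipped singletons strictly below the ceiling while leaving signal
splits near-deterministic.  Empirically this reproduces the expected
qualitative pattern at p = 20, n = 1000: perfect recovery for one order-2
interaction at SNR 5, partial recovery for two interactions or higher orders,
degradation under correlation, overlap and heavy-tailed noise.  The
theoretically motivated alternative ⌈p/2⌉ maximizes the gap for
non-interactions but leaves interaction DWP ≈ 0.21 < (1−η)/4 at this sample
size, so the strict rule selects nothing; the admissible-η window of the
finite-sample theory is empty at these constants (b(ε) > 1), so the
small-sample regime is governed by the empirical trade-off above.

Theory helpers exposed: b(ε) = (4ε/(C_β²C_γ^{2s−1}))^{C_m^{2s}/ln(1/C_γ)}
(natural log — the source leaves the base unstated), the admissible η
interval (2^s·b(ε), C_m^{s/2}), and the non-interaction-bound-minimizing
mtry\* = p(0.5 − s/(2(p−2))), rounded half-up.

## Synthetic data generator

`build_simulation_model(J, L, p, coverage)` places J disjoint order-L
interactions on consecutive feature blocks, all signs −1, unit coefficients,
with a shared threshold τ = (1 − (1−coverage)^{1/J})^{1/L} so that the union
of active regions covers the target fraction (default 50%) of samples —
keeping label balance comparable across (J, L).  `sample_dataset` adds noise
scaled to a signal-to-noise ratio defined as Var(E[Y|X])/Var(noise); the
signal variance is closed-form Σⱼ βⱼ² qⱼ(1−qⱼ) for disjoint interactions
(independent Bernoulli activations) and Monte Carlo otherwise.

Misspecification modes:

- **Correlated features**: a stationary latent-normal AR(1) vector mapped
  through the normal CDF (Gaussian copula).  Marginals stay exactly uniform;
  the latent-scale correlation between features j₁, j₂ is exactly
  α^{|j₁−j₂|}.  Trees are invariant to monotone marginal transforms, so the
  copula choice is the least intrusive way to realize the stated pattern.
- **Overlapping interactions**: two order-L blocks sharing k features
  (k = 1, L = 2 gives supports {1,2} and {2,3}); the threshold solves
  2τ^L − τ^{2L−k} = coverage numerically.
- **Heavy-tailed noise**: Laplace scaled so its variance equals the Gaussian
  recipe's σ²; Cauchy has no variance, so its scale is set to the same
  nominal σ (a variance-matched Cauchy does not exist — SNR is undefined
  there and the reported "SNR" is nominal).

What the generator does **not** emulate: discrete genotype encodings,
non-uniform marginals, feature-count-dependent effect sizes, heteroscedastic
or feature-dependent noise, and real linkage-disequilibrium correlation
structure.  A green recovery test therefore establishes correctness of the
pipeline under the stated generative family, not performance on real omics
data.

## Numerical choices

- Strict inequality ΔI > ε (ties at ε excluded); support and selection
  comparisons carry an absolute slack of 1e−12 against floating-point
  boundary flakiness.
- Path weights 2^(−depth) are summed with compensated summation where
  exactness matters (per-tree weights sum to exactly 1).
- Per-dataset and per-tree random streams derive deterministically from one
  integer seed (`numpy` SeedSequence); experiment rows record their own seed
  and are reproducible standalone.
- Eq-style "<" vs "≤" at thresholds differs on a measure-zero set for
  continuous features; "≤" is used uniformly (samples at the threshold go to
  the left branch).

## Limitations

- Recovery at η = 0.01 is intrinsically fragile for |S| ≥ 3 at n = 1000: the
  interaction's region holds O(2^(−|S|) n) samples and the prevalence margin
  shrinks geometrically, so scores drop sharply for more or larger
  interactions — this is a property of the method, reproduced, not a defect.
- With no row resampling, tree diversity comes only from feature
  subsampling; mtry = p is degenerate and values very close to p trade false
  negatives against singleton false positives as described above.
- The miner enumerates signed sets above the pruning support; for very small
  ε together with very small min-support on deep forests the candidate space
  can grow quickly — smax and the pruning rule are the intended guards.
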