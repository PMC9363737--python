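# Methods

This note documents the statistical model, the simulation machinery, the
numerical choices, and the limitations of `gpbreed`.

## Phenotype normalization

Traits are modeled jointly on a normalized scale. For trait *i* with raw
phenotype vector `y_i` over the n training accessions,

    w_i = (y_i − δ_i 1_n) / s_i

where `s_i` is the sample standard deviation (n−1 denominator; the unbiased
convention) and the centering constant `δ_i` depends on the breeding goal:
the sample mean for larger-/smaller-the-better traits, and the
breeder-specified target for nominal-the-best traits. For nominal traits
`s_i` remains the sample SD of the raw phenotypes — only the centering
differs — so a normalized GEBV of 0 corresponds exactly to the target after
back-transformation (`value·s_i + δ_i`). Constant traits (s = 0) are
rejected rather than silently passed through.

## Multi-trait GBLUP

With normalized phenotypes stacked trait-major, `w = [w_1; …; w_t]`:

    w = μ ⊗ 1_n + g + e,  g ~ MVN(0, Σ_A ⊗ K),  e ~ MVN(0, Σ_e ⊗ I_n)

`K = MMᵀ/p` is computed from the uncentered −1/0/1 coding matrix, so
`diag(K)_i` equals the homozygous fraction of accession *i* — it is a
relationship measure on the coded scale, not an allele-frequency-centered
kinship.

**REML.** After the eigendecomposition `K = U D Uᵀ`, rotating each trait
vector by `Uᵀ` decouples the restricted likelihood into n independent
t-variate Gaussian terms with covariance `d_j Σ_A + Σ_e`. We maximize this
exact restricted likelihood directly with L-BFGS-B over
Cholesky-parameterized `(Σ_A, Σ_e)` (log-diagonal, free off-diagonal). The
parameterization keeps both matrices positive semi-definite by
construction; for t ≤ 5 the parameter space is at most 30-dimensional and
each likelihood evaluation costs O(n t³), so quasi-Newton iteration is both
cheaper and more robust here than hand-rolled EM/AI updates. Convergence:
relative log-likelihood tolerance 1e-9, iteration cap 200; non-convergence
raises with the optimizer trace. Initial values: half the phenotypic
covariance for each component. A univariate REML oracle (profiled
eigen-rotated likelihood over the variance ratio) verifies the single-trait
fixed point independently in the test suite.

**BLUE/BLUP.** `(μ̂, ĝ)` solve the mixed-model equations assembled in the
Σ_e-premultiplied block form

    [ n I_t            I_t ⊗ 1_nᵀ                  ] [μ̂]   [(I_t ⊗ 1_nᵀ) w]
    [ I_t ⊗ 1_n        I_nt + (Σ_e Σ_A⁻¹) ⊗ K⁻¹    ] [ĝ] = [      w       ]

which is algebraically equivalent to the textbook R⁻¹-weighted form for
this model (premultiply the standard equations blockwise by Σ_e and
Σ_e ⊗ I_n); the equivalence with the dense GLS/BLUP solution
`μ̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹w`, `ĝ = G V⁻¹(w − Xμ̂)`, `V = Σ_A⊗K + Σ_e⊗I_n` is
asserted to 1e-8 relative error on random instances in the tests. The
system is solved densely; at the panel sizes this package targets
(n ≤ a few hundred, t ≤ 5) the (nt+t)² solve is negligible.

**Regularization.** The equations require `K⁻¹` and `Σ_A⁻¹`. If K's
condition number exceeds 1e10 (e.g. duplicated accessions), a ridge of
1e-6·mean(diag K) is added to its diagonal and the event logged. Σ updates
supplied externally are projected to the nearest PSD matrix by eigenvalue
clipping at 1e-8·trace.

**Prediction.** GEBVs of unphenotyped individuals with coding matrix `M_p`
are `μ̂_i + K_pt K⁻¹ ĝ_i` per trait, with `K_pt = M_p Mᵀ/p`. Variance
components and the training fit are estimated **once** and reused for every
generation of progeny prediction; the breeding cycle re-predicts, never
re-trains. Prediction is affine in the marker row, so a mid-parent genotype
receives the parental-average GEBV — a property the tests exploit.

## Selection index

`SI = Σ w_i Z_i`, weights non-negative and summing to 1, with
`Z = GEBV`, `−GEBV`, `−|GEBV|` for larger/smaller/nominal goals. The index
is computed on the normalized scale, where trait scores are dimensionless
and comparable; reported GEBVs are always back-transformed. Ties in SI are
broken by accession id so that every selection is deterministic.

## Parental-subset strategies

The candidate pool `S_c` contains accessions with SI **strictly** above the
mean (the boundary case matters only for degenerate all-equal inputs, which
yield an empty pool). GEBV-O ranks the *whole* panel, not just `S_c`, by SI.
The D-score of a subset is the determinant of the corresponding principal
submatrix of K.

Subset search: exhaustive enumeration whenever `C(|pool|, k)` ≤ the
configurable cap (default 10⁶); otherwise greedy forward selection on
marginal log-determinant gain followed by steepest-ascent single-swap
exchange to a local optimum. Determinants are compared via the eigenvalue
key `(rank, Σ log λ⁺)` so that singular subsets (duplicated genotypes) rank
below any positive-definite subset and log-scale comparison avoids
underflow. Both search modes are deterministic given candidate order; tests
verify the heuristic reproduces the exhaustive optimum on enumerable
fixtures.

## Progeny simulation

Individuals are phased: two ±1 haplotypes per marker; the genotype code is
their mean. Candidate accessions are phased at initialization —
deterministically at homozygous loci, uniformly at random per heterozygous
locus. Elite panels are essentially inbred, so the random-phase choice has
negligible downstream effect, but it is seeded and reproducible.

Gametes follow a two-state Markov chain along each chromosome: the starting
haplotype is uniform, and between adjacent markers at distance d Morgans
(ΔcM/100 from the linkage map) the chain switches with the Haldane
recombination fraction `r = (1 − e^(−2d))/2`. Independent inter-interval
switch events are exactly the no-interference crossover model, so no
crossover-count sampling is needed. Implementation detail: a single
Bernoulli switch vector per gamete with probability 1/2 at each chromosome
start simultaneously randomizes the start state and decouples chromosomes,
which vectorizes across thousands of gametes.

Crossing takes one gamete from each parent; selfing takes two independent
gametes from the same individual. The half-diallel mates every unordered
parent pair once (k parents → k(k−1)/2 F1 hybrids, no reciprocals or
selfs).

## Breeding-cycle orchestration

Defaults encode the standard design: 10 parents → 45 F1 → 60 selfed
offspring each → 2,700 F2; thereafter each generation predicts GEBVs,
selects the top 45 by SI, and selfs each selectee ×60, ending at F10, by
which point repeated selfing has driven heterozygosity to ≈(1/2)⁸ ≈ 0.4%
per initially-segregating locus ("fixed" inbred lines).

Per experiment: the training fit, candidate SI, and parental subsets are
deterministic, so they are computed once and the parents held fixed across
repetitions; each repetition re-runs only the stochastic progeny phase with
an independent RNG stream spawned from the root seed (keyed by weight
setting × strategy × repetition, so any sub-experiment with the same key
reproduces exactly). Reported per cell (strategy × weight setting):
parental mean GEBV, mean F10 GEBV (averaged over repetitions and the full
2,700-individual final population), genetic gain
`mean(GEBV_F10) − mean(GEBV_P)` — or `mean|GEBV_F10 − δ| − mean|GEBV_P − δ|`
for nominal traits, negative meaning improvement — plus the per-generation
best-individual trace (max-SI line, back-transformed) and, when at least
two weight settings are run, the percent improvement rate of each setting
relative to the last (conventionally the single-trait baseline).

The LSD comparison pools a one-way ANOVA MSE across cells per trait:
`LSD = t(1−α/2, df_err)·√(2·MSE/n)`, α = 0.01. Compact letters come from
maximal runs of mutually non-significant means in descending order — exact
for a distance-threshold criterion like LSD.

## Synthetic data

The generator emulates what the model assumes: a panel of (by default)
inbred founder accessions, markers placed uniformly on each chromosome with
MAF drawn from a configurable range, and phenotypes `y = mean + g + e` with
`vec(G) ~ MVN(0, Σ_A ⊗ K)` and iid residual rows `~ MVN(0, Σ_e)`. A sparse
alternative draws correlated QTL effects and recolors the realized genetic
values so their sample covariance equals Σ_A exactly. True genetic values
are returned for recovery and accuracy tests.

What it does **not** emulate: linkage disequilibrium between founder loci
(founder alleles are drawn independently per marker, so K's off-diagonal
structure comes from finite-marker sampling and allele-frequency
covariance, not realistic LD blocks), subpopulation structure, dominance or
epistasis, and genotype × environment interaction. Passing tests therefore
demonstrate internal statistical correctness of the machinery — unbiased
variance components, exact MME solutions, Mendelian-consistent simulation,
optimal subset search — not field-level predictive validity on any real
panel.

Default test scenario: 50 founders, 3 chromosomes × 100 markers (100 cM
each), two traits with genetic correlation 0.4 and heritability ≈ 2/3. A
full three-strategy experiment with 3 repetitions to F6 runs in well under
a minute; the heavier REML-recovery checks use a 300-accession,
1,000-marker panel. These sizes were chosen as the smallest panels at which
the Monte-Carlo checks have useful power.

## Known limitations

- The additive-only model ignores dominance/epistasis; for selfing
  programs to near-fixation this is the standard first-order approximation.
- Missing genotype calls are imputed as the **major homozygote** (code 1)
  after coding — a deliberate convention of this framework, kept verbatim.
  It is statistically crude (it biases toward the common class) and
  documented here so users with substantial missingness can pre-impute by
  other means.
- `K = MMᵀ/p` on uncentered codes differs from allele-frequency-centered
  kinship estimators; D-scores and GEBVs are internally consistent but not
  numerically comparable to centered-kinship pipelines.
- The greedy-plus-exchange subset search guarantees only a local optimum
  beyond the exhaustive cap.
- LSD controls the per-comparison, not family-wise, error rate; with many
  cells the letters should be read accordingly.
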