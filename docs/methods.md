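# Methods

## Relationship kernels

**Pedigree (A).** The average numerator relationship matrix is built by
the tabular method over an ordered pedigree (parents before offspring):
`a_jj = 1 + a(dam_j, sire_j)/2` and, for k earlier than j,
`a_jk = (a(k, dam_j) + a(k, sire_j))/2`, unknown parents contributing
zero. This equals twice the coancestry matrix and yields the familiar
expectations (half-sibs 0.25, full-sibs 0.5, parent–offspring 0.5,
selfed offspring diagonal 1.5). Under the OP half-sib assumption the
pedigree consists of founder dams and their offspring with unknown
sires, so A is block diagonal with 0.25 within families — exactly the
structure whose failure the genomic kernels expose.

**Additive genomic (G_add).** VanRaden's first kernel:
`G_add = ZZ' / (2 Σ_i p_i q_i)`, `Z = M − 2p`, where `M` holds
alternative-allele dosages (0/1/2) and `p` the frequency of the counted
allele. Frequencies are computed from the observed sample by default;
externally supplied (e.g. founder) frequencies are accepted, since which
reference population is used is an analysis choice with visible effects
on the scale of G. Monomorphic loci are dropped (the denominator
requires `p q > 0`). Missing dosages are mean-imputed with `2p`
(centered value zero), which preserves the zero-centering of Z;
exclusion instead of imputation can be emulated by pre-filtering loci.

**Dominance (G_dom).** The classical parameterization codes the
reference homozygote `−2p²`, the heterozygote `2pq` and the alternative
homozygote `−2q²`, with denominator `Σ_i (2 p_i q_i)²`. This coding has
zero mean under HWE and is orthogonal to the additive coding, so
additive and dominance variances partition rather than compete. The
printed form of the denominator is read as a sum over loci — the only
reading that gives E[diag] ≈ 1. The genotypic alternative centers a
heterozygosity indicator by `2pq` with denominator
`Σ 2 p_i q_i (1 − 2 p_i q_i)`; at `p = 0.5` the two coincide.

**Epistatic kernels.** First-order interaction covariances are
Hadamard products of the marginal kernels (`AxA`, `DxD`, `AxD`); the
Schur product theorem guarantees PSD-ness. `AxA` is numerically close
to `I` plus a small multiple of `G_add`-squared structure, which is why
additive×additive variance is intrinsically hard to separate from
additive and residual variance — a feature of the model class, not of
the implementation (see *Known limitations*).

**Stabilization.** `stabilize(K, ε)` shrinks a kernel toward the
identity, `K* = (1−ε)K + εI` (default ε = 0.01 when invoked). It is
only needed when a genomic kernel is numerically singular (fewer
effective markers than individuals); the residual term keeps the
phenotypic covariance matrix positive definite during REML regardless,
so stabilization is applied on demand rather than by default.

## Mixed models and REML

The individual-tree model is `y = 1μ + Σ_t Z_t u_t + e` with
`u_t ~ N(0, σ²_t K_t)`: genetic terms carry a relationship kernel
(`Z_t` selecting the phenotyped individuals), design terms
(replication; replication×family as the crossing of block and family
labels, empty cells simply absent) carry identity covariance. The model
ladder is ABLUP (A), GBLUP-A (G_add), GBLUP-AD (+G_dom), GBLUP-ADE
(+AxA, DxD, AxD) and GBLUP-AE (G_add + AxA), all with the two design
terms and a residual.

Estimation is **average-information REML**: three EM-flavored updates
for stable start-up, then Newton steps with the AI matrix
`AI_ts = ½ y'P B_t P B_s P y` (with `B_t = Z_t K_t Z_t'`), step-halving
whenever a step would decrease the restricted likelihood, and variance
components constrained to a lower bound of 1e−6 × the phenotypic
variance. Convergence requires |Δ logL| < 1e−6 together with a small
parameter change (relative < 1e−6, or absolute below 1e−6 × phenotypic
variance to terminate cleanly at boundary-adjacent stationary points);
the iteration cap is 200 and a non-converged fit is returned flagged
with its trace rather than discarded. Starting values split the
phenotypic variance equally across all variance parameters.

Standard errors come from the inverse AI matrix restricted to the free
(non-pinned) parameters; parameters pinned at the lower bound are
reported with SE marked not estimable. BLUPs are
`û_t = σ̂²_t K_t Z_t' P y` — defined for *all* individuals in a kernel,
which is what lets training fits predict unphenotyped validation trees —
and each effect's SEP is the square root of its prediction error
variance `σ²_t K_t − σ⁴_t K_t Z_t' P Z_t K_t` (diagonal), never larger
than the prior SD.

**Heritability.** `h² = σ̂²_a / σ̂²_p` where the denominator sums the
genetic components and the residual; replication and
replication×family are *excluded* (they are design, not phenotype-
intrinsic, variance). The percent-of-total decomposition, by contrast,
divides by the sum of *all* components. Both conventions are exposed as
separate operations because published component tables commonly mix
them. The h² SE uses the delta method with the AI-based covariance
matrix.

**AIC** is `−2 logL + 2t` with `t` the number of variance parameters in
the model (bound-pinned parameters included, so nested models are
penalized consistently). The REML log-likelihood omits
software-specific constants; AIC values are therefore comparable only
within this implementation.

**Eigen-diagnostic.** `F = L^(−1/2) V L^(−1/2)` converts the asymptotic
covariance of the variance-component estimates into their sampling
correlation matrix; sorted eigenvalues and their cumulative proportion
express how far the components are from orthogonality (all eigenvalues
1 ⇒ straight diagonal). Boundary parameters (zero sampling variance)
are excluded with a warning.

## Cross-validation

k-fold (default 10) with replications (default 5), three schemes:
random; family-restricted (whole families assigned to folds, removing
all pedigree links between training and validation); and block
restricted, a leave-one-block-out scenario in which the remaining
blocks are additionally divided into k training folds. The published
description of the block scheme does not fully determine how the k
training folds are combined; the default here trains k models (each
omitting one training fold) and averages their predictions for the
validation block within a replication, and `block_mode="loo"` provides
the simpler single-model alternative. During training fits the
validation individuals keep their kernel rows/columns but lose their
phenotypes. Accuracy is the Pearson correlation per replication between
PBVs and the full-data EBVs of the reference model, summarized as mean
± sd/√reps; a constant PBV vector (the pedigree model under family
folding, where predictions collapse exactly to the model mean) yields a
missing value rather than zero. Per-replication fold seeds derive
deterministically from the master seed.

## The synthetic-data generator

The generator emulates a single-site OP progeny trial: unrelated founder
dams and per-family pollen pools drawn in HWE at locus frequencies
uniform on a configurable MAF interval; offspring produced by
per-locus Mendelian sampling (loci unlinked — linkage is irrelevant to
the kernel estimators being validated); contamination via a selfing
probability and a repeated-sire probability (hidden full-sibs); a
fresh pollen draw takes an unused pool candidate while any remain, so
zero contamination with a sufficient pool yields exact half-sib
families. Defaults mirror the dimensions of a realistic spruce trial
(214 families, 8 offspring, 6 blocks, thousands of SNPs); the
contamination defaults (selfing 0.05, repeated-sire 0.10) are
plausible placeholders for wind-pollinated conifers and are
configurable, since true contamination rates in any given trial are
unknown.

Phenotypes follow the estimated decomposition: additive values linear
in centered dosages, dominance as heterozygote effects at a random
locus subset, additive×additive as products of centered dosages at
random locus pairs — matching the orthogonal structure the kernels
estimate. Genetic components are **rescaled post hoc to hit their
target variances exactly**, which makes parameter-recovery experiments
sharp; block, block×family and residual effects are drawn (not
rescaled) at their targets. Families are spread round-robin over
blocks, giving ~1–2 trees per family×block cell, as in real row-plot
trials.

What the generator does *not* emulate: linkage and LD, population or
provenance structure, multi-site genotype×environment effects,
spatial field trends, selection across generations, genotyping error.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to these real-data
complications.

## Validation experiments and problem sizes

The test suite validates the estimators against independent oracles:
the tabular A-matrix against recursive-coancestry brute force on random
pedigrees; REML against closed-form ANOVA estimators on balanced
one-way layouts; GBLUP at fixed variance ratio against ridge-regression
marker effects (exact equivalence); hand-evaluated single-locus
kernels. Recovery experiments use 200 families × 8 offspring × 3000
loci over 10 seeds — the scale at which within-family information is
sufficient for the genomic decomposition while keeping a full run of
the suite in the minutes range; contamination-direction experiments use
80 families with heavier contamination (selfing 0.10, repeated-sire
0.30) where the A-vs-G contrast is pronounced.

## Known limitations

* Additive×additive variance is weakly identified: `AxA` is nearly
  collinear with `G_add` and `I`, so single-seed estimates of σ²_aa
  (and consequently σ²_a, σ²_e) have large sampling variance and
  frequent boundary solutions. Means over seeds recover truth; single
  fits should be read together with their SEs and the eigen-diagnostic.
* With ~1–2 trees per family×block cell, replication×family variance
  and residual variance are only weakly separable (a property of the
  trial design, mirrored in the generator).
* Single-trait, single-site models only; no spatial residual
  structures, no Bayesian alternatives, no single-step blending of A
  and G.
* The genotypic dominance parameterization changes the scale of σ²_d;
  its estimates are not directly comparable with the classical ones.
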