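# Methods

## Model and procedure

Let Y be an M×p table of taxon counts from n subjects (or clusters), subject
i contributing mᵢ samples, M = Σᵢ mᵢ. The pipeline:

1. **Normalization.** Counts are shifted by a pseudocount (default 0.5),
   closed to relative abundances, and CLR-transformed:
   clr(x)ₖ = log xₖ − (1/p) Σⱼ log xⱼ. CLR output rows sum to zero; the
   pseudocount makes zero counts finite and is configurable. Bray-Curtis is
   available as an alternative dissimilarity and then operates on relative
   abundances — CLR values are signed and are rejected for it.
2. **Kernel.** Pairwise Euclidean distance between CLR rows (the Aitchison
   distance) is Gower-centered: K = −½(I−H)(D∘D)(I−H) with
   H = 1(1′1)⁻¹1′. For Euclidean-embeddable D, K is PSD and classical MDS
   is exact: distances among the full PC embedding reproduce D to machine
   precision (this is a tested invariant).
3. **Kernel PCA.** K = UΛU′ with eigenvalues sorted nonincreasingly
   (stable sort under ties) and each eigenvector sign-fixed so its
   largest-magnitude entry is positive (reproducible orientation across
   platforms). Kernel PCs are Φ = UΛ₊^{1/2}; negative eigenvalues (possible
   for Bray-Curtis) are clipped to zero with a warning reporting the
   clipped mass fraction — standard PCoA practice that keeps Φ real.
4. **Retention.** The smallest ℓ leading PCs whose cumulative
   positive-eigenvalue fraction reaches the threshold (default 0.90) are
   kept. Tail PCs carry so little variance that their mixed-model fits are
   numerically fragile; dropping them barely affects the ordination.
5. **Per-PC mixed model.** Each retained PC is regressed on the nuisance
   fixed covariates with a per-subject random intercept (optional random
   slope on numeric time): Φᵢ⁽ʳ⁾ = xᵢβ⁽ʳ⁾ + zᵢγᵢ⁽ʳ⁾ + εᵢ⁽ʳ⁾. Estimation is
   REML (statsmodels MixedLM); if the optimizer fails it retries with ML,
   and as a last resort falls back to OLS with Ĝ = 0 and `converged=False`
   recorded. PCs whose fit fails outright are dropped with a warning rather
   than aborting. BLUPs are computed directly as γ̂ᵢ = ĜZᵢ′V̂ᵢ⁻¹(Φᵢ−xᵢβ̂),
   which stays defined when the REML solution lands on the boundary
   (singular Ĝ). Time enters the fixed design as a categorical factor by
   default (visit indices); numeric coding is a flag.
6. **Residuals.** Marginal (Φᵢ−xᵢβ̂), conditional (additionally minus
   zᵢγ̂ᵢ), or — the default — standardized: e*ᵢ = Lᵢ⁻¹(Φᵢ−xᵢβ̂) with
   V̂ᵢ = ZᵢĜZᵢ′+σ̂²I = LᵢLᵢ′ (lower Cholesky, applied block by block in the
   canonical subject/time order). Standardization is the default because
   plugging in estimated fixed effects leaves within-subject dependence in
   the marginal residuals; whitening removes it, which is what one wants
   when the dependence itself is nuisance. A numerically singular V̂ᵢ gets a
   ridge jitter of 1e−8·tr(V̂ᵢ)/mᵢ before a hard failure.
7. **Re-ordination.** K* = EE′ (PSD by construction) is eigendecomposed
   with the same conventions as step 3; per-axis proportions are
   λ*ⱼ/Σλ* — fractions of the *residual* variability (trace of K*). E
   itself is not plotted: adjustment redistributes variance across columns,
   so a fresh eigendecomposition is required.

The cross-sectional fixed-effects-only adjustment
K_adj = (I−P_X)K(I−P_X) is implemented by two independent routes
(projection and per-PC OLS residuals) that must agree to 1e−10, and it is
the exact degenerate case of the pipeline (one sample per subject, marginal
residuals, full retention) — both facts are enforced by tests. With no
covariates, no random effects, marginal residuals and full retention the
whole pipeline is the identity on PCoA coordinates up to axis sign.

## Assumptions and caveats

- The LMM treats each kernel PC as Gaussian with linear covariate effects
  and iid error given the random effects. The target is visualization, not
  inference: no standard errors or p-values are reported for β̂, and no
  hypothesis tests (e.g. PERMANOVA) should be run on adjusted PCs or K* —
  plugging in estimated effects induces dependence that invalidates them.
- PCs are adjusted independently; cross-PC covariance of the estimates is
  ignored.
- Fits need adequate replication; with a single observation per subject the
  intercept and residual variances are not separately identified and the
  code falls back to OLS with an explicit warning.

## Synthetic data

The generative scenarios reproduce three repeated-measures designs with
known truth. Defaults are the study conditions, not tuning knobs:

- **Scenario 1** (time-invariant nuisance): n=100 subjects, m=4 visits,
  p=233 taxa. Baselines are Dirichlet perturbations (pseudocount 0.5,
  library size preserved up to rounding) of rows drawn from a seed table;
  each later visit draws multinomial(previous library size,
  Dirichlet(previous counts + 0.5)), then multiplies 20 shared taxa by
  0.25, 20 treatment taxa by 3 (treated arm only), and 20 sex-affected taxa
  by 8 (females only). The sex taxa are chosen as the pairs with observed
  prevalence closest to 0, 0.1, …, 0.9 so the nuisance spans the prevalence
  range; all effect sets are disjoint and constant over time; counts are
  rounded at the end. Because each visit evolves from already-affected
  counts before the multiplier is applied again, the realized fold change
  compounds over visits (≈3 at the first post-baseline visit, growing
  thereafter) — this is what makes treatment points migrate over time.
- **Scenario 2** (time-varying nuisance): as scenario 1 but the nuisance is
  a sickness indicator redrawn Bernoulli(½) per subject-visit (applied at
  baseline too), multiplier 24.
- **Scenario 3** (clustered): n=30 families × 3 members, no time axis.
  Member 1 is a baseline draw; members 2 and 3 are drawn per taxon from a
  bivariate normal centred at member 1's count with covariance
  [[17, 10], [10, 17]] — this matrix is a documented stand-in (the source
  value could not be established) and is configurable; treatment
  multipliers 8 (member 2) and 32 (member 3) on disjoint 20-taxon sets;
  counts rounded, negatives truncated to zero.

The default seed table is fully synthetic: 270 samples × 233 taxa,
log-normal library sizes (median 10⁴, σ=0.7), per-sample Dirichlet
compositions around a heavy-tailed global profile (log-normal weights,
σ=2; per-taxon concentration 0.25·p·wₖ/Σw). This yields the sparsity
(mostly-zero rows, a few dominant taxa) and depth heterogeneity typical of
vaginal 16S surveys. It does **not** reproduce a real cohort's taxon
identities, phylogenetic structure, or covariate-abundance associations —
passing scenario tests shows the adjustment removes the *injected* nuisance
structure under a realistic count-generating mechanism, not that it
recovers biology in any particular real dataset. A real count table can be
passed via `ScenarioConfig(baseline=...)`.

RNG: one `numpy` Generator per study seeded from the config, with spawned
per-subject substreams, so studies are byte-reproducible.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) and the end-to-end tests
use: equivalence and MDS checks at 30–40 samples; whitening calibration at
n=50 subjects × 4 visits × 10⁴ replicates (fixed effects re-estimated per
replicate by GLS at the fitted components — the REML β̂ given those
components — instead of a full REML refit per replicate); variance-component
recovery at n=100 × 4 over 40 REML replicates with a 3-Monte-Carlo-SE
criterion; scenario 1 at its full default size (400 samples, ℓ ≈ 79 PCs ≈
90% variability) and scenario 3 at 90 samples. Group separation is scored
as the mean per-time-point silhouette of the grouping variable on PC1–PC2
of the joint embedding, post-baseline visits only (the treatment effect is
injected from the first post-baseline visit).

## Known limitations

- No phylogeny-aware kernels (UniFrac family) and no tree handling.
- No rarefaction or library-size normalizations beyond relative abundance
  and CLR.
- Linear mean structure and Gaussian random effects only; no GLMMs or
  serial correlation structures beyond the random effects plus iid error.
- BIOM support covers the v1 JSON layout only (dense and sparse), not
  BIOM v2/HDF5.
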