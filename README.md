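# rmapcoa

**Covariate-adjusted principal coordinates analysis for repeated-measures
microbiome studies.**

Principal Coordinates Analysis (PCoA) is the standard way to visualize
microbiome beta-diversity: samples are embedded so that their Euclidean
distances approximate an ecological dissimilarity. In longitudinal or
clustered designs, however, the leading axes are routinely hijacked by
nuisance covariates (sex, age, sickness episodes) and by within-subject
correlation — a subject's repeated samples cluster together and drown out
the structure of interest. Cross-sectional adjusted PCoA (aPCoA) projects
fixed covariates out of the similarity matrix, but it assumes independent
samples and cannot absorb the repeated-measures correlation.

`rmapcoa` implements a mixed-model extension of aPCoA for anyone analyzing
longitudinal or family/household-clustered 16S or metagenomic count tables:

1. Transform counts (CLR by default) and compute a dissimilarity matrix
   (Aitchison by default; Bray-Curtis supported).
2. Gower-center into a kernel **K** and extract kernel PCs
   **Φ** = **U Λ**^1/2; retain the top ℓ PCs covering a target fraction
   (default 90%) of the variability.
3. Regress each retained PC on the nuisance covariates with a linear mixed
   model: Φᵢ⁽ʳ⁾ = xᵢβ⁽ʳ⁾ + zᵢγᵢ⁽ʳ⁾ + εᵢ⁽ʳ⁾, with a random intercept per
   subject/cluster (optional random slope on time), fitted by REML.
4. Form standardized residuals e*ᵢ = Lᵢ⁻¹(Φᵢ − xᵢβ̂) where
   V̂ᵢ = ZᵢĜZᵢ' + σ̂²I = LᵢLᵢ' — block Cholesky whitening, so
   var(e*) ≈ I and the estimated within-subject dependence is removed.
   (Marginal and conditional residuals are available as alternatives.)
5. Reconstruct the adjusted kernel **K\*** = **E E**′ and re-ordinate;
   per-axis fractions of residual variability come from the eigenvalues of
   **K\***.

The cross-sectional projection formula
K_adj = (I − X(X′X)⁻¹X′) K (I − X(X′X)⁻¹X′) is included both as a baseline
method and as an exact internal cross-check (it must agree with the per-PC
residual construction to numerical precision).

A simulation module generates three repeated-measures study designs with
known ground truth — a time-invariant nuisance (sex) masking a treatment
effect, a time-varying nuisance (sickness), and family-clustered sampling —
built on Dirichlet count perturbation and multinomial community evolution
over a sparse synthetic baseline community table.

## Worked example

```python
import rmapcoa as r

study = r.scenario_time_invariant(
    r.ScenarioConfig(n_subjects=40, n_timepoints=4, n_taxa=120, seed=2)
)
model = r.RepeatedMeasuresAPCoA(
    study.table, study.design.metadata,
    fixed_formula="sex + time + sex:time",
    random_formula="1|subject",
)
res = model.fit()
print(res.summary())
```

```
Repeated-measures adjusted PCoA
===============================================
samples: 160   subjects/clusters: 40   taxa: 120
kernel: aitchison (clr transform, pseudocount 0.5)
fixed effects: sex + time + sex:time
random effects: 1|subject
residual type: standardized
retained PCs: l = 32 of 119 (90.2% of variability)
LMM fits converged: 32/32
adjusted axes (top 5): PC1 9.8%, PC2 9.4%, PC3 6.9%, PC4 5.7%, PC5 5.5%
```

32 kernel PCs carry 90.2% of the kernel variability; each was adjusted by
its own converged REML fit. Quantifying group separation on the first two
axes at the post-baseline visits (mean per-visit silhouette):

```python
md = res.design.metadata
adj, unadj = res.ordination.coordinates((1, 2)), res.unadjusted.pcs[:, :2]
for name, coords in [("unadjusted", unadj), ("adjusted", adj)]:
    print(name,
          r.stratified_silhouette(coords, md["arm"], md["time"], include=[1, 2, 3]),
          r.stratified_silhouette(coords, md["sex"], md["time"], include=[1, 2, 3]))
```

```
unadjusted treatment silhouette: 0.134  sex silhouette: 0.462
adjusted   treatment silhouette: 0.279  sex silhouette: 0.016
```

Before adjustment the embedding is organized by sex (silhouette 0.46, the
injected nuisance) and the treatment arms barely separate; after mixed-model
adjustment the sex structure is gone (0.016) and the treatment separation
doubles. `res.frame()` joins coordinates with metadata for export, and
`res.plot(color="arm", shape="sex", facet="time")` renders the faceted
scatter.

The same pipeline is available from the shell:

```bash
rmapcoa simulate --scenario 1 --seed 2 --out sim/
rmapcoa adjust --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --fixed "sex + time + sex:time" --random "1|subject" --out adj/
rmapcoa plot --ordination adj/ordination.tsv --color arm --shape sex \
    --facet time --out pcoa.png
```

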