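# Methods

## Model

For each gene the trait vector `y` (length n) is modelled as

    y = X b + Q v + u + e,
    u ~ N(0, σ²_g K),    e ~ N(0, σ²_e I),

where `X` is the collapsed rare-variant indicator of the gene, `Q` an
optional matrix of genotype principal components, and `K` a relatedness
matrix. The random-effect design is the identity: one polygenic effect per
observed individual. The six supported configurations differ only in which
of `Q` and `K` are present (REG/PC: no random effect; KIN/PC-KIN: `K = 2Φ`
from the pedigree; IBS/PC-IBS: `K` = marker identity-by-state matrix).

Assumptions worth stating explicitly: the trait is continuous with
approximately Gaussian residuals; relatedness acts additively (no dominance
or shared-environment components); all rare variants of a gene act in the
same direction, which is what presence/absence collapsing implicitly
assumes; and the same MAF threshold defines "rare" for every gene.

## Collapsing

A variant is rare when its folded MAF is strictly below the threshold
(default 0.01). MAF is the allele count over twice the number of
non-missing subjects, folded to [0, 0.5], computed on the full related
sample. A subject is a carrier (X = 1) iff it has dosage ≥ 1 at ≥ 1 rare
variant of the gene; missing dosages count as non-carrier, a conservative
presence/absence reading. Genes whose indicator is constant (no carriers,
or all carriers) are reported with status `untestable` rather than dropped,
so evaluation denominators remain auditable.

## Relatedness matrices

*Pedigree kinship* φ follows the classical recursion over a
parents-before-children order, with memoised values: φ(i,i) = ½(1 +
φ(father, mother)) and φ(i,j) = ½(φ(father_i, j) + φ(mother_i, j)) taking i
such that j is not a descendant of i; missing-parent terms contribute 0;
between-family entries are exactly 0 by construction. Inbreeding is fully
supported through the diagonal recursion. The mixed models use the additive
relationship matrix 2Φ so that σ²_g is on the additive-genetic scale.

*IBS* is mean allele sharing, s(i,j) = mean over markers of
1 − |g_i − g_j|/2, with pairwise deletion of missing genotypes and the
diagonal forced to exactly 1. The package's evaluation pipeline builds it
from 5,000 markers sampled (seeded) once per study from the variants with
MAF > 0.05. The IBS matrix is used unscaled as `K`.

*Principal components* are eigenvectors of the n×n covariance of the
normalised dosage matrix over variants with MAF > 10%: missing dosages are
mean-imputed, each variant centred and scaled by √(p̂(1−p̂)) with the shrunk
estimate p̂ = (1 + Σ dosages)/(2 + 2n). Eigenvector signs are fixed by
making the largest-magnitude entry positive; no outlier-removal iterations
are performed. Ten components enter the PC models by default.

## REML and the Wald test

With `V = σ²_g(K + δ I)`, δ = σ²_e/σ²_g, the restricted likelihood is
profiled over σ²_g to a function of δ alone. One spectral decomposition
`K = U Λ Uᵀ` per matrix (cached; `K` does not depend on the gene) turns
every likelihood evaluation into O(n·p²) diagonal-weighted least squares.
The optimum over δ is located on a log₁₀ δ grid over [−10, 10] with 101
points, then refined with bounded Brent search in every bracket around a
grid local maximum; the global maximiser is returned, flagged when it lies
at a grid end. Eigenvalues in [−1e−8, 0) are clipped to zero (finite-marker
IBS matrices can be numerically indefinite); anything smaller is rejected.
REML rather than ML avoids the downward bias of fixed-effect-ignorant
variance estimates; variance components are re-estimated per gene, with `X`
in the mean model.

The burden effect is tested by a GLS Wald statistic: b̂ = (FᵀV̂⁻¹F)⁻¹FᵀV̂⁻¹y
with its standard error from the corresponding diagonal, referred to a t
distribution with df = n − p (p = number of fixed-effect columns). The same
statistic is used for all six methods so that method comparisons are not
confounded by different test conventions; the df convention is recorded in
the output (`df` column). With `K = I` the procedure reduces exactly to the
OLS t-test (only the total variance is identified and it cancels from the
statistic), which is verified in the tests. p-values are two-sided and
floored at the smallest positive double.

## Synthetic family studies

The simulator emulates a multi-family sequencing study in which genotypes
are fixed and the trait is re-simulated per replicate.

* **Pedigrees.** Default: 8 independent families, 3 generations each. A
  family starts from one founder couple; every child of a non-final
  generation marries a new founder and each couple's offspring count is
  drawn uniformly from {6,…,10}. This yields ~700 subjects in total (the
  draw, not a fixed number) with rich within-family relatedness and zero
  between-family kinship.
* **Genotypes.** Gene dropping: founders draw two alleles i.i.d.
  Bernoulli(founder frequency); non-founders inherit one uniformly chosen
  allele per parent, independently across variants (no linkage
  disequilibrium). Defaults: 60 genes × 8 rare variants with founder MAF
  uniform on [0.0005, 0.009], plus 6,000 common markers with founder MAF
  uniform on [0.05, 0.5] for the IBS/PCA panel. An optional two-
  subpopulation Balding–Nichols split of the common-marker founder
  frequencies gives PCA genuine structure when wanted; it is off by
  default.
* **Traits.** y = Σ_c β_c X_c + u + e per replicate, with X_c the collapsed
  indicator of causal gene c (so simulated effects are exactly what the
  tested model estimates; a per-rare-allele mode exists to stress
  misspecification), u ~ N(0, σ²_g 2Φ), e ~ N(0, σ²_e I). Defaults:
  polygenic heritability 0.6 with σ²_e = 0.4 (total variance ≈ 1), 200
  replicates. σ²_g is derived from the heritability as σ²_e·h²/(1−h²).
* **Seeding.** A single study seed feeds per-component `SeedSequence`
  streams (pedigree, founder frequencies, gene dropping, traits), so any
  component is reproducible in isolation.

What the simulator does **not** emulate: linkage disequilibrium and
realistic exome site-frequency spectra, genotyping error and missingness,
non-Gaussian traits, shared-environment covariance, and ascertainment.
Passing tests therefore demonstrate correctness of the machinery and the
relative behaviour of the methods under the assumed generating model, not
performance guarantees on real exome family data.

## Evaluation harness

Null summaries (Q-Q curves, type-I error) use all non-causal genes across
replicates; truth-causal genes are always excluded from null denominators,
and rows whose fit failed or was untestable are excluded everywhere with
counts reported. Rejection is p ≤ α (inclusive). Q-Q plotting positions are
(i − 0.5)/m; the genomic inflation factor λ is the median implied 1-df χ²
statistic divided by the null χ² median (≈ 0.4549). ROC curves sweep the
p-value threshold over observed values and are truncated at FPR ≤ 0.1,
since only the low-false-positive regime matters for gene discovery; the
staircase partial area up to the truncation point is the scalar summary.
No multiple-testing correction is applied: the comparison is of raw
per-gene p-value distributions, not of significance declarations.

Evaluation problem sizes in the shipped tests and acceptance script — the
8-family ~700-subject default with 60 genes (null) or 60 + 10 causal genes
(power) and 200 replicates, i.e. ≥ 10,000 null tests per method — were
chosen to make binomial uncertainty on a 5% rate small (±0.005 at 99%
confidence) while a full REG/KIN/IBS scan completes in a few minutes on one
CPU. The causal effects, β from 0.15 to 0.5 trait units across ten genes,
span low to substantial power at α = 0.05.

## Numerical and design notes

* Fixed-design rank handling: a constant indicator, or an X collinear with
  the covariates, marks the gene untestable; rank-deficient PC columns are
  dropped with a warning.
* The δ grid bounds [1e−10, 1e10] cover effective heritabilities from ~0 to
  ~1; boundary solutions are returned (flagged), not errors, since null
  genes legitimately drive σ²_g to the boundary.
* The weighted RSS in the profiled likelihood is floored at 1e−300 to keep
  logs finite for numerically perfect fits.
* Between-family kinship is set to exact zero without computation (block
  structure), making 2Φ block diagonal.
* Study files round-trip bit-exactly: trait values are written with 17
  significant digits and parsed with round-trip float precision.
* Known limitation: with the trait generated on 2Φ, the IBS-adjusted model
  retains a small residual inflation (λ ≈ 1.07 at the default scale,
  type-I error ≈ 0.058 at α = 0.05) because expected IBS is not an affine
  function of kinship — it depends on the full IBD-state distribution
  (e.g. full sibs and parent–offspring pairs share φ = 0.25 but differ in
  two-allele IBD probability), so σ²_g·IBS cannot exactly reproduce the
  familial covariance. Pedigree kinship, when available, is the better
  adjustment for false-positive control; this is visible directly in the
  package's own evaluation output.
* Wald t with df = n − p is a large-sample convention; no small-sample
  (Satterthwaite/Kenward–Roger-style) df correction is implemented.
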