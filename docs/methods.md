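# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
matter when reading results.

## Clinical framing and data model

Gingivitis is graded as the number of dental-arch sextants with
bleeding on probing (BoP, an integer 0–6) and treated as a continuous
covariate; periodontitis is a binary classification. The universal
input is a taxon × sample matrix of raw (unnormalized) read counts
plus per-sample covariates: BoP, periodontitis, study site (4 levels),
nutritional intervention arm (IFA/MMN/LNS), HIV status, sequencing run
(4 levels), and optional demographics (age, BMI, education,
socioeconomic z-score, anemia, malaria). Missing optional fields are
kept as missing, never imputed; each modeling stage drops incomplete
records explicitly and reports how many.

The package carries a reference table of printed stratum marginals from
a 962-woman cross-sectional cohort (counts, mean age, HIV/anemia/
malaria prevalence, and site/arm/run splits per (BoP, periodontitis)
stratum). Expanding that table record-by-record reproduces the headline
descriptive statistics exactly: 822 women with gingivitis (85.4%), 307
with periodontitis (31.9%; the source table's own rounding prints
32.0%), 140 disease-free (14.6%), weighted mean age 25.4 years, and a
tie-corrected Spearman correlation of 0.44 between BoP and the
periodontitis indicator. A related single-table breakdown elsewhere in
the same source sums to 963 with 311 periodontitis cases; the
per-stratum demographic table (962/307) is treated as authoritative.

## Diversity

Per-sample richness (observed taxa) and Shannon index are averaged
over repeated random subsamples ("rarefactions") to a common depth.
Defaults: depth 5,000 reads, 100 iterations. Classical rarefaction
draws without replacement (multivariate hypergeometric); a
with-replacement (multinomial) mode is also provided because both
conventions circulate for this analysis and which one a given study
used is often ambiguous. Samples shallower than the depth are excluded
and reported, not extrapolated. Shannon uses natural logarithm (nats),
the common ecology default, with 0·ln 0 ≡ 0; the expected rarefied
richness has the closed form Σᵢ [1 − C(N−nᵢ, d)/C(N, d)], which the
tests use as an independent oracle.

Diversity is modeled against covariates by ordinary least squares with
backward stepwise elimination under AIC = n·ln(RSS/n) + 2k (k counts
all coefficients including the intercept). Categorical terms enter and
leave as whole dummy blocks; ties are broken by dropping the
later-listed term, for determinism. Note the statistical fact that AIC
eliminates a 1-degree-of-freedom pure-noise term only when its
likelihood-ratio statistic is below 2, i.e. with probability
P(χ²₁ < 2) ≈ 0.84 — not with near certainty; the tests assert that
rate, not a stricter one.

## Differential abundance

Counts for each taxon are modeled as negative binomial with a log
link and variance μ + αμ²:

    ln μ_ij = ln s_j + β₀ + β_bop·BoP_j + β_perio·perio_j + (adjustments)

with one joint model per taxon containing both focal covariates and all
adjustment terms (site, arm, HIV, run; treatment coding, reference =
lexicographically first level). s_j is the median-of-ratios size
factor: the median over reference taxa (those with no zero count) of
counts divided by the taxon's geometric mean, rescaled to geometric
mean 1; a pseudo-reference fallback (geometric mean over positive
counts) handles tables with no all-positive taxon. Coefficients are fit
by iteratively reweighted least squares (relative tolerance 1e-8, max
100 iterations) with standard errors from the Fisher information;
dispersion is the per-taxon profile-likelihood MLE, floored at 1e-8,
with a method-of-moments fallback on non-convergence. Inference is by
Wald z-tests with Benjamini–Hochberg correction across taxa at
q < 0.05.

This is deliberately the NB-GLM core only: no empirical-Bayes
dispersion shrinkage, no outlier replacement, no independent filtering.
Those refinements matter most at small n; the claims this package is
used to test concern model structure (joint BoP + periodontitis
fitting with confounder adjustment), for which per-taxon MLE dispersion
is adequate and simpler to audit.

Two behaviors of this model family are worth knowing. First,
fold-change hit lists are directional: the intersection report
("periodontitis-associated but not gingivitis-associated") intersects
taxa that are significantly *more* abundant with each covariate
(positive β), matching how such lists are defined in practice. Second,
when a sizeable fraction of taxa carries strong effects, median-of-
ratios size factors absorb part of the composition shift and unaffected
taxa acquire a small opposite-signed coefficient; with large n this can
reach significance. This is inherent to median-of-ratios normalization,
not to this implementation; the directional lists are robust to it.

## Compositional cooccurrence networks

Correlations between taxa cannot be read off relative abundances: the
constant-sum constraint biases naive Pearson correlations negative.
The package implements the SparCC-style basis estimator. Per inference
iteration (default 20), relative abundances are drawn from each
sample's Dirichlet(counts + 1) posterior (the add-one prior also
handles zeros); the log-ratio variation matrix t_ij = Var ln(x_i/x_j)
is reduced to basis variances ω²ᵢ via the sparse approximation
Σ_j t_ij ≈ |K_i|·ω²ᵢ + Σ_{j∈K_i} ω²_j, and basis correlations follow
as ρ_ij = (ω²ᵢ + ω²_j − t_ij)/(2ωᵢω_j). The most strongly correlated
pair above the exclusion threshold (default 0.1) is iteratively removed
from the approximation and the system re-solved, keeping every taxon
attached to at least two partners and capping exclusions at half the
number of pairs. The reported matrix is the componentwise median over
iterations, clamped to [−1, 1]. At D = 3 the linear system coincides
with the exact three-equation closed form (which forces ρ = 0 — the
system is solvable exactly under the zero-correlation assumption), so
the implementation accepts D ≥ 3 although meaningful inference needs
more taxa.

Edge significance comes from permutations that shuffle each taxon's
counts independently across samples (destroying inter-taxon dependence,
preserving marginals; default 100 permutations), with the add-one
two-sided pseudo p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm) so p is
never exactly 0. The strong-edge threshold is mean + 1.96 × SD
(population SD, for determinism) of the strict upper-triangle
correlations. Networks keep edges with ρ above the threshold and p
below the significance level (default 0.05; 0.01 is sometimes used for
display and is a flag), dropping and counting isolated nodes. Nodes
are ranked by unweighted shortest-path betweenness (Brandes); a
weighted variant uses 1/ρ as edge length. Layouts use
Fruchterman–Reingold with a fixed seed, for export only.

Stratum-level structure is compared on the *unadjusted* correlation
matrices (significance filtering would couple the comparison to
per-stratum sample sizes): the Mantel distance between two strata is
1 − Pearson r of the vectorized strict upper triangles, and strata are
clustered agglomeratively with complete linkage (the common default of
the tool family used for this analysis; average/single are available),
serialized as Newick with branch lengths from merge heights.

## Sequence matching

Phylotypes are matched to reference sequences by global
Needleman–Wunsch alignment with match +1, mismatch −1, linear gap −2;
N matches nothing. Identity is matches / alignment columns (gap
columns counted in the denominator; a matched-columns-only mode is a
flag, since published pipelines differ and rarely say which they used).
Among equally scoring alignments the summary maximizes matches and
then minimizes columns, which makes the reported identity well defined
and symmetric. Selection uses a strict inequality against the
threshold (default 98.5%, the species-level cutoff used to define oral
taxa). All-vs-all exact alignment is used — no heuristic prefilter —
which is fine at the scale of hundreds of ~370 nt representatives.

## Synthetic cohorts and what they do (not) show

The generator emulates the cohort the analysis targets:

- **Metadata**: BoP drawn from the reference stratum weights,
  periodontitis Bernoulli with the stratum-empirical P(perio | BoP),
  and site/arm/run/HIV/anemia/malaria/demographics drawn from the
  printed within-stratum distributions.
- **Library sizes**: lognormal, moment-matched to the printed
  13,565 ± 6,833 reads per sample.
- **Counts**: per-taxon lognormal base abundances (log-SD 2.0, a
  modeling choice — the source analysis reports no within-sample
  abundance distribution), log-linear covariate effects, optional
  per-taxon-per-sample log-normal noise (SD 0.5), and NB sampling with
  Var = μ + αμ² (default α = 0.3, a typical amplicon overdispersion).
  Per-sample relative intensities are closed (normalized) so the
  expected total equals the drawn library size; without this, latent
  and noise terms would inflate the realized mean ~10% above the
  calibration target. A consequence of closure is a small attenuation
  of planted fold changes when the affected taxon is a large share of
  the community; at 100+ taxa the attenuation is negligible.
- **Cooccurrence modules**: a per-sample standard-normal latent factor,
  scaled by a loading λ and added to the log mean of the module's taxa
  only in the module's active periodontitis stratum. With taxon log
  noise σ the induced latent correlation is λ²/(λ² + σ²) (0.8 at the
  defaults λ = 1, σ = 0.5), which is what the ground-truth basis
  correlation matrices record.

The generator does **not** simulate reads, chimeras, PCR/primer bias,
taxonomic misassignment, or the fine-grained phylotype decomposition
upstream of the count table. Passing recovery tests therefore
demonstrates that the statistical machinery is correct under its own
assumptions — NB counts with log-linear effects and factor-induced
cooccurrence — not that those assumptions hold for any particular real
data set. Headline counts from real cohorts (numbers of significant
taxa, specific network topologies, specific thresholds such as a 0.405
strong-edge cutoff) depend on the underlying raw data and are out of
reach of desk-scale synthesis by design.

## Pipeline, seeds and problem sizes

The pipeline runs load/generate → cohort summary → diversity →
differential abundance → phylotype selection (references = the
periodontitis-associated taxa's representatives) → per-stratum
networks → stratum clustering, writing TSV/JSON/GraphML/Newick outputs
and a manifest of SHA-256 hashes, seeds, parameters and versions. One
global seed spawns a fixed, independent substream per stage
(spawn-key = stage index), so toggling stages never shifts another
stage's stream and single stages re-run bit-identically. Stage defaults
are the analysis's stated values: depth 5,000 × 100 iterations,
q < 0.05, 20 inference iterations, 0.1 exclusion threshold, 100
permutations, 98.5% identity, complete linkage.

Problem sizes in the shipped tests and acceptance script are chosen to
finish in minutes on one CPU while keeping every statistical claim
testable: the full default synthetic pipeline (500 samples × 100 taxa)
completes in about three minutes; the acceptance script uses 20-taxon /
500-sample fixtures for correlation recovery (50 seeds), n = 800 with
100 taxa for the 1.45-fold NB-GLM recovery (12 seeds), and 30-taxa /
500-sample cohorts over 20 seeds for the stratum-clustering rate.

## Known limitations

- Per-taxon MLE dispersion is noisier than shrinkage estimators at
  small n; significance calls for very low-abundance taxa are
  correspondingly conservative or unstable.
- The SparCC-style estimator assumes a sparse true correlation
  structure; dense strong correlations violate the basis approximation.
- Betweenness rankings on thresholded networks are sensitive to the
  threshold when the correlation distribution is flat near the cutoff.
- The stepwise model treats rarefaction-averaged diversity as an
  observed response, ignoring its Monte Carlo error (small at 100
  iterations).
- Mantel distances compare strata on the shared taxon set only; taxa
  absent from any stratum are dropped from the comparison.
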