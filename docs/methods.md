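# Methods

This note records the models implemented, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Study design and data model

The pipeline assumes a crossed field design: 10 cultivars (5 resistant, 5
susceptible to nutrient deficiency) x 2 fertilization levels (control,
fertilized) x 3 replicates = 60 samples, giving the four derived groups
CS/CR/FS/FR.  Inputs are integer OTU count tables (taxa x samples, one per
kingdom), 7-rank taxonomy, a rooted phylogeny with branch lengths whose
tips cover the table's taxa, per-sample metadata (yield, t/ha scale, and
six soil variables: pH, AP, moisture, DOC, NH4-N, NO3-N), and a list of
putatively beneficial taxa keyed at a taxonomic rank (genus by default,
matched case-insensitively after stripping `g__`-style prefixes).

Count tables are canonically taxa-as-rows; orientation is auto-detected on
read (the larger dimension is taken as taxa) and can be forced.  Taxa are
retained when their total read count strictly exceeds 20; rarefaction is an
exact multivariate-hypergeometric subsample to a fixed depth, dropping (and
logging) under-depth samples rather than failing.

## Community assembly (betaMNTD / betaNTI / RC-Bray)

Abundance-weighted betaMNTD between communities A and B is
½[Σᵢ f_iA · min_{j∈B} d(i,j) + Σ_j f_jB · min_{i∈A} d(j,i)] on patristic
distances.  betaNTI is the z-score of the observed value against nulls that
shuffle tip labels across the whole tree ("taxa.labels" style); one shuffle
per replicate is shared by all pairs, and null moments are accumulated
running (sum and sum of squares), so memory is independent of the null
count.  Pairs whose null standard deviation is zero (e.g. star trees, where
the metric is permutation-invariant) are reported missing with a warning.
The Raup–Crick null rebuilds each sample at its observed richness, drawing
taxa with probability proportional to metacommunity occupancy and
abundances by a multinomial draw of the observed read total at
metacommunity relative abundances; RC = 2·[(#{null<obs} + ½#{null=obs})/n − ½]
∈ [−1, 1].  Null replicates are drawn once per sample and shared across
pairs — each pair's RC remains a valid quantile; only cross-pair dependence
is introduced.  Process assignment: betaNTI < −2 homogeneous selection,
> 2 heterogeneous selection; otherwise RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else drift.  Default pair set: pairs
within each cultivar class (the class contrast); `pair_mode` switches to
between-class or all pairs.  Group comparisons of betaNTI use t-tests on
pair values as is conventional, although pairs sharing a sample are not
independent — a caveat, not a correction we apply.

## Sloan neutral model

With N the mean read depth and d = 1/N (one read) as detection limit, the
predicted occurrence frequency of a taxon with mean relative abundance p is
1 − BetaCDF(d; N·m·p, N·m·(1−p)).  m is estimated by least squares on
observed frequencies over a 50-point log-grid on [10⁻⁶, 1] refined by
bounded scalar minimization (the objective can be flat near the bounds);
R² = 1 − SSE/SST may be negative for poor fits and is reported as-is.
Per-taxon 95% bands are Wilson intervals around the predicted frequency at
the observed sample count.

A known property worth stating: on data generated with multinomial read
sampling, detection is P(count ≥ 1) = 1 − E[(1−x)^N] (the exact
beta-binomial occupancy), which the sharp-threshold prediction above
systematically understates for rare taxa.  Fitting the threshold model to
such data overestimates m by roughly a quarter at N = 2000 (asymptotically
m̂ ≈ 0.126–0.129 for a true m = 0.10, across lognormal abundance shapes);
the recovery experiment in `analysis/04_neutral_model.py` shows the effect.
We keep the sharp-threshold convention because it is the standard fit and
report the bias rather than absorbing it.

## Niche breadth

Levins B = 1/Σ_j p_j² over a taxon's read shares across samples, ranging
from 1 (single-sample specialist) to the sample count.  The null preserves
every taxon total and every sample total exactly by sampling fixed-margin
contingency tables uniformly with Patefield's algorithm — the same null
space as fixed-fixed swap chains, sampled exactly and without convergence
diagnostics.  Two-sided 95% bands use empirical quantiles (linear
interpolation); taxa below the 2.5% quantile are specialists, above the
97.5% generalists, otherwise neutral.  Single-occurrence taxa are
classifiable (B = 1) but flagged, since their null is nearly degenerate.
Breadth is computed per cultivar-class table by default, matching the
network stratification.  Note that at high read depths the fixed-margin
null is very tight, so any genuine overdispersion (habitat tracking,
co-fluctuation) classifies a taxon as a specialist; specialist fractions
on real or realistically simulated data are therefore large.

## Co-occurrence networks

Per cultivar class, both kingdoms' tables are converted to relative
abundance, taxa below 20% prevalence are removed, and all-pairs Spearman
correlations (mid-ranks; p from the t approximation) are thresholded at
|ρ| > 0.6 and raw p < 0.01 (an optional Benjamini–Hochberg flag exists but
is off, matching the raw-p convention).  Isolated nodes are dropped.
Modules come from seeded Louvain on the unweighted graph; modules smaller
than 3 nodes go to a rest pool excluded from Zi standardisation.
Zi = (k_within − mean)/sd within the node's module (0 where sd = 0);
Pi = 1 − Σ_s (k_is/k_i)².  Roles: module hub Zi > 2.5, connector
Pi > 0.62, network hub both, else peripheral; keystones are all
non-peripheral nodes.  The keystone score √((Zi/2.5)² + (Pi/0.62)²) is a
package-defined proxy (a normalised distance past the role cutoffs) used
only for ranking and the score-vs-degree/betweenness regressions; it is
labelled a proxy in outputs.

## KBS screen and yield coupling

KBS = keystone ∩ specialist ∩ beneficial, computed as an exact set
intersection per cultivar class, bacteria-only by default.  Beneficial
matching is at genus rank; the package ships no curated database — the
list is user-supplied input (the synthetic bundle emits one).  KBS
abundance is the summed relative abundance on the rarefied table;
composition is normalised within the KBS set at class rank.  Yield
coupling is the per-class Pearson correlation of per-sample KBS abundance
with yield.

## Path analysis

Observed-variable recursive path model x = Bx + ζ with free edge
coefficients, free variances (residual for endogenous variables) and free
covariances among exogenous variables; Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ and
F_ML = log|Σ| + tr(SΣ⁻¹) − log|S| − p.  For this model class the
equation-by-equation OLS solution is the ML optimum, and it is used as the
starting point; L-BFGS-B with 10 seeded random restarts polishes it.  The
discrepancy is invariant to per-variable rescaling, so the fit runs on
unit-variance columns for conditioning and maps coefficients back.
χ² = (n−1)·F at the optimum; GFI = 1 − tr[(Σ⁻¹S−I)²]/tr[(Σ⁻¹S)²];
RMSEA = √(max((χ²−df)/(df(n−1)), 0)), zero when df = 0.  Residual
variances are bounded below at 10⁻⁸ (a Heywood case triggers a warning at
the bound).  Standard errors come from the numerical Hessian of F
(cov = 2/(n−1)·H⁻¹), p-values from z = estimate/SE.  Standardized
coefficients use model-implied standard deviations; total effects are
(I−B)⁻¹ − I on the standardized matrix.  The default study model is
soil PC1 → {community PCoA1, yield}, community PCoA1 → {keystone
abundance, yield}, keystone → KBS abundance, KBS → yield (df = 4 at five
variables); the edge list is user-overridable.  Soil PC1 is the first
principal axis of z-scored soil variables (equivalently PCoA axis 1 of
Euclidean distances on them), sign-oriented to correlate positively with
DOC for determinism.  If the keystone and KBS sets coincide, the two
abundance columns are identical and the model is not estimable; the
pipeline reports the skip instead of fitting.

## Synthetic study generator

Defaults are the study conditions at desk scale: 60 samples as in the
field design; 400 taxa, 2000 reads/sample and migration rate m = 0.10 for
the neutral community (the scale at which the recovery experiments are
defined); lognormal(0, 2) metacommunity abundances.  Four generators plant
the signals:

- **Neutral**: per-sample composition ~ Dirichlet(N·m·p), reads
  multinomial — the stationary approximation of Sloan's immigration
  birth–death process, so the occupancy–abundance relationship the NCM
  fits is exactly the generated one (up to the read-sampling effect noted
  above).
- **Selected**: habitat optima evolve by Brownian motion on a unit-depth
  Yule tree (so selection is phylogenetically autocorrelated — the signal
  betaNTI detects); resistant samples draw from environment +1,
  susceptible from −1, with weights p·exp(−s(h−e)²).  s = 0 reduces
  bit-for-bit to the neutral generator at the same seed; the "strong
  selection" scenario uses s = 8, at which the weight ratio between clades
  separated by two trait standard deviations is e³² — effectively
  exclusive habitat use, an unambiguous planted signal.
- **Correlated**: one latent factor per module; hubs load ≈ 1 on their
  module's factor and regular members load `within_module_corr` (default
  0.75), so hub–member correlation is the loading and member–member its
  square.  An all-to-all equicorrelation at 0.8 with stronger hub rows is
  not positive definite and would give members the same degree as hubs, so
  the factor parameterisation is used; it makes planted modules
  hub-centred stars whose hubs are unambiguous in degree and Zi.  Module
  taxa share 25% of the metacommunity so their ranks resolve at realistic
  depths without dominating the composition; background taxa carry mild
  independent latent noise (sd 0.3).  Network-stage scenarios use 20000
  reads/sample, the order of real rarefaction depths, because rank
  correlations need count resolution.  One module can be
  habitat-restricted (its factor boosted by ±2 in 8 resistant samples),
  making its taxa specialists while preserving co-fluctuation.
- **Metadata/yield**: soil from a fixed multivariate normal with mild
  nutrient-pool correlations; yield = 8 + 2·(b_soil·z(PC1) +
  b_kbs(class)·z(KBS) + noise) t/ha, with b_kbs = +0.8 for resistant and
  −0.8 for susceptible cultivars, b_soil = 0.5, noise sd 0.5 — within-class
  standardized effects chosen to be detectable at n = 30/class, as the
  reported field correlations are.

The full bundle uses the correlated generator for bacteria (restricted
module 0; hubs of modules 0 and 1 carry beneficial genera — the planted
KBS) and an independent neutral community for fungi (so the fungal NCM fit
has a known m and cross-kingdom edges exist without further structure).
The beneficial list covers the planted KBS genera plus a random 10% of
bacterial genera.

What the generator does **not** emulate: compositional coupling between
kingdoms, sequencing error and chimeras, taxonomy assignment uncertainty,
spatial or temporal autocorrelation between replicates, and realistic SAD
tails at the full 10³–10⁴-taxon scale.  Passing tests therefore show that
the inference chain recovers planted structure of the stated kinds at the
stated sizes — not that any particular field system behaves this way.

## Null counts, problem sizes, determinism

Reference null/permutation counts are 999 (assembly, PERMANOVA) and 1000
(niche).  The recovery experiments and the acceptance script run assembly
nulls at 199, which leaves z-scores and quantiles amply resolved at these
effect sizes; the end-to-end pipeline check runs at 49–199 nulls with a
150–400-taxon community.  Every stochastic operation takes an explicit
seed; the pipeline derives per-stage seeds deterministically from one
master seed (CRC-salted SeedSequence), so repeated runs are bit-identical.
The realized KBS set of a pipeline run is whatever passes the screen on
that seed's data — typically one or two taxa including a planted hub, and
occasionally empty in the susceptible class, in which case downstream
steps report the skip honestly.

## Known limitations

- The NCM migration-rate estimate inherits the ~25–30% upward bias on
  read-sampled data described above.
- The Zi > 2.5 module-hub cutoff is conservative on dense modules: with
  several equally connected hubs the within-module degree spread inflates
  and no node clears the cutoff, so planted hubs can be top-decile in
  degree yet peripheral by role.
- PERMANOVA permutes labels freely; the block design (cultivar,
  fertilization) is not used as strata by default.
- LSD letters use unadjusted pairwise comparisons, by definition of the
  procedure.
- Negative PCoA eigenvalues are dropped (no Lingoes/Cailliez correction);
  the discarded mass is logged.
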