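# Methods

This note records the models, estimators and design choices behind
`gmrc-screen`, in the order the pipeline applies them.

## Abundance scale

All profile arithmetic (group profiles, effect profiles, the remodeling
score) runs on log₁₀ pseudocounted relative abundances,

    m_{t,s} = log10 (x_{t,s} + c0) / (N_s + c0 T),   c0 = 0.5 by default,

where N_s is the library size and T the number of taxa.  The pseudocounted
proportions sum to one per sample exactly, so the transform is a proper
composition before the log.  The log scale is deliberate: 16S relative
abundances span four or more orders of magnitude, and on a linear scale the
single most abundant genus would dominate any distance-based score.  A
linear-relative mode is not offered at the transform level, but
`score_compound` accepts any profile series, so callers preferring linear
abundances can pass them directly.  Replicates are aggregated by the
arithmetic mean of the transformed values (mean of logs, not log of means),
which keeps the score additive across genera.

## Differential abundance

The two-group test is a deliberately closed-form variant of the standard
negative-binomial machinery for count tables:

* **Size factors** — median-of-ratios over the taxa observed in every
  sample, rescaled to geometric mean one; when no taxon is ubiquitous, the
  per-taxon geometric means fall back to positive counts only.
* **Dispersion** — per-taxon method of moments, solving
  E[RSS] = Σ_G (n_G − 1)(μ_G + α μ_G²) for α from the pooled within-group
  residuals, floored at 1e-8.  No shrinkage toward a mean–dispersion trend,
  no outlier refitting, no independent filtering: every number is a
  documented function of the counts, which is what makes the estimator
  testable by simulation.
* **Wald test** — β = log2((μ̂_B + ½)/(μ̂_A + ½)) on normalized group means;
  the ½ pseudocount keeps β finite for all-zero groups at the cost of exact
  invariance to global rescaling (the shift is O(0.5/mean count)).  The
  standard error follows from the delta method under Var = μ + αμ²; p-values
  are two-sided normal, corrected by step-up Benjamini–Hochberg.

Calibration, measured by the test-suite on synthetic nulls (2,000 taxa,
n = 5/group, dispersion 0.05): the empirical type-I error at p < 0.05 sits
near 0.04 — slightly conservative, as expected when a moment dispersion
estimate is floored and counts are discrete.  A planted log2 fold change of
2 is recovered with bias well under 0.1 at n = 6/group.  The recovery check
plants effects direction-balanced (equal numbers of up- and down-shifted
taxa): planting a large one-directional block shifts the median-of-ratios
size factors — a compositional artefact, not an estimator defect — and the
balanced design isolates the property under test.

**Key genera.** A genus is selected when q < 0.05 in *both* the in vivo
(M vs N) and in vitro (MD vs ND) contrasts with agreeing fold-change signs.
A relaxed mode (`require="vivo"`) demands significance only in vivo and sign
agreement in vitro, for screens whose cultured replication is too shallow to
reach significance; the strict both-significant rule is the default because
the panel defines the scoring statistic and false panel members dilute every
downstream score.

## Remodeling score

For key genus g, Δ_g(c) = |μ_MD(g) − μ_ND(g)| − |μ_c(g) − μ_ND(g)|, summed
into S(c).  The signed form is primary: movement toward the healthy
reference counts positive, away (including overshoot past ND) negative, and
the untreated baseline scores exactly zero.  An `absolute` mode summing
|Δ_g| is provided for sensitivity analyses, since "distance moved" is
occasionally read as an unsigned quantity; it rewards any displacement and
is not recommended as a ranking statistic.  Genera are unweighted — no
published weighting exists for this statistic — but the per-genus Δ vector
is returned so callers can reweight.

Strictness conventions for the growth rules mirror their verbal definitions:
MIC is the lowest concentration with inhibition *strictly above* 90% (an
inhibition of exactly 0.90 does not qualify), and the mixed-community
viability filter excludes concentrations whose ΔOD₆₀₀ reduction is strictly
above 80%.

## Clustering and cocktail design

Compound effect profiles e_c = μ_c − μ_MD are compared by Pearson
correlation and clustered with average linkage on d = 1 − r, cut to k = 8
clusters by default.  Average linkage is the common default for correlation
heat maps; complete and single linkage are available.  Cluster labels are
renumbered by first appearance in the input order so the labeling is
canonical.  Each cluster's argmax-score compound represents it in the
cocktail; clusters whose best score falls below θ = 0 are dropped — a
representative must at least improve on the untreated model.  Effects are
computed relative to MD rather than on raw profiles so that what clusters is
what the compound *does*, not what the community already was; a raw-profile
clustering can be had by passing the profiles themselves.

## Alpha/beta diversity conventions

Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even
when no doubletons exist; Shannon is in nats.  Rarefaction is the analytic
expectation E[S_n] = Σ_t [1 − C(N−x_t, n)/C(N, n)].  Bray–Curtis runs on
relative abundances.  PCoA (Gower centering, eigendecomposition) drops
negative eigenvalues and reports their count rather than applying a
Lingoes/Cailliez correction.  ANOSIM ranks all pairwise distances,
R = (r̄_B − r̄_W)/(n(n−1)/4); the permutation null enumerates all distinct
labelings exhaustively whenever there are no more than `n_perm` of them
(p = #{R* ≥ R}/#labelings, which includes the observed labeling), otherwise
it uses seeded random shuffles with the +1/+1 rule so p can never be zero.

## Synthetic study generator

The generator emits the full screening design — N/M at n = 5, ND/MD and 51
compound well groups at n = 3 — over 120 genera with planted, recoverable
ground truth.  What it emulates, and how:

* **Baseline community** — genus log-abundances ~ Normal(0, 1.5²) through a
  softmax; phyla assigned with gut-like probabilities (Firmicutes 0.45,
  Bacteroidota 0.30, Proteobacteria 0.15, Actinobacteriota 0.07, other
  0.03).  Seven literature-named genera of inflammatory dysbiosis are always
  present with their reported directions (*Enterobacter*,
  *Escherichia-Shigella*, *Bacteroides*, *Parabacteroides*, *Enterococcus*
  up; *Lactobacillus*, *Bifidobacterium* down).
* **Disease panel** — 17 genera (the named seven plus ten drawn from the
  above-median-abundance pool) with |log2FC| ~ Uniform(1, 3).  Planting the
  panel in the detectable abundance range reflects how such panels arise in
  practice — differential-abundance screens cannot nominate genera they
  cannot see — and makes the planted truth recoverable at the study's
  replicate depth.
* **Culture effect** — a fixed fraction (62/80) of taxa survives culturing;
  the dropped taxa are drawn with probability ∝ exp(−baseline), so rare taxa
  are preferentially lost.  The disease panel is exempt from drop-out: key
  genera are by definition genera observed in both designs, so a panel
  member invisible in vitro would make the selection rule unevaluable rather
  than wrong.
* **Compounds** — 51 compounds in 8 families.  A family shares a target set
  (60–90% of the disease panel) and a shared off-target log-signature
  (σ = 0.4), the mode-of-action fingerprint that makes family members
  resemble each other even when they restore little; each compound
  additionally gets independent off-target noise (σ = 0.05 by default) and a
  restoration fraction ρ: its mean log profile interpolates fraction ρ of
  the way from the MD profile toward ND on its targets.  ρ may be negative,
  modeling a compound that pushes its targets *further* from health — the
  analogue of the screen's excluded low-scoring cluster representative.
  Within each family the planted ρ values form a shuffled ladder whose lead
  compound is separated from the runner-up by 40% of the family's ρ range.
  This separation is an identifiability choice, fixed from a power analysis
  of the score's replicate noise at the study design (n = 3 wells, ~30k
  reads, dispersion 0.05): with i.i.d.-uniform ρ, near-ties between the top
  two family members occur frequently, and no method can then name the best
  member from three wells — the question, not the answer, would be
  ill-posed.
* **Counts** — NB with Var = μ + αμ² (α = 0.05, shared across taxa; per-taxon
  dispersion is an estimator-side concern) on log-normal library sizes
  (ln N ~ Normal(ln 30000, 0.3)).
* **Growth curves** — per-compound steep Hill inhibition with known IC₅₀;
  a fifth of compounds have no effect on the tested strains.  The true MIC
  is read off the noiseless endpoint-inhibition curve, so the rule-based MIC
  caller can be validated exactly at zero noise.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: compositional zero inflation beyond NB
sampling, per-taxon dispersion heterogeneity, taxonomic mis-assignment,
cross-well contamination, batch effects between the in vivo and in vitro
arms, and any chemistry-driven structure in compound families beyond the
shared target set and signature.  Recovery rates measured on these
simulations are upper bounds for field performance.

## Determinism and numerics

Every stochastic step flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical tables, and
the pipeline report contains no timestamps, so identical inputs reproduce it
byte-for-byte.  Floats in the report are rounded to 10 decimals purely to keep the JSON
compact; statistics are computed at full precision.  Degenerate inputs fail loudly with the
offending taxon/sample/stage named: empty tables, zero library sizes,
zero-variance effect profiles, missing canonical groups.  Ties are broken
lexicographically throughout (top-genus ranking, score ranking,
representative selection), making every ranking reproducible.

## Problem sizes used by the test suite

Unit and acceptance tests run the generator at its default size (120 genera,
169 samples) or smaller; the calibration checks use 2,000-taxon nulls and
500-taxon effect-recovery panels, and the recovery checks average 10 seeded
replicates.  The complete suite and the acceptance script each finish in
well under a minute on one core.
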