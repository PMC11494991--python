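# gmrc-screen

Analysis toolkit for **in vitro screening of gut-microbiome-remodeling
compounds (GMRCs)**: given 16S count tables from a screen in which a
dysbiotic gut community is incubated with candidate compounds, the package
quantifies how far each compound shifts the community back toward a healthy
reference, clusters compounds by the similarity of their effects, and
assembles a cocktail from the best representative of each cluster.

## The experimental design it analyses

Four canonical sample groups anchor the analysis:

| group | meaning |
|-------|---------|
| `N`   | uncultured control community (healthy donor material) |
| `M`   | uncultured model community (dysbiotic, e.g. from systemic inflammation) |
| `ND`  | cultured control — the *healthy reference* for scoring |
| `MD`  | cultured model — the *untreated dysbiotic baseline* |

plus one treatment-well group (typically n = 3) per compound or cocktail.

## The statistics at its core

**Key genera.** A genus *g* joins the scoring panel when a negative-binomial
Wald test (median-of-ratios size factors, method-of-moments dispersion under
Var = μ + αμ², Benjamini–Hochberg correction) calls it significantly shifted
with the *same sign* in both the in vivo contrast (M vs N) and the in vitro
contrast (MD vs ND), at adjusted *P* < 0.05.

**Remodeling score.** With μ_G(g) the replicate-mean log₁₀ relative
abundance of genus *g* in group *G* (pseudocount c₀ = 0.5), each compound
*c* is scored over the key-genus panel *K*:

    Δ_g(c) = |μ_MD(g) − μ_ND(g)| − |μ_c(g) − μ_ND(g)|
    S(c)   = Σ_{g∈K} Δ_g(c)

A genus moved closer to the healthy reference contributes positively, a
genus pushed away (including overshoot past ND) negatively; S(MD) = 0 and
S ≤ S_max = Σ_g |μ_MD(g) − μ_ND(g)|, attained on exact restoration.

**Cocktail design.** Compounds are clustered by average-linkage hierarchical
clustering of d(c, c′) = 1 − Pearson r between effect profiles
e_c = μ_c − μ_MD (k = 8 by default). Each cluster contributes its top-scoring
compound to the cocktail unless its best score falls below a threshold θ
(default 0: a representative must at least improve on the untreated model).

Supporting statistics — Chao1 and Shannon alpha diversity, analytic
rarefaction, Bray–Curtis dissimilarity, PCoA, ANOSIM, the
Firmicutes/Bacteroidetes ratio — plus the growth-based screening rules (MIC
= lowest concentration inhibiting >90% of growth; exclusion of
concentrations causing >80% OD₆₀₀ reduction; cocktail alpha-diversity
exclusion) are included, as is a seeded synthetic study generator with
planted ground truth for every pipeline stage.

## Worked example

```python
from gmrc_screen import (
    SimulationConfig, simulate_study, run_screening_pipeline, PipelineParams,
)

table, tax, meta, truth = simulate_study(SimulationConfig(seed=7))
report = run_screening_pipeline(table, tax, meta, PipelineParams(seed=7))

print(f"samples: {report['n_samples']}, genera: {report['n_taxa_rank']}, "
      f"treatments: {report['n_treatments']}")
print(f"ANOSIM over N/M/ND/MD: R = {report['anosim']['R']:.3f}, "
      f"p = {report['anosim']['p']:.3f}")
print(f"key genera selected: {len(report['key_genera'])}")
for rec in report["scores"][:3]:
    print(f"  {rec['compound_id']}  S = {rec['score']:.2f}  "
          f"(S_max = {rec['s_max']:.2f})")
print("cocktail:", [m["compound_id"] for m in report["cocktail"]["members"]])
```

prints

```
samples: 169, genera: 120, treatments: 51
ANOSIM over N/M/ND/MD: R = 0.831, p = 0.001
key genera selected: 17
  C26  S = 7.20  (S_max = 10.22)
  C44  S = 7.19  (S_max = 10.22)
  C45  S = 6.47  (S_max = 10.22)
cocktail: ['C26', 'C44', 'C45', 'C03', 'C09', 'C39', 'C16', 'C14']
```

The synthetic study plants 169 wells (N/M at n = 5, ND/MD and 51 compound
wells at n = 3) over 120 genera with a 17-genus disease panel; the pipeline
recovers all 17 as key genera, ANOSIM confirms the four canonical groups are
strongly separated (R = 0.83), the best compounds restore roughly 70% of the
attainable score, and the cocktail holds one representative per compound
cluster.

The same workflow is available from the shell:

```sh
gmrc-screen simulate --seed 7 --out-dir study/
gmrc-screen run --table study/feature_table.tsv --taxonomy study/taxonomy.tsv \
    --metadata study/metadata.tsv --out-dir results/ --seed 7
```

with subcommands `alpha`, `beta`, `ordinate`, `anosim`, `diffabund`,
`key-genera`, `score`, `mic`, `cluster` and `cocktail` for the individual
stages.

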