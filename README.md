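# syntopy

Quantifying regional Batesian color and size mimicry in ants from
hierarchical RGB morphometrics.

## The problem

A palatable mimic ant (*Camponotus lateralis*) co-occurs across the
Mediterranean with three chemically defended *Crematogaster* model
species that differ regionally in coloration: *Cr. scutellaris*
(reddish head, blackish body), *Cr. schmidti* (reddish head, mesosoma
and petiole) and *Cr. ionia* (homogeneously dark).  If the mimic tracks
its local model, its phenotype should be closer to the *syntopic* model
(the one at its own collection site) than to *allotopic* models from
other sites.  This package implements the full analysis pipeline for
that question, for workers measured as 18 mean RGB channel intensities
on six body parts (head, pronotum, mesonotum, propodeum, petiole,
gaster) plus cephalic length/width (CL, CW, µm), sampled from nests
within collection sites.

It is aimed at researchers doing multivariate morphometrics of mimicry
or color polymorphism: the statistical machinery is generic for any
model/mimic system measured on a shared trait battery with a nested
(nest-within-site) sampling design.

## The methods

All color statistics run on square-rooted channels (raw RGB is
right-skewed).  Cephalic size is CS = (CL + CW)/2.

1. **Trait comparisons.**  Per body part, the three sqrt channels are
   reduced to PC1 (covariance PCA).  Each PC1 and CS is modelled as
   y = µ + β_group + u_site + v_nest(site) + ε, a Gaussian mixed model
   with nest nested in site, fitted by REML; pairwise group contrasts
   are Wald z tests with Holm step-down control at a global α = 0.05.
2. **Syntopy statistic.**  Nest means of the 18 sqrt channels are
   pooled and reduced to the leading principal components reaching 80 %
   cumulative variance.  For each site s, the syntopic value is the mean
   Euclidean distance between every local mimic nest and every local
   model nest; the allotopic value is the unweighted mean over the 17
   foreign sites t of the mean distance from s's mimic nests to t's
   model nests.  The 18 site pairs enter a one-sided paired t-test
   (syntopic < allotopic).  Size runs identically with |ΔCS|.
3. **Classification.**  A stepwise Wilks'-lambda LDA (F-to-enter 3.84,
   F-to-remove 2.71, equal priors) is calibrated on model-species
   workers only, evaluated by leave-one-out cross-validation with the
   selected variable set held fixed, and mimic workers are then
   allocated as wild cards; "correct" means allocation to the syntopic
   model species.
4. **Reporting.**  Per-site mean color cards on the raw RGB scale
   (mesosoma = mean of pronotum/mesonotum/propodeum), rendered as an
   SVG strip; PCA scatter tables with 95 % (χ²₂) confidence ellipses;
   means ± SD summary tables.

A hierarchical synthetic generator stands in for specimen data: traits
are Gaussian on the analysis scale with site, nest and individual
variance layers, and the mimic archetype at a site blends a mimic
baseline toward the syntopic model archetype with mimicry accuracy
λ ∈ [0, 1] (λ_size for CS), so the syntopy statistic is testable
against known ground truth.  See `docs/methods.md` for the model and
parameter details.

## Worked example

```python
from syntopy import (SyntheticConfig, generate_dataset,
                     color_similarity, run_lda)

cfg = SyntheticConfig(seed=1)           # 18 sites, lambda_color = 0.9
specimens, truth = generate_dataset(cfg)
color, size = color_similarity(specimens)
print(f"color distance syntopic {color.syntopic_mean:.2f} "
      f"allotopic {color.allotopic_mean:.2f} p={color.p:.2e}")
res = run_lda(specimens, cfg.registry)
print(res["confusion"].round(1))
```

prints

```
color distance syntopic 0.92 allotopic 6.48 p=3.47e-15
             scutellaris  schmidti  ionia
true_class
scutellaris        100.0       0.0    0.0
schmidti             0.0     100.0    0.0
ionia                0.0       0.0  100.0
```

With λ = 0.9 the mimic nests sit far closer to their syntopic models
(mean PC-space distance 0.92) than to allotopic ones (6.48), and the
paired one-sided t-test over the 18 sites is decisive.  The clean
leave-one-out diagonal says the three synthetic model species are
fully separable from color alone — the calibration side of the
wild-card allocation.  The same size comparison (74.3 µm syntopic vs
69.4 µm allotopic, p = 0.74) shows no size mimicry at the default
λ_size = 0.3: size noise between nests dominates.

The same stages are available from the shell:

```sh
syntopy simulate --seed 1 --out data/
syntopy all --input data/specimens.csv --registry data/registry.csv --out run/
```

`run/` then holds the contrast tables, per-site distance tables, the
stepwise trace, LOO confusion and wild-card allocation tables, color
cards (CSV + SVG) and a manifest with input checksums and settings.

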