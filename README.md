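# habdiv

Incidence-based Hill-number diversity analysis for multi-habitat benthic
surveys, built around the question of whether structurally complex algal
habitats (e.g. fleshy red-algae mats) harbour more sessile-invertebrate
diversity than neighbouring seagrass meadows.

Surveys of sessile invertebrates typically yield a phenotype × sampling-unit
table per habitat (mat frames, seagrass leaves, rhizome specimens), with
unequal effort across habitats and many rare phenotypes. `habdiv` implements
the estimation chain that makes such habitats comparable:

1. **Sample-completeness profiles** — the detected share of order-*q*
   diversity, anchored at `C₀ = S_obs / Ŝ_Chao2` (richness completeness) and
   `C₁ = Ĉ` (sample coverage), with bootstrap confidence bands.
2. **Rarefaction/extrapolation** — size-based curves of the Hill number
   ```
   qD = (Σᵢ λᵢ^q)^(1/(1−q)),   λᵢ = πᵢ / Σⱼ πⱼ
   ```
   (*q* = 0 richness, *q* = 1 exponential Shannon, *q* = 2 inverse Simpson;
   πᵢ the per-unit detection probability of phenotype *i*), interpolated
   exactly below the observed effort *T* and extrapolated up to 2*T* with
   Chao2-anchored estimators.
3. **Coverage standardisation at C_max** — diversities compared at the
   lowest coverage any habitat reaches when extrapolated to double its
   effort, instead of at raw (incomparable) sample sizes.
4. **Evenness** — normalised-slope evenness profiles
   `E(q) = (qD − 1)/(0D − 1)` and Pielou's `J = ln 1D / ln 0D`, both at
   C_max, plus the classical base-2 Shannon / Simpson-concentration /
   evenness indices used for cross-study comparison tables.

Around the estimation core: reading/writing count tables, abundance
normalisation to habitat-m² and seafloor-m² via surface-area **enlargement
factors** (wet-weight-calibrated thallus area for algal mats, geometric
leaf/rhizome models for seagrass, ball-chain + Heron's formula for bare
rock), Bray–Curtis **PERMANOVA** with pairwise tests and a
multivariate-dispersion check, **nMDS** ordination, Venn partitions of
phenotype sets, and a synthetic-assemblage generator with analytically known
richness, Hill numbers and coverage for validation.

## Worked example

```python
import numpy as np
from habdiv import (IncidenceFrequencies, empirical_hill, chao2_richness,
                    sample_coverage, estimate_at_coverage, coverage_at_size)

# 4 sampling units; four phenotypes seen in 4, 2, 1 and 1 units
f = IncidenceFrequencies(T=4, Q=np.array([4, 2, 1, 1]))
print(f"observed richness      S_obs = {f.S_obs}")
print(f"Chao2 estimate         0D    = {chao2_richness(f).value:.3f}")
print(f"sample coverage        C     = {sample_coverage(f):.4f}")
print(f"exp. Shannon           1D    = {empirical_hill(f, 1.0).value:.3f}")
print(f"coverage at 2T               = {coverage_at_size(f, 8):.4f}")
print(f"richness at C = 0.90         = {estimate_at_coverage(f, 0.0, 0.90).estimate:.3f}")
```

prints

```
observed richness      S_obs = 4
Chao2 estimate         0D    = 5.500
sample coverage        C     = 0.8125
exp. Shannon           1D    = 3.364
coverage at 2T               = 0.9407
richness at C = 0.90         = 4.700
```

Two singletons among four phenotypes signal undetected diversity: Chao2
raises the richness floor from 4 to 5.5, and only 81% of the incidence mass
is covered. Standardising to a common coverage of 0.90 (between the observed
coverage and the doubled-effort coverage 0.94) yields a partially
extrapolated richness of 4.7.

The same workflow runs end to end from the shell on the built-in synthetic
three-habitat study (16 mat frames, 29 leaves, 20 rhizomes; a 90-phenotype
shared core):

```
habdiv diversity  --seed 1 --out results/demo     # completeness, R/E, C_max, evenness CSVs
habdiv composition --seed 1 --out results/demo    # Bray-Curtis, PERMANOVA, nMDS, Venn
```

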