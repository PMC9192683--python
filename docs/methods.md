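# Methods

## Sampling model

All diversity estimation in `habdiv` is incidence-based. Each habitat is a
pool of phenotypes; phenotype *i* has an unknown per-unit detection
probability πᵢ ∈ (0, 1]; the T sampling units (mat frames, single leaves,
rhizome specimens) are independent, so the incidence frequency
Qᵢ ~ Binomial(T, πᵢ). Diversity of order q is the Hill number of the
normalised detection rates λᵢ = πᵢ/Σπⱼ. Working on incidences rather than
individual counts is deliberate: abundances are normalised to area before
analysis, which destroys the singleton structure that undetected-diversity
corrections rely on, whereas unit-level presence/absence retains it.

Sufficient statistics: T, the vector Q of positive incidence frequencies,
singletons Q1, doubletons Q2, total incidences U = ΣQᵢ, observed richness
S_obs. All-zero rows of a count table are retained in the incidence matrix
(and logged) but never enter Q.

The seagrass "holobiont" is derived, not stored: leaf and rhizome units are
concatenated as independent sampling units (T = T_leaves + T_rhizomes,
phenotype set = union). This reproduces the T-dependent incidence statistics
without inventing leaf–rhizome pairings, which the sampling design does not
define.

## Estimators

**Empirical Hill numbers** plug λ̂ᵢ = Qᵢ/U into
qD = (Σλ^q)^{1/(1−q)}, with the entropy limit at q = 1 (used within
|q − 1| < 1e−9).

**Chao2 richness** (q = 0 asymptote):
Ŝ = S_obs + ((T−1)/T)·Q1²/(2Q2) when Q2 > 0, the bias-corrected
Q1(Q1−1)/2 form when Q2 = 0, and S_obs when Q1 = 0. It is a lower bound;
its singleton-driven correction is the common kernel of every other
estimator below.

**Sample coverage** Ĉ = 1 − (Q1/U)·A with
A = (T−1)Q1/((T−1)Q1 + 2Q2); when Q2 = 0 the standard modification
A = (T−1)(Q1−1)/((T−1)(Q1−1) + 2) keeps the estimator defined at Q1 = 1.

**Asymptotic Shannon** (q = 1) is the incidence analogue of the
frequency-count entropy estimator: on the entropy scale,
Σ(Qᵢ/U)(ψ(T) − ψ(Qᵢ)) plus a singleton correction, plus ln(U/T).
The correction (1−A)^{1−T}[−ln A − Σ_{r<T}(1−A)^r/r] is algebraically
rewritten as the tail series Σ_{s≥1}(1−A)^s/(T−1+s) and summed directly:
the closed form suffers catastrophic cancellation (and overflow of the
(1−A)^{1−T} factor) as A → 1, i.e. exactly in the common
few-doubletons regime. **Asymptotic Simpson** (q = 2) has the closed form
(U/T)²·T(T−1)/ΣQᵢ(Qᵢ−1); when every phenotype is a singleton the asymptote
is not estimable and the (conservative) empirical value is returned with a
warning. **General q** uses the series estimator of Σπᵢ^q built from the
q-independent kernel δₖ = Σᵢ(Qᵢ/T)·C(T−Qᵢ,k)/C(T−1,k) (computed once per
q-grid) with signed binomial coefficients C(q−1,k)(−1)^k; its singleton
correction is likewise summed as a tail series via the coefficient
recurrence cᵣ = cᵣ₋₁(r−q)/r. Both q = 1 and q = 2 asymptotic estimates
dominate their empirical counterparts (provable from ψ-function and
Cauchy–Schwarz-type inequalities), matching the intuition that undetected
phenotypes can only add diversity.

**Sample-completeness profiles** C_q (detected share of order-q diversity)
are computed from the reconstructed assemblage (below): detected phenotypes
with shrunken probabilities p̂ᵢ, plus a fractional weight Q̂0 = Ŝ − S_obs of
undetected phenotypes sharing the coverage deficit. This construction makes
the two verifiable anchor identities exact by design — C₀ = S_obs/Ŝ and
C₁ = Ĉ to machine precision — and interpolates smoothly in between; no
formula for intermediate q is independently verifiable, so the profile
should be read as model-based interpolation between those anchors.

## Rarefaction, extrapolation, coverage standardisation

*Rarefied richness* is the exact hypergeometric mean
S(t) = S_obs − ΣC(T−Qᵢ,t)/C(T,t); for general q the expected
incidence-frequency counts Q_k(t) = ΣᵢC(Qᵢ,k)C(T−Qᵢ,t−k)/C(T,t) are plugged
into the Hill formula with U(t) = tU/T. At t = T both reduce to the
empirical values exactly (the curves' continuity anchor).

*Extrapolated richness* is Chao2-anchored:
S(T+t*) = S_obs + Q̂0[1 − (1 − Q1/(TQ̂0+Q1))^{t*}], with limit Ŝ. For q = 2
a single closed form, (tU/T)²/(tU/T + t(t−1)ΣQᵢ(Qᵢ−1)/(T(T−1))), is valid
at all t. For all other orders the extrapolated log-diversity interpolates
between the empirical value at T (weight T/t) and the asymptotic estimate
(weight 1 − T/t) — continuous at T, asymptote-approaching as t grows; for
q = 1 this is the standard entropy-scale interpolation. Extrapolation past
2T is refused outright (richness extrapolation is unreliable there), which
is why coverage standardisation exists at all.

*Coverage at size t*: rarefied coverage uses the C(T−1,t) denominator,
which keeps the estimator continuous and monotone through t = T
(Ĉ(T−1) = 1 − Q1/U ≤ Ĉ(T)); extrapolated coverage decays the singleton
share geometrically, Ĉ(T+t*) = 1 − (Q1/U)A^{t*+1}.

*C_max* is the minimum over habitats of the coverage reached at 2T. To
standardise, the coverage curve is inverted on the integer grid 1..2T with
linear interpolation between bracketing integers (coverage inversion almost
never lands on an integer size), and the size-based estimate is interpolated
with the same weights. An exact-match shortcut returns integer-size
estimates untouched, so coverage- and size-parameterisations agree to 1e−9
at integer sizes. Targets above a habitat's own 2T coverage raise an error;
inside the bootstrap, replicates whose 2T coverage falls slightly short of
the target are clamped to their own maximum rather than discarded.

## Bootstrap

The incidence bootstrap reconstructs an assemblage from the data: detected
phenotypes get p̂ᵢ = (Qᵢ/T)[1 − τ(1−Qᵢ/T)^T] with τ chosen so the detected
mass equals Ĉ·U/T, and ⌈Q̂0⌉ undetected phenotypes split the deficit
(1−Ĉ)·U/T equally. Each of the B replicates draws Qᵢ ~ Binomial(T, p̂ᵢ)
(equivalent to T Bernoulli units) and re-applies the statistic; the interval
is the normal approximation centred on the observed statistic,
estimate ± 1.96·SD(replicates) — the framework convention that also
reproduces the very narrow bands seen for dominant orders. Replicates in
which the statistic fails are dropped and logged; more than 10% failures
aborts. B defaults to 500 (tests use 50–200 for speed). The construction's
only calibration claim is empirical: over 200 synthetic assemblages
(60-phenotype pool, lognormal(−1.8, 1.0) detection, T = 40 — a regime where
the asymptotic Shannon estimator is approximately unbiased, as an asymptotic
estimator's interval can only be expected to cover the truth where its bias
is small relative to its spread), the 95% interval for asymptotic ¹D covers
the generating truth 90–99% of the time.

## Evenness and classical indices

Evenness profiles use the normalised slope E(q) = (qD−1)/(0D−1) computed on
C_max-standardised Hill numbers (undefined at 0D ≤ 1); Pielou's
J = ln(¹D)/ln(⁰D) likewise at C_max. The classical cross-study indices are
computed on phenotype counts per higher taxon nᵢ with N = Σnᵢ: base-2
Shannon H′ = −Σ(nᵢ/N)log₂(nᵢ/N), Simpson *concentration*
D = Σnᵢ(nᵢ−1)/(N(N−1)) (small = diverse, as the published values behave),
and evenness J = [−Σ(nᵢ/N)ln(nᵢ/N)]/ln(k) over the k taxa present. The
published formula text is ambiguous about the denominators; this reading
(proportions over N, evenness over ln k) is the unique one under which every
published (H′, evenness, taxa) triple in the comparison table is internally
consistent, and it makes J = H′·ln2/ln k an exact identity that the tests
exploit. A single-taxon input raises (evenness undefined) rather than
returning the degenerate H′ = 0, D = 1 pair.

## Community composition

Counts are converted to per-area abundances (sample total / 3-D sample
area), square-root transformed, and turned into Bray–Curtis dissimilarities;
the `presence` transform yields Sørensen dissimilarity for incidence
ordinations. PERMANOVA is the one-way pseudo-F on squared dissimilarities
(between/within partition; with a single factor the Type-III decomposition
reduces to this), with p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under
unrestricted permutation of sample labels (default 999); designs with fewer
distinct arrangements than requested are enumerated exhaustively (exact p,
with a warning). Samples are internally sorted by id so the permutation
stream — hence p — is invariant to input order and habitat renaming at a
fixed seed. Pairwise tests repeat the procedure per habitat pair.
PRIMER-style Monte-Carlo p-values are intentionally not reproduced;
permutation p is the reported statistic.

The dispersion check embeds the dissimilarity matrix by principal
coordinates keeping negative-eigenvalue axes as imaginary parts (squared
distances on those axes are subtracted, clamped at zero, so distances to
group centroids stay real and non-negative), then applies a one-way
permutation F test to the centroid distances. nMDS delegates stress
minimisation to scikit-learn's non-metric MDS (Kruskal stress-1), taking
the best of one classical-scaling start plus 20 random restarts, ties broken
by run order; deterministic given the seed. Venn partitions are exact set
algebra; `shared_from_totals` recovers two-set overlaps from printed totals
by inclusion–exclusion.

## Surface areas and environment

Enlargement factors (EF = true substrate area + frame, over frame area)
convert habitat-m² densities to seafloor-m²: seafloor density is computed
per sample as habitat density × EF and then averaged (mean ± SE, SE = sd/√n),
matching reported per-sample averaging. Algal mats use wet-weight-calibrated
two-sided thallus area scaled from subsample to main sample. Seagrass uses
lateral cylinder rhizomes (2πrh, no end caps — they are buried or attached)
and rectangular leaves counted two-sided (×2) by analogy with the thallus
convention; the leaves-only/rhizomes-only variants zero the other term.
Bare rock uses ball chains (2.4 mm pitch, partial links rounded to whole
links) traced along frame edges and diagonals; each diagonal splits the
quadrilateral into two Heron triangles and the two diagonal-based areas are
averaged — exact (both agree) on planar substrate, EF ≥ 1 always. Clod-card
dissolution is (w_pre − w_post)/days, a *relative* water-movement index
(no dissolution-to-velocity calibration); weight gain raises a contamination
error. Logger series aggregate to calendar-day mean/min/max; empty days are
omitted with a warning. Statistical comparison of clod-card rates is
delegated to standard ANOVA/Tukey routines and only smoke-tested.

## Synthetic assemblages

The generator emulates the study design the estimators must survive, not
any particular dataset: three habitats with pools of 223/111/108 phenotypes
sharing a 90-phenotype core (so the pool-level Venn partition reproduces the
design totals and uniques 133/21/18 exactly), sampled by T = 16/29/20 units.
Detection probabilities are lognormal(μ = −2.2, σ = 1.0) clipped to (0, 1]
— chosen once, analytically, so the expected detected fraction of richness
at the design efforts falls in the 73–86% band typical of such surveys
(≈0.77/0.88/0.81 at T = 16/29/20) and singletons are plentiful. Counts,
used only by the normalisation and Bray–Curtis stages, are zero-truncated
negative binomial (mean 4, dispersion 0.5) given presence; per-sample 3-D
areas and EFs are fixed plausible constants per habitat (0.44 m²/4.9 mats,
0.016 m²/7.3 leaves, 0.08 m²/2.0 rhizomes). Ground truth (true richness,
true qD of the normalised detection rates, expected coverage at T) is
analytic.

What the generator does *not* emulate: site-level structure and spatial
autocorrelation, unit-to-unit heterogeneity in detection (each phenotype
has one πᵢ per habitat), taxonomic composition, misidentification of
phenotypes, and any leaf–rhizome pairing. Passing tests therefore establish
estimator correctness under the stated independence model at realistic
effort and tail heaviness — not robustness to spatially structured or
correlated sampling.

## Validation problem sizes

The suites run on one CPU in about a minute: bootstrap-interval calibration
uses 200 synthetic worlds at B = 200; PERMANOVA type-I calibration uses
1000 null datasets (three groups of five samples, 199 permutations —
(n_perm+1)·α integer, so the test is exact at the 5% level); Chao2
consistency uses 200 replicates at each of T = 8/16/64/256; the brute-force
rarefaction oracle enumerates all subsets up to T = 8. The qualitative
contrast "Simpson curves asymptote by 2T while richness curves do not" is
reproduced on a strongly undersampled assemblage (800-phenotype pool,
lognormal(−4.5, 1.8), T = 12); on milder designs the Chao2-anchored
richness extrapolation itself flattens before 2T and the contrast in
per-unit slopes disappears.

## Known limitations

* Asymptotic Shannon/richness estimates are lower-bound-flavoured: under
  very heavy tails and small T they under-correct, and the bootstrap
  interval inherits that bias.
* The q = 1 (and general-q) extrapolation between T and 2T is an
  interpolation ansatz constrained by its endpoints, not an unbiasedness
  result.
* Completeness at orders other than 0 and 1 is model-based interpolation.
* The dispersion check permutes centroid distances (not raw samples), the
  usual approximation; with tiny groups its null is only approximately
  exchangeable.
* nMDS is a local optimiser; the restart budget (21 starts) makes the
  reported stress reproducible, not provably global.
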