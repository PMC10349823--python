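# Methods

This note records the models implemented in `thermomorph`, the assumptions
behind them, the defaults and why they were chosen, and the places where a
design decision was genuinely open.

## The phylogenetic random-slope model

The central model treats species *i* in family *j* as

    y_ij = α_j + β_j · T_ij + x_ij'γ + ε_ij,      ε_ij ~ N(0, σ_o²)

with y the log trait (ln body mass in grams, or the log/composite bill
size), T the mean annual temperature of the species' breeding range in °C,
and x optional fixed covariates — for the bill model a linear and quadratic
ln-mass term (bill allometry is visibly curved) and a 5-level diet factor
entered as four treatment contrasts against the first level. The family
intercepts and slopes deviate from grand means (μ_α, μ_β) with covariance
Σ ⊗ Ω: Σ is an unstructured 2×2 matrix (σ_α², σ_αβ, σ_β²) and Ω the matrix
of shared root-to-ancestor path lengths of an ultrametric family tree, so
related families pool information. Ω is scaled to unit height before
fitting; this only rescales Σ and conditions the linear algebra, and the
slope units (per °C) are unaffected. Polytomies are handled naturally by
the shared-path definition; ultrametricity is enforced to a relative 1e-6.

**Sampler.** All full conditionals are conjugate, so inference is a blocked
Gibbs sampler: (1) the fixed effects and the stacked 2J-vector of family
intercept/slope deviations are drawn as *one* joint multivariate normal
block — sampling them separately mixes badly because the grand mean trades
off against the family deviations (separate blocks gave R̂ ≈ 1.19 where the
joint block gives R̂ ≤ 1.01); (2) Σ from an inverse-Wishart; (3) σ_o² from
an inverse-gamma. Chains are seeded `seed + chain_index` and are
bit-reproducible. Default chain settings are 13,000 iterations, 3,000
burn-in, thinning 10, three chains; the test suite uses shorter, well-mixed
chains (R̂ < 1.01 throughout).

**Priors.** The random-effect prior is inverse-Wishart in the convention of
the MCMCglmm sampler: scale ψ·ν·I with ψ = 1 and ν = 0.02, i.e. nearly
scale-free but not quite. A consequence worth knowing: the posterior for
the slope variance is bounded below at roughly ψν/J, so with J ≈ 15–30
families σ_β² cannot fall much under ~1e-3 even when the data carry no
slope heterogeneity at all. At realistic slope magnitudes (|β| ~ 0.01/°C)
this floor is material; a genuinely scale-free check (e.g. ψ = 1e-6) lets
family slopes collapse to a common value when the truth has σ_β² = 0, and a
mildly informative option (`prior="weakly_informative"`, scale I, ν = 3) is
available for very small problems. Fixed effects get a flat N(0, 1e8)
prior; the residual variance an IG(0.001, 0.001).

**Temperature centering.** `center_temperature=True` subtracts the mean
temperature before sampling (helps mixing when the temperature range is far
from zero); slopes are unchanged and intercepts are back-transformed on
output, so reported quantities are always on the raw per-°C scale.

**Diagnostics.** Gelman–Rubin is the *split* potential scale reduction
factor on plain (not rank-normalized) draws; constant chains report 1.
ESS uses the chain-averaged autocorrelation function with Geyer's
initial-positive-sequence truncation; a constant chain reports 0. VIFs come
from ordinary auxiliary regressions. All three are hand-implemented and
cross-checked against independent library implementations in the tests.

## Conformance classification

A family *conforms to Bergmann's rule* when the central 95% credible
interval of its body-mass slope lies entirely below zero, and *to Allen's
rule* when the interval of its bill-size slope lies entirely above zero.
Among families non-significant on both axes, those whose medians
nevertheless point the expected ways (body < 0, bill > 0) are counted
separately — the "weak but appropriately directed" group that motivates the
complementarity reading. Intervals are type-7 quantiles of the pooled
post-burn-in draws; the posterior SD doubles as the standard error passed
downstream.

## The errors-in-variables meta-regression

Across families, the observed bill slope is modelled as normal around
θ_j = α + β_meta·x_j with its known posterior SD; the observed body slope is
normal around the latent true slope x_j with its known SD; and the latents
share a population N(μ_body, τ²) with τ estimated (vague inverse-gamma).
The latent population term is what identifies μ_body and is the standard
measurement-error construction; without it the model is unidentified.  No
residual term is added on the bill side — the reported SEs are taken at
face value — except in the degenerate case where *all* bill SEs are zero,
where an estimated residual SD is switched on with a warning (the stated
likelihood is otherwise a delta function); in that limit the posterior
median reproduces ordinary least squares. An `extra_tau` option adds the
bill-side residual in general. Priors on α, β_meta, μ_body are N(0, 1);
at the slope magnitudes involved (≪ 1) they are effectively flat, and
doubling the prior SD moves the slope by less than Monte-Carlo error.

Two properties of this estimator deserve mention:

- **Finite-information attenuation.** When the measurement SDs are
  comparable to the latent spread (e.g. 100 families, SE 0.004 against a
  latent SD 0.010), the posterior median of β_meta is attenuated by roughly
  10% in absolute value; the 95% interval remains calibrated (≈ 95%
  coverage over replicates). The attenuation vanishes as J grows or the
  SEs shrink.
- **Two-stage double-correction.** Feeding in posterior-*shrunk* family
  slope medians together with their posterior SDs — the natural end-to-end
  pipeline — violates the model's assumption that observed = latent +
  independent noise: shrinkage has already removed most sampling noise, and
  the measurement-error correction then inflates |β_meta| (by up to ~2× at
  the default synthetic signal-to-noise). This is a property of the
  two-stage design itself, which the pipeline reproduces deliberately; the
  calibration claims in the tests therefore apply to the meta-regression
  under its own generative assumptions, not to the two-stage composition.

## Surface-to-volume geometry

The body is idealised as two spheres (head, torso) plus a conical bill with
base radius proportional to height (r_b = k·h). Total surface and volume
are plain sums of the primitive surfaces and volumes; **overlaps at the
joins are deliberately ignored** — the model is a scaling argument, not
anatomy — and all SVR statements are exactly scale-inverse (lengths × s ⇒
SVR / s). `shrink_body(f)` reduces combined sphere volume by exactly f;
`grow_beak(g)` raises cone volume by exactly g; both are isometric, and
they commute. The compensating beak growth for a target ΔSVR is found by
Brent root-finding on [0, 10] to |ΔSVR error| < 1e-10, and the iso-ΔSVR
curve interpolates between the pure-body and pure-beak solutions; its
interior points need strictly less change in *both* traits than either
single-trait endpoint, which is the geometric content of the
complementarity argument. The default geometry (r_head = 1, r_torso = 2,
h_bill = 1, k = 0.3) is illustrative, not canonical — no published
dimensions exist for the cartoon — so quantitative outputs (e.g. the ~35%
beak-volume growth matching a 1% body shrink under the defaults) depend on
it and only the qualitative relations are portable.

The conical-bill proxy simulation draws bill heights allometrically coupled
to an independent lognormal body size (exponent 0.33, lognormal noise 0.25).
Surface area of a fixed-shape cone is ∝ h², so its Spearman correlation with
absolute bill size is exactly 1, while the correlation with *relative* bill
size (the residual of ln h on ln body size) is attenuated to the share of
variation not explained by allometry. The coupling is essential: with fully
independent traits the residual equals the absolute size and the contrast is
vacuous.

## Morphometrics

Bill size is a composite of four linear measurements (exposed culmen,
tip-to-nares distance, bill width, bill depth, mm): each is Box-Cox
transformed at its own MLE (golden-section search of the profile
log-likelihood on [−5, 5], tolerance 1e-6), then the first unrotated
principal component of the correlation matrix is taken, with signs fixed so
all PC1 loadings are positive. A phylogenetic PCA variant decomposes the
evolutionary correlation matrix (GLS-centred cross-products weighted by
Ω⁻¹, Brownian model); on a star phylogeny it reduces exactly to ordinary
PCA, and with a dominant common size factor the two PC1s correlate > 0.999.
Centroid size (the square root of summed squared landmark distances to
their centroid) supports landmark-based size input; the conventional ingest
expects 79 3-D landmarks but the function accepts any configuration when
told to.

Relative bill size is the residual of a phylogenetic GLS of the bill
composite on ln mass and ln mass², with Pagel's λ (a multiplier on the
off-diagonal covariances) estimated by ML on a coarse grid refined by
bounded optimisation to 1e-4. Residuals are invariant to affine shifts of
the composite.

Bill specialization is the *rarity* of a species' position in the PC1–PC2
morphospace: a 2-D Gaussian product-kernel density with per-axis
normal-reference (Scott) bandwidths h_d = σ_d·n^(−1/6), evaluated exactly at
the species' coordinates (no grid interpolation, so there is no resolution
knob), then averaged within families. Absolute density values depend on
the bandwidth rule; rank orderings — the quantity the downstream tests use —
are robust to it, and rescaling the morphospace by c rescales every density
by c⁻² without reordering anything.

## Randomization tests and intensity regressions

For each family trait (mean ln body mass, mean absolute and relative bill
size, temperature range = max − min family member mean breeding temperature,
ln number of sampled species, mean kernel density), the null distribution of
each conformance category's mean is built by permuting trait values among
families with category sizes fixed — univariately per trait, matching the
univariate design. The reported p is the one-sided proportion of null means
at or beyond the observed mean toward the nearer extreme; ties count as
"beyond" (conservative), no add-one correction is applied (p = 0 is possible
at 1,000 permutations), and significance means the observed mean sits in the
outer 2.5% tail on either side. Measured over 1,200+ independent null
datasets the flag rate is ≈ 5.3%, i.e. the test is calibrated with a slight
Monte-Carlo inflation from estimating p with 1,000 permutations. Families
significant for both rules (possible on synthetic data) are counted in both
rule categories.

Conformance *intensity* is regressed on the family traits by phylogenetic
GLS with ML-estimated Pagel's λ; the Bergmann response is −1 × the body
slope so larger = stronger. The Bergmann model uses mean body size and the
Allen model mean bill size (never both — they are far too collinear);
constant predictors (e.g. ln N under perfectly balanced sampling) are
dropped with a warning, VIFs above 2 warn, and perfect collinearity is an
error.

## The synthetic-data generator

The generator runs the hierarchical model forwards and is the package's
ground truth: a unit-height pure-birth family tree; (α_j, β_j^body) drawn
from N((μ_α, μ_β), Σ ⊗ Ω); bill slopes on the across-family line
β_j^bill = a + b·β_j^body + η_j; species temperatures uniform on a
configurable range; ln mass and ln bill size from the two model equations;
and four linear measurements back-generated from ln bill size with fixed
positive loadings and lognormal noise.

Defaults (chosen once, as the study conditions): 30 families × 30 species;
temperatures uniform on (−10, 25) °C, the span of mean annual breeding
temperatures for most terrestrial birds; μ_α = 3.9 ln g (a ~50 g bird,
matching the family-mean ln-mass scale of real data); μ_β = −0.005 and
σ_β = 0.01 ln-g/°C, so most family slopes are individually weak;
σ_o,body = 0.3 (moderate within-family mass variation); meta slope −0.25
with η SD 0.005 (the complementarity scenario); allometry 0.4·lnM −
0.015·lnM²; five diet offsets spanning ±0.10; measurement noise 0.2 so the
leading component of the four measurements carries roughly four fifths of
their variance, as in real bill data.

What the generator does *not* emulate: geographic structure (temperatures
are exchangeable within family, not spatially autocorrelated), migratory
behaviour, within-species measurement replication, non-uniform temperature
occupancy, and species-level phylogenetic structure below the family tips.
Passing tests therefore demonstrate correctness of the estimators under the
model's own assumptions — parameter recovery, interval calibration, type-I
control — not robustness to the field-data pathologies the real study had
to handle with filters and robustness reruns (which the pipeline supports
via its config: minimum species per family, default 10; optional minimum
temperature-range filter; order-level grouping by column choice).

## Numerical and engineering choices

- Every stochastic routine takes an integer seed; chains use `seed + k`;
  the pipeline derives stage seeds as `seed + offset`. Identical
  config + seed reproduces every output byte for byte.
- MVN draws with possibly singular covariances use an eigendecomposition
  with negative eigenvalues clipped at 0; precision-parameterised draws use
  Cholesky back-substitution.
- The Box-Cox switch to the log form happens at |λ| < 1e-8; bisection
  brackets and tolerances are stated at each call site.
- Ultrametricity tolerance 1e-6 (relative); PSD tolerance −1e-8 on the
  smallest eigenvalue; Pagel-λ grid step 0.05 with 1e-4 refinement.
- Degenerate inputs fail loudly and early: non-ultrametric trees, missing
  branch lengths, constant Box-Cox input, fewer than 20 points for the
  KDE bandwidth, fewer than 3 families for the meta-regression, fewer than
  10 for the intensity regressions (the pipeline skips that stage with a
  warning instead of aborting the run).

## Known limitations

- The inverse-Wishart default prior's variance floor (above) makes
  near-zero variance components unreachable; this mirrors the convention it
  implements rather than a sampler defect.
- The two-stage pipeline inherits the double-correction bias described
  under the meta-regression when family slopes are strongly shrunk.
- The family-level tree is the finest phylogenetic resolution; species
  within a family are treated as exchangeable.
- Box-Cox per-variable MLEs are computed independently per measurement;
  no joint transformation is attempted.
- The SVR model's absolute numbers are tied to the illustrative default
  geometry; only its scale-free and ordinal statements generalise.
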