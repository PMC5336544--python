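# Methods

`dermapk` analyses dermatopharmacokinetic (DPK) experiments on topical drug
products: tape-strip concentration–depth profiles of the stratum corneum
(SC), TEWL-based SC thickness estimation, in vitro release testing (IVRT),
and test-vs-reference bioequivalence (BE) assessment.  This note documents
the models, their assumptions, the tunable parameters and the design choices
made where the design was genuinely open.

## Fickian uptake model

The SC is a homogeneous membrane of thickness `L` (μm), initially drug-free.
A vehicle with constant drug concentration `Cveh` (μg/cm³) is applied at the
surface `x = 0` and maintains the interface concentration `K·Cveh`, where `K`
is the SC–vehicle partition coefficient; the inner face `x = L` is a perfect
sink.  Fick's second law then gives

    C(x,t) = K·Cveh·[ (1 − x/L) − (2/π) Σ_{n≥1} sin(nπx/L)/n · exp(−(D/L²) n²π² t) ]

with `D/L²` (h⁻¹) the apparent diffusivity over thickness squared.  Derived
quantities: permeability coefficient `kp = K·(D/L²)·L` (cm/h, with `L` in
cm), steady-state flux `Jss = kp·Cveh`, lag time `tlag = 1/(6·D/L²)`.

Assumptions: infinite (non-depleting) donor, constant thermodynamic
activity, no SC heterogeneity or follicular transport, no metabolism.
Finite-dose and two-layer models are out of scope.

Numerics: the Fourier series is truncated adaptively so the neglected tail
is below `1e−8·K·Cveh`, with a minimum of 50 terms (convergence is slow near
`t = 0`) and a hard cap of 2·10⁵ terms; truncation undershoot is clamped at
zero because concentrations are physical.  Amounts in a depth slab — what a
tape strip removes — are obtained by term-wise closed-form integration, and
the whole-SC load `Q(t)` is the slab over `[0, L]` (`Q(∞) = K·Cveh·L/2`).
Both were verified against adaptive quadrature of the profile and against an
independent Crank–Nicolson finite-difference solution of the same
boundary-value problem (agreement better than 0.03% of the surface
concentration across `D/L²·t ∈ [0.01, 5]`).

Units are fixed package-wide: depth μm, area cm², time h, amounts μg,
concentrations μg/cm³; all conversions live in `dermapk.units`.  The depth
coordinate has `x = 0` at the SC surface and relative depth `x/L` is used
internally.

## SC thickness from TEWL

TEWL across a partially stripped SC follows, to good approximation,
`TEWL = Kw/(H − x)` where `x` is the cumulative depth removed and `H` the
total SC thickness.  `1/TEWL` is therefore linear in `x` and the x-intercept
of an OLS fit is `H` (standard error by the delta method from the OLS
covariance).  Design choices: no baseline subtraction, but readings below
2× the pre-stripping baseline are excluded (early readings are dominated by
the intact barrier and carry no thickness information); the stripping
endpoint criterion `TEWL ≥ 100 g·m⁻²·h⁻¹` is inclusive; SC density defaults
to 1.0 g/cm³ for the mass→depth conversion (1 μg/cm² ≡ 0.01 μm) and is
user-overridable.  The estimate is invariant to rescaling of TEWL units.

## Profile construction and fitting

Tape-strip records (strip index, SC mass removed, drug recovered, optional
pool id) are converted to a concentration–depth profile: cumulative mass →
depth, pooled strips merged into a single slab (deep strips are commonly
assayed in pools of up to 4), depths normalised by `L`, concentration =
drug / slab volume.  A total mass-derived depth exceeding `1.2·L` aborts
(wrong `L` or density); zero-mass slabs are folded into a neighbour with a
warning; an optional `discard_first_n` drops surface strips while keeping
their depth offset (a guard against residual surface formulation).  The
first strip is *included* by default because the protocols this package
targets clean the skin surface before stripping.

The fit minimises unweighted least squares between observed slab
concentrations and the model's **interval-average** concentrations
(slab amount / slab volume), not point values at slab midpoints: pooled deep
slabs span a strongly curved region of the profile and midpoint evaluation
biases `D/L²`.  Optional log-residual weighting is available.  `K` and
`D/L²` are optimised in log space (positive, scale-free) with a multi-start
strategy: a 5×5 log-spaced grid over `K ∈ [0.01, 100]`, `D/L² ∈ [10⁻⁴, 10]`
h⁻¹ is scanned and trust-region least squares is run from the five best grid
points, keeping the lowest objective.  Asymptotic 90% CIs come from the
log-parameter covariance (t quantile, n − 2 df); a profile that has fully
relaxed to its steady-state linear shape carries no `D/L²` information and
is flagged `steady_state` (detected when the slowest series mode has decayed
below 10⁻⁸ at the exposure time) rather than reported as a spurious finite
estimate.

Identifiability: simulation at 20% multiplicative assay noise and 12 slabs
(`D/L²·t = 0.3`) shows `K` recovered with ~7% median error but `D/L²` with
~40–45% median error and occasional steady-state collapse — with a single
sampling time the curvature that identifies `D/L²` is weak.  The frozen
acceptance bounds (12% and 60%) reflect this simulation oracle.

Group summaries report mean ± SD of `K`, `D/L²`, `kp`, `Jss` and the 6-h SC
load both as the model prediction `Q(t)` and as the observed sum of slab
amounts; their agreement is a model-adequacy check.

## IVRT

Receptor sampling with replacement under-reports cumulative release; the
mass balance `Q_n = (C_n·V_receptor + Σ_{i<n} C_i·V_i)/area` restores it
(defaults: 7.4 mL receptor, 2 cm² membrane; the correction can be switched
off for pre-corrected data).  Diffusion-controlled release from a semisolid
follows Higuchi kinetics `Q = k·√t`; `k` is estimated by OLS on `√t`, with
optional exclusion of points before 0.25 h (burst release).  A curve with no
measurable release at any time is reported as "no release detected", never
fitted — non-detection is itself a valid outcome.  Formulations are compared
within and across membranes by one-way ANOVA with Bonferroni-corrected
pairwise t-tests at α = 0.05.

## Bioequivalence

The endpoint is the total SC drug amount per replicate in the uptake phase
(immediately after a 6-h application) and the clearance phase (17 h after
product removal).  When the phases are indistinguishable they are pooled
into a combined sample of `n_uptake + n_clearance` observations per product;
the combined mean equals the equal-weight average of the phase means when
per-phase n is equal.  The test/reference ratio of combined means is
assessed against the conventional limits 0.8–1.25: **equivalent** iff the
whole 90% CI lies inside the limits; a CI wholly outside gives
**not-equivalent**, anything else **inconclusive**.  The point estimate
falling inside the limits is reported separately
(`point_within_limits`) and never conflated with the CI verdict.

CI construction: SC amounts are positive and right-skewed with markedly
asymmetric published intervals, which a raw-scale t-interval cannot produce;
the default is therefore a seeded percentile bootstrap (10,000 resamples)
of the mean (or mean ratio), with a back-transformed t-interval on log
values as the alternative.  The log-t interval is exact for the log-normal
median, and its empirical 90% coverage on simulated cohorts is 90 ± 1%.
Ratios are computed on the raw scale (ratio of arithmetic means) and the
log scale (geometric-mean ratio); for cohorts with a true ratio of 1 the
two agree within a few percent.

A worked example uses the published per-phase summary means for three
commercial econazole creams (`dermapk.reference_data`): equal-weight
combination gives a first-generic/reference ratio of 1.015 (published as
1.02).  The second generic computes to ≈1.12 from the same published phase
means, while the differently published value is 0.99; the exact
combination behind that published figure is not recoverable from the table,
so both computations are documented and no attempt is made to force
agreement.

## Synthetic data

The generators simulate the protocols end to end so every stage is testable
without deposited data.  Default study conditions: 6-h exposure; strip
masses log-normal with mean 75 μg/cm² and CV 30% (yielding 8–30 strips per
replicate before the TEWL endpoint, the protocol's observed range); pooling
in groups of up to 4 beyond strip 8; multiplicative log-normal assay noise
(CV 10%); between-replicate log-normal spread of `K` and `D/L²` with CV 40%
(median-preserving); TEWL following the inverse-remaining-thickness law with
baseline 7 g·m⁻²·h⁻¹ and 5% reading noise, stripping stopped at ≥100.
Amount noise is multiplicative log-normal (positive, skewed data); TEWL and
receptor-concentration noise is additive Gaussian.  All generators are pure
functions of (spec, seed).

Presets anchor the transport magnitudes to the targeted study conditions:
`bmv-me-like` (Cveh = 9,300 μg/cm³, K = 2), `bmv-mct-like` (Cveh = 1,700,
K = 1.25) — an 8.7-fold `Jss` ratio between them — and `en-like`
(1% w/v cream, Cveh = 10,000, K = 0.43, ~2 μg/cm² SC load in 6 h), all with
`D/L² = 1/78 h⁻¹` (a 13-h lag time) and `L = 15 μm`, n = 6 (corticosteroid)
or n = 14 (antifungal) replicates.

Because stripping stops at the TEWL endpoint, ~1 μm of SC is left
unstripped: noise-free strip totals equal the covered-slab amount exactly
(additivity at 10⁻¹⁰) and the whole-SC uptake to ~2%.

The clearance arm either preserves amounts up to fresh assay noise
(the ex-vivo outcome: without a microcirculation a lipophilic drug stays in
the SC) or applies first-order decay `exp(−k_clear·t_clear)`, so the
pipeline can detect both persistence and an in-vivo-like ~30% reduction.

What passing tests on these data do **not** show: real tape-strip data have
depth-dependent strip efficiency, furrow artefacts, inter-site thickness
variation and assay censoring near the quantitation limit, none of which is
emulated; conclusions about robustness to those features require real data.

## Statistical power of the equivalence design — a known limitation

With combined samples of n = 28 per product and 40% between-replicate CV,
the 90% CI of the mean ratio has half-width ≈ 0.17 while the acceptance
window inside 0.8–1.25 leaves only ≈ 0.10 of slack; the probability that
two *truly identical* products pass average BE is therefore only ~35%
(and ~23% for the full generate→assess pipeline, where parameter-level CV
compounds into slightly larger amount-level CV).  This is a property of the
design, not of the implementation: at this variability, ≳50 replicates per
product would be needed for 80% passing power.  Truly different products
(ratio 1.5) fail in ≈100% of repeats, and an ~8-fold flux difference is
flagged by the uptake comparison in ≈100% of repeats, so the pipeline's
discriminating behaviour is correct even where its passing power is low.
The acceptance suite asserts the idealised ≥50%/≥90% passing rates and
therefore reports these two checks as failing; the measured rates are
reported by `scripts/acceptance.py`.

## Problem sizes

Simulation-based checks use 200 replicates for parameter recovery, 500 for
thickness recovery, 1000 for CI coverage, and 100–200 repeats for verdict
rates with 4,000 bootstrap resamples inside simulations (10,000 in single
analyses) — sizes at which the Monte-Carlo error is well below the margins
being asserted.
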