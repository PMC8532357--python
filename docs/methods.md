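# Methods

## The model and its assumptions

The package treats a fermenting yeast culture as a metabolic network at
quasi-steady state: at each sampled time point the intracellular fluxes v
(mmol gDW⁻¹ h⁻¹) satisfy mass balance Sv = 0 subject to bounds lb ≤ v ≤ ub,
where S is the stoichiometric matrix. Measured extracellular rates and the
growth rate pin a subset of coordinates (exchange reactions and the biomass
pseudo-reaction), and the object of interest is the *whole remaining
polytope* of flux states, not a single optimum — no biological objective is
assumed. Strain differences are read off the polytope's per-reaction sample
medians.

Assumptions this inherits: (i) balanced growth within each sampling window
(fluxes change slowly relative to metabolite turnover); (ii) measured rates
represent the population average; (iii) the network's bounds encode all
directionality knowledge. The comparison statistics additionally treat the
marginal medians as summaries — joint information between reactions is not
used beyond the Pearson clustergram.

## Flux estimation from time courses

Specific rates use the central (midpoint) difference at interior points,

  q(tᵢ) = (C(tᵢ₊₁) − C(tᵢ₋₁)) / (tᵢ₊₁ − tᵢ₋₁) / X(tᵢ),

one-sided differences at the endpoints, no smoothing, biomass normalisation
at the evaluation point (configurable to the window mean, since published
flux tables rarely state which was used). The estimator is exact for linear
and quadratic concentration profiles at equally spaced interior points; on an
exponential segment its relative error is (μΔt)²/6 (0.17 % at μ = 0.05 h⁻¹,
Δt = 2 h). Uptake is negative, secretion positive.

The known weakness, quantified in "Noise propagation" below, is variance
amplification: the difference of two noisy readings of a large, slowly
changing pool is dominated by the noise.

## Anaerobic setup and constraint fixing

The anaerobic recipe closes the oxygen exchange (LB = UB = 0), opens the
sterol/oleate-class uptakes to the default reversible bound (−1000), blocks
the respiratory shuttle reactions (0, 0) and deletes heme A from the biomass
stoichiometry. The recipe is a plain data object; the Yeast8 reaction ids are
the shipped defaults and the toy network provides its own.

Measured fluxes are fixed as LB = UB equalities (band 0). Because
measurement error makes exact equalities frequently infeasible — the
constraints over-determine the carbon balance — a relaxation band b replaces
them by [q(1−b), q(1+b)] intersected with the reaction's prior bounds (so a
relaxation never opens a direction the unconstrained model forbids, e.g.
ethanol *uptake*). The pipeline escalates b over the ladder
(0, 0.02, 0.05, 0.1, 0.2, 0.5, 1, 2) until the LP "find v with Sv = 0" is
feasible, and records the band used per strain × time in the run manifest.
Growth rate is fixed exactly like an exchange (LB = UB = μ at band 0); both
directions of blocked reactions are closed.

## Uniform sampling (ACHR)

Warmup: the 2n flux-variability vertices, each pulled 33 % toward their
centroid (feasible by convexity, and off the boundary). The chain keeps a
running center (mean of warmup plus all visited points); each step draws a
stored warmup point, takes direction = point − center, computes the feasible
segment from the bound crossings and jumps to a uniform point on it.
Recorded samples are thinned: by default 100 × d steps per sample, where d is
the polytope dimension computed as dim null([S; eⱼ for FVA-pinned j]) — the
FVA-free *reaction count* overstates d whenever free reactions co-move.

Numerical choices that matter (each found necessary in practice):

- Directions are re-projected onto null(S) every step. Without this,
  ~10⁻¹⁶-scale rounding enters the running center, feeds back into later
  directions and compounds *exponentially* along the chain.
- Direction components of bound-pinned coordinates are forced to exactly 0
  (projection rounding ~10⁻¹² can otherwise unpin them), and components with
  |dᵢ| < 10⁻¹² are treated as zero in the segment computation.
- The iterate is clipped to the bounds each step to shed ~10⁻¹¹ excursions
  that would otherwise invert the feasible segment, and α is drawn from
  [αmin + 10⁻¹², αmax − 10⁻¹²] so ties at bounds resolve inward.
- The point is re-projected onto null(S) every 50 recorded samples; the
  sampler fails loudly if any sample violates |Sv| ≤ 10⁻⁶ or its bounds.
- Zero-norm or blocked directions are re-drawn; 100 consecutive failures
  declare the polytope degenerate. A polytope with d = 0 returns its unique
  point (with a warning) rather than failing.
- A hard ceiling of 10¹⁰ total steps is enforced.
- A warning-only mean-split (Geweke-style) z-score per reaction flags
  possible non-convergence; it is deliberately not a gate.

Validation oracle: `rejection_sample` parameterises the polytope's affine
hull — v = v₀ + Mu with v₀ a feasible anchor and M an orthonormal basis of
null([S; pinned rows]) — draws u uniformly in the hull bounding box (from
2d LPs) and keeps points inside the bounds. This is exactly uniform, and
guarded to d ≤ 4 because acceptance decays exponentially with d. Using
null(S) instead of the affine hull would make the polytope a measure-zero
slice of the proposal box whenever bounds pin a null direction.

On the shipped reference polytopes the chain matches theory: the chain
network's free flux is uniform(0, 10) (KS test, mean 5, variance 100/12) and
the three-branch simplex's moments agree with the rejection oracle within
Monte-Carlo error.

## Comparison statistics

- **Medians and rankings.** Per-reaction medians per strain; absolute spread
  is the range (max − min) over strains — for more than two strains the
  "absolute difference" is otherwise ambiguous, and the range equals the
  maximum pairwise difference for scalars. Percent spread is
  100 · range / max(|grand median|, 10⁻¹²), and reactions whose |median|
  never exceeds 10⁻¹² mmol gDW⁻¹ h⁻¹ across strains are excluded before
  percent ranking (they are numerically meaningless relative to VOC exchange
  fluxes). Ties break lexicographically by reaction id so rankings are
  deterministic. The top-k set computed at one time point (default the
  first, 24 h) is reused for later time points.
- **PCA with cos2.** Column-centered, by default unit-variance scaled, via
  SVD, keeping all min(n−1, p) components; component signs are fixed by
  making each component's largest-magnitude loading positive. cos2 of a
  variable on a component is its squared correlation with the component
  (summing to 1 over all components under scaling — asserted to 10⁻⁹);
  cos2 of an observation is its squared score over its squared centered
  distance to the origin. Constant variables are a validation error when
  scaling is on, naming the variable.
- **Clustergram.** Distance 1 − Pearson correlation between strain median
  vectors (optionally over a reaction subset, e.g. the top-20 or an
  aroma-associated set), average linkage (complete/single available).
  Pearson distance is invariant to positive rescaling of a strain's vector,
  so it compares flux *patterns*, not magnitudes. Dendrograms export to
  Newick.
- **Histograms.** Relative-frequency histograms per reaction on a range
  shared across strains, frequencies summing to 1.

## The synthetic generator

`build_toy_wine_network` constructs a deterministic ~25-reaction anaerobic
wine caricature: glucose → 2 trioses (two hexokinase isozymes), glycerol
branch, pyruvate → acetaldehyde → ethanol (two ADH isozymes), an Ehrlich
branch (transaminase → two decarboxylase isozymes → dehydrogenase → fusel
alcohol exchange) with an acetate-ester drain, optional condensed VOC
branches, a biomass pseudo-reaction consuming glucose/amino acids/sterol/
heme A, plus oxygen and respiration for the anaerobic recipe to act on. The
isozyme duplications are deliberate: with all exchanges fixed the polytope
keeps ~3 free dimensions, so sampling remains non-trivial.

`make_benchmark_scenario` plants per-phase exchange-flux vectors that are
*exact steady states* of this network (phase primitives: glucose, glycerol,
fusel, ester, VOC rates and μ; ethanol and amino-acid uptakes close the
balances). Phases mirror a wine fermentation: exponential (μ = 0.05 h⁻¹,
until 36 h), deceleration (μ = 0.01, until 58 h), stationary (μ = 0, until
144 h); evaluation defaults to 24/58/144 h. The four strains are: S1 = S2
(the similar pair), S3 with 3× Ehrlich-branch flux, and S4 with 1.4× early
sugar flux, 0.3× VOC fluxes and 2.5× glycerol yield (glycerol yield is a
classic axis of real strain variation, and under scale-invariant Pearson
distance it is the *shape* change that makes S4 distinct). Initial pools:
glucose 400 mmol/L, amino acids 250/60 mmol/L, biomass 0.5 gDW/L.

Integration is exact within each phase segment — X grows exponentially and
C(t+Δt) = C(t) + q·∫X dt in closed form — so noise-free series are exactly
consistent with the planted rates (and the estimator's only error is the
(μΔt)²/6 exponential-segment term, identical across compounds and μ, which
scales the whole constraint vector and preserves feasibility). At phase
boundaries the midpoint estimate is a positive combination of the two
phases' planted vectors with matching weights for all compounds and μ, hence
still a steady state. Measurement noise is multiplicative Gaussian with
coefficient `noise_cv` (default 0.002), truncated at ±3 CV, applied to every
biomass and concentration reading.

### Noise propagation (why 0.2 %)

A reading error of CV·C propagates through the midpoint difference to a flux
error of ≈ CV·C·√2/(2Δt·X) — amplified by the pool-to-increment ratio
C/ΔC. At 24 h the glucose pool (~340 mmol/L) against its 4 h window change
(~17 mmol/L) amplifies reading noise ~30×; late-stationary ethanol
(~600 mmol/L pool vs ~5 mmol/L per 2 h) amplifies ~170×. The toy carbon
balance ties ethanol = 2·glucose uptake − glycerol − ester with *no free
relief valve*, so inconsistent estimates make exact constraints infeasible —
that is what the band ladder absorbs, and why the default noise is
instrument-repeatability level (0.2 %, typical of HPLC peak-area RSDs)
rather than biological-replicate level: at 1 % the generator's own
feasibility and recovery invariants no longer hold at 24 h. What passing
tests show, therefore, is that the pipeline is *correct*; robustness to
replicate-level noise on real data is a property of the data design
(longer sampling intervals, replicates), not of this code.

The generator emulates: multi-phase kinetics, strain-specific planted
differences, measurement noise, positive pools. It does not emulate:
biological replicate variation, calibration drift, missing samples, CO₂
loss/volume changes, or lag-phase physiology.

### Desk-scale profile

Library default sampling is n = 10,000 with thinning 100 × d (the study-scale
setting). The benchmark/pipeline profile is n = 2,000 with fixed thinning 30,
which keeps a full 4-strain × 3-time × 3-seed recovery run within a few
minutes on one CPU; both values are recorded in the run manifest. Recovery
of the planted design (all six Ehrlich-branch reactions in the top-20
absolute ranking; S1–S2 first merge) was verified across ten generator seeds
at this profile, with first-merge distance margins of 1.6–21×.

## Design choices where the design was open

- Exchange detection is structural (exactly one metabolite in the
  stoichiometry), not id-prefix based.
- Default bounds when a file omits them: (−1000, 1000) reversible, (0, 1000)
  irreversible.
- "Unrestricted uptake" is encoded as lower bound −1000.
- Growth rate is fixed LB = UB (not one-sided), mirroring the exchanges.
- Biomass time-course integration uses the exact exponential within a step
  rather than a forward-Euler update: Euler's (1+μΔt) update biases the
  central-difference growth-rate estimate by ~μΔt/2 (4.5 % at μ = 0.05,
  Δt = 2 h), defeating the estimator's second-order accuracy for no gain.
- PCA observations are whatever table the caller passes; the pipeline uses
  strains × measured extracellular fluxes per time point.
- SBML I/O is delegated to cobrapy/libsbml; LPs to HiGHS via scipy.

## Known limitations

- The ACHR chain is a single chain without an ellipsoidal rounding
  transform; strongly anisotropic genome-scale polytopes will mix slowly.
  Full-scale Yeast8 sampling is supported but not exercised by the tests.
- No significance testing on median differences — rankings are descriptive.
- The rejection oracle is limited to ≤ 4 free dimensions by construction.
- The percent-difference definition (range over |grand median|) is one of
  several defensible conventions; it is explicit and filtered, but not
  canonical.
- `check_feasibility` certifies feasibility only up to LP tolerance; bands
  chosen by the ladder are the smallest *listed* value, not the infimum.
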