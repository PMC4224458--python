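# Methods

## The detwinning model

A still snapshot from crystal *i* records partial intensities
*I*<sub>*i*</sub>(*h*) = *p*<sub>*ih*</sub> · *I*<sub>full</sub>(*T*<sub>*t(i)*</sub>*h*)
plus noise, where *p*<sub>*ih*</sub> ∈ (0, 1] is the (unknown)
partiality, *T*<sub>*t*</sub> is one of *n* candidate integer
reindexing operators, and *t*(*i*) is the pattern's unknown indexing
mode.  The goal is to recover {*t*(*i*)} up to a global gauge so that
Monte Carlo merging approximates {*I*<sub>full</sub>} instead of a
twinned mixture.

EM alternates a correlation E-step with a merging M-step.  The
objective being ascended is the summed per-pattern best Pearson
correlation with the current merged model; its per-pattern mean is the
monitored target score.  Pearson correlation is the right statistic
here because it is invariant to per-pattern scale (shot-to-shot beam
fluctuations, crystal size) and to the average partiality factor; only
the *pattern* of relative intensities across common reflections
matters, and that pattern differs between the two twin settings
because twin-related reflections have independent true intensities.

Assumptions inherited from this design:

* partialities are random factors that average out over many
  observations of one reflection (plain unweighted merging, no
  per-pattern scaling, no partiality post-refinement);
* twin-related reflection pairs carry (nearly) independent full
  intensities — reflections fixed by the twin law carry no mode
  information;
* patterns share enough reflections with the merged model for a
  meaningful correlation (`min_common`, default 5).

The algorithm never sees reference intensities; `run_em` has no
reference argument by construction, and evaluation against a reference
or ground truth is a separate, read-only step.

## Symmetry conventions

Operators act on (*h*, *k*, *l*) column vectors as integer 3×3
matrices.  The default ambiguity group for point group 6 is
{identity, (*h*,*k*,*l*) → (*k*,*h*,−*l*)}; the default merging point
group is proper 6 (rotations about **c**) with Friedel pairing on.
Users working in another space group must supply their own operator
list (validated for determinant ±1, identity-first, and involution in
the two-mode case); the ambiguity operator appropriate for a given
space group is the user's responsibility to verify.

Merged accumulators are keyed by a canonical asymmetric-unit
representative: the lexicographically greatest (*h*, *k*, *l*) tuple
over the point-group orbit (± Friedel).  Any fixed total order would
serve; this one is deterministic and cheap, and tests assert
idempotence and orbit invariance exhaustively on small index blocks.

## Numerical and algorithmic choices

* **Convergence** — stop when no assignment changes, or fewer than
  `convergence_fraction` (default 0.1%) change, or `max_iterations`
  (default 20) is reached; non-convergence is flagged, not raised.
* **Ties** — equal correlations keep the previous iteration's mode
  (hysteresis avoids oscillation); otherwise the lowest mode index
  wins.
* **Undefined correlations** — fewer than `min_common` shared
  reflections or zero variance yields "no information" (NaN), distinct
  from a low correlation.  Patterns undefined in every mode get a
  seeded random mode each iteration so they still contribute to the
  merge.
* **Low-resolution cutoff** — reflections with *d* > 20 Å (default,
  configurable) are excluded from correlation sums: their extreme
  intensities dominate the moments while carrying little mode
  information.  They are still merged.
* **Winsorization** — an optional percentile clip of intensities for
  correlation purposes only (default off), a guard against saturated
  measurements.
* **Model visibility** — entries observed by no pattern under the
  current assignment have `n_obs = 0` and are invisible to the next
  E-step (an unmeasured mean is undefined).
* **Vectorization** — a dataset is compiled once into concatenated
  observation arrays plus per-mode model-row indices; each iteration
  is a fixed number of `bincount` passes, so runtime is linear in the
  total observation count times the number of modes.  A 10,000-pattern
  run takes well under a minute on one core.
* **Reproducibility** — one integer seed per run governs the random
  starting model and any random assignments.

## The synthetic generator

`simulate_dataset` emulates exactly the statistical structure the
method exploits:

* **True intensities** — i.i.d. Exponential(mean = `intensity_scale`,
  default 1000 photons) per canonical reflection: the acentric Wilson
  law.  This replaces structure-factor calculations from coordinates
  while preserving what matters — heavy-tailed positive intensities
  independent across twin mates.
* **Partiality** — `uniform`: *p* ~ U(0, 1) independent of resolution;
  `resolution_dependent`: *p* ~ U(lo(*q*), 1] with
  lo(*q*) = `p_floor` + (1 − `p_floor`) · *q*/*q*<sub>max</sub>,
  a monotone family expressing that the thicker Ewald shell at high
  scattering angle measures reflections more completely.  Note the
  mean partiality of this family is ≥ 0.5 by construction; it models
  the qualitative high-*q* trend, not any particular instrument.
* **Noise** — `poisson` replaces each expected intensity with a
  Poisson draw (intensities are photon counts); `none` for exact
  arithmetic in oracle tests.
* **Modes** — each pattern's true mode is drawn from
  `mode_probabilities` (default 50/50).
* **Lattice** — default hexagonal cell *a* = *b* = 60 Å, *c* = 40 Å
  truncated at *d*<sub>min</sub> = 3 Å (≈ 1.7k unique reflections).
  This small cell keeps desk-scale multiplicities high (2,000 patterns
  of ~100 reflections give ~120 observations per unique reflection)
  while the 3–5 Å shell stays populated for shell-restricted
  comparisons.  A Photosystem-I-like preset
  (`SimulationConfig.psi_preset()`, *a* = *b* = 281 Å, *c* = 165.2 Å,
  *d*<sub>min</sub> = 10 Å) is provided for realistic cell dimensions;
  at that volume a 3 Å lattice would hold ~10⁵ unique reflections and
  desk-scale pattern counts could not cover it.
* **Subsets** — each pattern observes a uniform random subset of the
  lattice (count ~ Poisson(`reflections_per_pattern`), truncated to
  ≥ 5).  Real stills sample a curved Ewald slab; no such geometry is
  modelled, so completeness-versus-orientation effects are out of
  scope.

Because the generator reproduces the method's assumptions exactly,
passing tests demonstrate the algorithm's correctness and its
statistical behaviour (50/50 first split, 1/√2 twinned ceiling,
*N*<sup>−1/2</sup> merge error, failure at degenerate sizes).  They do
not demonstrate robustness to effects the generator omits: indexing
errors, background and saturation artifacts, per-pattern scale drift,
or partiality correlations induced by real geometry.

## Evaluation conventions

* The CIM gauge between two models is the mode whose reindexing
  maximizes their correlation; per-construction r(CIM) ≥ r(AIM).
* Pattern-level consistency fractions are gauge-corrected: flipping
  the reference's setting changes labels, never fractions.
* Multi-run matrices report CIM values in the lower triangle and AIM
  values in the upper triangle; shell restriction (default 3–5 Å when
  requested) reduces the leverage of extreme low-resolution
  intensities.
* The separability statistic (standardized mean difference between
  best-mode and alternative-mode correlation populations) is a scalar
  summary of how cleanly a correlation flavour splits the modes; it is
  a package convention, chosen because it is deterministic and
  comparable across methods.
* Statistics that quantify twin mixing (e.g. the twinned-merge
  ceiling) exclude twin-invariant reflections via
  `twin_invariant_mask`: those entries are identical in both settings
  and would dilute the measurement — noticeably so on the small
  default lattice, where they are ~17% of the unique reflections.

## Problem sizes

The bundled studies use 2,000 patterns (twinned-merge ceiling, five
seeds), 10,000 patterns (resolution-dependent recovery), 5,000
patterns × 10 random starts (self-consistency), and 24 starting models
on 1,000 patterns (first-iteration split).  These sizes give
per-reflection multiplicities comparable in effect to much larger
experimental datasets on bigger cells, because the lattice is small.

## Known limitations

* Only the two-mode (twin-like) ambiguity is exercised end to end;
  the data structures accept *n* > 2 modes, and consistency logic
  composes operators within the group, but no >2-mode study ships.
* No per-pattern scaling or partiality refinement: merged means
  estimate (mean partiality) × *I*<sub>full</sub>, a uniform factor
  under the uniform model but a mild resolution-dependent factor under
  the resolution-dependent model (visible as a model–truth correlation
  slightly below 1 even with perfect assignments).
* The EM objective is ascended greedily from one random start; like
  any EM it can stall in local optima on tiny, noisy datasets
  (multi-start with score selection is the practical remedy, and the
  size-sweep tooling shows where the degenerate regime begins).
* The stream reader is a tolerant subset: chunk delimiters and
  reflection tables only.
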