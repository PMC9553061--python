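# Methods

This note documents the model equations as implemented, the parameter
defaults and how they were chosen, what the synthetic generators emulate,
and the numerical and design choices a user should know before trusting —
or extending — the simulations.

## The filter

Phase φ is measured in seconds and advances at nominal rate 1, so phase
and stimulus time share a scale; templates are aperiodic point-process
rates over the real line. For a multi-repetition stimulus the cycle
template is *tiled* — event phases copied at k·T for each tracked cycle,
plus the shared closing onset — rather than wrapped on a circle, which
keeps the filter equations unchanged and matches stimuli whose cycle
boundaries are shared single onsets.

Between and at events the Gaussian posterior (μₜ, Vₜ) takes one Euler
step per dt of

    dμ = dt + (μ̂ − μₜ)(dNₜ − Λ dt) + η_μ √dt z,   z ~ 𝒩(0,1)
    dV = σ² dt + (V̂ − Vₜ)(dNₜ − Λ dt)

with dNₜ ∈ {0,1}. Two conventions deserve note:

- **The hazard includes the background.** We use Λ = λ₀ + Σᵢ Λᵢ. The
  reset moments weight each expectation by Λᵢ/Λ and the background by
  λ₀/Λ; only with the background included do these weights sum to one and
  the reset become the exact moment match of the one-event posterior
  p(φ) ∝ 𝒩(φ|μₜ,Vₜ)·λ(φ). This is verified directly against a dense-grid
  Bayes oracle in the tests.
- **The full coupled drift is implemented**, not plain drift between
  events: the −Λdt term lets strong unfulfilled expectations pull the
  mean, which is part of the model's behavior, not an artifact.

Pattern inference shares a single posterior across templates. Per step,
candidate (Λᵐ, μ̂ᵐ, V̂ᵐ) are computed per template from the shared
posterior; probabilities update by the replicator-style rule
dpᵐ = pᵐ(Λᵐ/Λ − 1)(dNₜ − Λdt) with Λ = Σₘ pᵐΛᵐ; the candidates are then
marginalized with the updated weights. We deliberately do not maintain
separate per-template posteriors between events (single-estimate
reading); a one-template bank therefore reduces *exactly* (to the last
bit) to the single-template filter, which the tests assert at 1e-12.

Numerical choices:

- dt = 1 ms by default; simulations run at millisecond resolution.
  Events are mapped to the nearest grid step; two events in one bin raise
  an error rather than silently merging.
- Euler steps can push pᵐ slightly negative at sharp hazard transients;
  values are clipped at 0 and the vector renormalized each step. V is
  floored at 1e-12 and floor hits counted on the trajectory record (none
  occur under default parameters).
- The mixture variance uses the centred form Σpᵐ(V̂ᵐ + (μ̂ᵐ − μ̂)²), which
  is algebraically identical to the raw-moment expression but immune to
  cancellation when μ̂ ≫ V̂ (phase grows to tens of seconds over a run).
- Probabilities of implausible templates are never pruned; hazards are
  computed for all templates at every step so the filter can revise its
  interpretation if the rhythm changes.
- The per-dt loops are numba-compiled; all randomness is drawn outside
  the kernels from a seeded numpy Generator, so runs are reproducible
  bit-for-bit given (config, seed).

## Noise channels

Two implementation-noise channels sit outside the observer's generative
model: event noise η_e (each stimulus onset except the anchoring first
one is perturbed by η_e·z, emulating noisy auditory transduction; z is
redrawn for onsets that would reorder, preserving marginal normality
conditional on order) and phase-tracking noise η_μ (the dμ increment is
perturbed by η_μ√dt·z, emulating noisy timekeeping; the √dt scaling makes
its per-second effect dt-invariant — whether the original formulation
intends a per-step or per-second scale is not stated, so we chose the
discretization-stable reading).

## Parameter defaults and calibration

The source publications for the simulated paradigms do not ship a usable
parameter table, so all parameters are config-exposed with defaults in
`src/pippet/defaults.yaml` (one versioned file). Defaults were calibrated
once, against the qualitative phenomena the simulations are meant to
exhibit, and then frozen:

| parameter | default | role / rationale |
| --- | --- | --- |
| dt | 1 ms | simulation resolution |
| σ | 0.02 /√s | expected phase diffusion; small enough that V grows only modestly between events (so template precision differences matter), large enough that event resets carry weight |
| λ₀ | 0.01 /s | background rate; keeps resets template-dominated while leaving a nonzero ambiguity floor |
| λᵢ (hand-built banks) | 0.02 | two-interval template strength |
| v (1:1 template) | 1e-4 s² (sd 10 ms) | precise prototype for the even rhythm |
| v (2:1, 4:3 templates) | 2e-3 s² (sd ~45 ms) | imprecise uneven prototypes; the 1:1/2:1 precision gap is what attracts uneven rhythms to the 2:1 interpretation |
| η_e | 20 ms | auditory event jitter, human-scale |
| η_μ | 0.03 | timekeeping noise; with η_e it sets run-to-run variability so that genuinely small uncertainty differences (4:3 vs 2:1 under the 4:3-aware model) are statistically indistinguishable at n = 26 runs, as observed empirically |
| V₀ | 2e-4 s² | initial phase uncertainty |
| λmax, vmax | 1.0, 5e-4 s² | corpus-bank parameterization λᵐ = p₀ᵐλmax, vᵐ = (1−p₀ᵐ)vmax; vmax sets the per-event correction gain V/(V+v) ≈ 0.2–0.4 that lets five reproduction iterations converge onto category modes |
| constant strength/variance | 0.02, 1e-3 | used when pattern inference runs with template parameters held constant |
| N (restriction) | 22 | templates kept per stimulus, nearest by Euclidean distance between interval vectors (ms) |

## Corpus-style priors

A metrical table gives P(n | M): the probability of an onset at each
16th-note position n of meter M, for meters 2/4 (8 positions), 4/4 (16),
6/8 (12) and 3/4 (12). Every strictly increasing position triple defines
a three-interval pattern; the third interval closes the cycle (wrap to
nᵢ + period), so each triple yields exactly two consecutive-interval
ratios ⟨r₁, r₂⟩ with r₁ = d₁/d₂, r₂ = d₂/d₃. Pattern probability is the
product of its onset probabilities, summed over realizations within a
meter, averaged over meters with weight 1/|M|, and normalized over the
deduplicated (gcd-reduced) pattern set. Ratios map to durations by
d₃ = t_d/(r₁r₂ + r₂ + 1), d₂ = r₂d₃, d₁ = r₁d₂, which is the unique
convention under which the three durations sum to t_d — verified by a
round-trip property test. Patterns whose realized intervals violate the
rhythm space's 300 ms minimum are dropped and priors renormalized.

A consequence of exact cycle closure worth knowing: interval triples must
sum to a meter period (8, 12 or 16), so the 2:2:3 family (sum 7, coprime
with all supported periods) can never enter a bank built from these
meters. The mildly complex family used for the cultural contrast is
therefore 3:3:2 (cyclic class 2:3:3; sums to 8 and 16), which is
realizable in the binary meters and is itself a culturally diagnostic
category.

## Synthetic metrical tables

The generator emulates the *shape* of corpus onset statistics, not any
corpus's numeric values. The hierarchical profile assigns onset
probability ∝ exp(−c·depth), where depth is the position's metrical level
(downbeat 0, mid-cycle beat 1, beat subdivision 2, offbeat 16ths 3+),
with a small seeded multiplicative jitter bounded so the between-level
ordering is never violated. The cultural pair uses c = 1.2 (strongly
stratified, the Eurogenetic-folk analog) and c = 0.4 (flatter, the
makam analog — less stratified but not structureless); a strictly uniform
profile is also available. Flatter tables provably yield higher-entropy
bank priors, mirroring the corpus contrast the simulations depend on.

What the synthetic tables do **not** capture: position-specific
idiosyncrasies of real corpora (anacrusis conventions, style-specific
syncopation), cross-meter frequency differences (meters are weighted
equally), and any correlation between successive onsets (onset
probabilities are independent per position, as in the pattern-probability
model itself). Passing tests therefore show that the *mechanism* —
from metrical stratification through priors to biased entrainment —
behaves as described, not that any specific culture's statistics are
reproduced.

## The simulated studies

**Two-interval tracking.** Three stimuli (1:1, 58:42, 2:1; 1000 ms
period; 25 repetitions; shared cycle-boundary onsets) × two banks
(with/without the 4:3 template, equiprobable priors) × 26 noisy runs per
condition. Recorded: phase corrections at the event closing each cycle's
first interval, and per-run mean pre-event variance (Vₜ on the step
before each event). Welch's t-tests (Satterthwaite df) compare per-run
mean uncertainties between stimuli within banks and between banks. The
published t/p magnitudes are parameter-dependent and are not reproduced;
the sign and significance pattern is.

**Rhythm-space categorization.** The bank is built from the hierarchical
table with constant strengths/variances (isolating the effect of the
prior p₀ᵐ), restricted per stimulus to the N = 22 nearest templates; each
grid rhythm is presented once (events at 0, d₁, d₁+d₂, 2000 ms) and the
final posterior over templates is summarized by entropy (bits) and
argmax. The full grid has 6216 rhythms; the automated checks use a
500-rhythm subsample (the full map is available through the CLI).

**Iterated reproduction.** Per trial: a uniform triple from the
constrained simplex; five iterations of (present 10 noisy repetitions →
infer the template on repetition 1 with constant parameters → track the
full sequence with the inferred, prior-parameterized template → place the
next stimulus's events at the mean across cycles 2–10 of the post-event
posterior phase, renormalized to the 2000 ms period). All cycles are
averaged equally; reproduced rhythms pass back through the η_e channel on
the next presentation; non-positive reproduced intervals flag the trial
excluded (none occur under defaults). The automated checks use 200 trials
per bank; the reference paradigm uses 2000, so per-class weights carry
visible Monte-Carlo error at this size and only orderings/signs are
asserted.

**Density and category weights.** The KDE is a Gaussian
`scipy.stats.gaussian_kde` (Silverman bandwidth) in 2-D ternary-projected
coordinates (the projection is an isometry up to scale, so isotropy is
preserved), normalized against the uniform density over the feasible
region. Category weights come from a hand-written EM fit of a mixture
with component means *fixed* at the small-integer-ratio centers (all
gcd-reduced triples with entries ≤ 3 that satisfy the 300 ms floor), one
shared isotropic variance, and a uniform background component; weights of
cyclic rotations are grouped, and bootstrap resampling (N = 250 by
default) gives weight SDs. Cross-bank weight comparisons use a normal
approximation on the bootstrap SDs with Bonferroni correction. The fit
recovers planted weights within ±0.01 at n = 2000, sd = 60 ms.

## Known limitations

- Tempo is fixed: the filter infers phase only, so rhythms are tracked at
  their nominal rate and tempo drift is outside the model.
- The Euler discretization of the probability update requires clipping at
  sharp transients; at dt = 1 ms the deviation from sequential Bayes is
  below 1% on the tested instances, but very strong, very precise
  expectations (λᵢ/√(2πvᵢ) approaching 1/dt) would need a smaller step.
- The constrained-mixture weights are only as meaningful as the center
  set; rhythms far from every center load on the uniform background, so
  grouped weights underestimate diffuse category mass.
- The 26-runs-per-condition design matches the reference analysis's
  degrees of freedom (t(50)), but that reading of the published df is an
  interpretation, not a documented fact.
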