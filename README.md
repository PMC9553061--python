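# pippet

Bayesian phase inference from point-process event timing, with rhythmic
pattern inference and corpus-style metrical priors.

## The problem

A listener tracking a musical rhythm is solving an inference problem:
events (note onsets) arrive at precise times, and the listener must
continuously estimate the *phase* φ of the underlying pattern — a hidden
variable that advances at a nominal rate of 1 with diffusion noise σ —
from those event times alone. Temporal expectations are encoded as an
*expectation template*, an inhomogeneous point-process rate over phase

    λ(φ) = λ₀ + Σᵢ λᵢ 𝒩(φ | φᵢ, vᵢ),

a uniform background λ₀ plus one Gaussian bump per expected event, with
strength λᵢ and precision 1/vᵢ. A variational (Kalman–Bucy-style) filter
maintains a Gaussian posterior on phase (mean μₜ, variance Vₜ):

    dμ = dt + (μ̂ − μₜ)(dNₜ − Λ dt)
    dV = σ² dt + (V̂ − Vₜ)(dNₜ − Λ dt)

where Nₜ counts events, Λ = λ₀ + Σᵢ Λᵢ is the *subjective hazard rate*
with Λᵢ = λᵢ 𝒩(μₜ | φᵢ, vᵢ + Vₜ), and (μ̂, V̂) are the precision-weighted
reset moments an event would impose (each expectation contributes its
conjugate Gaussian update weighted by Λᵢ/Λ; the background keeps the prior
with weight λ₀/Λ).

Real listeners do more: they also infer *which* rhythmic pattern they are
hearing, drawing on culturally learned priors. The pattern-inference
extension tracks a bank of candidate templates λᵐ(φ) with probabilities
pᵐ, updated at every time step from the hazard ratios,

    dpᵐ = pᵐ (Λᵐ/Λ − 1)(dNₜ − Λ dt),   Λ = Σₘ pᵐ Λᵐ,

and marginalizes the per-template candidate posteriors into the single
Gaussian the filter carries (mixture moments). Template banks can be
hand-built or derived from metrical onset statistics: every
position triple in a meter yields a three-interval ratio pattern whose
corpus probability sets the template's prior p₀ᵐ, its strength
λᵐ = p₀ᵐ λmax and its variance vᵐ = (1 − p₀ᵐ) vmax — patterns frequent
in a musical culture get strong, precise expectations.

On top of the filters, the package reproduces three simulated studies:

1. **Two-interval tracking bias** — models with and without a 4:3
   template (realized as 58:42) track 1:1, 4:3 and 2:1 rhythms; the model
   lacking the 4:3 prototype attributes the rhythm to its imprecise 2:1
   template and shows systematically skewed phase corrections.
2. **Rhythm-space categorization** — one-pass pattern inference over the
   6216-point simplex of three-interval rhythms (2000 ms period, 300 ms
   minimum interval, 10 ms grid); posterior entropy maps show attractors
   at small-integer-ratio rhythms.
3. **Iterated reproduction** — pattern inference picks a template on the
   first repetition, single-template tracking of the remaining nine
   repetitions yields a reproduced rhythm that seeds the next iteration;
   after five iterations reproductions concentrate at small-integer-ratio
   categories, and banks built from flatter metrical hierarchies put more
   weight on mildly complex patterns (the 3:3:2 family).

## Worked example

Track 25 repetitions of a 4:3 (58:42) two-interval rhythm with a bank
holding 1:1, 2:1 and 4:3 templates:

```python
from pippet import FilterConfig, PatternPippetModel, make_stimulus
from pippet.fixtures import experiment1_banks

european, malian = experiment1_banks()
config = FilterConfig.from_defaults(event_noise_scale=0.0,
                                    phase_noise_scale=0.0)
stimulus = make_stimulus((580.0, 420.0), repetitions=25, event_noise=0.0)
result = PatternPippetModel(stimulus, malian, config,
                            tile_repetitions=25).filter()
print(result.summary())
```

```
PIPPET filter results
============================================
template:            bank of 3
events observed:     51
steps (dt=0.001s): 25002
mean phase corr.:    +0.00002 s
mean |phase corr.|:  0.00009 s
mean pre-event V:    0.000741
final posterior:     mu=25.0019, V=0.000561
variance floor hits: 0
templates:           3
MAP template:        4:3
posterior entropy:   0.000 bits
top probabilities:   4:3=1.000, 2:1=0.000, 1:1=0.000
```

The filter identifies the 4:3 pattern (MAP template) and tracks it with
tiny phase corrections (mean reset +0.02 ms per event). Running the same
stimulus through the `european` bank — which lacks a 4:3 template —
attributes the events to the imprecise 2:1 template instead, and the mean
first-interval correction grows to roughly +7 ms: the signature of
enculturated bias. `result.to_dataframe()` exposes the full trajectory
(μₜ, Vₜ, Λ, per-template probabilities, entropy) and
`pippet.plotting.plot_trajectory(result)` plots it.

The experiment drivers are also available from the shell:

```sh
pippet exp1 --seed 1 --out exp1_out
pippet exp2 --seed 1 --subsample 500 --out exp2_out --plots
pippet exp3 --seed 1 --trials 200 --out exp3_out
pippet fixtures make --out fixtures_out
```

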