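# scrubcomfort

Tactile somatosensory comfort modelling for robot-assisted scrubbing.

Assistive bathing robots must choose how hard and how fast to scrub.
`scrubcomfort` implements a quantitative comfort model that links the
robot's control variables — normal force *N*, stroke speed *v* and
duration Δ*t* — to the comfort a person perceives, and optimises the
operating point against it. It is aimed at researchers in physical
human–robot interaction, haptics and ergonomics who need a predictive,
control-oriented comfort objective rather than post-hoc subjective
ratings.

## The model

1. **Stimulus = energy transfer.** The mechanical stimulus of one
   stroke is the friction energy the brush delivers to the skin. With
   the skin-friction power law *f* = *μN^m* (*m* ≈ 0.7) and the brush
   rim speed matched to the stroke speed,

   *E* = (4/3) · *v* · *μN^m* · Δ*t*.

2. **Stevens' power law.** Perceived magnitude follows
   *S* = *k·I^n*; calibrated by log-log regression of normalised VAS
   ratings on stimulus energy (*k* = 2.88, *n* = 1.52 for a nylon
   brush). Introducing sensitivity indices *x* and *y* on speed and
   force gives the extended model

   *S* = *c₀* · *v^x* · *N^{m·y}* · Δ*t^n*,  *c₀* = *k*(4/3·*μ*)*^n* ≈ 0.54.

3. **Bell-shaped comfort function.** Comfort is non-monotone in
   stimulation: *g*(*S*) = exp(−π·|*S^b* − *μ′*|*^a*) with
   *μ′* = (ln 2/π)^(1/*a*), the unique normalisation for which the
   maximum of *g* is exactly 1 and the no-stimulus baseline *g*(0) is
   exactly 0.5. Fitted shape values: *x* = 1.66, *y* = 3.87,
   *a* = 1.04, *b* = 2.01.

4. **Optimisation.** A particle swarm minimises (G − *g**(v, N))² over
   the feasible box (*v* ∈ [0.02, 0.05] m/s-scaled units,
   *N* ∈ [0.5, 3] N). The minimiser is a one-dimensional iso-comfort
   ridge *S*(v, N) = *S**, which the package exposes explicitly.

5. **HRV validation metrics.** SDNN, RMSSD, pNN50, LFnorm, HFnorm and
   LF/HF from RR-interval series, for physiological validation of
   chosen operating points.

Synthetic-data generators reproduce every input (VAS rating tables,
comfort surfaces, RR series) from known ground truth, so the whole
chain is testable end to end.

## Worked example

Evaluate one operating point (speeds on the CLI are mm/s):

```sh
$ scrubcomfort eval --v 36.47 --n 1.68
{
  "v_mm_s": 36.47,
  "N_newton": 1.68,
  "dt_s": 10.0,
  "magnitude": 0.30015417729498167,
  "comfort": 0.6562973652686473
}
```

The perceived magnitude 0.30 sits below the comfort peak
*S** ≈ 0.485, so this condition scores 0.66 — above the neutral
baseline 0.5 but short of maximal comfort. Optimising instead:

```sh
$ scrubcomfort optimize --seed 1
{
  "best_v_mm_s": 24.769576744793774,
  "best_N": 2.542725346552745,
  "best_objective": 1.4314977531985197e-15,
  "ridge_in_box": true,
  ...
}
```

The swarm lands on the iso-comfort ridge (objective ≈ 0, comfort ≈ 1);
`ridge_sample_mm_s` lists other equally optimal (v, N) pairs — a
faster stroke needs less force. The same library API is available in
Python (`scrubcomfort.optimize_comfort`, `comfort_from_condition`,
`fit_comfort_params`, `hrv_metrics`, ...), and
`scrubcomfort reproduce --seed 1` runs the full synthetic pipeline
(simulate → fit Stevens → fit sensitivity indices → optimise) and
prints a recovery report.

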