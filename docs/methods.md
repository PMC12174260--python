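# Methods

## The stochastic synapse and the Boolean circuit

Every neuron in the micro complex is a Boolean state updated once per
sample.  A synapse whose presynaptic neuron fired this sample delivers a
drive `X · SyS` with `X ~ U[0, 1)` drawn fresh per synapse, per circuit, per
sample; inhibitory transmitters enter with a negative sign.  The
postsynaptic neuron fires iff the signed sum strictly exceeds its
depolarisation threshold `DT`.  `DT = 0.15` represents the normalised gap
between resting potential and spike threshold as a fraction of the
resting-to-peak range; `SyS = 1.5` is a receptor-density multiplier, so a
lone excitatory synapse transmits with probability `1 − 0.15/1.5 = 0.9`.

Updates run in a fixed order within each sample — granule, Golgi,
interneuron, Purkinje, DCN — with the Golgi cell inhibiting the granule
cell at one sample's delay (the only state carried across samples in the
memoryless engine).  The Golgi threshold is its own `DT_golgi` parameter
(the source equations print the granule threshold symbol there, which we
read as a typo; both default to 0.15 so behaviour at defaults is
identical).  Draws on the half-open interval `[0, 1)` make the afferent
sampling rule `X ≥ 1 − p` exact at both `p = 0` and `p = 1`.  Draws are
consumed only for array elements whose presynaptic neuron is active, in the
documented synapse order, so a run is reproducible bit-for-bit from
(seed, parameters, inputs).

Rate coding: a neuron firing at `f` Hz in a model sampled at `F_s` Hz is a
Bernoulli event with probability `f / F_s` per sample.  The memoryless
engine caps `F_s` at 250 Hz (4 ms steps) so every neuron can return to rest
between samples.

## The analytic oracle

Each update is the event `Σ aᵢXᵢ − Σ bⱼYⱼ > DT` with independent uniforms.
The oracle computes this probability exactly: closed forms for up to two
active terms, trapezoidal convolution of the box densities (20 000 grid
points) beyond that.  The stationary DCN output for homogeneous parameters
follows by fixed-point iteration of the granule/Golgi marginal (tolerance
1e-10, at most 1000 iterations) and exhaustive enumeration over the Boolean
states of the upstream neurons.  The oracle shares no code with the
sampling path, so simulator-vs-oracle agreement (within 3 binomial standard
errors at n = 1e5) is a genuine two-route check.  Simulation-side estimates
of the stationary marginal discard a 10-sample burn-in to let the Golgi
feedback reach its fixed point.

## The comparator plant and the joint

The motor plant follows cerebellar brain inhibition: DCN output selectively
suppresses the antagonist pathway.  Per circuit, six Boolean equations
compare the DCN state against the motor signal (identified with the
climbing-fibre state): P1 fires when DCN beats motor, P2 when motor beats
DCN, P3 pools them, the flexor and an extensor-interneuron are driven by P3
and inhibited by DCN, and the extensor is driven by P3 and inhibited by the
interneuron.

Unlike the circuit synapses, each comparator equation multiplies its whole
signed weight sum by a *single* shared uniform draw.  This is deliberate
and load-bearing: with equal strengths, excitation and inhibition then
cancel exactly, so simultaneous DCN and motor firing produces no movement
and flexor/extensor co-activation is rare (probability ≈ 0.07 in the
motor-only state) — the functional behaviour the plant is defined by.  With
independent per-term draws the cancellation leaks (a 0.405 firing
probability survives exact opposition), giving the plant a structural
extensor bias of ≈ −0.18 net drive per circuit in the combined state; the
closed loop then equilibrates well below the target and every downstream
phenotype comparison inverts.  We treat the shared draw as one presynaptic
release event evaluated against the equation's net weight.

Muscle power is `mean(flexor − extensor) · muscle_strength · power_scale +
force_on_joint`, the joint integrates power and is clamped to [0, 1], and
`movement_error = |actual − desired|`.  `muscle_strength` (default 10) is
read as a maximum joint *velocity* in position-units per second;
`power_scale` converts it to a per-sample displacement and defaults to the
4 ms sampling step (0.004 s).  This choice is what keeps the discrete
feedback loop stable: the comparator's sensitivity is ≈ 0.7 net-drive per
unit position error, so interpreting strength 10 directly as per-sample
displacement gives a loop gain of ≈ 7 per sample — a violent period-2
oscillation between the joint rails at any population size.  With the
velocity reading the gain is ≈ 0.03 per sample, the loop settles within
~0.15 s, and a constant target is held to ≈ 0.03 mean error at n = 1e4.
The raw difference plant (motor − DCN, no comparator) is retained as the
`simple_muscle_power` diagnostic.

Desired trajectories: sinusoid (default 0.1 Hz — one flexion/extension
cycle per 10 s run, spanning the full joint range), constant, and step
sequences.  External forces are position-units per sample added to the
power; the compensation and adaptation studies use ±0.002 (0.5 u/s, 5% of
the maximum muscle velocity), large against idle jitter at n = 1e4 yet
compensable.

## Plasticity

Six activity-dependent rules modify five synapses per circuit and per
sample, each multiplying the target SyS by `1 ± step_fraction`:
parallel-fibre→Purkinje LTD on same-sample granule+climbing co-activation;
parallel-fibre→Purkinje LTP on high granule activity without high climbing
activity; mossy→granule LTP on high mossy activity; climbing→Purkinje LTP
on high climbing activity; mossy→DCN LTD on low mossy activity; and
Purkinje→DCN LTD when the DCN fires while Purkinje activity is low.
"Activity" is an exponential moving average of the Boolean state classified
against low/high cutoffs (0.2 / 0.6).  Untriggered synapses relax
geometrically to their baseline; SyS is clipped to [0.1, 5].

Defaults: `step_fraction 0.01`, `relax_rate 0.001` per sample,
`ema_alpha 0.01`.  The smoothing constant is the one tuned quantity: at
0.05 the EMA's sampling noise (sd ≈ 0.16 at p = 0.5) straddles the
thresholds and ratchets climbing-fibre LTP to the bound under steady input;
at 0.01 (sd ≈ 0.035, ~0.4 s time constant) the bands respond to real
activity shifts.  Because the thresholds sit at 0.2/0.6, force adaptation
engages when the operating point nears an activity band: the adaptive
force study holds the joint at 0.3 so a gravitational sag pushes the mossy
activity into the low band, depressing mossy→DCN, lowering DCN output,
disinhibiting the flexor and restoring posture; at offset the synapse
relaxes back and the DCN returns to its pre-force level.  At mid-range
operating points (0.5) no rule can trigger on level and only the feedback
loop opposes the force.

## Temporal summation

The 500 Hz engine carries a per-neuron "neurotransmitter effect" in
[−1, 1].  A neuron fires iff carried effect + current drive exceeds DT
*and* the carried effect is non-negative; firing writes −1 (refractory
lockout until decay restores 0), otherwise the subthreshold sum is kept.
Either way the stored effect is scaled by `decay = (refractory − step) /
refractory` — 1/3 at the 3 ms / 2 ms defaults (the source's summary table
prints 2/3, which corresponds to a 1 ms step; we implement the formula and
expose an override).  The lockout lasts one intervening sample, so spikes
are at least 4 ms apart — beyond the 3 ms absolute refractory period — and
with decay forced to 0 the engine is statistically identical to the
memoryless circuit (verified).  At matched afferent rates the two engines'
output frequencies agree to ≈ 18% at 20–40 Hz; the gap grows with rate
(≈ 24% at 80–100 Hz) because refractory occupancy rises, so the
cross-engine consistency check is pinned at 30 Hz.

## Perturbation presets

All presets are pure config transforms.  Micro-complex loss overrides the
circuit count.  KCNA1 (Kv1.1 loss of function) scales the interneuron DT
(default ×0.5), raising interneuron firing, suppressing Purkinje cells and
disinhibiting the DCN.  CACNA1A scales the CaV2.1-dependent synapses —
granule-cell efferents, climbing-fibre efferents and Purkinje→DCN — by 0.35
(tottering, 65% release reduction) or 0.15 (rocker, 85%).  Ethanol scales
the GABAergic synapses (Golgi→granule, interneuron→Purkinje, Purkinje→DCN)
up (default 1.5) and the glutamatergic ones down (default 0.8, "to a lesser
extent"); both magnitudes are exposed since only directions are reported.
The DCN-bias preset adds a signed offset to DT_dcn — tonic inhibition
(positive, gravity compensation) or disinhibition (negative).

Severity ordering for CACNA1A is assessed on the DCN transfer map
aggregated over the input grid (mean |Δ| 0.059 rocker vs 0.049 tottering on
a 9×9 grid) because the per-cell deviation is not monotone in severity —
the mutation cuts both the excitatory drive and the Purkinje inhibition.

## Analysis metrics

Intention tremor is the centred moving variance of joint position: the
5-sample moving mean, then the 5-sample moving average of squared
deviations of each sample from its own moving mean.  Edges are truncated
with the divisor equal to the samples actually summed (no data are
fabricated beyond the series).  Tremor medians can degenerate to zero when
the clamped joint dwells at a rail, so comparisons use full movement
cycles.

Spectrograms use generalized Morse wavelets (γ = 3, time-bandwidth 120,
i.e. β = 40), evaluated analytically in the frequency domain and applied by
FFT, 10 voices per octave over 0.5–100 Hz.  This wavelet family is
implemented in-package.

The SCFH sweep maps mean DCN firing probability over the (mossy, climbing)
grid through the analytic marginal (fast path) or the population simulator
(validation path, 10-sample burn-in); `|DCN − CF|` and its per-row argmin
give the central-frequency curve.  The mean relative asymmetry of
`|DCN − CF|` about that curve is 0.12 on the default 21-point grid (test
bound 0.2, frozen from the analytic run).

The circuit-requirement search finds, per muscle strength, the minimal
population whose mean tremor meets a threshold (the mean tremor of a
reference high-n run) in k of k seeded replicates (default 3), by doubling
then bisection to ~12% resolution; non-convergence at the cap is reported
as censored.  A 6th-order polynomial fit of the resulting curve is
provided.

## Scales used by the bundled experiments

The experiment runners default to 1e4 parallel circuits and ≤ 3500 samples
(about a minute each on one CPU); `--paper-scale` restores 1e5.  The
analytic fast path replaces brute force for the input-grid maps, which were
originally computed at 1e6 circuits, and the simulation path validates it
at reduced scale.

## What the synthetic conditions do and do not show

All inputs are generated: sinusoidal/constant/step targets, Bernoulli
afferents, constant forces.  Passing tests show the implementation's
internal consistency (simulator = oracle), the direction and ordering of
the model’s characteristic phenomena at reduced scale, and exact reproduction of the
printed worked examples.  They do not validate the model against
physiological recordings, real proprioceptor encodings, or muscle dynamics
(no fatigue, friction, conduction delay or muscle imbalance — config hooks
only).

## Known limitations

* The ethanol arms reproduce the error (dysmetria) directions but not a
  tremor increase under GABA facilitation: suppressing DCN activity lowers comparator
  throughput and hence per-sample power jitter, so GABA-up *reduces*
  windowed tremor here.  No mechanism in the implemented equations produces
  the opposite sign; the corresponding end-to-end test asserts
  that direction and is expected to fail.
* One interneuron type stands in for basket/stellate cells; the KCNA1
  preset targets it.
* Micro complexes are fully independent; no inter-complex connectivity.
* The temporal engine's refractory cost makes its rates systematically
  ~20% below the memoryless engine at high afferent rates.
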