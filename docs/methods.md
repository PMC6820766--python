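# Methods

## The circuit model

The core of the package is a two-dimensional spiking circuit: an `N x N`
periodic square lattice of conductance-based exponential integrate-and-fire
(EIF) neurons, 75% excitatory and 25% inhibitory, the inhibitory neurons
occupying the even-even sublattice so their spacing is twice the excitatory
spacing.  Each site's membrane potential obeys

    C dV/dt = -g_L (V - V_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
              - g_E (V - V_E) - g_I (V - V_I) + I,

with a spike cut at -40 mV, reset to -70 mV and a 5-ms absolute refractory
period during which the voltage is held at reset.  Synaptic conductances
are a tonic drive (F_E = F_I = 0.01 uS) plus sums over afferent spikes of
normalized difference-of-exponentials responses
`G(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r)` (rise 0.3 ms;
decay 2 ms excitatory, 3 ms inhibitory).  Excitatory coupling falls off as
`W_E * exp(-d^2 / sigma_E)` with `sigma_E = 18` and `W_E = 0.2235` uS;
inhibitory coupling is flat at `W_I = 0.0578` uS.  Both are cut off at a
Euclidean (minimum-image) distance of 45 grid points, giving each neuron
about 6,360 connections.  One grid spacing corresponds to 6.1e-3 mm of
cortex (62,500 neurons ~ a 2.36 mm^2 patch at layer-2/3 densities).

Integration is forward Euler at dt = 0.1 ms.  Synaptic state uses two
exponentially decaying accumulators per conductance type with per-step
decay factors `exp(-dt/tau)`; because the decay is applied exactly, the
conductance at any sampled step equals the analytic sum of `G` responses
to all past spikes to machine precision (the test suite holds this to
1e-9 uS against a per-pair quadratic reference).  Spike kernels are
stamped after all sites have decayed, so results are independent of the
site iteration order.  Initial voltages are drawn uniformly between rest
(-75.625 mV) and threshold (-40 mV); every run discards a 1.5-s transient.
The default model is deterministic given the seed; optional Gaussian
white/pink noise perturbs the tonic drive F_E, and optional Poisson
background spikes arrive as excitatory events of weight W_E at single
sites.

Numerical notes and choices made where the formulation was open:

* The difference-of-exponentials is implemented with decaying (negative)
  exponents, the only bounded reading.
* The Gaussian coupling exponent divides by `sigma_E` itself, exactly as
  specified.  We verified the alternative reading (`sigma_E` as a Gaussian
  s.d., i.e. dividing by its square) empirically: it drives every neuron
  to its refractory-limited maximum rate (~196 Hz) and destroys the
  localized-pattern regime, so the literal reading is the physical one.
* Self-connections are excluded; no synaptic delays.
* The exponential nonlinearity argument is capped at 30 before
  exponentiation; a spike fires long before the cap can distort dynamics,
  and non-finite voltages abort the run naming the offending site.

With the default parameters the network settles into coexisting localized
activity patterns - slowly wandering patchy blobs and fast crescent waves -
at a population rate near 10 Hz.

## Stimuli

Input images pass a Difference-of-Gaussians filter (s.d. 1 and 2 px,
reflective borders), are resized bilinearly to the lattice, normalized,
scaled to `S` (default 0.5 nA) and switched on as a Heaviside step at
t_onset (default 2 s).  Because a DoG output is a zero-sum band-pass
signal whose plain mean is a boundary artifact, normalization divides by
the mean *absolute* value (identical to the plain mean for non-negative
fields); negative values pass through unrectified.

The synthetic face generator stands in for a normalized face-photograph
set that could not be redistributed; the stand-in status is flagged in its
docstring.  Each face is a smooth oval outline plus fine-contrast texture
patches at RoI anchors (eyes/nose/mouth analogues), jittered per seed.
After DoG filtering the intensity magnitude peaks at the RoIs and decays
with distance, which is the property that makes patterns drift toward and
get trapped at RoIs.  What the generator does **not** emulate: realistic
face photometry, hair/background clutter, or inter-feature correlations of
real faces; tests passing on these stimuli show that the modulation
machinery works on RoI-structured inputs, not that the specific published
percentages transfer to any natural-image ensemble.

## Patterns, cascades and criticality

Patterns are 8-connected components (periodic wrap) of the spike image in
5-ms windows.  Shape is classified by the Euler characteristic of the
recentered mask (8-connected foreground, 4-connected background): simply
connected patterns (chi = 1) are crescents, patterns with holes are
patchy.  The local order parameter |phi| is the magnitude of the mean
azimuth phasor of member spikes about the pattern's center of mass
(computed by circular-mean embedding to respect the torus).  Tracking uses
greedy nearest-COM matching with a 10-grid-point gate per 5-ms window;
velocities are minimum-image displacements per window.  The collective
order parameter Phi, the speed-heterogeneity index H (population variance,
1/N normalization) and the distance-binned velocity-fluctuation
correlation C(r) (bins of 10 grid points; normalized by the mean squared
fluctuation; correlation length xi = first zero crossing) follow from the
tracked velocities.

Cascades are chains of 1-ms spike clusters (4-connectivity, i.e. radius
r_S = 1).  A cluster joins the live cascade whose previous COM is nearest
within r_T = 5 grid points; a cascade may absorb several clusters per step
(localized patterns fragment at 1-ms resolution), a cluster joins exactly
one cascade, and an unextended cascade dies - which is how a collision
between two cascades terminates one of them.  Cascades touching the
analysis-window boundary are censored from the distributions.  Size and
duration distributions are fitted with the discrete truncated power law
`f(x) = x^-beta / sum_{k=x_min}^{x_max} k^-beta` by maximum likelihood,
with `x_min` chosen to minimize the discrete Kolmogorov-Smirnov distance
(scanned over `x_min <= 50`; fits in practice select small cutoffs on
clean power-law data) and `x_max` the largest observation.  Vuong
log-likelihood-ratio tests compare the fit against discretized normal,
lognormal, gamma and exponential alternatives fitted by MLE on the same
tail; "power law preferred" means no alternative is significantly better
(the lognormal family contains a power-law-mimicking degenerate limit, so
a near-zero lognormal LLR is the expected outcome even for exact
power-law data).

The wave-participation statistic counts, per wave, the distinct neurons
that spiked in it as a fraction of the full 250 x 250 circuit.  A "wave"
is a tracked pattern persisting for at least two detection windows - the
minimal requirement for a propagating object (it must have a measurable
velocity); single-window blips are transient fluctuations, not waves.

## Modulation analyses

The shape modulation index eta compares the pattern-averaged |phi| in a
50-ms-binned spontaneous span against the 25-75-ms post-onset window; the
rate index zeta compares population rates 250 ms before/after onset (both
as normalized differences, spontaneous minus evoked).  Fano factors use
250-ms windows slid by 10 ms and the unbiased variance across trials;
mean-matching bins trial-mean rates at 10 Hz, takes the greatest common
histogram across time points and subsamples neurons per bin (averaged over
20 random subsamples) so FF dynamics cannot be a trivial rate effect.

A pattern is "trapped" when its tracked COM stays within one RoI radius
for a dwell time (50 ms at full scale, shorter in scaled runs - the
criterion is configurable; it is our operationalization, the notion is not
formally defined elsewhere).  Response time is onset-to-first-trapping;
trials that never trap are right-censored and reported separately.  The
modulated-spike fraction attributes a post-onset spike to modulation when
its pattern's trajectory lineage began before onset.  Spontaneous-evoked
coupling samples 52 neurons near RoIs and correlates, across trials, the
pre-onset mean Vm over T with (i) the post-onset mean Vm over T, (ii) the
spike count in 2T, (iii) the first-spike latency, where T is the trial's
trapping time bounded to [2, 120] ms; shuffling spontaneous Vm among
neurons is the null control.

## Decoding and bubbles

Population decoding sums the spike counts of 100 neurons sampled under the
best bubble mask into 200-ms bins slid by 50 ms, classifies each held-out
trial per bin by smallest distance to class templates averaged over
bootstrapped sub-training sets (B = 10 votes), and estimates decoding
latency as the earliest post-onset bin whose accuracy exceeds the
(1 - 0.05/N_b) quantile of a label-permutation null (Bonferroni over the
N_b post-onset bins; the permutation decoding defaults to B = 1 for
tractability of the 1000-permutation null).  The control condition
permutes the membrane potentials among all sites at stimulus onset,
destroying the spatial organization of the spontaneous patterns while
preserving the voltage distribution.

Bubble masks are planes punctured by 13-17 Gaussian windows (s.d. = the
coupling range D_E, scaled with the lattice), clipped to [0, 1] where
bubbles overlap.  The ideal observer scores a mask by the mean pairwise
2D Pearson correlation of the element-wise masked face set and keeps the
minimizer.  Trapped evoked patterns are converted to the same
representation (unit Gaussians at trapped COMs inside the face outline,
clipped) and compared with the best mask by 2D Pearson correlation.

## The walker model

The modulation of a single pattern toward an RoI is abstracted as an
overdamped walker at distance x with dx = -(theta/x) dt + sqrt(2 Dc) dW:
the logarithmic potential U = theta*ln x captures a pull that strengthens
with proximity.  Defaults theta = 1, Dc = 1 grid^2/ms, absorbing radius 1,
reflecting boundary at 125 grid points (half the lattice).  For theta = 0
the first-passage density has the classical -3/2 tail, which the suite
verifies against the Levy-Smirnov closed form; theta > 0 steepens the
tail while keeping it scale-free, which is the model's account of the
power-law-tailed response times.

## Problem sizes used by the test suite and acceptance script

The packaged analyses run at the full published scale (N = 250, >= 10 s
of post-transient activity, 10^6 bubble masks, 250 trials) when invoked
with their defaults or via the recipes.  The test suite and the
acceptance script exercise the same code paths at the sizes we consider
adequate for their purpose: criticality statistics from a single
N = 250 x 11.5 s run (acceptance) or N = 150 x 10 s (in-suite),
modulation statistics at N = 150 with 10-16 trials and 600-800 masks,
decoding with 4 synthetic faces and leave-one-out over 2 trials per face.
N = 150 is the smallest lattice that leaves the modulation physics
intact: below it the 45-grid-point inhibitory range wraps far enough
around the torus that stimuli suppress rather than excite their RoIs.
At the reduced sizes the qualitative orderings (modulated vs control
decodability, coupling signs, scale-free response-time tails) hold,
while the cascade exponents and the wave-participation mean carry
noticeable seed-to-seed spread (see Limitations).

## Known limitations

* The cascade size/duration distributions of this reimplementation are
  not as cleanly scale-free as the published ones: the KS-optimal lower
  cutoff drifts with the seed and the fitted exponents scatter by a few
  tenths around ~2 (size) and ~2.2 (duration).  The pattern dynamics also
  show long-lived regime fluctuations (pattern counts varying ~2x between
  seeds over 10-s spans), which the wave-participation statistic
  inherits.  We attribute this to unpublished implementation details of
  the original cascade tracker (cluster-to-cascade assignment and
  fragment handling at 1-ms resolution are stated only loosely) rather
  than to the circuit itself, whose qualitative regime structure (patchy
  vs critical vs wave states, localized ~10 Hz activity, RoI trapping)
  reproduces well.
* The trapping criterion, the modulated-fraction attribution and the
  STA patch-spacing procedure are declared operationalizations; published
  values for the corresponding statistics were obtained with unspecified
  procedures.
* Synthetic faces are a stand-in ensemble (see Stimuli).
* The permutation null for decoding latency uses single-vote decoding by
  default; with the full B the null would be marginally tighter.
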