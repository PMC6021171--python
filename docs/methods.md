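# Methods

This note records the models implemented in `plugdyn`, the choices made
where the underlying methods leave room, and what the synthetic-data tests
do and do not demonstrate.

## Synthetic confocal photon streams

`simulate_confocal_photons` emulates a µsALEX measurement of ~100 nm
proteoliposomes carrying zero or one two-state emitter.

* **Diffusion.** Discrete-time Brownian steps (default Δt = 10 µs) in a
  periodic box centred on the focus. Box sides default to 14× the lateral
  waist (x, y) and 4× the axial waist (z); with two particles per box this
  puts the detection-volume occupancy near 0.03, a dilution at which more
  than 90 % of burst pairs within 80 ms originate from the same particle
  (verified against the simulator's particle bookkeeping) — the regime the
  recurrence analysis requires. The default diffusion coefficient,
  4.4 µm²/s, is the Stokes–Einstein value for a 100 nm vesicle in water at
  25 °C.
* **Detection.** 3D-Gaussian profile with 0.35 µm lateral / 1.5 µm axial
  1/e² waists (conventional confocal values; both configurable). Peak
  detected count rate defaults to 150 kHz per excitation branch.
* **Emission.** Photons are generated by Poisson thinning of a
  dominating rate, so each timestamp is exactly consistent with its ALEX
  slot (40 µs period, 40 % donor duty cycle, slot = timestamp modulo
  period). During donor excitation a photon lands in the acceptor channel
  with probability equal to the current state's E (0.2 open / 0.4 closed);
  acceptor-excitation signal photons all go to the acceptor channel. The
  state path is an exactly sampled continuous-time Markov chain; the
  brightness ratio ε between states scales the donor-excitation intensity.
* **Background.** Homogeneous Poisson, default 1.5 kHz per detector
  channel.
* **Ground truth** (per-photon particle id and state, full state paths) is
  carried on the returned stream; background photons have id −1.

Not modelled: optical point-spread physics, polarisation, triplet
photophysics, vesicle polydispersity, detector dead time or afterpulsing.
Passing tests therefore show the *estimators* are correct under the
model's assumptions, not that real detectors introduce no further biases.

## Synthetic TIRF traces

`simulate_tirf_traces` alternates exponential closed dwells and gamma open
dwells with mean `offset + length/rate` (shape 4). Defaults are the
no-chaperone translocation condition: rate 39.6 aa/s, offset 4.7 s,
substrate lengths 100/233/354/683 aa. The closed-dwell mean defaults to
8 s — comparable to the open dwells, as in published example traces, and
long relative to the 0.2 s frame so that sub-frame closed visits are rare.
Each dye photobleaches at an exponential time (mean 60 s); the first
bleach truncates the usable trace with a single-step intensity drop
(acceptor bleach also restores the full donor signal). Noise is
EMCCD-like — Gaussian read noise plus scaled-Poisson shot noise with the
variance split evenly — and the SNR knob is defined as the open↔closed
intensity step divided by the per-frame noise SD (default 3, i.e. E-noise
≈ 0.067 for a 0.2 step).

## Burst analysis

* **Background estimation**: maximum-likelihood exponential fit to
  inter-photon delays per 10 s window and per channel×slot sub-stream.
  Burst photons are excluded by fitting only delays above a threshold set
  to twice the current mean-delay estimate (two refinement passes),
  exploiting the memorylessness of the exponential tail.
* **DCBS**: a burst requires the local rate over m = 10 consecutive
  photons to exceed F = 6× the local background simultaneously in the
  donor-excitation stream and the acceptor-excitation acceptor stream,
  evaluated at every photon (sliding window). The burst interval is the
  intersection of the two hot spans; counts are split by channel×slot and
  background-corrected with the local rates. m, F and the minimum burst
  size (30) are conventions, exposed in configuration.
* **E/S**: proximity ratio and stoichiometry always come from
  background-corrected counts; the γ/leakage/direct-excitation correction
  is applied at the population level (per-burst count transform, never
  per-photon reweighting) and defaults to the identity (l = d = 0, γ = 1)
  — calibration factors are inputs, not estimated here. The S window
  0.25–0.75 is applied as a closed interval.

## RASP

* **P_same** is estimated as 1 − 1/g from direct pair counting of burst
  times in 1 ms bins, normalised by the Poisson expectation; lookups use a
  ±5 ms local average because single bins are Poisson-noisy at high
  dilution.
* **Recurrence clock.** Pair selection uses the gap between the end of the
  initial burst and the start of the second (the interval during which the
  molecule is unobserved); this is also what makes sub-millisecond pairs
  from recurrence trains observable at all. Because bursts here last
  several milliseconds — comparable to 1/λ — the state also evolves
  *during* the bursts. Two measures keep the kinetic clock honest: E(b1)
  is estimated from the last 30 donor-excitation photons of the initial
  burst and E(b2) from the first 30 of the second (background-subtracted
  over each window's span), and the model is evaluated at the mean
  measurement-window-to-measurement-window time of each interval's pairs.
* **Peak decomposition.** Each recurrence histogram is decomposed into two
  Gaussians fixed at the state E values with widths set by the binomial
  shot noise of the 30-photon estimate (plus a small intrinsic width);
  only the weights are free per interval (non-negative least squares).
  pA_new — the state-A probability of newly arriving molecules — is
  determined from the same decomposition applied to all bursts (the
  globally fitted areas), not fit as a free parameter; since a recurring
  molecule at τ→∞ carries the same equilibrium marginal, ρA_eq is tied to
  the same number by default (`fix_rho_eq`), leaving λ and the initial
  conditional probabilities free.
* **Detailed balance.** At equilibrium the time-reversed selection
  (initial window on the *later* burst's entry segment, histogramming the
  earlier burst's exit segment) is statistically equivalent and is fit
  jointly by default, roughly doubling the pair count; a second initial-E
  window mirrored onto the other state's peak is fit jointly as well,
  sharing λ and the equilibrium.
* **Uncertainties**: percentile bootstrap over bursts (default 200
  resamples), which correctly propagates the strong correlation of pairs
  within recurrence trains.
* ε (the state brightness ratio entering pA_recur) defaults to 1; it is a
  free input, not estimated.

Known limitation: with burst durations of order 1/λ the head/tail windows
still average over some state evolution, which attenuates the apparent
initial contrast (absorbed by ρA(0)) and leaves a residual upward bias of
order 10 % on λ at λ ≈ 200 s⁻¹; recovered time constants carry bootstrap
CIs that cover this.

## BVA

Sub-bursts are consecutive windows of exactly n = 5 donor-excitation
photons (the trailing remainder is dropped; bursts with fewer than two
windows are excluded); a time-based partitioner (default 0.1 ms windows)
is provided for probing a fixed timescale. The empirical SD uses the
population denominator to match the Monte Carlo reference, which replays
each proximity-ratio bin's exact window structure with binomial draws
(999 replicates) and takes the (1 − α) quantile, α = 0.001. BVA operates
on raw proximity ratios only — corrected E would bias the variance — and
the entry points require photon-backed burst sets, refusing table-only
input.

## TIRF analysis

* **QC.** Median pre-bleach S within 0.25–0.75; donor/acceptor Pearson
  correlation over the pre-bleach trace below −0.3 for traces showing
  provisional transitions (midline-crossing detector; transition-free
  traces pass and are later dropped as non-responsive); bleach steps
  located per dye by a recursive cumulative-sum change-point detector with
  a 4× frame-noise minimum step. Down-steps smaller than half the largest
  one are treated as noise artefacts, not extra emitters; more than one
  emitter-scale down-step per dye excludes the trace. The whole-trace
  correlation replaced a transition-local statistic that proved badly
  diluted by false transition candidates at realistic noise.
* **Segmentation**: per-trace two-state Gaussian HMM on E (means
  initialised at 0.2/0.4, all parameters refined by EM, Viterbi decoding;
  lower-mean state = open). Terminal dwells are censored; traces with no
  decoded transition are non-responsive and excluded from state
  statistics, which also removes the inverted (inward-facing) population
  in reconstituted samples. Histogram-level removal of that population is
  available as `correct_orientation_histogram` (subtract the scaled
  reference distribution, clip, renormalise; inverted fraction defaults
  to 0.5).
* **Photobleach distribution**: exponential MLE with right-censored
  entries for traces that never bleach, made robust to the QC's
  preferential removal of early bleachers by fitting only above a 10 s
  threshold (memorylessness makes this unbiased under any selection below
  it).
* **Length regression**: every uncensored open dwell is a point, weighted
  by 1/S_photobleach(duration) (inverse probability of censoring); the
  covariance is clustered by trace. Sub-resolution closed visits merge
  flanking open dwells; the missed fraction is extrapolated from the
  exponential fit to resolvable closed dwells and the slope/intercept are
  corrected analytically (observed mean = (1+p)·true + p·closed-mean).
  Residual segmentation artefacts (spurious chops of long dwells) leave a
  small upward bias (~5 %) on the recovered rate at the default
  conditions; the intercepts are unbiased within their errors.
* **Eq-style deconvolution**: the censored-gamma reconvolution fits a
  two-parameter gamma (shape and scale both free — a unit-scale template
  alone would fix the time unit arbitrarily) whose predicted observed
  density gamma·S_photobleach best matches the dwell histogram; a
  regularised non-negative reconstruction (second-difference penalty,
  weight 10⁻³) is exposed alongside.

## Dye accessible volumes

AV1-style Monte Carlo: uniform candidates in the linker-length sphere
(default 20 Å length, 4.5 Å width, 3.5 Å dye radius — typical maleimide
linker values), rejected on vdW clash (per-element radii, dye radius
added) or when a straight linker segment to the candidate lacks half-width
clearance. Acceptance is deterministic given the seed. Residue mapping
onto homolog structures is user input, not computed. Distances convert to
E via 1/(1+(r/R₀)⁶) with R₀ = 6 nm for the Alexa 488/594 pair.

## Problem sizes in the recovery checks

The acceptance computations use ~300 observed open dwells per substrate
length (trace counts scaled per length to offset photobleaching losses)
for the translocation-rate recovery, 50 replicates × 7 ATP levels, 20
replicates × 5 temperatures, and a 2400 s confocal stream (~12 000
filtered bursts) for the kinetic recovery — sizes chosen so each
estimator's statistical error is comfortably below the quantity being
recovered while the whole script completes in minutes on one CPU. The
same pipelines accept arbitrarily larger inputs.

## Open choices made here

* The "within 0.25–0.75" stoichiometry window is applied closed on both
  ends; boundary bursts are vanishingly rare.
* Recurrence intervals default to 8 logarithmic bins over 0.5–80 ms, the
  usable window set by the same-molecule probability.
* The kinetic-recovery condition uses a 0.25 µm lateral waist and a
  10×-waist box — a smaller focus shortens transits (less within-burst
  state averaging) and yields the pair statistics the fit needs within a
  desk-scale simulation; the generator's dilution default (14×) is the
  more conservative regime used for the recurrence-probability property.
* Sub-burst photon count n = 5: millisecond bursts carry too few
  donor-excitation photons for the larger windows sometimes used on
  slower systems; the 0.1 ms time-window partitioner probes the
  sub-millisecond scale explicitly.
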