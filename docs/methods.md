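# Methods

This note documents the models and numerical procedures implemented in
`agecircuit`, the assumptions behind them, and what the synthetic circuit
does and does not emulate.

## Aging-mechanism parameterization

Three cellular/synaptic aging mechanisms are modeled as linear functions of
an age offset in years relative to a middle-aged (~50 y) reference:

| mechanism | rate | scalar applied |
|---|---|---|
| SST / VIP / PV interneuron loss | 1.21 / 0.88 / 0.52 %/y | survival fraction on interneuron counts |
| NMDA receptor loss | 2.5 %/y | multiplier on NMDA conductance onto Pyr (recurrent and stimulus synapses) |
| Spine loss | 1 %/y | multiplier on Pyr→Pyr connection probability |

All losses clamp at total loss; profiles are evaluated by default at
+20 years (the "older" condition). The PV loss over 20 years is carried at
the rate's exact value (10.4%) rather than a rounded 10.3%.

Spine loss additionally reduces the Pyr dendritic leak conductance and
membrane capacitance through a surface-area argument: spine loss with age
is predominantly loss of thin spines, which make up 25% of spines in older
tissue and hence 25%/(1−0.20) = 31.25% at middle age. With 8169 spines per
neuron, a thin-spine geometry of a truncated cone (length 1.2 μm, tip
diameter 0.35 μm, base diameter half the tip diameter) plus the tip
end-cap disc, the thin-spine membrane is ≈2779 μm², i.e. ≈8.6% of the
total spine + dendrite membrane (11,954 + 20,410 μm²). Losing 20% of
spines — all thin — therefore removes ≈1.72% of the membrane, and G_pas
and c_m of Pyr cells are scaled by 0.9828. The cone orientation (base
smaller than tip) is the reading that reproduces the published area to
0.15%; the alternative reading misses by roughly a factor of two.

## Reduced spiking microcircuit

The circuit is a conductance-based leaky integrate-and-fire network with
four populations at human L2/3 proportions (80% Pyr, 5% SST, 7% PV, 8%
VIP) and the canonical connectivity motif (Pyr→all; SST→Pyr apical;
PV→Pyr basal; VIP→SST; VIP→PV). It replaces a morphologically detailed
compartmental model, so all of its absolute magnitudes (rates in part,
EEG magnitudes entirely) are surrogate-scale; the pipeline around it is
magnitude-agnostic and the scientific claims carried by the package are
claims about directions of effects and about the analysis machinery.

Synapses are double-exponential conductances: NMDA τ_rise/τ_decay =
2/65 ms with a Jahr–Stevens magnesium block (1 mM), AMPA 0.3/3 ms, GABA_A
1/10 ms. Excitatory recurrent synapses carry both AMPA and NMDA peaks.
Connection probabilities and peak conductances are configuration tables,
defined at a 1000-neuron reference network; weights scale as 1/N so the
mean input per neuron is invariant to the simulated size (experiments here
use 400–1000 neurons).

Key dynamical choices, made so that the network sits in a fluctuation-
driven, inhibition-stabilized regime with Pyr baseline near 1 Hz and
CV(ISI) > 0.5, and so that the five aging conditions separate in the
directions the mechanisms imply:

* **Background drive.** One independent excitatory Ornstein–Uhlenbeck
  conductance per neuron (τ = 5 ms, floored at zero). SST cells are driven
  mostly by their OU input rather than by Pyr feedback, so interneuron
  *count* loss translates directly into lost tonic inhibition instead of
  being compensated by the feedback loop.
* **Recurrent NMDA share.** A large fraction of recurrent Pyr→Pyr drive is
  NMDA (peak ratio NMDA:AMPA ≈ 3), so halving NMDA conductance measurably
  lowers baseline and evoked rates.
* **Spike-frequency adaptation** on Pyr (and weakly SST/VIP) cells: an
  adaptation conductance (reversal −90 mV, τ = 250 ms for Pyr) incremented
  at each spike. Without it, strong stimulation tips the network into a
  persistent up-state; with it, evoked reverberation terminates within
  ~100–200 ms, which is essential for clean pre-stimulus baselines in the
  decoding protocol.
* **Burst-selective PV brake.** PV cells are nearly silent at baseline
  (weak OU) but strongly recruited by Pyr activity and strongly inhibitory
  in return, capping population bursts without adding tonic inhibition.
* **Alpha-band drive.** A reduced point-neuron L2/3 network does not
  generate an alpha rhythm intrinsically. The circuit therefore receives a
  weak *common* alpha-band conductance modulation on Pyr cells — a
  noise-driven damped harmonic resonator (10 Hz, relative damping 0.15,
  unit variance, 0.25 nS gain) shared across cells — standing in for
  rhythmic thalamocortical input. Because it is coherent across neurons it
  dominates the dipole at ~10 Hz, giving the EEG spectrum its periodic
  alpha peak on top of the 1/f background produced by irregular synaptic
  activity. Consequence: the alpha peak's *center frequency* is anchored
  near 10 Hz by construction, and mechanism effects on peak frequency are
  much weaker than in a circuit whose rhythm is emergent.

Stimulus protocols follow the study design: a brief feedforward stimulus
(55 Pyr at 4 nS with 2–4 ms delays; 35 PV at 2 nS; 65 early VIP at 2.8 nS;
80 late VIP at 2.2 nS, 7–12 ms) and a stronger, de-correlated stimulus (PV
stimulation removed; VIP conductances doubled; Pyr excitation prolonged to
2–22 ms with doubled synapse count at 2 nS). Two translation choices map
these dendritic conductances onto point neurons: a somatic-efficacy factor
of 0.3 (dendritic attenuation), and an NMDA-rich stimulus composition
(NMDA:AMPA peak ratio 2, consistent with basal-dendrite targeting), which
places the 25–75 ms response window under NMDA control. Target cells are a
fixed random subset per circuit; per-neuron delays are redrawn each trial.
Requested target counts are capped at the available population size.

Integration is forward-Euler at dt = 0.05 ms (configurable; AMPA rise is
resolved by 6 steps), with exact-discretization OU updates, bit-exact
reproducibility under a fixed seed, and a runtime error naming the first
step at which a non-finite state appears. The current-dipole proxy is the
sum of Pyr synaptic currents weighted by signed depth offsets per synapse
class (recurrent/stimulus excitation and PV inhibition basal at −150 μm;
SST inhibition apical at +300 μm; OU drive at +150 μm), boxcar-decimated
to 2 kHz. An open-loop replay mode recomputes the dipole from frozen spike
trains at resting driving force; it is exactly linear in the synaptic
weights and serves as the linearity check.

## Four-sphere EEG forward model

The scalp potential of a current dipole in the brain shell is computed
from the standard four-concentric-shell volume conductor (brain / CSF /
skull / scalp radii 79/80/85/90 mm; conductivities 0.047/1.71/0.02/0.41
S/m, used exactly as specified for the study even where other literature
differs). For each Legendre order the radial two-point boundary-value
problem (potential and radial current continuity at the three interfaces,
zero radial current at the scalp) is solved as a 7×7 linear system with
per-shell-normalized radial basis functions — numerically stable to high
order — and the series is truncated adaptively when the last terms fall
below 10⁻¹² of the accumulated sum. The dipole sits radially at 78 mm
under a vertex electrode by default (a cortical column directly beneath
the electrode). Validation is against a closed-form homogeneous-sphere
solution derived independently by generating-function summation of the
point-source series plus a numerical source-position derivative; with
equal conductivities the two agree to ~10⁻⁸ relative.

## Spectral biomarkers

The EEG trace is converted to a PSD by Welch's method (2-s Hann windows,
50% overlap, constant detrend, 0.5 Hz resolution). Spectral
parameterization fits, in log10-power versus linear frequency over
3–30 Hz: a 1/f aperiodic component (offset, exponent; "fixed" mode, no
knee), and up to 3 Gaussian periodic peaks with bandwidth clamped to
[2, 6] Hz, accepted above 2 residual SD, fitted jointly and subtracted
before the final aperiodic refit. On the synthetic 1/f + Gaussian family
the fit recovers offset and exponent with MAE < 0.05 and peak center
frequency with MAE < 0.3 Hz. Band areas use trapezoidal integration with
interpolated edges (θ 4–8, α 8–12, β 12–30 Hz — the conventional ranges
consistent with the 3–30 Hz window); the aperiodic area ("1/f AUC") uses
the closed form of ∫10^b f^(−χ) df with the χ = 1 logarithmic case
handled separately.

Oscillation events are detected on a complex-Morlet spectrogram (7
cycles; 1–100 Hz in 0.5 Hz steps, capped at 0.45·fs) normalized per
frequency row by its median power. Connected regions above 4× the median
form candidate bounding boxes; boxes overlapping ≥ 50% of the smaller box
merge. Because median-thresholded colored noise exceeds a 4× threshold on
a few percent of smoothed pixels, candidates are accepted only if their
peak power also reaches 40× the median and their duration spans ≥ 3 cycles
at the peak frequency (two-threshold hysteresis). Calibrated on pink
noise, this yields no spurious events in 24 s while detecting injected
10-cycle bursts at 10× noise amplitude in 10/10 seeds. Wave height is the
peak-to-trough amplitude (reported in nV) of the zero-phase 4th-order
Butterworth band-filtered signal inside the event window. Analyses here
run at the surrogate's 2 kHz sampling rate; all detector parameters are
expressed in physical units (Hz, s, cycles), so no rate-dependent
rescaling is needed.

## Function metrics

Signal-detection error is the percent overlap between the distribution of
Pyr population rates at baseline (40 ms windows sliding in 1 ms steps over
3 s pre-stimulus) and the per-trial rates in the 10–50 ms post-stimulus
window of the brief stimulus (20 trials): both samples are histogrammed on
shared equal-width bins (Freedman–Diaconis count, floor of 10 — the
binning is otherwise unspecified) and overlap is 100·Σ min(p̂₁, p̂₂), with
a 1000-resample bootstrap for the interval. Decoding accuracy sums each
Pyr neuron's spikes in 50 ms pre-stimulus and 25–75 ms post-stimulus
windows of the stronger stimulus (40 windows per condition = 20 trials ×
2 window types), trains a classifier (linear SVM C = 1, or a 20-unit
single-hidden-layer ANN) on 70% and tests on 30%, over 100 random
stratified splits. Cohen's d uses the pooled-SD formula with the
(comparison − reference) sign convention, so negative d means a decrease
with aging; group tests are two-sided equal-variance t tests, with
|d| > 0.5 and p < 0.05 flagged jointly.

## Mechanism decoder

A 4→20→20→5 multilayer perceptron (ReLU hidden layers, softmax output)
classifies the EEG feature vector (offset, exponent, peak CF, 1/f AUC)
into the five conditions. Training: Adam with Nesterov momentum (Nadam),
learning rate 0.001, categorical cross-entropy, zero-centered normal
initialization (SD 0.1), batch size 32, at most 100 epochs with early
stopping when full-batch validation loss fails to improve for 10 epochs.
Fifty models are trained on independent random 60/10/30
train/validation/test splits. Features are z-scored by training-split
statistics; an absent peak CF is imputed with the training-split median;
both transforms are stored on the model. The implementation is plain
NumPy, making training bit-reproducible under a fixed seed. Feature
importance is the mean absolute Shapley value of the predicted-class
probability against a fixed background set; with four features the exact
2⁴-coalition enumeration is cheap and doubles as the oracle for the
permutation-sampling approximation.

## Experiment design and problem sizes

The full study design is five conditions × 20 randomized circuits of 1000
neurons, 28 s of resting activity per circuit and 20 trials per stimulus
protocol. The test suite and the acceptance script run a scaled design —
400-neuron circuits, 5 per condition, 8–12 s resting runs, 25 decoding
splits — chosen so the direction-of-effect pattern is resolved at
desk scale. Direction checks use medians across circuits. At this scale
the EEG feature clouds of the five conditions overlap substantially, so
the end-to-end mechanism-decoder accuracy reported by the acceptance
script is far below what a larger design yields; it is reported as
computed. Scaling up is a matter of configuration
(`ExperimentConfig(n_circuits=20, baseline_duration_ms=28000, ...)`).

## Known limitations

* The surrogate reproduces direction patterns, not absolute magnitudes;
  EEG power units are surrogate-scale (offsets near −5 log10 μV² rather
  than the detailed model's −13).
* The alpha peak is injected as common input; effects of aging mechanisms
  on peak center frequency are therefore strongly attenuated.
* Short-term plasticity is not implemented (its parameter values are not
  published for this model family); synapses are static.
* Single-compartment neurons cannot express the dendritic placement of
  the OU drive; it is replaced by one somatic process per neuron plus
  per-population gains, and dendritic attenuation of stimuli is collapsed
  into a single efficacy factor.
* Interneuron deletion is implemented as count reduction (populations are
  homogeneous, so deleting random members and reducing counts coincide).
* The decoding-accuracy direction (older < middle-aged) is the least
  robust effect at the scaled design: the condition effect (~5–9
  percentage points) is comparable to circuit-to-circuit variability.
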