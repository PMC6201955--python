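# Methods

This note documents the models and procedures implemented in `cogmap`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not establish about real recordings.

## The measurement model

A voltage-sensitive-dye recording of one soma is a 20-s fluorescence trace
sampled at 250 frames/s.  Three components are assumed: (i) fast optical
action potentials, heavily undersampled (a spike spans ~4 frames); (ii)
slower membrane-potential changes that are often larger than the spikes;
(iii) slow drift (bleaching, movement) plus white noise.  The analysis
chain mirrors this decomposition:

1. **Drift removal** subtracts the least-squares polynomial of degree 6
   (`poly_degree`, matching the drift model used for rendering).  The
   operation is idempotent and exact for polynomial inputs.
2. **Per-neuron high-pass tuning** selects, from a candidate list (default
   5/10/20/50 Hz), the cutoff maximising
   `score = max|fast band| − max|slow residual|`, where the fast band is
   the zero-phase second-order Butterworth high-pass of the trace and the
   slow residual is its complement.  Ties go to the lowest cutoff.  Spike
   amplitude varies across neurons while subthreshold amplitude varies
   independently, so a single global cutoff is not appropriate.
3. **Detection** thresholds at `threshold_k × median(|x|)/0.6745`
   (`threshold_k = 4`), the robust noise estimate standard in median-based
   spike detection; a spike is a local maximum above threshold, at most one
   per refractory window (4 ms, one frame), with a prominence floor of half
   the threshold to reject noise bumps riding on the decaying flank of a
   preceding spike.  Detected peaks are re-centred within one frame on the
   wideband (pre-filter) trace, since filtering can shift a peak when
   consecutive spike waveforms overlap.
4. **Validation** pairs detected and reference trains greedily by smallest
   absolute latency within a tolerance (one frame); unpaired detected
   spikes are overdetections, unpaired reference spikes underdetections.

At the default rendering SNR of 10 (kernel amplitude 10 × noise SD 1) this
chain attains ~0.97–0.98 recall and precision matched within one frame.
The residual errors are physical, not algorithmic: at 4-ms sampling the
rendered spike peak exceeds its neighbour sample by only ~2.6 noise SDs, so
a few percent of peaks shift by one frame.

## Response classification

For each condition the decision statistic is the trial-averaged spike-count
difference Δ between the 6-s stimulation window (stim_ON) and the 6 s
immediately before (stim_PRE).  A neuron is excited when Δ exceeds a dead
band, inhibited when −Δ does, nonresponsive otherwise.  The dead band is
`max(deadband_floor, z·SE)` with `SE = sqrt((c_PRE + c_ON)/n_trials)`,
floor 1 spike and z = 2.5.  The scaling is necessary: an unchanged neuron
firing at 6 Hz has SD(Δ) ≈ 3.7 spikes even after 6-trial averaging, so any
fixed small dead band mislabels most genuinely unchanged high-rate neurons
as responsive.  z = 2.5 was chosen from a rate-level simulation of the
generator's stated conditions (baselines 0.33–6.8 Hz, evoked 7–14 Hz,
inhibition factor 0.2, 6 trials), giving per-class error ≤ 3%; `z = 0`
restores a fixed absolute dead band.

Rate coding is probed by the frequency ratio f_ON/f_PRE (undefined and
omitted for spontaneously silent neurons) and the frequency difference.
Per-preparation histograms (bin 0.1, from 0 to the maximum observed ratio)
are normalised to their maximum count and averaged across preparations;
conditions are compared with the two-sample Kolmogorov–Smirnov test
(asymptotic p).

Latency is the time from stimulus onset to the first global maximum of the
trial-averaged trace within a 100-ms search window (ties to the earliest
sample), intended for the 1-Hz low-frequency protocol where responses are
pulse-locked.

Modality: multimodal = responsive to both IV and VCN, unimodal = exactly
one, nonparticipant = neither.  Unique responses over {IV, VCN, bimodal}:
a neuron is unique for the condition whose label differs while the other
two agree; neurons with three identical labels are not unique participants
and neurons with three pairwise-distinct labels fit no two-agree pattern —
both are omitted (and counted separately).  Proportions use all scored
neurons as denominator.

## Functional connectivity

Coherence is the Pearson correlation of drift-removed fluorescence traces
over the stimulation window (the functional maps describe activity during
stimulation; the window is configurable).  Zero-variance traces have
undefined correlations, reported as 0 and flagged.  An edge exists when
ρᵢⱼ > 0.45; a correlation t-test gate (df = n − 2, p < 0.05) can be
enabled in addition.  Only positive correlations form edges.  Density is
2m/(K(K−1)); global efficiency is the mean of 1/Lᵢⱼ over ordered pairs
with BFS path lengths and zero contribution from disconnected pairs.
Printed percentages truncate to one decimal (4.240 → 4.2, 2.563 → 2.5),
the convention of the reference values this package reproduces.

## Spatial statistics

The polygon contour around the outer neurons is the convex hull; the
centroid is the polygon-area centroid (vertex mean available as an
option).  d_ratio divides the neuron-to-centroid distance by the distance
from the centroid to the hull boundary *along the ray through the neuron*,
the only reading that bounds interior neurons by 1.  Directional
variability is the circular variance 1 − R̄.  Both are invariant under
translation, rotation and uniform scaling.

## Bimodal congruency

The additive-expectation table maps the 3 × 3 unimodal label pairs to an
expected bimodal label: same signs summate, a response plus no response
keeps its sign, and the two opposite-sign pairs are inconclusive
("no rule"), since the additive outcome would depend on the unknown
weighting of excitation and inhibition.  Scoring is Boolean on labels, not
firing rates — conservative, because frequency responses are rarely
linear.  Verdict proportions are reported per ganglion and sum to 100%.

## Pyloric motor pattern

Bursts are maximal runs of spikes with inter-spike intervals ≤ 0.2 s
(about a fifth of the ~1-s pyloric period) and ≥ 2 spikes; both parameters
are configurable since no standard criterion exists.  Metrics: within-burst
firing frequency (count/duration averaged over bursts), spikes per burst,
burst duration (first to last spike), cycle period (mean interval between
successive PD burst onsets; PD paces the rhythm).  Stimulus effects are
norm. Δ = (stim_POST − stim_PRE)/stim_PRE with bursts starting within an
exclusion gap after stimulus offset dropped (default 1.5 s, inside the
reported 1–2 s range for direct, CoG-independent sensory effects to
dissipate); metrics with no usable bursts or zero pre-value are flagged
undefined (NaN), not errors.

## The synthetic-data generator

The generator's defaults encode the published population statistics:
modality split 0.80/0.18/0.02; IV excitation probability 0.51 given a
response, with the VCN sign obtained by flipping the IV sign with
probability 0.4615 (the sign-switch rate); bimodal labels drawn
independently with proportions 0.5919/0.3356/0.0725, or additively
(`bimodal_rule="additive"`) for congruency closure tests; baselines
uniform on 0.33–6.8 Hz; evoked rates uniform on 7–14 Hz; inhibition scales
baseline by 0.2 (unspecified in the source data; chosen to give
unambiguous count decreases over 6-s windows); latencies truncated-normal
with (29.7, 11.4) ms for IV and (31.9, 7.7) ms for VCN.

Spikes come from a thinning sampler for a piecewise-constant-rate process
with a 10-ms dead time.  The dead time is biological refractoriness (peak
observed rates are ~14 Hz); it also keeps spikes resolvable at the 4-ms
frame interval.  Excited neurons step from baseline to the evoked rate at
onset + latency; under low-frequency protocols (≤ 2 Hz) they instead fire
one pulse-locked spike per pulse at an independently drawn latency — the
regime used for latency measurements.  A trial-to-trial dispersion
parameter for evoked rates exists but defaults to 0, as the source data do
not constrain it.

Rendering places a biexponential kernel (rise 2 ms, decay 8 ms, ~4 frames
wide, peak aligned to the nearest frame) per spike on a random degree-6
polynomial drift scaled to a target peak-to-peak span, plus white Gaussian
noise.  Excited neurons additionally receive a shared slow subthreshold
component during stimulation: a per-sweep smooth drive s(t) (three
random-phase 0.3–2 Hz sinusoids) scaled by the neuron's coupling strength
(uniform 0–1) and `subthreshold_amplitude` (default 10).  This component
is what gives co-activated neurons coherent fluorescence — independent
point processes alone have near-zero pairwise correlation — and it is why
the per-neuron high-pass stage exists.  With the default amplitude,
60-neuron populations yield functional densities of roughly 7 ± 5%,
matching the published few-percent range; global efficiency comes out
around 0.08 ± 0.05, somewhat below the published 0.18–0.25, because
coupling-thresholded graphs are clique-like rather than distributed.  The
same drive modulates evoked rates (depth `common_drive = 0.9`).

Soma positions are uniform inside an elliptical imaged field (192 × 128
image-plane units); no spatial structure is imposed, matching the reported
absence of clustering.

The pyloric generator builds a triphasic rhythm (PD/LP/PY burst-onset
phases 0/0.4/0.7 of the cycle, duty 0.25, 6/8/10 spikes per burst, period
1 s) with Gaussian burst-onset jitter (SD 1% of the period).  Cycles
starting after stimulus offset apply the requested relative changes.
Because spike counts are integers, an injected firing-frequency change is
realised exactly by adjusting the burst duration to the rounded count
(burst duration then changes as a side effect unless also pinned).

### What the generator does not emulate

Trial-to-trial latency drift, bursty baseline firing, dye bleaching
kinetics, optical cross-talk between neighbouring somata, non-Poisson
spike statistics, spatially structured connectivity, and any dependence of
evoked rate on stimulus pulse rate.  Passing recovery tests therefore
shows that the analysis chain is correct under the stated statistical
model, not that it is robust to every pathology of real recordings.

## Numerical choices

Half-open spike-count windows [start, end).  Matching tolerance one frame.
Greedy matching orders candidate pairs by (|latency|, test time, reference
time), making it symmetric under swapping the trains.  Coherence uses a
single vectorised centred cross-product; values are clipped to [−1, 1] and
symmetrised against floating-point asymmetry.  Shortest paths use BFS on
the sparse adjacency.  Degenerate inputs: all-constant traces detect no
spikes (empty train, not an error); a neuron at the centroid has d_ratio 0
and an undefined angle, flagged; fewer than two PD bursts make the cycle
period undefined, flagged.  CSV output uses 12 significant digits so
write→read round-trips stay below 1e−9.  All randomness flows from one
seed; the pipeline manifest records parameters and output hashes.

## Problem sizes

Test-suite and acceptance runs use populations of 60–100 neurons with 1–6
trials and 50-seed null ensembles — sizes chosen to match the scale of a
single imaged ganglion (~80 cells) while keeping each full run in the tens
of seconds.  The published grand averages over 12–19 ganglia derive from
unreleased raw data, so population-level percentages here are
self-consistency checks of the pipeline against its own generator, not
reproductions.

## Known limitations

Detection recall saturates near 0.98 at SNR 10 due to undersampling (see
above).  Global efficiency of synthetic populations is structurally low at
matched density (clique-like graphs).  The correlation significance gate
implements the conventional t-test; the exact procedure paired with the
0.45 threshold in the source analyses is not described, so the gate is off
by default and not asserted as equivalent.  The unique-response rule for
three pairwise-distinct labels is undefined in the source description;
such neurons are omitted and counted.
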