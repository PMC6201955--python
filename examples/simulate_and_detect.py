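"""Generate a labelled synthetic population and detect its optical spikes.

Renders fluorescence sweeps (250 frames/s, 20 s) for a small commissural
population, runs drift removal + per-neuron high-pass tuning + median-based
thresholding, and validates the detected trains against the generator's
ground truth.
"""

import numpy as np

from cogmap.synthetic_data import (
    PopulationSpec, TraceNoiseSpec, default_protocols, generate_population,
)
from cogmap.trace_processing import (
    DetectionParams, SpikeTrain, match_spike_trains, process_trace,
)

spec = PopulationSpec(n_neurons=12, seed=1)
noise = TraceNoiseSpec()  # kernel amplitude 10 x noise SD -> SNR 10
traces, truth = generate_population(spec, noise, default_protocols(("IV",)))

params = DetectionParams()
over = under = n_ref = n_det = 0
for trace in traces:
    detected = process_trace(trace, params)
    reference = truth.spike_times[(trace.neuron_id, "IV")][0]
    report = match_spike_trains(
        detected, SpikeTrain("ref", reference), tolerance=1 / noise.frame_rate
    )
    over, under = over + report.over, under + report.under
    n_ref, n_det = n_ref + reference.size, n_det + detected.n_spikes

print(f"{len(traces)} sweeps, {n_ref} true spikes, {n_det} detected")
print(f"recall    {1 - under / n_ref:.3f}")
print(f"precision {1 - over / n_det:.3f}")
# recall/precision near 0.97-0.98: at this signal-to-noise ratio optical
# detection recovers almost every action potential within one frame (4 ms),
# the regime the downstream response classification assumes
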