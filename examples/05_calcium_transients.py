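"""Quantify an ATP-evoked mitochondrial Ca2+ transient from a 490/420 record.

Simulates a two-channel ratiometric record (2 s frames, stimulus at 60 s,
double-exponential transient) and recovers the resting ratio, peak amplitude
and time to peak; detection requires the amplitude to exceed 3 pre-stimulus
standard deviations.
"""

from fibermito.calcium import transient_metrics
from fibermito.synthetic import TraceSimParams, simulate_trace

params = TraceSimParams(
    resting_ratio=1.0,
    transient_amplitude=0.5,
    rise_tau=10.0,
    decay_tau=60.0,
    noise_sd=0.01,
    seed=11,
)
trace, truth = simulate_trace(params)

metrics = transient_metrics(trace.ratio, trace.time, trace.stimulus_time)

print(f"resting 490/420 ratio: {metrics.resting_level:.3f} (truth {truth['resting']:g})")
print(f"peak amplitude: {metrics.peak_amplitude:.3f} (truth {truth['amplitude']:g})")
print(f"time to peak: {metrics.time_to_peak:.0f} s "
      f"(truth {truth['t_peak'] - trace.stimulus_time:.1f} s)")
print(f"detected: {metrics.detected} (k = {metrics.k:g} x prestim SD = "
      f"{metrics.k * metrics.prestim_sd:.4f})")
# The resting ratio tracks baseline mitochondrial Ca2+; the amplitude
# quantifies the stimulus-evoked uptake.
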