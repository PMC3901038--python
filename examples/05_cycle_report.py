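"""Assemble the transcription-cycle kinetic summary from measured inputs.

Combines the upstream measurements — non-productive dwell T0, probe-arrival
delay delta T_on, the dwell-vs-length regression, the hybridization on-rate,
and the efficiency/retention fractions — into the cycle's rate constants.
"""

import dataclasses
import json

from fastfish import dwell, postsync, simulate
import pandas as pd

from fastfish.cycle import CycleGeometry, fit_dwell_vs_length, summarize_cycle

# estimate efficiency and retention from a run-off-anchored probe heat map
p = simulate.SimulationParams(template_length=633, n_loci=150, fov_size=128,
                              duration=600.0, noise_sd=30.0, seed=11)
traces = simulate.render_traces(simulate.simulate_field(p))
events = pd.concat(
    [dwell.call_events(traces.rnap[i], p.frame_interval, max_gap_frames=1, locus=i)
     for i in range(p.n_loci)],
    ignore_index=True,
)
hm = postsync.postsynchronize(traces.probe, events[~events["censored"]],
                              p.frame_interval, anchor="off", min_dwell=1.2)
efficiency, _ = postsync.detection_efficiency(hm)
retention, _ = postsync.retention_fraction(hm)

# length series from the peak-dwell measurements (see example 03)
line = fit_dwell_vs_length([(295, 1.64), (633, 2.77), (910, 3.69)])

summary = summarize_cycle(
    T0=0.14,
    delta_t_on=0.69,
    geometry=CycleGeometry(),
    rate=line.rate,
    k_on=6e6,
    conc=500e-9,
    t_stationary=line.intercept,
    efficiency=efficiency,
    retention=retention,
    frame_interval=0.08,   # fast acquisition bounds the promoter search time
)
print(json.dumps(dataclasses.asdict(summary), indent=2))
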