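"""Interaction durations with and without chemotaxis.

Runs the mixed Brownian-dynamics / Metropolis simulation twice — once
unstimulated (chi = 0, no chemokine signalling) and once under strong
chemotaxis (chi = 1) — and compares the duration distribution of the
NK-DC interaction events.  Chemokine-mediated attraction holds cells
near the dendritic cells, shifting a large share of events to durations
of several minutes.
"""

import numpy as np

from lymphsim import SimParams, run_simulation

for chi in (0.0, 1.0):
    params = SimParams(chi=chi, n_steps=20_000, seed=11, record_stride=500,
                       n_nk=200)
    res = run_simulation(params)
    ev = res.events_frame
    done = ev[~ev["censored"]]
    print(f"chi = {chi:.0f}: {len(done)} completed events", end="")
    if len(done):
        d = done["duration_s"].to_numpy()
        print(f"; median {np.median(d):.0f} s; "
              f"{100 * np.mean(d < 300):.1f}% shorter than 300 s")
    else:
        print(" (unstimulated events are rare at this run length)")
# Unstimulated interactions end within seconds-to-minutes (any receding
# step interrupts them); under chemotaxis a substantial fraction lasts
# longer than 300 s — the signature of non-contact chemokine attraction.
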