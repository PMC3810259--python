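# lymphsim

Brownian-dynamics / Metropolis Monte Carlo simulation of **non-contact,
chemokine-mediated interactions between Natural Killer (NK) cells and
dendritic cells (DCs)** in a lymph-node-sized volume, together with the
track statistics used to compare simulations against two-photon
microscopy data.

Leukocyte interactions are usually scored by proximity — two cells
"interact" when they touch.  But stimulated DCs secrete chemokines that
attract NK cells from tens of micrometres away, and this action at a
distance changes how long the cells linger near each other.  `lymphsim`
quantifies that effect: it simulates NK cells as persistent random
walkers in a chemokine field and asks how the distribution of NK–DC
interaction durations depends on the chemotactic coupling and on the
chemokine lifetime.

## Model

* NK cells are overdamped Brownian walkers (Euler–Maruyama, `dt = 1 s`)
  with worm-like-chain directional persistence (turning angle
  `~ N(0, sigma_theta)`, `sigma_theta = 0.3 rad`) in a
  500 × 500 × 50 µm³ box; cells leaving the box are replaced at the
  boundary.
* Each immobile DC is a point source of chemokines that diffuse
  (`D_CK = 10 µm²/s`) and degrade (lifetime `k`), giving the screened
  steady profile `c_ss(r) = J₀ e^(−r/λ)/(4π D_CK r)` with
  `λ = sqrt(D_CK k) ≈ 77 µm`, modulated in time by a charging /
  discharging factor (time constant `τ = 3600 s`) driven by the
  interaction feedback.  The concentration is the separable product
  `c_ss(r)·f(t)`, validated against a finite-volume solver of the full
  diffusion–degradation equation.
* Contact interactions are folded into a space-dependent friction
  `γ(r) = γ₀(1 + k_γ Σ exp(−r²/2s_γ²))` that slows cells 11-fold at a DC.
* Interactions start and stop through Metropolis tests on the cell's
  radial leap `Δd` toward the DC, weighted by the local chemokine level
  `w = χ·c(r,t)/c_max`: start iff `Δd ≥ Δd_rms(1 − w)` within the 25 µm
  gate, stop iff `−Δd ≥ Δd_rms·w`, with `Δd_rms = sqrt(6 D₀ dt) = 0.2 µm`
  the free-motion RMS leap.  The chemotactic parameter `χ` is swept on a
  dimensionless 0–1 axis.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and known limitations.

## Worked example

```python
from lymphsim import SimParams, run_simulation

for chi in (0.0, 1.0):
    res = run_simulation(SimParams(chi=chi, n_steps=20_000, n_nk=200,
                                   seed=11, record_stride=500))
    ev = res.events_frame
    done = ev[~ev["censored"]]
    print(chi, len(done), (done["duration_s"] < 300).mean())
```

prints (as run by `examples/interaction_durations.py`):

```
chi = 0: 0 completed events (unstimulated events are rare at this run length)
chi = 1: 36 completed events; median 181 s; 63.9% shorter than 300 s
```

Without chemokine signalling (`chi = 0`) interaction starts require a
~5 σ approach leap, so events are rare and end within seconds-to-minutes;
under full chemotaxis the cells are captured and held, and roughly 60%
of durations stay below 300 s — the remainder forms the long-duration
population attributed to non-contact attraction.

The other example scripts each exercise one capability and print what
the numbers mean:

* `examples/free_diffusion_calibration.py` — recovers the input
  diffusion coefficient from the MSD slope to 0.55% on a 2×10⁶-step
  ensemble;
* `examples/chemokine_field_accuracy.py` — separable field vs PDE
  solver: maximum deviation 0.234% of the peak concentration;
* `examples/track_statistics.py` — confinement ratio, 3D speed,
  trajectory length, turning-angle persistence (lag-1 correlation 0.956
  vs the closed form 0.956) and the kinematic interaction detector on a
  track with a planted interaction.

A thin CLI wraps the same library calls:

```bash
lymphsim simulate --chi 1.0 --steps 30000 --seed 1 --out-prefix run
lymphsim durations run_events.csv --fit
lymphsim analyze run_tracks.csv --dc run_dcs.csv
lymphsim sweep --chi 0:1:0.25 --replicates 2
lymphsim validate
```

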