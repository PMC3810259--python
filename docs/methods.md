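# Methods

`lymphsim` simulates non-contact, chemokine-mediated interactions between
highly motile Natural Killer (NK) cells and immobile dendritic cells (DCs)
in a lymph-node-sized volume, and computes the track and interaction
statistics used to compare such simulations with two-photon microscopy
tracking data.  This note records the model, its assumptions, the
numerical choices, and the design decisions taken where the problem was
genuinely open.

## The model

### Cell motion

NK cells are independent overdamped Brownian walkers integrated with the
Euler–Maruyama scheme at a fixed step `dt` (default 1 s).  One step
combines:

* **Thermal noise.**  The stochastic displacement has the magnitude of a
  3-D Gaussian step with per-axis standard deviation `sqrt(2 D(r) dt)`,
  where `D(r)` is the local diffusion coefficient (below).
* **Directional persistence.**  The step direction follows a worm-like
  chain (WLC): it deviates from the previous step direction by a polar
  angle drawn from `N(0, sigma_theta)` (default 0.3 rad) at a uniform
  azimuth, giving the geometric decay `<cos theta>(lag) =
  exp(-sigma_theta^2/2)^lag` of the turning-angle autocorrelation that
  in-vivo leukocyte tracks show.  Setting `sigma_theta = None` recovers
  isotropic (memoryless) diffusion.
* **Space-dependent friction.**  Contact interactions with the DC and the
  surrounding tissue are modelled a-specifically by a friction dip,
  `gamma(r) = gamma0 (1 + k_gamma sum_k exp(-r_k^2 / 2 s_gamma^2))`
  with amplitude `k_gamma = 10` and range `s_gamma = 25 um`, so that
  `D(r) = kB T / gamma(r)` drops 11-fold at a DC centre.  The drift
  induced by the spatial variation is implemented as the attractive
  velocity `-grad D` (magnitude ~1e-4 um/s, dynamically negligible); the
  noise uses `D` at the pre-step position, so cells accumulate where they
  are slow — the mean-field "slowing down" near DCs.
* **Chemotactic drift.**  `v = chi_phys grad c / gamma(r)`, with
  `chi_phys = chi * chi_ref` and `chi_ref = (m v_typ^2 / 2) V_DC / N_CK`
  the kinetic-energy estimate of the chemotactic coupling
  (3.6e-15 kg um^5 s^-2 per molecule at defaults).  With this estimate the
  drift is ~1e-9 um/s — far below the 0.2 um/s noise scale — so the
  operative role of `chi` is in the Metropolis tests below.  The drift
  mechanism itself is exercised in the tests with an amplified coupling.

Cells live in a 500 x 500 x 50 um^3 box.  A cell crossing a face dies
(its track ends and any running interaction is censored) and a
replacement enters at a random point of a random face, 1 um inside, so
the live count stays at `n_nk` (default 100).

The default initial positions are drawn from the zero-chemotaxis
stationary density `p(r) ∝ gamma(r)` by rejection sampling.  The
reference statistics come from production runs of 1e7 steps that are
dominated by this equilibrated, friction-trapped density; a desk-scale
run started from uniform positions would spend its entire length inside
the equilibration transient (relaxation time ~1e5 s).  `init_mode =
"uniform"` restores uniform placement.

### The chemokine field

Each DC is a point source of a single chemokine species with intrinsic
strength `j0` (1000 molecules/s), diffusing with `D_CK = 10 um^2/s` and
degrading with characteristic time `k` (600–1200 s), giving the screened
(Yukawa) steady profile

    c_ss(r) = j0 exp(-r/lambda) / (4 pi D_CK r),   lambda = sqrt(D_CK k),

with `lambda ≈ 77 um` at defaults.  The divergence at the origin is
regularized by clamping `r` at `r_reg = r_NK = 5 um`; `c_max =
c_ss(r_reg)` and the gradient vanishes inside the core, so no force is
ever singular.

Sources are switched on adiabatically at t = 0 with time constant
`tau = 3600 s` and are modulated by the interaction feedback: a DC with
at least one active NK partner *discharges* (factor decays toward 0 with
`tau`), an idle DC *recharges* toward 1.  The factor is continuity-matched
at every mode switch — the level reached at the switch is the starting
point of the new branch — because any other matching would teleport
concentration.  The field a cell feels is the separable product
`c_ss(r) f(t)`.

Because the source varies slowly (`tau >> k`), the separable form is
accurate.  Three evaluators of increasing fidelity exist: the product
form (used in the simulation), the first-order charging form
`c_ss(r) - exp(-t/tau) c_mod(r)` with `c_mod` the Yukawa kernel at the
modified screening length `lambda' = sqrt(D_CK/(1/k - 1/tau))` (derived
from the exact Fourier solution; its small negative undershoot near t = 0
is clamped to zero), and the exact erfc-form transient.  A conservative
finite-volume Crank–Nicolson solver of the radial diffusion–degradation
PDE acts as the independent numerical oracle: it agrees with the exact
closed form to 0.007% and the first-order separable form deviates from it
by at most ≈0.23% of the peak concentration on the interaction shell
(5–25 um) over two source time constants.

### Interaction kinetics (Metropolis tests)

Interactions are governed by accept/reject tests on the *realized* radial
leap `delta_d` of the cell toward a DC over one step — the stochastic
displacement itself is the random variable; no additional random number
is drawn.  With `w = chi * c(r, t)/c_max` the local chemokine weight and
`dd_rms = sqrt(6 D0 dt)` the intrinsic 3-D RMS leap (0.2 um at defaults,
the typical per-second NK displacement):

* **start** (within the gate `a0 = 25 um`, not interacting):
  `delta_d >= dd_rms (1 - w)` — the emptier the chemokine cloud, the
  larger the approach must be; at full weight any approaching step
  starts an interaction, and a receding step never does.
* **stop** (interacting, tested wherever the cell is):
  `-delta_d >= dd_rms w` — the fuller the cloud, the larger the escape
  leap must be; an approaching step never interrupts.

The gate applies to starts only; an interacting cell that wanders beyond
`a0` keeps its partner but its weight is then small, so the interaction
ends within a step or two.  An NK cell holds at most one partner (nearest
eligible DC); a DC discharges while it has any partner.

Two scales make this engine work.  First, `dd_rms` uses the *intrinsic*
diffusion coefficient while the actual steps near a DC are up to
`sqrt(3 g)` ≈ 5.7 times smaller because of the friction dip: deep cells
essentially cannot produce the escape leap while the cloud is charged,
which is what generates interaction durations of hundreds of seconds.
Second, at `chi = 0` the weight vanishes, so starts require a ~5 sigma
leap (rare) and any receding step stops — unstimulated interactions are
scarce and short, matching the event abundance implied by the reference
histograms.

### What the model reproduces, and what it does not

With all parameters at their table defaults the simulation reproduces,
at desk scale:

* free-diffusion calibration: MSD-slope D within 1% (typically ~0.1–0.5%);
* the unstimulated split: ~100% of `chi = 0` durations below 300 s
  (reference: more than 90%);
* the stimulated split: ~60–65% of `chi = 1` durations below 300 s
  (reference: ~60%);
* a monotone, saturating percentage of interacting cells in `chi`;
* the separable-field accuracy (~0.2%).

Not reproduced: the two-component structure of the stimulated duration
histogram.  The reference analysis resolves a fast exponential
(`t1 ≈ 70 s`) plus a Gaussian bump whose centre grows with the
degradation time (450 → 570 → 630 s for k = 600 → 900 → 1200 s).  This
implementation yields a broad quasi-exponential (fitted `t1 ≈ 300 s`)
with a weak long tail centred near `tau ln((G - 2.5)/2.5) ≈ 900 s`
(`G = sqrt(3 g)` the leap-scale contrast) that does not shift with `k`.
An extensive exploration of the readings left open by the printed
equations (per-DC versus per-event weight clocks, discharge on `tau`
versus the combined rate `1/k + 1/tau`, spatial weight with and without
the `1/r` factor, local versus intrinsic reference leap on either test)
showed that every variant restoring a k-dependent peak position destroys
the 60% duration split or the event-rate scale, and vice versa.  The
capture-release race is the structural reason: the start test engages
cells at the weight where `G (1 - w) ≈ 2.5` and the stop test releases
them where `G w ≈ 2.5`, pinning the hold time to `tau ln((G-2.5)/2.5)`
regardless of `k`.  The two-component fit machinery is fully implemented
and validated on synthetic histograms with known parameters; the tests
that compare its output on simulated data against the reference centres
are expected to fail and are retained as an honest record of the
discrepancy.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| `dt` | integration step | 1 | s |
| `n_steps` | run length | 4e4 (desk scale; reference runs used 1e7) | steps |
| `box` | simulation volume | 500 x 500 x 50 | um |
| `n_nk` | NK cells per box | 100 | — |
| `n_dc` | DCs per box (uniform, >= 50 um apart, seeded) | 10 | — |
| `r_nk` | NK radius (also field regularization radius) | 5 | um |
| `d_nk0` | intrinsic NK diffusion coefficient | 0.2^2/6 ≈ 6.7e-3 | um^2/s |
| `temperature` | bath temperature | 310 | K |
| `k_gamma` | friction-dip amplitude | 10 | — |
| `s_gamma` | friction-dip range | 25 | um |
| `a0` | interaction gate radius | 25 | um |
| `chi` | chemotactic parameter (x `chi_ref`) | 0 | — |
| `d_ck` | chemokine diffusion coefficient | 10 | um^2/s |
| `k_deg` | chemokine degradation time | 600 | s |
| `tau` | source (de)activation time | 3600 | s |
| `j0` | source strength | 1000 | molecules/s |
| `sigma_theta` | WLC turning-angle std (None = isotropic) | 0.3 | rad |
| `t_th` | long-interaction threshold | 600 | s |
| `m_nk` | NK mass | 9e-13 | kg |
| `v_dc` | DC volume | 2e4 | um^3 |
| `n_ck` | chemokines per DC | 1e5 | — |
| `v_typ` | typical NK speed at 1 s sampling | 0.2 | um/s |

`d_nk0` is fixed so that the per-second RMS displacement
`sqrt(6 D0 * 1 s)` equals the 0.2 um/s typical instantaneous NK speed —
the one speed scale the reference data pin down.  The friction range
`s_gamma` follows the parameter table (25 um); the narrower 10–15 um
quoted in prose confines the dip to the inner third of the gate and
suppresses the long-duration component, so the table value is the
default (both are configurable).  Internal units are um, s, kg and
molecule counts; every force is carried as a drift velocity F/gamma in
um/s.

## Numerical choices

* **PDE oracle.**  Finite-volume discretization over spherical shells
  (dr = 0.1 um), Crank–Nicolson in time (dt = 2 s), point source smeared
  over a 0.5 um ball (exterior error O((a/lambda)^2) ~ 4e-5), absorbing
  boundary at 5 lambda (about 0.03% influence at 3 lambda when moved to
  7 lambda for the steady-state check).  Positivity is monitored; loss of
  positivity raises an error.
* **MSD.**  FFT-based time-averaged MSD per track, ensemble-averaged with
  per-lag weights; D is fitted by a line through the origin over lags
  1–100 s.
* **Two-component duration fit.**  `A exp(-t/t1) + B exp(-(t-t0)^2 /
  2 sigma^2)` by bounded nonlinear least squares; data-driven starting
  values (exponential from the first decade, Gaussian from the counts
  beyond three lifetimes); covariance-based uncertainties.  Validated by
  parameter recovery on Poisson-noised synthetic histograms.
* **Sigmoid fit** of percent-interacting vs chi:
  `y = a - b/(1 + exp((chi - chi0)/w))`, bounded, with raw percentages
  always reported on fit failure.
* **Censoring.**  Events still open at run end (or whose cell left the
  box) are censored and excluded from duration statistics by default.
  The steady-state duration fractions additionally (i) drop events
  starting during the first `2 tau` of a run (source charging transient)
  and (ii) count only events whose outcome relative to the threshold is
  decided before run end — a censored event that already outlived the
  threshold counts as long, and events starting too late to be decided
  are dropped — which removes the desk-scale bias toward short durations.
* **Kinematic detector.**  A frame qualifies if the nearest-DC distance
  is below 25 um, the confinement ratio on a 5-frame sliding window
  decreases between consecutive windows, and the instantaneous speed is
  below the mean speed of all cells and frames; maximal runs of at least
  two qualifying frames become events.  The window length operationalizes
  an otherwise unstated "confinement is decreasing" rule.
* **Rebinning** keeps every 25th sample by default, mapping the 1 s
  simulation step onto a typical two-photon acquisition interval.

## Reproducibility

All randomness flows from a single master seed through
`numpy.random.Generator` (PCG64); identical parameters give bit-identical
track tables and event lists.  Independent substreams for separate
pipeline components are available via `spawn_rngs`.

## Synthetic data and its limits

The fixture generators produce free-diffusion tracks, WLC tracks,
two-component duration samples and a planted kinematic-interaction track
with exactly known ground truth.  They emulate sampling noise, direction
persistence and censoring, but not tissue anisotropy, imaging
localization error, track fragmentation or cell–cell collisions — so
passing tests demonstrate the correctness of the estimators on clean
tracks, not their robustness to real microscopy artefacts.

## Known limitations

* The chemotactic drift at the physical `chi_ref` is too weak to affect
  kinematics; `chi`'s observable effect is through the Metropolis weight.
  The MSD-curvature test therefore uses an amplified coupling to
  exercise the drift mechanism.
* The two-component duration structure and its degradation-time scaling
  are not reproduced (see above).
* A single chemokine species, no receptor kinetics, no NK–NK
  interactions, no tissue mesh; DC placement is uniform with a minimal
  pairwise distance because no placement protocol is stated.
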