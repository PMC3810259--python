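# Example simulation configuration for `lymphsim simulate -c config.yaml`.
# Any omitted key keeps its documented default (see lymphsim.params.SimParams).
# Units: lengths in um, times in s, mass in kg, counts in molecules.

seed: 42
chi: 1.0          # chemotactic parameter on the dimensionless 0-1 axis
n_steps: 30000    # 1 s per step
n_nk: 100         # NK cells kept alive in the box
n_dc: 10          # immobile dendritic cells (seeded random placement)
k_deg: 600        # chemokine degradation time [s]
tau: 3600         # source activation/deactivation time [s]
j0: 1000          # chemokine production [molecules/s]
d_ck: 10          # chemokine diffusion [um^2/s]
sigma_theta: 0.3  # worm-like-chain turning-angle std [rad]
record_stride: 10 # trajectory sampling interval [steps]
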