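# entropull

Hsp70 chaperones drive the post-translational import of proteins into
mitochondria (and the ER and chloroplasts) by binding the incoming chain on
the far side of the membrane pore. `entropull` quantifies *how much* that
binding helps, with a two-stage computation:

1. **Entropic pulling profile.** The chaperone and the substrate are
   coarse-grained to one bead per residue (Cα). The substrate's *n*-th
   imported residue is tethered on the membrane — a flat wall that is a hard
   constraint for substrate beads and transparent to the chaperone — while a
   chaperone is clamped onto residues 1–7. Metropolis Monte Carlo samples the
   complex at equilibrium, and the fraction of configurations in which no
   chaperone bead crosses the wall estimates the partition-function ratio
   Z₇₀(n)/Z(n). The free-energy cost of chaperone binding near the wall is

       ΔF_c(n) = −k_BT ln [ Z₇₀(n) / Z(n) ],   8 ≤ n ≤ 26,

   and its slope along *n* is the entropic pulling force (in pN after
   multiplying by k_BT per 3.8 Å of contour).

2. **Import kinetics.** Import of an L-residue substrate is a 1D Metropolis
   walk of the number of imported residues n_in on the landscape

       F_import(n_in) = F_u(n_in) + ΔF_c(n_in − n_B),

   where F_u is a sigmoidal unfolding free energy with height F_u^max and
   cooperativity width δn, and n_B is the closest bound chaperone site
   (chaperones bind each site irreversibly as soon as it is exposed).
   Mean first-passage times to n_in = L give the unassisted (τ₀) and
   chaperone-assisted (τ_C) import times; τ₀/τ_C is the chaperone-induced
   acceleration.

Intended users: biophysicists and computational biologists studying
chaperone-driven translocation who want a tested, reproducible, desk-scale
implementation of the entropic-pulling free-energy calculation and the
kinetic model built on it.

## Worked example

```python
import numpy as np
from entropull import (build_synthetic_chaperone, ForceFieldParams,
                       SamplerConfig, compute_pull_profile, pulling_force,
                       ImportLandscapeSpec, UnfoldingParams,
                       average_import_time, acceleration_ratio,
                       generate_binding_sites)

# stage 1: pulling profile with the synthetic Hsp70-sized chaperone
geom = build_synthetic_chaperone()            # NBD ~25 A, SBD ~20 A, 9-bead linker
prof = compute_pull_profile(geom, ForceFieldParams(),
                            SamplerConfig(n_sweeps=40_000, seed=11))
print(round(prof.delta_F[0], 2), round(pulling_force(prof, 8), 1))
# 3.77 18.1    -> dF_c(8) = 3.77 kT; initial pulling force ~18 pN

# stage 2: import of a 300-residue protein with F_u^max = 8 kT, dn = 100
unf = UnfoldingParams(F_max=8.0, delta_n=100.0)
tau0 = average_import_time(
    ImportLandscapeSpec(L=300, unfolding=unf, mode="unassisted"),
    None, n_distributions=8, n_realizations=4, seed=81)
tauC = average_import_time(
    ImportLandscapeSpec(L=300, unfolding=unf, profile=prof, mode="assisted"),
    lambda rng: generate_binding_sites(300, 35.0, rng),
    n_distributions=25, n_realizations=10, seed=82)
print(f"{tau0.mean_tau:.2g} {tauC.mean_tau:.2g} "
      f"{acceleration_ratio(tau0, tauC).ratio:.0f}")
# 4.1e+07 1.9e+06 22   -> ~20-fold faster with chaperones at this seed
```

The first block says that with only 8 residues imported the bound chaperone
costs ~3.8 k_BT of conformational entropy, i.e. it is pulled inward with
~18 pN; the force decays as more chain is imported. The second block shows
that for a protein of typical stability (8 k_BT) chaperone binding shortens
the mean import time by more than an order of magnitude relative to
unassisted barrier crossing. The assisted mean is heavy-tailed across
binding-site maps (a single map with one long inter-site gap can dominate
it), so the measured acceleration fluctuates between roughly 20× and 45×
across seeds at this ensemble size; see `docs/methods.md` for why the
spherical stand-in geometry bounds the attainable acceleration.

A CLI wraps the same functionality (`entropull show-config`,
`entropull sample-profile`, `entropull simulate-import`, `entropull scan`,
`entropull run` for the full two-stage pipeline, `entropull fixtures ...`
for synthetic inputs).

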