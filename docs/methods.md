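# Methods

## Model

Both the substrate and the chaperone are represented at one bead per
residue (Cα). Energies are in units of k_BT throughout; temperature enters
only when free-energy slopes are converted to forces.

**Interactions.** Consecutive beads are joined by stiff harmonic bonds
(rest length 3.8 Å, default stiffness 100 k_BT/Å²). All non-bonded bead
pairs repel through a purely repulsive Lennard-Jones potential in the WCA
form — truncated at its minimum 2^(1/6)σ and shifted to zero — with
σ = 3.8 Å and ε = 3 k_BT. Local bending and torsion potentials are cosine
series in the bond/dihedral angles; the default coefficients are zero, so
the chain is a freely-jointed excluded-volume chain. A "standin" parameter
set (`standard_params("standin")`) adds a small stiffness (−0.2 cos θ
bending, −0.1 cos φ torsion) calibrated to a Kuhn length of ≈4.3 Å — a
declared stand-in for sequence-specific local potentials of
glycine/proline-free sequences, not a literature force field. Since the
entropic-pulling free energy is dominated by rigid-body excluded volume
rather than chain stiffness at these short leash lengths, the fallback and
stand-in sets give profiles that agree within sampling error; the stand-in
is exercised by the test suite's cross-validation.

**Geometry.** The chaperone has two rigid domains — the nucleotide-binding
domain (NBD) and the substrate-binding domain (SBD) — joined by a flexible
9-bead linker. Geometries come from either a CA-only PDB extraction
(DnaK-style residue intervals NBD 4–387, linker 388–396, SBD 397–603) or a
synthetic stand-in: two filled cubic-lattice balls (NBD radius 25 Å, SBD
radius 20 Å, spacing 3.8 Å, surface-to-surface gap 12 Å), total extent
≈99 Å. The bound substrate heptapeptide (residues 1–7) sits on seven clamp
sites that move rigidly with the SBD.

The clamp of the synthetic chaperone is laid *through a carved cleft* two
bead layers (7.6 Å) beneath the SBD surface, with an exit channel
(radius 4.5 Å) continuing along the clamp axis through the surface. This
mirrors the architecture of the Hsp70 substrate-binding site, where the
peptide is enclosed between the β-sandwich and the helical lid and the
chain exits from within the domain body. The enclosure is what makes
entropic pulling strong: with material on all sides of the exit, the
domain cannot sit close to the wall in most orientations. A clamp placed
on the outside of a sphere (no enclosure) yields forces of only ~2–3 pN;
the cleft geometry yields ~15–20 pN at n = 8, the experimentally and
theoretically expected scale. For PDB-loaded structures the clamp is placed
tangentially at the SBD surface point farthest from the NBD, along the
local principal axis of the bead patch, sliding along that axis until every
clamp site has structural support; pass `clamp_sites` explicitly to use a
crystallographic peptide pose instead.

**Wall.** The membrane is the plane z = 0. It is a *hard constraint on
substrate bead centres* (moves proposing z < 0 are rejected and counted)
and transparent to chaperone and linker beads; a configuration "overlaps"
when any chaperone/linker bead centre has z strictly below 0. Residue n is
pinned at the origin. The overlap fraction of this ensemble is exactly
Z₇₀(n)/Z(n): the numerator restricts the chaperone's excluded volume
against the wall, the denominator does not. (The sampled denominator
ensemble retains chaperone–substrate excluded volume; whether the "bare"
partition function should include the chaperone at all is a modelling
ambiguity — we use the operational definition, the fraction of
non-overlapping samples, which is self-consistent and parameter-free.)

## Sampling

Metropolis Monte Carlo with symmetric proposals. One sweep attempts: one
move per free substrate bead (Gaussian displacement of 0.22 Å or a
crankshaft rotation about the axis through its chain neighbours), one per
linker bead (displacement or crankshaft), two SBD-unit moves (a swing about
the axis through the chain attachment and the linker anchor — both
connecting bonds are preserved exactly, so large angles are possible — or a
small general rotation plus ≤0.12 Å translation), three NBD/arm moves
(rotation about the linker anchor, small translation, or a rigid swing of
the whole NBD + linker arm about the SBD anchor), and two pivots (rotation
of everything on the clamp side of a random substrate bead, chaperone
included). The bond-preserving compound moves exist because the stiff
bonds otherwise freeze domain mobility; all proposals are symmetric, so the
chain satisfies detailed balance with respect to exp(−E/k_BT) restricted to
wall-legal substrate configurations.

Correctness is pinned two ways in the tests: every move type's incremental
energy delta is compared exactly (1e-8 k_BT) against a full re-evaluation
with the reference energy implementation, and the sampled overlap fraction
is compared statistically against an independent naive Python sampler and,
for the estimator machinery, against exhaustive enumeration of a 2D lattice
toy (a self-avoiding chain with a rigid obstacle at a wall line).

Implementation notes: rigid-body poses are stored as rotation + translation
and re-orthonormalized on every update, keeping intra-domain distances
conserved to <1e-12 Å over arbitrarily long runs. For filled synthetic
domains only the outer shell (plus the cleft walls) enters the interaction
and overlap evaluations: the minimum bead z is attained on the hull, and a
particle cannot reach an interior bead without first paying a prohibitive
repulsive penalty at the shell. Rigid-move deltas use the inverse-transform
identity E(moved′, static) = E(moved, inverse-moved static), with exact
dual bounding-sphere checks.

**Fraction and error.** The per-frame indicator (1 = no overlap) is
recorded once per sweep after a default burn-in of 10% of the production
sweeps. The standard error uses block averaging with block-size doubling;
the reported block is the smallest whose error changes by <5% upon
doubling, and the absence of a plateau is flagged. ΔF_c = −ln(fraction)
with the delta-method error err(fraction)/fraction.

**Profile.** ΔF_c(n) is tabulated on n = 8..26 (n ≥ 8 exposes one complete
binding site). Values are absolute −ln(fraction), not shifted at n = 26.
Linear interpolation between grid points; constant beyond n = 26 (the
force has decayed); arguments below n = 8 with a bound chaperone are a hard
ratchet wall. Forces use central differences (one-sided at the edges)
times k_B·300 K / 3.8 Å ≈ 10.9 pN per k_BT/residue, computed from physical
constants at run time.

## Import simulation

F_u(n_in) = F_u^max / (1 + exp[5 − 10(n_in − 10)/δn]). The import walk
starts at n_in = 0 with a reflecting origin, proposes ±1 with probability ½
and accepts with min(1, e^(−ΔF_import)); every attempt is one MC timestep.
No acceptance-rate rescaling of times is applied (pooled acceptance stays
above 95% in the regimes studied, where the rescaling is a no-op within
error). A site at n_B binds instantly and irreversibly once
n_in ≥ n_B + 8 (the argument of ΔF_c is then valid); only the bound site
nearest the pore contributes, as both the force decay over ~18 residues and
the 35-residue mean site spacing justify. `ratchet_only` mode keeps the
hard wall at the same threshold but drops the pulling term, giving an
apples-to-apples Brownian-ratchet comparison. Acceptance probabilities are
precomputed per landscape and rebuilt at each binding event, which keeps
the walk at ~10⁷–10⁸ attempts/s.

Ensembles follow the proteome-heterogeneity protocol: 25 independent
binding-site distributions (i.i.d. geometric gaps of mean 35 residues — the
maximum-entropy law for integer gaps with the prescribed mean; a terminus
site is possible but not forced) × 10 realizations each. The independent
statistical unit is the distribution, so standard errors come from the
between-distribution variance. Runs that do not complete within the step
cap (default 10⁹) are excluded from means with a warning; regimes beyond
direct reach (F_u^max ≳ 12 k_BT) are handled by fitting ln τ₀ vs F_u^max
over 4–11 k_BT and extrapolating (`fit_exponential_extrapolation`).

An absorbing-Markov-chain solver (`exact_mean_first_passage`, tridiagonal
linear solve of the same walk) provides an independent oracle for mean
first-passage times, and a non-absorbing histogram utility
(`walk_histogram`) verifies Boltzmann stationarity.

## Problem sizes and what the tests show

Test-suite and acceptance-script runs use reduced sampling chosen as the
package's own desk-scale operating point: 30,000–60,000 sweeps per n for
the profile (ΔF_c errors of 0.03–0.2 k_BT, largest at n = 8 where the
fraction is ~0.03), 32–60 unassisted runs and 250 assisted runs per
ensemble point. At these sizes the initial-force estimate carries a ~10–15%
statistical uncertainty and acceleration ratios a ~20–40% one (the
assisted-time distribution over random site maps is heavy-tailed: a
distribution with one long inter-site gap can dominate the mean).

With the spherical stand-in the package obtains an initial pulling force
of ~16 pN, a ~20–25× acceleration for marginally stable substrates
(F_u^max = 4 k_BT) and a ~30–45× acceleration for stable ones
(F_u^max = 8 k_BT, δn = 100). The acceleration scales roughly as
exp[ΔF_c(8) − ΔF_c(26)]: what matters is the *integrated* pull per
inter-site period, ~2.6 k_BT here. A sphere of the SBD's volume loses its
wall-exclusion penalty within a few residues of slack, so while the
initial force is reproduced, the force *range* — and hence the integrated
pull and the acceleration attainable for very stable substrates — is
smaller than an elongated domain of the same volume would give. Profiles
computed from a real CA structure are expected to sustain the force to
larger n and correspondingly larger accelerations.

The synthetic chaperone reproduces the *sizes*, *two-domain topology*, and
*enclosed substrate groove* of Hsp70, not its shape details, surface
chemistry, or nucleotide-state conformational changes. Passing tests
therefore demonstrate the mechanism and its magnitude for a realistic
geometry, not structure-specific values; profiles from a real CA structure
can be computed through `load_chaperone_ca` with an explicit clamp pose.
The import model likewise ignores chaperone unbinding, the ATPase cycle,
pore friction and sequence-specific unfolding — all absorbed into F_u and
the instant-binding assumption, which rest on the timescale separation
between chain reconfiguration (~100 ns), chaperone binding (~10 ms), import
(minutes) and chaperone release (~10³ s).

## Numerical choices and degenerate inputs

* Overlap is strict (z < 0); bead centres exactly on the plane do not
  overlap.
* A zero overlap count yields fraction 0 with a warning: only a lower bound
  on ΔF_c exists, and `build_profile` refuses to construct a profile from
  it.
* Coincident beads (r = 0) raise rather than returning infinity.
* The binding-site generator measured on finite windows under-estimates the
  mean gap (long gaps are censored); generator statistics are therefore
  validated on long substrates.
* Seeds: every stage derives independent 31-bit streams from one master
  seed via `numpy.random.SeedSequence`; identical configurations reproduce
  results bit-for-bit.

## Known limitations

* Only the Metropolis sampler is implemented; the `overdamped_langevin`
  mode in `SamplerConfig` is reserved and raises `NotImplementedError`.
* The ΔF_c statistics at n = 8 are the weakest point of the pipeline (rare
  non-overlapping configurations); the initial force inherits that error.
* Multi-chaperone additivity is deliberately excluded (nearest-site-only
  contribution), so regimes with site spacings ≪ 20 residues would need a
  model extension.
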