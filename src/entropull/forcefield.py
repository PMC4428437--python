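"""Energy terms of the coarse-grained model.

Energies are in units of k_BT.  The model has four ingredients:

* harmonic CA-CA bonds along the substrate chain and the interdomain linker,
* optional local bending / torsion potentials expressed as cosine series,
* purely repulsive excluded volume between all non-bonded bead pairs in the
  WCA form (Lennard-Jones truncated at its minimum and shifted to zero),
* the flat wall, which is a hard constraint handled by the sampler and not
  an energy term.

The default bending/torsion coefficients are zero, reducing the substrate to
a freely-jointed excluded-volume chain; ``standard_params("standin")``
activates a small cosine-series stiffness calibrated so the chain's Kuhn
length is ~4.3 A (slightly stiffer than freely jointed), a declared stand-in
for sequence-specific local potentials of glycine/proline-free sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .geometry import ChainConformation, ChaperoneGeometry

__all__ = [
    "ForceFieldParams",
    "standard_params",
    "excluded_volume_energy",
    "bond_energy",
    "bending_energy",
    "torsion_energy",
    "bonded_energy",
    "total_energy",
    "STANDIN_BENDING",
    "STANDIN_TORSION",
]

#: cosine-series coefficients (a0, a1, ...): U(theta) = sum_m a_m cos(theta)^m
#: with cos(theta)=1 for a straight chain.  a1 = -0.2 k_BT gives a Kuhn
#: length of ~4.3 A for a 3.8 A bond -- a stand-in local stiffness, not a
#: literature force field.
STANDIN_BENDING: tuple[float, ...] = (0.0, -0.2)
STANDIN_TORSION: tuple[float, ...] = (0.0, -0.1)


@dataclass
class ForceFieldParams:
    """Parameters of the coarse-grained force field (energies in k_BT)."""

    sigma: float = 3.8              # excluded-volume diameter, A
    epsilon: float = 3.0            # repulsion strength, k_BT
    bond_length: float = 3.8        # A
    bond_stiffness: float = 100.0   # k_BT / A^2
    bending_params: tuple[float, ...] = ()
    torsion_params: tuple[float, ...] = ()
    temperature: float = DEFAULT_TEMPERATURE  # K, used only for pN conversion

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.bond_stiffness <= 0:
            raise ValueError("bond_stiffness must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def cutoff(self) -> float:
        """WCA cutoff 2^(1/6) sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma


def standard_params(flavor: str = "freely_jointed") -> ForceFieldParams:
    """Canonical parameter sets.

    ``freely_jointed``: bending/torsion off (the documented fallback model).
    ``standin``: small cosine-series local stiffness (see module docstring).
    """
    if flavor == "freely_jointed":
        return ForceFieldParams()
    if flavor == "standin":
        return ForceFieldParams(bending_params=STANDIN_BENDING,
                                torsion_params=STANDIN_TORSION)
    raise ValueError(f"unknown force-field flavor: {flavor!r}")


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def excluded_volume_energy(r, params: ForceFieldParams):
    """Repulsive WCA pair energy at distance r (scalar or array), k_BT.

    4 eps [(sigma/r)^12 - (sigma/r)^6] + eps for r < 2^(1/6) sigma, else 0.
    r = 0 raises (infinite overlap).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("excluded-volume distance must be positive")
    sr6 = (params.sigma / r) ** 6
    e = np.where(r < params.cutoff, 4.0 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon, 0.0)
    return float(e) if e.ndim == 0 else e


def bond_energy(r, params: ForceFieldParams):
    """Harmonic bond energy 1/2 k (r - r0)^2, k_BT."""
    r = np.asarray(r, dtype=float)
    e = 0.5 * params.bond_stiffness * (r - params.bond_length) ** 2
    return float(e) if e.ndim == 0 else e


def _cos_series(c, coeffs) -> float:
    e = 0.0
    for m, a in enumerate(coeffs):
        e += a * c ** m
    return e


def bending_energy(r0: np.ndarray, r1: np.ndarray, r2: np.ndarray,
                   params: ForceFieldParams) -> float:
    """Bending energy of the triple (r0, r1, r2) with angle at r1.

    cos(theta) is taken between the bond vectors r1-r0 and r2-r1, so a
    straight chain has cos(theta) = 1.
    """
    if not params.bending_params:
        return 0.0
    u = r1 - r0
    v = r2 - r1
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return _cos_series(c, params.bending_params)


def torsion_energy(r0: np.ndarray, r1: np.ndarray, r2: np.ndarray, r3: np.ndarray,
                   params: ForceFieldParams) -> float:
    """Torsion energy of the quadruple, cosine series in the dihedral angle."""
    if not params.torsion_params:
        return 0.0
    b1 = r1 - r0
    b2 = r2 - r1
    b3 = r3 - r2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    d = np.linalg.norm(n1) * np.linalg.norm(n2)
    if d < 1e-12:
        return _cos_series(1.0, params.torsion_params)
    c = float(np.clip(n1 @ n2 / d, -1.0, 1.0))
    return _cos_series(c, params.torsion_params)


# ---------------------------------------------------------------------------
# chain-level sums
# ---------------------------------------------------------------------------

def _chain_bonded(coords: np.ndarray, params: ForceFieldParams,
                  torsion: bool = True) -> float:
    """Bond + bending (+ torsion) energy along one linear chain."""
    e = 0.0
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    e += float(np.sum(bond_energy(d, params)))
    if params.bending_params:
        for j in range(1, len(coords) - 1):
            e += bending_energy(coords[j - 1], coords[j], coords[j + 1], params)
    if torsion and params.torsion_params:
        for j in range(len(coords) - 3):
            e += torsion_energy(coords[j], coords[j + 1], coords[j + 2],
                                coords[j + 3], params)
    return e


def bonded_energy(conf: ChainConformation, params: ForceFieldParams) -> float:
    """Bond, bending and torsion energy of the substrate chain (and the
    linker chain when a chaperone is attached), k_BT.

    Terms entirely internal to a rigid unit are constants of the sampling
    and are still included here (they are well defined); the sampler skips
    them because they never change.
    """
    if conf.n < 2:
        raise ValueError("need at least two substrate beads")
    e = _chain_bonded(conf.substrate_coords, params)
    if conf.attached and conf.geometry is not None:
        g = conf.geometry
        lchain = np.vstack([
            g.nbd_beads[g.nbd_anchor],
            g.linker_beads,
            g.sbd_beads[g.sbd_anchor],
        ])
        # torsion is applied on the substrate chain only (linker torsions are
        # dominated by the rigid anchors and are left out by construction)
        e += _chain_bonded(lchain, params, torsion=False)
    return e


def total_energy(conf: ChainConformation, geom: ChaperoneGeometry | None,
                 params: ForceFieldParams) -> float:
    """Bonded energy plus excluded volume over all non-bonded pairs, k_BT.

    Pairs internal to a rigid body (NBD, SBD + clamped residues 1-7) and
    directly bonded pairs are excluded.  Intended for tests and small
    systems; the sampler evaluates the same terms incrementally.
    """
    conf.validate_wall()
    geom = geom if geom is not None else conf.geometry
    e = bonded_energy(conf, params)

    sub = conf.substrate_coords
    n = len(sub)

    def pair_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        if np.any(d == 0):
            raise ValueError("coincident beads: excluded volume diverges")
        sr6 = np.where(d < params.cutoff, (params.sigma / d) ** 6, 0.0)
        return np.where(d < params.cutoff,
                        4 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon, 0.0)

    # substrate-substrate beyond nearest neighbours (within the free part and
    # across the clamp boundary)
    full = sub
    dmat = np.linalg.norm(full[:, None, :] - full[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=2)
    if conf.attached and geom is not None:
        keep = ~((iu < 7) & (ju < 7))  # intra-clamp pairs are rigid constants
        iu, ju = iu[keep], ju[keep]
    dd = dmat[iu, ju]
    if np.any(dd == 0):
        raise ValueError("coincident beads: excluded volume diverges")
    sr6 = np.where(dd < params.cutoff, (params.sigma / dd) ** 6, 0.0)
    e += float(np.sum(np.where(dd < params.cutoff,
                               4 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon,
                               0.0)))

    if conf.attached and geom is not None:
        free = sub[7:]
        # cross terms between the four mobile groups
        e += float(np.sum(pair_sum(geom.sbd_beads, free)))
        e += float(np.sum(pair_sum(geom.nbd_beads, np.vstack([sub, geom.linker_beads]))))
        e += float(np.sum(pair_sum(geom.nbd_beads, geom.sbd_beads)))
        e += float(np.sum(pair_sum(geom.linker_beads, np.vstack([geom.sbd_beads, sub]))))
        # linker-internal non-bonded pairs (|i-j| >= 2)
        lnk = geom.linker_beads
        if len(lnk) >= 3:
            li, lj = np.triu_indices(len(lnk), k=2)
            dl = np.linalg.norm(lnk[li] - lnk[lj], axis=-1)
            e += float(np.sum(excluded_volume_energy(dl, params))) if len(dl) else 0.0
        # remove pairs that are directly bonded through the linker chain
        la, sa = geom.nbd_beads[geom.nbd_anchor], geom.sbd_beads[geom.sbd_anchor]
        for a, b in ((la, geom.linker_beads[0]), (geom.linker_beads[-1], sa)):
            e -= excluded_volume_energy(float(np.linalg.norm(a - b)), params)
    return e
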