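"""Synthetic inputs: binding-site maps, a stand-in chaperone, PDB fixtures
and an exactly enumerable 2D lattice toy.

Everything the pipeline consumes can be generated here without downloads:

* ``generate_binding_sites`` draws chaperone binding-site positions along a
  substrate with geometrically distributed gaps of mean 35 residues (only
  the mean spacing is prescribed by experiment; the geometric law is the
  maximum-entropy choice for integer gaps with a fixed mean).
* ``build_synthetic_chaperone`` builds a two-sphere bead model with the
  proportions of a two-domain Hsp70 (NBD ~25 A radius, SBD ~20 A radius,
  flexible 9-bead linker, 7-bead clamp on the SBD surface pointing away
  from the NBD).  A declared geometric approximation, not a structure.
* ``enumerate_lattice_ratio`` exhaustively enumerates a small self-avoiding
  lattice chain with a rigid obstacle near a wall line -- an exact oracle
  for the overlap-fraction machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .geometry import ChainConformation, ChaperoneGeometry, geometry_to_pdb

__all__ = [
    "BindingSiteMap",
    "generate_binding_sites",
    "build_synthetic_chaperone",
    "LatticeToy",
    "enumerate_lattice_ratio",
    "sample_lattice_ratio",
    "write_fixture_pdb",
    "fixture_chain_pdb",
]


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------

@dataclass
class BindingSiteMap:
    """Ordered binding-site positions n_B (residues from the matrix terminus)."""

    positions: np.ndarray
    L: int
    mean_spacing: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if len(self.positions) and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 0
            or self.positions[-1] >= self.L
        ):
            raise ValueError("positions must be strictly increasing within [0, L-1]")


def generate_binding_sites(
    L: int = 300,
    mean_spacing: float = 35.0,
    seed: int | np.random.Generator | None = None,
) -> BindingSiteMap:
    """Draw a binding-site distribution with mean gap ``mean_spacing``.

    Gaps between consecutive sites are i.i.d. geometric (support 1, 2, ...)
    with mean ``mean_spacing``; the first site is one such gap from the
    matrix terminus, shifted by one so a site at the terminus itself
    (n_B = 0) is possible but not forced.  An empty map is a legal draw for
    small L.
    """
    if L <= 0 or mean_spacing <= 0:
        raise ValueError("L and mean_spacing must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = 1.0 / mean_spacing
    positions = []
    pos = int(rng.geometric(p)) - 1
    while pos < L:
        positions.append(pos)
        pos += int(rng.geometric(p))
    return BindingSiteMap(
        positions=np.asarray(positions, dtype=int),
        L=L,
        mean_spacing=mean_spacing,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# synthetic chaperone
# ---------------------------------------------------------------------------

def _lattice_ball(radius: float, spacing: float, center: np.ndarray) -> np.ndarray:
    """Cubic-lattice points strictly inside a sphere."""
    m = int(np.floor(radius / spacing))
    ax = np.arange(-m, m + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + center


def build_synthetic_chaperone(
    nbd_radius: float = 25.0,
    sbd_radius: float = 20.0,
    bead_spacing: float = 3.8,
    linker_beads: int = 9,
    domain_gap: float = 12.0,
    seed: int | None = None,
) -> ChaperoneGeometry:
    """Two quasi-spherical bead clusters joined by a flexible linker.

    Deterministic construction (``seed`` is accepted for interface symmetry
    but unused).  The SBD sits at the body-frame origin with the NBD along
    +x at centre distance ``sbd_radius + domain_gap + nbd_radius``; the
    7-bead clamp lies tangentially on the -x side of the SBD (pointing away
    from the NBD), offset 2 A outward from the surface.  The linker is laid
    over the inter-domain gap with enough initial arc length for its bonds.
    """
    if not (nbd_radius > bead_spacing > 0) or not (sbd_radius > bead_spacing):
        raise ValueError("radii must exceed bead_spacing, spacing must be positive")
    if sbd_radius < 12.0:
        raise ValueError(
            "sbd_radius must be >= 12 A: the substrate-binding cleft has to "
            "enclose the 26.6 A clamped heptapeptide"
        )

    sbd_center = np.zeros(3)
    nbd_center = np.array([sbd_radius + domain_gap + nbd_radius, 0.0, 0.0])
    sbd = _lattice_ball(sbd_radius, bead_spacing, sbd_center)
    nbd = _lattice_ball(nbd_radius, bead_spacing, nbd_center)

    # linker anchors: facing surface beads of each domain
    sbd_anchor = int(np.argmax(sbd[:, 0]))
    nbd_anchor = int(np.argmin(nbd[:, 0]))
    a = sbd[sbd_anchor]
    b = nbd[nbd_anchor]

    # lay the linker on a tent path NBD-anchor -> apex -> SBD-anchor (bond
    # order) with total path length n_bonds * 3.8 so initial bonds are near
    # their rest length; the apex lifts the chain clear of both domains
    n_bonds = linker_beads + 1
    path = n_bonds * 3.8
    chord = np.linalg.norm(b - a)
    h = np.sqrt(max((path / 2.0) ** 2 - (chord / 2.0) ** 2, 1.0))
    apex = (a + b) / 2.0 + np.array([0.0, 0.0, h])
    pts = []
    for k in range(1, linker_beads + 1):
        s = k * path / n_bonds
        if s <= path / 2.0:
            t = s / (path / 2.0)
            pts.append(b + t * (apex - b))
        else:
            t = (s - path / 2.0) / (path / 2.0)
            pts.append(apex + t * (a - apex))
    lnk = _relax_linker(np.asarray(pts), b, a, np.vstack([nbd, sbd]))

    # clamp: a straight 7-bead chord laid THROUGH a cleft carved beneath the
    # far (-x) surface of the SBD.  In the chaperone the bound heptapeptide
    # is enclosed by the substrate-binding cleft (beta-sandwich below, lid
    # above) and the chain exits from within the domain body -- that
    # enclosure, with domain material on all sides of the exit, is what
    # generates the strong entropic-pulling force near the wall.  The cleft
    # floor sits two bead layers (7.6 A) beneath the surface; an exit
    # channel continues along the clamp axis through the surface.
    depth = 2.0 * 3.8
    h = max(sbd_radius - depth, 2.0)
    clamp_y = (3.0 - np.arange(7)) * 3.8  # clamp[6] at -11.4: the exit end
    clamp = np.column_stack([-h * np.ones(7), clamp_y, np.zeros(7)])
    half_chord = np.sqrt(max(sbd_radius**2 - h**2, 0.0))
    p0 = np.array([-h, 13.0, 0.0])
    p1 = np.array([-h, -(half_chord + 2.0), 0.0])
    d_seg = _dist_to_segment(sbd, p0, p1)
    channel_r = 4.5
    sbd = sbd[d_seg >= channel_r]
    d_seg = d_seg[d_seg >= channel_r]
    sbd_anchor = int(np.argmax(sbd[:, 0]))  # re-derive after carving

    shell = 1.6 * bead_spacing
    geom = ChaperoneGeometry(
        nbd_beads=nbd,
        sbd_beads=sbd,
        linker_beads=lnk,
        clamp_sites=clamp,
        provenance="synthetic",
        sbd_anchor=sbd_anchor,
        nbd_anchor=nbd_anchor,
        nbd_subset=np.flatnonzero(
            np.linalg.norm(nbd - nbd_center, axis=1) >= nbd_radius - shell
        ),
        # the interacting subset needs the outer shell plus the cleft walls
        sbd_subset=np.flatnonzero(
            (np.linalg.norm(sbd - sbd_center, axis=1) >= sbd_radius - shell)
            | (d_seg < channel_r + 2.0 * bead_spacing)
        ),
    )
    geom.validate()
    return geom


def _dist_to_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(pts - proj, axis=1)


def _relax_linker(lnk0: np.ndarray, start: np.ndarray, end: np.ndarray,
                  obstacles: np.ndarray, sigma: float = 3.8) -> np.ndarray:
    """Deterministically relax the initial linker path (bonds + repulsion).

    Minimizes harmonic bonds along start -> beads -> end plus a soft WCA-like
    repulsion from the domain beads, so the constructed geometry starts free
    of steric clashes.  Build-time convenience only; the sampler's energies
    are defined by the force field, not by this relaxation.
    """
    from scipy.optimize import minimize
    from scipy.spatial.distance import cdist

    nl = len(lnk0)
    rc = 2.0 ** (1.0 / 6.0) * sigma

    def energy(x: np.ndarray) -> float:
        pts = np.vstack([start, x.reshape(nl, 3), end])
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        e = float(np.sum(50.0 * (d - 3.8) ** 2))
        dd = cdist(pts[1:-1], obstacles)
        close = dd[dd < rc]
        if close.size:
            sr6 = (sigma / np.maximum(close, 0.5)) ** 6
            e += float(np.sum(4.0 * 3.0 * (sr6 * sr6 - sr6) + 3.0))
        return e

    res = minimize(energy, lnk0.ravel(), method="L-BFGS-B",
                   options={"maxiter": 300})
    return res.x.reshape(nl, 3)


# ---------------------------------------------------------------------------
# 2D lattice toy: exact oracle for the overlap-fraction estimator
# ---------------------------------------------------------------------------

@dataclass
class LatticeToy:
    """Self-avoiding chain on Z^2 with a rigid obstacle and a wall line.

    The chain has ``chain_length`` beads; bead ``chain_length`` is pinned at
    the origin on the wall line y = 0 and every chain bead must satisfy
    y >= 0 (the wall is hard for the chain).  ``obstacle_cells`` are integer
    offsets rigidly attached to bead 1 (translation only); the wall is
    transparent to the obstacle, and a configuration overlaps when any
    obstacle cell has y < 0.
    """

    chain_length: int
    obstacle_cells: tuple[tuple[int, int], ...] = ()
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise ValueError("chain needs at least 2 beads")


_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _enumerate_chains(toy: LatticeToy):
    """Yield all legal chains as tuples of (x, y) with bead N first."""
    m = toy.chain_length

    def rec(chain: tuple) -> list:
        if len(chain) == m:
            return [chain]
        out = []
        x, y = chain[-1]
        for dx, dy in _STEPS:
            nxt = (x + dx, y + dy)
            if nxt[1] < 0 or nxt in chain:
                continue
            out.extend(rec(chain + (nxt,)))
        return out

    return rec(((0, 0),))


def enumerate_lattice_ratio(toy: LatticeToy) -> Fraction:
    """Exact non-overlap fraction by exhaustive enumeration.

    Counts all self-avoiding, wall-legal chain configurations and the subset
    whose obstacle cells all satisfy y >= 0.  Exact rational result.
    """
    if toy.chain_length > 12:
        raise ValueError("enumeration is limited to chains of <= 12 beads")
    total = 0
    good = 0
    for chain in _enumerate_chains(toy):
        total += 1
        bead1 = chain[-1]  # chains are built from bead N back to bead 1
        if all(bead1[1] + dy >= 0 for _, dy in toy.obstacle_cells):
            good += 1
    if total == 0:
        raise ValueError("no legal chain configurations")
    return Fraction(good, total)


def sample_lattice_ratio(
    toy: LatticeToy, n_sweeps: int, seed: int | None = None, thin: int = 1
) -> np.ndarray:
    """Metropolis sampling of the lattice toy; returns 0/1 indicators.

    Moves: end-bead regrowth (bead 1 proposed uniformly among the 4 lattice
    neighbours of bead 2) and kink flips for interior beads (uniform over
    the common neighbours of the two chain neighbours; the proposal-set size
    depends only on their relative position, hence symmetric).  Bead N stays
    pinned at the origin.  All legal configurations have equal weight.
    """
    rng = np.random.default_rng(seed)
    m = toy.chain_length
    # internal order: index 0 = bead N (pinned) ... index m-1 = bead 1
    chain = [(0, i) for i in range(m)]
    indicators = []
    for sweep in range(n_sweeps):
        for _ in range(m - 1):
            i = int(rng.integers(1, m))
            if i == m - 1:  # bead 1: regrow around its single neighbour
                bx, by = chain[m - 2]
                dx, dy = _STEPS[int(rng.integers(4))]
                cand = (bx + dx, by + dy)
            else:
                (ax, ay), (bx, by) = chain[i - 1], chain[i + 1]
                cands = [
                    (ax + dx, ay + dy)
                    for dx, dy in _STEPS
                    if abs(ax + dx - bx) + abs(ay + dy - by) == 1
                ]
                cand = cands[int(rng.integers(len(cands)))]
            if cand[1] < 0:
                continue
            if any(cand == c for j, c in enumerate(chain) if j != i):
                continue
            chain[i] = cand
        if sweep % thin == 0:
            b1y = chain[m - 1][1]
            ok = all(b1y + dy >= 0 for _, dy in toy.obstacle_cells)
            indicators.append(1 if ok else 0)
    return np.asarray(indicators, dtype=np.int8)


# ---------------------------------------------------------------------------
# PDB fixtures
# ---------------------------------------------------------------------------

def fixture_chain_pdb(n_residues: int, drop_residues: tuple[int, ...] = ()) -> str:
    """CA-only PDB text of an n-residue curve with sequential numbering.

    Residues are laid on a loose helix (3.8 A spacing along the arc) so no
    two CA positions coincide; ``drop_residues`` omits the listed residues,
    useful for exercising missing-atom error paths.
    """
    if n_residues <= 0:
        raise ValueError("need a positive residue count")
    lines = []
    serial = 1
    # gentle solenoid: ~3.6 A horizontal arc step + 1.2 A rise = 3.8 A per
    # residue, with low curvature so the chain is locally straight
    radius = 40.0
    turn = 3.6 / radius
    rise = 1.2
    for res in range(1, n_residues + 1):
        if res in drop_residues:
            continue
        x = radius * np.cos(res * turn)
        y = radius * np.sin(res * turn)
        z = res * rise
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA A{res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fixture_pdb(obj, path) -> None:
    """Write a CA-only PDB fixture.

    ``obj`` may be a residue count (a synthetic chain is generated) or a
    ``ChaperoneGeometry`` (exported with sequential residue numbering).
    """
    if isinstance(obj, (int, np.integer)):
        text = fixture_chain_pdb(int(obj))
    elif isinstance(obj, ChaperoneGeometry):
        if len(obj.nbd_beads) == 0 or len(obj.sbd_beads) == 0:
            raise ValueError("cannot export an empty geometry")
        text = geometry_to_pdb(obj)
    else:
        raise TypeError("expected a residue count or a ChaperoneGeometry")
    with open(path, "w") as fh:
        fh.write(text)
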