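"""Coarse-grained geometry of the chaperone/substrate/wall system.

One bead per residue (C-alpha position).  The membrane is a flat wall at
z = 0 that acts as a hard constraint on substrate beads only; the chaperone
may cross it, and configurations in which any chaperone or linker bead
centre lies at z < 0 are flagged as overlapping.  The nucleotide-binding
domain (NBD) and the substrate-binding domain (SBD) are rigid bodies; the
interdomain linker is flexible.  The substrate heptapeptide clamped in the
SBD cleft (residues 1-7 of the substrate) moves rigidly with the SBD.

Residue numbering is 1-based throughout; substrate residue 1 is the
matrix-side terminus and residue ``n`` (the last imported one) is tethered
at the origin on the wall plane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChaperoneGeometry",
    "ChainConformation",
    "WallModel",
    "MissingResidueError",
    "load_chaperone_ca",
    "attach_chaperone",
    "build_complex",
    "check_overlap",
    "geometry_to_pdb",
]


class MissingResidueError(ValueError):
    """A requested residue has no CA atom in the supplied PDB text."""


@dataclass
class ChaperoneGeometry:
    """Rigid two-domain chaperone with a flexible linker and a clamp site.

    Coordinates are in Angstrom.  ``clamp_sites`` holds the 7 positions at
    which the bound substrate heptapeptide (residues 1-7) sits; it belongs
    to the SBD rigid unit.  ``sbd_anchor`` / ``nbd_anchor`` index the domain
    beads to which the linker chain is bonded.
    """

    nbd_beads: np.ndarray
    sbd_beads: np.ndarray
    linker_beads: np.ndarray
    clamp_sites: np.ndarray
    provenance: str = "synthetic"
    sbd_anchor: int = 0
    nbd_anchor: int = 0
    #: optional index subsets used by the sampler for excluded-volume and
    #: overlap evaluation (outer shell of a filled domain); None = all beads
    nbd_subset: np.ndarray | None = None
    sbd_subset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nbd_beads = np.asarray(self.nbd_beads, dtype=float).reshape(-1, 3)
        self.sbd_beads = np.asarray(self.sbd_beads, dtype=float).reshape(-1, 3)
        self.linker_beads = np.asarray(self.linker_beads, dtype=float).reshape(-1, 3)
        self.clamp_sites = np.asarray(self.clamp_sites, dtype=float).reshape(-1, 3)

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if len(self.nbd_beads) == 0 or len(self.sbd_beads) == 0:
            raise ValueError("both NBD and SBD must contain at least one bead")
        if self.clamp_sites.shape != (7, 3):
            raise ValueError("clamp_sites must hold exactly 7 coordinates")
        # clamp must sit in/on the SBD cleft
        d = np.linalg.norm(
            self.clamp_sites[:, None, :] - self.sbd_beads[None, :, :], axis=-1
        )
        if not np.all(d.min(axis=1) < 8.0):
            raise ValueError("each clamp site must lie within 8 A of an SBD bead")

    # -- helpers --------------------------------------------------------
    def all_chaperone_beads(self) -> np.ndarray:
        """NBD + SBD + linker beads (clamp excluded: those are substrate)."""
        return np.vstack([self.nbd_beads, self.sbd_beads, self.linker_beads])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChaperoneGeometry":
        """Apply a rigid transform x -> R x + t to every coordinate set."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return replace(
            self,
            nbd_beads=self.nbd_beads @ R.T + t,
            sbd_beads=self.sbd_beads @ R.T + t,
            linker_beads=self.linker_beads @ R.T + t,
            clamp_sites=self.clamp_sites @ R.T + t,
        )

    def interaction_sets(self) -> tuple[np.ndarray, np.ndarray]:
        """(nbd, sbd) bead sets actually used for excluded volume/overlap.

        For a filled synthetic domain only the outer shell matters: the
        wall-overlap minimum over z is attained on the convex hull, and a
        particle cannot reach an interior bead without first paying a huge
        repulsive penalty at the shell.
        """
        nbd = self.nbd_beads if self.nbd_subset is None else self.nbd_beads[self.nbd_subset]
        sbd = self.sbd_beads if self.sbd_subset is None else self.sbd_beads[self.sbd_subset]
        return nbd, sbd


@dataclass
class WallModel:
    """Flat wall at z = 0.

    Hard constraint on substrate bead centres (z >= 0); transparent to the
    chaperone, whose bead centres merely flag an overlap when z < 0.
    The boundary convention is strict: a centre exactly on the plane does
    not overlap.
    """

    #: numerical slack when validating the substrate-side hard constraint
    tol: float = 1e-9


@dataclass
class ChainConformation:
    """Substrate chain of ``n`` imported residues plus the chaperone pose.

    Row ``i`` of ``substrate_coords`` is residue ``i+1``.  Residue ``n``
    (``tether_index``) is pinned at the origin on the wall.  When attached,
    residues 1-7 coincide with the chaperone clamp sites and move rigidly
    with the SBD.
    """

    substrate_coords: np.ndarray
    geometry: ChaperoneGeometry | None = None
    attached: bool = False

    def __post_init__(self) -> None:
        self.substrate_coords = np.asarray(self.substrate_coords, dtype=float).reshape(-1, 3)

    @property
    def n(self) -> int:
        return len(self.substrate_coords)

    @property
    def tether_index(self) -> int:
        return self.n

    def validate_wall(self, wall: WallModel | None = None) -> None:
        """Check the hard-wall condition z >= 0 for every substrate bead."""
        wall = wall or WallModel()
        z = self.substrate_coords[:, 2]
        if np.any(z < -wall.tol):
            bad = int(np.argmin(z))
            raise ValueError(
                f"substrate residue {bad + 1} at z={z[bad]:.3f} A violates the wall"
            )

    def validate_tether(self, wall: WallModel | None = None) -> None:
        """Check that residue n sits exactly at the origin on the wall
        (the sampling constraint; in-plane translations of the whole
        complex are physically equivalent and allowed elsewhere)."""
        wall = wall or WallModel()
        self.validate_wall(wall)
        if np.linalg.norm(self.substrate_coords[-1]) > wall.tol:
            raise ValueError("tethered residue must sit exactly at the origin")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def load_chaperone_ca(
    pdb_text: str,
    nbd_range: tuple[int, int] = (4, 387),
    sbd_range: tuple[int, int] = (397, 603),
    linker_range: tuple[int, int] = (388, 396),
    chain_id: str | None = None,
    clamp_sites: np.ndarray | None = None,
) -> ChaperoneGeometry:
    """Extract a one-bead-per-residue chaperone from PDB text.

    Only CA atoms of the first model are read (HETATM ignored).  The default
    residue intervals are the DnaK domain boundaries: NBD 4-387, linker
    388-396, SBD 397-603 (intervals inclusive, 1-based PDB numbering).

    If ``clamp_sites`` is not given, a 7-bead extended clamp (3.8 A spacing)
    is laid tangentially at the SBD surface point farthest from the NBD
    centroid, i.e. in the peptide groove region pointing away from the NBD.
    """
    import biotite.structure.io.pdb as _pdb

    for name, (lo, hi) in (
        ("nbd_range", nbd_range),
        ("sbd_range", sbd_range),
        ("linker_range", linker_range),
    ):
        if hi < lo:
            raise ValueError(f"{name} is empty: {lo}..{hi}")

    pdb_file = _pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = _pdb.get_structure(pdb_file, model=1)
    mask = (atoms.atom_name == "CA") & (~atoms.hetero)
    if chain_id is not None:
        mask &= atoms.chain_id == chain_id
    ca = atoms[mask]
    coord_by_res = {int(r): c for r, c in zip(ca.res_id, ca.coord)}

    def pick(lo: int, hi: int) -> np.ndarray:
        out = []
        for res in range(lo, hi + 1):
            if res not in coord_by_res:
                raise MissingResidueError(
                    f"no CA atom for residue {res} in requested interval {lo}-{hi}"
                )
            out.append(coord_by_res[res])
        return np.asarray(out, dtype=float)

    nbd = pick(*nbd_range)
    sbd = pick(*sbd_range)
    linker = pick(*linker_range)

    # linker attachment: domain beads adjacent in sequence to the linker
    sbd_anchor = 0 if sbd_range[0] > linker_range[1] else len(sbd) - 1
    nbd_anchor = len(nbd) - 1 if nbd_range[1] < linker_range[0] else 0

    if clamp_sites is None:
        clamp_sites = _default_clamp(sbd, nbd)

    geom = ChaperoneGeometry(
        nbd_beads=nbd,
        sbd_beads=sbd,
        linker_beads=linker,
        clamp_sites=clamp_sites,
        provenance="pdb",
        sbd_anchor=sbd_anchor,
        nbd_anchor=nbd_anchor,
    )
    geom.validate()
    return geom


def _default_clamp(sbd: np.ndarray, nbd: np.ndarray, spacing: float = 3.8) -> np.ndarray:
    """Extended 7-bead clamp laid tangentially on the SBD surface.

    Placed at the surface point farthest from the NBD centroid (pointing
    away from the NBD), offset slightly outward so the peptide does not
    clash with domain beads, and oriented perpendicular to the local radial
    direction.
    """
    c_sbd = sbd.mean(axis=0)
    c_nbd = nbd.mean(axis=0)
    away = c_sbd - c_nbd
    nrm = np.linalg.norm(away)
    away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
    # farthest surface bead in the "away" direction
    proj = (sbd - c_sbd) @ away
    surf = sbd[int(np.argmax(proj))]
    radial = surf - c_sbd
    radial /= max(np.linalg.norm(radial), 1e-9)
    anchor = surf + 2.0 * radial
    # groove axis: the leading principal axis of the local bead patch, so
    # the clamp hugs the structure instead of sticking out into space
    d2 = ((sbd - surf) ** 2).sum(axis=1)
    patch = sbd[np.argsort(d2)[: min(8, len(sbd))]]
    patch = patch - patch.mean(axis=0)
    _, _, vt = np.linalg.svd(patch, full_matrices=False)
    tang = vt[0]
    offsets = (np.arange(7) - 3.0) * spacing
    # slide the clamp along the groove axis until every site has structural
    # support (an SBD bead within 8 A) -- near a domain edge the farthest
    # surface bead may otherwise leave part of the clamp unsupported
    for shift in (0.0, -spacing, spacing, -2 * spacing, 2 * spacing,
                  -3 * spacing, 3 * spacing):
        clamp = (anchor + shift * tang)[None, :] + offsets[:, None] * tang[None, :]
        d = np.linalg.norm(clamp[:, None, :] - sbd[None, :, :], axis=-1)
        if np.all(d.min(axis=1) < 8.0):
            return clamp
    raise ValueError(
        "could not place a supported clamp on the SBD surface; pass explicit "
        "clamp_sites"
    )


# ---------------------------------------------------------------------------
# Complex construction
# ---------------------------------------------------------------------------

def attach_chaperone(chain: ChainConformation, geom: ChaperoneGeometry) -> ChainConformation:
    """Clamp substrate residues 1-7 into the chaperone SBD cleft.

    Residues 1-7 are superposed exactly onto ``clamp_sites`` (they then
    belong to the SBD rigid unit); the remaining residues keep their
    coordinates.  Requires n >= 8 so that a complete binding site is
    exposed.  Idempotent.
    """
    if chain.n < 8:
        raise ValueError("binding site not exposed: need n >= 8 residues")
    coords = chain.substrate_coords.copy()
    coords[0:7] = geom.clamp_sites
    return ChainConformation(substrate_coords=coords, geometry=geom, attached=True)


def build_complex(
    n: int,
    geom: ChaperoneGeometry,
    bond_length: float = 3.8,
) -> ChainConformation:
    """Construct a wall-legal, non-overlapping starting complex.

    The substrate is laid along +z from the tether at the origin; the
    chaperone is rigidly posed so that its clamp meets the top of the chain
    with the SBD body above the wall, and residues 1-7 are attached to the
    clamp.  This is only a starting point for equilibration.
    """
    if n < 8:
        raise ValueError("binding site not exposed: need n >= 8 residues")
    geom.validate()

    # pose the chaperone so the chain-exit direction of the clamp (from the
    # first clamped residue toward the last, where the free chain continues)
    # points straight down at the wall; the substrate then descends from the
    # clamp through the cleft exit to the tether at the origin
    exit_dir = geom.clamp_sites[6] - geom.clamp_sites[0]
    exit_dir /= np.linalg.norm(exit_dir)
    R = _rotation_between(exit_dir, np.array([0.0, 0.0, -1.0]))
    posed = geom.transformed(R, np.zeros(3))

    # chain beads n..8 go straight down to the origin; clamp bead 7 (index
    # 6) sits one bond above the top of that stalk
    top = np.array([0.0, 0.0, (n - 8) * bond_length])
    target = top + np.array([0.0, 0.0, bond_length])
    shift = target - posed.clamp_sites[6]
    posed = posed.transformed(np.eye(3), shift)
    # the chaperone body may dip below the wall here: that is legal (the
    # wall is transparent to it) and equilibration relaxes the pose

    coords = np.zeros((n, 3))
    for i in range(7, n):
        coords[i] = [0.0, 0.0, (n - 1 - i) * bond_length]
    chain = ChainConformation(substrate_coords=coords)
    return attach_chaperone(chain, posed)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


# ---------------------------------------------------------------------------
# Overlap indicator
# ---------------------------------------------------------------------------

def check_overlap(conf: ChainConformation, wall: WallModel | None = None) -> bool:
    """True iff any chaperone or linker bead centre lies strictly below z=0.

    Pure function of the coordinates.  Raises if a substrate bead violates
    the hard wall (that would be a sampler bug, not a physical state).
    """
    wall = wall or WallModel()
    if np.any(conf.substrate_coords[:, 2] < -wall.tol):
        raise ValueError("substrate bead below the wall: hard constraint violated")
    if conf.geometry is None:
        return False
    return bool(conf.geometry.all_chaperone_beads()[:, 2].min() < 0.0)


# ---------------------------------------------------------------------------
# PDB export
# ---------------------------------------------------------------------------

def geometry_to_pdb(geom: ChaperoneGeometry) -> str:
    """Render the chaperone as CA-only PDB text for visual inspection.

    Residues are numbered sequentially: NBD first, then linker, then SBD,
    then the 7 clamp positions (chain S).
    """
    import biotite.structure as _struc
    import biotite.structure.io.pdb as _pdb

    blocks = [
        (geom.nbd_beads, "A"),
        (geom.linker_beads, "A"),
        (geom.sbd_beads, "A"),
        (geom.clamp_sites, "S"),
    ]
    total = sum(len(b) for b, _ in blocks)
    arr = _struc.AtomArray(total)
    i = 0
    res = 1
    for coords, ch in blocks:
        for xyz in coords:
            arr.coord[i] = xyz
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
            arr.res_name[i] = "ALA"
            arr.res_id[i] = res
            arr.chain_id[i] = ch
            arr.hetero[i] = False
            i += 1
            res += 1
    f = _pdb.PDBFile()
    _pdb.set_structure(f, arr)
    out = io.StringIO()
    f.write(out)
    return out.getvalue()
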