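"""Equilibrium sampling of the wall-tethered, chaperone-bound complex.

The central quantity is the fraction of sampled configurations in which no
chaperone bead crosses the wall.  In this model the wall is transparent to
the chaperone during sampling, so that fraction is exactly the ratio of the
partition function with the excluded chaperone volume enforced against the
wall to the partition function without that restriction -- the quantity
whose negative logarithm is the entropic-pulling free energy.

Errors on the fraction are estimated by block averaging with block-size
doubling until the error estimate plateaus, which accounts for the
autocorrelation of the Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from . import _mcmc
from .forcefield import ForceFieldParams
from .geometry import ChainConformation, ChaperoneGeometry, build_complex

__all__ = [
    "SamplerConfig",
    "OverlapTrace",
    "FractionEstimate",
    "BlockAnalysis",
    "sample_overlap_trace",
    "estimate_overlap_fraction",
    "block_error_analysis",
]


@dataclass
class SamplerConfig:
    """Sampler settings.

    One sweep attempts one move per free substrate bead, one per linker
    bead, two rigid SBD moves, two rigid NBD moves and two pivots.  The
    default equilibration is 10% of the production sweeps; one indicator
    frame is recorded per ``thinning`` sweeps.
    """

    n_sweeps: int = 50_000
    equilibration_sweeps: int | None = None
    thinning: int = 1
    seed: int = 0
    mode: str = "metropolis_mc"
    # proposal scales.  Bonds are stiff (k ~ 100 k_BT/A^2), so displacement
    # steps are small and the workhorse moves are bond-preserving rotations:
    # crankshafts, the SBD swing about its chain/linker attachment axis,
    # NBD rotations about its anchor, and pivots of the whole head group.
    step_sub: float = 0.22       # A, free-bead displacement
    crank_sub: float = 1.6       # rad, crankshaft about the neighbour axis
    step_lnk: float = 0.20       # A, linker-bead displacement
    crank_lnk: float = 1.6       # rad
    rot_sbd_axis: float = 0.9    # rad, SBD swing about the attachment axis
    rot_sbd_small: float = 0.05  # rad, general SBD rotation about sub[6]
    trans_sbd: float = 0.12      # A
    rot_nbd: float = 0.5         # rad, NBD rotation about its anchor
    trans_nbd: float = 0.14      # A
    rot_arm: float = 0.4         # rad, NBD+linker swing about the SBD anchor
    rot_pivot: float = 0.35      # rad

    def __post_init__(self) -> None:
        if self.n_sweeps <= 0 or self.thinning <= 0:
            raise ValueError("n_sweeps and thinning must be positive")
        eq = self.resolved_equilibration
        if not self.n_sweeps > eq >= 0:
            raise ValueError("need n_sweeps > equilibration_sweeps >= 0")
        if self.mode not in ("metropolis_mc", "overdamped_langevin"):
            raise ValueError(f"unknown sampler mode: {self.mode!r}")

    @property
    def resolved_equilibration(self) -> int:
        if self.equilibration_sweeps is None:
            return self.n_sweeps // 10
        return self.equilibration_sweeps


@dataclass
class OverlapTrace:
    """Ordered 0/1 record (1 = no chaperone bead below the wall) per frame."""

    indicators: np.ndarray
    n: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        if self.indicators.size == 0:
            raise ValueError("trace must contain at least one frame")
        if not np.all((self.indicators == 0) | (self.indicators == 1)):
            raise ValueError("indicators must be 0/1")


MOVE_NAMES = ("substrate", "pivot", "sbd", "nbd", "linker")


def _prepare_state(conf: ChainConformation):
    """Split an attached complex into the kernel's state arrays."""
    geom = conf.geometry
    nbd_set, sbd_set = geom.interaction_sets()
    # the linker anchors must be part of the interacting arrays
    if geom.sbd_subset is not None:
        idx = list(geom.sbd_subset)
        if geom.sbd_anchor not in idx:
            idx.append(geom.sbd_anchor)
            sbd_set = geom.sbd_beads[np.asarray(idx)]
        ia_s = idx.index(geom.sbd_anchor)
    else:
        ia_s = geom.sbd_anchor
    if geom.nbd_subset is not None:
        idx = list(geom.nbd_subset)
        if geom.nbd_anchor not in idx:
            idx.append(geom.nbd_anchor)
            nbd_set = geom.nbd_beads[np.asarray(idx)]
        ia_n = idx.index(geom.nbd_anchor)
    else:
        ia_n = geom.nbd_anchor
    return (
        np.ascontiguousarray(conf.substrate_coords, dtype=np.float64),
        np.ascontiguousarray(geom.clamp_sites, dtype=np.float64),
        np.ascontiguousarray(sbd_set, dtype=np.float64),
        np.ascontiguousarray(nbd_set, dtype=np.float64),
        np.ascontiguousarray(geom.linker_beads, dtype=np.float64),
        int(ia_s),
        int(ia_n),
    )


def sample_overlap_trace(
    n: int,
    geom: ChaperoneGeometry,
    ff: ForceFieldParams,
    cfg: SamplerConfig,
    return_state: bool = False,
):
    """Sample the complex with ``n`` imported residues; return the overlap
    trace (and optionally the final coordinates for diagnostics).

    Requires n >= 8 (a complete binding site must be exposed).  The run is
    deterministic for a fixed ``cfg`` (including the seed).
    """
    if n < 8:
        raise ValueError("need n >= 8: a complete binding site must be exposed")
    if cfg.mode != "metropolis_mc":
        raise NotImplementedError(
            "only the metropolis_mc sampling mode is implemented"
        )
    if len(geom.linker_beads) < 1:
        raise ValueError("the chaperone must have at least one linker bead")

    conf = build_complex(n, geom, bond_length=ff.bond_length)
    sub, clamp_ref, sbd_ref, nbd_ref, lnk, ia_s, ia_n = _prepare_state(conf)

    R_s = np.eye(3)
    t_s = np.zeros(3)
    R_n = np.eye(3)
    t_n = np.zeros(3)
    ba = np.asarray(ff.bending_params, dtype=np.float64)
    ta = np.asarray(ff.torsion_params, dtype=np.float64)
    acc = np.zeros((5, 2), dtype=np.int64)
    common = dict(
        sub=sub, clamp_ref=clamp_ref, sbd_ref=sbd_ref, nbd_ref=nbd_ref, lnk=lnk,
        R_s=R_s, t_s=t_s, R_n=R_n, t_n=t_n, ia_s=ia_s, ia_n=ia_n,
        sigma=ff.sigma, eps=ff.epsilon, r0=ff.bond_length, kb=ff.bond_stiffness,
        ba=ba, ta=ta,
        step_sub=cfg.step_sub, crank_sub=cfg.crank_sub,
        step_lnk=cfg.step_lnk, crank_lnk=cfg.crank_lnk,
        rot_sbd_axis=cfg.rot_sbd_axis, rot_sbd_small=cfg.rot_sbd_small,
        trans_sbd=cfg.trans_sbd,
        rot_nbd=cfg.rot_nbd, trans_nbd=cfg.trans_nbd, rot_arm=cfg.rot_arm,
        rot_pivot=cfg.rot_pivot,
    )

    eq = cfg.resolved_equilibration
    if eq > 0:
        none_rec = np.empty(0, dtype=np.int8)
        _mcmc.run_sampler(n_sweeps=eq, thin=1, seed=_sub_seed(cfg.seed, 0),
                          indicators=none_rec, acc=acc, **common)
        if acc[:, 1].sum() == 0:
            raise RuntimeError(
                "no move was accepted during equilibration; "
                "reduce the proposal step sizes"
            )
        acc[:] = 0

    n_frames = (cfg.n_sweeps - 1) // cfg.thinning + 1
    indicators = np.zeros(n_frames, dtype=np.int8)
    rec = _mcmc.run_sampler(n_sweeps=cfg.n_sweeps, thin=cfg.thinning,
                            seed=_sub_seed(cfg.seed, 1),
                            indicators=indicators, acc=acc, **common)
    indicators = indicators[:rec]

    attempts = acc[:, 0]
    rates = {
        name: (acc[i, 1] / attempts[i] if attempts[i] else float("nan"))
        for i, name in enumerate(MOVE_NAMES)
    }
    trace = OverlapTrace(
        indicators=indicators,
        n=n,
        metadata={
            "seed": cfg.seed,
            "n_sweeps": cfg.n_sweeps,
            "equilibration_sweeps": eq,
            "thinning": cfg.thinning,
            "acceptance_rates": rates,
        },
    )
    if not return_state:
        return trace
    final_geom = replace(
        conf.geometry,
        sbd_beads=sbd_ref @ R_s.T + t_s,
        nbd_beads=nbd_ref @ R_n.T + t_n,
        linker_beads=lnk,
        clamp_sites=clamp_ref @ R_s.T + t_s,
        nbd_subset=None,
        sbd_subset=None,
    )
    final = ChainConformation(substrate_coords=sub, geometry=final_geom, attached=True)
    return trace, final


def _sub_seed(seed: int, stream: int) -> int:
    """Derive independent 31-bit kernel seeds from a master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# fraction estimation with block averaging
# ---------------------------------------------------------------------------

class FractionEstimate(NamedTuple):
    fraction: float
    error: float


class BlockAnalysis(NamedTuple):
    block_sizes: np.ndarray
    errors: np.ndarray
    chosen_block: int
    plateau_found: bool


def block_error_analysis(x: np.ndarray, min_blocks: int = 8,
                         rel_tol: float = 0.05) -> BlockAnalysis:
    """Standard error of the mean of a correlated series by block doubling.

    Block size doubles until either the error estimate changes by less than
    ``rel_tol`` upon doubling (plateau) or fewer than ``min_blocks`` blocks
    remain; without a plateau the largest-block error is reported and
    flagged.
    """
    x = np.asarray(x, dtype=float)
    sizes = []
    errs = []
    b = 1
    while len(x) // b >= min_blocks:
        nb = len(x) // b
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        errs.append(float(np.std(means, ddof=1) / np.sqrt(nb)))
        sizes.append(b)
        b *= 2
    sizes_a = np.asarray(sizes)
    errs_a = np.asarray(errs)
    if np.all(errs_a == 0.0):  # constant series: no error at any block size
        return BlockAnalysis(sizes_a, errs_a, int(sizes_a[0]), True)
    chosen = sizes_a[-1]
    plateau = False
    for i in range(len(sizes_a) - 1):
        if errs_a[i] > 0 and abs(errs_a[i + 1] - errs_a[i]) < rel_tol * errs_a[i + 1]:
            chosen = sizes_a[i]
            plateau = True
            break
    idx = int(np.where(sizes_a == chosen)[0][0])
    return BlockAnalysis(sizes_a, errs_a, int(chosen), plateau)


def estimate_overlap_fraction(trace: OverlapTrace) -> FractionEstimate:
    """Mean non-overlap fraction and its block-averaged standard error."""
    x = trace.indicators.astype(float)
    if len(x) < 64:
        raise ValueError("need at least 64 frames for a block-averaged error")
    f = float(x.mean())
    if f == 0.0:
        warnings.warn(
            "no acceptable configurations observed; the free energy is only "
            "bounded from below -- sample longer",
            RuntimeWarning,
            stacklevel=2,
        )
        return FractionEstimate(0.0, 0.0)
    ba = block_error_analysis(x)
    if not ba.plateau_found:
        warnings.warn(
            "block-averaging error did not plateau; reporting the "
            "largest-block estimate (error may be underestimated)",
            RuntimeWarning,
            stacklevel=2,
        )
    err = float(ba.errors[np.where(ba.block_sizes == ba.chosen_block)[0][0]])
    return FractionEstimate(f, err)
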