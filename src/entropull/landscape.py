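"""Total import free-energy landscape F_import(n_in).

F_import combines a sigmoidal unfolding contribution F_u(n_in) -- the free
energy spent unfolding the substrate as it threads the pore -- with the
pulling contribution dF_c(n_in - n_B) of the bound chaperone closest to the
pore (binding site at n_B residues from the matrix terminus).  Chaperones
bind each site instantly and irreversibly as soon as it is fully exposed
(eight residues imported past the site start), a consequence of the
timescale separation between import and chaperone binding/unbinding.

Modes:

* ``unassisted``  -- F_u only.
* ``assisted``    -- F_u plus the nearest bound chaperone's dF_c term and a
                     hard wall forbidding retrotranslocation below the
                     exposure threshold of the nearest bound site.
* ``ratchet_only`` -- the same hard wall but no pulling term (the classical
                     Brownian-ratchet picture of chaperone action).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profile import BelowProfileRange, FreeEnergyProfile, profile_value

__all__ = [
    "UnfoldingParams",
    "ImportLandscapeSpec",
    "BindingState",
    "unfolding_free_energy",
    "update_binding",
    "import_free_energy",
    "hard_wall_position",
    "landscape_table",
]

MODES = ("assisted", "unassisted", "ratchet_only")


@dataclass(frozen=True)
class UnfoldingParams:
    """Sigmoidal unfolding free energy: height F_max (k_BT) and
    cooperativity width delta_n (residues; smaller = more cooperative)."""

    F_max: float
    delta_n: float

    def __post_init__(self) -> None:
        if self.F_max < 0:
            raise ValueError("F_max must be nonnegative")
        if self.delta_n <= 0:
            raise ValueError("delta_n must be positive")


def unfolding_free_energy(n_in, p: UnfoldingParams):
    """F_u(n_in) = F_max / (1 + exp[5 - 10 (n_in - 10) / delta_n]), k_BT.

    Monotone increasing, bounded by F_max, with midpoint at
    n_in = 10 + delta_n / 2.  Accepts scalars or arrays.
    """
    n_in = np.asarray(n_in, dtype=float)
    out = p.F_max / (1.0 + np.exp(5.0 - 10.0 * (n_in - 10.0) / p.delta_n))
    return float(out) if out.ndim == 0 else out


@dataclass
class ImportLandscapeSpec:
    """Everything needed to evaluate F_import along the import coordinate."""

    L: int = 300
    unfolding: UnfoldingParams = field(default_factory=lambda: UnfoldingParams(5.0, 100.0))
    sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    profile: FreeEnergyProfile | None = None
    mode: str = "assisted"
    binding_threshold: int = 8

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        if self.L <= 0:
            raise ValueError("L must be positive")
        if len(self.sites) and (
            np.any(self.sites < 0)
            or np.any(self.sites >= self.L)
            or np.any(np.diff(self.sites) <= 0)
        ):
            raise ValueError("sites must be strictly increasing within [0, L)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "assisted" and len(self.sites) and self.profile is None:
            raise ValueError("assisted mode with binding sites needs a profile")


@dataclass(frozen=True)
class BindingState:
    """Monotone chaperone occupancy: once a site is bound it stays bound.

    ``nearest`` is the bound site position n_B closest to the pore (largest
    bound n_B); None when nothing is bound yet.
    """

    bound_sites: frozenset = frozenset()
    nearest: int | None = None


def update_binding(state: BindingState, n_in: float, spec: ImportLandscapeSpec) -> BindingState:
    """Bind every site whose full binding region has been imported.

    A site at n_B is exposed once n_in >= n_B + binding_threshold.  The
    bound set never shrinks; ``nearest`` is the maximum bound n_B.
    """
    newly = {
        int(s) for s in spec.sites if n_in >= s + spec.binding_threshold
    }
    bound = frozenset(state.bound_sites | newly)
    nearest = max(bound) if bound else None
    if state.nearest is not None and (nearest is None or nearest < state.nearest):
        nearest = state.nearest  # monotone even if called with a smaller n_in
        bound = frozenset(bound | state.bound_sites)
    return BindingState(bound_sites=bound, nearest=nearest)


def hard_wall_position(state: BindingState, spec: ImportLandscapeSpec) -> int | None:
    """Smallest n_in reachable with the current binding state, or None.

    With a bound chaperone (assisted or ratchet_only mode) the substrate
    cannot retrotranslocate below nearest + binding_threshold.
    """
    if spec.mode == "unassisted" or state.nearest is None:
        return None
    return int(state.nearest + spec.binding_threshold)


def import_free_energy(n_in: float, state: BindingState, spec: ImportLandscapeSpec) -> float:
    """F_import(n_in) in k_BT for the given binding state.

    Only the nearest bound chaperone contributes (the pulling force decays
    quickly with the distance from the wall, and sites are ~35 residues
    apart on average).
    """
    fu = unfolding_free_energy(n_in, spec.unfolding)
    wall = hard_wall_position(state, spec)
    if wall is not None and n_in < wall:
        raise BelowProfileRange(
            f"n_in={n_in} is below the hard wall at {wall}: the caller must "
            "reject such moves"
        )
    if spec.mode != "assisted" or state.nearest is None:
        return float(fu)
    return float(fu + profile_value(spec.profile, n_in - state.nearest))


def landscape_table(spec: ImportLandscapeSpec, state: BindingState) -> np.ndarray:
    """F_import on the integer grid 0..L for a frozen binding state.

    Positions below the hard wall are set to +inf (unreachable).
    """
    out = np.empty(spec.L + 1)
    wall = hard_wall_position(state, spec)
    for n_in in range(spec.L + 1):
        if wall is not None and n_in < wall:
            out[n_in] = np.inf
        else:
            out[n_in] = import_free_energy(n_in, state, spec)
    return out
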