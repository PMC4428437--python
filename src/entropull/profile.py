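"""Entropic-pulling free-energy profile dF_c(n) and forces.

dF_c(n) = -ln(fraction of non-overlapping configurations) in k_BT, tabulated
on the integer grid n = 8..26 (shorter imported segments do not expose a
complete binding site; beyond the grid the chaperone is too far from the
wall to matter and the profile is extended as a constant, i.e. zero force).
The stored values are absolute -ln(fraction), not shifted to zero at the
grid end.

The negative slope of the profile along n, converted with k_BT per residue
contour length, is the thermodynamic pulling force in pN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, RESIDUE_CONTOUR_A, force_pN_per_kT_slope
from .sampling import OverlapTrace, estimate_overlap_fraction

__all__ = [
    "FreeEnergyProfile",
    "BelowProfileRange",
    "delta_F_from_fraction",
    "build_profile",
    "profile_value",
    "pulling_force",
    "compute_pull_profile",
]


class BelowProfileRange(ValueError):
    """The profile was queried below its first grid point.

    With a bound chaperone, imported lengths below the grid minimum are
    forbidden (hard ratchet wall); callers must treat this as a rejected
    move rather than extrapolating.
    """


@dataclass
class FreeEnergyProfile:
    """Tabulated (n, fraction, dF_c, error) with interpolation rules."""

    n_values: np.ndarray
    fractions: np.ndarray
    delta_F: np.ndarray
    errors: np.ndarray
    extrapolation_rule: str = "constant-beyond-max"
    hard_wall_below_min: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.delta_F = np.asarray(self.delta_F, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(np.diff(self.n_values) <= 0):
            raise ValueError("n_values must be strictly increasing")
        if not np.allclose(self.delta_F, -np.log(self.fractions), atol=1e-9):
            raise ValueError("delta_F must equal -ln(fraction) elementwise")

    @property
    def n_min(self) -> int:
        return int(self.n_values[0])

    @property
    def n_max(self) -> int:
        return int(self.n_values[-1])

    # -- persistence ----------------------------------------------------
    def to_frame(self, temperature: float = DEFAULT_TEMPERATURE) -> pd.DataFrame:
        force = np.array([pulling_force(self, int(n), temperature) for n in self.n_values])
        frac_err = self.errors * self.fractions  # errors are on dF (delta method)
        return pd.DataFrame(
            {
                "n": self.n_values,
                "fraction": self.fractions,
                "fraction_err": frac_err,
                "dFc_kT": self.delta_F,
                "dFc_err_kT": self.errors,
                "force_pN": force,
            }
        )

    def to_table(self, path, temperature: float = DEFAULT_TEMPERATURE) -> None:
        self.to_frame(temperature).to_csv(path, sep="\t", index=False)
        meta = dict(self.metadata)
        meta["extrapolation_rule"] = self.extrapolation_rule
        meta["hard_wall_below_min"] = self.hard_wall_below_min
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def from_table(cls, path) -> "FreeEnergyProfile":
        df = pd.read_csv(path, sep="\t")
        meta: dict = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except OSError:
            pass
        return cls(
            n_values=df["n"].to_numpy(),
            fractions=df["fraction"].to_numpy(),
            delta_F=df["dFc_kT"].to_numpy(),
            errors=df["dFc_err_kT"].to_numpy(),
            extrapolation_rule=meta.get("extrapolation_rule", "constant-beyond-max"),
            hard_wall_below_min=meta.get("hard_wall_below_min", True),
            metadata=meta,
        )


def delta_F_from_fraction(fraction: float) -> float:
    """-ln(fraction) in k_BT; requires 0 < fraction <= 1."""
    if not 0.0 < fraction <= 1.0:
        if fraction == 0.0:
            raise ValueError(
                "fraction is zero: only a lower bound on dF_c exists; sample longer"
            )
        raise ValueError("fraction must lie in (0, 1]")
    return float(-np.log(fraction))


def build_profile(traces) -> FreeEnergyProfile:
    """Assemble a profile from per-n overlap traces.

    ``traces`` maps n -> OverlapTrace (or is an iterable of traces carrying
    their own n); the n values must form a contiguous integer range starting
    at 8.  The error on dF_c is propagated by the delta method,
    err(dF) = err(fraction)/fraction.
    """
    if isinstance(traces, dict):
        items = {int(k): v for k, v in traces.items()}
    else:
        items = {t.n: t for t in traces}
    ns = sorted(items)
    if not ns or ns[0] != 8 or ns != list(range(8, ns[-1] + 1)):
        missing = sorted(set(range(8, (ns[-1] if ns else 8) + 1)) - set(ns))
        raise ValueError(
            f"traces must cover a contiguous range starting at n=8; missing {missing}"
        )
    fractions = []
    errors = []
    for n in ns:
        f, e = estimate_overlap_fraction(items[n])
        if f == 0.0:
            raise ValueError(
                f"no acceptable configurations at n={n}; the profile is undefined"
            )
        fractions.append(f)
        errors.append(e / f)
    fr = np.asarray(fractions)
    return FreeEnergyProfile(
        n_values=np.asarray(ns),
        fractions=fr,
        delta_F=-np.log(fr),
        errors=np.asarray(errors),
    )


def profile_value(profile: FreeEnergyProfile, x: float) -> float:
    """dF_c at a real-valued imported-length argument.

    Linear interpolation on the grid; constant beyond the last point (the
    chaperone no longer pulls); below the first point the hard-wall
    condition is signalled to the caller via ``BelowProfileRange``.
    """
    if x < profile.n_min:
        if profile.hard_wall_below_min:
            raise BelowProfileRange(
                f"argument {x} is below the profile grid (n_min={profile.n_min})"
            )
        return float(profile.delta_F[0])
    return float(np.interp(x, profile.n_values, profile.delta_F))


def pulling_force(
    profile: FreeEnergyProfile,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    contour_a: float = RESIDUE_CONTOUR_A,
) -> float:
    """Pulling force -d(dF_c)/dn at grid point n, in pN.

    Central finite difference in the grid interior, one-sided at the edges;
    a slope of -1 k_BT/residue maps to k_B*T/(contour per residue) pN.
    """
    nv = profile.n_values
    i = int(np.where(nv == n)[0][0]) if n in nv else None
    if i is None:
        raise ValueError(f"n={n} is not on the profile grid")
    dF = profile.delta_F
    if 0 < i < len(nv) - 1:
        slope = (dF[i + 1] - dF[i - 1]) / (nv[i + 1] - nv[i - 1])
    elif i == 0:
        slope = (dF[i + 1] - dF[i]) / (nv[i + 1] - nv[i])
    else:
        slope = (dF[i] - dF[i - 1]) / (nv[i] - nv[i - 1])
    return float(-slope * force_pN_per_kT_slope(temperature, contour_a))


def compute_pull_profile(
    geom,
    ff,
    cfg,
    n_min: int = 8,
    n_max: int = 26,
    progress: bool = False,
) -> FreeEnergyProfile:
    """Sample every n in [n_min, n_max] and build the profile.

    Per-n sampler seeds are derived deterministically from ``cfg.seed`` so
    the whole profile is reproducible from one master seed.
    """
    from dataclasses import replace as _replace

    from .sampling import sample_overlap_trace

    traces = {}
    for n in range(n_min, n_max + 1):
        seed_n = int(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 1000 + n])
                     .generate_state(1)[0] & 0x7FFFFFFF)
        cfg_n = _replace(cfg, seed=seed_n)
        traces[n] = sample_overlap_trace(n, geom, ff, cfg_n)
        if progress:
            f = traces[n].indicators.mean()
            print(f"  n={n:3d}  fraction={f:.4g}")
    prof = build_profile(traces)
    prof.metadata.update(
        {
            "master_seed": int(cfg.seed),
            "n_sweeps": cfg.n_sweeps,
            "thinning": cfg.thinning,
            "acceptance_rates": {
                n: traces[n].metadata.get("acceptance_rates") for n in traces
            },
        }
    )
    return prof
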