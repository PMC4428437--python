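"""1D Metropolis Monte Carlo of the import coordinate.

The import of an L-residue substrate is a nearest-neighbour random walk of
the number of imported residues n_in on the landscape F_import: from n_in a
trial move to n_in +/- 1 is drawn with equal probability and accepted with
the Metropolis probability min(1, exp(-dF)).  Every attempt counts as one
MC timestep; first-passage to n_in = L is the import time.  Moves to -1 are
rejected (reflecting origin) and, once a chaperone is bound, moves below
its exposure threshold are rejected (hard ratchet wall).  Chaperone binding
is instantaneous and irreversible on site exposure and the landscape is
updated after every accepted move.

Ensembles follow the proteome-heterogeneity protocol: several independent
binding-site distributions, several import realizations each; the
independent statistical unit is the distribution, so ensemble standard
errors are computed from the between-distribution variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import solve_banded

from .landscape import (
    BindingState,
    ImportLandscapeSpec,
    hard_wall_position,
    import_free_energy,
    unfolding_free_energy,
    update_binding,
)
from .profile import profile_value

__all__ = [
    "ImportResult",
    "EnsembleResult",
    "AccelerationRatio",
    "ExponentialFit",
    "metropolis_step",
    "run_import",
    "average_import_time",
    "acceleration_ratio",
    "fit_exponential_extrapolation",
    "exact_mean_first_passage",
    "walk_histogram",
]

_MODE_CODE = {"unassisted": 0, "assisted": 1, "ratchet_only": 2}


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_probs(Fu, dfc, thresh, L, mode, nearest, p_up, p_down):
    wall = 0
    if mode != 0 and nearest >= 0:
        wall = nearest + thresh
    for i in range(L + 1):
        f = Fu[i]
        if mode == 1 and nearest >= 0:
            f += dfc[i - nearest]
        if i < L:
            fn = Fu[i + 1]
            if mode == 1 and nearest >= 0:
                fn += dfc[i + 1 - nearest]
            d = fn - f
            p_up[i] = 1.0 if d <= 0.0 else np.exp(-d)
        if i <= wall:
            p_down[i] = 0.0
        else:
            fp = Fu[i - 1]
            if mode == 1 and nearest >= 0:
                fp += dfc[i - 1 - nearest]
            d = fp - f
            p_down[i] = 1.0 if d <= 0.0 else np.exp(-d)
    return wall


@njit(cache=True)
def _import_walk(Fu, dfc, sites, thresh, L, mode, step_cap, seed,
                 ev_steps, ev_sites):
    np.random.seed(seed)
    n = 0
    max_n = 0
    nearest = -1
    next_site = 0
    nsites = sites.shape[0]
    p_up = np.empty(L + 1)
    p_down = np.empty(L + 1)
    _build_probs(Fu, dfc, thresh, L, mode, nearest, p_up, p_down)
    steps = 0
    accepted = 0
    ev = 0
    while steps < step_cap:
        steps += 1
        if np.random.random() < 0.5:
            if np.random.random() < p_up[n]:
                n += 1
                accepted += 1
                if n > max_n:
                    max_n = n
                    changed = False
                    while (mode != 0 and next_site < nsites
                           and sites[next_site] + thresh <= max_n):
                        nearest = sites[next_site]
                        if ev < ev_steps.shape[0]:
                            ev_steps[ev] = steps
                            ev_sites[ev] = nearest
                            ev += 1
                        next_site += 1
                        changed = True
                    if changed:
                        _build_probs(Fu, dfc, thresh, L, mode, nearest, p_up, p_down)
                if n == L:
                    return steps, 1, accepted, ev
        else:
            if np.random.random() < p_down[n]:
                n -= 1
                accepted += 1
    return steps, 0, accepted, ev


@njit(cache=True)
def _histogram_walk(F, wall, n_steps, seed):
    """Metropolis walk on a fixed finite landscape without absorption;
    returns visit counts per state (recorded after every attempt)."""
    np.random.seed(seed)
    L = F.shape[0] - 1
    counts = np.zeros(L + 1, dtype=np.int64)
    n = wall
    for _ in range(n_steps):
        up = np.random.random() < 0.5
        if up and n < L:
            d = F[n + 1] - F[n]
            if d <= 0.0 or np.random.random() < np.exp(-d):
                n += 1
        elif (not up) and n > wall:
            d = F[n - 1] - F[n]
            if d <= 0.0 or np.random.random() < np.exp(-d):
                n -= 1
        counts[n] += 1
    return counts


def _dfc_gap_array(spec: ImportLandscapeSpec) -> np.ndarray:
    """dF_c as a function of the gap n_in - n_B on 0..L (entries below the
    binding threshold are never read; beyond the grid the profile rule
    applies)."""
    out = np.zeros(spec.L + 1)
    if spec.profile is None:
        return out
    for g in range(spec.binding_threshold, spec.L + 1):
        out[g] = profile_value(spec.profile, float(max(g, spec.profile.n_min)))
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class ImportResult:
    tau: int
    completed: bool
    acceptance_fraction: float
    seed: int
    binding_events: list = field(default_factory=list)


@dataclass
class EnsembleResult:
    mean_tau: float
    se_tau: float
    n_distributions: int
    n_realizations: int
    per_distribution_taus: pd.DataFrame
    n_incomplete: int = 0


class AccelerationRatio(NamedTuple):
    ratio: float
    se: float


class ExponentialFit(NamedTuple):
    tau: float
    slope: float
    intercept: float


def metropolis_step(
    n_in: int,
    state: BindingState,
    spec: ImportLandscapeSpec,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """One MC timestep of the import walk (pure-Python reference path).

    Proposes n_in +/- 1 with equal probability, rejects wall violations
    (origin and ratchet), otherwise applies the Metropolis criterion on
    F_import.  Returns (new n_in, accepted).
    """
    prop = n_in + (1 if rng.random() < 0.5 else -1)
    if prop < 0 or prop > spec.L:
        return n_in, False
    wall = hard_wall_position(state, spec)
    if wall is not None and prop < wall:
        return n_in, False
    dF = import_free_energy(prop, state, spec) - import_free_energy(n_in, state, spec)
    if dF <= 0 or rng.random() < np.exp(-dF):
        return prop, True
    return n_in, False


def run_import(
    spec: ImportLandscapeSpec,
    seed: int = 0,
    step_cap: int = 10**9,
) -> ImportResult:
    """Simulate one import from n_in = 0 until n_in = L or ``step_cap``.

    ``tau`` counts attempted MC steps.  Non-completion within the cap is a
    result (completed=False), not an error.
    """
    if step_cap <= 0:
        raise ValueError("step_cap must be positive")
    Fu = unfolding_free_energy(np.arange(spec.L + 1, dtype=float), spec.unfolding)
    dfc = _dfc_gap_array(spec)
    mode = _MODE_CODE[spec.mode]
    sites = np.ascontiguousarray(spec.sites, dtype=np.int64)
    ev_steps = np.zeros(max(len(sites), 1), dtype=np.int64)
    ev_sites = np.zeros(max(len(sites), 1), dtype=np.int64)
    kseed = _derive_seed(seed, 0, 0)
    steps, done, accepted, ev = _import_walk(
        Fu, dfc, sites, int(spec.binding_threshold), int(spec.L), mode,
        int(step_cap), kseed, ev_steps, ev_sites,
    )
    return ImportResult(
        tau=int(steps),
        completed=bool(done),
        acceptance_fraction=accepted / steps if steps else 0.0,
        seed=int(seed),
        binding_events=[(int(ev_steps[i]), int(ev_sites[i])) for i in range(ev)],
    )


def _derive_seed(*keys: int) -> int:
    ss = np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in keys])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def average_import_time(
    spec_template: ImportLandscapeSpec,
    site_generator: Callable[[np.random.Generator], np.ndarray] | None,
    n_distributions: int = 25,
    n_realizations: int = 10,
    seed: int = 0,
    step_cap: int = 10**9,
) -> EnsembleResult:
    """Ensemble-averaged import time over binding-site distributions.

    ``site_generator(rng)`` returns binding-site positions for one
    distribution (objects with a ``positions`` attribute are accepted);
    with ``None`` the template's own sites are reused, which reduces the
    grouping to bookkeeping (appropriate for unassisted runs).  Runs that
    do not complete within ``step_cap`` are excluded from the averages with
    a warning and reported in ``n_incomplete``.
    """
    from dataclasses import replace as _replace

    rows = []
    n_incomplete = 0
    for d in range(n_distributions):
        if site_generator is not None:
            rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7, d]))
            sites = site_generator(rng)
            sites = getattr(sites, "positions", sites)
            spec = _replace(spec_template, sites=np.asarray(sites, dtype=int))
        else:
            spec = spec_template
        for r in range(n_realizations):
            res = run_import(spec, seed=_derive_seed(seed, 11 + d, r), step_cap=step_cap)
            if not res.completed:
                n_incomplete += 1
            rows.append(
                {
                    "distribution": d,
                    "realization": r,
                    "tau": res.tau,
                    "completed": res.completed,
                    "acceptance_fraction": res.acceptance_fraction,
                }
            )
    df = pd.DataFrame(rows)
    if n_incomplete:
        warnings.warn(
            f"{n_incomplete} of {len(df)} runs did not complete within the "
            "step cap and are excluded from the ensemble averages",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = df[df["completed"]]
    if ok.empty:
        raise RuntimeError("no completed runs: raise step_cap or extrapolate")
    per_dist = ok.groupby("distribution")["tau"].mean()
    mean_tau = float(per_dist.mean())
    se_tau = (
        float(per_dist.std(ddof=1) / np.sqrt(len(per_dist)))
        if len(per_dist) > 1
        else float("nan")
    )
    return EnsembleResult(
        mean_tau=mean_tau,
        se_tau=se_tau,
        n_distributions=n_distributions,
        n_realizations=n_realizations,
        per_distribution_taus=df,
        n_incomplete=n_incomplete,
    )


def acceleration_ratio(tau0: EnsembleResult, tauC: EnsembleResult) -> AccelerationRatio:
    """tau_0 / tau_C with the standard error propagated in quadrature."""
    if tauC.mean_tau <= 0:
        raise ValueError("assisted ensemble mean must be positive")
    r = tau0.mean_tau / tauC.mean_tau
    rel = 0.0
    for e in (tau0, tauC):
        if np.isfinite(e.se_tau) and e.mean_tau > 0:
            rel += (e.se_tau / e.mean_tau) ** 2
    return AccelerationRatio(float(r), float(r * np.sqrt(rel)))


def fit_exponential_extrapolation(F_values, tau_values, F_target: float) -> ExponentialFit:
    """Fit tau = A exp(b F) by least squares on ln(tau) and evaluate at
    ``F_target``; returns (tau_extrapolated, slope b, intercept ln A)."""
    F = np.asarray(F_values, dtype=float)
    tau = np.asarray(tau_values, dtype=float)
    if len(F) < 3:
        raise ValueError("need at least 3 (F, tau) pairs")
    if np.any(tau <= 0):
        raise ValueError("tau values must be positive")
    slope, intercept = np.polyfit(F, np.log(tau), 1)
    return ExponentialFit(float(np.exp(intercept + slope * F_target)),
                          float(slope), float(intercept))


def exact_mean_first_passage(F, wall: int = 0, start: int = 0) -> float:
    """Mean first-passage time (attempted steps) to the last state of ``F``
    for the same Metropolis walk, from the absorbing-chain linear system.

    ``F`` is the landscape on states 0..L (absorbing at L); states below
    ``wall`` are unreachable (reflecting boundary, proposals rejected).
    Used as an independent cross-check of the stochastic simulation.
    """
    F = np.asarray(F, dtype=float)
    L = len(F) - 1
    if not wall <= start < L:
        raise ValueError("need wall <= start < L")
    m = L - wall  # transient states wall..L-1
    up = np.empty(m)
    down = np.empty(m)
    for idx, i in enumerate(range(wall, L)):
        up[idx] = 0.5 * min(1.0, np.exp(-(F[i + 1] - F[i])))
        down[idx] = 0.0 if i == wall else 0.5 * min(1.0, np.exp(-(F[i - 1] - F[i])))
    # (up+down) tau_i - up tau_{i+1} - down tau_{i-1} = 1, tau_L = 0
    ab = np.zeros((3, m))
    ab[0, 1:] = -up[:-1]      # super-diagonal
    ab[1, :] = up + down      # diagonal
    ab[2, :-1] = -down[1:]    # sub-diagonal
    tau = solve_banded((1, 1), ab, np.ones(m))
    return float(tau[start - wall])


def walk_histogram(F, n_steps: int, seed: int = 0, wall: int = 0) -> np.ndarray:
    """Visit-count histogram of the non-absorbing Metropolis walk on ``F``.

    Utility for stationarity checks: at equilibrium the counts are
    proportional to exp(-F)."""
    F = np.ascontiguousarray(F, dtype=float)
    return _histogram_walk(F, int(wall), int(n_steps), _derive_seed(seed, 99))
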