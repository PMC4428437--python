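import warnings

import numpy as np
import pytest

from entropull import ForceFieldParams, build_synthetic_chaperone
from entropull.profile import FreeEnergyProfile, compute_pull_profile
from entropull.sampling import SamplerConfig


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def small_geom():
    """Reduced-size synthetic chaperone for fast sampling tests."""
    return build_synthetic_chaperone(nbd_radius=14.0, sbd_radius=12.0,
                                     linker_beads=5)


@pytest.fixture(scope="session")
def hsp70_geom():
    """Stand-in chaperone at realistic Hsp70 dimensions (the defaults)."""
    return build_synthetic_chaperone()


def make_profile(dF_by_n: dict) -> FreeEnergyProfile:
    """Analytic profile helper for landscape/import tests."""
    ns = np.array(sorted(dF_by_n))
    dF = np.array([dF_by_n[n] for n in ns], dtype=float)
    return FreeEnergyProfile(
        n_values=ns,
        fractions=np.exp(-dF),
        delta_F=dF,
        errors=np.zeros_like(dF),
    )


@pytest.fixture(scope="session")
def linear_profile():
    """Linearly decaying pulling profile on n = 8..26 (1 k_BT per residue
    at the wall, flat at the far end)."""
    return make_profile({n: max(0.0, 18.0 - n) * 0.35 for n in range(8, 27)})


@pytest.fixture(scope="session")
def sampled_profile(hsp70_geom, ff):
    """Entropic-pulling profile sampled at reduced (test-scale) cost.

    Shared by the headline-reproduction tests; one computation per session.
    """
    cfg = SamplerConfig(n_sweeps=30_000, seed=2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return compute_pull_profile(hsp70_geom, ff, cfg)
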