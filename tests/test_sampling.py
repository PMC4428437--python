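import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from entropull.forcefield import total_energy
from entropull.geometry import ChainConformation, build_complex
from entropull.sampling import (
    OverlapTrace,
    SamplerConfig,
    block_error_analysis,
    estimate_overlap_fraction,
    sample_overlap_trace,
)


class TestSamplerMechanics:
    def test_identical_config_gives_identical_trace(self, small_geom, ff):
        cfg = SamplerConfig(n_sweeps=800, seed=42)
        t1 = sample_overlap_trace(9, small_geom, ff, cfg)
        t2 = sample_overlap_trace(9, small_geom, ff, cfg)
        assert np.array_equal(t1.indicators, t2.indicators)
        t3 = sample_overlap_trace(9, small_geom, ff, replace(cfg, seed=43))
        assert not np.array_equal(t1.indicators, t3.indicators)

    def test_rigid_units_and_wall_survive_many_sweeps(self, small_geom, ff):
        cfg = SamplerConfig(n_sweeps=2500, seed=7)
        trace, final = sample_overlap_trace(12, small_geom, ff, cfg,
                                            return_state=True)
        final.validate_tether()
        g = final.geometry
        # intra-unit pairwise distances are conserved to numerical precision
        from entropull.sampling import _prepare_state

        _, clamp0, sbd0, nbd0, _, _, _ = _prepare_state(
            build_complex(12, small_geom, ff.bond_length))
        assert np.abs(pdist(np.vstack([g.sbd_beads, g.clamp_sites]))
                      - pdist(np.vstack([sbd0, clamp0]))).max() < 1e-6
        assert np.abs(pdist(g.nbd_beads) - pdist(nbd0)).max() < 1e-6
        # bonds stay within 20% of the rest length under the stiff potential
        d = np.linalg.norm(np.diff(final.substrate_coords[6:], axis=0), axis=1)
        assert np.all(np.abs(d - ff.bond_length) < 0.2 * ff.bond_length)

    def test_langevin_mode_is_not_available(self, small_geom, ff):
        cfg = SamplerConfig(n_sweeps=100, seed=0, mode="overdamped_langevin")
        with pytest.raises(NotImplementedError):
            sample_overlap_trace(9, small_geom, ff, cfg)

    def test_short_imported_segment_is_rejected(self, small_geom, ff):
        with pytest.raises(ValueError, match="n >= 8"):
            sample_overlap_trace(7, small_geom, ff, SamplerConfig(n_sweeps=64))


class TestEquilibriumDistribution:
    def test_non_overlap_fraction_grows_with_imported_length(self, small_geom, ff):
        fr = {}
        for n in (8, 26):
            cfg = SamplerConfig(n_sweeps=6000, seed=100 + n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fr[n], _ = estimate_overlap_fraction(
                    sample_overlap_trace(n, small_geom, ff, cfg))
        assert fr[26] > fr[8]

    def test_long_leash_makes_overlap_unlikely(self, small_geom, ff):
        # with ~150 A of chain slack the chaperone rarely reaches the wall
        # (the coil still tethers it within a coil size, so the fraction
        # saturates well below 1 at accessible n)
        cfg = SamplerConfig(n_sweeps=4000, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f, _ = estimate_overlap_fraction(
                sample_overlap_trace(48, small_geom, ff, cfg))
        assert f > 0.65

    def test_first_and_second_half_fractions_agree(self, small_geom, ff):
        cfg = SamplerConfig(n_sweeps=12000, seed=5)
        tr = sample_overlap_trace(10, small_geom, ff, cfg)
        half = len(tr.indicators) // 2
        est = []
        for part in (tr.indicators[:half], tr.indicators[half:]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est.append(estimate_overlap_fraction(
                    OverlapTrace(part, tr.n)))
        diff = abs(est[0].fraction - est[1].fraction)
        comb = np.hypot(est[0].error, est[1].error)
        assert diff < 3 * comb

    def test_kernel_agrees_with_naive_reference_sampler(self, small_geom, ff):
        """Dual-route check: the optimized kernel vs an independent
        pure-Python Metropolis sampler that re-evaluates the total energy
        of every proposal."""
        f_naive, se_naive = _naive_fraction(10, small_geom, ff,
                                            n_sweeps=1200, seed=2)
        cfg = SamplerConfig(n_sweeps=25000, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f, e = estimate_overlap_fraction(
                sample_overlap_trace(10, small_geom, ff, cfg))
        assert abs(f - f_naive) < 3 * np.hypot(e, se_naive)


class TestFractionEstimator:
    def test_perfect_trace(self):
        f, e = estimate_overlap_fraction(OverlapTrace(np.ones(256), 10))
        assert (f, e) == (1.0, 0.0)

    def test_all_zero_trace_warns_and_bounds(self):
        with pytest.warns(RuntimeWarning, match="no acceptable"):
            f, e = estimate_overlap_fraction(OverlapTrace(np.zeros(256), 8))
        assert (f, e) == (0.0, 0.0)

    def test_iid_bernoulli_matches_binomial_error(self):
        rng = np.random.default_rng(12)
        x = (rng.random(100_000) < 0.3).astype(np.int8)
        f, e = estimate_overlap_fraction(OverlapTrace(x, 10))
        binom = np.sqrt(0.3 * 0.7 / len(x))
        assert abs(f - 0.3) < 3 * binom
        assert abs(e - binom) < 0.2 * binom

    def test_markov_correlated_trace_error_inflation(self):
        # stationary two-state Markov chain with stay probability s has
        # autocorrelation rho^k with rho = 2s - 1; the true standard error
        # of the mean is the i.i.d. value inflated by sqrt((1+rho)/(1-rho))
        rng = np.random.default_rng(3)
        s, N = 0.9, 200_000
        x = np.empty(N, dtype=np.int8)
        x[0] = 1
        flips = rng.random(N) > s
        for i in range(1, N):
            x[i] = x[i - 1] if not flips[i] else 1 - x[i - 1]
        rho = 2 * s - 1
        true_se = np.sqrt(0.25 / N) * np.sqrt((1 + rho) / (1 - rho))
        _, e = estimate_overlap_fraction(OverlapTrace(x, 10))
        assert abs(e - true_se) < 0.3 * true_se

    def test_block_doubling_reports_plateau(self):
        rng = np.random.default_rng(0)
        ba = block_error_analysis(rng.normal(size=4096))
        assert ba.plateau_found
        assert ba.chosen_block <= 8  # i.i.d. data plateaus immediately

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_overlap_fraction(OverlapTrace(np.ones(32), 9))


def _naive_fraction(n, geom, ff, n_sweeps, seed):
    """Independent reference sampler: same move geometry as the kernel but
    full total-energy re-evaluation per proposal and no incremental state."""
    rng = np.random.default_rng(seed)
    conf = build_complex(n, geom, ff.bond_length)
    g = conf.geometry
    sub = conf.substrate_coords.copy()
    sbd, nbd, lnk = g.sbd_beads.copy(), g.nbd_beads.copy(), g.linker_beads.copy()
    ia_s, ia_n = g.sbd_anchor, g.nbd_anchor

    def conf_of(sub, sbd, nbd, lnk):
        gg = replace(g, sbd_beads=sbd, nbd_beads=nbd, linker_beads=lnk,
                     clamp_sites=sub[0:7])
        return ChainConformation(substrate_coords=sub, geometry=gg, attached=True)

    def axis(v):
        return v / np.linalg.norm(v)

    E = total_energy(conf_of(sub, sbd, nbd, lnk), None, ff)
    inds = []
    equil = n_sweeps // 4
    for sweep in range(n_sweeps + equil):
        for _ in range(max(n - 8, 1) + 5):
            kind = rng.integers(0, 5)
            sub2, sbd2, nbd2, lnk2 = sub.copy(), sbd.copy(), nbd.copy(), lnk.copy()
            if kind == 0 and n > 8:
                i = int(rng.integers(7, n - 1))
                if rng.random() < 0.5:
                    sub2[i] += 0.25 * rng.normal(size=3)
                else:
                    R = Rotation.from_rotvec(
                        axis(sub[i + 1] - sub[i - 1]) * 1.6 * rng.normal()
                    ).as_matrix()
                    sub2[i] = (sub[i] - sub[i - 1]) @ R.T + sub[i - 1]
                if sub2[i, 2] < 0:
                    continue
            elif kind == 1:
                c = sub[6].copy()
                if rng.random() < 0.5:
                    R = Rotation.from_rotvec(
                        axis(sbd[ia_s] - c) * 0.9 * rng.normal()).as_matrix()
                    t = np.zeros(3)
                else:
                    R = Rotation.from_rotvec(0.05 * rng.normal(size=3)).as_matrix()
                    t = 0.12 * rng.normal(size=3)
                sub2[0:7] = (sub[0:7] - c) @ R.T + c + t
                sbd2 = (sbd - c) @ R.T + c + t
                if np.any(sub2[0:7, 2] < 0):
                    continue
            elif kind == 2:
                u = rng.random()
                if u < 1 / 3:
                    c = nbd[ia_n].copy()
                    R = Rotation.from_rotvec(0.5 * rng.normal(size=3)).as_matrix()
                    t = np.zeros(3)
                elif u < 2 / 3:
                    c = nbd[ia_n].copy()
                    R, t = np.eye(3), 0.14 * rng.normal(size=3)
                else:  # arm swing about the SBD anchor
                    c = sbd[ia_s].copy()
                    R = Rotation.from_rotvec(0.4 * rng.normal(size=3)).as_matrix()
                    t = np.zeros(3)
                    lnk2 = (lnk - c) @ R.T + c
                nbd2 = (nbd - c) @ R.T + c + t
            elif kind == 3:
                k = int(rng.integers(0, len(lnk)))
                lnk2[k] += 0.25 * rng.normal(size=3)
            else:
                j = int(rng.integers(7, n))
                c = sub[j].copy()
                R = Rotation.from_rotvec(
                    axis(rng.normal(size=3)) * 0.35 * rng.normal()).as_matrix()
                sub2[0:j] = (sub[0:j] - c) @ R.T + c
                sbd2 = (sbd - c) @ R.T + c
                nbd2 = (nbd - c) @ R.T + c
                lnk2 = (lnk - c) @ R.T + c
                if np.any(sub2[0:j, 2] < 0):
                    continue
            E2 = total_energy(conf_of(sub2, sbd2, nbd2, lnk2), None, ff)
            if E2 - E <= 0 or rng.random() < np.exp(-(E2 - E)):
                sub, sbd, nbd, lnk, E = sub2, sbd2, nbd2, lnk2, E2
        if sweep >= equil:
            inds.append(1 if np.vstack([sbd, nbd, lnk])[:, 2].min() >= 0 else 0)
    x = np.asarray(inds, dtype=float)
    b = 64
    nb = len(x) // b
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(x.mean()), float(means.std(ddof=1) / np.sqrt(nb))
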