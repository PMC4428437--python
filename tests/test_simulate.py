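import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import make_profile
from entropull.landscape import (
    BindingState,
    ImportLandscapeSpec,
    UnfoldingParams,
    unfolding_free_energy,
    update_binding,
)
from entropull.simulate import (
    acceleration_ratio,
    average_import_time,
    exact_mean_first_passage,
    fit_exponential_extrapolation,
    metropolis_step,
    run_import,
    walk_histogram,
)


def _flat_spec(L=30, F_max=0.0, dn=100.0, **kw):
    return ImportLandscapeSpec(L=L, unfolding=UnfoldingParams(F_max, dn), **kw)


class TestMetropolisStep:
    def test_downhill_proposals_always_accepted(self):
        spec = _flat_spec(F_max=0.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, acc = metropolis_step(5, BindingState(), spec, rng)
            assert acc and n in (4, 6)

    def test_two_kt_barrier_acceptance_rate(self):
        # stepping up costs 2 k_BT here, and the wall blocks stepping down,
        # so P(8 -> 9 per attempt) = 1/2 * e^-2
        prof = make_profile({8: 0.0, 9: 2.0})
        spec = ImportLandscapeSpec(L=100, unfolding=UnfoldingParams(0.0, 100.0),
                                   sites=np.array([0]), profile=prof,
                                   mode="assisted")
        state = update_binding(BindingState(), 8, spec)
        rng = np.random.default_rng(1)
        n_trials = 100_000
        ups = sum(metropolis_step(8, state, spec, rng)[0] == 9
                  for _ in range(n_trials))
        expect = 0.5 * np.exp(-2.0)
        se = np.sqrt(expect * (1 - expect) / n_trials)
        assert abs(ups / n_trials - expect) < 3 * se

    def test_ratchet_wall_blocks_retrotranslocation(self, linear_profile):
        spec = ImportLandscapeSpec(L=50, unfolding=UnfoldingParams(0.0, 100.0),
                                   sites=np.array([0]), profile=linear_profile,
                                   mode="assisted")
        state = update_binding(BindingState(), 8, spec)
        rng = np.random.default_rng(2)
        for _ in range(500):
            n, acc = metropolis_step(8, state, spec, rng)
            assert n >= 8

    def test_reflecting_origin(self):
        spec = _flat_spec()
        rng = np.random.default_rng(3)
        for _ in range(200):
            n, _ = metropolis_step(0, BindingState(), spec, rng)
            assert n >= 0


class TestFirstPassage:
    def test_mc_mean_matches_absorbing_chain_solve_flat(self):
        spec = _flat_spec(L=30)
        taus = np.array([run_import(spec, seed=s).tau for s in range(2000)])
        F = unfolding_free_energy(np.arange(31, dtype=float), spec.unfolding)
        exact = exact_mean_first_passage(F)
        se = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(taus.mean() - exact) < 3 * se

    def test_mc_mean_matches_solve_on_a_sloped_landscape(self):
        spec = _flat_spec(L=40, F_max=2.0, dn=60.0)
        taus = np.array([run_import(spec, seed=s).tau for s in range(1500)])
        F = unfolding_free_energy(np.arange(41, dtype=float), spec.unfolding)
        exact = exact_mean_first_passage(F)
        se = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(taus.mean() - exact) < 3 * se

    def test_insurmountable_barrier_reports_non_completion(self):
        spec = _flat_spec(L=300, F_max=50.0, dn=10.0)
        res = run_import(spec, seed=0, step_cap=20_000)
        assert not res.completed and res.tau == 20_000

    def test_seed_determinism(self):
        spec = _flat_spec(L=50, F_max=3.0)
        a = run_import(spec, seed=11)
        b = run_import(spec, seed=11)
        assert (a.tau, a.acceptance_fraction) == (b.tau, b.acceptance_fraction)

    def test_binding_events_are_ordered_and_complete(self, linear_profile):
        spec = ImportLandscapeSpec(L=120, unfolding=UnfoldingParams(3.0, 100.0),
                                   sites=np.array([0, 28, 70]),
                                   profile=linear_profile, mode="assisted")
        res = run_import(spec, seed=4)
        assert res.completed
        assert [s for _, s in res.binding_events] == [0, 28, 70]
        steps = [t for t, _ in res.binding_events]
        assert steps == sorted(steps)

    def test_assistance_shortens_the_fig4_import(self, linear_profile):
        base = dict(L=300, unfolding=UnfoldingParams(5.0, 100.0))
        spec0 = ImportLandscapeSpec(mode="unassisted", **base)
        specC = ImportLandscapeSpec(mode="assisted", sites=np.array([0, 28]),
                                    profile=linear_profile, **base)
        t0 = np.mean([run_import(spec0, seed=s).tau for s in range(8)])
        tC = np.mean([run_import(specC, seed=s).tau for s in range(8)])
        assert tC < t0


class TestStationarity:
    def test_visit_histogram_matches_boltzmann_on_five_states(self):
        F = np.array([0.0, 1.2, 0.3, 2.0, 0.7])
        counts = walk_histogram(F, n_steps=1_000_000, seed=0)
        p = np.exp(-F)
        p /= p.sum()
        # thin the correlated counts by comparing against expected with an
        # effective sample size; the walk mixes in O(L^2) steps
        n_eff = 1_000_000 / 50
        obs = counts / counts.sum() * n_eff
        stat, pval = chisquare(obs, p * n_eff)
        assert pval > 0.01


class TestEnsembles:
    def test_degenerate_ensemble_equals_single_run(self):
        spec = _flat_spec(L=40, F_max=1.0)
        ens = average_import_time(spec, None, n_distributions=1,
                                  n_realizations=1, seed=3)
        from entropull.simulate import _derive_seed

        single = run_import(spec, seed=_derive_seed(3, 11, 0))
        assert ens.mean_tau == single.tau

    def test_ensemble_mean_is_mean_of_distribution_means(self):
        spec = _flat_spec(L=30)
        ens = average_import_time(spec, None, n_distributions=4,
                                  n_realizations=3, seed=1)
        df = ens.per_distribution_taus
        per = df[df.completed].groupby("distribution")["tau"].mean()
        assert ens.mean_tau == pytest.approx(per.mean())

    def test_stability_raises_unassisted_import_time(self):
        t = {}
        for fmax in (4.0, 6.0):
            spec = _flat_spec(L=120, F_max=fmax, dn=30.0)
            t[fmax] = average_import_time(spec, None, 4, 3, seed=5).mean_tau
        assert t[6.0] > t[4.0]

    def test_incomplete_runs_are_excluded_with_warning(self):
        spec = _flat_spec(L=300, F_max=30.0, dn=10.0)
        with pytest.warns(RuntimeWarning, match="did not complete"):
            with pytest.raises(RuntimeError):
                average_import_time(spec, None, 2, 2, seed=0, step_cap=5000)


class TestAccelerationAndFit:
    def test_identical_ensembles_give_unit_ratio(self):
        spec = _flat_spec(L=40, F_max=1.0)
        ens = average_import_time(spec, None, 3, 2, seed=9)
        assert acceleration_ratio(ens, ens).ratio == pytest.approx(1.0)

    def test_order_of_magnitude_ratio(self):
        from dataclasses import replace

        spec = _flat_spec(L=40)
        a = average_import_time(spec, None, 2, 2, seed=1)
        b = replace(a, mean_tau=a.mean_tau / 100.0)
        assert acceleration_ratio(a, b).ratio == pytest.approx(100.0)

    def test_noiseless_exponential_recovery(self):
        F = np.linspace(4, 11, 8)
        A, b = 12.0, 1.7
        tau = A * np.exp(b * F)
        fit = fit_exponential_extrapolation(F, tau, 14.0)
        assert fit.slope == pytest.approx(b, rel=1e-9)
        assert np.exp(fit.intercept) == pytest.approx(A, rel=1e-9)
        assert fit.tau == pytest.approx(A * np.exp(b * 14.0), rel=1e-9)
        inside = fit_exponential_extrapolation(F, tau, 6.0)
        assert inside.tau == pytest.approx(A * np.exp(b * 6.0), rel=1e-9)

    def test_fitted_slope_distribution_under_lognormal_noise(self):
        rng = np.random.default_rng(8)
        F = np.linspace(4, 11, 8)
        b = 1.1
        slopes = []
        for _ in range(500):
            tau = np.exp(b * F + rng.normal(scale=0.1, size=len(F)))
            slopes.append(fit_exponential_extrapolation(F, tau, 12.0).slope)
        slopes = np.asarray(slopes)
        se_mean = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - b) < 3 * se_mean

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_extrapolation([1, 2], [3, 4], 5)
        with pytest.raises(ValueError):
            fit_exponential_extrapolation([1, 2, 3], [1.0, -2.0, 3.0], 5)
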