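from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import chisquare

from entropull.geometry import load_chaperone_ca
from entropull.synthetic import (
    LatticeToy,
    build_synthetic_chaperone,
    enumerate_lattice_ratio,
    fixture_chain_pdb,
    generate_binding_sites,
    sample_lattice_ratio,
    write_fixture_pdb,
)


class TestBindingSites:
    def test_mean_gap_matches_prescription(self):
        # measured on long substrates so finite-length censoring of the
        # last gap does not bias the generator statistics
        rng = np.random.default_rng(1)
        gaps = []
        for _ in range(50):
            pos = generate_binding_sites(150_000, 35.0, rng).positions
            gaps.extend(np.diff(pos))
        assert abs(np.mean(gaps) - 35.0) < 0.35  # within 1%

    def test_same_seed_reproduces_positions(self):
        a = generate_binding_sites(300, 35.0, seed=7)
        b = generate_binding_sites(300, 35.0, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_expected_site_count_from_renewal_oracle(self):
        # oracle: direct simulation of the generating law itself
        rng = np.random.default_rng(2)
        oracle_counts = []
        for _ in range(10_000):
            pos, cnt = int(rng.geometric(1 / 35.0)) - 1, 0
            while pos < 300:
                cnt += 1
                pos += int(rng.geometric(1 / 35.0))
            oracle_counts.append(cnt)
        rng2 = np.random.default_rng(3)
        counts = [len(generate_binding_sites(300, 35.0, rng2).positions)
                  for _ in range(10_000)]
        assert abs(np.mean(counts) - np.mean(oracle_counts)) \
            < 0.05 * np.mean(oracle_counts)

    def test_gap_distribution_is_geometric(self):
        rng = np.random.default_rng(4)
        gaps = []
        for _ in range(20):
            pos = generate_binding_sites(150_000, 35.0, rng).positions
            gaps.extend(np.diff(pos))
        gaps = np.asarray(gaps)
        p = 1 / 35.0
        edges = [1, 10, 20, 30, 45, 60, 90, 10_000]
        obs = np.array([((gaps >= lo) & (gaps < hi)).sum()
                        for lo, hi in zip(edges[:-1], edges[1:])])
        cdf = lambda k: 1 - (1 - p) ** k  # P(gap <= k), support 1,2,...
        exp = np.array([cdf(hi - 1) - cdf(lo - 1)
                        for lo, hi in zip(edges[:-1], edges[1:])]) * len(gaps)
        stat, pval = chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 0.01

    def test_positions_stay_inside_the_substrate(self):
        for seed in range(50):
            m = generate_binding_sites(120, 35.0, seed=seed)
            if len(m.positions):
                assert m.positions[0] >= 0 and m.positions[-1] < 120
                assert np.all(np.diff(m.positions) > 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_binding_sites(0, 35.0)
        with pytest.raises(ValueError):
            generate_binding_sites(300, -1.0)


class TestSyntheticChaperone:
    def test_nbd_bead_count_equals_lattice_points_in_sphere(self, hsp70_geom):
        spacing, radius = 3.8, 25.0
        m = int(np.floor(radius / spacing))
        cnt = sum(
            1
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            if np.sqrt(i * i + j * j + k * k) * spacing <= radius
        )
        assert len(hsp70_geom.nbd_beads) == cnt

    def test_nbd_radius_of_gyration_matches_uniform_ball(self, hsp70_geom):
        nbd = hsp70_geom.nbd_beads
        rg = np.sqrt(((nbd - nbd.mean(0)) ** 2).sum(1).mean())
        assert rg == pytest.approx(np.sqrt(3 / 5) * 25.0, rel=0.05)

    def test_geometry_invariants_hold(self, hsp70_geom):
        hsp70_geom.validate()
        assert len(hsp70_geom.linker_beads) == 9
        assert hsp70_geom.clamp_sites.shape == (7, 3)

    def test_overall_extent_brackets_a_two_domain_hsp70(self, hsp70_geom):
        beads = hsp70_geom.all_chaperone_beads()
        extent = beads[:, 0].max() - beads[:, 0].min()
        assert 80.0 <= extent <= 120.0

    def test_construction_is_deterministic(self):
        a = build_synthetic_chaperone(nbd_radius=14, sbd_radius=12)
        b = build_synthetic_chaperone(nbd_radius=14, sbd_radius=12)
        assert np.array_equal(a.sbd_beads, b.sbd_beads)
        assert np.array_equal(a.linker_beads, b.linker_beads)

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            build_synthetic_chaperone(nbd_radius=2.0, sbd_radius=20.0)
        with pytest.raises(ValueError, match="cleft"):
            build_synthetic_chaperone(nbd_radius=20.0, sbd_radius=8.0)


class TestLatticeOracle:
    def test_no_obstacle_never_overlaps(self):
        assert enumerate_lattice_ratio(LatticeToy(3)) == 1

    def test_unreachable_obstacle_never_overlaps(self):
        toy = LatticeToy(3, obstacle_cells=((0, 5), (1, 7)))
        assert enumerate_lattice_ratio(toy) == 1

    def test_two_bead_chain_by_hand(self):
        # bead 2 pinned at the origin; bead 1 occupies one of the 3 wall-legal
        # neighbours; a cell one lattice unit below bead 1 dips under the wall
        # only when bead 1 sits on the wall line: 2 of 3 placements overlap
        toy = LatticeToy(2, obstacle_cells=((0, -1),))
        assert enumerate_lattice_ratio(toy) == Fraction(1, 3)

    def test_enumeration_size_guard(self):
        with pytest.raises(ValueError):
            enumerate_lattice_ratio(LatticeToy(13))

    def test_metropolis_sampling_agrees_with_enumeration(self):
        toy = LatticeToy(3, obstacle_cells=((0, -1), (1, -1), (0, 0), (1, 0)))
        exact = float(enumerate_lattice_ratio(toy))
        ind = sample_lattice_ratio(toy, 120_000, seed=11, thin=20)
        f = ind.mean()
        se = np.sqrt(f * (1 - f) / len(ind))
        assert abs(f - exact) < 3 * se


class TestPdbFixtures:
    def test_round_trip_preserves_coordinates_to_pdb_precision(self, tmp_path):
        geom = build_synthetic_chaperone(nbd_radius=14, sbd_radius=12,
                                         linker_beads=5)
        path = tmp_path / "chap.pdb"
        write_fixture_pdb(geom, path)
        mN, nl, mS = len(geom.nbd_beads), len(geom.linker_beads), len(geom.sbd_beads)
        back = load_chaperone_ca(
            path.read_text(),
            nbd_range=(1, mN),
            linker_range=(mN + 1, mN + nl),
            sbd_range=(mN + nl + 1, mN + nl + mS),
            chain_id="A",
            clamp_sites=geom.clamp_sites,
        )
        assert np.abs(back.nbd_beads - geom.nbd_beads).max() < 1e-3
        assert np.abs(back.linker_beads - geom.linker_beads).max() < 1e-3

    def test_603_residue_fixture_yields_dnak_partition(self, tmp_path):
        path = tmp_path / "dnak.pdb"
        write_fixture_pdb(603, path)
        geom = load_chaperone_ca(path.read_text())
        assert (len(geom.nbd_beads), len(geom.sbd_beads),
                len(geom.linker_beads)) == (384, 207, 9)

    def test_invalid_fixture_inputs(self, tmp_path):
        with pytest.raises(ValueError):
            fixture_chain_pdb(0)
        with pytest.raises(TypeError):
            write_fixture_pdb("nonsense", tmp_path / "x.pdb")
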