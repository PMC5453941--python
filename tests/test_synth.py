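"""Statistical correctness of the synthetic generators.

Each generator is checked against closed-form or brute-force oracles:
Gaussian variance of a harmonic Boltzmann distribution, chi-square
goodness-of-fit of the Metropolis chain, analytic swap acceptance for
replica exchange on a harmonic well, quadrature inversion of the von
Mises-Fisher order parameter, exact ring geometry, and ion-count unit
conversion.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from poremap.model import R_KCAL
from poremap.synth import (
    PlacementScheme,
    PotentialSpec,
    ReplicaLadder,
    add_ions,
    ion_charge,
    kappa_for_order,
    make_bilayer,
    make_helix,
    make_pore_assembly,
    place_cargo_replicas,
    run_replica_exchange,
    sample_boltzmann_mc,
    vmf_mean_cos2,
)
from poremap.model import Frame, Topology, Trajectory
from poremap.membrane import chain_order_parameter
from poremap.synth import lipid_chain_pairs


class TestBoltzmannMC:
    def test_harmonic_variance_matches_rt_over_k(self):
        # equilibrium variance of 0.5 k x^2 is RT/k
        pot = PotentialSpec.harmonic(k=1.0)
        traj = sample_boltzmann_mc(pot, 310.0, n_steps=200_000, step_size=1.0,
                                   seed=7)
        var = traj.coordinates[:, 0, 0].var()
        assert var == pytest.approx(R_KCAL * 310.0, rel=0.05)

    def test_flat_potential_gives_uniform_histogram(self):
        pot = PotentialSpec.flat([(-10.0, 10.0)])
        traj = sample_boltzmann_mc(pot, 310.0, n_steps=200_000, step_size=4.0,
                                   seed=8)
        x = traj.coordinates[:, 0, 0]
        counts, _ = np.histogram(x, bins=20, range=(-10, 10))
        n = counts.sum()
        p = counts / n
        # each bin expected at 0.05 within 3 sigma of the multinomial error
        # (inflated for the chain's autocorrelation)
        sigma = math.sqrt(0.05 * 0.95 / n) * 4
        assert np.all(np.abs(p - 0.05) < 3 * sigma)

    def test_seed_determinism_bitwise(self):
        pot = PotentialSpec.harmonic(k=2.0)
        a = sample_boltzmann_mc(pot, 310.0, 5_000, seed=42)
        b = sample_boltzmann_mc(pot, 310.0, 5_000, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_histogram_matches_boltzmann_weights_chi2(self):
        # chi-square goodness of fit against exp(-U/RT)/Z on 20 bins,
        # thinned to reduce chain autocorrelation
        pot = PotentialSpec.harmonic(k=1.0)
        t = 310.0
        traj = sample_boltzmann_mc(pot, t, n_steps=400_000, step_size=2.5,
                                   seed=9)
        x = traj.coordinates[::10, 0, 0]
        sigma = math.sqrt(R_KCAL * t)
        edges = np.linspace(-3 * sigma, 3 * sigma, 21)
        obs, _ = np.histogram(x, bins=edges)
        cdf = stats.norm(scale=sigma).cdf
        probs = np.diff(cdf(edges))
        inside = obs.sum()
        chi2, p = stats.chisquare(obs, probs / probs.sum() * inside)
        assert p > 0.001

    def test_infinite_start_rejected(self):
        pot = PotentialSpec.flat([(-1.0, 1.0)])
        with pytest.raises(ValueError, match="finite"):
            sample_boltzmann_mc(pot, 310.0, 100, x0=[5.0])


class TestReplicaExchange:
    def test_equal_temperature_pair_always_accepts(self):
        ladder = ReplicaLadder([310.0, 310.0], swap_interval=50)
        pot = PotentialSpec.harmonic(k=1.0)
        res = run_replica_exchange(pot, ladder, n_steps=5_000, seed=1)
        assert res.acceptance[(0, 1)] == pytest.approx(1.0)

    def test_single_temperature_ladder_rejected(self):
        with pytest.raises(ValueError, match="degenerate|two"):
            ReplicaLadder([310.0])

    def test_acceptance_matches_bruteforce_metropolis_average(self):
        # harmonic well: U ~ (RT/2) chi^2_1 per replica; the expected swap
        # acceptance is the average of min(1, exp[(b_i - b_j)(U_i - U_j)])
        temps = np.linspace(309.0, 380.0, 8)
        ladder = ReplicaLadder(temps, swap_interval=100)
        pot = PotentialSpec.harmonic(k=1.0)
        res = run_replica_exchange(pot, ladder, n_steps=60_000, step_size=1.5,
                                   seed=3)
        rng = np.random.default_rng(99)
        z = rng.normal(size=(2, 1_000_000)) ** 2
        for i in range(7):
            bi, bj = 1 / (R_KCAL * temps[i]), 1 / (R_KCAL * temps[i + 1])
            ui = 0.5 * z[0] / bi
            uj = 0.5 * z[1] / bj
            expected = np.minimum(1.0, np.exp((bi - bj) * (ui - uj))).mean()
            assert res.acceptance[(i, i + 1)] == pytest.approx(expected,
                                                               abs=0.05)

    def test_lowest_temperature_marginal_matches_direct_mc(self):
        pot = PotentialSpec.harmonic(k=1.0)
        ladder = ReplicaLadder(np.linspace(309.0, 380.0, 4), swap_interval=200)
        res = run_replica_exchange(pot, ladder, n_steps=120_000, step_size=1.5,
                                   seed=5)
        direct = sample_boltzmann_mc(pot, 309.0, 120_000, step_size=1.5, seed=6)
        a = res.analysis_trajectory.coordinates[::11, 0, 0][:10_000]
        b = direct.coordinates[::11, 0, 0][:10_000]
        _, p = stats.ks_2samp(a, b)
        assert p > 0.01

    def test_acceptance_non_increasing_with_ladder_spacing(self):
        pot = PotentialSpec.harmonic(k=1.0)
        rates = []
        for t_hi in (315.0, 345.0, 380.0):
            ladder = ReplicaLadder([309.0, t_hi], swap_interval=100)
            res = run_replica_exchange(pot, ladder, n_steps=30_000,
                                       step_size=1.5, seed=11)
            rates.append(res.acceptance[(0, 1)])
        assert rates[0] >= rates[1] >= rates[2]


class TestBilayer:
    def test_infinite_kappa_aligns_all_chains(self):
        top, frame = make_bilayer(50, tilt_kappa=np.inf, seed=0)
        pairs = lipid_chain_pairs(top)
        vecs = frame.coordinates[[p[1] for p in pairs]] - \
            frame.coordinates[[p[0] for p in pairs]]
        cos = np.abs(vecs[:, 2]) / np.linalg.norm(vecs, axis=1)
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_zero_sigma_places_po4_exactly_at_planes(self):
        top, frame = make_bilayer(20, headgroup_z=24.0, z_sigma=0.0, seed=1)
        z = frame.coordinates[top.select(name="PO4"), 2]
        assert set(np.round(z, 9)) == {24.0, -24.0}

    def test_vmf_cos2_matches_quadrature(self):
        # closed-form <cos^2> against direct numerical quadrature
        for kappa in (0.5, 2.0, 5.0, 15.0, 50.0):
            num = integrate.quad(
                lambda t, k=kappa: t * t * np.exp(k * t), -1, 1)[0]
            den = integrate.quad(lambda t, k=kappa: np.exp(k * t), -1, 1)[0]
            assert vmf_mean_cos2(kappa) == pytest.approx(num / den, rel=1e-6)

    def test_kappa_inversion_recovers_target_order_parameter(self):
        kappa = kappa_for_order(0.60)
        top, frame = make_bilayer(1000, tilt_kappa=kappa, seed=2)
        traj = Trajectory(top, frame.coordinates[None], frame.box)
        mean_px, _ = chain_order_parameter(traj, lipid_chain_pairs(top))
        assert mean_px == pytest.approx(0.60, abs=0.02)


class TestPoreAssembly:
    def test_regular_hexagon_opposite_distances(self):
        top, frame = make_pore_assembly(6, ring_radius=24.0, stretch=1.0, seed=0)
        for lab in (1, 2, 3):
            com_a = frame.coordinates[top.dimer_assignments[lab]].mean(axis=0)
            com_b = frame.coordinates[top.dimer_assignments[lab + 3]].mean(axis=0)
            assert np.linalg.norm(com_a - com_b) == pytest.approx(48.0, abs=1e-9)

    def test_stretched_opposite_distances_match_ellipse_chords(self):
        r, s = 24.0, 1.3
        top, frame = make_pore_assembly(6, ring_radius=r, stretch=s, seed=0)
        angles = 2 * np.pi * np.arange(6) / 6
        for i in (0, 1, 2):
            com_a = frame.coordinates[top.dimer_assignments[i + 1]].mean(axis=0)
            com_b = frame.coordinates[top.dimer_assignments[i + 4]].mean(axis=0)
            expected = 2.0 * math.hypot(s * r * math.cos(angles[i]),
                                        r * math.sin(angles[i]))
            assert np.linalg.norm(com_a - com_b) == pytest.approx(expected,
                                                                  abs=1e-9)

    def test_odd_dimer_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_pore_assembly(5)


class TestCargoPlacement:
    def test_default_scheme_yields_48_replicas(self):
        _, cargo = make_helix(8)
        frames = place_cargo_replicas(cargo, PlacementScheme(seed=0))
        assert len(frames) == 48  # 6 axial positions x 8 orientations

    def test_single_placement_at_origin(self):
        _, cargo = make_helix(8)
        frames = place_cargo_replicas(cargo, PlacementScheme(1, 13.0, 1, seed=0))
        assert len(frames) == 1
        assert frames[0].coordinates.mean(axis=0)[2] == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_consecutive_axial_positions_spaced_exactly(self):
        _, cargo = make_helix(8)
        scheme = PlacementScheme(6, 13.0, 2, seed=0)
        frames = place_cargo_replicas(cargo, scheme)
        z = np.array([f.coordinates.mean(axis=0)[2] for f in frames])
        levels = np.unique(np.round(z, 9))
        np.testing.assert_allclose(np.diff(levels), 13.0, atol=1e-9)

    def test_mouth_placements_respect_clearance(self):
        pore_top, pore_frame = make_pore_assembly(6, ring_radius=10.0, seed=1)
        _, cargo = make_helix(8)
        frames = place_cargo_replicas(cargo, PlacementScheme(6, 13.0, 2, seed=2),
                                      pore_frame=pore_frame, clearance=3.0)
        z_levels = sorted({round(f.coordinates.mean(axis=0)[2], 6) for f in frames})
        half = np.ptp(pore_frame.coordinates[:, 2]) / 2
        mouth_levels = {min(z_levels, key=lambda z: abs(z - m)) for m in (-half, half)}
        for f in frames:
            if round(f.coordinates.mean(axis=0)[2], 6) in mouth_levels:
                d = np.linalg.norm(
                    f.coordinates[:, None, :] - pore_frame.coordinates[None],
                    axis=-1)
                assert d.min() >= 3.0


class TestIons:
    def test_counts_from_molarity_in_1e6_cubic_angstrom(self):
        frame = Frame(np.zeros((0, 3)).reshape(0, 3),
                      np.array([100.0, 100.0, 100.0]))
        top, out = add_ions(None, frame, {"NA": 0.035}, seed=0)
        # 0.035 mol/L * N_A * 1e-21 L = 21.08 -> 21 cations (+21 Cl)
        assert len(top.select(name="NA")) == 21
        assert len(top.select(name="CL")) == 21

    def test_electroneutrality_with_divalents(self):
        frame = Frame(np.zeros((0, 3)), np.array([120.0, 120.0, 140.0]))
        top, _ = add_ions(None, frame, {"NA": 0.035, "CA": 0.035},
                          surface_enrichment=3.0, seed=1)
        assert ion_charge(top) == 0

    def test_no_enrichment_gives_flat_axial_histogram(self):
        frame = Frame(np.zeros((0, 3)), np.array([200.0, 200.0, 200.0]))
        top, out = add_ions(None, frame, {"NA": 0.4}, surface_enrichment=1.0,
                            seed=2)
        z = out.coordinates[:, 2]
        counts, _ = np.histogram(z, bins=10, range=(-100, 100))
        n = counts.sum()
        sigma = math.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(counts / n - 0.1) < 4 * sigma)

    def test_enrichment_raises_slab_density(self):
        frame = Frame(np.zeros((0, 3)), np.array([200.0, 200.0, 140.0]))
        top, out = add_ions(None, frame, {"CA": 0.2}, surface_enrichment=5.0,
                            seed=3, leaflet_z=24.0, slab_halfwidth=5.0)
        ca = out.coordinates[top.select(name="CA"), 2]
        in_slab = np.mean((np.abs(np.abs(ca) - 24.0) <= 5.0))
        # slabs cover 20/140 of the box; 5x enrichment predicts ~42%
        assert in_slab > 0.25

    def test_negative_concentration_rejected(self):
        frame = Frame(np.zeros((0, 3)), np.array([100.0] * 3))
        with pytest.raises(ValueError, match="negative"):
            add_ions(None, frame, {"NA": -0.1})
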