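"""Gō Hamiltonian correctness and Metropolis sampler statistics."""

import numpy as np
import pytest
from scipy import integrate, stats

from gomelt.analysis import qn_series
from gomelt.go_model import (
    Conformation,
    GoParameters,
    GoSystem,
    acceptance_ratio,
    compute_energy,
    propagate_mc,
)
from gomelt.structure_io import ContactMap, build_contact_map


def brute_force_energy(xyz, cmap, params, b0, cos_theta0=None, angle_k=0.0):
    """Independent double-loop oracle for the full Hamiltonian."""
    n = len(xyz)
    nat = {tuple(p): (r, w) for p, r, w in zip(cmap.pairs.tolist(), cmap.r0, cmap.weight)}
    e_nat = e_bond = e_exc = 0.0
    if angle_k > 0:
        for j in range(1, n - 1):
            u, v = xyz[j - 1] - xyz[j], xyz[j + 1] - xyz[j]
            cos = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            e_bond += 0.5 * angle_k * (cos - cos_theta0[j - 1]) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            if j == i + 1:
                e_bond += 0.5 * params.bond_k * (r - b0[i]) ** 2
            elif (i + 1, j + 1) in nat:
                r0, w = nat[(i + 1, j + 1)]
                e_nat += w * params.epsilon * (5 * (r0 / r) ** 12 - 6 * (r0 / r) ** 10)
            elif r < params.excluded_sigma:
                e_exc += params.epsilon * ((params.excluded_sigma / r) ** 12 - 1.0)
    return e_nat, e_bond, e_exc


def two_bead_map():
    return ContactMap(
        pairs=np.empty((0, 2), dtype=int), r0=np.empty(0), weight=np.empty(0),
        min_seq_sep=3, cutoff=8.0, n_residues=2,
    )


class TestComputeEnergy:
    def test_single_contact_minimum(self):
        # pair (1,4) at exactly r0 with weight 1, epsilon 2 -> e_native = -2
        cmap = ContactMap(
            pairs=np.array([[1, 4]]), r0=np.array([5.0]), weight=np.array([1.0]),
            min_seq_sep=3, cutoff=8.0, n_residues=4,
        )
        params = GoParameters(epsilon=2.0)
        xyz = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [5.0, 0.01, 0]], dtype=float)
        xyz[3] = [0, 5.0, 0]  # distance 1-4 exactly 5 = r0
        e = compute_energy(Conformation(xyz), cmap, params)
        assert e.e_native == pytest.approx(-2.0, abs=1e-12)

    def test_native_conformation_sums_well_depths(self, barrel, barrel_map, go_params):
        sys_ = GoSystem.from_contact_map(barrel_map, go_params, barrel.ca_coordinates)
        e = compute_energy(Conformation(barrel.ca_coordinates), barrel_map, go_params, system=sys_)
        assert e.e_native == pytest.approx(-barrel_map.weight.sum() * go_params.epsilon, rel=1e-12)
        assert e.e_bond == pytest.approx(0.0, abs=1e-9)
        assert e.e_excluded == pytest.approx(0.0, abs=1e-9)

    def test_random_conformation_matches_brute_force(self, barrel, barrel_map, go_params, rng):
        sys_ = GoSystem.from_contact_map(barrel_map, go_params, barrel.ca_coordinates)
        xyz = barrel.ca_coordinates + rng.normal(0, 1.0, barrel.ca_coordinates.shape)
        e = compute_energy(Conformation(xyz), barrel_map, go_params, system=sys_)
        e_nat, e_bond, e_exc = brute_force_energy(
            xyz, barrel_map, go_params, sys_.b0, sys_.cos_theta0, sys_.angle_k
        )
        assert e.e_native == pytest.approx(e_nat, rel=1e-10)
        assert e.e_bond == pytest.approx(e_bond, rel=1e-10)
        assert e.e_excluded == pytest.approx(e_exc, rel=1e-10, abs=1e-10)
        assert e.e_total == pytest.approx(e_nat + e_bond + e_exc, rel=1e-10)

    def test_overlapping_beads_raise(self):
        cmap = two_bead_map()
        xyz = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero"):
            compute_energy(Conformation(xyz), cmap, GoParameters())


class TestPropagateMc:
    def test_zero_sweeps_returns_initial(self, barrel, barrel_map, go_params):
        conf = Conformation(barrel.ca_coordinates.copy(), 5)
        out = propagate_mc(conf, barrel_map, go_params, 300.0, 0, seed=1)
        assert len(out) == 1
        assert np.array_equal(out[0].coordinates, conf.coordinates)
        assert out[0].step_index == 5

    def test_same_seed_same_trajectory(self, barrel, barrel_map, go_params):
        conf = Conformation(barrel.ca_coordinates.copy(), 0)
        a = propagate_mc(conf, barrel_map, go_params, 400.0, 50, seed=42, record_every=10)
        b = propagate_mc(conf, barrel_map, go_params, 400.0, 50, seed=42, record_every=10)
        assert all(np.array_equal(x.coordinates, y.coordinates) for x, y in zip(a, b))
        c = propagate_mc(conf, barrel_map, go_params, 400.0, 50, seed=43, record_every=10)
        assert not np.array_equal(a[-1].coordinates, c[-1].coordinates)

    def test_two_bead_bond_length_boltzmann(self):
        """Sampled bond-length distribution matches the closed-form
        Boltzmann density p(r) ∝ r² exp(−β·½k(r−b0)²) (KS test)."""
        params = GoParameters(bond_k=10.0, step_sigma=0.3)
        cmap = two_bead_map()
        t = 300.0
        beta = 1.0 / (params.kB * t)
        conf = Conformation(np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        traj = propagate_mc(conf, cmap, params, t, 20_000, seed=9, record_every=2)
        r = np.array([np.linalg.norm(c.coordinates[1] - c.coordinates[0]) for c in traj[1000:]])

        grid = np.linspace(1e-3, 3.8 + 6 * np.sqrt(1 / (beta * params.bond_k)), 4000)
        dens = grid**2 * np.exp(-beta * 0.5 * params.bond_k * (grid - params.bond_r0) ** 2)
        cdf_grid = integrate.cumulative_trapezoid(dens, grid, initial=0)
        cdf_grid /= cdf_grid[-1]
        ks = stats.kstest(r, lambda x: np.interp(x, grid, cdf_grid))
        assert ks.pvalue > 0.01

    def test_acceptance_decreases_with_step_size(self, barrel, barrel_map):
        conf = Conformation(barrel.ca_coordinates.copy())
        ratios = []
        for step in (0.1, 0.5, 2.0):
            p = GoParameters(step_sigma=step)
            ratios.append(acceptance_ratio(conf, barrel_map, p, 350.0, 300, seed=5))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_cold_stays_folded_hot_unfolds(self, barrel, barrel_map, go_params):
        """Far below ε/kB the native state persists; far above it melts."""
        conf = Conformation(barrel.ca_coordinates.copy())
        sys_ = GoSystem.from_contact_map(barrel_map, go_params, barrel.ca_coordinates)
        cold = propagate_mc(conf, barrel_map, go_params, 100.0, 1000, seed=3,
                            record_every=100, system=sys_)
        qn_cold = qn_series(np.stack([c.coordinates for c in cold[1:]]), barrel_map)
        assert qn_cold.min() > 0.9
        hot = propagate_mc(conf, barrel_map, go_params, 2000.0, 1000, seed=3,
                           record_every=100, system=sys_)
        qn_hot = qn_series(np.stack([c.coordinates for c in hot[5:]]), barrel_map)
        assert qn_hot.mean() < 0.5

    def test_contact_basin_occupancy_matches_boltzmann(self):
        """Detailed balance on an enumerable toy: a 3-bead chain with a
        (1,3) native contact partitions into contact-formed and
        contact-broken states.  The long-run occupancy of the formed
        state must match the Boltzmann value computed by an independent
        importance-sampling oracle within 3 SE."""
        eps, k, b0, r0 = 6.0, 10.0, 3.8, 4.5
        t = 350.0
        params = GoParameters(epsilon=eps, bond_k=k, bond_r0=b0, step_sigma=0.5)
        beta = 1.0 / (params.kB * t)
        r_split = 5.5

        def config_energy(u, v):
            lu = np.linalg.norm(u, axis=1)
            lv = np.linalg.norm(v, axis=1)
            x = r0 / np.linalg.norm(u + v, axis=1)
            return (
                0.5 * k * (lu - b0) ** 2 + 0.5 * k * (lv - b0) ** 2
                + eps * (5 * x**12 - 6 * x**10)
            )

        # independent oracle: importance sampling over the two bond vectors
        rng = np.random.default_rng(2024)
        sig = 2.5
        u = rng.normal(0, sig, (2_000_000, 3))
        v = rng.normal(0, sig, (2_000_000, 3))
        log_w = -beta * config_energy(u, v) + (np.sum(u * u, 1) + np.sum(v * v, 1)) / (2 * sig**2)
        w = np.exp(log_w - log_w.max())
        r13 = np.linalg.norm(u + v, axis=1)
        p_formed_exact = float(np.sum(w * (r13 < r_split)) / np.sum(w))

        cmap = ContactMap(
            pairs=np.array([[1, 3]]), r0=np.array([r0]), weight=np.array([1.0]),
            min_seq_sep=2, cutoff=8.0, n_residues=3,
        )
        start = np.array([[0.0, 0, 0], [3.8, 0, 0], [2.0, 4.0, 0]])
        traj = propagate_mc(Conformation(start), cmap, params, t, 100_000, seed=21, record_every=5)
        r = np.array([np.linalg.norm(c.coordinates[2] - c.coordinates[0]) for c in traj[4000:]])
        p_formed = np.mean(r < r_split)
        # binomial SE with a correlation-inflated effective sample size
        n_eff = len(r) / 20
        se = np.sqrt(p_formed_exact * (1 - p_formed_exact) / n_eff)
        assert abs(p_formed - p_formed_exact) < 3 * se, (p_formed, p_formed_exact, se)
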