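"""Observable extraction: Q_N, strand content, block averaging,
histograms, free-energy surfaces."""

import numpy as np
import pytest

from gomelt.analysis import (
    block_stats,
    fraction_native,
    free_energy_landscape,
    histogram_observable,
    melting_curve,
    qn_series,
    sheet_contact_counts,
    strand_content,
)
from gomelt.go_model import KB, Conformation
from gomelt.rest2_engine import EffectiveTemperatureMap
from gomelt.structure_io import ContactMap


@pytest.fixture()
def small_map():
    # two contacts on a 7-residue chain
    return ContactMap(
        pairs=np.array([[1, 5], [2, 7]]), r0=np.array([5.0, 6.0]),
        weight=np.ones(2), min_seq_sep=3, cutoff=8.0, n_residues=7,
    )


def chain_with_pair_distances(d15, d27):
    xyz = np.zeros((7, 3))
    xyz[:, 0] = np.arange(7) * 3.8
    xyz[4] = xyz[0] + [d15, 0, 0]
    xyz[6] = xyz[1] + [0, d27, 0]
    return Conformation(xyz)


class TestFractionNative:
    def test_native_is_one(self, barrel, barrel_map):
        assert fraction_native(Conformation(barrel.ca_coordinates), barrel_map) == 1.0

    def test_stretched_chain_is_zero(self, barrel_map):
        n = barrel_map.n_residues
        xyz = np.zeros((n, 3))
        xyz[:, 0] = np.arange(n) * 3.8  # fully extended: all pairs beyond 1.2 r0
        assert fraction_native(Conformation(xyz), barrel_map) == 0.0

    def test_half_formed(self, small_map):
        conf = chain_with_pair_distances(5.0, 60.0)  # (1,5) formed, (2,7) broken
        assert fraction_native(conf, small_map) == 0.5

    def test_qn_series_matches_scalar(self, small_map):
        confs = [chain_with_pair_distances(5.0, 60.0), chain_with_pair_distances(5.0, 6.0)]
        stack = np.stack([c.coordinates for c in confs])
        per_frame = qn_series(stack, small_map)
        assert per_frame.tolist() == [fraction_native(c, small_map) for c in confs]

    def test_empty_map_raises(self):
        empty = ContactMap(
            pairs=np.empty((0, 2), dtype=int), r0=np.empty(0), weight=np.empty(0),
            min_seq_sep=3, cutoff=8.0, n_residues=4,
        )
        with pytest.raises(ValueError, match="empty"):
            fraction_native(Conformation(np.zeros((4, 3)) + np.arange(4)[:, None]), empty)


class TestStrandContent:
    def test_native_normalises_to_one(self, barrel, barrel_map):
        prof = strand_content(Conformation(barrel.ca_coordinates), barrel_map, barrel.strand_ranges)
        assert np.allclose(prof.content, 1.0)

    def test_broken_strand_scores_zero(self, small_map):
        strands = {"s1": (1, 2), "s2": (5, 7)}
        conf = chain_with_pair_distances(60.0, 60.0)  # both contacts broken
        prof = strand_content(conf, small_map, strands)
        assert np.allclose(prof.content, 0.0)

    def test_matches_double_loop_oracle(self, barrel, barrel_map, rng):
        xyz = barrel.ca_coordinates + rng.normal(0, 1.5, barrel.ca_coordinates.shape)
        prof = strand_content(Conformation(xyz), barrel_map, barrel.strand_ranges)
        for lab, (a, b) in barrel.strand_ranges.items():
            formed = total = 0
            for (i, j), r0 in zip(barrel_map.pairs, barrel_map.r0):
                if (a <= i <= b) or (a <= j <= b):
                    total += 1
                    d = np.linalg.norm(xyz[i - 1] - xyz[j - 1])
                    formed += d <= 1.2 * r0
            assert prof.as_dict()[lab] == pytest.approx(formed / total)

    def test_strand_without_contacts_raises(self, small_map):
        with pytest.raises(ValueError, match="s9"):
            strand_content(chain_with_pair_distances(5, 6), small_map, {"s9": (3, 4)})


class TestBlockAveraging:
    def test_constant_series(self):
        mean, sem = block_stats(np.full(1000, 0.8), 0.4, 12)
        assert mean == pytest.approx(0.8)
        assert sem == 0.0

    def test_burn_in_arithmetic(self):
        # 1000 frames, burn-in 0.4: only the last 600 analysed
        series = np.concatenate([np.zeros(400), np.ones(600)])
        mean, _ = block_stats(series, 0.4, 12)
        assert mean == 1.0

    def test_alternating_series_closed_form(self):
        # alternating 0/1 with 10 even-length blocks: every block mean is
        # exactly 0.5, so the SD of block means (and the SEM) is 0
        series = np.tile([0.0, 1.0], 250)
        mean, sem = block_stats(series, 0.0, 10)
        assert mean == pytest.approx(0.5)
        assert sem == pytest.approx(0.0)

    def test_too_few_blocks_raises(self):
        with pytest.raises(ValueError, match="block"):
            block_stats(np.ones(100), 0.0, 1)

    def test_melting_curve_shape(self):
        teff = EffectiveTemperatureMap(teff=np.array([300.0, 400.0, 500.0]), method="analytic")
        qn = np.vstack([np.full(100, 0.9), np.full(100, 0.5), np.full(100, 0.2)])
        curve = melting_curve(qn, teff, burn_in_fraction=0.4, n_blocks=5)
        assert curve.qn_mean == pytest.approx([0.9, 0.5, 0.2])
        assert curve.n_blocks == 5


class TestHistogram:
    def test_normalised_frequencies_sum_to_one(self, rng):
        h = histogram_observable(rng.random(10), np.linspace(0, 1, 6), normalize=True)
        assert h.counts.sum() == pytest.approx(1.0)

    def test_single_bin_occupancy(self):
        h = histogram_observable(np.full(7, 0.55), np.linspace(0, 1, 11))
        assert h.counts[5] == 7 and h.counts.sum() == 7

    def test_overflow_is_counted(self):
        h = histogram_observable(np.array([-0.5, 0.5, 1.7, 2.0]), np.linspace(0, 1, 6))
        assert h.n_below == 1 and h.n_above == 2

    def test_bimodal_modes_recovered(self, rng):
        x = np.concatenate([rng.normal(0.25, 0.04, 4000), rng.normal(0.75, 0.04, 4000)])
        h = histogram_observable(x, np.linspace(0, 1, 26), normalize=True)
        c = h.counts
        interior_maxima = [
            k for k in range(1, len(c) - 1) if c[k] > c[k - 1] and c[k] >= c[k + 1] and c[k] > 0.02
        ]
        assert len(interior_maxima) == 2

    def test_bad_edges_raise(self):
        with pytest.raises(ValueError):
            histogram_observable(np.ones(3), np.array([0.0]))


class TestFreeEnergyLandscape:
    def test_uniform_occupancy_is_flat_zero(self, rng):
        cv1 = np.repeat([0.5, 1.5], 500)
        cv2 = np.tile(np.repeat([0.5, 1.5], 250), 2)
        surf = free_energy_landscape(cv1, cv2, 300.0, (np.arange(3.0), np.arange(3.0)))
        occ = surf.f_values[~surf.mask]
        assert np.allclose(occ, 0.0)

    def test_two_bin_depth_closed_form(self):
        # P = 0.8 / 0.2 at 387 K -> dF = -kB*387*ln(0.25) = 4.46 kJ/mol
        cv1 = np.concatenate([np.full(800, 0.5), np.full(200, 1.5)])
        cv2 = np.full(1000, 0.5)
        surf = free_energy_landscape(cv1, cv2, 387.0, (np.arange(3.0), np.arange(2.0)))
        df = surf.f_values[1, 0] - surf.f_values[0, 0]
        assert df == pytest.approx(-KB * 387.0 * np.log(0.25), rel=1e-9)
        assert df == pytest.approx(4.46, abs=0.01)

    def test_minimum_is_exactly_zero(self, rng):
        cv1, cv2 = rng.random(500), rng.random(500)
        surf = free_energy_landscape(cv1, cv2, 300.0, (np.linspace(0, 1, 6), np.linspace(0, 1, 6)))
        assert np.nanmin(surf.f_values) == 0.0

    def test_single_occupied_bin_warns(self):
        with pytest.warns(UserWarning, match="single"):
            surf = free_energy_landscape(
                np.full(10, 0.5), np.full(10, 0.5), 300.0,
                (np.arange(3.0), np.arange(3.0)),
            )
        assert surf.f_values[0, 0] == 0.0
        assert np.sum(~surf.mask) == 1

    def test_two_basin_reconstruction(self, rng):
        """Sampling a known two-basin density and rebuilding F recovers the
        imposed depth difference within binning error."""
        t = 387.0
        dF = 3.0  # kJ/mol between basins
        p_hi = 1.0 / (1.0 + np.exp(dF / (KB * t)))
        pick = rng.random(40_000) < p_hi
        cv1 = np.where(pick, 10.0, 2.0) + rng.normal(0, 0.5, 40_000)
        cv2 = np.full(40_000, 5.0) + rng.normal(0, 0.5, 40_000)
        edges = (np.linspace(0, 12, 13), np.linspace(0, 10, 11))
        surf = free_energy_landscape(cv1, cv2, t, edges)
        f = surf.f_values
        low_basin = np.nanmin(f[:5, :])
        high_basin = np.nanmin(f[8:, :])
        assert high_basin - low_basin == pytest.approx(dF, abs=0.5)


class TestSheetContactCounts:
    def test_native_counts_all_within_sheet_contacts(self, barrel, barrel_map):
        c1, c2 = sheet_contact_counts(barrel.ca_coordinates, barrel_map, barrel.strand_ranges)
        # native conformation: every within-sheet contact is formed
        assert c1 > 0 and c2 > 0
        stretched = np.zeros_like(barrel.ca_coordinates)
        stretched[:, 0] = np.arange(len(barrel.ca_coordinates)) * 3.8
        z1, z2 = sheet_contact_counts(stretched, barrel_map, barrel.strand_ranges)
        assert z1 == 0 and z2 == 0
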