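"""Rate maps, autocorrelograms, grid score and field geometry."""

import numpy as np
import pytest

from gridcan.errors import AnalysisError
from gridcan.spatial import (
    Autocorrelogram,
    RateMap,
    compute_rate_map,
    detect_fields,
    field_spacing,
    grid_score,
    spacing_from_field_centers,
    spatial_autocorrelogram,
)
from gridcan.stimulus import Trajectory, synthesize_trajectory


def lattice_map(
    spacing: float,
    angle_deg: float = 15.0,
    kind: str = "hex",
    arena: float = 45.0,
    bin_cm: float = 3.0,
    sigma: float = 4.0,
) -> RateMap:
    """Constructed ideal lattice rate map (the geometric oracle)."""
    n = int(arena / bin_cm)
    xy = (np.indices((n, n)).reshape(2, -1).T[:, ::-1] + 0.5) * bin_cm
    th = np.deg2rad(angle_deg)
    second = th + (np.pi / 3 if kind == "hex" else np.pi / 2)
    v1 = spacing * np.array([np.cos(th), np.sin(th)])
    v2 = spacing * np.array([np.cos(second), np.sin(second)])
    reach = int(np.ceil(2 * arena / spacing))
    rate = np.zeros(n * n)
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            c = np.array([arena / 2, arena / 2]) + i * v1 + j * v2
            rate += np.exp(-np.sum((xy - c) ** 2, axis=1) / (2 * sigma**2))
    return RateMap(
        rate=rate.reshape(n, n),
        occupancy=np.ones((n, n)),
        bin_cm=bin_cm,
        smooth_cm=0.0,
        n_spikes=0,
    )


def uniform_trajectory(duration_s: float = 240.0, seed: int = 0) -> Trajectory:
    return synthesize_trajectory(duration_s, seed=seed)


class TestRateMap:
    def test_definitional_rate_single_bin(self):
        """One spike over 2 s of occupancy in one bin -> 0.5 spikes/s."""
        t = np.arange(0, 2.01, 0.02)
        traj = Trajectory(t=t, x=np.full(t.size, 1.0), y=np.full(t.size, 1.0))
        rm = compute_rate_map(np.array([1.0]), traj, smooth_cm=0.0)
        assert np.nansum(rm.rate) == pytest.approx(0.5, rel=0.02)

    def test_mass_conservation_unsmoothed(self, rng):
        traj = uniform_trajectory(120.0)
        spikes = rng.uniform(0.0, traj.duration, size=400)
        rm = compute_rate_map(spikes, traj, smooth_cm=0.0)
        total = np.nansum(np.where(rm.visited, rm.rate, 0.0) * rm.occupancy)
        assert total == pytest.approx(400, abs=1)

    def test_homogeneous_poisson_recovers_rate(self, rng):
        """Poisson spiking at 5 Hz over a long foraging path -> map near 5
        everywhere (sampling noise allowed)."""
        traj = uniform_trajectory(600.0, seed=3)
        n = rng.poisson(5.0 * traj.duration)
        spikes = np.sort(rng.uniform(0.0, traj.duration, size=n))
        rm = compute_rate_map(spikes, traj)
        rates = rm.rate[rm.visited]
        assert abs(np.median(rates) - 5.0) < 1.0

    def test_no_spikes_gives_zero_map(self):
        traj = uniform_trajectory(60.0)
        rm = compute_rate_map(np.array([]), traj)
        assert np.nanmax(rm.rate) == 0.0

    def test_zero_occupancy_rejected(self):
        t = np.array([0.0, 0.02])
        with pytest.raises(AnalysisError):
            traj = Trajectory(t=t[:1], x=np.array([1.0]), y=np.array([1.0]))
            compute_rate_map(np.array([]), traj)


class TestAutocorrelogram:
    def test_zero_lag_is_one_and_symmetric(self):
        rm = lattice_map(22.0)
        ac = spatial_autocorrelogram(rm)
        cy, cx = ac.center
        assert ac.corr[cy, cx] == 1.0
        finite = np.isfinite(ac.corr)
        np.testing.assert_array_equal(finite, finite[::-1, ::-1])
        np.testing.assert_allclose(
            ac.corr[finite], ac.corr[::-1, ::-1][finite], atol=1e-9
        )

    def test_periodic_stripes_peak_at_period(self):
        n, p = 20, 5
        stripe = np.tile(np.eye(1, p).ravel(), (n, n // p + 1))[:, :n] * 1.0
        rm = RateMap(rate=stripe, occupancy=np.ones((n, n)), bin_cm=1.0, smooth_cm=0.0, n_spikes=0)
        ac = spatial_autocorrelogram(rm)
        cy, cx = ac.center
        assert ac.corr[cy, cx + p] == pytest.approx(1.0, abs=1e-6)
        assert ac.corr[cy, cx - p] == pytest.approx(1.0, abs=1e-6)

    def test_constant_map_masked_with_warning(self):
        rm = RateMap(
            rate=np.ones((10, 10)), occupancy=np.ones((10, 10)),
            bin_cm=3.0, smooth_cm=0.0, n_spikes=0,
        )
        with pytest.warns(UserWarning, match="constant"):
            ac = spatial_autocorrelogram(rm)
        assert np.isnan(ac.corr[0, 0])


class TestGridScore:
    def test_hexagonal_lattice_scores_high(self):
        ac = spatial_autocorrelogram(lattice_map(22.0, kind="hex"))
        assert grid_score(ac) > 0.8

    def test_square_lattice_scores_negative(self):
        ac = spatial_autocorrelogram(lattice_map(22.0, kind="square"))
        assert grid_score(ac) < 0.0

    def test_radially_symmetric_autocorrelogram_scores_near_zero(self):
        r = np.hypot(*(np.indices((29, 29)) - 14.0))
        corr = np.exp(-((r / 4) ** 2)) - 0.4 * np.exp(-(((r - 9) / 6) ** 2))
        assert abs(grid_score(Autocorrelogram(corr=corr, bin_cm=3.0))) < 0.05

    def test_score_invariant_under_rate_scaling(self):
        rm = lattice_map(22.0)
        scaled = RateMap(
            rate=rm.rate * 7.5, occupancy=rm.occupancy,
            bin_cm=rm.bin_cm, smooth_cm=0.0, n_spikes=0,
        )
        s1 = grid_score(spatial_autocorrelogram(rm))
        s2 = grid_score(spatial_autocorrelogram(scaled))
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestFields:
    def test_single_gaussian_bump_level_set_oracle(self):
        """A sigma = 4 cm bump at 20% threshold has equivalent diameter
        2 * sigma * sqrt(2 ln 5); the center is recovered within a bin."""
        rm = lattice_map(200.0, sigma=4.0)  # effectively a single bump
        fields = detect_fields(rm)
        assert len(fields) == 1
        oracle = 2.0 * 4.0 * np.sqrt(2.0 * np.log(5.0))
        assert fields[0].diameter_cm == pytest.approx(oracle, abs=3.0)
        assert fields[0].center_cm[0] == pytest.approx(22.5, abs=3.0)
        assert fields[0].center_cm[1] == pytest.approx(22.5, abs=3.0)

    def test_uniform_map_has_no_fields(self):
        rm = RateMap(
            rate=np.ones((15, 15)), occupancy=np.ones((15, 15)),
            bin_cm=3.0, smooth_cm=0.0, n_spikes=0,
        )
        assert detect_fields(rm) == []

    def test_two_separated_bumps_give_two_fields(self):
        n = 15
        xy = (np.indices((n, n)).reshape(2, -1).T[:, ::-1] + 0.5) * 3.0
        rate = np.zeros(n * n)
        for c in ([10.0, 10.0], [35.0, 35.0]):
            rate += np.exp(-np.sum((xy - np.array(c)) ** 2, axis=1) / (2 * 16.0))
        rm = RateMap(rate=rate.reshape(n, n), occupancy=np.ones((n, n)), bin_cm=3.0, smooth_cm=0.0, n_spikes=0)
        fields = detect_fields(rm)
        assert len(fields) == 2
        assert spacing_from_field_centers(fields) == pytest.approx(
            np.hypot(25.0, 25.0), abs=4.0
        )


class TestSpacing:
    def test_recovers_47cm_lattice_on_large_domain(self):
        """On a domain wide enough to hold the first peak ring, spacing of a
        47-cm lattice is recovered within one bin."""
        rm = lattice_map(47.0, arena=135.0, sigma=6.0)
        spacing, _ = field_spacing(spatial_autocorrelogram(rm))
        assert spacing == pytest.approx(47.0, abs=3.0)

    def test_recovers_orientation_of_rotated_lattice(self):
        rm = lattice_map(30.0, angle_deg=15.0, arena=90.0, sigma=5.0)
        _, orientation = field_spacing(spatial_autocorrelogram(rm))
        assert orientation == pytest.approx(15.0, abs=2.0)

    def test_white_noise_map_is_undefined(self, rng):
        noise = rng.random((15, 15))
        rm = RateMap(rate=noise, occupancy=np.ones((15, 15)), bin_cm=3.0, smooth_cm=0.0, n_spikes=0)
        with pytest.raises(AnalysisError):
            field_spacing(spatial_autocorrelogram(rm))
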