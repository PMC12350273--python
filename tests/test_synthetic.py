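"""Generative truth, occurrence sampling and trait simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from timberzone.grids import GridError, GridTransform, SuitabilitySurface
from timberzone.synthetic import (
    TruthParams,
    annual_suitability_series,
    generate_climate_grid,
    perturb_climate_grid,
    rings_to_chronological,
    sample_occurrences,
    simulate_traits,
    true_suitability_surface,
)


class TestTrueSuitability:
    def test_zero_betas_give_half_everywhere(self, small_grid):
        truth = TruthParams(beta0=0.0, beta={"TD": 0.0, "MAP": 0.0, "CMD": 0.0})
        s = true_suitability_surface(small_grid, truth)
        np.testing.assert_allclose(s.values, 0.5)

    def test_logistic_hand_value(self):
        # beta0 = 1 with a single driver at z = 1, beta = 1: expit(2)
        assert expit(1.0 + 1.0 * 1.0) == pytest.approx(0.8807970779778823)

    def test_wetter_cell_more_suitable(self, small_grid):
        truth = TruthParams(beta0=0.0, beta={"MAP": 1.5})
        s = true_suitability_surface(small_grid, truth)
        m = small_grid.variables["MAP"]
        i, j = np.unravel_index(np.argmax(m), m.shape)
        k, l = np.unravel_index(np.argmin(m), m.shape)
        assert s.values[i, j] > s.values[k, l]

    def test_values_strictly_inside_unit_interval(self, truth_surface):
        assert truth_surface.values.min() > 0.0
        assert truth_surface.values.max() < 1.0

    def test_constant_driver_rejected(self, small_grid):
        bad = small_grid.copy()
        bad.variables["CMD"] = np.full(bad.shape, 100.0)
        with pytest.raises(GridError, match="constant"):
            true_suitability_surface(bad, TruthParams())

    def test_reference_standardisation_moves_with_uniform_shift(self, small_grid):
        """A uniform MAP increase must raise suitability when z-scores are
        anchored to the reference normals (and be absorbed when they are not)."""
        truth = TruthParams(beta0=0.0, beta={"MAP": 2.0})
        shifted = small_grid.copy()
        shifted.variables["MAP"] = shifted.variables["MAP"] * 1.2
        base = true_suitability_surface(small_grid, truth)
        anchored = true_suitability_surface(shifted, truth, reference=small_grid)
        floating = true_suitability_surface(shifted, truth)
        assert np.all(anchored.values >= base.values)
        assert np.any(anchored.values > base.values)
        # per-grid z-scoring absorbs a multiplicative shift only partially,
        # but the anchored surface must respond more strongly
        assert anchored.values.mean() > floating.values.mean()


class TestSampleOccurrences:
    def test_single_valid_cell_is_sampled(self):
        values = np.zeros((3, 3))
        values[1, 2] = 0.8
        s = SuitabilitySurface(values=values)
        df = sample_occurrences(s, 1, seed=0)
        lon, lat = s.transform.cell_center(1, 2)
        assert df.iloc[0]["lon"] == pytest.approx(lon)
        assert df.iloc[0]["lat"] == pytest.approx(lat)

    def test_indicator_surface_confines_presences(self):
        values = np.zeros((10, 10))
        values[:5, :] = 0.9  # suitable only in the northern half
        s = SuitabilitySurface(values=values)
        df = sample_occurrences(s, 20, seed=3)
        _, lat_border = s.transform.cell_center(5, 0)
        assert (df["lat"] > lat_border).all()

    def test_too_many_presences_rejected(self, truth_surface):
        with pytest.raises(ValueError, match="valid cells"):
            sample_occurrences(truth_surface, 10**6, seed=0)

    def test_same_seed_identical_draw(self, truth_surface):
        a = sample_occurrences(truth_surface, 50, seed=9)
        b = sample_occurrences(truth_surface, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_inclusion_frequencies_match_enumerated_probabilities(self):
        """Monte-Carlo inclusion frequencies against exact sequential-PPS
        probabilities enumerated over all ordered draws of 2 from 4 cells."""
        weights = np.array([0.1, 0.2, 0.3, 0.4])
        n_draw = 2
        # exact inclusion probabilities under successive weighted sampling
        incl = np.zeros(4)
        for perm in itertools.permutations(range(4), n_draw):
            p = 1.0
            remaining = weights.copy()
            for idx in perm:
                p *= remaining[idx] / remaining.sum()
                remaining[idx] = 0.0
            for idx in perm:
                incl[idx] += p
        s = SuitabilitySurface(values=weights.reshape(1, 4))
        reps = 500
        counts = np.zeros(4)
        for rep in range(reps):
            df = sample_occurrences(s, n_draw, seed=rep)
            _, cols = s.transform.cell_index(df["lon"].to_numpy(),
                                             df["lat"].to_numpy())
            counts[cols] += 1
        # 99% binomial bounds per cell
        se = np.sqrt(incl * (1 - incl) / reps)
        assert np.all(np.abs(counts / reps - incl) <= 2.576 * se + 1e-12)


class TestSimulateTraits:
    @staticmethod
    def _sites(n):
        return pd.DataFrame({"lon": np.linspace(105, 120, n),
                             "lat": np.linspace(24, 33, n)})

    def _noiseless(self, **kw):
        defaults = dict(noise_sd_growth=0.0, noise_sd_density=0.0,
                        site_sd_growth=0.0)
        defaults.update(kw)
        return TruthParams(**defaults)

    def test_constant_suitability_zero_noise(self):
        truth = self._noiseless(growth_coeffs=(0.1, 0.5, 0.1))
        S = np.full((3, 21), 0.5)
        traits = simulate_traits(self._sites(3), S, truth)
        expected = 0.1 + (0.5 + 0.1) * 0.5
        rings = traits[[f"ring{k:02d}_cm" for k in range(1, 21)]].to_numpy()
        np.testing.assert_allclose(rings, expected)
        np.testing.assert_allclose(traits["growth20_cm"], 20 * expected)

    def test_lagged_growth_hand_value(self):
        # g0=0.1, g1=0.5, g2=0.1 with S_{t-1}=0.8, S_t=0.4 -> 0.54 cm
        truth = self._noiseless(growth_coeffs=(0.1, 0.5, 0.1))
        S = np.full((1, 21), 0.4)
        S[0, -2] = 0.8  # the year before the final ring
        traits = simulate_traits(self._sites(1), S, truth)
        assert traits["ring01_cm"].iloc[0] == pytest.approx(0.54)

    def test_growth20_is_sum_of_rings(self, small_grid, truth):
        sites = self._sites(5)
        rng = np.random.default_rng(0)
        S = rng.uniform(0.2, 0.9, (5, 21))
        traits = simulate_traits(sites, S, truth, seed=4)
        rings = traits[[f"ring{k:02d}_cm" for k in range(1, 21)]].to_numpy()
        np.testing.assert_allclose(rings.sum(axis=1),
                                   traits["growth20_cm"], atol=1e-9)

    def test_density_monotone_in_mean_suitability(self):
        truth = self._noiseless(density_coeffs=(0.4, 0.3))
        S = np.tile(np.linspace(0.1, 0.9, 6)[:, None], (1, 21))
        traits = simulate_traits(self._sites(6), S, truth)
        assert traits["density_gcm3"].is_monotonic_increasing

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="preceding year"):
            simulate_traits(self._sites(2), np.full((2, 20), 0.5), TruthParams())

    def test_negative_increments_truncated_and_flagged(self):
        truth = TruthParams(growth_coeffs=(-1.0, 0.0, 0.0),
                            noise_sd_growth=0.0, site_sd_growth=0.0)
        traits = simulate_traits(self._sites(2), np.full((2, 21), 0.5), truth)
        assert (traits["truncated"] == 20).all()
        assert (traits["growth20_cm"] == 0).all()

    def test_ring_order_is_outermost_first(self):
        truth = self._noiseless(growth_coeffs=(0.0, 0.0, 1.0))
        S = np.linspace(0.0, 1.0, 21)[None, :]  # growth rises over time
        traits = simulate_traits(self._sites(1), S, truth)
        # ring01 (most recent) saw the highest suitability
        assert traits["ring01_cm"].iloc[0] > traits["ring20_cm"].iloc[0]
        chron = rings_to_chronological(traits)
        assert np.all(np.diff(chron[0]) > 0)

    def test_lag1_signal_recoverable_at_zero_noise(self):
        """Regressing zero-noise simulated growth on lag-1 suitability must
        recover the generative slope exactly (g2 = 0)."""
        truth = self._noiseless(growth_coeffs=(0.2, 0.6, 0.0))
        rng = np.random.default_rng(5)
        S = rng.uniform(0.1, 0.9, (10, 21))
        traits = simulate_traits(self._sites(10), S, truth)
        growth = rings_to_chronological(traits)
        prev = S[:, :-1]
        slope, intercept = np.polyfit(prev.ravel(), growth.ravel(), 1)
        assert slope == pytest.approx(0.6, abs=1e-9)
        assert intercept == pytest.approx(0.2, abs=1e-9)


class TestAnnualSeries:
    def test_interannual_variation_present(self, small_grid, truth):
        sites = pd.DataFrame({"lon": [105.5, 106.0], "lat": [32.0, 31.5]})
        series = annual_suitability_series(
            small_grid,
            lambda g: true_suitability_surface(g, truth, reference=small_grid),
            sites, n_years=6, seed=2)
        assert series.shape == (2, 6)
        assert np.all(series.std(axis=1) > 0)

    def test_perturbation_preserves_identities(self, small_grid):
        out = perturb_climate_grid(small_grid, np.random.default_rng(0))
        out.validate()
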