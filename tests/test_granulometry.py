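"""Lognormal droplet-size model: quantile algebra, binning, probit fit."""

import numpy as np
import pytest
from scipy import stats

from aerodist.granulometry import (
    BinnedSizeData,
    DropletDistribution,
    bin_distribution,
    fit_lognormal,
    gsd_from_quantiles,
    read_binned_csv,
    sample_diameters,
    write_binned_csv,
)
from aerodist.synthetic_data import generate_lds_histogram


class TestQuantiles:
    def test_median_identity(self):
        for gsd in (1.0, 1.3, 2.5):
            assert DropletDistribution(3.1, gsd).quantile(0.5) == pytest.approx(3.1)

    def test_reported_aerosol_quantiles(self, reference_dist):
        # Phi^{-1}(0.84) is ~ +1, so x16/x84 are ~ x50/gsd and x50*gsd
        assert reference_dist.quantile(0.16) == pytest.approx(2.59 / 1.73, rel=0.005)
        assert reference_dist.quantile(0.84) == pytest.approx(2.59 * 1.73, rel=0.005)

    def test_degenerate_gsd_one(self):
        d = DropletDistribution(4.2, 1.0)
        for q in (0.01, 0.5, 0.99):
            assert d.quantile(q) == pytest.approx(4.2)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_domain(self, reference_dist, q):
        with pytest.raises(ValueError):
            reference_dist.quantile(q)

    def test_quantile_algebra(self, reference_dist):
        d = reference_dist
        ratio_hi = d.quantile(0.84) / d.quantile(0.5)
        ratio_lo = d.quantile(0.5) / d.quantile(0.16)
        assert ratio_hi == pytest.approx(ratio_lo, abs=1e-9)
        # the x84/x50 ratio uses Phi^{-1}(0.84), not exactly gsd itself
        assert gsd_from_quantiles(d.quantile(0.16), d.quantile(0.84)) == pytest.approx(
            d.gsd ** abs(stats.norm.ppf(0.84)), abs=1e-9
        )
        # the one-geometric-sigma convention is exact on the properties
        assert d.x16_3 == pytest.approx(d.x50_3 / d.gsd, abs=1e-12)
        assert d.x84_3 == pytest.approx(d.x50_3 * d.gsd, abs=1e-12)
        assert gsd_from_quantiles(d.x16_3, d.x84_3) == pytest.approx(d.gsd, abs=1e-9)
        # and agrees with the exact quantiles to instrument precision
        assert d.x16_3 == pytest.approx(d.quantile(0.16), rel=0.005)
        assert d.x84_3 == pytest.approx(d.quantile(0.84), rel=0.005)


class TestGsdFromQuantiles:
    @pytest.mark.parametrize(
        "x16,x84,expected",
        [(1.497, 4.481, pytest.approx(1.73, abs=0.005)), (2.0, 2.0, 1.0), (1.0, 4.0, 2.0)],
    )
    def test_values(self, x16, x84, expected):
        assert gsd_from_quantiles(x16, x84) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            gsd_from_quantiles(-1.0, 2.0)
        with pytest.raises(ValueError):
            gsd_from_quantiles(4.0, 1.0)


class TestSampling:
    def test_monte_carlo_quantiles_converge(self, reference_dist):
        draws = sample_diameters(reference_dist, 10**6, seed=11)
        for q in (0.16, 0.5, 0.84):
            assert np.quantile(draws, q) == pytest.approx(reference_dist.quantile(q), rel=0.01)

    def test_degenerate_distribution_is_constant(self):
        draws = sample_diameters(DropletDistribution(2.0, 1.0), 100, seed=0)
        assert np.all(draws == 2.0)

    def test_seed_determinism(self, reference_dist):
        a = sample_diameters(reference_dist, 1000, seed=5)
        b = sample_diameters(reference_dist, 1000, seed=5)
        np.testing.assert_array_equal(a, b)


class TestBinning:
    def test_instrument_range_covers_reference_aerosol(self, reference_dist, lds_edges):
        # the 0.5-175 um grid leaves only ~1.3e-3 of volume outside
        raw_coverage = float(np.diff(reference_dist.cdf(lds_edges[[0, -1]]))[0])
        assert raw_coverage > 0.998
        binned = bin_distribution(reference_dist, lds_edges)
        assert binned.volume_fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_gets_all_mass(self, reference_dist):
        binned = bin_distribution(reference_dist, [1e-4, 1e4])
        assert binned.volume_fractions[0] == pytest.approx(1.0)

    def test_mass_below_median_is_half(self, reference_dist):
        binned = bin_distribution(reference_dist, [1e-4, 2.59, 1e4])
        assert binned.volume_fractions[0] == pytest.approx(0.5, abs=1e-9)

    def test_no_mass_errors(self, reference_dist):
        with pytest.raises(ValueError, match="no probability mass"):
            bin_distribution(reference_dist, [1000.0, 2000.0])

    def test_invalid_histograms_rejected(self):
        with pytest.raises(ValueError):
            BinnedSizeData(bin_edges=[2.0, 1.0, 3.0], volume_fractions=[0.5, 0.5])
        with pytest.raises(ValueError):
            BinnedSizeData(bin_edges=[1.0, 2.0], volume_fractions=[-1.0])


class TestFit:
    def test_noise_free_recovery_is_exact(self, lds_edges):
        true = DropletDistribution(2.0, 2.0)
        fitted = fit_lognormal(bin_distribution(true, lds_edges))
        assert fitted.x50_3 == pytest.approx(2.0, rel=1e-6)
        assert fitted.gsd == pytest.approx(2.0, rel=1e-6)

    def test_noisy_recovery_within_instrument_spread(self, reference_dist, lds_edges):
        binned = generate_lds_histogram(reference_dist, lds_edges, noise_cv=0.02, seed=7)
        fitted = fit_lognormal(binned)
        assert fitted.x50_3 == pytest.approx(2.59, abs=0.2)
        assert fitted.gsd == pytest.approx(1.73, abs=0.05)

    def test_agrees_with_grid_search_oracle(self, lds_edges):
        """Probit regression lands on the same optimum a dumb grid search
        finds by minimizing squared histogram error."""
        true = DropletDistribution(1.0, 1.5)
        target = bin_distribution(true, lds_edges).volume_fractions

        def loss(x50, gsd):
            model = bin_distribution(DropletDistribution(x50, gsd), lds_edges).volume_fractions
            return float(np.sum((model - target) ** 2))

        x50_grid = np.linspace(0.8, 1.2, 41)
        gsd_grid = np.linspace(1.3, 1.7, 41)
        losses = [(loss(a, b), a, b) for a in x50_grid for b in gsd_grid]
        _, best_x50, best_gsd = min(losses)
        fitted = fit_lognormal(BinnedSizeData(lds_edges, target))
        assert fitted.x50_3 == pytest.approx(best_x50, abs=0.011)  # grid pitch
        assert fitted.gsd == pytest.approx(best_gsd, abs=0.011)

    def test_diameter_unit_covariance(self, reference_dist, lds_edges):
        c = 3.7
        base = fit_lognormal(bin_distribution(reference_dist, lds_edges))
        scaled_dist = DropletDistribution(reference_dist.x50_3 * c, reference_dist.gsd)
        scaled = fit_lognormal(bin_distribution(scaled_dist, lds_edges * c))
        assert scaled.x50_3 == pytest.approx(base.x50_3 * c, rel=1e-9)
        assert scaled.gsd == pytest.approx(base.gsd, rel=1e-9)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_lognormal(BinnedSizeData([1.0, 2.0, 3.0], [0.5, 0.5]))


class TestCsv:
    def test_round_trip(self, reference_dist, lds_edges, tmp_path):
        binned = bin_distribution(reference_dist, lds_edges)
        path = write_binned_csv(binned, tmp_path / "bins.csv")
        back = read_binned_csv(path)
        np.testing.assert_allclose(back.bin_edges, binned.bin_edges)
        np.testing.assert_allclose(back.volume_fractions, binned.volume_fractions, atol=1e-12)
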