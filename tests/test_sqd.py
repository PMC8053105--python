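"""Squared-displacement pooling and Rayleigh-mixture fitting."""

import numpy as np
import pytest

from rmdynamics.simulate.tracks import (
    DiffusionModelParams,
    MTASE_LIKE,
    REASE_LIKE,
    simulate_tracks,
)
from rmdynamics.geometry import CellModelParams
from rmdynamics.sqd import (
    EmptyDistributionError,
    SQDDistribution,
    fit_rayleigh_mixture,
    select_model,
    squared_displacements,
)
from tests.conftest import make_trackset


def iid_exponential_sqd(rng, D, tau, n, fractions=None):
    """Directly sampled exponential-mixture squared displacements."""
    D = np.atleast_1d(D)
    fractions = np.atleast_1d(fractions if fractions is not None else [1.0])
    comp = rng.choice(len(D), size=n, p=fractions)
    vals = rng.exponential(scale=4 * D[comp] * tau)
    uniq, counts = np.unique(np.sort(vals), return_counts=True)
    return SQDDistribution(
        lag=1, tau=tau, values=uniq, ecdf=np.cumsum(counts) / n,
        counts=counts, n_total=n,
    )


class TestSquaredDisplacements:
    def test_three_four_five_triangle(self):
        ts = make_trackset({"t0": [(0, 0), (0.3, 0.4)]})
        sqd = squared_displacements(ts, lag=1, min_steps=1)
        assert np.allclose(sqd.values, [0.25])

    def test_track_shorter_than_lag_contributes_nothing(self):
        ts = make_trackset({"short": [(0, 0), (1, 0)], "long": [(0, 0)] * 7})
        sqd = squared_displacements(ts, lag=3, min_steps=1)
        # only the 6-step track can form lag-3 pairs; the 1-step track cannot
        assert sqd.n_total == 4

    def test_lag2_staircase_hand_enumeration(self):
        """All lag-2 pairs of the staircase track have squared displacement 2."""
        coords = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2)]
        sqd = squared_displacements(make_trackset({"t": coords}), lag=2, min_steps=1)
        assert sqd.n_total == 4
        assert np.allclose(sqd.values, [2.0])

    def test_min_steps_filter_excludes_short_tracks(self):
        ts = make_trackset({"a": [(0, 0)] * 5, "b": [(i, 0) for i in range(8)]})
        sqd = squared_displacements(ts, lag=1, min_steps=5)
        assert sqd.n_total == 7  # only the 7-step track contributes

    def test_empty_result_is_flagged(self):
        ts = make_trackset({"a": [(0, 0), (1, 1)]})
        with pytest.raises(EmptyDistributionError):
            squared_displacements(ts, lag=1, min_steps=5)

    def test_ecdf_is_valid_cdf(self):
        ts = simulate_tracks(MTASE_LIKE(seed=11), CellModelParams(), n_tracks=100)
        sqd = squared_displacements(ts)
        assert np.all(np.diff(sqd.values) > 0)
        assert np.all(np.diff(sqd.ecdf) >= 0)
        assert np.isclose(sqd.ecdf[-1], 1.0)
        assert sqd.tau == pytest.approx(0.02)


class TestRayleighMixtureFit:
    def test_single_population_closed_form(self, rng):
        """n=1e5 exponential draws: fitted D within 2% of truth; median of the
        values within 2% of 4*D*tau*ln2."""
        D, tau = 1.0, 0.02
        sqd = iid_exponential_sqd(rng, D, tau, 100_000)
        fit = fit_rayleigh_mixture(sqd, 1)
        assert fit.f[0] == pytest.approx(1.0)
        assert fit.D[0] == pytest.approx(D, rel=0.02)
        median = np.interp(0.5, sqd.ecdf, sqd.values)
        assert median == pytest.approx(4 * D * tau * np.log(2), rel=0.02)

    def test_matches_moment_estimator_within_1pct(self, rng):
        """k=1 least-squares D vs closed-form mean(x)/(4 tau) on clean data."""
        D, tau = 0.3, 0.02
        sqd = iid_exponential_sqd(rng, D, tau, 50_000)
        fit = fit_rayleigh_mixture(sqd, 1)
        moment = float(np.sum(sqd.values * sqd.counts) / sqd.n_total / (4 * tau))
        assert fit.D[0] == pytest.approx(moment, rel=0.01)

    def test_all_zero_displacements_degenerate(self):
        ts = make_trackset({"t": [(1.0, 1.0)] * 8})
        sqd = squared_displacements(ts, min_steps=5)
        with pytest.warns(UserWarning):
            fit = fit_rayleigh_mixture(sqd, 3)
        assert fit.k == 1
        assert fit.D[0] == 0.0
        assert fit.f[0] == 1.0

    def test_fractions_sum_to_one_and_D_ascending(self, rng):
        sqd = iid_exponential_sqd(rng, [0.05, 0.5, 2.0], 0.02, 20_000, [0.3, 0.3, 0.4])
        fit = fit_rayleigh_mixture(sqd, 3)
        assert fit.f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.D) >= 0)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_fitted_cdf_nondecreasing(self, rng):
        sqd = iid_exponential_sqd(rng, [0.05, 1.0], 0.02, 5_000, [0.5, 0.5])
        fit = fit_rayleigh_mixture(sqd, 2)
        grid = np.linspace(0, sqd.values.max(), 500)
        assert np.all(np.diff(fit.fitted_cdf(grid)) >= -1e-12)

    def test_localization_correction_shifts_D(self, rng):
        tau, sigma = 0.02, 0.03
        sqd = iid_exponential_sqd(rng, 0.5 + sigma**2 / tau, tau, 50_000)
        corrected = fit_rayleigh_mixture(sqd, 1, loc_sigma=sigma)
        apparent = fit_rayleigh_mixture(sqd, 1, loc_sigma=0.0)
        assert corrected.D[0] == pytest.approx(apparent.D[0] - sigma**2 / tau)
        assert corrected.D[0] == pytest.approx(0.5, rel=0.03)


class TestModelSelection:
    def test_r_squared_nondecreasing_in_k(self, rng):
        sqd = iid_exponential_sqd(rng, [0.05, 0.5, 2.0], 0.02, 10_000, [0.3, 0.3, 0.4])
        sel = select_model(sqd, k_max=3)
        r2 = [sel.fits[k].r_squared for k in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-9 and r2[1] <= r2[2] + 1e-9

    def test_single_state_data_selects_k1(self):
        p = DiffusionModelParams(k=1, D=(0.5,), f=(1.0,), loc_sigma=0.0, seed=21)
        ts = simulate_tracks(p, cell=None, n_tracks=2_000)
        sel = select_model(squared_displacements(ts))
        assert sel.best_k == 1

    def test_three_state_data_selects_k3(self):
        ts = simulate_tracks(REASE_LIKE(seed=22), CellModelParams(), n_tracks=3_000)
        sel = select_model(squared_displacements(ts), loc_sigma=0.03)
        assert sel.best_k == 3

    def test_empty_distribution_errors(self):
        ts = make_trackset({"a": [(0, 0), (1, 1)]})
        with pytest.raises(EmptyDistributionError):
            sel = select_model(squared_displacements(ts, min_steps=5))


class TestParameterRecovery:
    """Preset recovery across seeded replicates (median errors)."""

    @pytest.mark.parametrize(
        "preset, nucleoid, truth_f",
        [
            (MTASE_LIKE, True, np.array([0.26, 0.42, 0.32])),
            (REASE_LIKE, False, np.array([0.17, 0.26, 0.56]) / 0.99),
        ],
        ids=["mtase", "rease"],
    )
    def test_fraction_recovery_median_within_5_points(self, preset, nucleoid, truth_f):
        cell = CellModelParams(confine_slow_states_to_nucleoid=nucleoid)
        errs = []
        for seed in range(20):
            ts = simulate_tracks(preset(seed=seed), cell, n_tracks=1_500)
            fit = fit_rayleigh_mixture(
                squared_displacements(ts), 3, loc_sigma=0.03
            )
            errs.append(fit.f - truth_f)
        median_err = np.median(np.abs(errs), axis=0)
        assert np.all(median_err < 0.05), f"median |error| per component: {median_err}"

    def test_diffusion_constant_recovery(self):
        """Median fitted D within 25% of preset truth, after noise correction.

        The slowest component sits near the localization-noise floor
        sigma^2/tau = 0.045 um^2/s, so its corrected estimate additionally
        tolerates an absolute error of a tenth of the floor.
        """
        truth_D = np.array([0.01, 0.35, 1.2])
        ests = []
        for seed in range(10):
            ts = simulate_tracks(
                MTASE_LIKE(seed=seed), CellModelParams(), n_tracks=1_500
            )
            fit = fit_rayleigh_mixture(squared_displacements(ts), 3, loc_sigma=0.03)
            ests.append(fit.D)
        med = np.median(ests, axis=0)
        floor = 0.03**2 / 0.02
        tol = np.maximum(0.25 * truth_D, 0.1 * floor)
        assert np.all(np.abs(med - truth_D) < tol), f"median D: {med}"
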