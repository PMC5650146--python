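import numpy as np
import pytest

from coastcr import synthetic_data as syn
from coastcr.habitat import INSHORE, ISLAND, StratumAreas
from coastcr.photoid import build_capture_histories, marked_proportion_from_counts
from coastcr.secr_robust import (
    ModelConfig,
    annualize_survival,
    credible_interval,
    extrapolate_abundance,
    fit_model,
    split_rhat,
    summarize_density,
)


class TestCredibleInterval:
    def test_order_statistic_contract(self):
        lo, hi = credible_interval(np.arange(1, 1001))
        assert (lo, hi) == (26.0, 975.0)

    def test_constant_draws(self):
        lo, hi = credible_interval(np.full(100, 3.7))
        assert lo == hi == 3.7

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = credible_interval(rng.uniform(0, 1, 100_000))
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="too few draws"):
            credible_interval(np.arange(10))


class TestAnnualizeSurvival:
    def test_half_year_squares(self):
        out = annualize_survival(
            np.full((50, 1), 0.9), [182.625], {0: "yr1"}
        )
        assert out.iloc[0]["survival"] == pytest.approx(0.81)

    def test_full_year_identity(self):
        out = annualize_survival(np.full((50, 1), 0.73), [365.25], {0: "yr1"})
        assert out.iloc[0]["survival"] == pytest.approx(0.73)

    def test_mean_of_printed_annualized_points(self):
        # the four printed year-1 annualized interval estimates average
        # to 0.710; the posterior-based yearly summary in the original
        # analysis is 0.73, so agreement is deliberately not forced
        vals = np.array([[0.723, 0.812, 0.561, 0.745]])
        out = annualize_survival(
            np.repeat(vals, 50, axis=0), [365.25] * 4, {j: "yr1" for j in range(4)}
        )
        assert out.iloc[0]["survival"] == pytest.approx(0.710, abs=5e-4)

    def test_bad_delta_errors(self):
        with pytest.raises(ValueError, match="delta_days"):
            annualize_survival(np.full((50, 1), 0.9), [0.0], {0: "y"})

    def test_unassigned_interval_errors(self):
        with pytest.raises(ValueError, match="assigned"):
            annualize_survival(np.full((50, 2), 0.9), [100.0, 100.0], {0: "y"})

    def test_monotone_in_phi(self):
        grid = np.linspace(0.05, 0.95, 10)[:, None]
        out = grid ** (365.25 / 123.0)
        assert (np.diff(out.ravel()) > 0).all()


class TestExtrapolateAbundance:
    def test_printed_period1_reconstruction(self):
        areas = StratumAreas()
        ex = extrapolate_abundance({ISLAND: 4.78, INSHORE: 1.05}, areas)
        assert ex["total"] == pytest.approx(3462.56, abs=0.01)
        assert round(float(ex["overall_density"]), 2) == 1.42

    def test_zero_density(self):
        ex = extrapolate_abundance({ISLAND: 0.0, INSHORE: 0.0}, StratumAreas())
        assert ex["total"] == 0.0

    def test_printed_mean_densities(self):
        ex = extrapolate_abundance({ISLAND: 4.43, INSHORE: 1.09}, StratumAreas())
        assert ex[ISLAND] == pytest.approx(1072.06, abs=0.01)
        assert ex[INSHORE] == pytest.approx(2393.64, abs=0.01)

    def test_per_draw_identity(self):
        rng = np.random.default_rng(1)
        d_isl = rng.gamma(4.0, 1.0, 500)
        d_ins = rng.gamma(1.0, 1.0, 500)
        areas = StratumAreas()
        ex = extrapolate_abundance({ISLAND: d_isl, INSHORE: d_ins}, areas)
        assert np.array_equal(ex[ISLAND], d_isl * 242.0)
        assert np.array_equal(ex["total"], ex[ISLAND] + ex[INSHORE])
        assert np.allclose(ex["overall_density"], ex["total"] / 2438.0)

    def test_missing_area_errors(self):
        with pytest.raises(ValueError, match="no configured area"):
            extrapolate_abundance({"Offshore": 1.0}, StratumAreas())


def _tiny_fit(two_stratum_mask, n_primaries=3, seed=3, **cfg_kwargs):
    dates = syn.DEFAULT_PRIMARY_DATES[:n_primaries]
    truth = syn.make_world(
        {
            "density_by_stratum": {INSHORE: 1.0, ISLAND: 4.0},
            "p0": 0.5,
            "sigma_det": 1.0,
            "sigma_move": 0.5,
            "marked_prop": 1.0,
            "primary_dates": dates,
            "phi_by_interval": (0.8,) * (n_primaries - 1),
        },
        seed=seed,
        mask=two_stratum_mask,
    )
    pop = syn.simulate_population(truth)
    transects = [((0.0, y), (16.0, y)) for y in np.arange(0.5, 8.0, 2.0)]
    sight = syn.simulate_captures(truth, pop, transects)
    hist = build_capture_histories(sight, truth.n_primaries, truth.secondaries_per_primary)
    cfg = ModelConfig(
        M=3 * hist.n_individuals,
        transects=transects,
        n_chains=2,
        n_iter=300,
        n_burn=100,
        seed=99,
        sigma_move=0.5,
        sigma_init=1.0,
        **cfg_kwargs,
    )
    return truth, pop, hist, cfg


class TestFitModel:
    def test_empty_histories_error(self, two_stratum_mask):
        from coastcr.photoid import CaptureHistorySet

        empty = CaptureHistorySet([], np.zeros((0, 2, 3)), np.zeros((0, 2, 2)))
        cfg = ModelConfig(M=10, effort_dist=np.zeros(two_stratum_mask.n_cells))
        with pytest.raises(ValueError, match="empty capture histories"):
            fit_model(empty, two_stratum_mask, cfg)

    def test_m_must_exceed_observed(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        cfg.M = hist.n_individuals
        with pytest.raises(ValueError, match="must exceed"):
            fit_model(hist, two_stratum_mask, cfg)

    def test_draw_count_contract(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        draws = fit_model(hist, two_stratum_mask, cfg)
        assert draws.n_draws == cfg.n_chains * (cfg.n_iter - cfg.n_burn) // cfg.thin
        assert draws.density.shape == (draws.n_draws, 3, 2)
        assert (draws.density >= 0).all()
        assert ((draws.phi >= 0) & (draws.phi <= 1)).all()

    def test_reproducible_given_seed(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        d1 = fit_model(hist, two_stratum_mask, cfg)
        d2 = fit_model(hist, two_stratum_mask, cfg)
        assert np.array_equal(d1.density, d2.density)
        assert np.array_equal(d1.phi, d2.phi)

    def test_complete_detection_limit(self, all_water_mask):
        # p0 = 1 with effort everywhere and a single closed primary:
        # the posterior concentrates on the observed count
        truth = syn.make_world(
            {
                "density_by_stratum": {INSHORE: 1.0},
                "p0": 0.999,
                "sigma_det": 1.0,
                "marked_prop": 1.0,
                "primary_dates": syn.DEFAULT_PRIMARY_DATES[:1],
                "phi_by_interval": (),
            },
            seed=5,
            mask=all_water_mask,
        )
        pop = syn.simulate_population(truth)
        sight = syn.simulate_captures(
            truth, pop, [((0.0, y), (10.0, y)) for y in np.arange(0.5, 10.0)]
        )
        hist = build_capture_histories(sight, 1, 3)
        cfg = ModelConfig(
            M=2 * hist.n_individuals + 20,
            effort_dist=np.zeros(all_water_mask.n_cells),
            n_chains=2,
            n_iter=200,
            n_burn=50,
            seed=1,
            fix_p0=1.0,
            fix_sigma=1.0,
            report_strata=(INSHORE,),
        )
        draws = fit_model(hist, all_water_mask, cfg)
        assert np.all(draws.abundance_mask == hist.n_individuals)

    def test_snaps_off_mask_locations(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        hist.mean_locations[0, :, :] = [-5.0, -5.0]  # off the mask
        with pytest.warns(UserWarning, match="snapped"):
            fit_model(hist, two_stratum_mask, cfg)


class TestClosedM0Limit:
    def test_against_brute_force_m0_likelihood(self, all_water_mask):
        # uniform intensity, effort everywhere (distance 0 -> detection
        # p0 for every animal), one primary: the spatial model reduces
        # to closed-population M0.  Compare the posterior mean abundance
        # with the brute-force M0 maximum likelihood estimate.
        truth = syn.make_world(
            {
                "density_by_stratum": {INSHORE: 1.5},
                "p0": 0.45,
                "sigma_det": 1.0,
                "marked_prop": 1.0,
                "primary_dates": syn.DEFAULT_PRIMARY_DATES[:1],
                "phi_by_interval": (),
            },
            seed=11,
            mask=all_water_mask,
        )
        pop = syn.simulate_population(truth)
        sight = syn.simulate_captures(
            truth, pop, [((0.0, y), (10.0, y)) for y in np.arange(0.5, 10.0)]
        )
        hist = build_capture_histories(sight, 1, 3)
        n_obs = hist.n_individuals
        K = 3
        total_dets = int(hist.matrix.sum())

        from scipy.special import gammaln

        def neg_ll(N):
            # profile M0 likelihood: p profiled out analytically
            p_hat = total_dets / (N * K)
            ll = (
                gammaln(N + 1)
                - gammaln(N - n_obs + 1)
                + total_dets * np.log(p_hat)
                + (N * K - total_dets) * np.log1p(-p_hat)
            )
            return -ll

        candidates = np.arange(n_obs, 3 * n_obs)
        lls = np.array([neg_ll(N) for N in candidates])
        n_mle = candidates[np.argmin(lls)]

        cfg = ModelConfig(
            M=4 * n_obs,
            effort_dist=np.zeros(all_water_mask.n_cells),
            n_chains=2,
            n_iter=600,
            n_burn=200,
            seed=2,
            fix_sigma=1.0,
            report_strata=(INSHORE,),
        )
        draws = fit_model(hist, all_water_mask, cfg)
        post_mean = draws.abundance_mask.mean()
        post_sd = draws.abundance_mask.std()
        assert abs(post_mean - n_mle) < max(3 * post_sd, 0.1 * n_mle)


class TestSummaries:
    def test_summarize_density_inflation(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        draws = fit_model(hist, two_stratum_mask, cfg)
        props = [marked_proportion_from_counts(80, 100, t) for t in range(3)]
        block = summarize_density(draws, props)
        assert set(block["inflation"]) == {1.25}
        marked = block["density_marked"].to_numpy()
        total = block["density"].to_numpy()
        assert np.allclose(total, marked / 0.8)
        assert (block["lo95"] <= block["density"]).all()
        assert (block["density"] <= block["hi95"]).all()

    def test_constant_draw_degenerate_ci(self):
        from coastcr.secr_robust import PosteriorDraws

        nd = 100
        draws = PosteriorDraws(
            density=np.full((nd, 1, 2), 0.8),
            abundance_mask=np.full((nd, 1), 10.0),
            p0=np.full(nd, 0.3),
            sigma=np.full(nd, 1.0),
            beta_island=np.zeros(nd),
            phi=np.zeros((nd, 0)),
            strata=(ISLAND, INSHORE),
        )
        props = [marked_proportion_from_counts(80, 100, 0)]
        block = summarize_density(draws, props)
        assert block.iloc[0]["density"] == pytest.approx(1.0)
        assert block.iloc[0]["lo95"] == block.iloc[0]["hi95"] == pytest.approx(1.0)

    def test_proportion_count_mismatch_errors(self, two_stratum_mask):
        truth, pop, hist, cfg = _tiny_fit(two_stratum_mask)
        draws = fit_model(hist, two_stratum_mask, cfg)
        with pytest.raises(ValueError, match="one marked proportion"):
            summarize_density(draws, [marked_proportion_from_counts(1, 2)])


class TestSplitRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 500))
        assert split_rhat(chains) < 1.05

    def test_shifted_chains_large(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 400))
        chains[1] += 5.0
        assert split_rhat(chains) > 2.0
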