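"""Rejection-ABC machinery: priors, summaries, distance, posterior behaviour.

Cheap analytic forward models stand in for the cage simulator where the
property under test concerns the ABC machinery itself; the full simulator is
exercised through the reduced-scale protocol.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagedrive import (
    DriveParams,
    LifeHistoryParams,
    run_cage,
    suppression_day,
)
from cagedrive.cage_sim import reduced_protocol
from cagedrive.inference import (
    PosteriorSample,
    PriorSpec,
    abc_reject,
    default_priors,
    distance,
    make_simulator,
    posterior_predictive,
    posterior_summary,
    printed_posterior,
    sample_prior,
    summarize,
)


class TestSamplePrior:
    def test_reproducible_and_in_bounds(self):
        priors = default_priors()
        a = sample_prior(priors, 5, seed=1)
        b = sample_prior(priors, 5, seed=1)
        assert a.equals(b)
        for name, (lo, hi) in priors.bounds.items():
            assert a[name].between(lo, hi).all()

    def test_degenerate_prior_is_a_point(self):
        priors = PriorSpec({"rho": (0.3, 0.3)})
        draws = sample_prior(priors, 10, seed=2)
        assert (draws["rho"] == 0.3).all()

    def test_full_scale_shape(self):
        draws = sample_prior(default_priors(), 50_000, seed=3)
        assert draws.shape == (50_000, 5)

    def test_unknown_parameter_needs_opt_in(self):
        with pytest.raises(ValueError):
            PriorSpec({"h": (0.9, 1.0)})
        PriorSpec({"h": (0.9, 1.0)}, allow_extra=True)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec({"rho": (0.5, 0.1)})


class TestSummarize:
    def _cage(self, seed, rep=0):
        life, drive = LifeHistoryParams(), DriveParams()
        return run_cage(life, drive, reduced_protocol("medium"), seed=seed,
                        arm="medium", replicate=rep)

    def test_identical_cages_give_identical_blocks(self):
        a = self._cage(5, rep=0)
        b = self._cage(5, rep=1)
        v = summarize([a, b])
        half = len(v) // 2
        assert np.allclose(v[:half], v[half:])

    def test_order_invariant_after_canonical_sort(self):
        a, b = self._cage(5, rep=0), self._cage(6, rep=1)
        assert np.allclose(summarize([a, b]), summarize([b, a]))

    def test_suppression_component_delegates(self):
        s = self._cage(7)
        v = summarize([s])
        sup = suppression_day(s)
        expected = sup if sup is not None else s.records["day"].max()
        assert v[-1] == expected

    def test_constant_control_eggs(self):
        # constant egg output E: variance component 0, mean component log(E+1)
        days = [0, 3, 7, 10, 14, 17, 21, 24]
        df = pd.DataFrame({
            "day": days, "eggs_total": [500] * 8,
            "larvae_screened": [100] * 8, "rfp_positive": [0] * 8,
            "pupae_restocked": [100] * 8,
            "morph_female_fraction": [0.5] * 8,
        })
        from cagedrive.cage_sim import ObservedCageSeries
        s = ObservedCageSeries(df, arm="control")
        v = summarize([s], n_freq_points=4)
        assert v[4] == pytest.approx(np.log(501))  # mean log eggs
        assert v[5] == pytest.approx(0.0)          # variance
        assert v[6] == 24                          # censored suppression day

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestDistance:
    def test_zero_iff_equal(self):
        a = np.array([1.0, 2.0, 3.0])
        assert distance(a, a.copy(), np.ones(3)) == 0.0

    def test_one_scale_unit(self):
        a = np.zeros(4)
        b = np.array([0.0, 2.0, 0.0, 0.0])
        assert distance(a, b, np.full(4, 2.0)) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            distance(np.zeros(3), np.zeros(4), np.ones(4))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3).map(np.array),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3).map(np.array),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3).map(np.array))
    def test_triangle_inequality(self, a, b, c):
        scale = np.array([1.0, 2.0, 0.5])
        assert distance(a, c, scale) <= (distance(a, b, scale)
                                         + distance(b, c, scale) + 1e-9)


def _product_model(theta, seed):
    # informative about f_pat * f_mat only
    return np.array([theta["f_pat"] * theta["f_mat"]])


def _location_model(sigma):
    def model(theta, seed):
        rng = np.random.default_rng(seed)
        return np.array([theta["f_pat"] + sigma * rng.standard_normal()])
    return model


class TestAbcReject:
    def test_keep_all_returns_prior(self):
        draws = sample_prior(default_priors(), 40, seed=1)
        post = abc_reject(draws, _product_model, np.array([0.2]), keep=40, seed=2)
        got = post.params.sort_values("f_pat").reset_index(drop=True)
        want = draws.sort_values("f_pat").reset_index(drop=True)
        assert got.equals(want)  # the prior sample back, re-ordered by fit
        assert post.n_keep == post.n_total == 40

    def test_generating_draw_retained_at_distance_zero(self):
        draws = sample_prior(default_priors(), 50, seed=3)
        observed = _product_model(draws.iloc[17].to_dict(), None)
        post = abc_reject(draws, _product_model, observed, keep=1, seed=4)
        assert post.distances[0] == 0.0
        assert post.params.iloc[0]["f_pat"] == draws.iloc[17]["f_pat"]

    def test_retained_distances_bounded_by_rejected(self):
        draws = sample_prior(default_priors(), 60, seed=5)
        post = abc_reject(draws, _product_model, np.array([0.3]), keep=10, seed=6)
        assert (np.diff(post.distances) >= 0).all()

    def test_simulation_failure_excluded(self):
        def flaky(theta, seed):
            if theta["f_pat"] > 0.9:
                raise RuntimeError("boom")
            return np.array([theta["f_pat"]])
        draws = sample_prior(default_priors(), 50, seed=7)
        post = abc_reject(draws, flaky, np.array([0.5]), keep=5, seed=8)
        assert post.failures == (draws["f_pat"] > 0.9).sum()
        assert (post.params["f_pat"] <= 0.9).all()

    def test_posterior_concentrates_as_noise_shrinks(self):
        # 3-point ladder: interval width for f_pat shrinks monotonically
        widths = []
        for sigma, n in ((0.3, 300), (0.1, 1000), (0.02, 3000)):
            draws = sample_prior(default_priors(), n, seed=9)
            post = abc_reject(draws, _location_model(sigma), np.array([0.35]),
                              keep=30, seed=10, scale=np.array([1.0]))
            lo, hi = posterior_summary(post)["ci95"]["f_pat"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_product_data_induce_negative_covariance(self):
        draws = sample_prior(default_priors(), 3000, seed=11)
        post = abc_reject(draws, _product_model, np.array([0.25]), keep=100,
                          seed=12, scale=np.array([1.0]))
        cov = posterior_summary(post)["cov"]
        assert cov["f_pat"]["f_mat"] < 0


class TestPosteriorSummary:
    def test_single_draw_degenerate(self):
        p = PosteriorSample(pd.DataFrame({"f_pat": [0.4]}), np.array([0.0]),
                            n_total=10, n_keep=1)
        s = posterior_summary(p)
        assert s["mean"]["f_pat"] == 0.4
        assert s["ci95"]["f_pat"] == [0.4, 0.4]

    def test_mean_of_three(self):
        p = PosteriorSample(pd.DataFrame({"f_pat": [0.2, 0.3, 0.4]}),
                            np.zeros(3), n_total=9, n_keep=3)
        assert posterior_summary(p)["mean"]["f_pat"] == pytest.approx(0.3)

    def test_invalid_keep_counts(self):
        with pytest.raises(ValueError):
            PosteriorSample(pd.DataFrame({"a": [1]}), np.zeros(1),
                            n_total=0, n_keep=1)


class TestPosteriorPredictive:
    def test_no_cost_posterior_always_suppresses(self):
        # concentrated on a cost-free, near-complete-homing drive
        p = PosteriorSample(
            pd.DataFrame({"f_pat": [1.0], "f_mat": [1.0], "rho": [0.1],
                          "lambda_eggs": [116.0], "p_lay": [0.14]}),
            np.zeros(1), n_total=1, n_keep=1)
        drive = DriveParams(h=0.99)
        out = posterior_predictive(p, reduced_protocol("medium", 300),
                                   n_runs=25, seed=13, drive=drive)
        assert not out["censored"].any()
        assert out["quantiles"][100] <= 300

    def test_sterile_het_females_cannot_drive(self):
        # f_pat = f_mat = 0: daughters of carrier parents are sterile, so no
        # drive homozygous females form through het mothers and the population
        # is not suppressed within the horizon
        p = PosteriorSample(
            pd.DataFrame({"f_pat": [0.0], "f_mat": [0.0], "rho": [0.5],
                          "lambda_eggs": [116.0], "p_lay": [0.14]}),
            np.zeros(1), n_total=1, n_keep=1)
        out = posterior_predictive(p, reduced_protocol("medium", 200),
                                   n_runs=10, seed=14)
        assert out["censored"].mean() > 0.7

    def test_control_protocol_rejected(self):
        p = PosteriorSample(pd.DataFrame({"f_pat": [0.5]}), np.zeros(1), 1, 1)
        with pytest.raises(ValueError):
            posterior_predictive(p, reduced_protocol("control"), 5, seed=1)


class TestPrintedPosterior:
    def test_marginal_summaries_match_printed_values(self):
        pp = printed_posterior()
        m = pp["marginals"]
        assert m["f_pat"].mean() == pytest.approx(0.35, abs=0.01)
        lo, hi = m["f_pat"].ppf([0.025, 0.975])
        assert lo == pytest.approx(0.17, abs=0.05)
        assert hi == pytest.approx(0.57, abs=0.05)
        assert m["lambda_eggs"].mean() == pytest.approx(116, rel=0.02)
        assert pp["means"]["p_lay"] == 0.14


def test_reduced_scale_simulator_handle_runs():
    life, drive = LifeHistoryParams(), DriveParams()
    sim = make_simulator(reduced_protocol("medium"), life, drive,
                         n_replicates=1, arm="medium")
    v1 = sim({"f_pat": 0.35}, seed=100)
    v2 = sim({"f_pat": 0.35}, seed=100)
    assert np.allclose(v1, v2)
    assert v1.ndim == 1 and len(v1) == 11
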