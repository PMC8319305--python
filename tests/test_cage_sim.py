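"""Simulator mechanics: mortality, laying, re-stocking, protocol bookkeeping."""

import numpy as np
import pytest

from cagedrive import (
    CageProtocol,
    CageState,
    DriveParams,
    Genotype,
    LifeHistoryParams,
    equilibrium_adult_population,
    lay_eggs,
    release_pupae_fraction,
    restock,
    run_cage,
    step_day,
    study_protocol,
    suppression_day,
)
from cagedrive.cage_sim import (
    ObservedCageSeries,
    gompertz_survivorship,
    reduced_protocol,
    suppression_day_post_release,
)

import pandas as pd

WW = Genotype.from_string("WW")


def make_series(days, eggs, release_day=None):
    df = pd.DataFrame({
        "day": days, "eggs_total": eggs,
        "larvae_screened": [0] * len(days), "rfp_positive": [0] * len(days),
        "pupae_restocked": [0] * len(days),
        "morph_female_fraction": [np.nan] * len(days),
    })
    return ObservedCageSeries(df, arm="test", release_day=release_day)


class TestStepDay:
    def test_empty_cage_is_absorbing(self, default_life, default_drive, rng):
        protocol = CageProtocol()
        state = CageState(n_ages=default_life.max_adult_age())
        state.day = 200  # past all introductions
        step_day(state, default_life, default_drive, protocol, rng)
        assert state.total_adults() == 0 and state.day == 201

    def test_one_day_survival_matches_binomial_moments(self, default_drive, rng):
        # geometric mode: constant daily survival, here the median-6 calibration
        life = LifeHistoryParams(survival_model="geometric",
                                 s_adult_start=0.8909, s_adult_end=0.8909)
        protocol = CageProtocol()
        n_rep, n_adults, survivors = 400, 100, []
        for _ in range(n_rep):
            state = CageState(n_ages=life.max_adult_age())
            state.day = 30
            state.males[5, 0] = n_adults
            step_day(state, life, default_drive, protocol, rng)
            survivors.append(state.total_adults())
        mean = np.mean(survivors)
        expected = n_adults * 0.8909
        se = np.sqrt(n_adults * 0.8909 * (1 - 0.8909) / n_rep)
        assert abs(mean - expected) < 4 * se

    def test_conservation_audit_over_full_run(self, default_life, default_drive):
        # audit raises if any adult appears or vanishes outside the books
        run_cage(default_life, default_drive, study_protocol("control", monitoring_end_day=120),
                 seed=5, audit=True)


class TestLayEggs:
    def test_no_females_no_eggs(self, default_life, default_drive, rng):
        assert lay_eggs([], default_life, default_drive, rng).sum() == 0

    def test_compound_poisson_mean(self, default_drive, rng):
        # n p lambda = 1000 * 0.14 * 116 = 16,240 expected eggs per opportunity
        life = LifeHistoryParams(p_lay=0.14, lambda_eggs=116)
        females = [(WW, WW)] * 1000
        n_rep = 40
        totals = [lay_eggs(females, life, default_drive, rng).sum()
                  for _ in range(n_rep)]
        mu = 1000 * 0.14 * 116
        var = 1000 * 0.14 * 116 * (1 + 116 * (1 - 0.14))
        se = np.sqrt(var / n_rep)
        assert abs(np.mean(totals) - mu) < 3 * se

    def test_paternal_cost_scales_expected_output(self, rng):
        # per-opportunity expectation 0.35 * 0.14 * 116 = 5.684 eggs
        life = LifeHistoryParams(p_lay=0.14, lambda_eggs=116)
        drive = DriveParams(f_pat=0.35)
        mother = Genotype.from_string("WW", father_carrier=True)
        n = 4000
        total = lay_eggs([(mother, WW)] * n, life, drive, rng).sum()
        mu = n * 0.35 * 0.14 * 116
        var = n * 0.35 * 0.14 * 116 * (1 + 116 * (1 - 0.35 * 0.14))
        assert abs(total - mu) < 3 * np.sqrt(var)

    def test_intersex_female_rejected(self, default_life, default_drive, rng):
        dd = Genotype.from_string("DD")
        with pytest.raises(ValueError):
            lay_eggs([(dd, WW)], default_life, default_drive, rng)


class TestRestock:
    def test_under_cap_all_retained(self, rng):
        larvae = np.zeros((6, 2, 2), dtype=np.int64)
        larvae[0, 0, 0] = 300
        out = restock(larvae, CageProtocol(restock_cap=400), rng)
        assert out.sum() == 300

    def test_hypergeometric_moments(self, rng):
        larvae = np.zeros((6, 2, 2), dtype=np.int64)
        larvae[1, 0, 1] = 600  # carriers
        larvae[0, 0, 0] = 400
        protocol = CageProtocol(restock_cap=400)
        n_rep = 300
        carriers = [restock(larvae, protocol, rng)[1, 0, 1] for _ in range(n_rep)]
        # hypergeometric mean 240, variance n*p*(1-p)*(N-n)/(N-1)
        var = 400 * 0.6 * 0.4 * (1000 - 400) / 999
        se = np.sqrt(var / n_rep)
        assert abs(np.mean(carriers) - 240) < 4 * se

    def test_zero_larvae_suppression_pathway(self, rng):
        out = restock(np.zeros((6, 2, 2), dtype=np.int64), CageProtocol(), rng)
        assert out.sum() == 0


class TestRunCage:
    def test_seed_determinism_byte_identical(self, default_life, default_drive):
        protocol = study_protocol("low", monitoring_end_day=150)
        a = run_cage(default_life, default_drive, protocol, seed=42)
        b = run_cage(default_life, default_drive, protocol, seed=42)
        assert a.records.equals(b.records)
        assert a.records.to_csv() == b.records.to_csv()

    def test_control_never_produces_drive_or_resistance(self, default_life,
                                                        default_drive):
        # no spontaneous mutation: control cages must stay pure wild-type
        s = run_cage(default_life, default_drive,
                     study_protocol("control", monitoring_end_day=150),
                     seed=7, genotype_records=True)
        assert (s.records["rfp_positive"] == 0).all()
        for lab in ("WD", "DD", "DR", "WR", "RR"):
            assert (s.records[f"n_{lab}"] == 0).all()

    def test_control_egg_output_stable_and_positive(self, default_life,
                                                    default_drive):
        s = run_cage(default_life, default_drive, study_protocol("control"),
                     seed=11)
        eggs = s.records["eggs_total"]
        assert (eggs.tail(20) > 0).all()

    def test_control_equilibrium_eggs_match_closed_form(self, default_drive):
        # mean eggs/collection ~ n_mated_females * p_lay * lambda at equilibrium
        life = LifeHistoryParams()
        s = run_cage(life, default_drive, study_protocol("control"), seed=13)
        observed = s.records["eggs_total"].iloc[30:60].mean()
        # standing adults from the survivorship area at the mid-experiment median
        area = gompertz_survivorship(8.5, life.senescence_shape, 60).sum()
        adults = 800 / 7 * area
        expected = (adults / 2) * life.p_lay * life.lambda_eggs
        assert 0.6 * expected < observed < 1.5 * expected

    def test_release_bookkeeping(self):
        protocol = study_protocol("medium")
        assert sum(c for _, c, _, _ in protocol.release_events) == 285
        assert [c for _, c, _, _ in protocol.release_events] == [142, 143]
        days = [d for d, *_ in protocol.release_events]
        assert all(protocol.is_collection_day(d) for d in days)
        assert days[0] >= protocol.prerelease_end_day

    def test_release_arm_invades_and_suppresses(self, default_life, default_drive):
        # posterior-mean parameters: carrier frequency rises sigmoidally and
        # egg output collapses to permanent zero
        protocol = study_protocol("medium", monitoring_end_day=700)
        s = run_cage(default_life, default_drive, protocol, seed=3)
        sup = suppression_day_post_release(s)
        assert sup is not None and 100 < sup < 650
        df = s.records
        mid = df[(df.day > s.release_day) & (df.larvae_screened > 0)]
        freq = mid.rfp_positive / mid.larvae_screened
        # early fraction low, late fraction near fixation
        assert freq.iloc[:5].mean() < 0.35 < 0.9 <= freq.iloc[-5:].mean() + 0.1

    def test_ratchet_no_cost_drive_frequency_nondecreasing(self, rng):
        # with no fitness costs the drive's Monte-Carlo mean trajectory only rises
        life = LifeHistoryParams()
        drive = DriveParams(h=0.95, f_pat=1.0, f_mat=1.0)
        protocol = reduced_protocol("medium", monitoring_end_day=120)
        mats = []
        for rep in range(100):
            s = run_cage(life, drive, protocol, seed=900 + rep)
            df = s.records
            with np.errstate(invalid="ignore"):
                f = (df.rfp_positive / df.larvae_screened.replace(0, np.nan))
            mats.append(f.to_numpy())
        arr = np.array(mats)
        # two-week block means smooth out the release-pulse oscillation that the
        # twice-weekly screening process genuinely shows
        n_blocks = arr.shape[1] // 4
        blocks = np.nanmean(arr[:, : 4 * n_blocks].reshape(len(mats), n_blocks, 4),
                            axis=2)
        mean = np.nanmean(blocks, axis=0)
        se = np.nanstd(blocks, axis=0) / np.sqrt(len(mats))
        keep = mean > 0
        m, s_ = mean[keep], se[keep]
        assert (np.diff(m) > -3 * (s_[1:] + s_[:-1])).all()
        assert m[-1] > m[0]

    def test_inconsistent_config_rejected(self, default_life, default_drive):
        with pytest.raises(ValueError):
            run_cage(default_life, default_drive,
                     study_protocol("low", monitoring_end_day=400),
                     seed=1, horizon=50)


class TestSuppressionDay:
    def test_trailing_zeros(self):
        s = make_series([3, 7, 10, 14, 17], [100, 50, 0, 0, 0])
        assert suppression_day(s) == 10

    def test_all_positive_is_none(self):
        s = make_series([3, 7, 10], [10, 20, 30])
        assert suppression_day(s) is None

    def test_rebound_cancels_earlier_zeros(self):
        s = make_series([3, 7, 10, 14, 17], [100, 0, 40, 0, 0])
        assert suppression_day(s) == 14

    def test_post_release_offset(self):
        s = make_series([3, 7, 10, 14, 17], [100, 50, 0, 0, 0], release_day=7)
        assert suppression_day_post_release(s) == 3


class TestEquilibriumAdults:
    def test_zero_introductions(self):
        assert equilibrium_adult_population([1.0, 0.5], 0) == 0

    def test_uniform_death_curve(self):
        # S(d) = 1 - d/10 over d=1..9 sums to 4.5; 800/week -> 514.3
        S = [1 - d / 10 for d in range(1, 10)]
        assert equilibrium_adult_population(S, 800) == pytest.approx(514.285, abs=0.01)

    def test_geometric_curve(self):
        s = 0.8909
        S = s ** np.arange(1, 400)
        assert equilibrium_adult_population(S, 800) == pytest.approx(932.9, abs=1.0)

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_adult_population([0.5, 0.9], 800)


class TestProtocol:
    def test_release_week_pupae_fractions(self):
        # printed percentages: 15.2% low and 26.3% medium of that week's pupae
        assert round(100 * release_pupae_fraction(study_protocol("low")), 1) == 15.2
        assert round(100 * release_pupae_fraction(study_protocol("medium")), 1) == 26.3

    def test_release_day_off_grid_rejected(self):
        with pytest.raises(ValueError):
            CageProtocol(release_events=((75, 10, "WD", "male"),))

    def test_control_has_no_release_day(self):
        assert study_protocol("control").release_day is None
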