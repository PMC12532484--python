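"""Schedule constraints and the generative rating model."""

import numpy as np
import pandas as pd
import pytest

from extbeta.core_model import TRIAL_TABLE_COLUMNS
from extbeta.synthetic_data import (
    GeneratingParams,
    ParadigmConfig,
    generate_acquisition_schedule,
    generate_extinction_schedule,
    generate_preacquisition_schedule,
    simulate_study,
    simulate_vas_ratings,
)


def _max_run(schedule):
    best = run = 0
    prev = None
    for s in schedule:
        run = run + 1 if s["cs_type"] == prev else 1
        prev = s["cs_type"]
        best = max(best, run)
    return best


class TestAcquisitionSchedule:
    def test_counts_and_first_trial(self):
        sched = generate_acquisition_schedule(seed=0)
        assert len(sched) == 20
        plus = [s for s in sched if s["cs_type"] == "cs_plus"]
        minus = [s for s in sched if s["cs_type"] == "cs_minus"]
        assert len(plus) == 10 and len(minus) == 10
        assert sum(s["reinforced"] for s in plus) == 6
        assert sched[0]["cs_type"] == "cs_plus" and sched[0]["reinforced"]

    def test_distinct_spider_paths(self):
        sched = generate_acquisition_schedule(seed=3)
        paths = [s["spider_path"] for s in sched if s["reinforced"]]
        assert len(paths) == 6
        assert len(set(paths)) == 6
        assert all(1 <= p <= 6 for p in paths)

    def test_run_length_constraint_across_many_seeds(self):
        # the no-more-than-two-in-a-row rule must hold for every seed
        for seed in range(500):
            assert _max_run(generate_acquisition_schedule(seed=seed)) <= 2

    def test_deterministic_in_seed(self):
        assert generate_acquisition_schedule(seed=11) == generate_acquisition_schedule(seed=11)

    def test_unsatisfiable_config_rejected(self):
        with pytest.raises(ValueError):
            ParadigmConfig(n_reinforced=7)  # only 6 distinct paths


class TestExtinctionSchedule:
    def test_counts_and_reacquisition(self):
        sched = generate_extinction_schedule(seed=0)
        reacq = [s for s in sched if s["phase"] == "reacquisition"]
        ext = [s for s in sched if s["phase"] == "extinction"]
        assert len(reacq) == 1
        assert reacq[0]["reinforced"] and reacq[0]["spider_path"] == 5
        assert len(ext) == 40
        assert not any(s["reinforced"] for s in ext)
        assert sum(s["cs_type"] == "cs_plus" for s in ext) == 20

    def test_run_constraint_and_determinism(self):
        for seed in range(200):
            sched = generate_extinction_schedule(seed=seed)
            ext = [s for s in sched if s["phase"] == "extinction"]
            assert _max_run(ext) <= 2
        assert generate_extinction_schedule(seed=5) == generate_extinction_schedule(seed=5)


class TestPreAcquisition:
    def test_two_per_cs_unreinforced(self):
        sched = generate_preacquisition_schedule(seed=0)
        assert len(sched) == 4
        assert sum(s["cs_type"] == "cs_plus" for s in sched) == 2
        assert not any(s["reinforced"] for s in sched)


class TestSimulateStudy:
    def test_full_paradigm_shape(self):
        tab = simulate_study(3, seed=0)
        assert list(tab.columns) == TRIAL_TABLE_COLUMNS + ["rating_unit"]
        per_p = tab.groupby("participant_id").size()
        # 4 pre + 20 acq + 1 reacq + 40 ext
        assert (per_p == 65).all()

    def test_degenerate_all_zero(self):
        # gamma huge: theta -> 0, every rating is exactly zero
        p = GeneratingParams(
            intercept=0, b_trial=0, gamma=40.0,
            sd_participant_intercept=0, sd_participant_slope=0, sd_trial_intercept=0,
        )
        tab = simulate_study(5, params=p, seed=1, phases=("extinction",))
        assert (tab["rating_unit"] == 0).all()
        assert (tab["rating_raw"] == 0).all()

    def test_degenerate_mean_half(self):
        # no zero inflation, enormous precision: ratings pile up at mu = 0.5
        p = GeneratingParams(
            intercept=0, b_trial=0, gamma=-40.0, phi=12.0,
            sd_participant_intercept=0, sd_participant_slope=0, sd_trial_intercept=0,
        )
        tab = simulate_study(150, params=p, seed=2, phases=("extinction",))
        assert len(tab) >= 6000
        assert abs(tab["rating_unit"].mean() - 0.5) < 0.01

    def test_zero_fraction_matches_theta(self):
        # with all variance components off, the zero rate estimates 1 - theta
        from scipy.special import expit

        p = GeneratingParams(
            intercept=1.0, b_trial=0.0, gamma=2.0,
            sd_participant_intercept=0, sd_participant_slope=0, sd_trial_intercept=0,
        )
        tab = simulate_study(100, params=p, seed=3, phases=("extinction",))
        expected = 1 - expit(1.0 - 2.0)
        n = len(tab)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs((tab["rating_unit"] == 0).mean() - expected) < 4 * se

    def test_zero_rate_consistency_at_reference_values(self):
        # two independent Monte-Carlo estimates of P(y=0) at trial 0 agree:
        # one from simulated data, one integrating over the random effects
        params = GeneratingParams()  # reference extinction scenario
        tab = simulate_study(400, params=params, seed=4, phases=("extinction",))
        first = tab[(tab["trial_index"] == 0) & (tab["cs_type"] == "cs_plus")]
        emp = (first["rating_unit"] == 0).mean()

        rng = np.random.default_rng(99)
        from scipy.special import expit

        u0 = rng.normal(0, params.sd_participant_intercept, 200_000)
        w = rng.normal(0, params.sd_trial_intercept, 200_000)
        zeta0 = params.intercept + u0 + w
        expected = float(np.mean(1 - expit(zeta0 - params.gamma)))
        se_emp = np.sqrt(expected * (1 - expected) / len(first))
        assert abs(emp - expected) < 3 * se_emp

    def test_continuous_ratings_inside_open_interval(self):
        tab = simulate_study(50, seed=5, phases=("extinction",))
        cont = tab.loc[tab["rating_unit"] > 0, "rating_unit"]
        assert (cont > 0).all() and (cont < 1).all()

    def test_seed_reproducibility(self):
        a = simulate_study(4, seed=9)
        b = simulate_study(4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_raw_round_trip(self):
        tab = simulate_study(10, seed=6, phases=("extinction",))
        expected = np.clip(np.floor(tab["rating_unit"] * 101 + 0.5), 0, 100)
        assert (tab["rating_raw"] == expected.astype(int)).all()


def test_vas_ratings_shape_and_scale():
    wide = simulate_vas_ratings(30, seed=0)
    assert len(wide) == 30
    for col in wide.columns:
        if col != "participant_id":
            assert wide[col].between(0, 10).all()
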