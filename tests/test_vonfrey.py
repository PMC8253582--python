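"""Staircase mechanics and the Dixon up-down threshold estimator."""

import json
from importlib import resources

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import spearmanr

from qorscore.cohort import simulate_vonfrey_responses
from qorscore.vonfrey import (
    DEFAULT_FILAMENTS,
    InsufficientDataError,
    ThresholdEstimate,
    VonFreySession,
    VonFreyTrial,
    default_start_force,
    dixon_k,
    estimate_threshold,
    generate_k_table,
    mean_log_spacing,
    run_staircase,
)


def make_session(forces, responses, filament_set=DEFAULT_FILAMENTS):
    return VonFreySession(
        trials=tuple(VonFreyTrial(f, r) for f, r in zip(forces, responses)),
        filament_set=filament_set,
    )


class TestStaircase:
    def test_never_responds_censors_high(self):
        session = run_staircase(lambda f: False)
        assert session.censored_high and not session.censored_low
        assert session.trials[-1].force_g == max(DEFAULT_FILAMENTS)
        est = estimate_threshold(session)
        assert est == ThresholdEstimate(max(DEFAULT_FILAMENTS), censored=True)

    def test_always_responds_censors_low(self):
        session = run_staircase(lambda f: True)
        assert session.censored_low
        est = estimate_threshold(session)
        assert est == ThresholdEstimate(min(DEFAULT_FILAMENTS), censored=True)

    def test_deterministic_cutpoint_alternates(self):
        # cutpoint between the start filament (1.0 g) and its neighbour 1.4 g:
        # O at 1.0, X at 1.4, repeating until the trial cap
        session = run_staircase(lambda f: f > 1.2, max_trials=6)
        assert [t.force_g for t in session.trials] == [1.0, 1.4, 1.0, 1.4, 1.0, 1.4]
        assert session.pattern == "OXOXOX"

    def test_stops_four_trials_after_first_reversal(self):
        # cutpoint between 0.16 and 0.4: descend from 1.0, reverse at 0.16
        session = run_staircase(lambda f: f > 0.3)
        pattern = session.pattern
        first_rev = next(i for i in range(1, len(pattern))
                         if pattern[i] != pattern[i - 1])
        assert len(session.trials) == first_rev + 1 + 4

    def test_start_is_near_geometric_mean(self):
        start = default_start_force()
        gm_log = 0.5 * (np.log10(DEFAULT_FILAMENTS[0])
                        + np.log10(DEFAULT_FILAMENTS[-1]))
        dists = np.abs(np.log10(np.asarray(DEFAULT_FILAMENTS)) - gm_log)
        assert abs(np.log10(start) - gm_log) == dists.min()

    def test_staircase_rule_enforced_on_construction(self):
        with pytest.raises(ValueError, match="staircase"):
            make_session([1.0, 4.0], [False, False])


class TestDixonK:
    def test_symmetric_alternating_patterns(self):
        assert dixon_k("OX") == pytest.approx(-0.5, abs=1e-6)
        assert dixon_k("XO") == pytest.approx(0.5, abs=1e-6)
        assert dixon_k("OXOXOX") == pytest.approx(-0.5, abs=1e-6)

    def test_sign_symmetry(self):
        # swapping X<->O mirrors the level geometry, so k flips sign
        for pat in ("OOXX", "OXXO", "OOXOX", "XXOXO"):
            flipped = pat.translate(str.maketrans("OX", "XO"))
            assert dixon_k(pat) == pytest.approx(-dixon_k(flipped), abs=1e-6)

    def test_uniform_patterns_rejected(self):
        with pytest.raises(ValueError):
            dixon_k("XXXX")

    def test_shipped_table_matches_generator(self):
        text = resources.files("qorscore.data").joinpath("dixon_k.json").read_text()
        table = json.loads(text)["k"]
        regenerated = generate_k_table(6)
        assert set(table) == set(regenerated)
        for pat in ("OX", "XO", "OXOX", "OOXOXO", "XXOXOX"):
            assert table[pat] == pytest.approx(regenerated[pat], abs=1e-5)


class TestEstimator:
    def test_monotone_under_pattern_shift(self):
        # same response pattern one filament higher scales the estimate by
        # the local filament force ratio
        lo = make_session([0.6, 1.0, 0.6, 1.0, 0.6, 1.0],
                          [False, True, False, True, False, True])
        hi = make_session([1.0, 1.4, 1.0, 1.4, 1.0, 1.4],
                          [False, True, False, True, False, True])
        t_lo = estimate_threshold(lo).threshold_g
        t_hi = estimate_threshold(hi).threshold_g
        assert t_hi > t_lo
        assert t_hi / t_lo == pytest.approx(1.4 / 1.0, rel=1e-9)

    def test_estimate_within_filament_range(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            thr = float(10 ** rng.uniform(np.log10(0.04), np.log10(15)))
            sess = simulate_vonfrey_responses(thr, slope=6.0, seed=rng)
            est = estimate_threshold(sess)
            assert DEFAULT_FILAMENTS[0] <= est.threshold_g <= DEFAULT_FILAMENTS[-1]

    def test_too_short_session_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_threshold(make_session([1.0], [True]))

    def test_simulation_recovery_median_within_half_step(self):
        delta = mean_log_spacing(DEFAULT_FILAMENTS)
        ests = [estimate_threshold(simulate_vonfrey_responses(1.0, slope=10.0,
                                                              seed=s)).threshold_g
                for s in range(1000)]
        assert abs(np.log10(np.median(ests))) < delta / 2

    def test_rank_agreement_with_logistic_ml_fit(self):
        """Dixon estimates track a brute-force logistic psychometric MLE."""
        slope = 8.0

        def ml_threshold(session):
            forces = np.log10([t.force_g for t in session.trials])
            resp = np.array([t.response for t in session.trials], dtype=float)

            def nll(log_thr):
                p = expit(slope * (forces - log_thr))
                p = np.clip(p, 1e-9, 1 - 1e-9)
                return -np.sum(resp * np.log(p) + (1 - resp) * np.log(1 - p))

            res = minimize_scalar(nll, bounds=(np.log10(0.04) - 1,
                                               np.log10(15) + 1),
                                  method="bounded")
            return float(res.x)

        rng = np.random.default_rng(11)
        dixon, ml = [], []
        for _ in range(500):
            thr = float(10 ** rng.uniform(np.log10(0.1), np.log10(8)))
            sess = simulate_vonfrey_responses(thr, slope=slope, seed=rng)
            est = estimate_threshold(sess)
            if est.censored:
                continue
            dixon.append(np.log10(est.threshold_g))
            ml.append(ml_threshold(sess))
        rho = spearmanr(dixon, ml).statistic
        assert rho > 0.9
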