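"""Unit and property tests for the multistate Barker likelihood machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ternpath.barker import (
    EncounterHistoryRecord,
    availability,
    brute_force_loglik,
    build_observation,
    build_transition,
    compress_histories,
    hazard_linear,
    marginal_loglik,
    read_histories_csv,
    read_histories_inp,
    record_logliks,
    rprime,
    survival_from_hazard,
    write_histories_csv,
    write_histories_inp,
)
from ternpath.pipeline import _random_small_instance
from ternpath.simulate import default_truth, gen_environment

probs = st.floats(0.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# elemental rates
# ---------------------------------------------------------------------------

def test_survival_from_hazard_closed_forms():
    assert survival_from_hazard(0.0) == pytest.approx(np.exp(-1.0))
    assert survival_from_hazard(np.log(-np.log(0.5))) == pytest.approx(0.5)
    assert survival_from_hazard(-10.0) == pytest.approx(1.0, abs=1e-4)
    eps = np.linspace(-3, 3, 50)
    assert np.all(np.diff(survival_from_hazard(eps)) < 0)  # decreasing in risk


def test_availability_profile():
    alpha = [0.01, 0.08, 0.35, 0.70, 0.97]
    assert availability(1, alpha) == 0.0
    assert availability(3, alpha) == 0.08
    assert availability(7, alpha) == 1.0
    assert availability(12, alpha) == 1.0


@pytest.mark.parametrize("R,rule,expected", [
    (0.0, "half", 0.0), (0.0, "square", 0.0),
    (0.4, "half", 0.2), (0.4, "square", 0.16),
])
def test_rprime_rules(R, rule, expected):
    assert rprime(R, rule) == pytest.approx(expected)


def test_rprime_unknown_rule():
    with pytest.raises(ValueError):
        rprime(0.3, "cube")


def test_hazard_linear_caps_age_and_matches_dot_product(tiny_truth, tiny_env):
    sv = tiny_truth.demo_params.survival
    rng = np.random.default_rng(0)
    sv = type(sv)(beta0_A=rng.normal(size=3), beta_age=rng.normal(size=25),
                  beta_x_A=rng.normal(size=(3, 8)), Sigma_A=0.01 * np.eye(3))
    ye = rng.normal(size=3)
    # ages past the cap share the oldest modelled age
    assert hazard_linear(30, 1, sv, tiny_env, ye) == hazard_linear(25, 1, sv, tiny_env, ye)
    # independent dot-product oracle
    from ternpath.barker import hazard_covariate_matrix, age_class
    x = hazard_covariate_matrix(tiny_env)[2]
    a = 4
    A = age_class(a)
    expected = sv.beta0_A[A] + sv.beta_age[a - 1] + float(np.dot(sv.beta_x_A[A], x)) + ye[A]
    assert hazard_linear(a, 2, sv, tiny_env, ye) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def test_transition_survivor_rows():
    P = build_transition(S=1.0, F=0.9, psi=0.8, r=0.5)
    assert np.all(P[:3, 3:] == 0.0)           # no mortality mass
    assert P[0, 0] == pytest.approx(0.72)     # S*F*psi
    assert P[0, 1] == pytest.approx(0.18)
    assert P[0, 2] == pytest.approx(0.1)


def test_transition_mortality_split():
    P = build_transition(S=0.0, F=1.0, psi=1.0, r=0.2)
    for i in range(3):
        assert P[i, 3] == pytest.approx(0.2)
        assert P[i, 4] == pytest.approx(0.8)


def test_transition_movement_suppressed_before_breeding_age():
    P = build_transition(S=0.9, F=0.5, psi=0.5, r=0.1, move_allowed=False)
    assert P[0, 0] == pytest.approx(0.9)
    assert P[0, 1] == 0.0 and P[0, 2] == 0.0


@settings(max_examples=200, deadline=None)
@given(S=probs, F=probs, psi=probs, r=probs)
def test_transition_rows_stochastic(S, F, psi, r):
    P = build_transition(S, F, psi, r)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    # dead states absorb unidirectionally
    assert P[3, 5] == 1.0 and P[4, 5] == 1.0 and P[5, 5] == 1.0


def test_observation_certain_detection():
    O = build_observation(alpha=1.0, p_NC=1.0, p_VA=1.0, R=1.0, Rp=0.5)
    assert O[0, 0] == 1.0   # NC bird: seen in NC and Florida
    assert O[1, 1] == 1.0


def test_observation_no_detection():
    O = build_observation(alpha=0.5, p_NC=0.0, p_VA=0.0, R=0.0, Rp=0.0)
    for s in (0, 1, 2):
        assert O[s, 5] == 1.0
    assert O[3, 6] == 1.0   # recovery event is emitted regardless


@settings(max_examples=200, deadline=None)
@given(alpha=probs, pN=probs, pV=probs, R=probs, Rp=probs)
def test_observation_rows_stochastic(alpha, pN, pV, R, Rp):
    O = build_observation(alpha, pN, pV, R, Rp)
    assert np.allclose(O.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# marginalized likelihood vs exhaustive enumeration
# ---------------------------------------------------------------------------

def test_forward_matches_brute_force_sweep():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(40):
        env, records, params, effects = _random_small_instance(rng)
        a = marginal_loglik(records, params, env, effects)
        b = brute_force_loglik(records, params, env, effects)
        assert np.isfinite(a) == np.isfinite(b)
        if np.isfinite(a):
            worst = max(worst, abs(a - b))
    assert worst < 1e-8


def test_event_space_sums_to_one(tiny_truth):
    """Total probability over every possible 1-interval event sequence is 1."""
    truth = default_truth(n_years=3, per_year=10, seed=5)
    truth.missing = {}
    env = gen_environment(truth)
    total = 0.0
    found_positive = 0
    for e1 in range(1, 8):
        for e2 in range(1, 8):
            ev = np.array([0, e1, e2], dtype=np.int8)
            if e1 == 7:
                if e2 != 6:  # after recovery the chain is silent
                    continue
                ev = np.array([0, 7, 0], dtype=np.int8)
            rec = EncounterHistoryRecord(truth.start_year, "NC", "service", ev)
            ll = brute_force_loglik([rec], truth.demo_params, env)
            if np.isfinite(ll):
                total += np.exp(ll)
                found_positive += 1
    assert found_positive > 5
    assert total == pytest.approx(1.0, abs=1e-10)


def test_compression_and_permutation_invariance(tiny_truth, tiny_env, tiny_study):
    records = tiny_study.histories
    doubled = [EncounterHistoryRecord(r.release_year, r.natal_state, r.band_type,
                                      r.events, r.count * 2) for r in records]
    split = []
    for r in records:
        split.append(EncounterHistoryRecord(r.release_year, r.natal_state,
                                            r.band_type, r.events, r.count))
        split.append(EncounterHistoryRecord(r.release_year, r.natal_state,
                                            r.band_type, r.events, r.count))
    ll_doubled = marginal_loglik(doubled, tiny_truth.demo_params, tiny_env,
                                 tiny_study.effects)
    ll_split = marginal_loglik(split, tiny_truth.demo_params, tiny_env,
                               tiny_study.effects)
    assert ll_doubled == pytest.approx(ll_split, rel=1e-12)
    rng = np.random.default_rng(1)
    perm = list(records)
    rng.shuffle(perm)
    assert marginal_loglik(perm, tiny_truth.demo_params, tiny_env, tiny_study.effects) \
        == pytest.approx(marginal_loglik(records, tiny_truth.demo_params, tiny_env,
                                         tiny_study.effects), rel=1e-12)


def test_impossible_history_is_minus_inf(tiny_truth, tiny_env):
    # breeding-ground resight in the bird's second year: availability is 0
    ev = np.zeros(tiny_env.n_years, dtype=np.int8)
    ev[1] = 3
    ev[2:] = 6
    rec = EncounterHistoryRecord(int(tiny_env.years[0]), "NC", "service", ev)
    with pytest.warns(UserWarning, match="impossible"):
        ll = marginal_loglik([rec], tiny_truth.demo_params, tiny_env)
    assert ll == -np.inf


def test_never_reencountered_with_zero_detection_has_probability_one():
    truth = default_truth(n_years=4, per_year=10, seed=3)
    truth.missing = {}
    env = gen_environment(truth)
    det = truth.demo_params.detection
    det.p_mean = np.array([-40.0, -40.0])
    det.r_intercept = -40.0
    det.R_mean = -40.0
    det.beta_p_band = np.zeros(2)
    det.r_beta_band = np.zeros(2)
    det.R_beta_band = np.zeros(2)
    det.r_beta_x = np.zeros(7)
    det.sigma_r = det.sigma_R = 1e-9
    det.Sigma_p = 1e-18 * np.eye(2)
    ev = np.array([0, 6, 6, 6], dtype=np.int8)
    rec = EncounterHistoryRecord(truth.start_year, "NC", "service", ev)
    ll = marginal_loglik([rec], truth.demo_params, env)
    assert ll == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# CJS limit
# ---------------------------------------------------------------------------

def test_single_state_zero_recovery_limit_matches_cjs():
    """With one live state and r = R = R' = 0 the model collapses to a
    CJS-style live-resight likelihood."""
    truth = default_truth(n_years=5, per_year=10, seed=9)
    truth.missing = {}
    env = gen_environment(truth)
    demo = truth.demo_params
    demo.movement.F = 1.0
    demo.movement.psi = 1.0
    det = demo.detection
    det.r_intercept = -40.0
    det.R_mean = -40.0
    det.r_beta_NC = det.R_beta_NC = 0.0
    det.r_beta_x = np.zeros(7)
    det.r_beta_band = np.zeros(2)
    det.R_beta_band = np.zeros(2)
    det.beta_p_band = np.zeros(2)
    det.sigma_r = det.sigma_R = 1e-12
    det.Sigma_p = 1e-18 * np.eye(2)
    det.alpha_hat = np.ones(5)  # every age past 1 fully available
    det.p_mean = np.array([-1.2, -1.2])

    from ternpath.barker import YearEffects, realized_rates
    effects = YearEffects.zeros(env.n_years)
    rates = realized_rates(demo, env, effects)
    p_by_year = rates.p[:, 0, 0]

    histories = [
        np.array([8, 6, 3, 6, 3], dtype=np.int8),
        np.array([8, 6, 6, 6, 6], dtype=np.int8),
        np.array([8, 6, 3, 6, 6], dtype=np.int8),
        np.array([0, 8, 6, 3, 6], dtype=np.int8),
    ]
    total_model = 0.0
    total_cjs = 0.0
    for ev8 in histories:
        rel = int(np.argmax(ev8 == 8))
        ev = ev8.copy()
        ev[rel] = 0
        rec = EncounterHistoryRecord(int(env.years[rel]), "NC", "service", ev, 1)
        total_model += marginal_loglik([rec], demo, env, effects)
        # CJS oracle with age-dependent survival and availability-scaled p
        a_, d_ = 1.0, 0.0
        prob = 1.0
        for t in range(rel + 1, env.n_years):
            age = min(t - rel, 25)
            S = rates.S[age - 1, t - 1]
            pt = p_by_year[t] * rates.alpha[age]
            a_, d_ = a_ * S, d_ + a_ * (1.0 - S)
            seen = ev[t] == 3
            w_a = a_ * (pt if seen else 1.0 - pt)
            w_d = 0.0 if seen else d_
            norm = w_a + w_d
            prob *= norm
            a_, d_ = w_a / norm, w_d / norm
        total_cjs += np.log(prob)
    assert total_model == pytest.approx(total_cjs, abs=1e-10)


# ---------------------------------------------------------------------------
# history I/O
# ---------------------------------------------------------------------------

def test_history_csv_and_inp_round_trip(tmp_path, tiny_study, tiny_env):
    records = tiny_study.histories
    years = tiny_env.years
    csv_path = tmp_path / "hist.csv"
    inp_path = tmp_path / "hist.inp"
    write_histories_csv(records, years, csv_path)
    write_histories_inp(records, years, inp_path)
    back_csv = read_histories_csv(csv_path, years)
    back_inp = read_histories_inp(inp_path, years)
    for back in (back_csv, back_inp):
        assert {r.key for r in back} == {r.key for r in records}
        assert sum(r.count for r in back) == sum(r.count for r in records)


def test_record_validation_rejects_bad_histories(tiny_env):
    years = tiny_env.years
    bad = EncounterHistoryRecord(int(years[0]), "NC", "service",
                                 np.array([1, 6, 6, 6], dtype=np.int8))
    with pytest.raises(ValueError):
        bad.validate(years)
    bad2 = EncounterHistoryRecord(int(years[0]), "NC", "service",
                                  np.array([0, 7, 6, 6], dtype=np.int8))
    with pytest.raises(ValueError):
        bad2.validate(years)


def test_loglik_diagnostics_csv(tmp_path, tiny_truth, tiny_env, tiny_study):
    from ternpath.barker import write_loglik_diagnostics

    path = tmp_path / "diag.csv"
    df = write_loglik_diagnostics(tiny_study.histories, tiny_truth.demo_params,
                                  tiny_env, path, tiny_study.effects)
    assert path.exists()
    assert len(df) == len(tiny_study.histories)
    assert np.isfinite(df["loglik"]).all()
    # the table is sorted worst-first on the count-weighted contribution
    assert (np.diff(df["count_weighted_loglik"]) >= 0).all()


def test_compress_histories_merges_counts(tiny_env):
    ev = np.array([0, 6, 6, 6], dtype=np.int8)
    recs = [EncounterHistoryRecord(int(tiny_env.years[0]), "NC", "service", ev, 2),
            EncounterHistoryRecord(int(tiny_env.years[0]), "NC", "service", ev, 3)]
    merged = compress_histories(recs)
    assert len(merged) == 1 and merged[0].count == 5
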