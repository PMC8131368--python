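"""Forward EWA model: closed-form cases, limits and an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewalearn.core import (
    LearningParameters,
    ModelSpec,
    combined_choice_probs,
    individual_choice_probs,
    sequence_loglik,
    social_choice_probs,
    update_attraction,
)
from ewalearn.cues import CueSet

from conftest import make_log


def cueset(N, paybar=None, techniques=("CMS", "CMT", "CH"), **cues):
    K = len(techniques)
    nan = np.full(K, np.nan)
    arr = lambda v: np.asarray(v, dtype=float) if v is not None else nan.copy()
    return CueSet(
        techniques=techniques,
        N=np.asarray(N, dtype=int),
        paybar=arr(paybar),
        rank=arr(cues.get("rank")),
        kin=arr(cues.get("kin")),
        fem=arr(cues.get("fem")),
        samesex=arr(cues.get("samesex")),
    )


# -- attraction update -------------------------------------------------------

def test_update_attraction_arithmetic():
    assert update_attraction(0.5, 0.1, 1) == pytest.approx(0.55)
    assert update_attraction(0.7, 0.0, 1) == 0.7  # memory-only limit
    assert update_attraction(0.7, 1.0, 0) == 0.0  # full-recency limit
    with pytest.raises(ValueError):
        update_attraction(0.5, 1.5, 1)


@given(
    a0=st.floats(0, 1),
    phi=st.floats(0, 1),
    payoffs=st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=30),
)
@settings(deadline=None)
def test_attractions_stay_bounded(a0, phi, payoffs):
    a = a0
    for p in payoffs:
        a = update_attraction(a, phi, p)
        assert min(a0, 0.0) - 1e-12 <= a <= 1.0 + 1e-12


# -- individual choice -------------------------------------------------------

def test_lambda_zero_gives_uniform_choice():
    p = individual_choice_probs(np.array([3.0, -1.0, 0.2]), 0.0)
    assert np.allclose(p, 1 / 3)


def test_softmax_closed_form():
    p = individual_choice_probs(np.array([1.0, 0.0, 0.0]), 1.0)
    e = math.e
    assert np.allclose(p, [e / (e + 2), 1 / (e + 2), 1 / (e + 2)], atol=1e-12)


def test_softmax_overflow_safe():
    p = individual_choice_probs(np.array([50.0, 0.0, 0.0]), 10.0)
    assert np.isfinite(p).all()
    assert p[0] == pytest.approx(1.0)


@given(
    A=st.lists(st.floats(-5, 5), min_size=2, max_size=5),
    lam=st.floats(0, 20),
)
@settings(deadline=None)
def test_choice_probs_normalised(A, lam):
    p = individual_choice_probs(np.array(A), lam)
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p > 0).all()


def test_higher_lambda_sharpens_argmax():
    A = np.array([0.8, 0.3, 0.1])
    last = 0.0
    for lam in (0.5, 1.0, 2.0, 5.0, 10.0):
        p = individual_choice_probs(A, lam)[0]
        assert p > last
        last = p


# -- social choice -----------------------------------------------------------

def test_social_linear_imitation():
    cs = cueset([2, 1, 1])
    p = LearningParameters(gamma=0.5, fc=1.0)
    S = social_choice_probs(cs, p, ModelSpec("freq_dep"))
    assert np.allclose(S, [0.5, 0.25, 0.25])


def test_social_conformity_exponent():
    cs = cueset([2, 1, 1])
    p = LearningParameters(gamma=0.5, fc=2.0)
    S = social_choice_probs(cs, p, ModelSpec("freq_dep"))
    assert np.allclose(S, np.array([4, 1, 1]) / 6)


def test_social_payoff_bias_closed_form():
    cs = cueset([1, 1, 0], paybar=[1.0, 0.0, np.nan])
    p = LearningParameters(gamma=0.5, beta={"pay": 1.0})
    S = social_choice_probs(cs, p, ModelSpec("payoff_bias"))
    e = math.e
    assert np.allclose(S, [e / (e + 1), 1 / (e + 1), 0.0])


def test_social_undefined_without_observations():
    cs = cueset([0, 0, 0])
    assert social_choice_probs(cs, LearningParameters(), ModelSpec("freq_dep")) is None


def test_social_rejects_nonpositive_fc():
    with pytest.raises(ValueError):
        LearningParameters(fc=0.0)


def test_single_bias_specs_pin_fc_at_one():
    # a single-bias model ignores any configured fc (fixed at 1)
    cs = cueset([2, 1, 1], paybar=[0.5, 0.5, 0.5])
    p = LearningParameters(gamma=0.5, fc=3.0, beta={"pay": 0.0})
    S = social_choice_probs(cs, p, ModelSpec("payoff_bias"))
    assert np.allclose(S, [0.5, 0.25, 0.25])


# -- convex combination ------------------------------------------------------

def test_combined_limits_and_convexity():
    I = np.array([0.5, 0.25, 0.25])
    S = np.array([0.8, 0.1, 0.1])
    assert np.allclose(combined_choice_probs(I, S, 0.0), I)
    assert np.allclose(combined_choice_probs(I, S, 1.0), S)
    assert np.allclose(combined_choice_probs(I, S, 0.5), [0.65, 0.175, 0.175])
    assert np.allclose(combined_choice_probs(I, None, 0.7), I)  # fallback


@given(
    gamma=st.floats(0, 1),
    w=st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
    v=st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
)
@settings(deadline=None)
def test_combined_probs_normalised(gamma, w, v):
    I = np.array(w) / np.sum(w)
    S = np.array(v) / np.sum(v)
    assert abs(combined_choice_probs(I, S, gamma).sum() - 1.0) < 1e-12


# -- sequence likelihood -----------------------------------------------------

def brute_force_loglik(log, params, spec, width=20.0):
    """Independent recursion: plain dict/loop reimplementation of the model."""
    techniques = log.techniques
    A = {i: {t: 0.0 for t in techniques} for i in log.individuals}
    out = []
    for session in log.sessions:
        for idx, ev in enumerate(session.events):
            p = params[ev.actor]
            # individual softmax
            ex = {t: math.exp(p.lam * A[ev.actor][t]) for t in techniques}
            tot = sum(ex.values())
            I = {t: ex[t] / tot for t in techniques}
            prob = dict(I)
            if spec.name != "individual":
                window = [
                    w
                    for w in session.events[:idx]
                    if ev.time - width <= w.time < ev.time
                    and w.actor != ev.actor
                    and ev.actor in w.observers
                ]
                if window:
                    fc = p.fc if spec.name in ("freq_dep", "global") else 1.0
                    weights = {}
                    for t in techniques:
                        evs_t = [w for w in window if w.technique == t]
                        if not evs_t:
                            weights[t] = 0.0
                            continue
                        n = len(evs_t)
                        B = 0.0
                        for cue in spec.active_betas:
                            if cue == "pay":
                                val = sum(w.payoff for w in evs_t) / n
                            elif cue == "rank":
                                val = sum(log.individuals[w.actor].rank for w in evs_t) / n
                            elif cue == "kin":
                                val = sum(float(log.kin.loc[ev.actor, w.actor]) for w in evs_t) / n
                            elif cue == "fem":
                                val = sum(
                                    1.0
                                    for w in evs_t
                                    if log.individuals[w.actor].sex == "F"
                                    and log.individuals[w.actor].age_class == "adult"
                                ) / n
                            else:  # same sex
                                val = sum(
                                    1.0
                                    for w in evs_t
                                    if log.individuals[w.actor].sex == log.individuals[ev.actor].sex
                                ) / n
                            B += p.beta.get(cue, 0.0) * val
                        weights[t] = n**fc * math.exp(B)
                    wtot = sum(weights.values())
                    S = {t: weights[t] / wtot for t in techniques}
                    prob = {t: (1 - p.gamma) * I[t] + p.gamma * S[t] for t in techniques}
            out.append(math.log(prob[ev.technique]))
            A[ev.actor][ev.technique] = (1 - p.phi) * A[ev.actor][ev.technique] + p.phi * ev.payoff
    return np.array(out)


def random_tiny_log(rng, n_events=None):
    n_ind = int(rng.integers(2, 5))
    import pandas as pd

    individuals = []
    ids = [f"I{i}" for i in range(n_ind)]
    for i, iid in enumerate(ids):
        individuals.append(
            (
                iid,
                "G",
                "F" if rng.random() < 0.5 else "M",
                "adult" if rng.random() < 0.5 else "juvenile",
                i / max(n_ind - 1, 1),
            )
        )
    kin = pd.DataFrame(np.eye(n_ind), index=ids, columns=ids)
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            r = float(rng.choice([0.0, 0.25, 0.5]))
            kin.iloc[i, j] = kin.iloc[j, i] = r
    n_events = n_events or int(rng.integers(2, 11))
    times = np.sort(rng.uniform(0, 40, n_events))
    events = []
    for t in times:
        actor = ids[int(rng.integers(n_ind))]
        observers = {i for i in ids if i != actor and rng.random() < 0.7}
        events.append(
            (
                float(t),
                actor,
                ["CMS", "CMT", "CH"][int(rng.integers(3))],
                "success" if rng.random() < 0.5 else "failure",
                observers,
            )
        )
    return make_log(individuals, {("S1", "d"): events})


def random_params(rng, ids):
    return {
        i: LearningParameters(
            lam=float(rng.uniform(0, 10)),
            phi=float(rng.uniform(0, 1)),
            gamma=float(rng.uniform(0, 0.95)),
            fc=float(rng.uniform(0.3, 3.0)),
            beta={k: float(rng.normal(0, 1)) for k in ("pay", "rank", "kin", "fem", "sex")},
        )
        for i in ids
    }


def test_two_event_hand_recursion():
    """One individual, two events, individual spec: explicit two-step softmax."""
    log = make_log(
        [("A", "G", "F", "adult", 1.0)],
        {("S1", "d"): [(1.0, "A", "CMS", "success", set()), (2.0, "A", "CMS", "failure", set())]},
    )
    p = {"A": LearningParameters(lam=2.0, phi=0.3)}
    ll = sequence_loglik(log, p, ModelSpec("individual"))
    # step 1: A = (0,0,0) -> uniform 1/3; update A_CMS = 0.3
    # step 2: softmax(2 * (0.3, 0, 0))
    step2 = math.exp(0.6) / (math.exp(0.6) + 2)
    assert ll[0] == pytest.approx(math.log(1 / 3), abs=1e-12)
    assert ll[1] == pytest.approx(math.log(step2), abs=1e-12)


def test_gamma_zero_reduces_global_to_individual(small_sim):
    log = small_sim.log
    params = {
        i: LearningParameters(lam=3.0, phi=0.1, gamma=0.0, fc=1.2, beta={"pay": 1.0, "rank": 0.5})
        for i in log.individuals
    }
    ll_global = sequence_loglik(log, params, ModelSpec("global"))
    params_ind = {i: LearningParameters(lam=3.0, phi=0.1) for i in log.individuals}
    ll_ind = sequence_loglik(log, params_ind, ModelSpec("individual"))
    assert np.allclose(ll_global, ll_ind, atol=1e-12)


@pytest.mark.parametrize("spec_name", ["individual", "payoff_bias", "freq_dep", "global"])
def test_sequence_loglik_matches_brute_force(spec_name):
    rng = np.random.default_rng(42)
    spec = ModelSpec(spec_name)
    for _ in range(25):
        log = random_tiny_log(rng)
        params = random_params(rng, log.individuals)
        ref = brute_force_loglik(log, params, spec)
        got = sequence_loglik(log, params, spec)
        assert np.allclose(got, ref, atol=1e-10)
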