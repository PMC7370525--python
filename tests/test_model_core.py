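"""Unit tests for the Wright-Fisher generation update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tumorwave as tw
from tumorwave.model import _first_hits, initial_state

# ---------------------------------------------------------------------------
# growth factor and parameter validation


@pytest.mark.parametrize(
    "N0, NT, T, expected",
    [
        (1e6, 1e6, 4500, 1.0),
        (1e6, 1e9, 4500, math.exp(3 * math.log(10) / 4500)),
        (1.0, math.e, 1, math.e),
    ],
)
def test_growth_factor_closed_form(N0, NT, T, expected):
    alpha = tw.derive_growth_factor(N0, NT, T)
    assert alpha == pytest.approx(expected, rel=1e-12)
    assert alpha**T * N0 == pytest.approx(NT, rel=1e-9)


@pytest.mark.parametrize("bad", [dict(N0=0, NT=1e9, T=10),
                                 dict(N0=1e6, NT=-1, T=10),
                                 dict(N0=1e6, NT=1e9, T=0)])
def test_growth_factor_rejects_bad_inputs(bad):
    with pytest.raises(tw.InvalidParameterError):
        tw.derive_growth_factor(**bad)


def test_params_derived_fields_and_schedule():
    p = tw.ModelParams(s=0.01, c=2.0)
    assert p.r == pytest.approx(0.02)
    sched = p.schedule()
    assert sched[0] == 10**6 and sched[-1] == 10**9
    assert all(b >= a for a, b in zip(sched, sched[1:]))


@pytest.mark.parametrize("kwargs", [dict(c=0.5), dict(s=1.5), dict(mu=-0.1),
                                    dict(n=0), dict(NT=1e3, N0=1e6)])
def test_params_validation(kwargs):
    with pytest.raises(tw.InvalidParameterError):
        tw.ModelParams(**kwargs)


# ---------------------------------------------------------------------------
# relative fitness


def _state_from_freqs(freqs, total=1000):
    counts = np.round(np.asarray(freqs) * total).astype(np.int64)
    return tw.PopulationState(t=0, counts=counts)


def test_fitness_monomorphic_is_one():
    p = tw.ModelParams(n=2, m=3, s=0.1, c=2.0, N0=100, NT=100, T=5)
    counts = np.zeros((3, 4), dtype=np.int64)
    counts[1, 2] = 100
    fit = tw.relative_fitness(tw.PopulationState(t=0, counts=counts), p)
    assert fit.omega[1, 2] == pytest.approx(1.0)


def test_fitness_neutral_model_all_one():
    p = tw.ModelParams(n=2, m=2, s=0.0, c=1.0, N0=100, NT=100, T=5)
    counts = np.array([[50, 20, 5], [10, 10, 0], [5, 0, 0]], dtype=np.int64)
    fit = tw.relative_fitness(tw.PopulationState(t=0, counts=counts), p)
    assert np.allclose(fit.omega, 1.0)


def test_fitness_two_clone_hand_arithmetic():
    # x_00 = x_11 = 1/2, s = 0.01, c = 2 -> r = 0.02
    p = tw.ModelParams(n=1, m=1, s=0.01, c=2.0, N0=100, NT=100, T=5)
    counts = np.array([[50, 0], [0, 50]], dtype=np.int64)
    fit = tw.relative_fitness(tw.PopulationState(t=0, counts=counts), p)
    mean = (1 + 1.02 * 1.01) / 2
    assert fit.omega[0, 0] == pytest.approx(1 / mean)
    assert fit.omega[1, 1] == pytest.approx(1.02 * 1.01 / mean)
    assert fit.mean_fitness == pytest.approx(mean)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.integers(1, 3), st.integers(1, 4),
    st.floats(0.0, 0.3), st.floats(1.0, 3.0),
    st.data(),
)
def test_fitness_population_mean_is_one(n, m, s, c, data):
    """Mean relative fitness sums to one for arbitrary populations."""
    counts = np.array(
        data.draw(st.lists(
            st.lists(st.integers(0, 50), min_size=m + 1, max_size=m + 1),
            min_size=n + 1, max_size=n + 1)),
        dtype=np.int64)
    if counts.sum() == 0:
        counts[0, 0] = 1
    p = tw.ModelParams(n=n, m=m, s=s, c=c, N0=100, NT=100, T=5)
    state = tw.PopulationState(t=0, counts=counts)
    fit = tw.relative_fitness(state, p)
    assert (fit.omega * state.freqs).sum() == pytest.approx(1.0, abs=1e-10)


def test_fitness_symmetric_when_c_is_one():
    """With c = 1 (r = s) fitness depends only on the total mutation count."""
    p = tw.ModelParams(n=3, m=3, s=0.05, c=1.0, N0=100, NT=100, T=5)
    counts = np.full((4, 4), 5, dtype=np.int64)
    fit = tw.relative_fitness(tw.PopulationState(t=0, counts=counts), p)
    for k in range(4):
        for l in range(4):
            for k2 in range(4):
                l2 = k + l - k2
                if 0 <= l2 <= 3:
                    assert fit.omega[k, l] == pytest.approx(fit.omega[k2, l2])


# ---------------------------------------------------------------------------
# sampling distribution


def test_theta_mutation_free_limit_is_selection_only():
    p = tw.ModelParams(n=2, m=2, mu=0.0, s=0.1, c=2.0, N0=100, NT=100, T=5)
    counts = np.array([[40, 10, 0], [30, 20, 0], [0, 0, 0]], dtype=np.int64)
    state = tw.PopulationState(t=0, counts=counts)
    fit = tw.relative_fitness(state, p)
    theta = tw.sampling_distribution(state, fit, p)
    assert np.allclose(theta.theta, fit.omega * state.freqs)
    assert theta.raw_sum == pytest.approx(1.0)


def test_theta_monomorphic_wildtype_survival_term():
    p = tw.ModelParams(n=2, m=3, mu=0.01, s=0.1, c=2.0, N0=100, NT=100, T=5)
    state = initial_state(p)
    fit = tw.relative_fitness(state, p)
    theta = tw.sampling_distribution(state, fit, p)
    # raw theta_00 is the no-mutation term (1 - mu)^(n + m) * omega_00
    raw_00 = theta.theta[0, 0] * theta.raw_sum
    assert raw_00 == pytest.approx((1 - 0.01) ** 5 * fit.omega[0, 0])


def _theta_bruteforce(state, fitness, p, fitness_weighting="offspring"):
    """Quadruple-sum evaluation of the sampling weights, term by term."""
    x = state.freqs
    raw = np.zeros((p.n + 1, p.m + 1))
    for k in range(p.n + 1):
        for l in range(p.m + 1):
            acc = 0.0
            for i in range(k + 1):
                for j in range(l + 1):
                    w = (fitness.omega[k, l] if fitness_weighting == "offspring"
                         else fitness.omega[i, j])
                    acc += (math.comb(p.n - i, k - i)
                            * math.comb(p.m - j, l - j)
                            * p.mu ** (k - i + l - j)
                            * (1 - p.mu) ** (p.n - i + p.m - j)
                            * w * x[i, j])
            raw[k, l] = acc
    return raw / raw.sum(), raw.sum()


@pytest.mark.parametrize("weighting", ["offspring", "parent"])
def test_theta_matches_exhaustive_enumeration(weighting):
    """Kernel-factorized theta equals the brute-force quadruple sum."""
    p = tw.ModelParams(n=1, m=1, mu=0.1, s=0.1, c=2.0, N0=100, NT=100, T=5)
    state = initial_state(p)
    fit = tw.relative_fitness(state, p)
    theta = tw.sampling_distribution(state, fit, p,
                                     fitness_weighting=weighting)
    expected, raw_sum = _theta_bruteforce(state, fit, p, weighting)
    assert np.allclose(theta.theta, expected, atol=1e-14)
    assert theta.raw_sum == pytest.approx(raw_sum)
    # and on a polymorphic state with more loci
    p2 = tw.ModelParams(n=2, m=3, mu=0.05, s=0.2, c=1.5, N0=95, NT=95, T=5)
    counts = np.zeros((3, 4), dtype=np.int64)
    counts[0, 0], counts[1, 1], counts[0, 2], counts[2, 0] = 50, 25, 15, 5
    state2 = tw.PopulationState(t=0, counts=counts)
    fit2 = tw.relative_fitness(state2, p2)
    theta2 = tw.sampling_distribution(state2, fit2, p2,
                                      fitness_weighting=weighting)
    expected2, _ = _theta_bruteforce(state2, fit2, p2, weighting)
    assert np.allclose(theta2.theta, expected2, atol=1e-14)


def test_theta_no_back_mutation():
    """Clones below every occupied clone get zero sampling probability."""
    p = tw.ModelParams(n=2, m=2, mu=0.01, s=0.1, c=2.0, N0=100, NT=100, T=5)
    counts = np.zeros((3, 3), dtype=np.int64)
    counts[1, 1] = 100  # everyone already has one of each
    state = tw.PopulationState(t=0, counts=counts)
    theta = tw.sampling_distribution(
        state, tw.relative_fitness(state, p), p)
    assert theta.theta[0, 0] == 0
    assert theta.theta[0, 1] == 0
    assert theta.theta[1, 0] == 0
    assert theta.theta[1, 1] > 0


def test_theta_renormalization_deficit_small():
    """1 - raw_sum is of order (n + m) * mu for a wild-type population."""
    p = tw.ModelParams(n=10, m=100, mu=1e-4, s=0.01, c=2.0,
                       N0=1000, NT=1000, T=5)
    state = initial_state(p)
    theta = tw.sampling_distribution(state, tw.relative_fitness(state, p), p)
    deficit = abs(1.0 - theta.raw_sum)
    assert deficit < 10 * (p.n + p.m) * p.mu


def test_survival_exponent_variants_close_at_small_mu():
    p = tw.ModelParams(n=2, m=3, mu=1e-8, s=0.1, c=2.0, N0=100, NT=100, T=5)
    state = initial_state(p)
    fit = tw.relative_fitness(state, p)
    t1 = tw.sampling_distribution(state, fit, p, survival_exponent="as_printed")
    t2 = tw.sampling_distribution(state, fit, p, survival_exponent="per_locus")
    assert np.allclose(t1.theta, t2.theta, rtol=1e-6)


# ---------------------------------------------------------------------------
# step / simulate


def test_step_mutation_free_monomorphic(tiny_neutral_params):
    p = tiny_neutral_params
    rng = np.random.default_rng(0)
    state = initial_state(p)
    nxt = tw.step(state, p, rng)
    assert nxt.t == 1
    assert nxt.counts[0, 0] == p.population_size(1)
    assert nxt.counts.sum() == nxt.counts[0, 0]


def test_step_deterministic_under_fixed_seed(tiny_oracle_params):
    p = tiny_oracle_params
    state = initial_state(p)
    a = tw.step(state, p, np.random.default_rng(123))
    b = tw.step(state, p, np.random.default_rng(123))
    assert np.array_equal(a.counts, b.counts)


def test_step_multinomial_moments():
    """Empirical clone-count means across draws match N(t+1) * theta."""
    p = tw.ModelParams(n=1, m=2, mu=0.01, s=0.05, c=2.0,
                       N0=1000, NT=1000, T=5)
    counts = np.array([[600, 200, 0], [150, 50, 0]], dtype=np.int64)
    state = tw.PopulationState(t=0, counts=counts)
    theta = tw.sampling_distribution(
        state, tw.relative_fitness(state, p), p).theta
    rng = np.random.default_rng(2024)
    draws = np.stack([tw.step(state, p, rng).counts for _ in range(2000)])
    n_next = p.population_size(1)
    expected = n_next * theta
    se = np.sqrt(n_next * theta * (1 - theta) / 2000)
    mask = theta > 1e-9
    assert (np.abs(draws.mean(axis=0) - expected)[mask]
            <= 4 * se[mask] + 1e-9).all()


def test_simulate_neutral_mutation_free_stays_wildtype(tiny_neutral_params):
    traj = tw.simulate(tiny_neutral_params, seed=5)
    assert traj.counts[-1, 0, 0] == tiny_neutral_params.population_size(
        tiny_neutral_params.T)
    assert traj.counts[-1].sum() == traj.counts[-1, 0, 0]


def test_simulate_reproducible(tiny_oracle_params):
    a = tw.simulate(tiny_oracle_params, seed=77)
    b = tw.simulate(tiny_oracle_params, seed=77)
    assert np.array_equal(a.counts, b.counts)


def test_simulate_conserves_size_schedule():
    p = tw.ModelParams(n=2, m=3, mu=1e-3, s=0.05, c=2.0,
                       N0=500, NT=2000, T=30)
    traj = tw.simulate(p, seed=9)
    assert traj.counts.sum(axis=(1, 2)).tolist() == p.schedule()


def test_simulate_no_back_mutation_in_time():
    """A clone appears only after some ancestor clone is occupied."""
    p = tw.ModelParams(n=2, m=2, mu=5e-3, s=0.1, c=2.0,
                       N0=2000, NT=2000, T=60)
    traj = tw.simulate(p, seed=3)
    present = traj.counts > 0
    for k in range(3):
        for l in range(3):
            if (k, l) == (0, 0):
                continue
            hit = traj.first_hit[k, l]
            if hit < 0:
                continue
            ancestors = present[hit - 1, :k + 1, :l + 1]
            assert ancestors.any(), f"clone ({k},{l}) appeared with no ancestor"


def test_mean_fitness_nondecreasing(short_default_traj):
    """Only beneficial mutations: population mean fitness drifts upward."""
    traj = short_default_traj
    p = traj.params
    wbar = [tw.relative_fitness(traj.state(t), p).mean_fitness
            for t in range(0, p.T + 1, 10)]
    diffs = np.diff(wbar)
    assert (diffs >= -1e-4).all()
    assert wbar[-1] >= wbar[0]


# ---------------------------------------------------------------------------
# per-cell oracle


def test_oracle_step_guard():
    p = tw.ModelParams(N0=10**6, NT=10**6, T=5)
    with pytest.raises(tw.SimulationError):
        tw.oracle_step(initial_state(p), p, np.random.default_rng(0))


def test_oracle_step_mutation_free_monomorphic(tiny_neutral_params):
    p = tiny_neutral_params
    nxt = tw.oracle_step(initial_state(p), p, np.random.default_rng(0))
    assert nxt.counts[0, 0] == p.population_size(1)


def test_oracle_step_neutral_expected_frequencies():
    """With s = 0 the offspring clone frequencies are unbiased resamples."""
    p = tw.ModelParams(n=1, m=1, mu=0.0, s=0.0, c=1.0,
                       N0=400, NT=400, T=5)
    counts = np.array([[100, 100], [100, 100]], dtype=np.int64)
    state = tw.PopulationState(t=0, counts=counts)
    rng = np.random.default_rng(11)
    mean = np.zeros((2, 2))
    n_draws = 800
    for _ in range(n_draws):
        mean += tw.oracle_step(state, p, rng).counts
    mean /= n_draws
    se = np.sqrt(400 * 0.25 * 0.75 / n_draws)
    assert np.abs(mean - 100).max() <= 4 * se


def test_first_hit_helper_cumulative():
    counts = np.zeros((4, 2, 2), dtype=np.int64)
    counts[:, 0, 0] = 5
    counts[2, 1, 1] = 1          # (1,1) appears at t=2
    counts[3, 1, 0] = 1          # (1,0) appears at t=3
    exact = _first_hits(counts, at_least=False)
    cum = _first_hits(counts, at_least=True)
    assert exact[1, 0] == 3 and exact[1, 1] == 2
    # cumulative "at least (1,0)" is satisfied by (1,1) already at t=2
    assert cum[1, 0] == 2 and cum[1, 1] == 2
    assert exact[0, 1] == -1 and cum[0, 1] == 2
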