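"""Unit and property tests for the capacity-limited race model."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from pytva.core import (
    DegenerateDisplayError,
    DisplaySpec,
    InvalidParameterError,
    TVAParams,
    attentional_weights,
    effective_exposure,
    encoding_set_distribution,
    processing_rates,
    score_distribution,
    selectivity_index,
    simulate_race,
    simulate_races,
    spatial_bias_index,
)
from pytva.core import _capacity_set_probs


# --- parameters and displays -------------------------------------------------


class TestTVAParams:
    def test_nine_free_degrees_of_freedom(self):
        assert TVAParams.n_free_parameters() == 9

    def test_expected_K(self):
        p = TVAParams(pK=(0, 0, 0.5, 0.5, 0, 0), C=50, t0=10, w_index=0.5, alpha=0.3)
        assert p.expected_K == pytest.approx(3.5)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(pK=(0.5, 0.5, 0, 0, 0, 0.1)),  # does not sum to 1
            dict(pK=(1.2, -0.2, 0, 0, 0, 0)),  # negative entry
            dict(C=0.0),
            dict(C=-5.0),
            dict(t0=150.0),
            dict(w_index=1.5),
            dict(alpha=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        base = dict(pK=(1, 0, 0, 0, 0, 0), C=50.0, t0=10.0, w_index=0.5, alpha=0.4)
        base.update(kw)
        with pytest.raises(InvalidParameterError):
            TVAParams(**base)

    def test_from_expected_K_hits_requested_mean(self):
        for ek in (1.0, 2.7, 3.5, 5.9):
            p = TVAParams.from_expected_K(ek, 50, 10, 0.5, 0.4)
            assert p.expected_K == pytest.approx(ek, abs=1e-9)


class TestDisplaySpec:
    def test_type_composition_enforced(self):
        with pytest.raises(ValueError):
            DisplaySpec("WR6", 100, ("T", "T", "T", "T", "T", "D"))
        with pytest.raises(ValueError):
            DisplaySpec("PR", 100, ("T", "T", "T", "D", "D", "D"))

    def test_constructors_give_expected_composition(self):
        assert DisplaySpec.whole_report_6(50).roles.count("T") == 6
        wr2 = DisplaySpec.whole_report_2(50)
        assert wr2.roles.count("T") == 2 and wr2.roles.count("E") == 4
        pr = DisplaySpec.partial_report(50)
        assert pr.roles.count("T") == 2 and pr.roles.count("D") == 4

    def test_three_placeholders_per_hemifield(self):
        d = DisplaySpec.whole_report_6(50)
        assert d.sides.count("L") == 3 and d.sides.count("R") == 3


# --- effective exposure ------------------------------------------------------


@pytest.mark.parametrize(
    "duration, t0, expected",
    [(10, 16.26, 0.0), (200, 0, 0.200), (80, 15, 0.065), (16.26, 16.26, 0.0)],
)
def test_effective_exposure(duration, t0, expected):
    assert effective_exposure(duration, t0) == pytest.approx(expected)


def test_negative_duration_rejected():
    with pytest.raises(InvalidParameterError):
        effective_exposure(-1, 0)


# --- weights and rates -------------------------------------------------------


class TestWeights:
    def test_symmetric_whole_report_weights_equal(self):
        w = attentional_weights(DisplaySpec.whole_report_6(50), 0.5, 0.0)
        assert np.allclose(w, w[0])
        assert spatial_bias_index(DisplaySpec.whole_report_6(50), w) == pytest.approx(0.5)

    def test_left_bias_recoverable_from_weights(self):
        d = DisplaySpec.whole_report_6(50)
        w = attentional_weights(d, 0.7, 0.0)
        left = w[:3]
        assert np.allclose(left, 0.7 / 3)
        assert np.allclose(w[3:], 0.3 / 3)
        assert spatial_bias_index(d, w) == pytest.approx(0.7)

    def test_alpha_zero_gives_zero_distractor_weight(self):
        d = DisplaySpec.partial_report(50)
        w = attentional_weights(d, 0.5, 0.0)
        distractors = [i for i in range(6) if d.roles[i] == "D"]
        assert all(w[i] == 0.0 for i in distractors)
        assert selectivity_index(d, w) == 0.0

    def test_alpha_recoverable_from_weights(self):
        d = DisplaySpec.partial_report(50)
        for alpha in (0.25, 0.5, 1.0):
            w = attentional_weights(d, 0.6, alpha)
            assert selectivity_index(d, w) == pytest.approx(alpha)
            assert spatial_bias_index(d, w) == pytest.approx(0.6)

    def test_empty_slots_carry_zero_weight(self):
        d = DisplaySpec.whole_report_2(50)
        w = attentional_weights(d, 0.5, 0.4)
        empties = [i for i in range(6) if d.roles[i] == "E"]
        assert all(w[i] == 0.0 for i in empties)


class TestRates:
    def test_rates_sum_to_C(self):
        d = DisplaySpec.whole_report_6(50)
        w = attentional_weights(d, 0.62, 0.0)
        v = processing_rates(w, 50.0)
        assert v.sum() == pytest.approx(50.0, abs=1e-9)

    def test_equal_weights_split_equally(self):
        v = processing_rates(np.ones(6), 50.0)
        assert np.allclose(v, 50.0 / 6)

    def test_partial_report_target_distractor_rate_ratio(self):
        d = DisplaySpec.partial_report(50)
        w = attentional_weights(d, 0.5, 0.5)
        v = processing_rates(w, 60.0)
        targets = [i for i in range(6) if d.roles[i] == "T"]
        distractors = [i for i in range(6) if d.roles[i] == "D"]
        assert v[targets[0]] / v[distractors[0]] == pytest.approx(2.0)
        assert v.sum() == pytest.approx(60.0)

    def test_all_zero_weights_flagged_degenerate(self):
        with pytest.raises(DegenerateDisplayError):
            processing_rates(np.zeros(6), 50.0)


# --- exact encoding distribution --------------------------------------------


def _ordering_oracle_set_probs(rates, k, tau):
    """Independent oracle: P(first k finishers = S, T_(k) <= tau) summed over
    orderings, with the hypoexponential CDF computed via the matrix
    exponential of the bidiagonal stage-rate generator."""
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    total = rates.sum()
    probs = np.zeros(1 << n)
    for mask in range(1 << n):
        items = [i for i in range(n) if mask >> i & 1]
        size = len(items)
        if size < k:
            p = 1.0
            for i in range(n):
                pi = 1 - np.exp(-rates[i] * tau)
                p *= pi if i in items else (1 - pi)
            probs[mask] = p
        elif size == k:
            acc = 0.0
            for order in itertools.permutations(items):
                stage_rates = []
                remaining = total
                sel = 1.0
                for x in order:
                    stage_rates.append(remaining)
                    sel *= rates[x] / remaining
                    remaining -= rates[x]
                q = np.zeros((k + 1, k + 1))
                for i, r in enumerate(stage_rates):
                    q[i, i] = -r
                    q[i, i + 1] = r
                cdf = expm(q * tau)[0, k]
                acc += sel * cdf
            probs[mask] = acc
    return probs


@pytest.mark.parametrize(
    "rates, k, tau",
    [
        ([30.0, 20.0, 10.0], 2, 0.05),
        ([12.5, 12.5, 12.5, 12.5], 2, 0.08),  # tied rates
        ([40.0, 5.0, 5.0, 10.0], 3, 0.12),
        ([25.0, 25.0], 1, 0.02),
    ],
)
def test_exact_probs_match_ordering_hypoexponential_oracle(rates, k, tau):
    exact = _capacity_set_probs(np.array(rates), k, tau)[:, 0]
    oracle = _ordering_oracle_set_probs(rates, k, tau)
    assert np.max(np.abs(exact - oracle)) < 1e-10


def test_single_item_closed_form():
    p = _capacity_set_probs(np.array([50.0]), 1, 0.020)[:, 0]
    assert p[1] == pytest.approx(1 - np.exp(-1.0))
    assert p[0] == pytest.approx(np.exp(-1.0))


def test_two_equal_items_capacity_one_symmetry():
    v, tau = 10.0, 0.05
    p = _capacity_set_probs(np.array([v, v]), 1, tau)[:, 0]
    expected = (1 - np.exp(-2 * v * tau)) / 2
    assert p[0b01] == pytest.approx(expected)
    assert p[0b10] == pytest.approx(expected)
    assert p[0b11] == 0.0


def test_zero_exposure_encodes_nothing(default_params):
    dist = encoding_set_distribution([10.0, 20.0], default_params.pK, 0.0)
    assert dist.prob([]) == 1.0


def test_zero_rate_items_never_encoded(default_params):
    dist = encoding_set_distribution([30.0, 0.0, 30.0], default_params.pK, 0.1)
    for subset in ([1], [0, 1], [1, 2], [0, 1, 2]):
        assert dist.prob(subset) == 0.0
    assert dist.total() == pytest.approx(1.0, abs=1e-8)


@given(
    rates=st.lists(st.floats(0.5, 80.0), min_size=2, max_size=6),
    tau=st.floats(0.0, 0.3),
    kmass=st.integers(0, 5),
)
def test_probability_conservation(rates, tau, kmass):
    pK = [0.0] * 6
    pK[kmass] = 1.0
    dist = encoding_set_distribution(rates, pK, tau)
    assert dist.total() == pytest.approx(1.0, abs=1e-8)
    assert np.all(dist.probs >= -1e-12)


@given(
    rates=st.lists(st.floats(0.5, 60.0), min_size=3, max_size=5),
    k=st.integers(1, 6),
)
def test_relabeling_invariance(rates, k):
    """Permuting items permutes set probabilities."""
    tau = 0.06
    rates = np.array(rates)
    perm = np.random.default_rng(len(rates) * 7 + k).permutation(len(rates))
    base = _capacity_set_probs(rates, k, tau)[:, 0]
    permuted = _capacity_set_probs(rates[perm], k, tau)[:, 0]
    n = len(rates)
    for mask in range(1 << n):
        # the subset's image under the permutation: item perm[j] -> slot j
        image = 0
        for j in range(n):
            if mask >> perm[j] & 1:
                image |= 1 << j
        assert permuted[image] == pytest.approx(base[mask], abs=1e-12)


def test_capacity_slack_factorises_into_bernoulli():
    rates = np.array([10.0, 25.0, 40.0])
    tau = 0.07
    probs = _capacity_set_probs(rates, 6, tau)[:, 0]
    p_item = 1 - np.exp(-rates * tau)
    for mask in range(8):
        expected = np.prod(
            [p_item[i] if mask >> i & 1 else 1 - p_item[i] for i in range(3)]
        )
        assert probs[mask] == pytest.approx(expected, abs=1e-12)


# --- score distribution ------------------------------------------------------


class TestScoreDistribution:
    def test_below_threshold_scores_zero(self, default_params):
        dist = score_distribution(default_params, DisplaySpec.whole_report_6(10))
        assert dist[0] == pytest.approx(1.0)

    def test_saturation_at_full_capacity(self):
        p = TVAParams(pK=(0, 0, 0, 0, 0, 1.0), C=5000.0, t0=0.0, w_index=0.5, alpha=0.0)
        dist = score_distribution(p, DisplaySpec.whole_report_6(200))
        assert dist[6] == pytest.approx(1.0, abs=1e-3)

    def test_uniform_two_subset_combinatorial_oracle(self):
        # alpha=1, equal rates, capacity 2, huge exposure: the two VSTM slots
        # hold a uniformly random 2-subset of the six items -> P(both targets)
        # = 1/C(6,2) = 1/15
        p = TVAParams(pK=(0, 1, 0, 0, 0, 0), C=60.0, t0=0.0, w_index=0.5, alpha=1.0)
        dist = score_distribution(p, DisplaySpec.partial_report(10_000))
        assert dist[2] == pytest.approx(1 / 15, abs=1e-9)
        assert dist[1] == pytest.approx(8 / 15, abs=1e-9)
        assert dist[0] == pytest.approx(6 / 15, abs=1e-9)

    def test_sums_to_one(self, default_params):
        for make in (
            DisplaySpec.whole_report_6,
            DisplaySpec.whole_report_2,
            DisplaySpec.partial_report,
        ):
            dist = score_distribution(default_params, make(140))
            assert dist.sum() == pytest.approx(1.0, abs=1e-8)

    def test_score_probability_monotone_in_exposure_and_C(self, default_params):
        p_ge1 = []
        for dur in (10, 20, 50, 80, 140, 200):
            d = score_distribution(default_params, DisplaySpec.whole_report_6(dur))
            p_ge1.append(1 - d[0])
        assert np.all(np.diff(p_ge1) >= -1e-12)
        p_ge1_c = []
        for C in (10, 30, 50, 80, 120):
            p = TVAParams.from_expected_K(3.5, C, 15.0, 0.5, 0.4)
            d = score_distribution(p, DisplaySpec.whole_report_6(80))
            p_ge1_c.append(1 - d[0])
        assert np.all(np.diff(p_ge1_c) >= -1e-12)

    def test_alpha_zero_distractors_never_limit_targets(self):
        # with perfect selectivity PR behaves exactly like the 2-target display
        p = TVAParams.from_expected_K(3.5, 50.0, 15.0, 0.5, 0.0)
        pr = score_distribution(p, DisplaySpec.partial_report(80))
        wr2 = score_distribution(p, DisplaySpec.whole_report_2(80))
        assert np.allclose(pr, wr2, atol=1e-12)


# --- Monte-Carlo oracle ------------------------------------------------------


MC_SETTINGS = [
    # (display factory, w_index, alpha, C, k, exposure_ms) — binding and slack
    (DisplaySpec.whole_report_6, 0.5, 0.0, 50.0, 2, 140.0),  # k binding
    (DisplaySpec.whole_report_6, 0.7, 0.0, 80.0, 6, 200.0),  # k slack
    (DisplaySpec.partial_report, 0.5, 0.5, 60.0, 3, 80.0),
    (DisplaySpec.partial_report, 0.4, 1.0, 40.0, 6, 140.0),
    (DisplaySpec.whole_report_2, 0.6, 0.0, 30.0, 1, 50.0),
]


@pytest.mark.parametrize("make,w,alpha,C,k,dur", MC_SETTINGS)
def test_monte_carlo_matches_exact_distribution(make, w, alpha, C, k, dur):
    display = make(dur)
    disp = list(display.displayed)
    weights = attentional_weights(display, w, alpha)[disp]
    rates = processing_rates(weights, C)
    tau = effective_exposure(dur, 10.0)
    exact = _capacity_set_probs(
        np.asarray(rates)[rates > 0], k, tau
    )[:, 0]
    rng = np.random.default_rng(42)
    masks = simulate_races(np.asarray(rates)[rates > 0], k, tau, 200_000, rng)
    freqs = np.bincount(masks, minlength=len(exact)) / len(masks)
    assert np.max(np.abs(freqs - exact)) < 0.005


def test_single_item_race_frequency_within_binomial_error():
    rng = np.random.default_rng(7)
    n = 200_000
    masks = simulate_races([50.0], 1, 0.020, n, rng)
    p_hat = masks.mean()
    p = 1 - np.exp(-1.0)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(p_hat - p) < 3 * se


def test_simulate_race_deterministic_given_seed():
    out1 = simulate_race([10.0, 20.0, 30.0], 2, 0.1, 123)
    out2 = simulate_race([10.0, 20.0, 30.0], 2, 0.1, 123)
    assert out1 == out2


def test_simulate_race_zero_exposure_returns_empty():
    assert simulate_race([10.0, 20.0], 2, 0.0, 5) == frozenset()
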