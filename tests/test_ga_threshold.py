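import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedlingvision.errors import ConfigError, InvalidInputError
from seedlingvision.ga_threshold import (
    GaConfig,
    ThresholdPair,
    binarize,
    brute_force_optimal,
    decode_chromosome,
    entropy_fitness,
    ga_optimize,
)
from seedlingvision.preprocess import IntensityHistogram

from conftest import make_smooth_histogram


def hist_from_probs(p):
    p = np.asarray(p, dtype=float)
    return IntensityHistogram(probs=p / p.sum(), total_pixels=10_000)


def spike(level):
    p = np.zeros(256)
    p[level] = 1.0
    return IntensityHistogram(probs=p, total_pixels=16)


# ---------------------------------------------------------------------------
# chromosome decoding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "bits,expected",
    [
        ("0000000011111111", (0, 255)),
        ("0101010110000000", (85, 128)),
        ("1111111100000000", (0, 255)),  # swap repair of (255, 0)
        ("1111111111111111", (0, 255)),  # equal 255s: increment wraps, re-swap
        ("0010000000100000", (32, 33)),  # equal: t2 incremented
    ],
)
def test_decode_including_repair(bits, expected):
    assert decode_chromosome([int(b) for b in bits]) == expected


def test_decode_rejects_wrong_length_or_values():
    with pytest.raises(InvalidInputError):
        decode_chromosome([0] * 15)
    with pytest.raises(InvalidInputError):
        decode_chromosome([0] * 15 + [2])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 1), min_size=16, max_size=16))
def test_decode_always_yields_feasible_ordered_pair(bits):
    t1, t2 = decode_chromosome(bits)
    assert 0 <= t1 < t2 <= 255


# ---------------------------------------------------------------------------
# entropy objective
# ---------------------------------------------------------------------------


def loop_entropy(probs, t1, t2):
    """Independent straight-loop evaluation of the three-class entropy sum."""
    total = 0.0
    for lo, hi in ((0, t1), (t1 + 1, t2), (t2 + 1, 255)):
        mass = float(sum(probs[lo : hi + 1]))
        if mass <= 0:
            continue
        for i in range(lo, hi + 1):
            if probs[i] > 0:
                q = probs[i] / mass
                total -= q * math.log(q)
    return total


def test_entropy_zero_for_single_level():
    assert entropy_fitness(spike(42), ThresholdPair(10, 200)) == pytest.approx(0.0)
    assert entropy_fitness(spike(42), ThresholdPair(100, 101)) == pytest.approx(0.0)


def test_entropy_uniform_closed_form():
    hist = hist_from_probs(np.ones(256))
    expected = math.log(86) + 2 * math.log(85)
    assert entropy_fitness(hist, ThresholdPair(85, 170)) == pytest.approx(expected)


def test_entropy_matches_straight_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        hist = hist_from_probs(rng.random(256))
        pair = ThresholdPair(100, 200)
        assert entropy_fitness(hist, pair) == pytest.approx(
            loop_entropy(hist.probs, *pair), rel=1e-12
        )


def test_entropy_invariant_under_within_class_permutation():
    rng = np.random.default_rng(8)
    p = rng.random(256)
    pair = ThresholdPair(80, 180)
    shuffled = p.copy()
    # permute mass inside the middle class only
    mid = np.arange(81, 181)
    shuffled[mid] = p[rng.permutation(mid)]
    assert entropy_fitness(hist_from_probs(p), pair) == pytest.approx(
        entropy_fitness(hist_from_probs(shuffled), pair)
    )


def test_entropy_bounded_by_uniform_class_entropies():
    rng = np.random.default_rng(9)
    for _ in range(10):
        hist = hist_from_probs(rng.random(256))
        t1, t2 = sorted(rng.choice(255, size=2, replace=False))
        pair = ThresholdPair(int(t1), int(t2))
        bound = math.log(t1 + 1) + math.log(t2 - t1) + math.log(255 - t2)
        assert entropy_fitness(hist, pair) <= bound + 1e-9


def test_entropy_rejects_unordered_pair():
    with pytest.raises(InvalidInputError):
        entropy_fitness(spike(3), ThresholdPair(200, 100))


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------


def loop_brute_force(probs):
    """Independent double-loop argmax with lexicographic tie-break."""
    best = (-np.inf, None)
    p = np.asarray(probs)
    cum = np.concatenate([[0.0], np.cumsum(p)])
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cums = np.concatenate([[0.0], np.cumsum(plogp)])

    def seg(lo, hi):
        mass = cum[hi + 1] - cum[lo]
        if mass <= 0:
            return 0.0
        return np.log(mass) - (cums[hi + 1] - cums[lo]) / mass

    for t1 in range(255):
        for t2 in range(t1 + 1, 256):
            f = seg(0, t1) + seg(t1 + 1, t2) + seg(t2 + 1, 255)
            if f > best[0]:
                best = (f, (t1, t2))
    return best[1]


def test_brute_force_two_spike_histogram_achieves_global_max():
    p = np.zeros(256)
    p[10] = 0.5
    p[200] = 0.5
    hist = hist_from_probs(p)
    pair = brute_force_optimal(hist)
    best = entropy_fitness(hist, pair)
    rng = np.random.default_rng(0)
    for _ in range(200):
        t1, t2 = sorted(rng.choice(256, size=2, replace=False))
        assert best >= entropy_fitness(hist, ThresholdPair(int(t1), int(t2))) - 1e-12


def test_brute_force_dominates_fixed_pair_on_uniform():
    hist = hist_from_probs(np.ones(256))
    pair = brute_force_optimal(hist)
    assert entropy_fitness(hist, pair) >= entropy_fitness(hist, ThresholdPair(85, 170))


def test_brute_force_single_spike_lexicographic_tie_break():
    assert brute_force_optimal(spike(42)) == (0, 1)


def test_brute_force_agrees_with_independent_double_loop(smooth_histograms):
    for hist in smooth_histograms:
        assert tuple(brute_force_optimal(hist)) == loop_brute_force(hist.probs)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def test_ga_seeded_determinism():
    hist = make_smooth_histogram(np.random.default_rng(3))
    a = ga_optimize(hist, GaConfig(rng_seed=11))
    b = ga_optimize(hist, GaConfig(rng_seed=11))
    assert (a.t1, a.t2, a.fitness) == (b.t1, b.t2, b.fitness)


def test_ga_never_below_best_initial_individual():
    # elitist tracking: reconstruct the initial population the GA draws
    hist = make_smooth_histogram(np.random.default_rng(4))
    cfg = GaConfig(rng_seed=5)
    rng = np.random.default_rng(cfg.rng_seed)
    init = rng.integers(0, 2, size=(cfg.population_size, 16), dtype=np.int8)
    best_init = max(
        entropy_fitness(hist, decode_chromosome(c)) for c in init
    )
    assert ga_optimize(hist, cfg).fitness >= best_init - 1e-12


def test_ga_degenerate_landscape_matches_oracle():
    hist = spike(99)
    res = ga_optimize(hist, GaConfig(rng_seed=0))
    assert res.fitness == pytest.approx(0.0)
    assert entropy_fitness(hist, brute_force_optimal(hist)) == pytest.approx(0.0)


def test_ga_close_to_exhaustive_on_smooth_histograms(smooth_histograms):
    # the GA is stochastic: require every run within 3% of the exhaustive
    # optimum and allow at most one of the five outside 1%
    ratios = []
    for i, hist in enumerate(smooth_histograms):
        opt = entropy_fitness(hist, brute_force_optimal(hist))
        res = ga_optimize(hist, GaConfig(rng_seed=i))
        ratios.append(res.fitness / opt)
    assert min(ratios) >= 0.97
    assert sum(r >= 0.99 for r in ratios) >= 4


def test_ga_rejects_tiny_population():
    with pytest.raises(ConfigError):
        GaConfig(population_size=1)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

GRAY = np.array([[100, 200], [10, 150]])


@pytest.mark.parametrize(
    "mode,expected",
    [
        ("geq_min", [[1, 1], [0, 1]]),
        ("upper_class", [[0, 1], [0, 0]]),
        ("band", [[1, 0], [0, 1]]),
    ],
)
def test_binarize_modes(mode, expected):
    out = binarize(GRAY, ThresholdPair(90, 180), mode)
    assert out.tolist() == expected


def test_binarize_all_zero_image():
    out = binarize(np.zeros((3, 3), dtype=int), ThresholdPair(1, 5), "geq_min")
    assert not out.any()


def test_binarize_geq_min_monotone_in_threshold():
    rng = np.random.default_rng(6)
    gray = rng.integers(0, 256, size=(12, 12))
    lo = binarize(gray, ThresholdPair(50, 200), "geq_min")
    hi = binarize(gray, ThresholdPair(120, 200), "geq_min")
    # raising min(t1, t2) never turns a 0 into a 1
    assert not np.any((lo == 0) & (hi == 1))


def test_binarize_unknown_mode():
    with pytest.raises(ConfigError):
        binarize(GRAY, ThresholdPair(1, 2), "sideways")
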