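"""Two-threshold maximum-entropy segmentation optimized by a genetic algorithm.

The segmentation statistic is the Kapur-style three-class entropy: a
threshold pair ``(T1, T2)`` with ``T1 < T2`` splits the 256 gray levels
into classes ``[0, T1]``, ``(T1, T2]`` and ``(T2, 255]``, and the
objective is the sum of the within-class Shannon entropies

    F(T1, T2) = sum_k [ -sum_{i in C_k} (P_i / P_Ck) ln(P_i / P_Ck) ]

where ``P_Ck`` is the total probability mass of class ``k``.  A class
with zero mass contributes 0, and ``0 ln 0 := 0``.

The GA encodes a threshold pair as a 16-bit chromosome (8 bits per
threshold), uses roulette selection on linearly scaled fitness with one
elite individual, single-point crossover, and independent bit-flip
mutation.  :func:`brute_force_optimal` exhaustively scores all 32,640
ordered pairs and serves as the optimizer's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError
from .preprocess import IntensityHistogram


class ThresholdPair(NamedTuple):
    t1: int
    t2: int


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings.

    Defaults: population 21, at most 100 generations, crossover
    probability 0.6, per-bit mutation probability 0.03, and early stop
    after 20 generations without improvement of the best fitness.
    """

    population_size: int = 21
    max_generations: int = 100
    crossover_prob: float = 0.6
    mutation_prob: float = 0.03
    stall_generations: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.max_generations < 1 or self.stall_generations < 1:
            raise ConfigError("generation counts must be >= 1")


@dataclass(frozen=True)
class GaResult:
    """Best threshold pair found, with its fitness and run length."""

    t1: int
    t2: int
    fitness: float
    generations: int

    @property
    def pair(self) -> ThresholdPair:
        return ThresholdPair(self.t1, self.t2)


def decode_chromosome(bits: Sequence[int]) -> ThresholdPair:
    """Decode a 16-bit chromosome into an ordered threshold pair.

    The first 8 bits encode T1, the last 8 encode T2 (MSB first).  A
    decoded pair with t1 >= t2 is repaired: swap, and if still equal,
    increment t2 modulo 256 and re-order.  Every 16-bit string therefore
    maps to a feasible pair.
    """
    arr = np.asarray(bits, dtype=np.int64).ravel()
    if arr.shape != (16,) or np.any((arr != 0) & (arr != 1)):
        raise InvalidInputError("chromosome must be exactly 16 binary digits")
    weights = 1 << np.arange(7, -1, -1)
    t1 = int(arr[:8] @ weights)
    t2 = int(arr[8:] @ weights)
    if t1 > t2:
        t1, t2 = t2, t1
    if t1 == t2:
        t2 = (t2 + 1) % 256
        if t1 > t2:
            t1, t2 = t2, t1
    return ThresholdPair(t1, t2)


class _HistTables:
    """Cumulative mass / mass-weighted-log tables for O(1) class entropy."""

    def __init__(self, hist: IntensityHistogram):
        p = hist.probs
        plogp = np.zeros_like(p)
        nz = p > 0
        plogp[nz] = p[nz] * np.log(p[nz])
        self.cum_p = np.concatenate([[0.0], np.cumsum(p)])
        self.cum_plogp = np.concatenate([[0.0], np.cumsum(plogp)])

    def class_entropy(self, lo: int, hi: int) -> float:
        """Entropy of the class-conditional distribution over levels lo..hi."""
        mass = self.cum_p[hi + 1] - self.cum_p[lo]
        if mass <= 0.0:
            return 0.0
        s = self.cum_plogp[hi + 1] - self.cum_plogp[lo]
        return float(np.log(mass) - s / mass)


def entropy_fitness(hist: IntensityHistogram, pair: ThresholdPair) -> float:
    """Sum of the three within-class entropies for thresholds (t1, t2)."""
    t1, t2 = int(pair[0]), int(pair[1])
    if not (0 <= t1 < t2 <= 255):
        raise InvalidInputError(f"need 0 <= t1 < t2 <= 255, got ({t1}, {t2})")
    tab = _HistTables(hist)
    return (
        tab.class_entropy(0, t1)
        + tab.class_entropy(t1 + 1, t2)
        + tab.class_entropy(t2 + 1, 255)
    )


def _fitness_matrix(hist: IntensityHistogram) -> np.ndarray:
    """256x256 matrix of F(t1, t2); -inf where t1 >= t2."""
    tab = _HistTables(hist)

    def seg(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        mass = tab.cum_p[hi + 1] - tab.cum_p[lo]
        s = tab.cum_plogp[hi + 1] - tab.cum_plogp[lo]
        out = np.zeros(np.broadcast(lo, hi).shape)
        ok = mass > 0
        out[ok] = np.log(mass[ok]) - s[ok] / mass[ok]
        return out

    t1 = np.arange(256)[:, None]
    t2 = np.arange(256)[None, :]
    zero = np.zeros_like(t1 + t2)
    fit = (
        seg(zero, np.broadcast_to(t1, zero.shape))
        + seg(t1 + 1, np.broadcast_to(t2, zero.shape))
        + seg(
            np.broadcast_to(t2 + 1, zero.shape),
            np.broadcast_to(np.array(255), zero.shape),
        )
    )
    fit[t1 >= t2] = -np.inf
    return fit


def brute_force_optimal(hist: IntensityHistogram) -> ThresholdPair:
    """Exhaustive argmax of the entropy objective over all ordered pairs.

    All 32,640 pairs with 0 <= t1 < t2 <= 255 are scored; ties are broken
    by the lexicographically smallest (t1, t2).
    """
    fit = _fitness_matrix(hist)
    best = fit.max()
    ties = np.argwhere(fit == best)
    t1, t2 = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
    return ThresholdPair(int(t1), int(t2))


def _linear_scale(fit: np.ndarray) -> np.ndarray:
    """Goldberg linear fitness scaling: preserve the mean, map max -> 2*mean.

    If that would drive the minimum negative, rescale so the minimum maps
    to 0 instead (mean still preserved).  Degenerate populations (all
    fitness equal, or non-positive mean) scale to uniform weights.
    """
    favg = fit.mean()
    fmax = fit.max()
    fmin = fit.min()
    if fmax <= fmin or favg <= 0:
        return np.ones_like(fit)
    a = favg / (fmax - favg) if fmax > favg else 1.0
    b = favg * (1.0 - a)
    if a * fmin + b < 0:
        a = favg / (favg - fmin)
        b = favg * (1.0 - a)
    return np.maximum(a * fit + b, 0.0)


def ga_optimize(hist: IntensityHistogram, cfg: GaConfig | None = None) -> GaResult:
    """Run the genetic algorithm and return the best-ever threshold pair.

    Deterministic for a fixed ``cfg.rng_seed``: a single generator drives
    initialization, selection, crossover and mutation in a fixed order.
    Elitist tracking guarantees the result is never worse than the best
    individual of the initial population.
    """
    cfg = cfg or GaConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.population_size
    tab = _HistTables(hist)

    def evaluate(pop: np.ndarray) -> tuple[np.ndarray, list[ThresholdPair]]:
        pairs = [decode_chromosome(c) for c in pop]
        fits = np.array(
            [
                tab.class_entropy(0, p.t1)
                + tab.class_entropy(p.t1 + 1, p.t2)
                + tab.class_entropy(p.t2 + 1, 255)
                for p in pairs
            ]
        )
        return fits, pairs

    pop = rng.integers(0, 2, size=(n, 16), dtype=np.int8)
    fits, pairs = evaluate(pop)
    i_best = int(np.argmax(fits))
    best_fit = float(fits[i_best])
    best_pair = pairs[i_best]
    best_chrom = pop[i_best].copy()

    stall = 0
    generations = 0
    for _ in range(cfg.max_generations):
        generations += 1
        scaled = _linear_scale(fits)
        total = scaled.sum()
        probs = scaled / total if total > 0 else np.full(n, 1.0 / n)

        parents = pop[rng.choice(n, size=n, p=probs)].copy()
        # single-point crossover on consecutive mated pairs, both kept
        for i in range(0, n - 1, 2):
            if rng.random() < cfg.crossover_prob:
                cut = int(rng.integers(1, 16))
                tail = parents[i, cut:].copy()
                parents[i, cut:] = parents[i + 1, cut:]
                parents[i + 1, cut:] = tail
        flips = rng.random(parents.shape) < cfg.mutation_prob
        parents ^= flips.astype(np.int8)
        parents[0] = best_chrom  # elitism

        pop = parents
        fits, pairs = evaluate(pop)
        i_gen = int(np.argmax(fits))
        if fits[i_gen] > best_fit + 1e-12:
            best_fit = float(fits[i_gen])
            best_pair = pairs[i_gen]
            best_chrom = pop[i_gen].copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall_generations:
                break

    return GaResult(best_pair.t1, best_pair.t2, best_fit, generations)


_BINARIZE_MODES = ("geq_min", "upper_class", "band")


def binarize(
    levels: np.ndarray, pair: ThresholdPair, mode: str = "geq_min"
) -> np.ndarray:
    """Binarize a quantized gray image (1 = seedling, 0 = background).

    Modes
    -----
    geq_min
        pixel = 1 iff level >= min(t1, t2) (literal two-threshold rule).
    upper_class
        pixel = 1 iff level > t2 (the top entropy class only; appropriate
        when the foreground is the brightest material, as leaves are
        under the green index).
    band
        pixel = 1 iff t1 < level <= t2.
    """
    arr = np.asarray(levels)
    t1, t2 = int(pair[0]), int(pair[1])
    if mode == "geq_min":
        out = arr >= min(t1, t2)
    elif mode == "upper_class":
        out = arr > max(t1, t2)
    elif mode == "band":
        out = (arr > min(t1, t2)) & (arr <= max(t1, t2))
    else:
        raise ConfigError(
            f"unknown binarize mode {mode!r}; expected one of {_BINARIZE_MODES}"
        )
    return out.astype(np.uint8)
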