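"""Block-matching 3-D transform-domain denoising (BM3D, hard-threshold flavor).

The segmented seedling mask is cleaned by grouping similar K x K patches
into a 3-D stack, filtering the stack in a separable orthonormal
transform domain (2-D DCT-II per block, 1-D DCT along the stack axis),
zeroing coefficients with magnitude <= lambda_3d * sigma, and
aggregating the overlapping filtered blocks back into the image with
per-stack weights.  In this pipeline the input is a {0,1} mask treated
as real-valued; the aggregated estimate is re-binarized by the caller.

Matching distance follows d = ||X_P - X_Q||_2 / h (Frobenius norm,
normalized by the sliding step h, not by block area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, dctn, idct, idctn

from .errors import InvalidInputError


@dataclass(frozen=True)
class Bm3dConfig:
    """BM3D tuning parameters.

    block_size
        K, patch side in pixels.
    step
        h, the reference/sliding stride; also normalizes the matching
        distance.
    distance_threshold
        tau_d; candidate blocks with d >= tau_d are rejected.
    max_stack
        cap on the number of blocks per 3-D group.
    lambda_3d, sigma
        hard-threshold multiplier and the noise level (in image intensity
        units); coefficients with |X| <= lambda_3d * sigma are zeroed.
    search_radius
        half-size of the square search window around each reference block.
    """

    block_size: int = 8
    step: int = 4
    distance_threshold: float = 2.5
    max_stack: int = 16
    lambda_3d: float = 2.7
    sigma: float = 0.25
    search_radius: int = 16

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise InvalidInputError("block_size must be >= 2")
        if self.step < 1:
            raise InvalidInputError("step must be >= 1")
        if self.distance_threshold <= 0:
            raise InvalidInputError("distance_threshold must be > 0")
        if self.max_stack < 1:
            raise InvalidInputError("max_stack must be >= 1")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")


@dataclass
class BlockStack:
    """The 3-D group of mutually similar blocks for one reference block.

    ``blocks[0]`` is always the reference block itself (distance 0); the
    remaining members are sorted by ascending distance, scan order
    breaking ties.
    """

    ref_position: tuple[int, int]
    positions: list[tuple[int, int]]
    blocks: np.ndarray  # (n, K, K)
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]


def _candidate_lattice(ref: int, limit: int, cfg: Bm3dConfig) -> np.ndarray:
    """Stride-h lattice positions within the search window, anchored at ref."""
    h, r = cfg.step, cfg.search_radius
    lo = max(0, ref - r)
    hi = min(limit, ref + r)
    first = ref - ((ref - lo) // h) * h
    return np.arange(first, hi + 1, h)


def match_blocks(
    image: np.ndarray, ref_position: tuple[int, int], cfg: Bm3dConfig | None = None
) -> BlockStack:
    """Group blocks similar to the reference block at ``ref_position``.

    Candidates lie on the stride-h lattice (anchored at the reference)
    inside a square window of half-size ``search_radius``; a candidate Q
    joins the group iff d = ||X_P - X_Q||_2 / h < tau_d.  The group is
    sorted by distance, truncated to ``max_stack``, and always leads with
    the reference block itself.
    """
    cfg = cfg or Bm3dConfig()
    arr = np.asarray(image, dtype=np.float64)
    k = cfg.block_size
    r0, c0 = ref_position
    if not (0 <= r0 <= arr.shape[0] - k and 0 <= c0 <= arr.shape[1] - k):
        raise InvalidInputError("reference block exceeds image bounds")

    ref_block = arr[r0 : r0 + k, c0 : c0 + k]
    rows = _candidate_lattice(r0, arr.shape[0] - k, cfg)
    cols = _candidate_lattice(c0, arr.shape[1] - k, cfg)
    sw = sliding_window_view(arr, (k, k))
    cand = sw[np.ix_(rows, cols)]  # (nr, nc, k, k)
    d = np.sqrt(((cand - ref_block) ** 2).sum(axis=(2, 3))) / cfg.step

    entries = []
    for i, rr in enumerate(rows):
        for j, cc in enumerate(cols):
            if (rr, cc) == (r0, c0):
                continue
            if d[i, j] < cfg.distance_threshold:
                entries.append((float(d[i, j]), int(rr), int(cc)))
    entries.sort()
    entries = entries[: cfg.max_stack - 1]

    positions = [(r0, c0)] + [(rr, cc) for _, rr, cc in entries]
    blocks = np.stack([arr[rr : rr + k, cc : cc + k] for rr, cc in positions])
    dists = np.array([0.0] + [e[0] for e in entries])
    return BlockStack(ref_position=(r0, c0), positions=positions, blocks=blocks, distances=dists)


def _forward_3d(blocks: np.ndarray) -> np.ndarray:
    coeffs = dctn(blocks, axes=(1, 2), norm="ortho")
    return dct(coeffs, axis=0, norm="ortho")


def _inverse_3d(coeffs: np.ndarray) -> np.ndarray:
    blocks = idct(coeffs, axis=0, norm="ortho")
    return idctn(blocks, axes=(1, 2), norm="ortho")


def hard_threshold_filter(
    stack: BlockStack | np.ndarray, cfg: Bm3dConfig | None = None
) -> tuple[np.ndarray, int]:
    """Hard-threshold the 3-D group in the transform domain.

    Returns the filtered block array and N_P, the number of transform
    coefficients surviving the threshold |X| > lambda_3d * sigma.
    """
    cfg = cfg or Bm3dConfig()
    blocks = stack.blocks if isinstance(stack, BlockStack) else np.asarray(stack)
    if blocks.ndim != 3:
        raise InvalidInputError("block stack must be a (n, K, K) array")
    coeffs = _forward_3d(blocks.astype(np.float64))
    keep = np.abs(coeffs) > cfg.lambda_3d * cfg.sigma
    kept = np.where(keep, coeffs, 0.0)
    n_nonzero = int(np.count_nonzero(kept))
    return _inverse_3d(kept), n_nonzero


def basic_weight(n_nonzero: int) -> float:
    """Aggregation weight of the hard-threshold pass: 1/N_P, or 1 if N_P < 1."""
    if n_nonzero < 0:
        raise InvalidInputError("n_nonzero must be >= 0")
    return 1.0 / n_nonzero if n_nonzero >= 1 else 1.0


def wiener_weight(coeff_energy: float, cfg: Bm3dConfig | None = None) -> float:
    """Empirical-Wiener aggregation weight E / (E + sigma^2).

    ``coeff_energy`` is the squared magnitude of the transformed group;
    the weight grows toward 1 as the group's signal dominates the noise.
    """
    cfg = cfg or Bm3dConfig()
    if coeff_energy < 0:
        raise InvalidInputError("coeff_energy must be >= 0")
    denom = coeff_energy + cfg.sigma**2
    if denom == 0.0:
        return 1.0
    return coeff_energy / denom


@dataclass
class DenoiseResult:
    """Weighted-aggregation estimate plus per-stack bookkeeping."""

    estimate: np.ndarray
    weights: np.ndarray  # aggregation weight of each reference stack
    n_nonzero: np.ndarray  # N_P per reference stack


def _ref_lattice(length: int, k: int, h: int) -> np.ndarray:
    pos = list(range(0, length - k + 1, h))
    if pos[-1] != length - k:
        pos.append(length - k)
    return np.asarray(pos)


def bm3d_denoise(
    image: np.ndarray, cfg: Bm3dConfig | None = None, two_pass: bool = False
) -> DenoiseResult:
    """Denoise a single-channel image by block matching and 3-D filtering.

    The image is reflect-padded by ``block_size - 1`` on every side so each
    pixel falls under at least one reference block; reference blocks slide
    on a stride-``step`` lattice.  Each group is hard-threshold filtered
    and aggregated with the 1/N_P weight.  With ``two_pass=True`` a second
    pass re-matches on the first-pass estimate and aggregates with the
    empirical-Wiener weight E / (E + sigma^2).
    """
    cfg = cfg or Bm3dConfig()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError("expected a 2-D single-channel image")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("non-finite pixel values")
    k = cfg.block_size
    if arr.shape[0] < k or arr.shape[1] < k:
        raise InvalidInputError("image smaller than block_size")

    basic, weights, nnz = _denoise_pass(arr, cfg, match_on=None, wiener=False)
    if not two_pass:
        return DenoiseResult(estimate=basic, weights=weights, n_nonzero=nnz)
    final, weights2, nnz2 = _denoise_pass(arr, cfg, match_on=basic, wiener=True)
    return DenoiseResult(estimate=final, weights=weights2, n_nonzero=nnz2)


def _denoise_pass(
    arr: np.ndarray, cfg: Bm3dConfig, match_on: np.ndarray | None, wiener: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k, h = cfg.block_size, cfg.step
    pad = k - 1
    padded = np.pad(arr, pad, mode="reflect")
    guide = padded if match_on is None else np.pad(match_on, pad, mode="reflect")
    hp, wp = padded.shape

    sw_img = sliding_window_view(padded, (k, k))
    sw_guide = sw_img if match_on is None else sliding_window_view(guide, (k, k))

    rows = _ref_lattice(hp, k, h)
    cols = _ref_lattice(wp, k, h)
    num = np.zeros_like(padded)
    den = np.zeros_like(padded)
    all_w: list[float] = []
    all_n: list[int] = []

    thr = cfg.lambda_3d * cfg.sigma
    for r0 in rows:
        crows = _candidate_lattice(r0, hp - k, cfg)
        for c0 in cols:
            ccols = _candidate_lattice(c0, wp - k, cfg)
            ref = sw_guide[r0, c0]
            cand = sw_guide[np.ix_(crows, ccols)]
            d = np.sqrt(((cand - ref) ** 2).sum(axis=(2, 3))) / h
            sel = np.argwhere(d < cfg.distance_threshold)
            order = sorted(
                (float(d[i, j]), int(crows[i]), int(ccols[j])) for i, j in sel
            )
            positions = [(r0, c0)]
            for _, rr, cc in order:
                if (rr, cc) != (r0, c0):
                    positions.append((rr, cc))
                if len(positions) >= cfg.max_stack:
                    break
            blocks = np.stack([sw_img[rr, cc] for rr, cc in positions])

            coeffs = _forward_3d(blocks)
            if wiener:
                energy = float((coeffs**2).sum())
                denom = coeffs**2 + cfg.sigma**2
                # a zero coefficient contributes nothing regardless of shrinkage
                shrink = np.divide(
                    coeffs**2, denom, out=np.zeros_like(coeffs), where=denom > 0
                )
                filtered = _inverse_3d(coeffs * shrink)
                n_p = int(np.count_nonzero(np.abs(coeffs) > thr))
                w = wiener_weight(energy, cfg)
            else:
                kept = np.where(np.abs(coeffs) > thr, coeffs, 0.0)
                n_p = int(np.count_nonzero(kept))
                filtered = _inverse_3d(kept)
                w = basic_weight(n_p)

            # zero-energy stacks get zero Wiener weight; keep an epsilon so
            # all-flat-zero regions still aggregate to their (zero) estimate
            w_eff = w if w > 0 else 1e-12
            for (rr, cc), blk in zip(positions, filtered):
                num[rr : rr + k, cc : cc + k] += w_eff * blk
                den[rr : rr + k, cc : cc + k] += w_eff
            all_w.append(w)
            all_n.append(n_p)

    estimate = num / den
    core = estimate[pad : pad + arr.shape[0], pad : pad + arr.shape[1]]
    return core, np.asarray(all_w), np.asarray(all_n)
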