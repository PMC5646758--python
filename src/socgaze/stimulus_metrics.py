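"""Image-side computations for stimulus matching.

Global RMS contrast is SD(luminance) / mean(luminance); the local variant
averages the same statistic over a non-overlapping tiling.  Grid scrambling
permutes 10-pixel tiles to build control mosaics that preserve the pixel
multiset while destroying recognizable structure.  Pair matching is tested
by taking the social/nonsocial ratio of a parameter across pairs and
running a one-sample t test against 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import TestResult, one_sample_t

__all__ = [
    "to_luminance",
    "global_rms_contrast",
    "local_rms_contrast",
    "grid_scramble",
    "ratio_matching_test",
    "MatchResult",
]

_REC601 = np.array([0.299, 0.587, 0.114])


def to_luminance(image) -> np.ndarray:
    """Greyscale luminance as float; RGB collapsed with Rec. 601 weights."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[..., :3]
        if img.shape[2] != 3:
            raise ValueError("expected greyscale or RGB(A) image")
        img = img @ _REC601
    elif img.ndim != 2:
        raise ValueError("expected a 2-D or 3-D image array")
    return img


def global_rms_contrast(image) -> float:
    """SD of luminance divided by mean luminance (scale-invariant)."""
    img = to_luminance(image)
    mean = img.mean()
    if mean == 0:
        raise ValueError("RMS contrast undefined for a zero-mean image")
    return float(img.std() / mean)


def local_rms_contrast(image, window_px: int | None = None) -> float:
    """Mean of per-window RMS contrasts over a non-overlapping tiling.

    ``window_px`` defaults to 10% of the smaller image dimension.  With the
    window equal to the whole image this reduces to the global contrast.
    """
    img = to_luminance(image)
    h, w = img.shape
    if window_px is None:
        window_px = max(1, min(h, w) // 10)
    if window_px < 1 or window_px > min(h, w):
        raise ValueError("window must be >=1 px and fit inside the image")
    contrasts = []
    for r in range(0, h, window_px):
        for c in range(0, w, window_px):
            tile = img[r:r + window_px, c:c + window_px]
            mean = tile.mean()
            if mean == 0:
                raise ValueError("RMS contrast undefined for a zero-mean window")
            contrasts.append(tile.std() / mean)
    return float(np.mean(contrasts))


def grid_scramble(image, block_px: int = 10, seed=None) -> np.ndarray:
    """Permute ``block_px`` x ``block_px`` tiles uniformly at random.

    Edge tiles narrower/shorter than the block are permuted only among
    same-shape tiles, so output dimensions and the pixel multiset are
    preserved exactly.  ``seed`` may be an int or a Generator.
    """
    img = np.asarray(image)
    if img.shape[0] < block_px or img.shape[1] < block_px:
        raise ValueError("image must be at least one block in each dimension")
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    rows = list(range(0, h, block_px))
    cols = list(range(0, w, block_px))
    coords = [(r, c) for r in rows for c in cols]
    shapes: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in coords:
        shape = (min(block_px, h - r), min(block_px, w - c))
        shapes.setdefault(shape, []).append((r, c))
    out = np.empty_like(img)
    for shape, members in shapes.items():
        perm = rng.permutation(len(members))
        for (r, c), k in zip(members, perm):
            sr, sc = members[k]
            out[r:r + shape[0], c:c + shape[1]] = img[sr:sr + shape[0], sc:sc + shape[1]]
    return out


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the ratio matching test for one stimulus parameter."""

    mean_ratio: float
    ci_low: float
    ci_high: float
    test: TestResult
    matched: bool  # 95% CI of the mean ratio overlaps 1


def ratio_matching_test(values_social, values_nonsocial,
                        confidence: float = 0.95) -> MatchResult:
    """Per-pair social/nonsocial ratios tested against 1 (one-sample t).

    The pair is judged matched when the confidence interval of the mean
    ratio overlaps 1.
    """
    vs = np.asarray(values_social, dtype=float)
    vn = np.asarray(values_nonsocial, dtype=float)
    if vs.shape != vn.shape or vs.ndim != 1:
        raise ValueError("need paired 1-D value arrays")
    if len(vs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(vs <= 0) or np.any(vn <= 0):
        raise ValueError("matching parameters must be strictly positive")
    ratios = vs / vn
    result = one_sample_t(ratios, 1.0)
    se = result.sd / np.sqrt(result.n)
    tcrit = float(sps.t.ppf(0.5 + confidence / 2, result.df))
    lo, hi = result.mean - tcrit * se, result.mean + tcrit * se
    return MatchResult(mean_ratio=result.mean, ci_low=float(lo), ci_high=float(hi),
                       test=result, matched=bool(lo <= 1.0 <= hi))
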