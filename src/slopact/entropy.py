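"""Slope entropy and four comparator entropy measures.

Slope entropy (SlopEn) symbolises a series by the slopes between
consecutive samples: with thresholds ``gamma > delta > 0`` each difference
``d = x[j+1] - x[j]`` maps to one of five symbols,

    +2  if d >  gamma
    +1  if delta <  d <= gamma
     0  if |d| <= delta
    -1  if -gamma <= d < -delta
    -2  if d < -gamma

a window of ``m`` samples contributes the pattern of its ``m - 1``
symbols, and the measure is the Shannon entropy (natural log) of the
relative frequencies of the distinct patterns observed across all
``N - m + 1`` windows.  The boundary ``d = -delta`` is assigned to symbol
0 (the rule is symmetric in ``|d|``); ``d = gamma`` maps to +1 and
``d = -gamma`` to -1.

The comparator measures — sample entropy, permutation entropy, weighted
permutation entropy and bubble entropy — follow their standard
definitions and share the :class:`EntropyResult` contract.  All measures
are pure functions of (values, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateInputError, ParameterError, UndefinedEntropyError

__all__ = [
    "SlopEnParams",
    "EntropyResult",
    "slope_symbols",
    "slope_entropy",
    "normalize_entropies",
    "sample_entropy",
    "permutation_entropy",
    "weighted_permutation_entropy",
    "bubble_entropy",
    "compute_entropy",
    "ENTROPY_METHODS",
]


@dataclass(frozen=True)
class SlopEnParams:
    """Embedding length and slope thresholds (in z-units on a normalised
    epoch).  The defaults are the configuration used throughout the
    classification experiments: m=6, gamma=0.94, delta=1e-3."""

    m: int = 6
    gamma: float = 0.94
    delta: float = 1e-3

    def validate(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 2):
            raise ParameterError("m must be an integer >= 2")
        if not (self.gamma > self.delta > 0):
            raise ParameterError("thresholds must satisfy gamma > delta > 0")


@dataclass(frozen=True)
class EntropyResult:
    """Value of one entropy measure on one series."""

    method: str
    params: dict = field(compare=False)
    value: float
    n_patterns_observed: int | None = None


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def slope_symbols(values: Iterable[float], params: SlopEnParams) -> np.ndarray:
    """Map consecutive differences to the five-symbol slope alphabet."""
    params.validate()
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("slope_symbols requires at least 2 samples")
    d = np.diff(x)
    sym = np.zeros(d.size, dtype=np.int8)
    sym[d > params.gamma] = 2
    sym[(d > params.delta) & (d <= params.gamma)] = 1
    sym[(d < -params.delta) & (d >= -params.gamma)] = -1
    sym[d < -params.gamma] = -2
    return sym


def slope_entropy(values: Iterable[float], params: SlopEnParams | None = None) -> EntropyResult:
    """Shannon entropy (nats) of slope-pattern frequencies.

    Each of the ``N - m + 1`` length-``m`` windows yields the pattern of
    its ``m - 1`` slope symbols; frequencies are relative to the patterns
    actually observed (the running pattern list), never to the full
    ``5^(m-1)`` alphabet.
    """
    params = params if params is not None else SlopEnParams()
    params.validate()
    x = np.asarray(values, dtype=float)
    if x.size < params.m:
        raise ParameterError(f"series of length {x.size} is shorter than m={params.m}")
    sym = slope_symbols(x, params)
    width = params.m - 1
    # Encode each symbol window as a base-5 integer for fast counting.
    windows = sliding_window_view(sym.astype(np.int64) + 2, width)
    codes = windows @ (5 ** np.arange(width - 1, -1, -1, dtype=np.int64))
    _, counts = np.unique(codes, return_counts=True)
    value = _shannon(counts / counts.sum())
    return EntropyResult("slopen",
                         {"m": params.m, "gamma": params.gamma, "delta": params.delta},
                         value, n_patterns_observed=int(counts.size))


def normalize_entropies(values: Iterable[float], mode: str = "dataset_max") -> np.ndarray:
    """Divide a collection of entropy values by its maximum, mapping the
    dataset onto [0, 1] with at least one value equal to 1."""
    if mode != "dataset_max":
        raise ParameterError(f"unknown normalisation mode {mode!r}")
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ParameterError("normalize_entropies requires a non-empty collection")
    top = float(v.max())
    if top <= 0:
        raise DegenerateInputError("cannot normalise: collection maximum is not positive")
    return v / top


def sample_entropy(values: Iterable[float], m: int = 2, r: float = 0.25) -> EntropyResult:
    """Sample entropy: -ln(A/B) with Chebyshev template matching.

    Both template counts range over the ``N - m`` windows that admit an
    ``(m+1)``-length extension; ``B`` counts pairs matching over their
    first ``m`` samples within tolerance ``r``, ``A`` pairs matching over
    all ``m + 1``.  ``r`` is interpreted on the scale of the (already
    z-normalised) series.  Self-matches are excluded.
    """
    x = np.asarray(values, dtype=float)
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not r > 0:
        raise ParameterError("r must be positive")
    if x.size <= m + 1:
        raise ParameterError(f"series of length {x.size} is too short for m={m}")
    wins = sliding_window_view(x, m + 1)  # (N - m, m + 1)
    nt = wins.shape[0]
    dist_m = np.zeros((nt, nt))
    for k in range(m):
        np.maximum(dist_m, np.abs(wins[:, None, k] - wins[None, :, k]), out=dist_m)
    dist_m1 = np.maximum(dist_m, np.abs(wins[:, None, m] - wins[None, :, m]))
    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(dist_m[iu] <= r))
    a = int(np.count_nonzero(dist_m1[iu] <= r))
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"sample entropy undefined: A={a}, B={b} template matches")
    return EntropyResult("sampen", {"m": m, "r": r}, float(-math.log(a / b)))


def _ordinal_patterns(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Rank patterns of delay-embedded windows; ties rank by earlier index."""
    n_windows = x.size - (m - 1) * tau
    idx = np.arange(n_windows)[:, None] + tau * np.arange(m)[None, :]
    windows = x[idx]
    # Stable argsort: equal values keep index order, i.e. the earlier
    # sample receives the lower rank.
    return np.argsort(windows, axis=1, kind="stable")


def permutation_entropy(values: Iterable[float], m: int = 5, tau: int = 1) -> EntropyResult:
    """Shannon entropy (nats) of ordinal-pattern frequencies."""
    x = np.asarray(values, dtype=float)
    if m < 2:
        raise ParameterError("m must be >= 2")
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    if x.size < (m - 1) * tau + 1:
        raise ParameterError(
            f"series of length {x.size} is too short for m={m}, tau={tau}")
    patterns = _ordinal_patterns(x, m, tau)
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    value = _shannon(counts / counts.sum())
    return EntropyResult("pe", {"m": m, "tau": tau}, value,
                         n_patterns_observed=int(counts.size))


def weighted_permutation_entropy(values: Iterable[float], m: int = 6,
                                 tau: int = 1) -> EntropyResult:
    """Permutation entropy with each window weighted by its variance."""
    x = np.asarray(values, dtype=float)
    if m < 2:
        raise ParameterError("m must be >= 2")
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    if x.size < (m - 1) * tau + 1:
        raise ParameterError(
            f"series of length {x.size} is too short for m={m}, tau={tau}")
    n_windows = x.size - (m - 1) * tau
    idx = np.arange(n_windows)[:, None] + tau * np.arange(m)[None, :]
    windows = x[idx]
    weights = windows.var(axis=1)
    total = float(weights.sum())
    if total == 0.0:
        raise DegenerateInputError("all windows are constant: total weight is zero")
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, inverse = np.unique(patterns, axis=0, return_inverse=True)
    mass = np.bincount(inverse, weights=weights) / total
    return EntropyResult("wpe", {"m": m, "tau": tau}, _shannon(mass),
                         n_patterns_observed=int(mass.size))


def _swap_counts(x: np.ndarray, m: int) -> np.ndarray:
    """Bubble-sort swap count (number of inversions) of every length-m window."""
    windows = sliding_window_view(x, m)
    counts = np.zeros(windows.shape[0], dtype=np.int64)
    for i in range(m - 1):
        for j in range(i + 1, m):
            counts += windows[:, i] > windows[:, j]
    return counts


def _renyi2(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-np.log(np.sum(p ** 2)))


def bubble_entropy(values: Iterable[float], m: int = 3) -> EntropyResult:
    """Bubble entropy: growth of the Renyi-2 entropy of bubble-sort swap
    counts between window sizes m and m+1, normalised by ln((m+1)/(m-1))."""
    x = np.asarray(values, dtype=float)
    if m < 2:
        raise ParameterError("m must be >= 2")
    if x.size < m + 2:
        raise ParameterError(f"series of length {x.size} is too short for m={m}")
    h_m = _renyi2(np.unique(_swap_counts(x, m), return_counts=True)[1])
    h_m1 = _renyi2(np.unique(_swap_counts(x, m + 1), return_counts=True)[1])
    value = (h_m1 - h_m) / math.log((m + 1) / (m - 1))
    return EntropyResult("be", {"m": m}, value)


#: Dispatch table for the uniform (values, **params) entry point.
ENTROPY_METHODS = {
    "slopen": lambda values, m=6, gamma=0.94, delta=1e-3, **_: slope_entropy(
        values, SlopEnParams(m=m, gamma=gamma, delta=delta)),
    "sampen": lambda values, m=2, r=0.25, **_: sample_entropy(values, m=m, r=r),
    "pe": lambda values, m=5, tau=1, **_: permutation_entropy(values, m=m, tau=tau),
    "wpe": lambda values, m=6, tau=1, **_: weighted_permutation_entropy(
        values, m=m, tau=tau),
    "be": lambda values, m=3, **_: bubble_entropy(values, m=m),
}


def compute_entropy(values: Iterable[float], method: str, **params) -> EntropyResult:
    """Uniform entry point over the five measures."""
    try:
        fn = ENTROPY_METHODS[method]
    except KeyError:
        raise ParameterError(
            f"unknown method {method!r}; choose from {sorted(ENTROPY_METHODS)}") from None
    return fn(values, **params)
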