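"""Cross-sample and cross-fuzzy entropy between two equal-length time series.

Both measures quantify the asynchrony of two signals by comparing delay-embedded
template vectors of one series against those of the other.  Cross-sample entropy
(C-SampleEn) counts templates whose Chebyshev distance falls strictly below a
tolerance ``r`` (a Heaviside match) and is undefined whenever no matches occur at
either embedding order.  Cross-fuzzy entropy (C-FuzzyEn) replaces the hard match
by the exponential membership ``exp(-d**n / r)`` and removes each template's own
baseline (window mean) before comparison, so it is defined for every valid input.

Low values mean the two series share many patterns (high synchrony/symmetry);
high values mean their local patterns differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

__all__ = [
    "TimeSeriesPair",
    "EntropyParams",
    "CrossEntropyResult",
    "embed_templates",
    "chebyshev_distance",
    "heaviside_similarity",
    "fuzzy_similarity",
    "cross_sample_entropy",
    "cross_fuzzy_entropy",
]


@dataclass(frozen=True)
class TimeSeriesPair:
    """Two equal-length, finite, one-dimensional series ``u`` and ``v``."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.ndim != 1 or v.ndim != 1:
            raise ValueError("u and v must be one-dimensional")
        if u.size != v.size:
            raise ValueError(
                f"series must have equal length (got {u.size} and {v.size})"
            )
        if u.size == 0:
            raise ValueError("series must be non-empty")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("series must contain only finite values")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def N(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class EntropyParams:
    """Entropy parameters: embedding dimension ``m``, tolerance ``r``, fuzzy
    gradient ``n`` (exponent of the membership function, conventionally 2).

    ``r`` is an absolute tolerance in the units of the series, not a multiple
    of the series standard deviation.
    """

    m: int = 2
    r: float = 0.2
    n: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.n <= 0:
            raise ValueError("fuzzy gradient n must be positive")


@dataclass(frozen=True)
class CrossEntropyResult:
    """Outcome of a cross-entropy computation.

    ``phi_m`` / ``phi_m1`` are the grand-mean similarity statistics at orders
    ``m`` and ``m + 1`` (match fractions for the Heaviside variant, average
    fuzzy memberships for the fuzzy variant).  ``value`` is ``nan`` when the
    statistic is undefined, which is flagged by ``defined`` rather than raised:
    an undefined C-SampleEn is an informative outcome, not an error.
    """

    measure: str
    value: float
    defined: bool
    phi_m: float
    phi_m1: float
    m: int
    r: float
    n: Optional[float]
    N: int

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "m": self.m,
            "r": self.r,
            "n": self.n,
            "N": self.N,
            "phi_m": self.phi_m,
            "phi_m1": self.phi_m1,
            "value": self.value,
            "defined": self.defined,
        }


def embed_templates(
    series: np.ndarray,
    m: int,
    center: bool = False,
    count: Optional[int] = None,
) -> np.ndarray:
    """Delay-embed ``series`` into overlapping windows of length ``m``.

    Parameters
    ----------
    series : array-like, shape (N,)
    m : int
        Window (template) length.
    center : bool
        If True, subtract each window's own mean (baseline removal), so every
        template sums to zero.  Used by the fuzzy variant.
    count : int, optional
        Number of leading templates to keep.  Defaults to ``N - m``.  The
        entropy computations request ``N - m`` templates at both orders ``m``
        and ``m + 1`` so the two orders are averaged over equally many
        templates.

    Returns
    -------
    ndarray, shape (count, m)
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if arr.size < m + 1:
        raise ValueError(
            f"series of length {arr.size} too short to embed with m={m} "
            f"(need at least {m + 1} points)"
        )
    windows = sliding_window_view(arr, m)
    if count is None:
        count = arr.size - m
    if count > windows.shape[0]:
        raise ValueError(
            f"requested {count} templates but only {windows.shape[0]} windows exist"
        )
    templates = np.array(windows[:count], dtype=float)
    if center:
        templates -= templates.mean(axis=1, keepdims=True)
    return templates


def chebyshev_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum absolute componentwise difference between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.max(np.abs(x - y)))


def heaviside_similarity(d: float, r: float) -> float:
    """Hard match: 1 if ``d`` is strictly below the tolerance ``r``, else 0."""
    if d < 0 or r <= 0:
        raise ValueError("require d >= 0 and r > 0")
    return 1.0 if d < r else 0.0


def fuzzy_similarity(d: float, n: float, r: float) -> float:
    """Exponential membership ``exp(-d**n / r)``: 1 at d=0, decreasing in d,
    strictly positive for every finite distance."""
    if d < 0 or r <= 0 or n <= 0:
        raise ValueError("require d >= 0, r > 0 and n > 0")
    return float(np.exp(-(d**n) / r))


def _pairwise_chebyshev(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Chebyshev distances between the rows of X and Y."""
    d = np.abs(X[:, 0, None] - Y[None, :, 0])
    for k in range(1, X.shape[1]):
        np.maximum(d, np.abs(X[:, k, None] - Y[None, :, k]), out=d)
    return d


def _prepare(pair: TimeSeriesPair, params: EntropyParams, normalize: bool):
    if pair.N < params.m + 2:
        raise ValueError(
            f"series length N={pair.N} too short for m={params.m} (need N >= m + 2)"
        )
    u, v = pair.u, pair.v
    if normalize:
        u = (u - u.mean()) / u.std()
        v = (v - v.mean()) / v.std()
    return u, v


def cross_sample_entropy(
    pair: TimeSeriesPair,
    params: EntropyParams,
    normalize: bool = False,
) -> CrossEntropyResult:
    """Cross-sample entropy ``-ln(B^{m+1} / B^m)`` with Heaviside matching.

    ``B^m`` is the fraction of the ``(N - m)^2`` template pairs whose Chebyshev
    distance is strictly below ``r``, with no baseline removal; likewise
    ``B^{m+1}`` at order ``m + 1``.  When either fraction is zero the statistic
    is undefined and reported as a flagged ``nan`` — with small ``N`` or small
    ``r`` no template of one series may match any template of the other.

    Set ``normalize=True`` to z-score each series first (off by default; the
    tolerance ``r`` is interpreted on the raw series units).
    """
    u, v = _prepare(pair, params, normalize)
    m, r = params.m, params.r
    n_templates = pair.N - m
    X_m = embed_templates(u, m, center=False, count=n_templates)
    Y_m = embed_templates(v, m, center=False, count=n_templates)
    X_m1 = embed_templates(u, m + 1, center=False, count=n_templates)
    Y_m1 = embed_templates(v, m + 1, center=False, count=n_templates)
    b_m = float(np.mean(_pairwise_chebyshev(X_m, Y_m) < r))
    b_m1 = float(np.mean(_pairwise_chebyshev(X_m1, Y_m1) < r))
    defined = b_m > 0.0 and b_m1 > 0.0
    value = -float(np.log(b_m1 / b_m)) if defined else float("nan")
    return CrossEntropyResult(
        measure="csampleen",
        value=value,
        defined=defined,
        phi_m=b_m,
        phi_m1=b_m1,
        m=m,
        r=r,
        n=None,
        N=pair.N,
    )


def cross_fuzzy_entropy(
    pair: TimeSeriesPair,
    params: EntropyParams,
    normalize: bool = False,
) -> CrossEntropyResult:
    """Cross-fuzzy entropy ``-ln(phi^{m+1} / phi^m)``.

    Same averaging structure as :func:`cross_sample_entropy`, but templates are
    baseline-centered (window mean removed) at both orders and similarity is
    the exponential membership ``exp(-d**n / r)``.  Every membership is
    positive, so the result is finite for every valid input.
    """
    u, v = _prepare(pair, params, normalize)
    m, r, n = params.m, params.r, params.n
    n_templates = pair.N - m
    X_m = embed_templates(u, m, center=True, count=n_templates)
    Y_m = embed_templates(v, m, center=True, count=n_templates)
    X_m1 = embed_templates(u, m + 1, center=True, count=n_templates)
    Y_m1 = embed_templates(v, m + 1, center=True, count=n_templates)
    # log-space evaluation: the memberships exp(-d**n/r) underflow for tiny r,
    # but log(phi_m) - log(phi_m1) stays finite, keeping the measure total
    log_w_m = -(_pairwise_chebyshev(X_m, Y_m) ** n) / r
    log_w_m1 = -(_pairwise_chebyshev(X_m1, Y_m1) ** n) / r
    log_phi_m = float(logsumexp(log_w_m) - np.log(log_w_m.size))
    log_phi_m1 = float(logsumexp(log_w_m1) - np.log(log_w_m1.size))
    phi_m = float(np.exp(log_phi_m))
    phi_m1 = float(np.exp(log_phi_m1))
    value = log_phi_m - log_phi_m1
    return CrossEntropyResult(
        measure="cfuzzyen",
        value=value,
        defined=True,
        phi_m=phi_m,
        phi_m1=phi_m1,
        m=m,
        r=r,
        n=n,
        N=pair.N,
    )
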