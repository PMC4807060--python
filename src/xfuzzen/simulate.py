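"""Test-signal generators: i.i.d. uniform noise, MIX(p) processes, and
synthetic left/right stride-interval pairs.

The MIX(p) process interpolates between a pure deterministic sine and pure
noise: a unit-variance sine ``sqrt(2) * sin(2*pi*j / 12)`` has ``round(p * N)``
randomly chosen points replaced by i.i.d. Uniform(-sqrt(3), sqrt(3)) draws
(also unit variance), so larger ``p`` means more disorder at constant variance.

The gait generator is fixture machinery: it emulates paired stride-interval
series with a controllable cross-limb coupling so that "control-like" cohorts
(high coupling) carry low cross-entropy and "PD-like" cohorts (low coupling,
larger variability) carry high cross-entropy, plus injectable turnaround-style
outliers for exercising preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .entropy import TimeSeriesPair
from .gait import GaitRecord

__all__ = [
    "MixParams",
    "SyntheticGaitParams",
    "iid_uniform",
    "mix_sine",
    "mix_process",
    "synthetic_gait_pair",
    "synthetic_cohort",
]

SeedLike = Union[None, int, Sequence[int], np.random.Generator]

MIX_PERIOD = 12
MIX_NOISE_HALF_WIDTH = float(np.sqrt(3.0))  # Uniform(-sqrt3, sqrt3) has unit variance


def _rng(seed: SeedLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class MixParams:
    """MIX(p) parameters: substituted proportion ``p``, length ``n_points``."""

    p: float
    n_points: int
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")


def iid_uniform(
    n: int, seed: SeedLike = None, low: float = 0.0, high: float = 1.0
) -> np.ndarray:
    """``n`` i.i.d. Uniform(low, high) draws (default Uniform(0, 1))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _rng(seed).uniform(low, high, size=n)


def mix_sine(n: int) -> np.ndarray:
    """The deterministic component of MIX: ``sqrt(2)*sin(2*pi*j/12)``, j=1..n."""
    j = np.arange(1, n + 1)
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * j / MIX_PERIOD)


def mix_process(params: MixParams, seed: SeedLike = None) -> np.ndarray:
    """Generate a MIX(p) series.

    ``round(p * N)`` distinct positions of the unit-variance sine are replaced
    with i.i.d. Uniform(-sqrt(3), sqrt(3)) draws.  ``seed`` overrides
    ``params.seed`` when given (handy for sweep drivers that pass a Generator).
    """
    rng = _rng(seed if seed is not None else params.seed)
    n = params.n_points
    x = mix_sine(n)
    k = int(np.rint(params.p * n))
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        x[idx] = rng.uniform(-MIX_NOISE_HALF_WIDTH, MIX_NOISE_HALF_WIDTH, size=k)
    return x


@dataclass(frozen=True)
class SyntheticGaitParams:
    """Knobs of the synthetic stride-interval pair generator.

    ``coupling`` in [0, 1] is the fraction of each limb's fluctuation that is
    shared between limbs; ``noise_sd`` (seconds) scales the stationary SD of
    the fluctuation components; ``outlier_rate`` is the per-point probability
    of a turnaround-style interval inflated by a factor of 2-4.
    """

    n_strides: int = 200
    base_interval: float = 1.1
    coupling: float = 0.9
    noise_sd: float = 0.03
    outlier_rate: float = 0.0
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ValueError("n_strides must be >= 2")
        if self.base_interval <= 0:
            raise ValueError("base_interval must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")


def _ar1(n: int, rng: np.random.Generator, phi: float = 0.9, burn: int = 50) -> np.ndarray:
    """Stationary AR(1) fluctuation with unit marginal variance."""
    innov_sd = np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, size=n + burn)
    x = np.empty(n + burn)
    x[0] = rng.normal(0.0, 1.0)
    for t in range(1, n + burn):
        x[t] = phi * x[t - 1] + e[t]
    return x[burn:]


def synthetic_gait_pair(params: SyntheticGaitParams) -> TimeSeriesPair:
    """Generate a coupled (left, right) stride-interval pair.

    Each limb's series is ``base + coupling*shared + (1-coupling)*own`` where
    ``shared`` and each limb's ``own`` component are smooth AR(1) fluctuations
    with stationary SD ``noise_sd``.  Outliers, when enabled, multiply a point
    by Uniform(2, 4) independently per limb.  High coupling implies strongly
    synchronised limbs (low cross-entropy); low coupling with larger
    ``noise_sd`` emulates asymmetric, more variable gait.
    """
    rng = _rng(params.seed)
    n = params.n_strides
    shared = params.noise_sd * _ar1(n, rng)
    own_left = params.noise_sd * _ar1(n, rng)
    own_right = params.noise_sd * _ar1(n, rng)
    c = params.coupling
    left = params.base_interval + c * shared + (1.0 - c) * own_left
    right = params.base_interval + c * shared + (1.0 - c) * own_right
    if params.outlier_rate > 0:
        for series in (left, right):
            mask = rng.random(n) < params.outlier_rate
            series[mask] *= rng.uniform(2.0, 4.0, size=int(mask.sum()))
    # stride intervals are strictly positive durations
    tiny = 1e-3
    np.clip(left, tiny, None, out=left)
    np.clip(right, tiny, None, out=right)
    return TimeSeriesPair(left, right)


def synthetic_cohort(
    seed: SeedLike = 0,
    n_pd: int = 15,
    n_co: int = 16,
    pd_coupling: float = 0.3,
    co_coupling: float = 0.95,
    pd_noise_sd: float = 0.045,
    co_noise_sd: float = 0.025,
    base_interval: float = 1.1,
    stride_range: tuple[int, int] = (170, 260),
    outlier_rate: float = 0.02,
) -> list[GaitRecord]:
    """A synthetic two-group cohort of paired stride-interval records.

    Defaults mirror the study layout: 15 "PD-like" subjects (weak cross-limb
    coupling, larger stride variability) and 16 "control-like" subjects
    (strong coupling, smaller variability), raw series lengths drawn uniformly
    from ``stride_range``, with a small rate of turnaround outliers so the
    preprocessing step has work to do.
    """
    master = np.random.SeedSequence(
        seed if not isinstance(seed, np.random.Generator) else seed.integers(2**31)
    )
    records: list[GaitRecord] = []
    specs = [("PD", pd_coupling, pd_noise_sd)] * n_pd + [
        ("CO", co_coupling, co_noise_sd)
    ] * n_co
    for child, (group, coupling, noise_sd) in zip(master.spawn(len(specs)), specs):
        rng = np.random.default_rng(child)
        n_strides = int(rng.integers(stride_range[0], stride_range[1] + 1))
        pair = synthetic_gait_pair(
            SyntheticGaitParams(
                n_strides=n_strides,
                base_interval=base_interval,
                coupling=coupling,
                noise_sd=noise_sd,
                outlier_rate=outlier_rate,
                seed=rng,
            )
        )
        idx = len(records) + 1
        records.append(
            GaitRecord(
                subject_id=f"{group.lower()}{idx:02d}",
                group=group,
                left_stride=pair.u,
                right_stride=pair.v,
            )
        )
    return records
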