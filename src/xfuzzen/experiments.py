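"""Monte-Carlo performance experiments for the two cross entropies.

Three experiments probe the estimators' practical behaviour, each repeated 200
times per parameter point with fresh surrogate pairs:

* tolerance sweep  — C-FuzzyEn / C-SampleEn vs r on an (i.i.d. uniform,
  MIX(0.6)) pair, exposing the tolerance floor below which C-SampleEn is
  undefined;
* length sweep     — both measures vs data length N on independent i.i.d.
  uniform pairs at r = 0.3, quantifying the length dependence via the mean of
  the per-N SDs and the SD of the per-N means;
* relative consistency — both measures on the (MIX(0.2), MIX(0.3)) and
  (MIX(0.3), MIX(0.4)) pairs across the full r grid; a measure is relatively
  consistent when the less-disordered pair scores lower at EVERY tolerance.

Undefined C-SampleEn runs are excluded from means/SDs and tracked through
``defined_fraction``.  All sweeps are reproducible bit-for-bit from a master
seed: each (experiment, parameter point, run) gets its own child generator, so
results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .entropy import (
    EntropyParams,
    TimeSeriesPair,
    cross_fuzzy_entropy,
    cross_sample_entropy,
)
from .simulate import MixParams, mix_process

__all__ = [
    "SweepGrid",
    "ConsistencyReport",
    "default_sim_r_grid",
    "r_sweep",
    "length_sweep",
    "length_sweep_summary",
    "relative_consistency",
    "plot_sweep",
]

# experiment tags entering the per-run seed tuple
_TAG_RSWEEP, _TAG_LENSWEEP, _TAG_CONSISTENCY = 1, 2, 3


def default_sim_r_grid() -> np.ndarray:
    """The simulation tolerance grid [0.01:0.01:0.1] followed by [0.11:0.1:1]."""
    return np.concatenate([np.arange(1, 11) * 0.01, 0.11 + 0.1 * np.arange(9)])


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grids for the sweeps (defaults are the study grids)."""

    r_values: np.ndarray = field(default_factory=default_sim_r_grid)
    N_values: tuple[int, ...] = tuple(range(50, 501, 50))
    m_values: tuple[int, ...] = (2, 3)
    runs: int = 200

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=float)
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("r_values must be non-empty, positive, strictly increasing")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        object.__setattr__(self, "r_values", r)


def _summarise(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, sd, defined_fraction) over a run vector with nan = undefined."""
    defined = np.isfinite(values)
    frac = float(defined.mean())
    if not defined.any():
        return float("nan"), float("nan"), frac
    sel = values[defined]
    return float(sel.mean()), float(sel.std(ddof=0)), frac


def _both_measures(pair: TimeSeriesPair, m: int, r: float, n: float = 2.0):
    params = EntropyParams(m=m, r=r, n=n)
    return (
        cross_fuzzy_entropy(pair, params).value,
        cross_sample_entropy(pair, params).value,
    )


# The experiment signals use zero-mean, unit-variance uniforms, the same
# convention as both MIX components, so the absolute tolerance grid spans
# 0.01 .. ~1 series-SD and the C-SampleEn tolerance floor is exercised.
_UNIFORM_HALF_WIDTH = float(np.sqrt(3.0))


def _uniform_pair(N: int, rng: np.random.Generator) -> TimeSeriesPair:
    w = _UNIFORM_HALF_WIDTH
    return TimeSeriesPair(rng.uniform(-w, w, N), rng.uniform(-w, w, N))


def _uniform_vs_mix_pair(N: int, rng: np.random.Generator, p: float = 0.6) -> TimeSeriesPair:
    w = _UNIFORM_HALF_WIDTH
    return TimeSeriesPair(
        rng.uniform(-w, w, N), mix_process(MixParams(p=p, n_points=N), seed=rng)
    )


def _mix_pair(N: int, rng: np.random.Generator, p1: float, p2: float) -> TimeSeriesPair:
    return TimeSeriesPair(
        mix_process(MixParams(p=p1, n_points=N), seed=rng),
        mix_process(MixParams(p=p2, n_points=N), seed=rng),
    )


def r_sweep(
    seed: int,
    N: int = 100,
    m: int = 2,
    grid: Optional[SweepGrid] = None,
    mix_p: float = 0.6,
) -> pd.DataFrame:
    """Tolerance sweep on (i.i.d. Uniform(0,1), MIX(p)) pairs.

    For every r in the grid, ``grid.runs`` fresh pairs are generated and both
    measures computed; one output row per (measure, r) with mean, SD and the
    fraction of runs where the measure was defined.
    """
    grid = grid or SweepGrid()
    rows = []
    for i_r, r in enumerate(grid.r_values):
        fuzzy = np.empty(grid.runs)
        sample = np.empty(grid.runs)
        for run in range(grid.runs):
            rng = np.random.default_rng([seed, _TAG_RSWEEP, i_r, run])
            pair = _uniform_vs_mix_pair(N, rng, p=mix_p)
            fuzzy[run], sample[run] = _both_measures(pair, m, float(r))
        for measure, values in (("cfuzzyen", fuzzy), ("csampleen", sample)):
            mean, sd, frac = _summarise(values)
            rows.append(
                {
                    "measure": measure,
                    "m": m,
                    "r": float(r),
                    "N": N,
                    "pair": f"uniform-mix{mix_p:g}",
                    "mean": mean,
                    "sd": sd,
                    "defined_fraction": frac,
                    "runs": grid.runs,
                }
            )
    return pd.DataFrame(rows)


def length_sweep(
    seed: int,
    r: float = 0.3,
    grid: Optional[SweepGrid] = None,
) -> pd.DataFrame:
    """Data-length sweep on pairs of independent i.i.d. Uniform(0,1) series.

    The same generated pair feeds both measures and every embedding dimension
    in ``grid.m_values``, matching a protocol where the comparison measure is
    "calculated with the same testing process".
    """
    grid = grid or SweepGrid()
    rows = []
    for N in grid.N_values:
        values = {
            (measure, m): np.empty(grid.runs)
            for m in grid.m_values
            for measure in ("cfuzzyen", "csampleen")
        }
        for run in range(grid.runs):
            rng = np.random.default_rng([seed, _TAG_LENSWEEP, N, run])
            pair = _uniform_pair(N, rng)
            for m in grid.m_values:
                f, s = _both_measures(pair, m, r)
                values[("cfuzzyen", m)][run] = f
                values[("csampleen", m)][run] = s
        for (measure, m), vals in values.items():
            mean, sd, frac = _summarise(vals)
            rows.append(
                {
                    "measure": measure,
                    "m": m,
                    "r": r,
                    "N": N,
                    "pair": "uniform-uniform",
                    "mean": mean,
                    "sd": sd,
                    "defined_fraction": frac,
                    "runs": grid.runs,
                }
            )
    return pd.DataFrame(rows)


def length_sweep_summary(
    df: pd.DataFrame,
    min_defined_fraction: float = 0.5,
    N_min: Optional[int] = None,
) -> pd.DataFrame:
    """Aggregate a length sweep into the two stability statistics.

    Per (measure, m): ``mean_of_sd`` — the mean over N of the per-N SDs — and
    ``sd_of_mean`` — the SD across N of the per-N means.  Parameter points
    whose ``defined_fraction`` falls at or below ``min_defined_fraction`` are
    excluded (the undefined-dominated short-length region of C-SampleEn);
    ``N_min`` restricts to N >= N_min on top of that.
    """
    sel = df[df["defined_fraction"] > min_defined_fraction]
    if N_min is not None:
        sel = sel[sel["N"] >= N_min]
    rows = []
    for (measure, m), sub in sel.groupby(["measure", "m"], sort=True):
        rows.append(
            {
                "measure": measure,
                "m": m,
                "mean_of_sd": float(sub["sd"].mean()),
                "sd_of_mean": float(sub["mean"].std(ddof=0)),
                "n_points": int(len(sub)),
                "N_used": tuple(int(x) for x in sub["N"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConsistencyReport:
    """Relative-consistency experiment output.

    ``table`` holds one row per (measure, pair, r); ``verdicts`` maps measure
    -> True when the less-disordered pair's mean is below the more-disordered
    pair's mean at every tolerance where both are defined; ``mean_of_sd`` maps
    (measure, pair) -> the average per-r SD over the defined portion of the
    grid.
    """

    table: pd.DataFrame
    verdicts: dict
    mean_of_sd: dict
    N: int
    runs: int


def relative_consistency(
    seed: int,
    N: int = 100,
    m: int = 2,
    grid: Optional[SweepGrid] = None,
    pair_specs: Sequence[tuple[float, float]] = ((0.2, 0.3), (0.3, 0.4)),
    min_defined_fraction: float = 0.5,
) -> ConsistencyReport:
    """Relative-consistency test on MIX-process pairs.

    ``pair_specs`` orders the pairs from less to more disordered; the verdict
    for a measure is True iff the first pair's mean entropy is strictly below
    the second pair's at every r where both have a defined mean.
    """
    grid = grid or SweepGrid()
    rows = []
    for pair_id, (p1, p2) in enumerate(pair_specs):
        label = f"mix{p1:g}-mix{p2:g}"
        for i_r, r in enumerate(grid.r_values):
            fuzzy = np.empty(grid.runs)
            sample = np.empty(grid.runs)
            for run in range(grid.runs):
                rng = np.random.default_rng([seed, _TAG_CONSISTENCY, pair_id, i_r, run])
                pair = _mix_pair(N, rng, p1, p2)
                fuzzy[run], sample[run] = _both_measures(pair, m, float(r))
            for measure, values in (("cfuzzyen", fuzzy), ("csampleen", sample)):
                mean, sd, frac = _summarise(values)
                rows.append(
                    {
                        "measure": measure,
                        "m": m,
                        "r": float(r),
                        "N": N,
                        "pair": label,
                        "mean": mean,
                        "sd": sd,
                        "defined_fraction": frac,
                        "runs": grid.runs,
                    }
                )
    table = pd.DataFrame(rows)
    labels = [f"mix{p1:g}-mix{p2:g}" for p1, p2 in pair_specs]
    verdicts = {}
    mean_of_sd = {}
    for measure in ("cfuzzyen", "csampleen"):
        sub = table[table["measure"] == measure]
        a = sub[sub["pair"] == labels[0]].set_index("r")
        b = sub[sub["pair"] == labels[1]].set_index("r")
        both = (a["defined_fraction"] > 0) & (b["defined_fraction"] > 0)
        verdicts[measure] = bool(
            both.any() and (a.loc[both, "mean"] < b.loc[both, "mean"]).all()
        )
        for label in labels:
            s = sub[sub["pair"] == label]
            ok = s["defined_fraction"] > min_defined_fraction
            mean_of_sd[(measure, label)] = (
                float(s.loc[ok, "sd"].mean()) if ok.any() else float("nan")
            )
    return ConsistencyReport(
        table=table, verdicts=verdicts, mean_of_sd=mean_of_sd, N=N, runs=grid.runs
    )


def plot_sweep(df: pd.DataFrame, x: str = "r", ax=None, logx: bool = False):
    """Basic mean +/- SD errorbar plot of a sweep table, one line per
    (measure, pair) combination present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (measure, pair), sub in df.groupby(["measure", "pair"]):
        sub = sub[sub["defined_fraction"] > 0]
        ax.errorbar(
            sub[x], sub["mean"], yerr=sub["sd"], label=f"{measure} ({pair})",
            marker="o", capsize=2, markersize=3, linestyle="-",
        )
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel("cross entropy (nats)")
    ax.legend(fontsize=8)
    return ax
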