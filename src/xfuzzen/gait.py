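"""Gait symmetry pipeline: stride-interval readers, turnaround-outlier
removal, per-subject symmetry features (C-FuzzyEn, C-SampleEn, ASI) and the
tolerance-selection screen based on the Mann-Whitney U test.

The feature extraction mirrors the standard bilateral workflow: each subject
contributes a left and a right stride-interval series; after outlier removal
both series are truncated to a fixed analysis length ``N_use`` (default 150)
and the cross entropies are computed on the (left, right) pair with embedding
dimension m = 1, the choice appropriate for short physiological series.  The
absolute symmetry index

    ASI = 100 * (T_R - T_L) / (0.5 * (T_R + T_L))

is computed from a per-limb scalar feature T, here the mean stride interval
over the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import (
    CrossEntropyResult,
    EntropyParams,
    TimeSeriesPair,
    cross_fuzzy_entropy,
    cross_sample_entropy,
)

__all__ = [
    "GaitRecord",
    "SymmetryFeatures",
    "read_gait_file",
    "remove_outliers",
    "remove_outliers_paired",
    "asi",
    "symmetry_features",
    "feature_table",
    "select_r",
    "default_gait_r_grid",
    "mann_whitney_u",
    "min_max_normalize",
]

#: Screening grid for the entropy tolerance on stride-interval data (seconds):
#: [0.0001 : 0.0001 : 0.001] followed by [0.002 : 0.001 : 0.01].
GAIT_R_GRID_FINE = np.concatenate(
    [np.arange(1, 11) * 1e-4, np.arange(2, 11) * 1e-3]
)
#: Optional coarse tail [0.02 : 0.01 : 0.1] for wider screens.
GAIT_R_GRID_COARSE_TAIL = np.arange(2, 11) * 1e-2


def default_gait_r_grid(include_coarse_tail: bool = False) -> np.ndarray:
    grid = GAIT_R_GRID_FINE
    if include_coarse_tail:
        grid = np.concatenate([grid, GAIT_R_GRID_COARSE_TAIL])
    return grid.copy()


@dataclass
class GaitRecord:
    """One subject's paired stride-interval series (seconds)."""

    subject_id: str
    group: str
    left_stride: np.ndarray
    right_stride: np.ndarray

    def __post_init__(self) -> None:
        self.left_stride = np.asarray(self.left_stride, dtype=float)
        self.right_stride = np.asarray(self.right_stride, dtype=float)
        if self.left_stride.size != self.right_stride.size:
            raise ValueError(
                f"{self.subject_id}: left/right series lengths differ "
                f"({self.left_stride.size} vs {self.right_stride.size})"
            )

    @property
    def n_strides(self) -> int:
        return self.left_stride.size


@dataclass(frozen=True)
class SymmetryFeatures:
    """Per-subject symmetry features feeding the statistics and the classifier."""

    subject_id: str
    group: str
    cfuzzyen: float
    csampleen: float          # nan when undefined
    csampleen_defined: bool
    asi: float                # percent
    T_L: float                # mean left stride interval (s) over the window
    T_R: float                # mean right stride interval (s) over the window
    n_used: int
    n_outliers_removed: int

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "cfuzzyen": self.cfuzzyen,
            "csampleen": self.csampleen,
            "csampleen_defined": self.csampleen_defined,
            "asi": self.asi,
            "T_L": self.T_L,
            "T_R": self.T_R,
            "n_used": self.n_used,
            "n_outliers_removed": self.n_outliers_removed,
        }


def read_gait_file(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, Union[int, str]]] = None,
    subject_id: Optional[str] = None,
    group: str = "",
) -> GaitRecord:
    """Read a multicolumn gait-rhythm text file into a :class:`GaitRecord`.

    ``column_map`` names the left- and right-stride columns, either by 0-based
    position or by header name, e.g. ``{"left": 1, "right": 2}`` — the default,
    matching the common gait-rhythm layout (elapsed time, left stride, right
    stride, ...).  Trailing missing values are trimmed so both series end up
    with the common length.
    """
    path = Path(path)
    if column_map is None:
        column_map = {"left": 1, "right": 2}
    if path.stat().st_size == 0 or not path.read_text().strip():
        raise ValueError(f"{path}: file is empty")
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    # promote a header row if the first row is non-numeric
    first = df.iloc[0]
    if not all(_is_number(x) for x in first):
        df.columns = [str(c).strip() for c in first]
        df = df.iloc[1:].reset_index(drop=True)

    def pick(which: str) -> pd.Series:
        key = column_map[which]
        if isinstance(key, int):
            if key >= df.shape[1]:
                raise ValueError(
                    f"{path}: {which} column index {key} out of range "
                    f"(file has {df.shape[1]} columns)"
                )
            col = df.iloc[:, key]
        else:
            if key not in df.columns:
                raise ValueError(f"{path}: no column named {key!r}")
            col = df[key]
        values = pd.to_numeric(col, errors="coerce")
        if values.notna().sum() == 0:
            raise ValueError(f"{path}: {which} column contains no numeric data")
        bad = values.isna() & col.notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric cell in {which} column at row {int(bad.idxmax())}"
            )
        return values

    left = pick("left").to_numpy(dtype=float)
    right = pick("right").to_numpy(dtype=float)
    n = min(_trimmed_length(left), _trimmed_length(right))
    if n == 0:
        raise ValueError(f"{path}: no numeric rows found")
    return GaitRecord(
        subject_id=subject_id or path.stem,
        group=group,
        left_stride=left[:n],
        right_stride=right[:n],
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _trimmed_length(values: np.ndarray) -> int:
    finite = np.isfinite(values)
    return int(np.max(np.nonzero(finite)[0]) + 1) if finite.any() else 0


def remove_outliers(
    series: np.ndarray, n_sd: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop points outside ``median +/- n_sd * SD`` of the series.

    Emulates the turnaround preprocessing applied to hallway gait recordings:
    strides spanning the turn at the end of the walkway are grossly inflated
    and sit far outside the bulk of the distribution.  The median centre keeps
    the rule robust to the outliers themselves; the SD is computed over the
    full series.

    Returns ``(kept_values_in_order, removed_indices)``.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 10:
        raise ValueError("series too short to estimate spread (need >= 10 points)")
    centre = np.median(arr)
    spread = arr.std()
    keep = np.abs(arr - centre) <= n_sd * spread
    return arr[keep], np.nonzero(~keep)[0]


def remove_outliers_paired(
    left: np.ndarray, right: np.ndarray, n_sd: float = 3.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outlier removal that preserves left/right pairing.

    Each side's outlier indices are found with :func:`remove_outliers`'s rule
    and the union of indices is dropped from BOTH series, so stride ``i`` on
    the left always remains paired with stride ``i`` on the right.  Returns
    ``(left_clean, right_clean, removed_indices)``.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ValueError("left and right series must have equal length")
    _, bad_left = remove_outliers(left, n_sd=n_sd)
    _, bad_right = remove_outliers(right, n_sd=n_sd)
    bad = np.union1d(bad_left, bad_right)
    keep = np.setdiff1d(np.arange(left.size), bad)
    return left[keep], right[keep], bad


def asi(T_L: float, T_R: float) -> float:
    """Absolute symmetry index, percent: ``100*(T_R - T_L)/(0.5*(T_R + T_L))``."""
    return 100.0 * (T_R - T_L) / (0.5 * (T_R + T_L))


def symmetry_features(
    record: GaitRecord,
    params: Optional[EntropyParams] = None,
    N_use: int = 150,
    preprocess: bool = True,
    n_sd: float = 3.0,
) -> SymmetryFeatures:
    """Extract the per-subject symmetry features.

    After (optional) paired outlier removal both series are truncated to their
    first ``N_use`` points; C-FuzzyEn and C-SampleEn are computed on the
    (left, right) pair and ASI from the per-side mean stride interval over the
    same window.  A subject left with fewer than ``N_use`` strides fails
    loudly rather than silently analysing a shorter window.
    """
    if params is None:
        params = EntropyParams(m=1, r=0.004, n=2.0)
    if preprocess:
        left, right, removed = remove_outliers_paired(
            record.left_stride, record.right_stride, n_sd=n_sd
        )
    else:
        left, right = record.left_stride, record.right_stride
        removed = np.array([], dtype=int)
    if left.size < N_use:
        raise ValueError(
            f"subject {record.subject_id}: only {left.size} strides remain after "
            f"preprocessing but N_use={N_use}"
        )
    left = left[:N_use]
    right = right[:N_use]
    pair = TimeSeriesPair(left, right)
    fuzzy = cross_fuzzy_entropy(pair, params)
    sample = cross_sample_entropy(pair, params)
    T_L = float(left.mean())
    T_R = float(right.mean())
    return SymmetryFeatures(
        subject_id=record.subject_id,
        group=record.group,
        cfuzzyen=fuzzy.value,
        csampleen=sample.value,
        csampleen_defined=sample.defined,
        asi=asi(T_L, T_R),
        T_L=T_L,
        T_R=T_R,
        n_used=N_use,
        n_outliers_removed=int(removed.size),
    )


def feature_table(
    records: Iterable[GaitRecord],
    params: Optional[EntropyParams] = None,
    N_use: int = 150,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Per-subject feature table (one row per record)."""
    rows = [
        symmetry_features(rec, params=params, N_use=N_use, preprocess=preprocess).to_dict()
        for rec in records
    ]
    return pd.DataFrame(rows)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have at most 8 values and no ties span
    the groups; otherwise the tie-corrected normal approximation.  Returns
    ``(U, p)`` with U oriented as the number of (a, b) pairs with a > b
    (plus half-ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= 8 and b.size <= 8
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def select_r(
    records: Sequence[GaitRecord],
    r_grid: Optional[np.ndarray] = None,
    m: int = 1,
    n: float = 2.0,
    N_use: int = 150,
    preprocess: bool = True,
    positive_group: str = "PD",
) -> tuple[float, pd.DataFrame]:
    """Screen the tolerance grid for the r giving the best group separation.

    For each candidate ``r`` the per-subject C-FuzzyEn is computed and the two
    groups compared with a two-sided Mann-Whitney U test; the returned
    ``best_r`` minimises the p-value.  The full table (r, U, p-value, group
    means) is returned alongside for inspection.
    """
    if r_grid is None:
        r_grid = default_gait_r_grid()
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ValueError("r_grid must be non-empty")
    groups = pd.Series([rec.group for rec in records])
    counts = groups.value_counts()
    if counts.size != 2:
        raise ValueError(f"expected exactly two groups, found {list(counts.index)}")
    if counts.min() < 3:
        raise ValueError("each group needs at least 3 subjects for the screen")

    # prepare each subject's analysis window once; sweep r over the same windows
    pairs = []
    for rec in records:
        if preprocess:
            left, right, _ = remove_outliers_paired(rec.left_stride, rec.right_stride)
        else:
            left, right = rec.left_stride, rec.right_stride
        if left.size < N_use:
            raise ValueError(
                f"subject {rec.subject_id}: fewer than N_use={N_use} strides remain"
            )
        pairs.append((rec.group, TimeSeriesPair(left[:N_use], right[:N_use])))

    rows = []
    for r in r_grid:
        params = EntropyParams(m=m, r=float(r), n=n)
        values = {
            g: [
                cross_fuzzy_entropy(pair, params).value
                for grp, pair in pairs
                if grp == g
            ]
            for g in counts.index
        }
        pos = positive_group if positive_group in values else counts.index[0]
        neg = [g for g in counts.index if g != pos][0]
        U, p = mann_whitney_u(values[pos], values[neg])
        rows.append(
            {
                "r": float(r),
                "U": U,
                "p_value": p,
                f"mean_{pos}": float(np.mean(values[pos])),
                f"mean_{neg}": float(np.mean(values[neg])),
            }
        )
    table = pd.DataFrame(rows)
    best_r = float(table.loc[table["p_value"].idxmin(), "r"])
    return best_r, table


def min_max_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1] via ``(x - min) / (max - min)`` (display helper)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("all values identical: zero range")
    return (arr - lo) / (hi - lo)
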