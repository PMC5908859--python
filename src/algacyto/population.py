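"""Population-structure statistics over per-cell measurements.

Per-cell values are put on a *relative* scale by dividing each parameter by
its mean over the snapshot (one timepoint x condition), yielding the five
dimensionless columns used throughout:

====  =================================  ==============
RCS   relative cellular size             pixel_count
RCCA  relative cellular chl amount       chl_amount
RCLA  relative cellular lipid amount     lipid_amount
RCCD  relative cellular chl density      chl_density
RCLD  relative cellular lipid density    lipid_density
====  =================================  ==============

Association between parameters is summarized by Spearman's rank correlation
(mid-ranks for ties), cell-to-cell heterogeneity by the coefficient of
variation, and lipid accumulation across a time course by *transition
states*: bands of absolute lipid density defined as fold multiples of the
day-0 (baseline) population level.  States use absolute densities, not the
per-snapshot relative RCLD — each snapshot renormalizes to mean 1, so a
relative scale could not be anchored to day 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AnalysisError,
    DegenerateScaleError,
    GroupingError,
    UndefinedCorrelationError,
)
from .quantify import CellRecord, records_to_frame

__all__ = [
    "RELATIVE_COLUMNS",
    "PopulationSnapshot",
    "TransitionStateModel",
    "relativize",
    "build_snapshot",
    "spearman_rho",
    "heterogeneity",
    "fit_transition_model",
    "assign_states",
    "correlation_matrix",
]

#: relative column -> source per-cell measurement
RELATIVE_COLUMNS = {
    "RCS": "pixel_count",
    "RCCA": "chl_amount",
    "RCLA": "lipid_amount",
    "RCCD": "chl_density",
    "RCLD": "lipid_density",
}


def relativize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Divide each value by the snapshot mean; the output has mean 1."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise DegenerateScaleError("cannot relativize an empty vector")
    mean = v.mean()
    if mean <= 0:
        raise DegenerateScaleError(f"non-positive mean {mean}")
    return v / mean


@dataclasses.dataclass
class PopulationSnapshot:
    """All cells of one timepoint/condition with their relative columns."""

    frame: pd.DataFrame
    timepoint: float
    condition: str

    @property
    def n(self) -> int:
        return len(self.frame)


def build_snapshot(records: Iterable[CellRecord] | pd.DataFrame) -> PopulationSnapshot:
    """Attach RCS/RCCA/RCLA/RCCD/RCLD columns to one timepoint's records.

    All records must share timepoint and condition.  A parameter whose
    snapshot mean is zero (e.g. a completely unstained lipid channel) gets a
    NaN relative column and a warning instead of failing the whole snapshot.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise GroupingError("cannot build a snapshot from zero records")
    for key in ("timepoint", "condition"):
        if frame[key].nunique() > 1:
            raise GroupingError(
                f"records mix several values of {key}: {sorted(frame[key].unique())}"
            )
    frame = frame.reset_index(drop=True).copy()
    for rel_col, src_col in RELATIVE_COLUMNS.items():
        try:
            frame[rel_col] = relativize(frame[src_col].to_numpy())
        except DegenerateScaleError:
            warnings.warn(f"{src_col}: zero snapshot mean, {rel_col} set to NaN",
                          stacklevel=2)
            frame[rel_col] = np.nan
    return PopulationSnapshot(
        frame=frame,
        timepoint=float(frame["timepoint"].iloc[0]),
        condition=str(frame["condition"].iloc[0]),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Undefined (raises) when either vector has
    zero rank variance or fewer than 3 observations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError("constant ranks in one of the vectors")
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def heterogeneity(values: Sequence[float]) -> float:
    """Cell-to-cell heterogeneity as coefficient of variation (sample SD / mean).

    Dimensionless, hence comparable across parameters and timepoints; scale
    invariant: CV(k*v) == CV(v) for k > 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise DegenerateScaleError("need at least 2 observations for a CV")
    mean = v.mean()
    if mean <= 0:
        raise DegenerateScaleError(f"non-positive mean {mean}")
    return float(v.std(ddof=1) / mean)


@dataclasses.dataclass
class TransitionStateModel:
    """Baseline-anchored fold-change bands over absolute lipid density.

    ``thresholds[i] = baseline_level * folds[i]`` partition [0, inf) into
    ``len(folds) + 1`` states.  A cell exactly at a threshold belongs to the
    higher state.
    """

    baseline_level: float
    folds: tuple[float, ...]
    thresholds: np.ndarray
    state_labels: tuple[str, ...]
    baseline_stat: str = "median"

    def assign(self, lipid_densities: Sequence[float]) -> np.ndarray:
        """State index (0 = start band) per cell; boundary goes to the higher state."""
        d = np.asarray(lipid_densities, dtype=np.float64)
        return np.searchsorted(self.thresholds, d, side="right")


def _state_labels(folds: Sequence[float]) -> tuple[str, ...]:
    return ("Start-RCLD",) + tuple(f"{f:g}-fold" for f in folds)


def fit_transition_model(
    baseline: PopulationSnapshot,
    folds: Sequence[float] = (2.0, 10.0),
    baseline_stat: str = "median",
) -> TransitionStateModel:
    """Anchor fold-change bands to the day-0 population's lipid density.

    The baseline level is the median (robust to the heavy right tail already
    present at day 0) or, if configured, the mean of the baseline snapshot's
    absolute lipid densities.
    """
    folds = tuple(float(f) for f in folds)
    if not folds or any(f <= 1 for f in folds) or any(
        b <= a for a, b in zip(folds, folds[1:])
    ):
        raise ValueError(f"folds must be strictly increasing and all > 1, got {folds}")
    if baseline.n == 0:
        raise AnalysisError("empty baseline snapshot")
    dens = baseline.frame["lipid_density"].to_numpy(dtype=np.float64)
    if baseline_stat == "median":
        level = float(np.median(dens))
    elif baseline_stat == "mean":
        level = float(dens.mean())
    else:
        raise ValueError("baseline_stat must be 'median' or 'mean'")
    if level <= 0:
        raise AnalysisError("baseline lipid density level is non-positive")
    return TransitionStateModel(
        baseline_level=level,
        folds=folds,
        thresholds=level * np.asarray(folds),
        state_labels=_state_labels(folds),
        baseline_stat=baseline_stat,
    )


def assign_states(
    model: TransitionStateModel,
    snapshot: PopulationSnapshot | Sequence[float],
) -> pd.Series:
    """Fraction of cells per transition state (sums to 1).

    Accepts a snapshot or a bare vector of absolute lipid densities.
    """
    if isinstance(snapshot, PopulationSnapshot):
        dens = snapshot.frame["lipid_density"].to_numpy(dtype=np.float64)
    else:
        dens = np.asarray(snapshot, dtype=np.float64)
    if dens.size == 0:
        raise AnalysisError("cannot assign states for an empty snapshot")
    idx = model.assign(dens)
    counts = np.bincount(idx, minlength=len(model.state_labels))
    return pd.Series(counts / dens.size, index=list(model.state_labels), name="fraction")


def correlation_matrix(snapshot: PopulationSnapshot) -> pd.DataFrame:
    """Pairwise Spearman table over {RCS, RCCA, RCLA, RCCD, RCLD}.

    Symmetric with unit diagonal.  Relative columns share ranks with their
    source measurements, so this equals the raw-parameter correlation table.
    """
    cols = list(RELATIVE_COLUMNS)
    n = len(cols)
    mat = np.eye(n)
    data = {c: snapshot.frame[c].to_numpy(dtype=np.float64) for c in cols}
    for i in range(n):
        for j in range(i + 1, n):
            rho = spearman_rho(data[cols[i]], data[cols[j]])
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=cols, columns=cols)
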