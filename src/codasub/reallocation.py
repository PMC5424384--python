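"""Compositional isotemporal substitution.

A fixed duration is moved from one behaviour to another while the
remaining behaviours are held constant, keeping the 24-h total intact;
the fitted ilr model then predicts the outcome for the original and the
reallocated composition, and the difference between the two predictions
is the substitution estimate.  Unlike traditional isotemporal
substitution the result depends on the baseline composition, and moves
in opposite directions are not mirror images (moving 15 min out of a
26-min MVPA budget is a far larger relative change than moving 15 min
into a 510-min sedentary budget).

Grids follow the convention that rows receive time and columns donate
it.  Confidence intervals come from the delta method on the coefficient
covariance; since the move only changes the ilr block, the contrast
vector is zero on every covariate column and the interval is
profile-independent, like the difference itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .composition import Composition, CompositionError, compositional_mean
from .model import IlrLinearModel

__all__ = [
    "Reallocation",
    "ReallocationResult",
    "InfeasibleReallocation",
    "reallocate",
    "predicted_difference",
    "difference_grid",
    "grid_table",
    "group_baseline_grids",
    "DEFAULT_DURATIONS",
    "FINE_DURATIONS",
]

#: Main-grid durations in minutes (0 to 25 in 5-min steps).
DEFAULT_DURATIONS: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
#: Fine grid in 2.5-min steps.
FINE_DURATIONS: tuple[float, ...] = tuple(np.arange(0.0, 25.01, 2.5))


class InfeasibleReallocation(ValueError):
    """Requested move exceeds the minutes available in the donor part."""


@dataclass(frozen=True)
class Reallocation:
    """Move ``minutes`` from ``from_part`` to ``to_part``."""

    from_part: str
    to_part: str
    minutes: float

    def __post_init__(self) -> None:
        if self.from_part == self.to_part:
            raise ValueError("from_part and to_part must differ")
        if self.minutes < 0:
            raise ValueError(f"minutes must be nonnegative, got {self.minutes}")


@dataclass(frozen=True)
class ReallocationResult:
    """Predicted outcome difference for one substitution around a baseline."""

    baseline: Composition
    reallocation: Reallocation
    outcome: str
    difference: float
    se: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "from": self.reallocation.from_part,
            "to": self.reallocation.to_part,
            "minutes": self.reallocation.minutes,
            "outcome": self.outcome,
            "difference": self.difference,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def reallocate(baseline: Composition, r: Reallocation) -> Composition:
    """Construct the reallocated composition.

    The donor part loses exactly ``r.minutes``, the receiver gains
    exactly the same, every other part is untouched, so the total is
    preserved bit-for-bit.
    """
    for part in (r.from_part, r.to_part):
        if part not in baseline.parts:
            raise CompositionError(f"unknown part {part!r}; parts: {baseline.parts}")
    available = baseline[r.from_part]
    if r.minutes >= available:
        raise InfeasibleReallocation(
            f"cannot move {r.minutes:g} min out of {r.from_part!r}: only "
            f"{available:g} min available (strict positivity required)"
        )
    return baseline.replace(**{
        r.from_part: baseline[r.from_part] - r.minutes,
        r.to_part: baseline[r.to_part] + r.minutes,
    })


def predicted_difference(model: IlrLinearModel, baseline: Composition,
                         r: Reallocation, outcome: str = "",
                         alpha: float = 0.05) -> ReallocationResult:
    """Predicted outcome difference (reallocated minus baseline).

    Exactly zero when ``r.minutes == 0``.  The delta-method standard
    error uses the coefficient covariance; with a linear model and a
    contrast touching only the ilr block it is exact and
    profile-independent.
    """
    if r.minutes == 0:
        return ReallocationResult(baseline, r, outcome, 0.0, 0.0, 0.0, 0.0)
    new = reallocate(baseline, r)
    row_base = model.profile_row(baseline)
    row_new = model.profile_row(new)
    contrast = row_new - row_base
    params = model.results_.params.to_numpy()
    diff = float(contrast @ params)
    cov = np.asarray(model.results_.cov_params())
    se = float(np.sqrt(contrast @ cov @ contrast))
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, model.resid_df_)
    return ReallocationResult(baseline, r, outcome, diff, se,
                              diff - tcrit * se, diff + tcrit * se)


def difference_grid(model: IlrLinearModel, baseline: Composition,
                    durations: Sequence[float] = DEFAULT_DURATIONS,
                    pairs: Iterable[tuple[str, str]] | None = None,
                    outcome: str = "") -> pd.DataFrame:
    """Tidy table of predicted differences over (pair, duration) cells.

    One row per ordered pair and duration.  Zero-duration rows are
    exactly zero; infeasible cells (duration >= donor minutes) are kept
    with ``NaN`` difference and ``feasible=False`` rather than raising,
    so a full grid can always be written.
    """
    if pairs is None:
        pairs = [(a, b) for a in baseline.parts for b in baseline.parts if a != b]
    rows = []
    for from_part, to_part in pairs:
        for t in durations:
            r = Reallocation(from_part, to_part, float(t))
            try:
                res = predicted_difference(model, baseline, r, outcome)
                rows.append({**res.to_dict(), "feasible": True})
            except InfeasibleReallocation:
                rows.append({"from": from_part, "to": to_part, "minutes": float(t),
                             "outcome": outcome, "difference": np.nan, "se": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "feasible": False})
    return pd.DataFrame(rows)


def grid_table(model: IlrLinearModel, baseline: Composition,
               minutes: float = 15.0, outcome: str = "") -> pd.DataFrame:
    """Square substitution table for one duration.

    Rows are the behaviour receiving time, columns the behaviour
    donating it; the diagonal is empty.
    """
    parts = baseline.parts
    tab = pd.DataFrame(np.nan, index=list(parts), columns=list(parts))
    tab.index.name = "receives"
    tab.columns.name = "donates"
    for donor in parts:
        for receiver in parts:
            if donor == receiver:
                continue
            try:
                res = predicted_difference(
                    model, baseline, Reallocation(donor, receiver, minutes), outcome)
                tab.loc[receiver, donor] = res.difference
            except InfeasibleReallocation:
                pass
    return tab


def group_baseline_grids(model: IlrLinearModel, records: pd.DataFrame,
                         group_col: str = "weight_status",
                         durations: Sequence[float] = DEFAULT_DURATIONS,
                         parts: Sequence[str] | None = None,
                         outcome: str = "",
                         kappa: float | None = None) -> dict[str, pd.DataFrame]:
    """Substitution grids around each group's own compositional mean.

    The model is shared (fitted on everyone); only the baseline moves.
    Because substitution estimates are baseline-dependent, groups with
    different mean compositions get different grids from the same model.
    """
    parts = tuple(parts) if parts is not None else tuple(model.parts)
    if kappa is None:
        kappa = 1440.0
    grids: dict[str, pd.DataFrame] = {}
    for group, sub in records.groupby(group_col, observed=True, sort=False):
        if len(sub) == 0:
            continue
        baseline = compositional_mean(sub[list(parts)].to_numpy(dtype=float),
                                      kappa=kappa, parts=parts)
        grid = difference_grid(model, baseline, durations, outcome=outcome)
        grid.insert(0, "group", group)
        grids[str(group)] = grid
    return grids
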