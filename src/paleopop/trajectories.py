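"""Effective-population-size trajectories on a calendar (CE) time axis.

An :class:`NeTrajectory` is the ground truth of the synthetic studies and
the estimand of skyline inference: a strictly positive function of calendar
time, evaluated in units of effective individuals.  Four functional forms
are supported:

``constant``
    Ne(t) = base_ne.
``exponential``
    Ne(t) = base_ne * fold_change ** ((t - breakpoint_date) / tau), a
    convenience form for growth at a constant per-year rate; ``steepness``
    is the per-year log growth rate.
``piecewise_constant``
    Step function through user-supplied (date, Ne) knots; the value before
    the first knot is the first Ne, afterwards the last.
``sigmoidal_breakpoint``
    Logistic increase from base_ne to base_ne * fold_change centred on
    ``breakpoint_date``:

        Ne(t) = base_ne * (1 + (fold_change - 1) / (1 + exp(-s (t - b))))

    with steepness ``s`` (1/yr) and breakpoint ``b`` (CE).  The midpoint
    of the rise sits exactly at the breakpoint date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NeTrajectory", "make_ne_trajectory"]

_KINDS = ("constant", "exponential", "piecewise_constant", "sigmoidal_breakpoint")


@dataclass(frozen=True)
class NeTrajectory:
    """Deterministic Ne as a function of calendar date (CE years).

    Instances are callable: ``traj(dates)`` evaluates Ne at scalar or array
    dates and always returns strictly positive values.
    """

    kind: str
    base_ne: float = 1000.0
    fold_change: float = 1.0
    breakpoint_date: float = 1784.0
    steepness: float = 0.1
    grid: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}; expected one of {_KINDS}")
        if not self.base_ne > 0:
            raise ValueError(f"base_ne must be > 0, got {self.base_ne}")
        if self.fold_change < 0:
            raise ValueError(f"fold_change must be >= 0, got {self.fold_change}")
        if self.kind == "piecewise_constant":
            if len(self.grid) < 1:
                raise ValueError("piecewise_constant requires at least one (date, Ne) knot")
            dates = [d for d, _ in self.grid]
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValueError("piecewise knots must be strictly increasing in date")
            if any(ne <= 0 for _, ne in self.grid):
                raise ValueError("piecewise Ne values must be > 0")
        if self.kind == "sigmoidal_breakpoint" and self.fold_change * self.base_ne <= 0:
            raise ValueError("sigmoidal trajectory would reach Ne <= 0")

    def __call__(self, dates):
        t = np.asarray(dates, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.base_ne, dtype=float)
        elif self.kind == "exponential":
            out = self.base_ne * np.exp(self.steepness * (t - self.breakpoint_date))
        elif self.kind == "piecewise_constant":
            knot_dates = np.array([d for d, _ in self.grid])
            knot_ne = np.array([ne for _, ne in self.grid])
            idx = np.clip(np.searchsorted(knot_dates, t, side="right") - 1, 0, len(knot_ne) - 1)
            out = knot_ne[idx]
        else:  # sigmoidal_breakpoint
            z = -self.steepness * (t - self.breakpoint_date)
            # clip keeps exp() finite for extreme dates; the limit values are exact
            sig = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
            out = self.base_ne * (1.0 + (self.fold_change - 1.0) * sig)
        if np.ndim(dates) == 0:
            return float(out)
        return out


def make_ne_trajectory(
    kind: str,
    base_ne: float = 1000.0,
    fold_change: float = 1.0,
    breakpoint_date: float = 1784.0,
    steepness: float = 0.1,
    grid: Sequence[tuple[float, float]] | None = None,
) -> NeTrajectory:
    """Build an :class:`NeTrajectory`.

    Parameters
    ----------
    kind
        One of ``constant``, ``exponential``, ``piecewise_constant``,
        ``sigmoidal_breakpoint``.
    base_ne
        Effective size before the increase (must be > 0).
    fold_change
        Ratio of late to early Ne for the sigmoidal form.
    breakpoint_date
        Calendar year (CE) at the centre of the sigmoidal rise.
    steepness
        Logistic rate (1/yr) for the sigmoidal form; log growth rate for
        the exponential form.
    grid
        (date, Ne) knots for the piecewise-constant form.
    """
    return NeTrajectory(
        kind=kind,
        base_ne=float(base_ne),
        fold_change=float(fold_change),
        breakpoint_date=float(breakpoint_date),
        steepness=float(steepness),
        grid=tuple((float(d), float(n)) for d, n in (grid or ())),
    )
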