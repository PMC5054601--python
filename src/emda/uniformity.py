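"""Coverage-uniformity statistics: Lorenz curve, Gini coefficient, CV.

The Lorenz curve plots the cumulative fraction of mapped bases against the
cumulative fraction of genome positions, positions sorted by ascending
depth; a perfectly uniform coverage is the diagonal.  By default the
x-axis runs over the covered positions only (``basis="covered_only"``),
since breadth is reported separately; ``basis="whole_genome"`` includes
zero-depth positions.

The Gini coefficient is computed from the area between the diagonal and
the curve using the Riemann middle sum over the curve's points — exact for
a piecewise-linear curve.  Two scales are offered: ``standard`` returns
2 x area (range [0, 1], the conventional Gini), ``area`` returns the raw
area (range [0, 0.5]).  The conventional scale is the default; see the
methods note for why both exist.

The coefficient of variation is the population standard deviation of
per-position depth divided by the mean, over the whole genome including
zero-depth positions, as a percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import DepthVector, breadth

__all__ = [
    "LorenzCurve",
    "UniformityStats",
    "UndefinedStatisticError",
    "lorenz_curve",
    "gini",
    "coefficient_of_variation",
    "uniformity_report",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this depth vector (e.g. all zeros)."""


@dataclass
class LorenzCurve:
    """Piecewise-linear cumulative-coverage curve from (0,0) to (1,1)."""

    x: np.ndarray  # cumulative genome fraction, increasing, starts at 0
    y: np.ndarray  # cumulative mapped-base fraction, increasing, starts at 0
    basis: str  # {"covered_only", "whole_genome"}


@dataclass(frozen=True)
class UniformityStats:
    """The three per-genome coverage-uniformity columns."""

    breadth_percent: float
    cv_percent: float
    gini: float


def lorenz_curve(depth: DepthVector, basis: str = "covered_only") -> LorenzCurve:
    """Lorenz curve of per-position depth, sorted ascending.

    ``x_i = i / N`` and ``y_i = (sum of the i smallest depths) / (total)``,
    with the implicit origin (0, 0) included; the final point is exactly
    (1, 1).
    """
    if basis not in ("covered_only", "whole_genome"):
        raise ValueError(f"unknown basis {basis!r}")
    d = depth.depth
    if basis == "covered_only":
        d = d[d > 0]
    if d.size == 0 or d.sum() == 0:
        raise UndefinedStatisticError(
            f"Lorenz curve undefined: no covered positions on {depth.genome_id!r}"
        )
    d = np.sort(d, kind="stable")
    total = float(d.sum())
    n = d.size
    x = np.concatenate(([0.0], np.arange(1, n + 1) / n))
    y = np.concatenate(([0.0], np.cumsum(d) / total))
    y[-1] = 1.0  # pin against floating-point drift
    return LorenzCurve(x=x, y=y, basis=basis)


def gini(curve: LorenzCurve, scale: str = "standard") -> float:
    """Gini coefficient from the area between the diagonal and the curve.

    The area under the curve is the Riemann middle sum over consecutive
    points, sum of (x_{i+1}-x_i) * (y_i+y_{i+1})/2, which is exact for the
    piecewise-linear Lorenz polyline.  ``standard`` scales the between-area
    by 2 (Gini in [0, 1]); ``area`` returns it raw (in [0, 0.5]).
    """
    if scale not in ("standard", "area"):
        raise ValueError(f"unknown scale {scale!r}")
    x, y = curve.x, curve.y
    if np.any(np.diff(x) < 0) or np.any(np.diff(y) < -1e-12):
        raise ValueError("Lorenz curve must be nondecreasing in x and y")
    area_under = float(np.sum(np.diff(x) * (y[:-1] + y[1:]) / 2.0))
    area_between = 0.5 - area_under
    return 2.0 * area_between if scale == "standard" else area_between


def coefficient_of_variation(depth: DepthVector) -> float:
    """Population SD of per-position depth / mean depth, as a percent.

    Computed over the entire genome, zero-depth positions included.
    """
    d = depth.depth.astype(float)
    if d.size == 0 or d.sum() == 0:
        raise UndefinedStatisticError(
            f"CV undefined: no coverage on {depth.genome_id!r}"
        )
    mean = d.mean()
    return 100.0 * float(d.std(ddof=0)) / mean


def uniformity_report(depth: DepthVector) -> UniformityStats:
    """Breadth (>= 1x), CV and standard-scale Gini for one depth vector."""
    return UniformityStats(
        breadth_percent=breadth(depth, min_depth=1),
        cv_percent=coefficient_of_variation(depth),
        gini=gini(lorenz_curve(depth, basis="covered_only"), scale="standard"),
    )
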