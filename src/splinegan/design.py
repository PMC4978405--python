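"""Natural cubic spline basis and the two-group time-course design matrix.

The per-gene regression model is

    y(t, x) = b0 + b1 B1(t - t0) + ... + bm Bm(t - t0)
              + x * (d0 + d1 B1(t - t0) + ... + dm Bm(t - t0))

with x = 0 for control samples and x = 1 for treatment samples, t0 the time
of the first measurement, and B1..Bm a natural cubic spline basis with
m = df functions.  The b coefficients describe the control time course and
the d coefficients the *differential* time course between the groups, so
testing the d block tests time-dependent differential expression.

A natural cubic spline is piecewise cubic between its knots, twice
continuously differentiable everywhere, and linear (zero second derivative)
beyond the two boundary knots.  With df basis functions there are df - 1
interior knots, placed at equally spaced quantiles of the pooled sampling
times of both groups (for df = 3: the 1/3- and 2/3-quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TimecourseExperiment


class IdentifiabilityError(ValueError):
    """Raised when the requested model cannot be identified from the design."""


@dataclass(frozen=True)
class KnotSet:
    """Boundary and interior knots on the original time axis (hours)."""

    boundary: tuple[float, float]
    interior: tuple[float, ...]
    df: int

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        knots = (lo, *self.interior, hi)
        if len(self.interior) != self.df - 1:
            raise IdentifiabilityError(
                f"df={self.df} requires {self.df - 1} interior knots, got {len(self.interior)}"
            )
        if any(b >= a for a, b in zip(knots[1:], knots[:-1])):
            raise IdentifiabilityError(
                f"knots must be strictly increasing with interior knots strictly "
                f"inside the boundary: {knots}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary[0], *self.interior, self.boundary[1]], float)


@dataclass
class SplineDesign:
    """Basis evaluations and the assembled two-group design matrix.

    ``matrix`` columns are ordered [1, B1..Bm, x, x*B1..x*Bm] so the
    differential block is always the last m + 1 columns.
    """

    knots: KnotSet
    t0: float
    m: int
    basis_values: np.ndarray   # samples x m
    matrix: np.ndarray         # samples x 2(m+1)
    samples: list[str]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    @property
    def diff_slice(self) -> slice:
        """Column slice of the differential (d) coefficient block."""
        return slice(self.m + 1, 2 * (self.m + 1))


def compute_knots(times: np.ndarray, df: int) -> KnotSet:
    """Choose boundary and interior knots from the pooled sampling times.

    Boundary knots are the min/max of the pooled times; interior knots sit
    at the k/df quantiles (k = 1..df-1) of the full pooled time vector,
    replicates included, using linear interpolation between order statistics
    (the type-7 convention).  Order of the input vector is irrelevant.
    """
    if df < 1:
        raise IdentifiabilityError(f"df must be >= 1, got {df}")
    times = np.asarray(times, float)
    distinct = np.unique(times)
    if distinct.size < df + 1:
        raise IdentifiabilityError(
            f"model with df={df} needs at least {df + 1} distinct time points, "
            f"got {distinct.size}"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(times, probs, method="linear") if df > 1 else np.array([])
    return KnotSet(
        boundary=(float(distinct[0]), float(distinct[-1])),
        interior=tuple(float(k) for k in interior),
        df=df,
    )


def natural_cubic_basis(times: np.ndarray, knots: KnotSet, t0: float | None = None) -> np.ndarray:
    """Evaluate m = df natural cubic spline basis functions at ``times``.

    Uses the truncated-power natural basis: with knots xi_1 < ... < xi_K on
    the shifted axis s = t - t0,

        d_k(s) = [ (s - xi_k)_+^3 - (s - xi_K)_+^3 ] / (xi_K - xi_k)

    and columns [s, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}].  Each column is
    cubic between consecutive knots, C2 everywhere, and exactly linear
    outside the boundary knots.  Together with an intercept the column space
    has dimension df + 1.
    """
    times = np.asarray(times, float)
    if t0 is None:
        t0 = float(knots.boundary[0])
    xi = knots.all_knots - t0
    s = times - t0
    cols = [s]
    k_total = xi.size
    if k_total > 2:
        def cube_plus(x: np.ndarray) -> np.ndarray:
            return np.where(x > 0, x, 0.0) ** 3

        def d(k: int) -> np.ndarray:
            return (cube_plus(s - xi[k]) - cube_plus(s - xi[-1])) / (xi[-1] - xi[k])

        d_last = d(k_total - 2)
        cols.extend(d(k) - d_last for k in range(k_total - 2))
    return np.column_stack(cols)


def build_design(experiment: TimecourseExperiment, df: int = 3) -> SplineDesign:
    """Assemble the two-group spline design for a validated experiment.

    Raises :class:`IdentifiabilityError` if either group observes fewer
    than df + 1 distinct time points or if the design is rank-deficient.
    """
    pooled = experiment.times()
    for group in ("control", "treatment"):
        distinct = np.unique(experiment.times(group))
        if distinct.size < df + 1:
            raise IdentifiabilityError(
                f"group '{group}' has {distinct.size} distinct time points; "
                f"df={df} requires at least {df + 1}"
            )
    knots = compute_knots(pooled, df)
    t0 = float(pooled.min())
    basis = natural_cubic_basis(pooled, knots, t0)
    x = experiment.group_indicator().astype(float)
    ones = np.ones_like(x)
    control_block = np.column_stack([ones, basis])
    matrix = np.column_stack([control_block, x[:, None] * control_block])
    m = basis.shape[1]
    if np.linalg.matrix_rank(matrix) < 2 * (m + 1):
        raise IdentifiabilityError(
            "rank-deficient design matrix: the two groups do not identify "
            f"all {2 * (m + 1)} spline coefficients"
        )
    return SplineDesign(
        knots=knots, t0=t0, m=m, basis_values=basis,
        matrix=matrix, samples=experiment.samples,
    )
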