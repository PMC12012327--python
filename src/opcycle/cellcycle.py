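"""Cumulative-labeling and pulse-chase cell-cycle inference.

Implements the classical cumulative-labeling framework for an asynchronous,
steady-state population of cycling cells.  Continuous availability of an
S-phase label (EdU) makes the labeling index (L.I.) rise linearly with
exposure time,

    L.I.(t) = G * (t + T_S) / T_C        for t <= T_C - T_S,

then plateau abruptly at the growth fraction ``G`` once every cycling cell
has traversed S-phase.  Fitting the linear rise with slope ``m`` and
intercept ``y0`` yields

    T_C = G / m,        T_S = y0 * G / m.

Two corrections for an incompletely recombined (mixed) population are
provided, and short closed-form estimators for G2 duration (from labeled
mitoses in a pulse-chase design) and for G1 by subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PhaseDurations",
    "PopulationSpec",
    "LabelingCurvePoint",
    "CumulativeFit",
    "PulseChaseObservation",
    "G2Estimate",
    "InvalidPhasesError",
    "NonIdentifiableError",
    "PlateauOnlyError",
    "InconsistentMixtureError",
    "InconsistentDurationsError",
    "expected_li",
    "fit_labeling_curve",
    "estimate_tc_ts",
    "correct_mixture_arithmetic",
    "correct_mixture_harmonic",
    "estimate_g2",
    "estimate_g1",
    "format_duration",
]

# Fraction of the plateau below which a point still counts as "on the rise".
PLATEAU_TOLERANCE = 0.02


class InvalidPhasesError(ValueError):
    """Phase durations do not describe a valid cell cycle."""


class NonIdentifiableError(ValueError):
    """The labeling curve has a non-positive slope; T_C is not identifiable."""


class PlateauOnlyError(ValueError):
    """Every observation sits on the plateau; the linear rise is unobserved."""


class InconsistentMixtureError(ValueError):
    """Mixture correction produced a non-positive cycle time."""


class InconsistentDurationsError(ValueError):
    """Phase durations exceed the total cycle time."""


@dataclass(frozen=True)
class PhaseDurations:
    """Durations (hours) of the four cell-cycle phases G1, S, G2, M.

    The total cycle time ``t_c`` is derived.  S-phase must have positive
    length for labeling-based inference to make sense.
    """

    t_g1: float
    t_s: float
    t_g2: float
    t_m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_g1", "t_s", "t_g2", "t_m"):
            if getattr(self, name) < 0:
                raise InvalidPhasesError(f"{name} must be >= 0")
        if self.t_s <= 0:
            raise InvalidPhasesError("t_s must be > 0")
        if self.t_c <= 0:
            raise InvalidPhasesError("total cycle time must be > 0")

    @property
    def t_c(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2 + self.t_m

    @property
    def s_start(self) -> float:
        """Cycle position at which S-phase begins (G1 -> S -> G2 -> M)."""
        return self.t_g1

    @property
    def m_start(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2


@dataclass(frozen=True)
class Subpopulation:
    weight: float
    phases: PhaseDurations
    growth_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("subpopulation weight must be >= 0")
        if not 0.0 <= self.growth_fraction <= 1.0:
            raise ValueError("growth_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of cycling subpopulations, e.g. recombined vs. unrecombined.

    Weights must sum to 1.  Each subpopulation carries its own phase
    durations and growth fraction (fraction of that subpopulation actively
    cycling).
    """

    subpopulations: tuple[Subpopulation, ...]

    def __post_init__(self) -> None:
        if len(self.subpopulations) == 0:
            raise ValueError("PopulationSpec needs at least one subpopulation")
        total = sum(s.weight for s in self.subpopulations)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"subpopulation weights must sum to 1 (got {total})")

    @classmethod
    def single(cls, phases: PhaseDurations, growth_fraction: float = 1.0) -> "PopulationSpec":
        return cls((Subpopulation(1.0, phases, growth_fraction),))

    @classmethod
    def two_way(
        cls,
        f_first: float,
        phases_first: PhaseDurations,
        phases_second: PhaseDurations,
        g_first: float = 1.0,
        g_second: float = 1.0,
    ) -> "PopulationSpec":
        return cls(
            (
                Subpopulation(f_first, phases_first, g_first),
                Subpopulation(1.0 - f_first, phases_second, g_second),
            )
        )

    def expected_li(self, t: float) -> float:
        """Weight-averaged analytic labeling index at exposure time ``t``."""
        return sum(
            s.weight * expected_li(s.phases, s.growth_fraction, t)
            for s in self.subpopulations
        )

    @property
    def analytic_slope(self) -> float:
        """Pre-plateau slope of the mixture curve: sum_i w_i g_i / t_c_i."""
        return sum(
            s.weight * s.growth_fraction / s.phases.t_c for s in self.subpopulations
        )


@dataclass(frozen=True)
class LabelingCurvePoint:
    """One cumulative-labeling observation: ``n_labeled`` of ``n_total``
    scored cells are label-positive after ``t`` hours of exposure.

    Counts may be fractional: noise-free analytic curves (used to probe
    the fitting machinery) carry exact expected counts.
    """

    t: float
    n_total: float
    n_labeled: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("exposure time must be >= 0")
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if not 0 <= self.n_labeled <= self.n_total:
            raise ValueError("n_labeled must lie in [0, n_total]")

    @property
    def li(self) -> float:
        return self.n_labeled / self.n_total


@dataclass(frozen=True)
class CumulativeFit:
    """Result of the weighted linear fit to the pre-plateau rise."""

    m: float
    y0: float
    g: float
    t_c: float
    t_s: float
    se_m: float
    se_y0: float
    se_t_c: float
    se_t_s: float
    n_points_used: int
    plateau_reached: bool
    excluded_plateau_times: tuple[float, ...] = ()


@dataclass(frozen=True)
class PulseChaseObservation:
    """Pulse-chase counts: of ``n_edu`` label-positive cells scored after a
    chase of ``t_chase`` hours, ``n_edu_ph3`` are also in mitosis (pH3+)."""

    t_chase: float
    n_edu: int
    n_edu_ph3: int

    def __post_init__(self) -> None:
        if self.t_chase <= 0:
            raise ValueError("t_chase must be > 0")
        if not 0 <= self.n_edu_ph3 <= self.n_edu:
            raise ValueError("n_edu_ph3 must lie in [0, n_edu]")

    @property
    def f_ph3(self) -> float:
        if self.n_edu == 0:
            return 0.0
        return self.n_edu_ph3 / self.n_edu


@dataclass(frozen=True)
class G2Estimate:
    t_g2: float
    lower_bound: bool = False
    clipped: bool = False


def expected_li(phases: PhaseDurations, g: float, t: float) -> float:
    """Analytic cumulative labeling index at exposure time ``t`` hours.

    ``min(g * (t + t_s) / t_c, g)``: linear rise with slope ``g/t_c`` and
    intercept ``g*t_s/t_c``, plateauing at the growth fraction ``g`` once
    ``t >= t_c - t_s``.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("growth fraction g must lie in [0, 1]")
    if t < 0:
        raise ValueError("t must be >= 0")
    return min(g * (t + phases.t_s) / phases.t_c, g)


def _plateau_split(
    points: Sequence[LabelingCurvePoint], g: float
) -> tuple[list[LabelingCurvePoint], list[LabelingCurvePoint]]:
    cutoff = g * (1.0 - PLATEAU_TOLERANCE)
    rise = [p for p in points if p.li < cutoff]
    plateau = [p for p in points if p.li >= cutoff]
    return rise, plateau


def _resolve_g(points: Sequence[LabelingCurvePoint], g: float | Literal["auto"]) -> float:
    if g != "auto":
        gv = float(g)
        if not 0 < gv <= 1:
            raise ValueError("g must lie in (0, 1]")
        return gv
    # A plateau is credible only if at least two points sit within 2% of the
    # maximum observed L.I.; otherwise assume every cell cycles (G = 1).
    li_max = max(p.li for p in points)
    near = [p for p in points if p.li >= li_max * (1.0 - PLATEAU_TOLERANCE)]
    if li_max > 0 and len(near) >= 2:
        return li_max
    return 1.0


def fit_labeling_curve(
    points: Sequence[LabelingCurvePoint], g: float | Literal["auto"] = 1.0
) -> CumulativeFit:
    """Weighted least-squares fit of the linear rise of a cumulative curve.

    Points with L.I. within 2% of the plateau ``g`` are excluded, the rest
    fit with binomial variance weights ``n / (li (1 - li) + eps)``,
    ``eps = 1/(4 n)``, which keeps weights finite at L.I. of 0 or 1.
    ``g="auto"`` takes the plateau from the data when at least two points
    reach it, else defaults to 1.

    Returns slope ``m``, intercept ``y0`` and the derived ``t_c = g/m``,
    ``t_s = y0 g/m`` with first-order propagated standard errors.
    """
    if len(points) == 0:
        raise ValueError("no labeling points supplied")
    g_val = _resolve_g(points, g)
    rise, plateau = _plateau_split(points, g_val)
    if len(rise) == 0:
        raise PlateauOnlyError(
            "all points sit on the plateau; the linear rise is unobserved"
        )
    t = np.array([p.t for p in rise])
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 pre-plateau points with distinct times")
    li = np.array([p.li for p in rise])
    n = np.array([p.n_total for p in rise], dtype=float)
    eps = 1.0 / (4.0 * n)
    w = n / (li * (1.0 - li) + eps)

    model = sm.WLS(li, sm.add_constant(t), weights=w).fit()
    y0, m = model.params
    se_y0, se_m = model.bse
    cov = model.cov_params()

    if m <= 0:
        raise NonIdentifiableError(f"fitted slope m = {m:.3g} <= 0")
    if y0 < 0:
        y0 = 0.0  # tiny negative intercepts from noise are clipped

    t_c = g_val / m
    t_s = y0 * g_val / m
    # Delta method on (y0, m) with the WLS covariance.
    # t_c = g/m: d/dm = -g/m^2.  t_s = g*y0/m: d/dy0 = g/m, d/dm = -g*y0/m^2.
    se_t_c = g_val * se_m / m**2
    grad = np.array([g_val / m, -g_val * y0 / m**2])
    var_t_s = float(grad @ np.asarray(cov) @ grad)
    se_t_s = math.sqrt(max(var_t_s, 0.0))

    return CumulativeFit(
        m=float(m),
        y0=float(y0),
        g=g_val,
        t_c=float(t_c),
        t_s=float(t_s),
        se_m=float(se_m),
        se_y0=float(se_y0),
        se_t_c=float(se_t_c),
        se_t_s=float(se_t_s),
        n_points_used=len(rise),
        plateau_reached=len(plateau) > 0,
        excluded_plateau_times=tuple(p.t for p in plateau),
    )


def estimate_tc_ts(m: float, y0: float, g: float) -> tuple[float, float]:
    """Invert slope and intercept to cycle and S-phase times.

    ``t_c = g/m`` and ``t_s = y0 g/m``.
    """
    if m <= 0:
        raise NonIdentifiableError("slope m must be > 0")
    if not 0 <= y0 < g <= 1:
        raise ValueError("need 0 <= y0 < g <= 1")
    return g / m, y0 * g / m


def correct_mixture_arithmetic(t_c_avg: float, f_rec: float, t_c_other: float) -> float:
    """Mixture correction on the scale of cycle times.

    If the fitted ``t_c_avg`` is a weighted arithmetic mean of a
    recombined fraction ``f_rec`` (unknown T_C) and an unrecombined
    remainder cycling with ``t_c_other``, the recombined subpopulation's
    cycle time is ``(t_c_avg - (1 - f_rec) * t_c_other) / f_rec``.
    """
    if not 0 < f_rec <= 1:
        raise ValueError("f_rec must lie in (0, 1]")
    if t_c_avg <= 0 or t_c_other <= 0:
        raise ValueError("cycle times must be > 0")
    out = (t_c_avg - (1.0 - f_rec) * t_c_other) / f_rec
    if out <= 0:
        raise InconsistentMixtureError(
            "mixture correction gives a non-positive cycle time"
        )
    return out


def correct_mixture_harmonic(
    m_avg: float, f_rec: float, t_c_other: float, g: float = 1.0
) -> float:
    """Mixture correction on the scale of slopes (division rates).

    The analytic pre-plateau slope of a two-way mixture is the weighted sum
    of subpopulation slopes, ``m_avg = f_rec * g / t_c + (1-f_rec) * g /
    t_c_other``; solving for the recombined subpopulation gives
    ``t_c = f_rec * g / (m_avg - (1 - f_rec) * g / t_c_other)``.
    """
    if not 0 < f_rec <= 1:
        raise ValueError("f_rec must lie in (0, 1]")
    if t_c_other <= 0:
        raise ValueError("t_c_other must be > 0")
    denom = m_avg - (1.0 - f_rec) * g / t_c_other
    if denom <= 0:
        raise InconsistentMixtureError(
            "average slope is at or below the unrecombined contribution"
        )
    return f_rec * g / denom


def estimate_g2(t_chase: float, f_ph3: float, t_s: float) -> G2Estimate:
    """G2 duration from the labeled-mitoses fraction after a chase.

    With an instantaneous S-phase pulse, cells labeled within
    ``t_chase - t_g2`` hours of S-phase exit have reached mitosis by the
    time of sampling, so the pH3+ fraction among labeled cells is
    ``(t_chase - t_g2) / t_s`` and

        t_g2 = t_chase - f_ph3 * t_s.

    A zero ``f_ph3`` means no labeled cell has cleared G2 yet; the chase
    time is then only a lower bound on ``t_g2`` and is flagged as such.
    The estimate is clipped below at 0 (with a flag) when
    ``f_ph3 * t_s > t_chase``.
    """
    if t_chase <= 0:
        raise ValueError("t_chase must be > 0")
    if not 0 <= f_ph3 <= 1:
        raise ValueError("f_ph3 must lie in [0, 1]")
    if t_s <= 0:
        raise ValueError("t_s must be > 0")
    raw = t_chase - f_ph3 * t_s
    if f_ph3 == 0:
        return G2Estimate(t_g2=t_chase, lower_bound=True)
    if raw < 0:
        return G2Estimate(t_g2=0.0, clipped=True)
    return G2Estimate(t_g2=raw)


def estimate_g1(t_c: float, t_s: float, t_g2: float, t_m: float = 0.0) -> float:
    """G1 duration by subtraction: ``t_c - t_s - t_g2 - t_m``.

    With the default ``t_m = 0`` the result is an upper bound on G1.
    """
    for name, v in (("t_c", t_c), ("t_s", t_s), ("t_g2", t_g2), ("t_m", t_m)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    out = t_c - t_s - t_g2 - t_m
    if out < 0:
        raise InconsistentDurationsError(
            f"phase durations exceed the cycle time by {-out:.3g} h"
        )
    return out


def format_duration(hours: float) -> str:
    """Report-string rounding: one decimal below 10 h, nearest integer above.

    Rounding is half-up, matching how hand-reported durations are rounded.
    """
    # Small epsilon keeps exact halves (e.g. 204.5 stored as 204.4999...97)
    # rounding up as hand arithmetic would.
    if hours < 10:
        return f"{math.floor(hours * 10 + 0.5 + 1e-9) / 10:.1f}"
    return f"{math.floor(hours + 0.5 + 1e-9):.0f}"
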