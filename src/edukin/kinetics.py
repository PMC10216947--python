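"""Closed-form cumulative / pulse labeling model.

The model is the classic cumulative-labeling description of a steady-state
renewing cell population (Nowakowski et al., 1989).  A fraction GF of cells
(the growth fraction, in percent) cycles with period ``Tc`` hours, of which
``Ts`` hours are spent in S-phase.  Under continuous exposure to a thymidine
analog such as EdU, the labeling index (percent of labeled nuclei) rises
linearly and then saturates::

    LI(t) = GF * (t + Ts) / Tc    for t <= Tc - Ts
    LI(t) = GF                    for t >= Tc - Ts

The rising segment, written as ``y = a + b t``, links curve geometry to the
kinetic parameters: ``a = GF*Ts/Tc`` (the instantaneous S-phase fraction),
``b = GF/Tc`` (the rate of S-phase entry), and the breakpoint ``Tc - Ts =
(GF - a)/b``.  These identities are exact only for a constant-size population
with a uniform cell-cycle age distribution; see ``docs/methods.md``.

Units: percent for LI and GF, hours for all times, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "CellCycleParams",
    "LineSegment",
    "expected_cumulative_li",
    "expected_pulse_li",
    "params_from_line",
    "params_from_breakpoint",
    "line_from_params",
]


@dataclass(frozen=True)
class CellCycleParams:
    """Kinetic triple (Tc, Ts, GF) plus the position of S within the cycle.

    Parameters
    ----------
    tc : float
        Total cell-cycle length in hours, > 0.
    ts : float
        S-phase length in hours, 0 < ts < tc.
    gf : float
        Growth fraction in percent, 0 < gf <= 100.
    g1_fraction : float, optional
        Fraction of the non-S cycle time that precedes S (default 0.5).
        The cumulative labeling curve does not depend on it; it only fixes
        when a labeled cell divides in pulse-chase simulations.
    """

    tc: float
    ts: float
    gf: float
    g1_fraction: float = field(default=0.5)

    def __post_init__(self) -> None:
        if not (self.tc > 0 and np.isfinite(self.tc)):
            raise ParameterError(f"tc must be a positive finite number, got {self.tc}")
        if not (0 < self.ts < self.tc):
            raise ParameterError(
                f"ts must satisfy 0 < ts < tc, got ts={self.ts}, tc={self.tc}"
            )
        if not (0 < self.gf <= 100):
            raise ParameterError(f"gf must be in (0, 100] percent, got {self.gf}")
        if not (0 <= self.g1_fraction <= 1):
            raise ParameterError(
                f"g1_fraction must be in [0, 1], got {self.g1_fraction}"
            )

    # --- phase layout: G1 = [0, s_start), S = [s_start, s_end), G2/M rest ---
    @property
    def s_start(self) -> float:
        """Cycle age (hours) at which S-phase begins."""
        return self.g1_fraction * (self.tc - self.ts)

    @property
    def s_end(self) -> float:
        """Cycle age (hours) at which S-phase ends."""
        return self.s_start + self.ts

    @property
    def breakpoint(self) -> float:
        """Time Tc - Ts at which the cumulative curve reaches its plateau."""
        return self.tc - self.ts

    @property
    def s_fraction_percent(self) -> float:
        """Steady-state percent of all cells in S-phase: GF * Ts / Tc."""
        return self.gf * self.ts / self.tc


@dataclass(frozen=True)
class LineSegment:
    """Rising segment ``y = a + b t`` plus the plateau of a cumulative curve.

    ``intercept_a`` and ``plateau_gf`` are in percent, ``slope_b`` in
    percent/hour.  A valid rising segment has ``slope_b > 0`` and
    ``intercept_a >= 0``; the breakpoint is where the line meets the plateau.
    """

    intercept_a: float
    slope_b: float
    plateau_gf: float

    def __post_init__(self) -> None:
        if not (self.slope_b > 0):
            raise ParameterError(
                f"slope_b must be > 0 for a rising segment, got {self.slope_b}"
            )
        if self.intercept_a < 0:
            raise ParameterError(
                f"intercept_a must be >= 0, got {self.intercept_a}"
            )

    @property
    def breakpoint(self) -> float:
        """Time at which the rising line reaches the plateau value."""
        return (self.plateau_gf - self.intercept_a) / self.slope_b


def expected_cumulative_li(params: CellCycleParams, t):
    """Expected labeling index (percent) after ``t`` hours of cumulative
    exposure.

    Piecewise linear: ``GF*(t+Ts)/Tc`` before the breakpoint ``Tc-Ts``, the
    plateau ``GF`` after; continuous and non-decreasing.  ``t`` may be a
    scalar or array of non-negative hours.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("exposure time t must be >= 0 hours")
    li = np.minimum(params.gf * (t_arr + params.ts) / params.tc, params.gf)
    return float(li) if np.isscalar(t) or t_arr.ndim == 0 else li


def expected_pulse_li(params: CellCycleParams, pulse_duration):
    """Expected labeling index (percent) immediately after a pulse of the
    given duration (hours).

    A pulse of length tau labels every cell that passes through S during the
    exposure — the same accounting as cumulative labeling at ``t = tau`` —
    so at tau = 0 this is the steady-state S-phase fraction ``GF*Ts/Tc`` and
    a long pulse saturates at GF.
    """
    return expected_cumulative_li(params, pulse_duration)


def line_from_params(params: CellCycleParams) -> LineSegment:
    """Rising-segment geometry implied by kinetic parameters
    (``a = GF*Ts/Tc``, ``b = GF/Tc``, plateau = GF)."""
    return LineSegment(
        intercept_a=params.gf * params.ts / params.tc,
        slope_b=params.gf / params.tc,
        plateau_gf=params.gf,
    )


def params_from_line(segment: LineSegment, g1_fraction: float = 0.5) -> CellCycleParams:
    """Kinetic parameters from fitted curve geometry.

    Inverts the identities of the cumulative model: extrapolating the rising
    line to the y-axis gives ``Ts = a/b``; the plateau divided by the slope
    gives ``Tc = GF/b`` (equivalently breakpoint + Ts).

    Raises
    ------
    ParameterError
        If the slope is non-positive (rise non-identifiable), the plateau
        does not exceed the intercept (degenerate geometry), or the implied
        Ts is not strictly positive.
    """
    if segment.slope_b <= 0:
        raise ParameterError("non-identifiable rise: slope must be > 0")
    if segment.plateau_gf <= segment.intercept_a:
        raise ParameterError(
            "degenerate geometry: plateau must exceed the line intercept "
            f"(plateau={segment.plateau_gf}, intercept={segment.intercept_a})"
        )
    ts = segment.intercept_a / segment.slope_b
    tc = segment.plateau_gf / segment.slope_b
    # CellCycleParams rejects ts <= 0 (zero intercept implies no S-phase)
    return CellCycleParams(tc=tc, ts=ts, gf=segment.plateau_gf, g1_fraction=g1_fraction)


def params_from_breakpoint(
    breakpoint_h: float, ts_h: float, gf_percent: float, g1_fraction: float = 0.5
) -> CellCycleParams:
    """Kinetic parameters from a breakpoint time and S-phase length:
    ``Tc = breakpoint + Ts`` (the plateau-onset identity)."""
    return CellCycleParams(
        tc=breakpoint_h + ts_h, ts=ts_h, gf=gf_percent, g1_fraction=g1_fraction
    )
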