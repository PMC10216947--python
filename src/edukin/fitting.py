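"""Broken-line-with-plateau least squares for cumulative labeling curves.

Estimates the growth fraction GF, S-phase length Ts and cycle length Tc
from labeling-index measurements under continuous label exposure, using the
piecewise-linear model of :mod:`edukin.kinetics`:

    LI(t) = a + b t   for t <= breakpoint,      LI(t) = GF  otherwise,

with the continuity constraint breakpoint = (GF - a) / b, and the kinetic
bijection Ts = a/b, Tc = GF/b (so Tc = breakpoint + Ts exactly).

Fitting strategy
----------------
For a candidate breakpoint lying between two adjacent sampling times the
least-squares problem decouples exactly: an ordinary (weighted) line through
the pre-breakpoint points and the (weighted) mean of the post-breakpoint
points.  The fitter therefore scans every placement of the breakpoint
between adjacent distinct sampling times, keeps the placements that are
*self-consistent* (the implied breakpoint falls inside the interval that
generated it), and among those selects the earliest breakpoint —
equivalently the smallest Tc.

Earliest rather than smallest-SSE selection is deliberate.  A breakpoint
placed just before the last sampling time always fits that final point
exactly (a one-point plateau has zero residual by construction), so raw SSE
systematically favors late breakpoints that reinterpret plateau scatter as
continued rise and inflate Tc.  Reading the curve as saturating at the
earliest time compatible with the two-phase geometry is the conservative
choice and matches how cumulative-labeling curves are read in practice.
``selection="sse"`` restores the raw global-SSE rule.

If no interior placement is self-consistent the fitter falls back to
breakpoints pinned at sampling times (a constrained linear fit in
``min(t, B)``); if even those do not improve on a single straight line the
curve never visibly saturates and the fit is flagged non-identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .kinetics import (
    CellCycleParams,
    LineSegment,
    expected_cumulative_li,
    params_from_line,
)

__all__ = ["CumulativeFit", "fit_cumulative", "bootstrap_ci"]


@dataclass(frozen=True)
class CumulativeFit:
    """Result of a broken-line-with-plateau fit."""

    params: Optional[CellCycleParams]
    segment: Optional[LineSegment]
    sse: float
    n_points: int
    converged: bool
    ci: Optional[dict] = None
    bounds: Optional[dict] = None  # e.g. {"gf_lower": ...} when non-identifiable

    @property
    def gf(self) -> float:
        return self.params.gf

    @property
    def ts(self) -> float:
        return self.params.ts

    @property
    def tc(self) -> float:
        return self.params.tc

    @property
    def breakpoint(self) -> float:
        return self.params.breakpoint

    def predict(self, t):
        """Model curve at time(s) ``t`` (hours), percent."""
        if not self.converged:
            raise ParameterError("cannot predict from a non-identifiable fit")
        return expected_cumulative_li(self.params, t)

    def to_dict(self) -> dict:
        d = {
            "converged": self.converged,
            "n_points": self.n_points,
            "sse": self.sse,
        }
        if self.converged:
            d.update(
                gf_percent=self.params.gf,
                ts_h=self.params.ts,
                tc_h=self.params.tc,
                breakpoint_h=self.params.breakpoint,
                intercept_percent=self.segment.intercept_a,
                slope_percent_per_h=self.segment.slope_b,
            )
        if self.bounds:
            d["bounds"] = dict(self.bounds)
        if self.ci is not None:
            d["ci"] = {
                k: list(v) if isinstance(v, (tuple, list)) else v
                for k, v in self.ci.items()
            }
        return d


def _wls_line(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b t; returns (a, b)."""
    sw = w.sum()
    tm = (w * t).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (t - tm) ** 2).sum()
    if sxx <= 0:
        return None
    b = (w * (t - tm) * (y - ym)).sum() / sxx
    return ym - b * tm, b


def fit_cumulative(
    times: Sequence[float],
    li_values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    selection: str = "earliest",
    g1_fraction: float = 0.5,
) -> CumulativeFit:
    """Fit the broken-line-with-plateau model to cumulative-labeling data.

    Parameters
    ----------
    times, li_values : sequences of float
        Exposure times (hours) and labeling indices (percent, in [0, 100]).
        Repeated times are allowed (per-specimen data); at least 4 distinct
        times are required.
    weights : optional sequence of float
        Per-point least-squares weights (default equal).
    selection : {"earliest", "sse"}
        Rule for choosing among self-consistent breakpoint placements; see
        the module docstring.

    Returns
    -------
    CumulativeFit
        With ``converged=True`` and the kinetic parameters, or
        ``converged=False`` (non-identifiable) when no breakpoint interior
        to the sampled time range improves on a single straight line; in
        that case the plateau is only bounded below by the largest observed
        LI, reported in ``bounds``.
    """
    if selection not in ("earliest", "sse"):
        raise ParameterError(f"selection must be 'earliest' or 'sse', got {selection!r}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(li_values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ParameterError("times and li_values must be 1-D of equal length")
    if np.any(y < 0) or np.any(y > 100):
        raise ParameterError("li_values must be percentages in [0, 100]")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w <= 0):
        raise ParameterError("weights must be positive and match the data length")
    order = np.argsort(t, kind="stable")
    t, y, w = t[order], y[order], w[order]
    u = np.unique(t)
    m = u.size
    if m < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct time points, got {m}"
        )

    def make_fit(a, b, gf, sse):
        segment = LineSegment(intercept_a=a, slope_b=b, plateau_gf=gf)
        params = params_from_line(segment, g1_fraction=g1_fraction)
        return CumulativeFit(
            params=params,
            segment=segment,
            sse=float(sse),
            n_points=t.size,
            converged=True,
        )

    # --- interior candidates: breakpoint between adjacent distinct times ---
    interior = []
    for k in range(2, m):  # rise = first k distinct times, plateau = rest
        rise = t <= u[k - 1]
        plat = ~rise
        line = _wls_line(t[rise], y[rise], w[rise])
        if line is None:
            continue
        a, b = line
        if b <= 0 or a <= 0:
            continue
        gf = float((w[plat] * y[plat]).sum() / w[plat].sum())
        if gf <= a:
            continue
        bp = (gf - a) / b
        # self-consistent: implied breakpoint falls in the generating
        # interval, strictly inside the sampled range
        if not (u[k - 1] <= bp <= u[k] and u[0] < bp < u[-1]):
            continue
        sse = float(
            (w[rise] * (y[rise] - (a + b * t[rise])) ** 2).sum()
            + (w[plat] * (y[plat] - gf) ** 2).sum()
        )
        interior.append((bp, gf / b, sse, a, b, gf))

    if interior:
        if selection == "earliest":
            bp, tc, sse, a, b, gf = min(interior, key=lambda c: (c[0], c[1]))
        else:
            bp, tc, sse, a, b, gf = min(interior, key=lambda c: (c[2], c[1]))
        return make_fit(a, b, gf, sse)

    # --- fallback: breakpoint pinned at an interior sampling time ---------
    pinned = []
    for k in range(1, m - 1):
        bp = u[k]
        x = np.minimum(t, bp)
        line = _wls_line(x, y, w)
        if line is None:
            continue
        a, b = line
        if b <= 0 or a <= 0:
            continue
        gf = a + b * bp
        if gf > 100 or gf <= a:
            continue
        sse = float((w * (y - (a + b * x)) ** 2).sum())
        pinned.append((sse, gf / b, bp, a, b, gf))

    line_all = _wls_line(t, y, w)
    sse_line = (
        float((w * (y - (line_all[0] + line_all[1] * t)) ** 2).sum())
        if line_all is not None
        else float("inf")
    )
    if pinned:
        sse, tc, bp, a, b, gf = min(pinned)
        if sse < sse_line * (1 - 1e-10):
            return make_fit(a, b, gf, sse)

    # no interior breakpoint improves on a single line: the curve never
    # saturates within the sampled range
    return CumulativeFit(
        params=None,
        segment=None,
        sse=sse_line,
        n_points=t.size,
        converged=False,
        bounds={"gf_lower": float(y.max())},
    )


def bootstrap_ci(
    times: Sequence[float],
    li_values: Sequence[float],
    n_boot: int,
    level: float = 0.95,
    seed=None,
    specimen_ids: Optional[Sequence] = None,
    selection: str = "earliest",
) -> dict:
    """Case-resampling percentile bootstrap intervals for (GF, Ts, Tc).

    Resampling is over specimens when ``specimen_ids`` is given (whole
    specimens drawn with replacement, keeping each specimen's points
    together), otherwise over individual points.  Non-identifiable
    resamples are dropped; if every resample fails a degenerate-CI warning
    is issued and an empty dict returned.

    Returns a dict ``{"gf_percent": (lo, hi), "ts_h": (lo, hi),
    "tc_h": (lo, hi), "level": level, "n_converged": k}`` (empty when
    ``n_boot == 0``).
    """
    if not (0 < level < 1):
        raise ParameterError("level must be in (0, 1)")
    if n_boot == 0:
        return {}
    t = np.asarray(times, dtype=float)
    y = np.asarray(li_values, dtype=float)
    rng = np.random.default_rng(seed)
    if specimen_ids is not None:
        sid = np.asarray(specimen_ids)
        groups = [np.flatnonzero(sid == g) for g in np.unique(sid)]
    else:
        groups = [np.array([i]) for i in range(t.size)]
    est = []
    for _ in range(int(n_boot)):
        pick = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[j] for j in pick])
        try:
            fit = fit_cumulative(t[idx], y[idx], selection=selection)
        except (InsufficientDataError, ParameterError):
            continue
        if fit.converged:
            est.append((fit.gf, fit.ts, fit.tc))
    if not est:
        warnings.warn(
            "all bootstrap resamples were non-identifiable; intervals are "
            "degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return {}
    arr = np.asarray(est)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    keys = ("gf_percent", "ts_h", "tc_h")
    out = {
        k: (float(np.percentile(arr[:, j], lo)), float(np.percentile(arr[:, j], hi)))
        for j, k in enumerate(keys)
    }
    out["level"] = level
    out["n_converged"] = len(est)
    return out
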