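"""Four-parameter logistic curve fitting and drug sensitivity scores (DSS).

The viability model is the 4PL (Hill) curve on a log10-dose axis x:

    v(x) = bottom + (top - bottom) / (1 + 10^(slope * (x - log_ec50)))

with slope > 0 for inhibitors, so viability decreases with dose. The DSS
family summarizes the whole curve into one sensitivity scalar by integrating
excess inhibition over the tested concentration window [x_lo, x_hi]:

    y(x) = clip(100 - v(x), 0, 100)        (percent inhibition)
    x1   = first dose where y >= t          (activity onset; t = 10 default)
    x2   = first dose where y >= c          (c = 100 - f; viability floor f = 10)
    A    = integral of the thresholded, capped inhibition (see DSSConfig)

    DSS1  = 100 * A / ((100 - t) * (x_hi - x_lo))
    DSS2  = DSS1 / log10(d),  d = min(max window inhibition, 100)
    DSS3  = DSS2 * (x_hi - x1) / (x_hi - x_lo)
    mDSS3 = DSS1 * (x_hi - x1) / (x_hi - x_lo)

mDSS3 — the default — is DSS3 without the division by the logarithm of the
curve's upper asymptote, with the activity window 100%->10% on the viability
axis and the concentration window running from the minimum tested dose to
the viability-10% crossing. A higher score means higher ex vivo sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .plates import ConcentrationSeries, LibraryEntry

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

SLOPE_MIN = 1e-3
SLOPE_MAX = 10.0
TOP_BOUNDS = (50.0, 120.0)
BOTTOM_BOUNDS = (-10.0, 100.0)
POOR_FIT_RMSE = 15.0  # viability percentage points


def logistic4(x, top, bottom, log_ec50, slope):
    """4PL viability at log10 dose x (vectorized)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.power(10.0, slope * (x - log_ec50)))


@dataclass(frozen=True)
class CurveFit4PL:
    """Fitted 4PL viability curve.

    top/bottom are viability-% asymptotes at zero/infinite dose, log_ec50 is
    in log10(nM), slope is the (positive) Hill coefficient. A flat curve is
    represented with top == bottom.
    """

    top: float
    bottom: float
    log_ec50: float
    slope: float
    rmse: float
    converged: bool

    def viability(self, x) -> np.ndarray:
        return logistic4(x, self.top, self.bottom, self.log_ec50, self.slope)

    def inhibition(self, x) -> np.ndarray:
        """Percent inhibition y(x) = clip(100 - v(x), 0, 100)."""
        return np.clip(100.0 - self.viability(x), 0.0, 100.0)

    @property
    def is_flat(self) -> bool:
        return self.top == self.bottom


@dataclass(frozen=True)
class DSSConfig:
    """Windows and switches for DSS scoring.

    t : activity threshold in inhibition percentage points; dips below t are
        treated as assay noise and contribute nothing.
    f : viability floor in percent; the inhibition cap is c = 100 - f.
    tail_rule : what happens past the viability-f crossing x2 —
        "cap" accrues the capped rectangle (c - t) up to x_hi, so a drug that
        kills completely at the lowest dose scores maximally; "truncate"
        stops accrual at x2.
    metric : dss1 | dss2 | dss3 | mdss3 (default mdss3).
    """

    t: float = 10.0
    f: float = 10.0
    tail_rule: str = "cap"
    metric: str = "mdss3"

    def __post_init__(self) -> None:
        if not (0.0 <= self.t < 100.0 - self.f <= 100.0):
            raise ValueError(
                f"need 0 <= t < 100 - f <= 100 (got t={self.t}, f={self.f})"
            )
        if self.tail_rule not in ("cap", "truncate"):
            raise ValueError(f"unknown tail_rule: {self.tail_rule!r}")
        if self.metric not in ("dss1", "dss2", "dss3", "mdss3"):
            raise ValueError(f"unknown metric: {self.metric!r}")

    @property
    def cap(self) -> float:
        return 100.0 - self.f


@dataclass(frozen=True)
class DSSResult:
    """One entry's sensitivity score plus integration diagnostics."""

    entry_id: str
    score: float
    area: float
    x1: float | None
    x2: float | None
    metric: str
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def inactive(self) -> bool:
        return "inactive" in self.flags


def fit_4pl(series: ConcentrationSeries, viability) -> CurveFit4PL:
    """Bounded least-squares 4PL fit of per-dose viability percentages.

    Initialization is deterministic: top <- max observed (clipped to
    bounds), bottom <- min observed, log_ec50 <- dose whose viability is
    closest to the midpoint, slope <- 1. No random restarts. A fit that
    fails to converge falls back to a flat curve at the mean viability with
    converged=False (scored downstream with a poor_fit flag).
    """
    x = series.log10_values
    v = np.asarray(viability, dtype=float)
    if v.shape != x.shape:
        raise ValueError(f"viability length {v.size} != series length {x.size}")
    if v.size < 4:
        raise ValueError("4PL fit needs at least 4 dose points")
    if not np.all(np.isfinite(v)):
        raise ValueError("viability values must be finite")

    if np.ptp(v) == 0.0:
        # flat response: exact representation, no optimizer needed
        return CurveFit4PL(
            top=float(v[0]), bottom=float(v[0]), log_ec50=float(x.mean()),
            slope=SLOPE_MIN, rmse=0.0, converged=True,
        )

    top0 = float(np.clip(v.max(), *TOP_BOUNDS))
    bot0 = float(np.clip(v.min(), *BOTTOM_BOUNDS))
    mid = 0.5 * (v.max() + v.min())
    ec0 = float(x[np.argmin(np.abs(v - mid))])
    lo = [TOP_BOUNDS[0], BOTTOM_BOUNDS[0], series.x_lo - 2.0, SLOPE_MIN]
    hi = [TOP_BOUNDS[1], BOTTOM_BOUNDS[1], series.x_hi + 2.0, SLOPE_MAX]
    p0 = [top0, bot0, float(np.clip(ec0, lo[2], hi[2])), 1.0]
    fit = optimize.least_squares(
        lambda p: logistic4(x, *p) - v, p0, bounds=(lo, hi), method="trf",
        ftol=None, gtol=None, xtol=1e-15, max_nfev=20_000,
    )
    if fit.success:
        top, bottom, log_ec50, slope = (float(p) for p in fit.x)
        rmse = float(np.sqrt(np.mean((logistic4(x, *fit.x) - v) ** 2)))
        return CurveFit4PL(top, bottom, log_ec50, slope, rmse, converged=True)
    else:
        mean_v = float(v.mean())
        rmse = float(np.sqrt(np.mean((v - mean_v) ** 2)))
        return CurveFit4PL(
            top=mean_v, bottom=mean_v, log_ec50=float(x.mean()),
            slope=SLOPE_MIN, rmse=rmse, converged=False,
        )


def _inhibition_crossing(
    fit: CurveFit4PL, level: float, x_lo: float, x_hi: float
) -> float | None:
    """First x in [x_lo, x_hi] with inhibition y(x) >= level, or None.

    For the standard monotone case (y non-decreasing) the crossing is the
    single root of 100 - v(x) - level; otherwise a fine bracketing scan
    precedes the root solve.
    """
    y_lo = float(fit.inhibition(x_lo))
    if y_lo >= level:
        return x_lo
    if fit.is_flat:
        return None
    h = lambda x: 100.0 - float(fit.viability(x)) - level
    monotone = fit.top >= fit.bottom  # slope > 0 by construction
    if monotone:
        if float(fit.inhibition(x_hi)) < level:
            return None
        return float(optimize.brentq(h, x_lo, x_hi, xtol=1e-12))
    # y decreasing: y(x_lo) < level means no later x can reach it
    grid = np.linspace(x_lo, x_hi, 512)
    above = np.nonzero(fit.inhibition(grid) >= level)[0]
    if above.size == 0:
        return None
    i = above[0]
    return float(optimize.brentq(h, grid[i - 1], grid[i], xtol=1e-12))


def _viability_antiderivative(fit: CurveFit4PL, x: float) -> float:
    """Closed-form antiderivative of v(x) for the 4PL."""
    s, m = fit.slope, fit.log_ec50
    u = s * (x - m) * LN10
    # log(1 + e^u) computed stably
    log1p_exp = u + math.log1p(math.exp(-u)) if u > 0 else math.log1p(math.exp(u))
    return fit.bottom * x + (fit.top - fit.bottom) * (x - log1p_exp / (s * LN10))


def dss(
    fit: CurveFit4PL, series: ConcentrationSeries, cfg: DSSConfig | None = None,
    entry_id: str = "",
) -> DSSResult:
    """Score one fitted curve over its tested concentration window.

    The integral is evaluated in closed form on the logistic between the
    threshold/cap crossings; adaptive quadrature handles the non-monotone
    fallback shapes. Score 0 with flag "inactive" when inhibition never
    reaches t; flag "complete_kill_at_min" when the lowest tested dose is
    already past the cap; "poor_fit" travels with high-residual or
    unconverged fits (the score is still reported).
    """
    cfg = cfg or DSSConfig()
    x_lo, x_hi = series.x_lo, series.x_hi
    width = x_hi - x_lo
    if width <= 0:
        raise ValueError("degenerate concentration window (x_hi == x_lo)")

    flags = set()
    if not fit.converged or fit.rmse > POOR_FIT_RMSE:
        flags.add("poor_fit")

    t, c = cfg.t, cfg.cap
    x1 = _inhibition_crossing(fit, t, x_lo, x_hi)
    if x1 is None:
        flags.add("inactive")
        return DSSResult(entry_id, 0.0, 0.0, None, None, cfg.metric,
                         frozenset(flags))
    x2 = _inhibition_crossing(fit, c, x_lo, x_hi)
    if x2 is None:
        x2 = x_hi
    if float(fit.inhibition(x_lo)) >= c:
        flags.add("complete_kill_at_min")

    # closed form needs 100 - v unclipped on [x1, x2]; v <= v(x1) there by
    # monotonicity, and v(x1) > 100 can only occur with t = 0
    monotone = fit.top >= fit.bottom and float(fit.viability(x1)) <= 100.0 + 1e-9
    if monotone:
        # On [x1, x2] inhibition is exactly 100 - v (no clip engages there).
        area = (100.0 - t) * (x2 - x1) - (
            _viability_antiderivative(fit, x2) - _viability_antiderivative(fit, x1)
        )
    else:
        g = lambda x: max(min(float(fit.inhibition(x)), c) - t, 0.0)
        area = integrate.quad(g, x1, x2, limit=200, epsabs=1e-10)[0]
    if cfg.tail_rule == "cap":
        area += (c - t) * (x_hi - x2)

    dss1 = 100.0 * area / ((100.0 - t) * width)
    width_factor = (x_hi - x1) / width
    if cfg.metric == "dss1":
        score = dss1
    elif cfg.metric == "mdss3":
        score = dss1 * width_factor
    else:
        grid = np.linspace(x_lo, x_hi, 2049)
        d = min(float(fit.inhibition(grid).max()), 100.0)
        if d <= 10.0:
            score = 0.0
        else:
            dss2 = dss1 / math.log10(d)
            score = dss2 if cfg.metric == "dss2" else dss2 * width_factor
    return DSSResult(entry_id, float(score), float(area), float(x1), float(x2),
                     cfg.metric, frozenset(flags))


def score_entry(
    series: ConcentrationSeries, viability, cfg: DSSConfig | None = None,
    entry_id: str = "",
) -> tuple[CurveFit4PL, DSSResult]:
    """Fit and score one entry's dose-response in a single call."""
    fit = fit_4pl(series, viability)
    return fit, dss(fit, series, cfg, entry_id=entry_id)


def score_screen(
    viab: pd.DataFrame,
    library: list[LibraryEntry],
    cfg: DSSConfig | None = None,
) -> pd.DataFrame:
    """Score every library entry present in a viability table.

    viab is the output of normalize_viability (possibly concatenated across
    plates; replicate rows for the same (entry, conc_index) are averaged).
    Singles and combinations are scored identically: a combination is one
    curve on its shared fixed-molar series. Entries with an incomplete dose
    series are skipped with a warning. Output is sorted by descending
    score, ties broken by entry_id.
    """
    cfg = cfg or DSSConfig()
    by_entry = {e.entry_id: e for e in library}
    rows = []
    for entry_id, grp in viab.groupby("entry_id", sort=True):
        entry = by_entry.get(entry_id)
        if entry is None:
            logger.warning("entry %s not in library; skipped", entry_id)
            continue
        per_dose = grp.groupby("conc_index")["viability_percent"].mean()
        n = len(entry.series)
        if sorted(per_dose.index) != list(range(n)):
            logger.warning(
                "entry %s: incomplete dose series (%d/%d doses); skipped",
                entry_id, len(per_dose), n,
            )
            continue
        v = per_dose.sort_index().to_numpy()
        fit, res = score_entry(entry.series, v, cfg, entry_id=entry_id)
        rows.append(
            {
                "entry_id": entry_id,
                "kind": entry.kind,
                "score": res.score,
                "metric": res.metric,
                "area": res.area,
                "x1": res.x1,
                "x2": res.x2,
                "top": fit.top,
                "bottom": fit.bottom,
                "log_ec50": fit.log_ec50,
                "slope": fit.slope,
                "rmse": fit.rmse,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(
            ["score", "entry_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
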