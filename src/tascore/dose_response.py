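"""Logistic dose-response fitting and sensitivity metrics (DSS, AUC, pIC50).

A dilution series is modelled with a three-parameter log-logistic inhibition
curve

    y(x) = Rmax / (1 + 10^(s * (m - x))),    x = log10(concentration in nM),

with top asymptote ``Rmax`` (% inhibition), Hill slope ``s`` and half-maximal
point ``m = log10(IC50 nM)``.  The bottom asymptote is fixed at 0% inhibition:
a four-dose series cannot identify a fourth free parameter.

The drug sensitivity score (DSS) integrates the fitted curve above a minimal
activity threshold ``Amin`` over the tested log-concentration window and
normalises by the maximal achievable area, yielding a score in [0, 100].
The integral has the closed form

    F(x) = (Rmax / (s * ln 10)) * ln(1 + 10^(s * (x - m))),

so no numerical quadrature is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import FitError, InvalidConfigError

logger = logging.getLogger(__name__)

SLOPE_MIN = 0.2
SLOPE_MAX = 10.0

__all__ = [
    "DoseResponseSeries",
    "LogisticFit",
    "DSSConfig",
    "ResponseMatrix",
    "logistic_inhibition",
    "fit_logistic",
    "dss",
    "auc_normalized",
    "pic50",
    "pic50_from_fit",
    "build_response_matrix",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """One sample x compound dilution series, oriented as % inhibition.

    Parameters
    ----------
    sample_id, compound_id
        Identifiers of the tested sample and compound.
    concentrations_nM
        Strictly positive, strictly ascending concentrations in nM.
    responses
        % inhibition at each concentration.  Use :meth:`from_viability` for
        screens reporting % viability relative to no-drug controls.
    """

    sample_id: str
    compound_id: str
    concentrations_nM: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_nM, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations_nM", conc)
        object.__setattr__(self, "responses", resp)
        if conc.ndim != 1 or conc.shape != resp.shape:
            raise InvalidConfigError("concentrations and responses must be 1-D and equal length")
        if conc.size == 0:
            raise InvalidConfigError("empty dose-response series")
        if np.any(conc <= 0):
            raise InvalidConfigError("concentrations must be strictly positive (nM)")
        if np.any(np.diff(conc) <= 0):
            raise InvalidConfigError("concentrations must be strictly ascending")
        if np.any(~np.isfinite(resp)):
            raise InvalidConfigError("responses must be finite")

    @classmethod
    def from_viability(
        cls,
        sample_id: str,
        compound_id: str,
        concentrations_nM: Sequence[float],
        viability_pct: Sequence[float],
    ) -> "DoseResponseSeries":
        """Build a series from % viability; inhibition = 100 - viability."""
        inh = 100.0 - np.asarray(viability_pct, dtype=float)
        return cls(sample_id, compound_id, np.asarray(concentrations_nM, float), inh)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations_nM)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic curve parameters.

    ``rmax`` is the top asymptote in % inhibition, ``slope`` the Hill slope
    (> 0), ``log10_ic50`` the log10 of IC50 in nM.  ``converged`` is False when
    the optimiser failed and the parameters are a best-effort fallback.
    """

    rmax: float
    slope: float
    log10_ic50: float
    residual_sse: float = float("nan")
    converged: bool = True

    def predict(self, log10_conc: np.ndarray | float) -> np.ndarray | float:
        return logistic_inhibition(log10_conc, self.rmax, self.slope, self.log10_ic50)


@dataclass(frozen=True)
class DSSConfig:
    """DSS integration settings.

    ``amin`` is the minimal activity threshold in % inhibition below which
    response is ignored.  ``x_min``/``x_max`` bound the log10(nM) integration
    window; when None they default to the tested concentration range of the
    series being scored.  ``variant`` selects the plain normalised integral
    (DSS1) or the Rmax-weighted variant (DSS2).
    """

    amin: float = 10.0
    x_min: float | None = None
    x_max: float | None = None
    variant: Literal["DSS1", "DSS2"] = "DSS1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.amin < 100.0):
            raise InvalidConfigError("amin must satisfy 0 <= amin < 100")
        if self.x_min is not None and self.x_max is not None and not (self.x_min < self.x_max):
            raise InvalidConfigError("x_min must be < x_max")
        if self.variant not in ("DSS1", "DSS2"):
            raise InvalidConfigError(f"unknown DSS variant {self.variant!r}")

    def window_for(self, series: DoseResponseSeries) -> tuple[float, float]:
        x = series.log10_concentrations
        x_min = self.x_min if self.x_min is not None else float(x.min())
        x_max = self.x_max if self.x_max is not None else float(x.max())
        if not x_min < x_max:
            raise InvalidConfigError("degenerate integration window")
        return x_min, x_max


@dataclass
class ResponseMatrix:
    """Samples x compounds matrix of a single response metric.

    ``data`` holds samples as rows and compounds as columns; missing
    sample/compound pairs are NaN.  ``metric`` records which metric the
    values are (DSS, AUC or pIC50) so downstream stages can label output.
    """

    data: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise InvalidConfigError("duplicate sample or compound ids in response matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)


def logistic_inhibition(x, rmax, slope, m):
    """Three-parameter log-logistic inhibition curve, vectorised in ``x``."""
    x = np.asarray(x, dtype=float)
    out = rmax / (1.0 + 10.0 ** (slope * (m - x)))
    return float(out) if out.ndim == 0 else out


def _clip_responses(y: np.ndarray) -> np.ndarray:
    # Raw normalised screens routinely stray outside [0, 100]; the model
    # cannot, so responses are clipped before fitting.
    return np.clip(y, 0.0, 100.0)


def fit_logistic(series: DoseResponseSeries) -> LogisticFit:
    """Fit the logistic inhibition model by bounded least squares.

    Requires >= 3 distinct concentrations.  Bounds: Rmax in [0, 100], slope
    in [0.2, 10], m within the tested log10 range +- 1.  Initialisation uses
    the maximal observed response, the dose nearest half-max and unit slope;
    on failure two further slope seeds are tried, and if all fail the best
    initialisation is returned with ``converged=False``.

    An all-constant series short-circuits to Rmax = that constant (clipped),
    slope at its lower bound and m below the tested range.
    """
    x = series.log10_concentrations
    y = _clip_responses(series.responses)
    if np.unique(series.concentrations_nM).size < 3:
        raise FitError(
            f"{series.sample_id}/{series.compound_id}: need >=3 distinct concentrations, "
            f"got {np.unique(series.concentrations_nM).size}"
        )
    x_lo, x_hi = float(x.min()), float(x.max())
    m_bounds = (x_lo - 1.0, x_hi + 1.0)

    if np.ptp(y) == 0.0:
        const = float(y[0])
        resid = float(np.sum((logistic_inhibition(x, const, SLOPE_MIN, m_bounds[0]) - y) ** 2))
        return LogisticFit(const, SLOPE_MIN, m_bounds[0], resid, converged=True)

    rmax0 = float(y.max())
    half = rmax0 / 2.0
    m0 = float(x[np.argmin(np.abs(y - half))])
    lower = np.array([0.0, SLOPE_MIN, m_bounds[0]])
    upper = np.array([100.0, SLOPE_MAX, m_bounds[1]])

    # Rmax enters the model linearly, so for fixed (slope, m) the optimal
    # Rmax has the closed form clip(sum(y*g) / sum(g^2), 0, 100) with
    # g(x) = 1/(1 + 10^(s(m-x))).  The fit is therefore profiled down to a
    # 2-D search over (slope, m): a coarse grid seeds a Nelder-Mead polish.
    def _profiled(slope: float, m: float) -> tuple[float, float]:
        g = 1.0 / (1.0 + 10.0 ** (slope * (m - x)))
        denom = float(g @ g)
        rmax = min(max(float(g @ y) / denom, 0.0), 100.0) if denom > 0 else 0.0
        resid = rmax * g - y
        return rmax, float(resid @ resid)

    def objective(p: np.ndarray) -> float:
        return _profiled(p[0], p[1])[1]

    s_grid = np.array([0.5, 1.0, 2.0, 4.0])
    m_grid = np.linspace(m_bounds[0], m_bounds[1], 13)
    g = 1.0 / (1.0 + 10.0 ** (s_grid[:, None, None] * (m_grid[None, :, None] - x)))
    denom_g = np.sum(g * g, axis=2)
    rmax_grid = np.clip(np.sum(g * y, axis=2) / np.where(denom_g > 0, denom_g, 1.0), 0.0, 100.0)
    sse_grid = np.sum((rmax_grid[:, :, None] * g - y) ** 2, axis=2)
    i_s, i_m = np.unravel_index(np.argmin(sse_grid), sse_grid.shape)

    starts = [(float(s_grid[i_s]), float(m_grid[i_m]))]
    starts += [(s0, m0) for s0 in (1.0, 0.5, 3.0)]  # extra seeds on non-convergence
    bounds_2d = [(SLOPE_MIN, SLOPE_MAX), m_bounds]
    best: tuple[float, np.ndarray, bool] | None = None
    for p0 in starts:
        res = minimize(
            objective,
            np.clip(p0, [SLOPE_MIN, m_bounds[0]], [SLOPE_MAX, m_bounds[1]]),
            method="Nelder-Mead",
            bounds=bounds_2d,
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x, bool(res.success))
        if res.success:
            break

    sse, (slope, m), converged = best
    rmax, sse = _profiled(slope, m)
    if not converged:
        logger.warning(
            "fit_logistic did not converge for %s/%s", series.sample_id, series.compound_id
        )
    return LogisticFit(float(rmax), float(slope), float(m), sse, converged=converged)


def _dss_integral(rmax: float, slope: float, m: float, amin: float, x1: float, x2: float) -> float:
    """Closed-form integral of (y(x) - amin) over [x1, x2]."""

    def antideriv(x: float) -> float:
        # log1p form is stable for large exponents
        t = slope * (x - m) * math.log(10.0)
        return (rmax / (slope * math.log(10.0))) * (t + math.log1p(math.exp(-t)) if t > 0 else math.log1p(math.exp(t)))

    return antideriv(x2) - antideriv(x1) - amin * (x2 - x1)


def dss(fit: LogisticFit, config: DSSConfig | None = None, *,
        series: DoseResponseSeries | None = None) -> float:
    """Drug sensitivity score of a fitted curve.

    The fitted curve is integrated above ``amin`` from the concentration
    ``x1`` at which it first exceeds ``amin`` (clamped to the window) up to
    ``x_max``, then normalised so a curve pinned at 100% inhibition over the
    whole window scores 100.  Curves never exceeding ``amin`` score 0.

    The window comes from ``config``; when unset there, from the tested range
    of ``series``.
    """
    config = config or DSSConfig()
    if config.x_min is None or config.x_max is None:
        if series is None:
            raise InvalidConfigError("DSS window unset: provide x_min/x_max or a series")
        x_min, x_max = config.window_for(series)
    else:
        x_min, x_max = config.x_min, config.x_max

    rmax, slope, m, amin = fit.rmax, fit.slope, fit.log10_ic50, config.amin
    if rmax <= amin:
        return 0.0
    if amin > 0.0:
        x1 = m - (1.0 / slope) * math.log10(rmax / amin - 1.0)
        x1 = min(max(x1, x_min), x_max)
    else:
        x1 = x_min
    integral = _dss_integral(rmax, slope, m, amin, x1, x_max)
    if integral <= 0.0:
        return 0.0
    score = 100.0 * integral / ((100.0 - amin) * (x_max - x_min))
    if config.variant == "DSS2":
        if rmax <= 1.0:
            return 0.0
        score *= math.log10(rmax) / 2.0
    return max(score, 0.0)


def auc_normalized(series: DoseResponseSeries) -> float:
    """Normalised area under the observed responses over log10 concentration.

    Trapezoidal area of % inhibition between the lowest and highest tested
    concentration, divided by 100 * (x_max - x_min); lies in [0, 1] for
    responses within [0, 100].
    """
    x = series.log10_concentrations
    if np.unique(x).size < 2:
        raise FitError("AUC undefined for a single dose")
    y = _clip_responses(series.responses)
    area = float(np.trapezoid(y, x))
    return area / (100.0 * (x[-1] - x[0]))


def pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 in molar units)."""
    if not ic50_molar > 0:
        raise ValueError(f"IC50 must be positive (molar), got {ic50_molar}")
    return -math.log10(ic50_molar)


def pic50_from_fit(fit: LogisticFit) -> float:
    """pIC50 from a fitted log10(IC50 nM): 1 nM = 1e-9 M, so pIC50 = 9 - m."""
    return pic50(10.0 ** fit.log10_ic50 * 1e-9)


def build_response_matrix(
    series_collection: Iterable[DoseResponseSeries],
    metric: str = "DSS",
    dss_config: DSSConfig | None = None,
) -> ResponseMatrix:
    """Score every series and arrange the values as samples x compounds.

    ``metric`` is one of ``DSS``, ``AUC`` or ``pIC50``.  Pairs absent from
    the collection are NaN in the result; duplicated pairs are an error.
    For pIC50, series whose fit did not converge are recorded as missing
    rather than floor-substituted.
    """
    metric = metric.upper() if metric.lower() != "pic50" else "pIC50"
    if metric not in ("DSS", "AUC", "pIC50"):
        raise InvalidConfigError(f"unknown metric {metric!r}; expected DSS, AUC or pIC50")
    values: dict[tuple[str, str], float] = {}
    for s in series_collection:
        key = (s.sample_id, s.compound_id)
        if key in values:
            raise InvalidConfigError(f"duplicate series for sample/compound pair {key}")
        if metric == "AUC":
            values[key] = auc_normalized(s)
        else:
            fit = fit_logistic(s)
            if metric == "DSS":
                values[key] = dss(fit, dss_config, series=s)
            else:
                values[key] = pic50_from_fit(fit) if fit.converged else float("nan")
    ser = pd.Series(values)
    data = ser.unstack()
    data.index.name = "sample_id"
    data.columns.name = "compound_id"
    return ResponseMatrix(data=data, metric=metric)
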