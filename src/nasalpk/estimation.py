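"""Polyexponential fitting and non-compartmental analysis of mean profiles.

The study design is destructive sampling: each animal contributes a single
timepoint (paired plasma and brain values), so all estimation works on the
group mean profile per (route, matrix).  Compartmental macro-constants are
obtained by weighted nonlinear least squares on the polyexponential

    C(t) = C1 exp(-Ka t) + C2 exp(-lambda1 t) + C3 exp(-lambda2 t)

(the absorption term is absent for an IV bolus).  The fit is separable:
for any candidate rate set the coefficients are the solution of a weighted
linear least-squares problem, so the nonlinear search runs over the (log)
rates only, which is markedly more robust when the absorption rate lies
close to the fast hybrid rate — the usual situation for intranasal data.

Starting values come from classical curve stripping (method of residuals),
falling back to a documented heuristic grid when peeling fails.

NCA computes the linear-trapezoid AUC with terminal log-linear extrapolation,
plus C_max / t_max.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InvalidParameterError
from .model import MacroTriexponential, Route

__all__ = [
    "Matrix",
    "MeanProfile",
    "StripResult",
    "FitResult",
    "NCAResult",
    "Weighting",
    "load_observations",
    "mean_profiles",
    "strip_exponentials",
    "fit_polyexponential",
    "nca",
]

#: plasma lower limit of quantification (ng/mL) of the bioanalytical assay
PLASMA_LOQ_NG_PER_ML = 1.0

OBSERVATION_COLUMNS = ["animal_id", "route", "matrix", "time_min", "value", "unit"]


class Matrix(str, enum.Enum):
    PLASMA = "plasma"
    BRAIN = "brain"

    @classmethod
    def parse(cls, value: "Matrix | str") -> "Matrix":
        if isinstance(value, Matrix):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise InvalidParameterError(f"unknown matrix: {value!r}") from None


class Weighting(str, enum.Enum):
    """Residual weighting scheme for the least-squares fit."""

    UNIFORM = "uniform"
    ONE_OVER_Y = "one_over_y"
    ONE_OVER_Y_SQUARED = "one_over_y_squared"

    def weights(self, y: np.ndarray) -> np.ndarray:
        if self is Weighting.UNIFORM:
            return np.ones_like(y)
        floor = 1e-8 * max(float(np.max(y)), 1e-300)
        yf = np.maximum(y, floor)
        if self is Weighting.ONE_OVER_Y:
            return 1.0 / yf
        return 1.0 / yf**2


@dataclass
class MeanProfile:
    """Group-mean concentration (plasma, ng/mL) or amount (brain, ng) profile."""

    route: Route
    matrix: Matrix
    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    n_per_time: np.ndarray | None = None
    n_blq_excluded: int = 0

    def __post_init__(self) -> None:
        self.route = Route.parse(self.route)
        self.matrix = Matrix.parse(self.matrix)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be 1-D and equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise InvalidParameterError("times must be non-negative and strictly increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("values must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.n_per_time is not None:
            self.n_per_time = np.asarray(self.n_per_time)


def load_observations(path) -> pd.DataFrame:
    """Read a tidy observation CSV (animal_id, route, matrix, time_min, value, unit)."""
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"observation CSV is missing columns: {missing}")
    return df


def mean_profiles(
    df: pd.DataFrame, plasma_loq: float | None = PLASMA_LOQ_NG_PER_ML
) -> dict[tuple[Route, Matrix], MeanProfile]:
    """Aggregate tidy observations into mean profiles by (route, matrix, time).

    Plasma values below the limit of quantification are excluded (not
    imputed); the count of excluded records is carried on the profile.
    """
    out: dict[tuple[Route, Matrix], MeanProfile] = {}
    for (route_s, matrix_s), sub in df.groupby(["route", "matrix"], sort=True):
        route = Route.parse(route_s)
        matrix = Matrix.parse(matrix_s)
        n_blq = 0
        if matrix is Matrix.PLASMA and plasma_loq is not None:
            blq = sub["value"] < plasma_loq
            n_blq = int(blq.sum())
            sub = sub[~blq]
        g = sub.groupby("time_min")["value"]
        agg = g.agg(["mean", "std", "count"]).reset_index().sort_values("time_min")
        out[(route, matrix)] = MeanProfile(
            route=route,
            matrix=matrix,
            times=agg["time_min"].to_numpy(),
            values=agg["mean"].to_numpy(),
            sd=agg["std"].to_numpy(),
            n_per_time=agg["count"].to_numpy(),
            n_blq_excluded=n_blq,
        )
    return out


# ---------------------------------------------------------------------------
# curve stripping (method of residuals)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StripResult:
    macro: MacroTriexponential
    used_fallback: bool


def _loglinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit y = C exp(-k t) by log-linear regression; returns (C, k)."""
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return float(np.exp(intercept)), float(-slope)


def _lsq_coeffs(t: np.ndarray, y: np.ndarray, rates: np.ndarray) -> np.ndarray:
    basis = np.exp(-np.outer(t, rates))
    coeffs, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coeffs


def strip_exponentials(
    profile: MeanProfile, n_terms: int, n_terminal: int = 4
) -> StripResult:
    """Classical curve stripping to obtain feasible polyexponential starts.

    The terminal phase is fitted log-linearly to give (C3, lambda2); peeling
    the residuals gives the successive faster phases.  When a peel produces
    non-positive residuals or a disordered rate, a heuristic fallback start
    is constructed (rates spaced geometrically above the terminal slope,
    coefficients by linear least squares) and flagged.
    """
    if n_terms not in (2, 3):
        raise InvalidParameterError("n_terms must be 2 or 3")
    t, y = profile.times, profile.values
    if len(t) < 2 * n_terms + 1:
        raise InvalidParameterError(
            f"need at least {2 * n_terms + 1} points for an {n_terms}-term strip"
        )

    fallback = False
    n_term_pts = min(max(n_terminal, 3), len(t) - 1)
    lam_slow, c_slow = math.nan, math.nan
    tail_t, tail_y = t[-n_term_pts:], y[-n_term_pts:]
    if np.all(tail_y > 0):
        c_slow, lam_slow = _loglinear(tail_t, tail_y)
    if not (math.isfinite(lam_slow) and lam_slow > 0 and c_slow > 0):
        fallback = True
        lam_slow = math.log(2.0) / max(t[-1] / 2.0, t[1])
        c_slow = max(float(y[-1]), 1e-12 * max(float(np.max(y)), 1.0)) * math.exp(
            lam_slow * t[-1]
        )

    resid = y - c_slow * np.exp(-lam_slow * t)
    head = slice(0, len(t) - n_term_pts)
    # residuals must rise meaningfully above float noise to be peelable
    peel_floor = 1e-9 * float(np.max(y))

    # fast (distribution) phase
    tt, rr = t[head], resid[head]
    ok = rr > peel_floor
    c_fast = math.nan
    if ok.sum() >= 2 and not fallback:
        c_fast, lam_fast = _loglinear(tt[ok], rr[ok])
        if not (lam_fast > lam_slow and c_fast > 0):
            fallback = True
    else:
        fallback = True
    if fallback:
        lam_fast = 5.0 * lam_slow
        c_fast = math.nan  # resolved by least squares below

    c_abs = math.nan
    if n_terms == 3:
        if not fallback:
            resid2 = -(resid - c_fast * np.exp(-lam_fast * t))  # absorption term is negative
            tt2, rr2 = t[head], resid2[head]
            ok2 = rr2 > peel_floor
            if ok2.sum() >= 2:
                c_abs_mag, ka = _loglinear(tt2[ok2], rr2[ok2])
                c_abs = -c_abs_mag
                if not (ka > lam_fast and c_abs_mag > 0):
                    fallback = True
            else:
                fallback = True
        if fallback:
            ka = 2.5 * lam_fast

    # assemble rates, enforce strict ordering
    if n_terms == 2:
        rates = np.array([lam_fast, lam_slow])
        coeffs = np.array([c_fast, c_slow])
    else:
        rates = np.array([ka, lam_fast, lam_slow])
        coeffs = np.array([c_abs, c_fast, c_slow])
    for i in range(len(rates) - 2, -1, -1):
        if rates[i] <= rates[i + 1] * (1 + 1e-6):
            rates[i] = rates[i + 1] * 2.0
            fallback = True
    # peeled coefficients are kept when every peel succeeded; otherwise the
    # coefficients are re-solved by linear least squares on the final rates
    if fallback or np.any(~np.isfinite(coeffs)):
        coeffs = _lsq_coeffs(t, y, rates)

    if n_terms == 2:
        macro = MacroTriexponential(0.0, coeffs[0], coeffs[1], 0.0, rates[0], rates[1], 2)
    else:
        macro = MacroTriexponential(coeffs[0], coeffs[1], coeffs[2], rates[0], rates[1], rates[2], 3)
    return StripResult(macro, fallback)


# ---------------------------------------------------------------------------
# weighted separable least squares
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a polyexponential fit.

    Non-convergence is reported via ``converged = False`` (with ``macro``
    possibly ``None``); it is never raised as an exception.
    """

    macro: MacroTriexponential | None
    residual_sse: float
    weighting: Weighting
    converged: bool
    covariance: np.ndarray | None = None
    message: str = ""
    n_obs: int = 0
    strip_fallback: bool = False


def _design_matrix(
    t: np.ndarray, rates: np.ndarray, constrain_c0: bool
) -> np.ndarray:
    e = np.exp(-np.outer(t, rates))
    if not constrain_c0:
        return e
    # C1 = -(C2 + C3): free coefficients are (C2, C3) on basis columns
    # exp(-l_i t) - exp(-Ka t)
    return e[:, 1:] - e[:, [0]]


def _coeffs_from_free(free: np.ndarray, constrain_c0: bool) -> np.ndarray:
    if not constrain_c0:
        return free
    return np.concatenate(([-free.sum()], free))


def fit_polyexponential(
    profile: MeanProfile,
    n_terms: int = 3,
    weighting: Weighting | str = Weighting.ONE_OVER_Y,
    constrain_c0: bool = False,
    start: MacroTriexponential | None = None,
    max_nfev: int = 2000,
    multistart: bool = True,
) -> FitResult:
    """Fit an ``n_terms``-exponential to a mean profile by weighted least squares.

    Rates are optimised on the log scale (guaranteeing positivity) with the
    coefficients profiled out by weighted linear least squares at every
    iteration.  Coefficients are signed; with ``constrain_c0`` the intranasal
    coefficients are reparameterised to sum to zero (C(0) = 0) — default off,
    matching common practice of fitting the three coefficients freely.
    """
    weighting = Weighting(weighting)
    t, y = profile.times, profile.values
    n_coeff_free = n_terms if not constrain_c0 else n_terms - 1
    if len(t) < 2 * n_terms + 1:
        raise InvalidParameterError(
            f"need at least {2 * n_terms + 1} points for an {n_terms}-term fit"
        )
    if not np.any(y > 0):
        return FitResult(
            macro=None,
            residual_sse=math.nan,
            weighting=weighting,
            converged=False,
            message="profile carries no signal (all values zero)",
            n_obs=len(t),
        )

    w = weighting.weights(y)
    sw = np.sqrt(w)

    strip_fallback = False
    if start is None:
        strip = strip_exponentials(profile, n_terms)
        start = strip.macro
        strip_fallback = strip.used_fallback
    _, start_rates = start.terms()

    def solve_coeffs(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        basis = _design_matrix(t, rates, constrain_c0 and n_terms == 3)
        a = basis * sw[:, None]
        b = y * sw
        free, *_ = np.linalg.lstsq(a, b, rcond=None)
        return free, a @ free - b

    def resid(log_rates: np.ndarray) -> np.ndarray:
        # clip keeps the rate search inside a physically sensible window and
        # avoids exp overflow on wild optimizer excursions
        _, r = solve_coeffs(np.exp(np.clip(log_rates, -30.0, 10.0)))
        return r

    starts = [np.log(start_rates)]
    if multistart:
        # perturb the absorption/fast-rate seed: the absorption rate is the
        # hardest to locate when it sits close to the fast hybrid
        for factor in (0.5, 2.0, 5.0):
            s = np.log(start_rates).copy()
            s[0] += math.log(factor)
            starts.append(s)

    best = None
    for s0 in starts:
        try:
            res = least_squares(resid, s0, method="lm", max_nfev=max_nfev)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[1]:
            best = (res, sse)
    if best is None:
        return FitResult(
            macro=None,
            residual_sse=math.nan,
            weighting=weighting,
            converged=False,
            message="optimizer failed from every start",
            n_obs=len(t),
            strip_fallback=strip_fallback,
        )

    res, sse = best
    rates = np.exp(np.clip(res.x, -30.0, 10.0))
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    basis_constrained = constrain_c0 and n_terms == 3
    if basis_constrained:
        # re-solve on the ordered rates (constrained basis is order-sensitive)
        free, r = solve_coeffs(rates)
        sse = float(np.sum(r**2))
        coeffs = _coeffs_from_free(free, True)
    else:
        free, r = solve_coeffs(rates)
        coeffs = free
        sse = float(np.sum(r**2))

    sep_ok = bool(np.all(np.diff(rates) < -1e-9 * rates[0]))
    converged = bool(res.success and sep_ok and np.all(np.isfinite(coeffs)))

    macro = None
    if sep_ok:
        if n_terms == 2:
            macro = MacroTriexponential(0.0, coeffs[0], coeffs[1], 0.0, rates[0], rates[1], 2)
        else:
            macro = MacroTriexponential(
                coeffs[0], coeffs[1], coeffs[2], rates[0], rates[1], rates[2], 3
            )

    covariance = None
    dof = len(t) - (len(rates) + n_coeff_free)
    if converged and dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            covariance = np.linalg.inv(jtj) * sse / dof
        except np.linalg.LinAlgError:
            covariance = None

    return FitResult(
        macro=macro,
        residual_sse=sse,
        weighting=weighting,
        converged=converged,
        covariance=covariance,
        message=res.message if hasattr(res, "message") else "",
        n_obs=len(t),
        strip_fallback=strip_fallback,
    )


# ---------------------------------------------------------------------------
# non-compartmental analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NCAResult:
    """Model-free summary of one mean profile."""

    auc_0_last: float
    auc_0_inf: float
    lambda_z: float
    c_max: float
    t_max: float
    n_terminal_points: int = 0
    c0_policy: str = "none"

    @property
    def half_life_z(self) -> float:
        return math.log(2.0) / self.lambda_z


def nca(
    profile: MeanProfile,
    n_terminal_points: int = 4,
    c0_policy: str | None = None,
) -> NCAResult:
    """Non-compartmental AUC, terminal slope and peak of a mean profile.

    AUC(0-last) uses the linear trapezoid; AUC(0-inf) adds C_last/lambda_z,
    with lambda_z from a log-linear regression on the last
    ``n_terminal_points`` values.  If the profile does not start at t = 0,
    the origin is handled per ``c0_policy``:

    * ``"zero"`` (default for extravascular and brain profiles) — anchor the
      trapezoid at (0, 0);
    * ``"backextrapolate"`` (default for IV plasma) — log-linear
      back-extrapolation of C(0) from the first two positive values;
    * ``"none"`` — integrate over the observed times only.

    A failed terminal regression (non-positive values in the window) is
    reported as ``lambda_z = nan``; AUC(0-last) is still returned.
    """
    t, y = profile.times, profile.values
    if len(t) < 3:
        raise InvalidParameterError("NCA needs at least 3 timepoints")

    if c0_policy is None:
        if profile.route is Route.IV_BOLUS and profile.matrix is Matrix.PLASMA:
            c0_policy = "backextrapolate"
        else:
            c0_policy = "zero"
    if c0_policy not in ("zero", "backextrapolate", "none"):
        raise InvalidParameterError(f"unknown c0_policy: {c0_policy!r}")

    ti, yi = t, y
    if t[0] > 0 and c0_policy != "none":
        if c0_policy == "zero":
            c0 = 0.0
        else:
            if y[0] > 0 and y[1] > 0 and y[0] > y[1]:
                c0_val, _k = _loglinear(t[:2], y[:2])
                c0 = c0_val
            else:
                c0 = y[0]  # flat/rising start: carry the first value back
        ti = np.concatenate(([0.0], t))
        yi = np.concatenate(([c0], y))

    auc_last = float(np.trapezoid(yi, ti))

    npts = min(max(n_terminal_points, 3), len(t))
    tail_t, tail_y = t[-npts:], y[-npts:]
    lambda_z = math.nan
    auc_inf = math.nan
    if np.all(tail_y > 0):
        _c, k = _loglinear(tail_t, tail_y)
        if k > 0:
            lambda_z = k
            auc_inf = auc_last + float(y[-1]) / k

    imax = int(np.argmax(y))
    return NCAResult(
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        lambda_z=lambda_z,
        c_max=float(y[imax]),
        t_max=float(t[imax]),
        n_terminal_points=npts,
        c0_policy=c0_policy,
    )
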