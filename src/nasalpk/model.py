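"""Two-compartment open model with parallel systemic and direct-to-brain absorption.

The model describes intranasal drug delivery in which the administered dose
splits between two parallel first-order absorption routes: one into the
central compartment (plasma plus well-perfused organs, rate constant ``Ka1``)
and one directly into the brain (rate constant ``Ka2``).  The central and
brain compartments exchange drug by first-order distribution (``K12``,
``K21``) and elimination occurs from the central compartment only (``K10``);
there is no elimination from the brain.  All kinetics are linear
(first-order), appropriate for low doses.

States (amounts, ng):

* ``x_depot``   — drug remaining at the absorption site,
* ``x_central`` — drug in the central compartment (concentration =
  ``x_central / V1``),
* ``x_brain``   — drug in the brain,
* ``eliminated`` — cumulative amount metabolised/excreted.

The linear system has closed-form solutions obtained by Laplace transform
and partial-fraction inversion; :func:`central_profile` and
:func:`brain_profile` evaluate them, while :func:`ode_simulate` integrates
the same equations numerically and serves as an independent oracle.

Units are fixed throughout the package: time in minutes, amounts in ng,
volumes in mL, concentrations in ng/mL, all rate constants in min^-1.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import DegeneratePoleError, InvalidParameterError

__all__ = [
    "Route",
    "DoseRegimen",
    "MicroParams",
    "HybridConstants",
    "MacroTriexponential",
    "StateTrajectory",
    "micro_to_hybrid",
    "hybrid_to_micro_iv",
    "central_macro",
    "central_profile",
    "brain_coefficients",
    "brain_profile",
    "ode_simulate",
    "params_to_json",
    "params_from_json",
]

#: relative tolerance below which two exponential rates are considered
#: coincident ("degenerate poles")
POLE_RTOL = 1e-9


class Route(str, enum.Enum):
    """Administration route."""

    IV_BOLUS = "iv"
    INTRANASAL = "in"

    @classmethod
    def parse(cls, value: "Route | str") -> "Route":
        if isinstance(value, Route):
            return value
        v = str(value).strip().lower()
        aliases = {
            "iv": cls.IV_BOLUS,
            "iv_bolus": cls.IV_BOLUS,
            "intravenous": cls.IV_BOLUS,
            "in": cls.INTRANASAL,
            "intranasal": cls.INTRANASAL,
        }
        try:
            return aliases[v]
        except KeyError:
            raise InvalidParameterError(f"unknown route: {value!r}") from None


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class DoseRegimen:
    """An administered dose.

    Parameters
    ----------
    dose_ng
        Administered drug mass in ng (must be positive).
    route
        :class:`Route` (IV bolus or intranasal).
    bioavailability_f
        Fraction F of the dose absorbed into the body, in [0, 1].
        Fixed at 1 for IV bolus.
    body_mass_kg
        Optional animal body mass, only used for mg/kg reporting.
    """

    dose_ng: float
    route: Route
    bioavailability_f: float = 1.0
    body_mass_kg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route.parse(self.route))
        _require_finite("dose_ng", self.dose_ng)
        if self.dose_ng <= 0:
            raise InvalidParameterError(f"dose_ng must be > 0, got {self.dose_ng}")
        f = _require_finite("bioavailability_f", self.bioavailability_f)
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError(f"bioavailability_f must be in [0, 1], got {f}")
        if self.route is Route.IV_BOLUS and f != 1.0:
            raise InvalidParameterError("bioavailability_f is fixed at 1 for IV bolus")
        if self.body_mass_kg is not None and self.body_mass_kg <= 0:
            raise InvalidParameterError("body_mass_kg must be positive")

    @property
    def absorbed_ng(self) -> float:
        """F * dose — the amount that actually enters the body."""
        return self.bioavailability_f * self.dose_ng

    @property
    def dose_mg_per_kg(self) -> float | None:
        if self.body_mass_kg is None:
            return None
        return self.dose_ng * 1e-6 / self.body_mass_kg


@dataclass(frozen=True)
class MicroParams:
    """Mechanistic (micro) rate constants and volumes of the model.

    ``ka1``/``ka2`` are the parallel first-order absorption rate constants
    into the central compartment and the brain respectively (both zero for
    an IV bolus), ``k12``/``k21`` the central<->brain distribution rate
    constants, ``k10`` the elimination rate constant from the central
    compartment.  ``v1`` is the central volume of distribution (mL); ``v2``
    is carried for completeness but enters no equation.
    """

    ka1: float = 0.0
    ka2: float = 0.0
    k12: float = 0.0
    k21: float = 0.0
    k10: float = 0.0
    v1: float | None = None
    v2: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka1", "ka2", "k12", "k21", "k10"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.k10 <= 0:
            raise InvalidParameterError(f"k10 must be > 0, got {self.k10}")
        for name in ("v1", "v2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise InvalidParameterError(f"{name} must be > 0 when given, got {v}")

    @property
    def ka(self) -> float:
        """Overall absorption rate constant Ka = Ka1 + Ka2."""
        return self.ka1 + self.ka2

    def require_v1(self) -> float:
        if self.v1 is None:
            raise InvalidParameterError("central volume v1 is required for concentrations")
        return self.v1


@dataclass(frozen=True)
class HybridConstants:
    """Hybrid (eigenvalue) disposition rate constants lambda1 > lambda2 > 0.

    They satisfy lambda1 + lambda2 = K12 + K21 + K10 and
    lambda1 * lambda2 = K21 * K10 for the generating micro-constants.
    """

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        _require_finite("lambda1", self.lambda1)
        _require_finite("lambda2", self.lambda2)
        if not self.lambda1 >= self.lambda2 > 0:
            raise InvalidParameterError(
                f"require lambda1 >= lambda2 > 0, got ({self.lambda1}, {self.lambda2})"
            )


@dataclass(frozen=True)
class MacroTriexponential:
    """Macro-constants of a fitted/derived polyexponential profile.

    ``n_terms == 3`` (extravascular): C(t) = C1 e^{-Ka t} + C2 e^{-l1 t}
    + C3 e^{-l2 t} with the rate ordering Ka > lambda1 > lambda2.
    Coefficients are stored SIGNED — for an exactly model-generated profile
    the absorption coefficient C1 is negative and the three coefficients sum
    to zero (C(0) = 0).  ``n_terms == 2`` (IV bolus): the absorption term is
    absent (``coeff_abs`` and ``ka`` are 0 and unused).
    """

    coeff_abs: float
    coeff_fast: float
    coeff_slow: float
    ka: float
    lambda1: float
    lambda2: float
    n_terms: int = 3

    def __post_init__(self) -> None:
        if self.n_terms not in (2, 3):
            raise InvalidParameterError(f"n_terms must be 2 or 3, got {self.n_terms}")
        for name in ("coeff_abs", "coeff_fast", "coeff_slow", "ka", "lambda1", "lambda2"):
            _require_finite(name, getattr(self, name))
        if not self.lambda1 > self.lambda2 > 0:
            raise InvalidParameterError(
                f"require lambda1 > lambda2 > 0, got ({self.lambda1}, {self.lambda2})"
            )
        if self.n_terms == 3 and not self.ka > self.lambda1:
            raise InvalidParameterError(
                f"rate ordering Ka > lambda1 violated: Ka={self.ka}, lambda1={self.lambda1}"
            )

    def terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Signed coefficients and matching rates of the active terms."""
        if self.n_terms == 2:
            return (
                np.array([self.coeff_fast, self.coeff_slow]),
                np.array([self.lambda1, self.lambda2]),
            )
        return (
            np.array([self.coeff_abs, self.coeff_fast, self.coeff_slow]),
            np.array([self.ka, self.lambda1, self.lambda2]),
        )

    def evaluate(self, times: Sequence[float]) -> np.ndarray:
        """Evaluate the polyexponential at the given times (minutes)."""
        t = np.asarray(times, dtype=float)
        coeffs, rates = self.terms()
        return np.exp(-np.outer(t, rates)) @ coeffs

    def analytic_auc(self) -> float:
        """AUC from 0 to infinity of the polyexponential: sum(C_i / rate_i)."""
        coeffs, rates = self.terms()
        return float(np.sum(coeffs / rates))

    @property
    def hybrids(self) -> HybridConstants:
        return HybridConstants(self.lambda1, self.lambda2)

    def magnitudes(self) -> dict[str, float]:
        """Report coefficients as magnitudes with a sign flag, matching the
        convention of printed PK tables."""
        out: dict[str, float] = {}
        coeffs, _ = self.terms()
        names = ("C2", "C3") if self.n_terms == 2 else ("C1", "C2", "C3")
        for name, c in zip(names, coeffs):
            out[name] = abs(float(c))
            out[f"{name}_sign"] = float(np.sign(c))
        return out


@dataclass(frozen=True)
class StateTrajectory:
    """Time course of all model states (amounts, ng)."""

    times: np.ndarray
    x_depot: np.ndarray
    x_central: np.ndarray
    x_brain: np.ndarray
    eliminated: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "x_depot", "x_central", "x_brain", "eliminated"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("trajectory times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        """Mass balance: depot + central + brain + eliminated."""
        return self.x_depot + self.x_central + self.x_brain + self.eliminated

    def concentration(self, v1: float) -> np.ndarray:
        """Central-compartment concentration X1(t)/V1 in ng/mL."""
        return self.x_central / v1

    def to_frame(self, v1: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_min": self.times,
                "x_depot_ng": self.x_depot,
                "x_central_ng": self.x_central,
                "x_brain_ng": self.x_brain,
                "eliminated_ng": self.eliminated,
            }
        )
        if v1 is not None:
            df["c_central_ng_per_ml"] = self.concentration(v1)
        return df

    def to_csv(self, path, v1: float | None = None) -> None:
        self.to_frame(v1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# macro <-> micro conversions
# ---------------------------------------------------------------------------


def micro_to_hybrid(micro: MicroParams) -> HybridConstants:
    """Hybrid rate constants from the disposition micro-constants.

    lambda1 and lambda2 are the roots of
    ``s**2 - (K12 + K21 + K10) s + K21*K10``, ordered lambda1 > lambda2.
    For a mammillary model the discriminant is provably non-negative and both
    roots are real and positive.
    """
    if micro.k10 <= 0 or micro.k21 <= 0:
        raise InvalidParameterError("micro_to_hybrid requires k10 > 0 and k21 > 0")
    b = micro.k12 + micro.k21 + micro.k10
    c = micro.k21 * micro.k10
    disc = b * b - 4.0 * c
    # guard against negative rounding error in the provably >= 0 discriminant
    disc = max(disc, 0.0)
    lam1 = 0.5 * (b + math.sqrt(disc))
    lam2 = c / lam1  # product form: numerically stable for small lambda2
    return HybridConstants(lam1, lam2)


def hybrid_to_micro_iv(macro: MacroTriexponential) -> MicroParams:
    """Disposition micro-constants from a fitted IV biexponential.

    Given the bolus biexponential C(t) = C2 e^{-l1 t} + C3 e^{-l2 t}:

    * K21 = (C2*l2 + C3*l1) / (C2 + C3)  (coefficient-weighted hybrid mean)
    * K10 = l1*l2 / K21
    * K12 = l1 + l2 - K21 - K10

    Returns a :class:`MicroParams` with ``ka1 = ka2 = 0`` and no volumes.
    """
    if macro.n_terms != 2:
        raise InvalidParameterError("hybrid_to_micro_iv expects an IV biexponential (n_terms=2)")
    c2, c3 = macro.coeff_fast, macro.coeff_slow
    l1, l2 = macro.lambda1, macro.lambda2
    if c2 <= 0 or c3 <= 0:
        raise InvalidParameterError(f"IV coefficients must be positive, got C2={c2}, C3={c3}")
    k21 = (c2 * l2 + c3 * l1) / (c2 + c3)
    k10 = l1 * l2 / k21
    k12 = l1 + l2 - k21 - k10
    # k12 >= 0 holds exactly for any positive C2, C3 (AM-GM on the weighted
    # means); tiny negatives can only come from floating-point cancellation
    k12 = max(k12, 0.0)
    return MicroParams(ka1=0.0, ka2=0.0, k12=k12, k21=k21, k10=k10)


def _check_distinct(rates: Sequence[float], context: str) -> None:
    r = np.asarray(rates, dtype=float)
    for i in range(len(r)):
        for j in range(i + 1, len(r)):
            scale = max(abs(r[i]), abs(r[j]))
            if scale == 0 or abs(r[i] - r[j]) <= POLE_RTOL * scale:
                raise DegeneratePoleError(
                    f"{context}: rates {r[i]:g} and {r[j]:g} coincide within "
                    f"relative tolerance {POLE_RTOL:g}; the simple-pole closed form "
                    "does not apply"
                )


# ---------------------------------------------------------------------------
# closed-form solutions
# ---------------------------------------------------------------------------


def central_macro(micro: MicroParams, regimen: DoseRegimen) -> MacroTriexponential:
    """Closed-form macro-constants of the central (plasma) profile.

    IV bolus: the standard two-compartment biexponential
    ``C(t) = C2 e^{-l1 t} + C3 e^{-l2 t}`` with
    ``C2 = (D/V1)(l1-K21)/(l1-l2)`` and ``C3 = (D/V1)(K21-l2)/(l1-l2)``.

    Intranasal: partial-fraction inversion of the Laplace-domain solution
    X1_bar = F*D*[Ka1(s+K21) + K21*Ka2] / [(s+Ka)(s+lambda1)(s+lambda2)]
    gives a triexponential with signed coefficients summing to zero.
    """
    v1 = micro.require_v1()
    hyb = micro_to_hybrid(micro)
    l1, l2 = hyb.lambda1, hyb.lambda2
    if regimen.route is Route.IV_BOLUS:
        if micro.ka1 != 0 or micro.ka2 != 0:
            raise InvalidParameterError("IV bolus requires ka1 = ka2 = 0")
        _check_distinct([l1, l2], "IV hybrids")
        scale = regimen.dose_ng / v1
        c2 = scale * (l1 - micro.k21) / (l1 - l2)
        c3 = scale * (micro.k21 - l2) / (l1 - l2)
        return MacroTriexponential(0.0, c2, c3, 0.0, l1, l2, n_terms=2)

    ka = micro.ka
    if ka <= 0:
        raise InvalidParameterError("intranasal administration requires ka1 + ka2 > 0")
    _check_distinct([ka, l1, l2], "absorption/hybrid rates")
    scale = regimen.absorbed_ng / v1

    def numer(p: float) -> float:
        # N(s) = Ka1 (s + K21) + K21 Ka2 evaluated at the pole s = -p
        return micro.ka1 * (micro.k21 - p) + micro.k21 * micro.ka2

    c_abs = scale * numer(ka) / ((l1 - ka) * (l2 - ka))
    c_fast = scale * numer(l1) / ((ka - l1) * (l2 - l1))
    c_slow = scale * numer(l2) / ((ka - l2) * (l1 - l2))
    return MacroTriexponential(c_abs, c_fast, c_slow, ka, l1, l2, n_terms=3)


def central_profile(
    micro: MicroParams, regimen: DoseRegimen, times: Sequence[float]
) -> np.ndarray:
    """Central-compartment concentration (ng/mL) at the given times."""
    return central_macro(micro, regimen).evaluate(times)


def brain_coefficients(
    micro: MicroParams, regimen: DoseRegimen
) -> tuple[np.ndarray, np.ndarray]:
    """Signed coefficients and rates of the brain amount closed form.

    Intranasal: X2_bar = F*D*[K12*Ka1(s+K21) + K12*K21*Ka2 + Ka2(s+l1)(s+l2)]
    / [(s+K21)(s+Ka)(s+l1)(s+l2)], inverted term by term over the four simple
    poles.  (The residue at -K21 vanishes identically when the hybrids derive
    from the same micro-constants, so effectively three terms survive.)

    IV bolus: X2(t) = K12*D*(e^{-l2 t} - e^{-l1 t})/(l1 - l2).
    """
    hyb = micro_to_hybrid(micro)
    l1, l2 = hyb.lambda1, hyb.lambda2
    if regimen.route is Route.IV_BOLUS:
        if micro.ka1 != 0 or micro.ka2 != 0:
            raise InvalidParameterError("IV bolus requires ka1 = ka2 = 0")
        _check_distinct([l1, l2], "IV hybrids")
        a = micro.k12 * regimen.dose_ng / (l1 - l2)
        return np.array([-a, a]), np.array([l1, l2])

    ka = micro.ka
    if ka <= 0:
        raise InvalidParameterError("intranasal administration requires ka1 + ka2 > 0")
    if micro.k12 == 0:
        # no distribution: the hybrids collapse onto (K10, K21) and the brain
        # receives drug through direct absorption only
        if micro.ka2 == 0:
            return np.zeros(2), np.array([ka, micro.k10])
        _check_distinct([ka, micro.k21], "brain closed-form poles")
        a = micro.ka2 * regimen.absorbed_ng / (ka - micro.k21)
        return np.array([a, -a]), np.array([micro.k21, ka])
    poles = np.array([ka, l1, l2, micro.k21])
    if micro.k21 > 0:
        _check_distinct(poles, "brain closed-form poles")
    else:
        _check_distinct(poles[:3], "brain closed-form poles")

    def numer(p: float) -> float:
        # M(s) at s = -p
        return (
            micro.k12 * micro.ka1 * (micro.k21 - p)
            + micro.k12 * micro.k21 * micro.ka2
            + micro.ka2 * (l1 - p) * (l2 - p)
        )

    fd = regimen.absorbed_ng
    coeffs = np.empty(4)
    for j, p in enumerate(poles):
        denom = np.prod(np.delete(poles, j) - p)
        coeffs[j] = fd * numer(p) / denom
    return coeffs, poles


def brain_profile(
    micro: MicroParams, regimen: DoseRegimen, times: Sequence[float]
) -> np.ndarray:
    """Brain amount (ng) at the given times, from the closed form."""
    coeffs, rates = brain_coefficients(micro, regimen)
    t = np.asarray(times, dtype=float)
    return np.exp(-np.outer(t, rates)) @ coeffs


# ---------------------------------------------------------------------------
# ODE oracle
# ---------------------------------------------------------------------------


def ode_simulate(
    micro: MicroParams,
    regimen: DoseRegimen,
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Numerically integrate the model ODEs (independent of the closed forms).

    d(depot)/dt   = -(Ka1 + Ka2) * depot
    d(central)/dt = Ka1*depot + K21*brain - (K12 + K10)*central
    d(brain)/dt   = Ka2*depot + K12*central - K21*brain
    d(elim)/dt    = K10*central

    Mass balance (sum of all states = F*dose) holds to solver tolerance.
    """
    t = np.asarray(times, dtype=float)
    if t[0] != 0:
        raise InvalidParameterError("ode_simulate requires times starting at 0")
    if regimen.route is Route.IV_BOLUS:
        if micro.ka1 != 0 or micro.ka2 != 0:
            raise InvalidParameterError("IV bolus requires ka1 = ka2 = 0")
        y0 = [0.0, regimen.dose_ng, 0.0, 0.0]
    else:
        y0 = [regimen.absorbed_ng, 0.0, 0.0, 0.0]

    ka1, ka2, k12, k21, k10 = micro.ka1, micro.ka2, micro.k12, micro.k21, micro.k10

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        depot, central, brain, _ = y
        return [
            -(ka1 + ka2) * depot,
            ka1 * depot + k21 * brain - (k12 + k10) * central,
            ka2 * depot + k12 * central - k21 * brain,
            k10 * central,
        ]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        y0,
        method="LSODA",  # stiff-capable
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return StateTrajectory(sol.t, sol.y[0], sol.y[1], sol.y[2], sol.y[3])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_JSON_KEYS = ("Ka1", "Ka2", "K12", "K21", "K10", "V1", "V2", "F", "dose_ng", "route")


def params_to_json(micro: MicroParams, regimen: DoseRegimen) -> str:
    """Serialize parameters to a flat JSON document."""
    doc = {
        "Ka1": micro.ka1,
        "Ka2": micro.ka2,
        "K12": micro.k12,
        "K21": micro.k21,
        "K10": micro.k10,
        "V1": micro.v1,
        "V2": micro.v2,
        "F": regimen.bioavailability_f,
        "dose_ng": regimen.dose_ng,
        "route": regimen.route.value,
    }
    return json.dumps(doc, indent=2)


def params_from_json(doc: str | dict) -> tuple[MicroParams, DoseRegimen]:
    """Inverse of :func:`params_to_json`."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    missing = [k for k in _JSON_KEYS if k not in doc]
    if missing:
        raise InvalidParameterError(f"parameter JSON is missing keys: {missing}")
    micro = MicroParams(
        ka1=doc["Ka1"],
        ka2=doc["Ka2"],
        k12=doc["K12"],
        k21=doc["K21"],
        k10=doc["K10"],
        v1=doc["V1"],
        v2=doc["V2"],
    )
    regimen = DoseRegimen(
        dose_ng=doc["dose_ng"],
        route=Route.parse(doc["route"]),
        bioavailability_f=doc["F"],
        body_mass_kg=doc.get("body_mass_kg"),
    )
    return micro, regimen
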