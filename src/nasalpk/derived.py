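"""Derived pharmacokinetic quantities: micro-constant chains and targeting metrics.

Everything downstream of the macro-constant fits lives here:

* the IV chain K21 -> K10 -> K12 (:func:`nasalpk.model.hybrid_to_micro_iv`),
* the intranasal chain K21(IN) = lambda1*lambda2/K10 and
  K12(IN) = lambda1 + lambda2 - K21 - K10 (K10 imported from the IV fit),
* the split of the overall absorption rate constant Ka into its systemic
  (Ka1) and direct nose-to-brain (Ka2) components from the fitted
  triexponential coefficients,
* dose-corrected bioavailability, drug targeting efficiency (DTE%),
  output-input exchange ratios, brain input rate constant K_in and
  half-lives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InconsistentRatesError, InvalidParameterError
from .model import HybridConstants, MacroTriexponential, Route

__all__ = [
    "AbsorptionSplit",
    "BrainFitParams",
    "TargetingSummary",
    "intranasal_k21_k12",
    "ka_split",
    "bioavailability",
    "dte_percent",
    "exchange_ratio",
    "half_life",
    "brain_kin",
]


def intranasal_k21_k12(
    hybrids_in: HybridConstants, k10: float
) -> tuple[float, float]:
    """Intranasal distribution rate constants from the IN hybrids and IV K10.

    K21(IN) = lambda1*lambda2 / K10 and K12(IN) = lambda1 + lambda2 - K21 - K10.
    The elimination rate constant K10 is not identifiable from extravascular
    data alone and is imported from the IV bolus fit.
    """
    if k10 <= 0:
        raise InvalidParameterError(f"k10 must be > 0, got {k10}")
    l1, l2 = hybrids_in.lambda1, hybrids_in.lambda2
    k21 = l1 * l2 / k10
    k12 = l1 + l2 - k21 - k10
    if -1e-12 * (l1 + l2) < k12 < 0:
        k12 = 0.0  # cancellation noise in the no-distribution limit
    if k12 < 0:
        raise InconsistentRatesError(
            "K12(IN) came out negative: lambda1 + lambda2 < K21 + K10 — the IN "
            "hybrids are inconsistent with the supplied K10 "
            f"(lambda1={l1:g}, lambda2={l2:g}, K10={k10:g}, K21={k21:g})",
            value=k12,
        )
    return k21, k12


@dataclass(frozen=True)
class AbsorptionSplit:
    """Decomposition of the overall absorption rate constant.

    ``frac_systemic``/``frac_brain`` are the fractions of the absorbed dose
    taking each route (Ka1/Ka and Ka2/Ka); ``n_intermediate`` is the
    dimensionless ratio N = (Ka - lambda2)/(lambda1 - Ka) used in the
    coefficient-ratio inversion.
    """

    ka: float
    ka1: float
    ka2: float
    frac_systemic: float
    frac_brain: float
    n_intermediate: float

    def __post_init__(self) -> None:
        if abs(self.ka1 + self.ka2 - self.ka) > 1e-12 * max(self.ka, 1.0):
            raise InvalidParameterError("ka1 + ka2 must equal ka")


def ka_split(macro_in: MacroTriexponential, k21_in: float) -> AbsorptionSplit:
    """Split Ka into Ka1 (systemic) and Ka2 (direct brain) absorption rates.

    From the fitted intranasal triexponential (signed coefficients C2, C3 of
    the hybrid phases, rates Ka > lambda1 > lambda2) and K21(IN):

        N   = (Ka - lambda2) / (lambda1 - Ka)
        r   = C2 / (N * C3)
        Ka2 = [r*Ka*(K21 - lambda2) - Ka*(K21 - lambda1)] / (lambda1 - r*lambda2)
        Ka1 = Ka - Ka2

    The algebra follows from the closed-form coefficient ratio of the model
    and is validated against the forward model (coefficients generated from
    known Ka1/Ka2 invert exactly).  A Ka2 outside [0, Ka] signals mutually
    inconsistent fitted inputs and raises, carrying the raw value.
    """
    if macro_in.n_terms != 3:
        raise InvalidParameterError("ka_split requires an intranasal triexponential fit")
    ka, l1, l2 = macro_in.ka, macro_in.lambda1, macro_in.lambda2
    c2, c3 = macro_in.coeff_fast, macro_in.coeff_slow
    if c3 == 0:
        raise InvalidParameterError("C3 must be nonzero to form the coefficient ratio")
    # n_terms=3 construction already guarantees Ka > lambda1 > lambda2
    n = (ka - l2) / (l1 - ka)
    r = c2 / (n * c3)
    denom = l1 - r * l2
    if denom == 0:
        raise InvalidParameterError("degenerate coefficient ratio: lambda1 = r*lambda2")
    ka2 = (r * ka * (k21_in - l2) - ka * (k21_in - l1)) / denom
    tol = 1e-10 * ka
    if not (-tol <= ka2 <= ka + tol):
        raise InconsistentRatesError(
            f"Ka2 = {ka2:g} lies outside [0, Ka = {ka:g}]: the fitted "
            "coefficients and K21(IN) are mutually inconsistent",
            value=ka2,
        )
    ka2 = min(max(ka2, 0.0), ka)
    ka1 = ka - ka2
    return AbsorptionSplit(
        ka=ka,
        ka1=ka1,
        ka2=ka2,
        frac_systemic=ka1 / ka,
        frac_brain=ka2 / ka,
        n_intermediate=n,
    )


def bioavailability(
    auc_test: float,
    auc_ref: float,
    dose_test: float,
    dose_ref: float,
    dose_corrected: bool = True,
) -> float:
    """Absolute bioavailability in percent.

    Dose-corrected (default): 100 * (AUC_test * D_ref) / (AUC_ref * D_test).
    With ``dose_corrected=False`` the plain AUC ratio is returned, a variant
    sometimes quoted when the nominal doses are equal.
    """
    for name, v in (
        ("auc_test", auc_test),
        ("auc_ref", auc_ref),
        ("dose_test", dose_test),
        ("dose_ref", dose_ref),
    ):
        if not (math.isfinite(v) and v > 0):
            raise InvalidParameterError(f"{name} must be positive and finite, got {v}")
    if not dose_corrected:
        return 100.0 * auc_test / auc_ref
    return 100.0 * (auc_test * dose_ref) / (auc_ref * dose_test)


def dte_percent(
    auc_brain_test: float,
    auc_plasma_test: float,
    auc_brain_ref: float,
    auc_plasma_ref: float,
) -> float:
    """Drug targeting efficiency in percent.

    DTE% = 100 * (AUC_brain/AUC_plasma)_test / (AUC_brain/AUC_plasma)_ref,
    the brain-to-plasma exposure ratio of the test route relative to the
    reference (IV) route.  Invariant to rescaling both matrices of one route.
    """
    for name, v in (
        ("auc_brain_test", auc_brain_test),
        ("auc_plasma_test", auc_plasma_test),
        ("auc_brain_ref", auc_brain_ref),
        ("auc_plasma_ref", auc_plasma_ref),
    ):
        if not (math.isfinite(v) and v > 0):
            raise InvalidParameterError(f"{name} must be positive and finite, got {v}")
    return 100.0 * (auc_brain_test / auc_plasma_test) / (auc_brain_ref / auc_plasma_ref)


def exchange_ratio(
    route: Route | str,
    k12: float,
    k10: float,
    k21: float,
    ka1: float | None = None,
) -> float:
    """Output-input exchange ratio R of the peripheral (brain) compartment.

    R_IV = (K12 + K10) / K21 and R_IN = (K12 + K10) / (Ka1 + K21): the ratio
    of rate constants moving drug out of, versus into, the peripheral pool.
    """
    route = Route.parse(route)
    if route is Route.IV_BOLUS:
        denom = k21
    else:
        if ka1 is None:
            raise InvalidParameterError("ka1 is required for the intranasal exchange ratio")
        denom = ka1 + k21
    if denom <= 0:
        raise InvalidParameterError(f"exchange-ratio denominator must be > 0, got {denom}")
    if k12 < 0 or k10 <= 0:
        raise InvalidParameterError("k12 must be >= 0 and k10 > 0")
    return (k12 + k10) / denom


def half_life(rate: float) -> float:
    """Half-life ln(2)/rate in minutes for a first-order rate constant."""
    if not (math.isfinite(rate) and rate > 0):
        raise InvalidParameterError(f"rate must be positive and finite, got {rate}")
    return math.log(2.0) / rate


def brain_kin(
    route: Route | str, k12_brain: float, ka2: float | None = None
) -> float:
    """Aggregate rate constant of drug entry into the brain.

    IV: K_in = K12(brain) — distribution across the BBB is the only input.
    IN: K_in = Ka2 + K12(brain) — direct nasal absorption plus distribution.
    """
    route = Route.parse(route)
    if k12_brain < 0:
        raise InvalidParameterError(f"k12_brain must be >= 0, got {k12_brain}")
    if route is Route.IV_BOLUS:
        return k12_brain
    if ka2 is None:
        raise InvalidParameterError("ka2 is required for the intranasal K_in")
    if ka2 < 0:
        raise InvalidParameterError(f"ka2 must be >= 0, got {ka2}")
    return ka2 + k12_brain


@dataclass(frozen=True)
class BrainFitParams:
    """Biexponential description of a brain amount-time profile."""

    lambda1_brain: float
    lambda2_brain: float
    k_in: float | None = None

    def __post_init__(self) -> None:
        if not self.lambda1_brain > self.lambda2_brain > 0:
            raise InvalidParameterError(
                "require lambda1_brain > lambda2_brain > 0, got "
                f"({self.lambda1_brain}, {self.lambda2_brain})"
            )


@dataclass(frozen=True)
class TargetingSummary:
    """Machine-readable twin of the route-comparison parameter tables."""

    f_plasma_pct: float
    f_brain_pct: float
    dte_pct: float
    r_iv: float
    r_in: float
    k_in_iv: float = math.nan
    k_in_in: float = math.nan
    half_lives: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "F, %": self.f_plasma_pct,
            "F_brain, %": self.f_brain_pct,
            "DTE, %": self.dte_pct,
            "R_IV": self.r_iv,
            "R_IN": self.r_in,
            "K_in(IV), min^-1": self.k_in_iv,
            "K_in(IN), min^-1": self.k_in_in,
            **{f"t1/2 {name}, min": v for name, v in self.half_lives.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame({"parameter": list(d), "value": list(d.values())})
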