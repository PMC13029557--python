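"""Virtual destructive-sampling PK studies for pipeline testing and calibration.

Emulates the study design the analysis assumes: rats receive ~100 ug of drug
IV (solution, bolus) or intranasally (nanoparticle suspension), and each
animal is sampled terminally at a single timepoint, contributing one paired
plasma concentration and brain amount.  Group means over 6-12 animals per
timepoint form the profiles the estimation module consumes.

Observations are the closed-form model means perturbed by multiplicative
lognormal residual error (mean 1, specified CV) — plasma and brain noise are
independent within an animal, and there are no between-animal random effects
on the rate constants (a pooled-mean analysis cannot identify any).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .model import (
    DoseRegimen,
    MicroParams,
    Route,
    brain_profile,
    central_profile,
)

__all__ = ["StudyDesign", "TruthRecord", "default_truth", "generate_study"]

#: default sampling grid (minutes) — early-dense to resolve absorption,
#: extending to 6 h to pin the terminal phase
DEFAULT_TIMEPOINTS = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0, 360.0)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a virtual destructive-sampling study.

    Defaults reflect the experimental conditions the analysis targets:
    100 ug (1e5 ng) doses, at least six rats (~275 g) per timepoint per
    route, and a 15% residual coefficient of variation typical of LC-MS/MS
    bioanalysis of biological matrices.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_per_timepoint: int = 6
    routes: tuple[Route, ...] = (Route.IV_BOLUS, Route.INTRANASAL)
    dose_ng: float = 100_000.0
    body_mass_mean_kg: float = 0.275
    body_mass_sd_kg: float = 0.015
    residual_cv: float = 0.15
    plasma_loq: float = 1.0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(
            self, "routes", tuple(Route.parse(r) for r in self.routes)
        )
        if len(tp) == 0 or any(b - a <= 0 for a, b in zip(tp, tp[1:])) or tp[0] <= 0:
            raise InvalidParameterError("timepoints must be positive and strictly increasing")
        if self.n_per_timepoint < 1:
            raise InvalidParameterError("n_per_timepoint must be >= 1")
        if self.residual_cv < 0:
            raise InvalidParameterError("residual_cv must be >= 0")
        if self.dose_ng <= 0:
            raise InvalidParameterError("dose_ng must be > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a dataset bit-exactly."""

    design: StudyDesign
    micro: dict[Route, MicroParams]
    regimens: dict[Route, DoseRegimen]
    seed: int

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "design": {
                **dataclasses.asdict(self.design),
                "routes": [r.value for r in self.design.routes],
            },
            "truth": {
                route.value: {
                    "Ka1": m.ka1,
                    "Ka2": m.ka2,
                    "K12": m.k12,
                    "K21": m.k21,
                    "K10": m.k10,
                    "V1": m.v1,
                    "V2": m.v2,
                    "F": self.regimens[route].bioavailability_f,
                    "dose_ng": self.regimens[route].dose_ng,
                    "route": route.value,
                }
                for route, m in self.micro.items()
            },
        }
        return json.dumps(doc, indent=2)


def default_truth(
    v1_ml: float = 276.0, dose_ng: float = 100_000.0
) -> dict[Route, tuple[MicroParams, DoseRegimen]]:
    """Canonical simulation truth: the fitted rat CBD parameter set.

    IV: two-compartment disposition with K10 = 0.0275, K12 = 0.0897,
    K21 = 0.0146 min^-1 and V1 = 276 mL.  IN: the same elimination with
    intranasal distribution (K12 = 0.0697, K21 = 0.0107), absorption split
    Ka1 = 0.0489 (systemic) / Ka2 = 0.0623 (direct brain) min^-1 and
    absolute bioavailability F = 0.479.
    """
    iv_micro = MicroParams(ka1=0.0, ka2=0.0, k12=0.0897, k21=0.0146, k10=0.0275, v1=v1_ml)
    in_micro = MicroParams(
        ka1=0.0489, ka2=0.0623, k12=0.0697, k21=0.0107, k10=0.0275, v1=v1_ml
    )
    return {
        Route.IV_BOLUS: (iv_micro, DoseRegimen(dose_ng, Route.IV_BOLUS, 1.0)),
        Route.INTRANASAL: (
            in_micro,
            DoseRegimen(dose_ng, Route.INTRANASAL, 0.479),
        ),
    }


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal deviates with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=sigma, size=size)


def generate_study(
    design: StudyDesign,
    truth: dict[Route, tuple[MicroParams, DoseRegimen]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one destructive-sampling study.

    Each virtual animal is assigned to a single (route, timepoint) cell and
    contributes a paired plasma concentration (ng/mL) and brain amount (ng),
    each equal to the closed-form model mean times an independent lognormal
    deviate.  Plasma values below the LOQ are flagged, not removed.

    Returns a tidy observation table (estimation-module CSV schema plus a
    ``below_loq`` flag) and the :class:`TruthRecord` that regenerates it.
    """
    if truth is None:
        truth = default_truth(dose_ng=design.dose_ng)
    rng = np.random.default_rng(seed)
    times = np.asarray(design.timepoints)

    rows: list[dict] = []
    animal = 0
    for route in design.routes:
        micro, regimen = truth[route]
        plasma_mean = central_profile(micro, regimen, times)
        brain_mean = brain_profile(micro, regimen, times)
        for i, t in enumerate(times):
            n = design.n_per_timepoint
            mult_plasma = _lognormal_multipliers(rng, design.residual_cv, n)
            mult_brain = _lognormal_multipliers(rng, design.residual_cv, n)
            masses = rng.normal(design.body_mass_mean_kg, design.body_mass_sd_kg, n)
            for j in range(n):
                animal += 1
                cp = plasma_mean[i] * mult_plasma[j]
                xb = brain_mean[i] * mult_brain[j]
                rows.append(
                    {
                        "animal_id": f"{route.value}-{animal:04d}",
                        "route": route.value,
                        "matrix": "plasma",
                        "time_min": t,
                        "value": cp,
                        "unit": "ng_per_ml",
                        "body_mass_kg": round(masses[j], 4),
                        "below_loq": bool(cp < design.plasma_loq),
                    }
                )
                rows.append(
                    {
                        "animal_id": f"{route.value}-{animal:04d}",
                        "route": route.value,
                        "matrix": "brain",
                        "time_min": t,
                        "value": xb,
                        "unit": "ng",
                        "body_mass_kg": round(masses[j], 4),
                        "below_loq": False,
                    }
                )

    df = pd.DataFrame(rows)
    record = TruthRecord(
        design=design,
        micro={r: truth[r][0] for r in design.routes},
        regimens={r: truth[r][1] for r in design.routes},
        seed=seed,
    )
    return df, record
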