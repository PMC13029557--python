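"""Shared fixtures: the published rat CBD constants and random admissible models."""

from __future__ import annotations

import numpy as np
import pytest

from nasalpk.model import (
    DoseRegimen,
    MacroTriexponential,
    MicroParams,
    Route,
    micro_to_hybrid,
)

#: published plasma macro-constants (IV column): biexponential bolus profile
IV_MACRO = {"C2": 329.0, "C3": 33.3, "lambda1": 0.1286, "lambda2": 0.0031}

#: published plasma macro-constants (IN column): triexponential profile
IN_MACRO = {
    "C1": 1259.3,
    "C2": 1200.3,
    "C3": 18.0,
    "Ka": 0.1112,
    "lambda1": 0.1051,
    "lambda2": 0.0028,
}

#: published micro-constants and summary metrics
IV_MICRO = {"K10": 0.0275, "K12": 0.0897, "K21": 0.0146}
IN_MICRO = {"K12": 0.0697, "K21": 0.0107, "Ka1": 0.0489, "Ka2": 0.0623}
AUCS = {
    "plasma_iv": 13185.3,
    "plasma_in": 6844.3,
    "brain_iv": 14700.1,
    "brain_in": 4536.1,
}
DOSES_MG_PER_KG = {"iv": 0.36, "in": 0.39}


@pytest.fixture
def iv_macro_printed() -> MacroTriexponential:
    return MacroTriexponential(
        0.0,
        IV_MACRO["C2"],
        IV_MACRO["C3"],
        0.0,
        IV_MACRO["lambda1"],
        IV_MACRO["lambda2"],
        n_terms=2,
    )


@pytest.fixture
def in_macro_printed() -> MacroTriexponential:
    # stored signed: the absorption coefficient is negative
    return MacroTriexponential(
        -IN_MACRO["C1"],
        IN_MACRO["C2"],
        IN_MACRO["C3"],
        IN_MACRO["Ka"],
        IN_MACRO["lambda1"],
        IN_MACRO["lambda2"],
        n_terms=3,
    )


def random_micro(
    rng: np.random.Generator, with_absorption: bool = True, v1: float = 100.0
) -> MicroParams:
    """Draw an admissible micro-constant set with well-separated poles.

    Disposition rates are log-uniform over physiological ranges; the overall
    absorption rate is placed strictly above lambda1 (the rate ordering the
    model asserts) and away from all other poles.
    """
    k10 = float(np.exp(rng.uniform(np.log(0.01), np.log(0.3))))
    k21 = float(np.exp(rng.uniform(np.log(0.005), np.log(0.2))))
    k12 = float(np.exp(rng.uniform(np.log(0.005), np.log(0.5))))
    if not with_absorption:
        return MicroParams(0.0, 0.0, k12, k21, k10, v1=v1)
    lam1 = micro_to_hybrid(MicroParams(0, 0, k12, k21, k10)).lambda1
    ka = lam1 * float(rng.uniform(1.3, 8.0))
    frac_brain = float(rng.uniform(0.05, 0.95))
    return MicroParams(ka * (1 - frac_brain), ka * frac_brain, k12, k21, k10, v1=v1)


def regimen_for(micro: MicroParams, dose_ng: float = 100_000.0, f: float = 0.5) -> DoseRegimen:
    if micro.ka1 == 0 and micro.ka2 == 0:
        return DoseRegimen(dose_ng, Route.IV_BOLUS, 1.0)
    return DoseRegimen(dose_ng, Route.INTRANASAL, f)
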