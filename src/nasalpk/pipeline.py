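"""End-to-end orchestration: observations -> fits -> derived constants -> report.

The analysis sequence mirrors how a two-route (IV reference + intranasal)
brain-targeting study is evaluated:

1. aggregate tidy observations into mean profiles per (route, matrix);
2. fit the IV plasma biexponential; derive K21, K10, K12 (the elimination
   rate constant is only identifiable from the IV data);
3. fit the intranasal plasma triexponential; derive K21(IN), K12(IN) using
   the IV K10, then split Ka into Ka1/Ka2;
4. NCA AUCs for all profiles; bioavailability, brain bioavailability, DTE%,
   exchange ratios, half-lives;
5. render plasma and brain parameter tables, a brain/plasma ratio table and
   a predicted-vs-observed table, plus a machine-readable JSON bundle.

The intermediate constants (K21(iv), K10, N, r) are echoed in the report:
they are exactly where inconsistent fits first become visible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import derived, estimation, model
from .derived import TargetingSummary
from .estimation import FitResult, Matrix, MeanProfile, NCAResult, Weighting
from .exceptions import InvalidParameterError, PipelineError
from .model import MacroTriexponential, Route, hybrid_to_micro_iv

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "brain_plasma_ratio"]


@dataclass(frozen=True)
class RunConfig:
    """Options controlling one pipeline run; serialized into every report."""

    dose_iv_ng: float = 100_000.0
    dose_in_ng: float = 100_000.0
    weighting: Weighting = Weighting.ONE_OVER_Y
    constrain_c0: bool = False
    lambda_z_points: int = 4
    plasma_loq: float | None = estimation.PLASMA_LOQ_NG_PER_ML
    k12_brain_iv: float | None = None
    k12_brain_in: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "weighting", Weighting(self.weighting))
        if self.dose_iv_ng <= 0 or self.dose_in_ng <= 0:
            raise InvalidParameterError("doses must be positive")
        if self.lambda_z_points < 3:
            raise InvalidParameterError("lambda_z_points must be >= 3")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["weighting"] = self.weighting.value
        return d


def brain_plasma_ratio(plasma: MeanProfile, brain: MeanProfile) -> pd.DataFrame:
    """Element-wise brain/plasma ratio at the timepoints shared by both profiles.

    Times where plasma is zero yield a missing value (NaN), never infinity.
    """
    shared = np.intersect1d(plasma.times, brain.times)
    if len(shared) == 0:
        raise InvalidParameterError("profiles share no timepoints")
    p = plasma.values[np.isin(plasma.times, shared)]
    b = brain.values[np.isin(brain.times, shared)]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, b / np.where(p > 0, p, 1.0), np.nan)
    return pd.DataFrame({"time_min": shared, "ratio": ratio})


@dataclass
class PipelineReport:
    """Full result bundle of one pipeline run."""

    config: RunConfig
    fits: dict[str, FitResult]
    nca: dict[str, NCAResult]
    intermediates: dict[str, float]
    summary: TargetingSummary
    plasma_table: pd.DataFrame
    brain_table: pd.DataFrame | None
    ratio_tables: dict[str, pd.DataFrame]
    pred_obs_tables: dict[str, pd.DataFrame]

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())

    def to_json(self) -> str:
        def df_records(df: pd.DataFrame) -> list[dict]:
            # to_dict keeps full double precision through json round trips
            return df.to_dict(orient="records")

        doc: dict[str, Any] = {
            "config": self.config.to_dict(),
            "converged": {k: bool(f.converged) for k, f in self.fits.items()},
            "macros": {
                k: {
                    "coeff_abs": f.macro.coeff_abs,
                    "coeff_fast": f.macro.coeff_fast,
                    "coeff_slow": f.macro.coeff_slow,
                    "ka": f.macro.ka,
                    "lambda1": f.macro.lambda1,
                    "lambda2": f.macro.lambda2,
                    "n_terms": f.macro.n_terms,
                }
                for k, f in self.fits.items()
                if f.macro is not None
            },
            "nca": {
                k: dataclasses.asdict(r) for k, r in self.nca.items()
            },
            "intermediates": self.intermediates,
            "summary": self.summary.to_dict(),
            "tables": {
                "plasma": df_records(self.plasma_table),
                "brain": df_records(self.brain_table) if self.brain_table is not None else None,
                "ratio": {k: df_records(v) for k, v in self.ratio_tables.items()},
                "pred_obs": {k: df_records(v) for k, v in self.pred_obs_tables.items()},
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _fit_key(route: Route, matrix: Matrix) -> str:
    return f"{route.value}_{matrix.value}"


def _half_life_or_nan(rate: float) -> float:
    try:
        return derived.half_life(rate)
    except InvalidParameterError:
        return math.nan


def run_pipeline(
    observations: pd.DataFrame, config: RunConfig | None = None
) -> PipelineReport:
    """Run the full analysis on a tidy observation table.

    Raises :class:`PipelineError` if the IV plasma profile is missing (K10
    cannot be derived without it) or the plasma fits fail to converge.
    """
    config = config or RunConfig()
    profiles = estimation.mean_profiles(observations, plasma_loq=config.plasma_loq)

    key_iv_p = (Route.IV_BOLUS, Matrix.PLASMA)
    key_in_p = (Route.INTRANASAL, Matrix.PLASMA)
    if key_iv_p not in profiles:
        raise PipelineError(
            "no IV plasma observations: the elimination rate constant K10 can "
            "only be derived from the IV bolus profile"
        )
    if key_in_p not in profiles:
        raise PipelineError("no intranasal plasma observations: nothing to analyse")

    fits: dict[str, FitResult] = {}
    nca_results: dict[str, NCAResult] = {}

    fit_iv = estimation.fit_polyexponential(
        profiles[key_iv_p], n_terms=2, weighting=config.weighting
    )
    fits[_fit_key(*key_iv_p)] = fit_iv
    if not fit_iv.converged or fit_iv.macro is None:
        raise PipelineError(f"IV plasma fit did not converge: {fit_iv.message}")

    fit_in = estimation.fit_polyexponential(
        profiles[key_in_p],
        n_terms=3,
        weighting=config.weighting,
        constrain_c0=config.constrain_c0,
    )
    fits[_fit_key(*key_in_p)] = fit_in
    if not fit_in.converged or fit_in.macro is None:
        raise PipelineError(f"intranasal plasma fit did not converge: {fit_in.message}")

    macro_iv: MacroTriexponential = fit_iv.macro
    macro_in: MacroTriexponential = fit_in.macro

    # IV chain
    micro_iv = hybrid_to_micro_iv(macro_iv)
    k10 = micro_iv.k10
    v1_iv = config.dose_iv_ng / (macro_iv.coeff_fast + macro_iv.coeff_slow)

    # IN chain
    k21_in, k12_in = derived.intranasal_k21_k12(macro_in.hybrids, k10)
    split = derived.ka_split(macro_in, k21_in)

    # NCA everywhere available
    for key, prof in profiles.items():
        nca_results[_fit_key(*key)] = estimation.nca(
            prof, n_terminal_points=config.lambda_z_points
        )

    auc_iv_p = nca_results[_fit_key(*key_iv_p)].auc_0_inf
    auc_in_p = nca_results[_fit_key(*key_in_p)].auc_0_inf
    f_plasma = derived.bioavailability(
        auc_in_p, auc_iv_p, config.dose_in_ng, config.dose_iv_ng
    )

    # brain side (optional)
    key_iv_b = (Route.IV_BOLUS, Matrix.BRAIN)
    key_in_b = (Route.INTRANASAL, Matrix.BRAIN)
    have_brain = key_iv_b in profiles and key_in_b in profiles
    f_brain = math.nan
    dte = math.nan
    brain_fits: dict[Route, FitResult] = {}
    if have_brain:
        auc_iv_b = nca_results[_fit_key(*key_iv_b)].auc_0_inf
        auc_in_b = nca_results[_fit_key(*key_in_b)].auc_0_inf
        f_brain = derived.bioavailability(
            auc_in_b, auc_iv_b, config.dose_in_ng, config.dose_iv_ng
        )
        dte = derived.dte_percent(auc_in_b, auc_in_p, auc_iv_b, auc_iv_p)
        for key in (key_iv_b, key_in_b):
            bf = estimation.fit_polyexponential(
                profiles[key], n_terms=2, weighting=config.weighting
            )
            fits[_fit_key(*key)] = bf
            brain_fits[key[0]] = bf

    r_iv = derived.exchange_ratio(Route.IV_BOLUS, micro_iv.k12, k10, micro_iv.k21)
    r_in = derived.exchange_ratio(Route.INTRANASAL, k12_in, k10, k21_in, ka1=split.ka1)

    # K_in needs a brain-side K12, which a plasma-driven analysis cannot
    # identify; it is reported only when supplied in the config.
    k_in_iv = (
        derived.brain_kin(Route.IV_BOLUS, config.k12_brain_iv)
        if config.k12_brain_iv is not None
        else math.nan
    )
    k_in_in = (
        derived.brain_kin(Route.INTRANASAL, config.k12_brain_in, ka2=split.ka2)
        if config.k12_brain_in is not None
        else math.nan
    )

    half_lives = {
        "Ka (IN)": _half_life_or_nan(macro_in.ka),
        "lambda1 (IV)": _half_life_or_nan(macro_iv.lambda1),
        "lambda2 (IV)": _half_life_or_nan(macro_iv.lambda2),
        "lambda1 (IN)": _half_life_or_nan(macro_in.lambda1),
        "lambda2 (IN)": _half_life_or_nan(macro_in.lambda2),
    }
    if math.isfinite(k_in_iv):
        half_lives["K_in (IV)"] = _half_life_or_nan(k_in_iv)
    if math.isfinite(k_in_in):
        half_lives["K_in (IN)"] = _half_life_or_nan(k_in_in)

    summary = TargetingSummary(
        f_plasma_pct=f_plasma,
        f_brain_pct=f_brain,
        dte_pct=dte,
        r_iv=r_iv,
        r_in=r_in,
        k_in_iv=k_in_iv,
        k_in_in=k_in_in,
        half_lives=half_lives,
    )

    intermediates = {
        "K21(iv)": micro_iv.k21,
        "K10": k10,
        "K12(iv)": micro_iv.k12,
        "K21(in)": k21_in,
        "K12(in)": k12_in,
        "N": split.n_intermediate,
        "r": macro_in.coeff_fast / (split.n_intermediate * macro_in.coeff_slow),
        "V1(iv), mL": v1_iv,
    }

    plasma_table = _plasma_table(
        macro_iv, macro_in, nca_results, micro_iv, k21_in, k12_in, split, f_plasma, v1_iv
    )
    brain_table = (
        _brain_table(brain_fits, nca_results, f_brain, k_in_iv, k_in_in)
        if have_brain
        else None
    )

    ratio_tables: dict[str, pd.DataFrame] = {}
    pred_obs_tables: dict[str, pd.DataFrame] = {}
    for route in (Route.IV_BOLUS, Route.INTRANASAL):
        kp, kb = (route, Matrix.PLASMA), (route, Matrix.BRAIN)
        if kp in profiles and kb in profiles:
            ratio_tables[route.value] = brain_plasma_ratio(profiles[kp], profiles[kb])
        if kp in profiles:
            macro = macro_iv if route is Route.IV_BOLUS else macro_in
            prof = profiles[kp]
            pred_obs_tables[route.value] = pd.DataFrame(
                {
                    "time_min": prof.times,
                    "observed": prof.values,
                    "predicted": macro.evaluate(prof.times),
                }
            )

    return PipelineReport(
        config=config,
        fits=fits,
        nca=nca_results,
        intermediates=intermediates,
        summary=summary,
        plasma_table=plasma_table,
        brain_table=brain_table,
        ratio_tables=ratio_tables,
        pred_obs_tables=pred_obs_tables,
    )


def _plasma_table(
    macro_iv: MacroTriexponential,
    macro_in: MacroTriexponential,
    nca_results: dict[str, NCAResult],
    micro_iv: model.MicroParams,
    k21_in: float,
    k12_in: float,
    split: derived.AbsorptionSplit,
    f_plasma: float,
    v1_iv: float,
) -> pd.DataFrame:
    nan = math.nan
    rows = [
        ("C1", nan, abs(macro_in.coeff_abs)),
        ("C2", macro_iv.coeff_fast, macro_in.coeff_fast),
        ("C3", macro_iv.coeff_slow, macro_in.coeff_slow),
        ("lambda1, min^-1", macro_iv.lambda1, macro_in.lambda1),
        ("lambda2, min^-1", macro_iv.lambda2, macro_in.lambda2),
        (
            "t1/2 lambda2, min",
            _half_life_or_nan(macro_iv.lambda2),
            _half_life_or_nan(macro_in.lambda2),
        ),
        ("Ka, min^-1", nan, macro_in.ka),
        ("t1/2 Ka, min", nan, _half_life_or_nan(macro_in.ka)),
        ("V1, mL", v1_iv, nan),
        (
            "AUC 0-inf, ng*min/mL",
            nca_results["iv_plasma"].auc_0_inf,
            nca_results["in_plasma"].auc_0_inf,
        ),
        ("F, %", 100.0, f_plasma),
        ("K10, min^-1", micro_iv.k10, nan),
        ("K12, min^-1", micro_iv.k12, nan),
        ("K21, min^-1", micro_iv.k21, nan),
        ("K12(IN), min^-1", nan, k12_in),
        ("K21(IN), min^-1", nan, k21_in),
        ("Ka1, min^-1", nan, split.ka1),
        ("Ka2, min^-1", nan, split.ka2),
        ("Ka1 fraction, %", nan, 100.0 * split.frac_systemic),
        ("Ka2 fraction, %", nan, 100.0 * split.frac_brain),
    ]
    return pd.DataFrame(rows, columns=["parameter", "IV", "IN"])


def _brain_table(
    brain_fits: dict[Route, FitResult],
    nca_results: dict[str, NCAResult],
    f_brain: float,
    k_in_iv: float,
    k_in_in: float,
) -> pd.DataFrame:
    nan = math.nan

    def lam(route: Route, which: int) -> float:
        f = brain_fits.get(route)
        if f is None or f.macro is None:
            return nan
        return f.macro.lambda1 if which == 1 else f.macro.lambda2

    rows = [
        ("lambda1, min^-1", lam(Route.IV_BOLUS, 1), lam(Route.INTRANASAL, 1)),
        ("lambda2, min^-1", lam(Route.IV_BOLUS, 2), lam(Route.INTRANASAL, 2)),
        (
            "t1/2 lambda2, min",
            _half_life_or_nan(lam(Route.IV_BOLUS, 2)),
            _half_life_or_nan(lam(Route.INTRANASAL, 2)),
        ),
        ("K_in, min^-1", k_in_iv, k_in_in),
        (
            "t1/2 (in), min",
            _half_life_or_nan(k_in_iv),
            _half_life_or_nan(k_in_in),
        ),
        (
            "AUC 0-inf, ng*min",
            nca_results["iv_brain"].auc_0_inf,
            nca_results["in_brain"].auc_0_inf,
        ),
        ("F_brain, %", 100.0, f_brain),
    ]
    return pd.DataFrame(rows, columns=["parameter", "IV", "IN"])
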