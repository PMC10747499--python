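"""Empirical compartmental models and nonlinear least-squares estimation.

The parameter-estimation step fits first-order-depot compartmental models to
observed plasma concentration–time data: a one-compartment model (Bateman
kinetics) for IM administration and a two-compartment model for MAP
administration.  The depot rate constant ka plays the role of the
nanoparticle release rate K_NP, and the two-compartment inter-compartmental
clearance Q maps one-to-one onto the trans-skin volumetric rate K_SKIN
(canonical volumes are mL = cm³).  A second estimator wraps the full PBPK
simulator as the regression function to estimate CL/F (and optionally K_NP,
K_SKIN or the Vd correction) by curve-fitting.

Canonical units: µg, mL, h; concentrations µg/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .engine import ConcentrationSeries, Regimen, simulate_at
from .parameters import DrugParameters
from .physiology import Subject

#: default parameter bounds (canonical units)
DEFAULT_BOUNDS = {
    "ka_h": (1e-5, 1.0),
    "cl_ml_h": (1e-2, 1e6),
    "v_ml": (1.0, 1e7),
    "q_ml_h": (1e-6, 1e6),
    "v2_ml": (1.0, 1e8),
}

_PARAM_NAMES = {
    "one_compartment": ("ka_h", "cl_ml_h", "v_ml"),
    "two_compartment": ("ka_h", "cl_ml_h", "v_ml", "q_ml_h", "v2_ml"),
}


class FitFailureError(RuntimeError):
    """Raised when no optimisation start converges to a usable fit."""


@dataclass(frozen=True)
class EmpiricalModelSpec:
    """A fully parameterised empirical depot model.

    ``ka_h`` is the first-order depot input rate; ``cl_ml_h``/``v_ml`` the
    apparent clearance and central volume; ``q_ml_h``/``v2_ml`` the
    inter-compartmental clearance and peripheral volume (two-compartment
    only).  All parameters are apparent (divided by bioavailability).
    """

    kind: str
    ka_h: float
    cl_ml_h: float
    v_ml: float
    q_ml_h: float | None = None
    v2_ml: float | None = None
    dose_ug: float = 1.0
    dose_times_h: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.kind not in _PARAM_NAMES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        for name in _PARAM_NAMES[self.kind]:
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dose_ug <= 0:
            raise ValueError("dose must be positive")

    @property
    def parameters(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_NAMES[self.kind]}


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit."""

    estimates: dict[str, float]
    rss: float
    converged: bool
    residuals: np.ndarray
    n_starts: int
    seed: int
    spec: EmpiricalModelSpec | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("RSS cannot be negative")


def _one_compartment_unit(times: np.ndarray, ka: float, ke: float
                          ) -> np.ndarray:
    """Central amount per unit dose for first-order input; Bateman kinetics
    with the ka → ke limit handled analytically."""
    t = np.maximum(times, 0.0)
    out = np.zeros_like(t)
    pos = times >= 0
    if abs(ka - ke) <= 1e-10 * max(ka, ke):
        out[pos] = ka * t[pos] * np.exp(-ka * t[pos])
    else:
        out[pos] = ka / (ka - ke) * (np.exp(-ke * t[pos])
                                     - np.exp(-ka * t[pos]))
    return out


def _two_compartment_unit(times: np.ndarray, ka: float, k10: float,
                          k12: float, k21: float) -> np.ndarray:
    """Central amount per unit dose for depot + biexponential disposition,
    via the macro-constant (partial fraction) solution."""
    # α, β: roots of s² + (k10+k12+k21)s + k10·k21
    b = k10 + k12 + k21
    disc = math.sqrt(max(b * b - 4.0 * k10 * k21, 0.0))
    alpha, beta = (b + disc) / 2.0, (b - disc) / 2.0
    # nudge degenerate rate coincidences (measure-zero inputs)
    rates = [alpha, beta, ka]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(rates[i] - rates[j]) <= 1e-9 * max(rates[i], rates[j]):
                rates[j] *= 1.0 + 1e-7
    alpha, beta, ka = rates
    t = np.maximum(times, 0.0)
    coef_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_k = (k21 - ka) / ((alpha - ka) * (beta - ka))
    out = ka * (coef_a * np.exp(-alpha * t) + coef_b * np.exp(-beta * t)
                + coef_k * np.exp(-ka * t))
    out[times < 0] = 0.0
    return out


def predict_empirical(spec: EmpiricalModelSpec,
                      times_h: np.ndarray) -> np.ndarray:
    """Plasma concentrations (µg/mL) at the given times; multi-dose profiles
    by superposition of time-shifted single doses (linear kinetics)."""
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0):
        raise ValueError("times must be non-negative")
    ka, cl, v = spec.ka_h, spec.cl_ml_h, spec.v_ml
    conc = np.zeros_like(times_h)
    for td in spec.dose_times_h:
        shifted = times_h - td
        if spec.kind == "one_compartment":
            unit = _one_compartment_unit(shifted, ka, cl / v)
        else:
            unit = _two_compartment_unit(shifted, ka, cl / v,
                                         spec.q_ml_h / v,
                                         spec.q_ml_h / spec.v2_ml)
        conc += spec.dose_ug * unit / v
    return conc


def _rates_and_coefficients(spec: EmpiricalModelSpec
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential rates and absolute coefficients of the single-dose
    central concentration c(t) = Σ C_i·exp(−r_i·t)."""
    ka, v = spec.ka_h, spec.v_ml
    m = spec.dose_ug * ka / v
    if spec.kind == "one_compartment":
        ke = spec.cl_ml_h / v
        rates = np.array([ka, ke])
        coefs = np.array([-m / (ka - ke), m / (ka - ke)])
        return rates, coefs
    k10 = spec.cl_ml_h / v
    k12 = spec.q_ml_h / v
    k21 = spec.q_ml_h / spec.v2_ml
    b = k10 + k12 + k21
    disc = math.sqrt(max(b * b - 4.0 * k10 * k21, 0.0))
    alpha, beta = (b + disc) / 2.0, (b - disc) / 2.0
    rates = np.array([ka, alpha, beta])
    coefs = m * np.array([
        (k21 - ka) / ((alpha - ka) * (beta - ka)),
        (k21 - alpha) / ((ka - alpha) * (beta - alpha)),
        (k21 - beta) / ((ka - beta) * (alpha - beta)),
    ])
    return rates, coefs


def canonicalize_flip_flop(spec: EmpiricalModelSpec) -> EmpiricalModelSpec:
    """Return the equivalent parameter set with ka as the *slowest*
    exponential rate (the flip-flop convention for long-acting depots).

    First-order-depot compartment models are only identifiable up to an
    exchange of the exponential rates: distinct parameter sets produce
    identical curves.  For a long-acting formulation the depot release is
    the rate-limiting step, so the conventional representative assigns the
    slowest rate to ka.  If no valid (all-positive) parameter set exists
    with that assignment, the input is returned unchanged.
    """
    if spec.kind == "one_compartment":
        # (ka, ke, V) ≡ (ke, ka, V·ke/ka); CL is invariant
        ka, v = spec.ka_h, spec.v_ml
        ke = spec.cl_ml_h / v
        if ka <= ke * (1 + 1e-12):
            return spec
        return replace(spec, ka_h=ke, v_ml=v * ke / ka)
    rates, coefs = _rates_and_coefficients(spec)
    if np.argsort(rates)[0] == 0:  # ka already slowest
        return spec
    if np.min(np.diff(np.sort(rates))) <= 1e-12 * rates.max():
        return spec  # degenerate rate coincidence: keep as fitted
    ka, beta, alpha = np.sort(rates)     # target: ka slowest, alpha fastest
    c_alpha = float(coefs[np.argmin(np.abs(rates - alpha))])
    c_beta = float(coefs[np.argmin(np.abs(rates - beta))])
    if c_beta == 0 or not np.isfinite(c_alpha / c_beta):
        return spec
    rho = c_alpha / c_beta
    denom = rho * (ka - alpha) + (ka - beta)
    if denom == 0:
        return spec
    k21 = (rho * (ka - alpha) * beta + alpha * (ka - beta)) / denom
    if not 0 < k21:
        return spec
    k10 = alpha * beta / k21
    k12 = alpha + beta - k10 - k21
    v1 = spec.dose_ug * ka * (k21 - alpha) / (
        c_alpha * (ka - alpha) * (beta - alpha))
    if min(k10, k12, v1) <= 0:
        return spec
    return replace(spec, ka_h=ka, cl_ml_h=k10 * v1, v_ml=v1,
                   q_ml_h=k12 * v1, v2_ml=k12 * v1 / k21)


def kskin_from_two_compartment(fit: FitResult) -> float:
    """Map the fitted inter-compartmental clearance Q onto the trans-skin
    volumetric rate K_SKIN (cm³/h), one-to-one in canonical units."""
    if "q_ml_h" not in fit.estimates:
        raise ValueError("fit is not a two-compartment model")
    return fit.estimates["q_ml_h"]


def _multistart_least_squares(residual_fn, names, init, bounds, n_starts,
                              seed) -> tuple[np.ndarray, object, int]:
    """Multi-start NLS in log-parameter space; returns the best solution."""
    rng = np.random.default_rng(seed)
    lo = np.log([bounds[n][0] for n in names])
    hi = np.log([bounds[n][1] for n in names])
    starts = [np.log([init[n] for n in names])]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(lo, hi))
    best, best_cost = None, np.inf
    n_ok = 0
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, np.clip(x0, lo, hi),
                                bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if sol.success:
            n_ok += 1
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    if best is None:
        raise FitFailureError("no optimisation start converged")
    return np.exp(best.x), best, n_ok


def fit_empirical(observed: ConcentrationSeries, kind: str,
                  dose_ug: float, dose_times_h: tuple[float, ...] = (0.0,),
                  init: dict[str, float] | None = None,
                  bounds: dict[str, tuple[float, float]] | None = None,
                  log_scale: bool = False, n_starts: int = 10,
                  seed: int = 0, canonical: bool = True) -> FitResult:
    """Fit an empirical depot model to observed data by nonlinear least
    squares (multi-start, seeded; untransformed-concentration objective by
    default, log-concentration optional).

    ``canonical`` maps the winning solution to its flip-flop representative
    (ka = slowest exponential rate); depot models are only identifiable up
    to that exchange, and for a long-acting formulation the depot is the
    rate-limiting step.
    """
    names = _PARAM_NAMES[kind]
    if len(observed.times_h) < len(names):
        raise ValueError("need at least as many observations as parameters")
    if np.all(observed.conc_ug_ml <= 0):
        raise FitFailureError("observed concentrations are identically zero")
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    default_init = {"ka_h": 1e-2, "cl_ml_h": 1e2, "v_ml": 1e3,
                    "q_ml_h": 1e1, "v2_ml": 1e3}
    init = {**default_init, **(init or {})}

    obs = observed.conc_ug_ml
    floor = max(obs[obs > 0].min() * 1e-6, 1e-12)

    def residual(log_params: np.ndarray) -> np.ndarray:
        params = dict(zip(names, np.exp(log_params)))
        spec = EmpiricalModelSpec(kind=kind, dose_ug=dose_ug,
                                  dose_times_h=tuple(dose_times_h), **params)
        pred = predict_empirical(spec, observed.times_h)
        if log_scale:
            return np.log(np.maximum(pred, floor)) - np.log(
                np.maximum(obs, floor))
        return pred - obs

    values, sol, n_ok = _multistart_least_squares(
        residual, names, init, bnds, n_starts, seed)
    spec = EmpiricalModelSpec(kind=kind, dose_ug=dose_ug,
                              dose_times_h=tuple(dose_times_h),
                              **dict(zip(names, values)))
    if canonical:
        spec = canonicalize_flip_flop(spec)
    estimates = spec.parameters
    res = residual(np.log([estimates[n] for n in names]))
    return FitResult(estimates=estimates, rss=float(res @ res),
                     converged=True, residuals=res, n_starts=n_ok,
                     seed=seed, spec=spec, message=sol.message)


#: PBPK parameters that may be freed in the curve-fitting estimator
_PBPK_FREE = ("clf_l_h", "knp_h", "kskin_cm3_h", "vd_correction")
_PBPK_BOUNDS = {"clf_l_h": (1e-6, 1e2), "knp_h": (1e-6, 1.0),
                "kskin_cm3_h": (1e-8, 1e2), "vd_correction": (1e-4, 1e2)}


def estimate_clf_by_curvefit(subject: Subject, drug: DrugParameters,
                             regimen: Regimen,
                             observed: ConcentrationSeries,
                             free_params: tuple[str, ...] = ("clf_l_h",),
                             bounds: dict[str, tuple[float, float]] | None = None,
                             n_starts: int = 5, seed: int = 0) -> FitResult:
    """Estimate CL/F (and optionally K_NP, K_SKIN, Vd correction) by fitting
    the full PBPK simulator to observed concentrations."""
    bad = [p for p in free_params if p not in _PBPK_FREE]
    if bad:
        raise ValueError(f"cannot free {bad}; allowed: {_PBPK_FREE}")
    bnds = {**_PBPK_BOUNDS, **(bounds or {})}
    init = {"clf_l_h": drug.clf_l_h, "knp_h": drug.knp_h,
            "kskin_cm3_h": drug.kskin_cm3_h,
            "vd_correction": subject.vd_correction}

    def residual(log_params: np.ndarray) -> np.ndarray:
        params = dict(zip(free_params, np.exp(log_params)))
        vd = params.pop("vd_correction", subject.vd_correction)
        d = replace(drug, **params) if params else drug
        s = replace_subject_vd(subject, vd)
        pred = simulate_at(s, d, regimen, observed.times_h)
        return pred - observed.conc_ug_ml

    values, sol, n_ok = _multistart_least_squares(
        residual, free_params, init, bnds, n_starts, seed)
    estimates = dict(zip(free_params, values))
    res = residual(np.log(values))
    return FitResult(estimates=estimates, rss=float(res @ res),
                     converged=True, residuals=res, n_starts=n_ok,
                     seed=seed, message=sol.message)


def replace_subject_vd(subject: Subject, vd_correction: float) -> Subject:
    """Copy of a subject with a different Vd correction factor."""
    import copy

    out = copy.copy(subject)
    out.vd_correction = vd_correction
    return out
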