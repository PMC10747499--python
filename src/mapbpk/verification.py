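"""PK summary metrics and model-verification statistics.

Verification compares predicted against observed pharmacokinetic values with
two conventional statistics: the predicted:observed ratio (accepted in
[0.5, 2]) and the absolute average fold error,

    AAFE = 10^((1/N) Σ |log10(predicted_i / observed_i)|),

accepted in [1, 2].  Interval endpoints count as passes; reports display two
decimals but comparisons use full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import ConcentrationSeries

RATIO_LIMITS = (0.5, 2.0)
AAFE_LIMITS = (1.0, 2.0)


@dataclass
class PKSummary:
    """Summary metrics over a simulated or observed series.

    ``auc`` is over the stated window in the stated unit; ``c_at`` holds
    spot concentrations (e.g. day 28).  Steady-state peak/trough refer to
    the final complete dosing interval of the horizon.
    """

    auc: float | None = None
    auc_window: tuple[float, float] | None = None
    auc_unit: str = "ug_day_ml"
    cmax: float | None = None
    cmax_first: float | None = None
    cmax_ss: float | None = None
    cmin_ss: float | None = None
    c_at: dict[str, float] = field(default_factory=dict)
    time_to_threshold_days: dict[str, float | None] = field(
        default_factory=dict)

    def metrics(self) -> dict[str, float]:
        out = {}
        for name in ("auc", "cmax", "cmax_first", "cmax_ss", "cmin_ss"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        out.update(self.c_at)
        return out


def auc(series: ConcentrationSeries, t0_h: float, t1_h: float,
        unit: str = "ug_h_ml") -> float:
    """Trapezoidal area under the curve over [t0, t1] (h), in µg·h/mL or
    µg·day/mL."""
    if unit not in ("ug_h_ml", "ug_day_ml"):
        raise ValueError(f"unknown AUC unit {unit!r}")
    if t0_h > t1_h:
        raise ValueError("empty or inverted window")
    tmin, tmax = series.times_h[0], series.times_h[-1]
    if t0_h < tmin - 1e-9 or t1_h > tmax + 1e-9:
        raise ValueError("window outside the simulated span")
    if t0_h == t1_h:
        return 0.0
    # restrict to the window, interpolating the endpoints
    inside = (series.times_h > t0_h) & (series.times_h < t1_h)
    t = np.concatenate(([t0_h], series.times_h[inside], [t1_h]))
    c = np.concatenate(([series.at(t0_h)], series.conc_ug_ml[inside],
                        [series.at(t1_h)]))
    value = float(np.trapezoid(c, t))
    return value / 24.0 if unit == "ug_day_ml" else value


def ratio(predicted: float, observed: float) -> float:
    """Predicted:observed ratio."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed


def aafe(predicted, observed) -> float:
    """Absolute average fold error; 1 means perfect agreement, and for a
    single pair it equals max(ratio, 1/ratio)."""
    pred = np.atleast_1d(np.asarray(predicted, dtype=float))
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("need equal-length, non-empty vectors")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("all values must be positive")
    return float(10.0 ** np.mean(np.abs(np.log10(pred / obs))))


def profile_aafe(predicted: ConcentrationSeries,
                 observed: ConcentrationSeries,
                 timepoints_h: np.ndarray | None = None) -> float:
    """AAFE between a predicted curve (linearly interpolated) and observed
    concentrations at the observed timepoints."""
    t = np.asarray(observed.times_h if timepoints_h is None else timepoints_h,
                   dtype=float)
    if t.min() < predicted.times_h[0] or t.max() > predicted.times_h[-1]:
        raise ValueError("observed timepoints outside the predicted span")
    pred = np.interp(t, predicted.times_h, predicted.conc_ug_ml)
    obs = np.interp(t, observed.times_h, observed.conc_ug_ml)
    return aafe(pred, obs)


@dataclass
class MetricVerification:
    metric: str
    observed: float
    predicted: float
    ratio: float
    aafe: float
    ratio_pass: bool
    aafe_pass: bool


@dataclass
class VerificationReport:
    """Per-metric ratio/AAFE results plus optional whole-profile AAFE."""

    rows: list[MetricVerification]
    profile_aafe: float | None = None
    profile_pass: bool | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        ok = all(r.ratio_pass and r.aafe_pass for r in self.rows)
        if self.profile_pass is not None:
            ok = ok and self.profile_pass
        return ok

    def to_dict(self) -> dict:
        return {
            "metrics": [vars(r) for r in self.rows],
            "profile_aafe": self.profile_aafe,
            "profile_pass": self.profile_pass,
            "all_pass": self.all_pass,
            "criteria": {"ratio": list(RATIO_LIMITS),
                         "aafe": list(AAFE_LIMITS)},
            "notes": self.notes,
        }


def verify(predicted: dict[str, float], observed: dict[str, float],
           predicted_series: ConcentrationSeries | None = None,
           observed_series: ConcentrationSeries | None = None,
           notes: list[str] | None = None) -> VerificationReport:
    """Build a verification report for matched metric names.

    Boundary values (ratio 0.5 or 2, AAFE 1 or 2) count as passes (closed
    intervals).
    """
    missing = sorted(set(observed) - set(predicted))
    if missing:
        raise KeyError(f"no prediction for observed metrics: {missing}")
    rows = []
    for name in observed:
        r = ratio(predicted[name], observed[name])
        a = aafe([predicted[name]], [observed[name]])
        rows.append(MetricVerification(
            metric=name, observed=observed[name], predicted=predicted[name],
            ratio=r, aafe=a,
            ratio_pass=RATIO_LIMITS[0] <= r <= RATIO_LIMITS[1],
            aafe_pass=AAFE_LIMITS[0] <= a <= AAFE_LIMITS[1]))
    prof = prof_pass = None
    if predicted_series is not None and observed_series is not None:
        prof = profile_aafe(predicted_series, observed_series)
        prof_pass = AAFE_LIMITS[0] <= prof <= AAFE_LIMITS[1]
    return VerificationReport(rows=rows, profile_aafe=prof,
                              profile_pass=prof_pass, notes=notes or [])


def summarize(series: ConcentrationSeries, interval_h: float | None = None,
              n_doses: int = 1,
              c_at_h: dict[str, float] | None = None,
              auc_window_h: tuple[float, float] | None = None,
              auc_unit: str = "ug_day_ml") -> PKSummary:
    """Compute the standard summary metrics for one concentration series."""
    out = PKSummary(auc_unit=auc_unit)
    out.cmax = float(series.conc_ug_ml.max())
    if auc_window_h is not None:
        out.auc = auc(series, *auc_window_h, unit=auc_unit)
        out.auc_window = auc_window_h
    for name, t in (c_at_h or {}).items():
        out.c_at[name] = series.at(t)
    if interval_h is not None and n_doses >= 2:
        first = series.conc_ug_ml[series.times_h <= interval_h]
        out.cmax_first = float(first.max())
        t0, t1 = (n_doses - 1) * interval_h, n_doses * interval_h
        t1 = min(t1, float(series.times_h[-1]))
        last = (series.times_h >= t0) & (series.times_h <= t1)
        out.cmax_ss = float(series.conc_ug_ml[last].max())
        out.cmin_ss = float(series.conc_ug_ml[last].min())
    return out
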