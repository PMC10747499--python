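"""Synthetic observed datasets and packaged study fixtures.

Real concentration–time curves for the in vivo studies exist only as
figures; the repository deliberately ships just the printed summary metrics
(see ``load_fixture``).  For everything profile-shaped — parameter-recovery
studies, fitting demos, round-trip tests — this module generates synthetic
"observed" series with the statistical structure the analysis assumes:
sparse sampling schedules, proportional + additive measurement noise, and an
optional lower limit of quantification (LLOQ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .empirical import EmpiricalModelSpec, predict_empirical
from .engine import ConcentrationSeries, Regimen, simulate_at
from .parameters import DrugParameters
from .physiology import Subject

#: default sparse sampling schedules (h); exact in vivo sampling times are
#: not available, so these are design assumptions documented as such
SINGLE_DOSE_SCHEDULE_H = (6.0, 12.0, 24.0, 48.0, 72.0, 120.0, 168.0,
                          240.0, 336.0, 504.0, 672.0)
#: weekly study (6 doses): pre-dose troughs, 24 h post dose 4, day 42
WEEKLY_SCHEDULE_H = (24.0, 168.0, 336.0, 504.0, 528.0, 672.0, 840.0, 1008.0)


@dataclass(frozen=True)
class NoiseModel:
    """Proportional + additive measurement noise with an optional LLOQ."""

    proportional_cv: float = 0.15
    additive_sd_ug_ml: float = 0.01
    lloq_ug_ml: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd_ug_ml < 0:
            raise ValueError("noise magnitudes must be non-negative")


def synth_profile(truth: EmpiricalModelSpec
                  | tuple[Subject, DrugParameters, Regimen],
                  schedule_h, noise: NoiseModel
                  ) -> tuple[ConcentrationSeries, np.ndarray]:
    """One noisy synthetic series on a sampling schedule.

    ``truth`` is either an empirical model spec or a (subject, drug,
    regimen) triple simulated through the PBPK engine.  Observed value =
    prediction × (1 + CV·ε₁) + SD·ε₂, truncated at zero; returns the series
    and a boolean below-LLOQ flag per point.  Deterministic per seed.
    """
    times = np.asarray(schedule_h, dtype=float)
    if times.size == 0:
        raise ValueError("schedule is empty")
    if isinstance(truth, EmpiricalModelSpec):
        clean = predict_empirical(truth, times)
    else:
        subject, drug, regimen = truth
        clean = simulate_at(subject, drug, regimen, times)
    rng = np.random.default_rng(noise.seed)
    noisy = (clean * (1.0 + noise.proportional_cv * rng.standard_normal(
        times.size)) + noise.additive_sd_ug_ml * rng.standard_normal(
        times.size))
    noisy = np.maximum(noisy, 0.0)
    below = (np.zeros(times.size, dtype=bool) if noise.lloq_ug_ml is None
             else noisy < noise.lloq_ug_ml)
    return ConcentrationSeries(times_h=times, conc_ug_ml=noisy), below


@dataclass
class StudyBundle:
    """Synthetic in vivo study: per-animal series, their mean, and the
    generating truth for recovery assertions."""

    truth: EmpiricalModelSpec
    animals: list[ConcentrationSeries]
    schedule_h: tuple[float, ...]

    @property
    def mean_series(self) -> ConcentrationSeries:
        stack = np.vstack([a.conc_ug_ml for a in self.animals])
        return ConcentrationSeries(times_h=np.asarray(self.schedule_h),
                                   conc_ug_ml=stack.mean(axis=0))


#: generating truth for the synthetic rat MAP studies: two-compartment depot
#: kinetics at the rat-estimated release rate.  CL/V place the profile on
#: the observed µg/mL scale; Q/V2 are set so the peripheral phase is
#: identifiable at these designs (a global-identifiability requirement of
#: the recovery tests, documented in the methods note).
RAT_MAP_TRUTH = dict(kind="two_compartment", ka_h=3.43e-3, cl_ml_h=2.2,
                     v_ml=40.0, q_ml_h=0.6, v2_ml=30.0)


def make_rat_map_study(seed: int = 0, n_animals: int = 6,
                       noise: NoiseModel | None = None
                       ) -> dict[str, StudyBundle]:
    """Synthetic single-dose and once-weekly 11.72 mg rat MAP studies.

    Returns ``{"single": bundle, "weekly": bundle}``; each bundle carries
    the generating parameters (including K_NP = 3.43 × 10⁻³ h⁻¹) so fits can
    be checked against truth.  Deterministic per seed.
    """
    base_noise = noise or NoiseModel()
    dose_ug = 11.72e3
    out = {}
    designs = {
        "single": (SINGLE_DOSE_SCHEDULE_H, (0.0,)),
        "weekly": (WEEKLY_SCHEDULE_H,
                   tuple(168.0 * k for k in range(6))),
    }
    for si, (name, (schedule, dose_times)) in enumerate(designs.items()):
        truth = EmpiricalModelSpec(dose_ug=dose_ug, dose_times_h=dose_times,
                                   **RAT_MAP_TRUTH)
        animals = []
        for a in range(n_animals):
            nm = NoiseModel(proportional_cv=base_noise.proportional_cv,
                            additive_sd_ug_ml=base_noise.additive_sd_ug_ml,
                            lloq_ug_ml=base_noise.lloq_ug_ml,
                            seed=seed * 1000 + si * 100 + a)
            series, _ = synth_profile(truth, schedule, nm)
            animals.append(series)
        out[name] = StudyBundle(truth=truth, animals=animals,
                                schedule_h=schedule)
    return out


# --- packaged printed-table fixtures --------------------------------------


@dataclass(frozen=True)
class MetricValue:
    value: float
    sd: float | None
    unit: str


@dataclass(frozen=True)
class FixtureTable:
    """Printed observed/predicted summary metrics for one study."""

    name: str
    description: str
    species: str
    route: str
    dose_mg: float
    metrics: dict[str, MetricValue]
    profile_aafe: float | None = None
    raw: dict = field(default_factory=dict, repr=False)


def _load_raw_fixtures() -> dict:
    text = (resources.files("mapbpk") / "data"
            / "observed_metrics.json").read_text()
    return json.loads(text)


def available_fixtures() -> list[str]:
    names = []
    for study in _load_raw_fixtures():
        names += [study, f"{study}_observed", f"{study}_predicted"]
    return sorted(names)


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged metric table.

    ``name`` is a study key (``rat_im``, ``rat_map_single``,
    ``rat_map_weekly``, ``human_im``) optionally suffixed with
    ``_observed`` or ``_predicted`` to select that column.
    """
    raw = _load_raw_fixtures()
    column = "observed"
    study = name
    for suffix in ("_observed", "_predicted"):
        if name.endswith(suffix):
            study, column = name[: -len(suffix)], suffix[1:]
    if study not in raw:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {available_fixtures()}")
    entry = raw[study]
    metrics = {}
    for metric, row in entry["metrics"].items():
        if column not in row:
            continue
        metrics[metric] = MetricValue(value=float(row[column]),
                                      sd=row.get(f"{column}_sd"),
                                      unit=row["unit"])
    return FixtureTable(name=name, description=entry["description"],
                        species=entry["species"], route=entry["route"],
                        dose_mg=float(entry["dose_mg"]), metrics=metrics,
                        profile_aafe=entry.get("profile_aafe"), raw=entry)
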