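"""Tabular IO, run configuration and the pipeline runner.

Canonical on-disk units are stated in every file: times in hours,
concentrations in µg/mL, doses in mg, areas in cm².  Concentration series
are CSV with columns ``time_h, conc_ug_per_mL``; reports are JSON with
explicit unit fields (the source tables mix µg·day/mL and µg·h/mL, so
nothing is left implicit).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import ConcentrationSeries, Regimen
from .parameters import VD_CORRECTION, DrugParameters, cabotegravir
from .physiology import cohort_to_frame, generate_human_cohort, \
    generate_rat_cohort
from .regimen import TargetSpec, dose_ladder, simulate_cohort, \
    target_attainment
from .verification import verify

TIMESERIES_COLUMNS = ("time_h", "conc_ug_per_mL")


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


def read_timeseries_csv(path) -> ConcentrationSeries:
    """Read a concentration series; rejects malformed rows, duplicate times
    and negative concentrations, reporting the offending line."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in TIMESERIES_COLUMNS:
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ConfigError(
                    f"{path}:{line}: non-numeric {col}={row[col]!r}")
        if float(row["conc_ug_per_mL"]) < 0:
            raise ConfigError(f"{path}:{line}: negative concentration")
    df = df.astype(float).sort_values("time_h")
    if df["time_h"].duplicated().any():
        t = df.loc[df["time_h"].duplicated(), "time_h"].iloc[0]
        raise ConfigError(f"{path}: duplicate time {t}")
    return ConcentrationSeries(times_h=df["time_h"].to_numpy(),
                               conc_ug_ml=df["conc_ug_per_mL"].to_numpy())


def write_timeseries_csv(path, series: ConcentrationSeries,
                         extra_columns: dict[str, np.ndarray] | None = None
                         ) -> None:
    """Write a series at full precision with a units header comment."""
    path = Path(path)
    data = {"time_h": series.times_h, "conc_ug_per_mL": series.conc_ug_ml}
    data.update(extra_columns or {})
    with open(path, "w") as fh:
        fh.write("# times in hours, concentrations in ug/mL\n")
        pd.DataFrame(data).to_csv(fh, index=False,
                                  float_format=lambda x: repr(float(x)))


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    scenario: dict = field(default_factory=dict)   # species, route
    cohort: dict = field(default_factory=dict)
    regimen: dict = field(default_factory=dict)
    doses_mg: list[float] | None = None            # ladder mode
    drug_overrides: dict = field(default_factory=dict)
    solver: dict = field(default_factory=lambda: {"grid_dt_h": 0.5})
    seed: int = 0
    output_dir: str = "runs/out"
    verify_fixture: str | None = None

    _KEYS = ("scenario", "cohort", "regimen", "doses_mg", "drug_overrides",
             "solver", "seed", "output_dir", "verify_fixture")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = sorted(set(raw) - set(cls._KEYS))
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        cfg = cls(**{k: v for k, v in raw.items() if k in cls._KEYS})
        species = cfg.scenario.get("species")
        route = cfg.scenario.get("route")
        if (species, route) not in VD_CORRECTION:
            raise ConfigError(f"unknown scenario {species}/{route}")
        if not cfg.regimen and not cfg.doses_mg:
            raise ConfigError("config needs a regimen or a dose ladder")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific content (where outputs go is excluded)."""
        content = {k: v for k, v in asdict(self).items()
                   if k != "output_dir"}
        canon = json.dumps(content, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_cohort(cfg: RunConfig):
    species = cfg.scenario["species"]
    c = dict(cfg.cohort)
    n = int(c.pop("n", 100))
    if species == "rat":
        return generate_rat_cohort(
            n, c.pop("weight_mean_kg", 0.25), c.pop("weight_sd_kg", 0.02),
            seed=cfg.seed)
    return generate_human_cohort(
        n, c.pop("female_fraction", 0.5),
        tuple(c.pop("age_range", (18.0, 60.0))), seed=cfg.seed)


def _drug_for(cfg: RunConfig) -> DrugParameters:
    from dataclasses import replace

    drug = cabotegravir(cfg.scenario["species"], cfg.scenario["route"])
    return replace(drug, **cfg.drug_overrides) if cfg.drug_overrides else drug


# metric-name → (kind, arguments) recipes for the packaged study tables
_METRIC_RECIPES = {
    "auc_0_28": ("auc", (0.0, 28 * 24.0), "ug_day_ml"),
    "auc_0_w4": ("auc", (0.0, 4 * 168.0), "ug_h_ml"),
    "auc_0_w12": ("auc", (0.0, 12 * 168.0), "ug_h_ml"),
    "cmax": ("cmax", None, None),
    "cmax_first": ("cmax_first", None, None),
    "cmax_ss": ("cmax_ss", None, None),
    "c28": ("at", 28 * 24.0, None),
    "c42": ("at", 42 * 24.0, None),
    "c_w4": ("at", 4 * 168.0, None),
}


def predicted_metrics_for_study(series: ConcentrationSeries,
                                metric_names, interval_h: float = 168.0,
                                n_doses: int = 1) -> dict[str, float]:
    """Compute the named study metrics from a simulated mean curve."""
    from .verification import auc as auc_fn, summarize

    summary = summarize(series, interval_h=interval_h, n_doses=n_doses)
    out = {}
    for name in metric_names:
        if name not in _METRIC_RECIPES:
            raise KeyError(f"no recipe for metric {name!r}")
        kind, arg, unit = _METRIC_RECIPES[name]
        if kind == "auc":
            out[name] = auc_fn(series, *arg, unit=unit)
        elif kind == "at":
            out[name] = series.at(arg)
        else:
            out[name] = getattr(summary, kind)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute cohort → simulate → (verify | attainment) and write a run
    directory with curves, reports and a reproducibility manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    cohort = _build_cohort(config)
    cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)
    log.append(f"cohort: {len(cohort)} {config.scenario['species']} subjects")

    drug = _drug_for(config)
    vd = VD_CORRECTION[(config.scenario["species"],
                        config.scenario["route"])]
    grid_dt = float(config.solver.get("grid_dt_h", 0.5))

    reports: dict[str, object] = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "version": __version__,
        "units": {"time": "h", "concentration": "ug/mL", "dose": "mg"},
        "vd_correction": vd,
        "dermal_blood_flow_note": (
            "Q_DE derived from the configurable per-area perfusion default"),
    }

    if config.doses_mg:
        table, results = dose_ladder(
            list(config.doses_mg), cohort, drug,
            vd_correction=vd, grid_dt_h=grid_dt,
            **{k: v for k, v in config.regimen.items()
               if k in ("interval_h", "n_doses", "horizon_h")})
        for dose, res in results.items():
            write_timeseries_csv(
                out / f"mean_curve_{dose:g}mg.csv", res.mean_series,
                extra_columns={"sd_ug_per_mL": res.sd_conc})
        table.to_csv(out / "dose_ladder.csv", index=False)
        reports["dose_ladder"] = table.to_dict(orient="records")
        log.append(f"ladder: doses {config.doses_mg} mg")
    else:
        regimen = Regimen(route=config.scenario["route"], **config.regimen)
        result = simulate_cohort(cohort, drug, regimen, grid_dt_h=grid_dt,
                                 vd_correction=vd)
        write_timeseries_csv(out / "mean_curve.csv", result.mean_series,
                             extra_columns={"sd_ug_per_mL": result.sd_conc})
        att = target_attainment(result) if regimen.n_doses >= 2 else None
        if att is not None:
            reports["attainment"] = att.per_threshold
        if config.verify_fixture:
            from .synthetic import load_fixture

            fixture = load_fixture(config.verify_fixture)
            observed = {k: m.value for k, m in fixture.metrics.items()}
            predicted = predicted_metrics_for_study(
                result.mean_series, observed, interval_h=regimen.interval_h,
                n_doses=regimen.n_doses)
            report = verify(predicted, observed)
            reports["verification"] = report.to_dict()
            log.append(f"verified against fixture {config.verify_fixture}")
        log.append(f"simulated {regimen.route} {regimen.dose_mg} mg "
                   f"x{regimen.n_doses}")

    with open(out / "report.json", "w") as fh:
        json.dump(reports, fh, indent=2, default=_jsonable)
    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "version": __version__, "seed": config.seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
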