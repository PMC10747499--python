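"""Virtual subjects, species physiology and tissue:plasma partitioning.

Builds rat and human virtual subjects (organ volumes, blood flows, skin
thicknesses) from shipped reference tables, and computes tissue:plasma
partition coefficients and the steady-state volume of distribution with the
tissue-composition method, using the zwitterion-adjusted vegetable-oil:buffer
partition coefficient for adipose.

Internal canonical units: µg, mL, h (organ volumes mL, flows mL/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .parameters import DrugParameters

#: systemic organs represented in the whole-body model
ORGANS = ("adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
          "lung", "muscle", "skin", "spleen", "rest")


def load_physiology_defaults() -> dict:
    """Load the shipped reference physiology tables (deep-copied, editable)."""
    text = (resources.files("mapbpk") / "data" / "physiology.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class TissueComposition:
    """Fractional water / neutral-lipid / phospholipid content per tissue,
    plus the plasma reference composition."""

    tissues: dict[str, tuple[float, float, float]]
    plasma: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, frac in list(self.tissues.items()) + [("plasma", self.plasma)]:
            if any(not 0.0 <= f <= 1.0 for f in frac):
                raise ValueError(f"{name}: fractions must be in [0, 1]")
            if sum(frac) > 1.0 + 1e-9:
                raise ValueError(f"{name}: fractions sum above 1")

    @classmethod
    def for_species(cls, species: str, config: dict | None = None
                    ) -> "TissueComposition":
        cfg = config or load_physiology_defaults()
        table = cfg["tissue_composition"][species]
        tissues = {k: tuple(v) for k, v in table.items() if k != "plasma"}
        return cls(tissues=tissues, plasma=tuple(table["plasma"]))


@dataclass
class PartitionSet:
    """Tissue:plasma partition coefficients and the resulting Vss (mL)."""

    tp: dict[str, float]
    vdss_ml: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.tp.values()):
            raise ValueError("partition coefficients must be positive")


@dataclass
class Subject:
    """One virtual animal or human.

    ``blood_flows_ml_h`` holds organ blood flows (the lung carries the full
    cardiac output); the dermal blood flow under a patch is an exception to
    the cardiac-output fractions and is derived at simulation time as
    ``dermal_perfusion_ml_h_cm2 × patch area``.  ``vd_correction`` multiplies
    every tissue:plasma coefficient at the point of use.
    """

    species: str
    sex: str
    age_years: float
    body_weight_kg: float
    organ_volumes_ml: dict[str, float]
    blood_flows_ml_h: dict[str, float]
    cardiac_output_ml_h: float
    skin_thickness_um: tuple[float, float, float]
    height_cm: float | None = None
    vd_correction: float = 1.0
    dermal_perfusion_ml_h_cm2: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.organ_volumes_ml.values()):
            raise ValueError("organ volumes must be positive")
        if any(q < 0 for q in self.blood_flows_ml_h.values()):
            raise ValueError("blood flows must be non-negative")
        non_lung = sum(q for organ, q in self.blood_flows_ml_h.items()
                       if organ != "lung")
        if non_lung > self.cardiac_output_ml_h * (1 + 1e-9):
            raise ValueError("organ blood flows exceed cardiac output")

    @property
    def blood_volume_ml(self) -> float:
        return self.organ_volumes_ml["blood"]

    @property
    def arterial_volume_ml(self) -> float:
        return self.blood_volume_ml / 3.0

    @property
    def venous_volume_ml(self) -> float:
        return self.blood_volume_ml * 2.0 / 3.0

    @property
    def plasma_volume_ml(self) -> float:
        # plasma fraction of whole blood via hematocrit
        return self.blood_volume_ml * (1.0 - self._hct)

    _hct: float = 0.45


def _organ_volumes(body_weight_kg: float, mass_fractions: dict[str, float],
                   densities: dict[str, float]) -> dict[str, float]:
    """Organ volumes (mL) from mass fractions of body weight and densities;
    a 'rest' organ closes the mass balance so Σ organ masses = body weight."""
    fractions = dict(mass_fractions)
    fractions["rest"] = 1.0 - sum(fractions.values())
    if fractions["rest"] <= 0:
        raise ValueError("organ mass fractions sum above 1")
    vols = {}
    for organ, frac in fractions.items():
        density = densities.get(organ, densities["default"])
        vols[organ] = body_weight_kg * 1e3 * frac / density
    return vols


def _blood_flows(cardiac_output_ml_h: float,
                 flow_fractions: dict[str, float]) -> dict[str, float]:
    flows = {organ: cardiac_output_ml_h * f
             for organ, f in flow_fractions.items()}
    flows["lung"] = cardiac_output_ml_h
    return flows


def generate_rat_cohort(n: int, weight_mean_kg: float, weight_sd_kg: float,
                        seed: int, config: dict | None = None
                        ) -> list[Subject]:
    """Virtual rat cohort with weights ~ Normal(mean, sd) truncated at ±3 SD.

    Organ volumes and blood flows are scaled from the reference rat linearly
    with body weight.  Deterministic for a fixed seed.
    """
    if n < 1 or weight_mean_kg <= 0 or weight_sd_kg < 0:
        raise ValueError("need n ≥ 1, positive mean weight, sd ≥ 0")
    cfg = config or load_physiology_defaults()
    rng = np.random.default_rng(seed)
    weights = _truncated_normal(rng, weight_mean_kg, weight_sd_kg, n)

    rat = cfg["rat"]
    ref_bw = rat["reference_weight_kg"]
    co_ref = cfg["co_allometric_l_h_kg075"] * ref_bw**0.75 * 1e3  # mL/h
    subjects = []
    for i in range(n):
        bw = float(weights[i])
        scale = bw / ref_bw
        co = co_ref * scale
        subjects.append(Subject(
            species="rat", sex="n/a", age_years=0.25, body_weight_kg=bw,
            organ_volumes_ml=_organ_volumes(
                bw, rat["organ_mass_fractions"], cfg["organ_densities_g_ml"]),
            blood_flows_ml_h=_blood_flows(co, rat["flow_fractions"]),
            cardiac_output_ml_h=co,
            skin_thickness_um=tuple(rat["skin_thickness_um"]),
            dermal_perfusion_ml_h_cm2=cfg["dermal_perfusion_ml_h_cm2"],
        ))
    return subjects


def generate_human_cohort(n: int, female_fraction: float = 0.5,
                          age_range: tuple[float, float] = (18.0, 60.0),
                          seed: int = 0, config: dict | None = None
                          ) -> list[Subject]:
    """Virtual adult human cohort.

    Sex is allocated deterministically (round(n × female_fraction) females),
    ages are uniform on ``age_range``, height is normal and BMI log-normal
    per sex (both truncated at ±3 SD), weight = BMI × height².  Organ volumes
    come from sex-specific mass fractions of body weight with organ
    densities; cardiac output is allometric in body weight.
    """
    if n < 1:
        raise ValueError("need n ≥ 1")
    if not 0.0 <= female_fraction <= 1.0:
        raise ValueError("female_fraction must be in [0, 1]")
    if age_range[1] < age_range[0]:
        raise ValueError("empty age range")
    cfg = config or load_physiology_defaults()
    rng = np.random.default_rng(seed)
    human = cfg["human"]

    n_female = int(round(n * female_fraction))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    ages = rng.uniform(age_range[0], age_range[1], size=n)

    subjects = []
    for i, sex in enumerate(sexes):
        anthro = human["anthropometrics"][sex]
        height = float(_truncated_normal(
            rng, anthro["height_mean_cm"], anthro["height_sd_cm"], 1)[0])
        log_bmi = float(_truncated_normal(
            rng, math.log(anthro["bmi_median"]), anthro["bmi_log_sd"], 1)[0])
        bw = math.exp(log_bmi) * (height / 100.0) ** 2
        co = cfg["co_allometric_l_h_kg075"] * bw**0.75 * 1e3  # mL/h
        subjects.append(Subject(
            species="human", sex=sex, age_years=float(ages[i]),
            body_weight_kg=bw, height_cm=height,
            organ_volumes_ml=_organ_volumes(
                bw, human["organ_mass_fractions"][sex],
                cfg["organ_densities_g_ml"]),
            blood_flows_ml_h=_blood_flows(co, human["flow_fractions"]),
            cardiac_output_ml_h=co,
            skin_thickness_um=tuple(human["skin_thickness_um"]),
            dermal_perfusion_ml_h_cm2=cfg["dermal_perfusion_ml_h_cm2"],
        ))
    return subjects


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int) -> np.ndarray:
    """Normal draws truncated at ±3 SD (resampled, not clipped)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = np.abs(out - mean) > 3 * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > 3 * sd
    return out


# --- tissue:plasma partitioning -------------------------------------------


def _log_d_star(drug: DrugParameters, ph: float = 7.4) -> float:
    """Zwitterion-adjusted log distribution coefficient at the given pH.

    Ionisation at both the acidic and basic centres reduces the effective
    lipophilicity; for cabotegravir (pKa 10.04 acidic, −0.7 basic) the
    adjustment at pH 7.4 is small.
    """
    pka_acid, pka_base = max(drug.pka), min(drug.pka)
    ion = 1.0 + 10.0 ** (ph - pka_acid) + 10.0 ** (pka_base - ph)
    return drug.logp_ow - math.log10(ion)


def tissue_plasma_partition(drug: DrugParameters, comp: TissueComposition,
                            organ_volumes_ml: dict[str, float] | None = None,
                            vd_correction: float = 1.0) -> PartitionSet:
    """Tissue:plasma partition coefficients by the tissue-composition method.

    Non-adipose tissues use the octanol:water partition coefficient with the
    unbound-fraction ratio fu_p/fu_t (fu_t from the standard half-binding
    assumption); adipose uses the zwitterion-adjusted vegetable-oil:buffer
    coefficient D*_vo:w = 10^(1.115·logD* − 1.35) with fu_t = 1.

    ``vdss_ml`` = plasma volume + Σ V_t·tp_t (tissue coefficients multiplied
    by ``vd_correction``); it is only computed when organ volumes are given.
    """
    fu = drug.fraction_unbound
    if not 0.0 < fu <= 1.0:
        raise ValueError("fraction unbound must be in (0, 1]")
    p_ow = 10.0 ** drug.logp_ow
    d_vow = 10.0 ** (1.115 * _log_d_star(drug) - 1.35)
    fu_t = 1.0 / (1.0 + (1.0 - fu) / fu * 0.5)

    w_p, nl_p, ph_p = comp.plasma

    def lipid_term(p: float, frac: tuple[float, float, float]) -> float:
        w, nl, phl = frac
        return p * (nl + 0.3 * phl) + (w + 0.7 * phl)

    tp: dict[str, float] = {}
    for tissue, frac in comp.tissues.items():
        if tissue == "adipose":
            tp[tissue] = (lipid_term(d_vow, frac)
                          / lipid_term(d_vow, comp.plasma) * fu)
        else:
            tp[tissue] = (lipid_term(p_ow, frac)
                          / lipid_term(p_ow, comp.plasma) * (fu / fu_t))

    vdss = float("nan")
    if organ_volumes_ml is not None:
        missing = [o for o in organ_volumes_ml
                   if o not in tp and o != "blood"]
        if missing:
            raise KeyError(f"no tissue composition for: {missing}")
        plasma_vol = organ_volumes_ml["blood"] * 0.55
        vdss = plasma_vol + sum(
            v * tp[o] * vd_correction
            for o, v in organ_volumes_ml.items() if o != "blood")
    return PartitionSet(tp=tp, vdss_ml=vdss)


def cohort_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """One row per subject: demographics plus organ volumes and flows."""
    rows = []
    for i, s in enumerate(subjects):
        row: dict[str, object] = {
            "subject": i, "species": s.species, "sex": s.sex,
            "age_years": s.age_years, "body_weight_kg": s.body_weight_kg,
            "height_cm": s.height_cm,
            "cardiac_output_ml_h": s.cardiac_output_ml_h,
        }
        row.update({f"V_{o}_ml": v for o, v in s.organ_volumes_ml.items()})
        row.update({f"Q_{o}_ml_h": q for o, q in s.blood_flows_ml_h.items()})
        rows.append(row)
    return pd.DataFrame(rows)
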