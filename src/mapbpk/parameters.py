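"""Drug parameters and the cabotegravir defaults.

``DrugParameters`` bundles the physicochemical constants, skin permeability /
partition coefficients and route-specific kinetic parameters needed by the
intradermal PBPK model.  The class defaults are the long-acting cabotegravir
inputs; the route/species-specific triple (``knp_h``, ``kskin_cm3_h``,
``clf_l_h``) is set by the scenario constructors below using the estimates
obtained from the empirical-model fitting step.

Internal canonical units: µg, mL, h.  ``clf_l_h`` is kept in L/h for
familiarity and converted at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# protein-adjusted IC90 multiples used as efficacy thresholds (µg/mL)
PA_IC90_4X = 0.664
PA_IC90_8X = 1.33


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and pharmacokinetic constants for one compound."""

    name: str = "cabotegravir"
    molecular_weight: float = 405.358        # g/mol
    hbd: int = 2                             # hydrogen-bond donors
    logp_ow: float = 1.04                    # octanol:water log partition
    pka: tuple[float, ...] = (10.04, -0.7)   # acidic, basic
    protein_binding_pct: float = 99.8
    psa_a2: float = 99.18                    # polar surface area, Å²
    blood_plasma_ratio: float = 0.5          # R
    bioavailability_pct: float = 20.0        # MAP relative to IM

    # human IM reference constants
    clf_im_human_l_h: float = 0.197
    knp_im_human_h: float = 4.54e-4

    # skin permeability (cm/h) and partition coefficients (dimensionless)
    pc_sc_w: float = 0.304
    pc_ve_w: float = 0.106
    pc_de_w: float = 0.106
    pc_sc_ve: float = 3.993
    pc_ve_de: float = 1.0

    # active route/species-specific parameters (set by scenario helpers)
    knp_h: float = 4.54e-4                   # nanoparticle release rate, h⁻¹
    kskin_cm3_h: float = 1.73e-3             # trans-skin volumetric rate
    clf_l_h: float = 0.197                   # apparent clearance, L/h

    def __post_init__(self) -> None:
        positive = ("molecular_weight", "psa_a2",
                    "pc_sc_w", "pc_ve_w", "pc_de_w", "pc_sc_ve", "pc_ve_de",
                    "knp_h", "kskin_cm3_h", "clf_l_h")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.blood_plasma_ratio <= 2.0:
            raise ValueError("blood:plasma ratio must be in (0, 2]")
        if not 0.0 <= self.protein_binding_pct < 100.0:
            raise ValueError("protein binding must be in [0, 100)%")

    @property
    def fraction_unbound(self) -> float:
        return 1.0 - self.protein_binding_pct / 100.0

    @property
    def clf_map_human_l_h(self) -> float:
        """MAP apparent clearance in humans: CL/F_IM divided by the 20 %
        relative MAP bioavailability (F is inside CL/F)."""
        return self.clf_im_human_l_h / (self.bioavailability_pct / 100.0)


# --- scenario constructors: parameter estimates per route and species ------

#: volume-of-distribution correction factors applied via Subject.vd_correction
VD_CORRECTION = {
    ("rat", "IM"): 5.0,
    ("rat", "MAP"): 0.05,
    ("human", "IM"): 0.01,
    ("human", "MAP"): 0.01,
}

_KNP = {("rat", "IM"): 3.0e-3, ("rat", "MAP"): 3.43e-3,
        ("human", "IM"): 4.54e-4, ("human", "MAP"): 3.43e-3}
_CLF = {("rat", "IM"): 0.6, ("rat", "MAP"): 0.01,
        ("human", "IM"): 0.197}
_KSKIN_MAP = 1.73e-3  # cm³/h, rat-derived, reused for human MAP


def cabotegravir(species: str, route: str) -> DrugParameters:
    """Cabotegravir parameter set configured for a species/route scenario.

    The MAP skin rate constant and nanoparticle release rates estimated in
    rats are carried over to the human MAP scenario; CL/F for human MAP is
    derived from the human IM value and the 20 % relative bioavailability.
    """
    key = (species, route)
    if key not in VD_CORRECTION:
        raise ValueError(f"unknown scenario {key}")
    base = DrugParameters()
    clf = _CLF.get(key, base.clf_map_human_l_h)
    return replace(base, knp_h=_KNP[key], clf_l_h=clf,
                   kskin_cm3_h=_KSKIN_MAP)
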