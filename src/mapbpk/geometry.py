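"""Microneedle-array geometry and per-skin-layer dose partitioning.

A microarray patch (MAP) carries a square grid of right rectangular
pyramid-shaped microneedles on a drug-free cuboidal base.  On insertion the
needle tips penetrate the stratum corneum (SC), viable epidermis (VE) and
dermis (DE); the loaded dose is partitioned between the three layers in
proportion to the needle volume residing in each layer.  This module computes
those volumes, the lateral needle surface area per layer (the area across
which released drug enters the skin), patch-area arithmetic and the skin
compartment volumes under the patch.

Internal canonical units: lengths in µm for needle geometry, areas in cm²,
volumes in mL (= cm³).  1 mL = 1e12 µm³; 1 cm² = 1e8 µm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

UM3_PER_ML = 1e12
UM2_PER_CM2 = 1e8

#: skin layer labels, outermost first
LAYERS = ("SC", "VE", "DE")


@dataclass(frozen=True)
class MAPDesign:
    """Microarray-patch design parameters.

    Defaults describe the dissolving bilayer cabotegravir MAP: a 0.49 cm²
    baseplate of 16 × 16 right rectangular pyramidal needles (tip height
    600 µm, 300 µm square cross-section, 100 µm interspacing) on a 250 µm
    drug-free cuboidal base, inserted to 97 % of the tip height, loaded at
    5.86 mg/cm².
    """

    baseplate_area_cm2: float = 0.49
    needles_per_baseplate: int = 256
    needle_height_um: float = 600.0
    needle_width_um: float = 300.0
    needle_length_um: float = 300.0
    interspacing_um: float = 100.0
    base_height_um: float = 250.0
    insertion_fraction: float = 0.97
    dose_loading_mg_cm2: float = 5.86

    def __post_init__(self) -> None:
        if not 0.0 < self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in (0, 1]")
        if self.dose_loading_mg_cm2 <= 0:
            raise ValueError("dose_loading must be positive")
        for name in ("baseplate_area_cm2", "needle_height_um",
                     "needle_width_um", "needle_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def insertion_depth_um(self) -> float:
        """Depth of the needle tip below the skin surface."""
        return self.insertion_fraction * self.needle_height_um


@dataclass(frozen=True)
class LayerGeometry:
    """Per-layer needle volumes, lateral areas, dose fractions and skin
    compartment volumes for one patch.

    ``v_mn_ml`` and ``sa_mn_cm2`` are totals over all needles of the patch;
    ``dose_fraction`` is normalised over the inserted needle volume.
    """

    patch_area_cm2: float
    n_needles: float
    v_mn_ml: dict[str, float] = field(default_factory=dict)
    sa_mn_cm2: dict[str, float] = field(default_factory=dict)
    dose_fraction: dict[str, float] = field(default_factory=dict)
    v_layer_ml: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.dose_fraction.values())
        if self.dose_fraction and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"dose fractions sum to {total!r}, expected 1")


def pyramid_volume_from_tip(s_um: float, design: MAPDesign) -> float:
    """Volume (µm³) of the pyramid segment within distance ``s_um`` of the tip.

    The needle tapers linearly from its base cross-section (width × length)
    to a point, so the cross-section at distance s from the tip has width
    w·s/h and length l·s/h, giving V(s) = (1/3)·w·l·s³/h².
    """
    h = design.needle_height_um
    if not 0.0 <= s_um <= h:
        raise ValueError(f"s={s_um} outside [0, {h}] µm")
    w, l = design.needle_width_um, design.needle_length_um
    return (w * l * s_um**3) / (3.0 * h * h)


def pyramid_lateral_area_from_tip(s_um: float, design: MAPDesign) -> float:
    """Lateral (slant) surface area (µm²) within distance ``s_um`` of the tip.

    For a rectangular pyramid the two pairs of slant faces have apothems
    sqrt(h² + (w/2)²)·(s/h) and sqrt(h² + (l/2)²)·(s/h); the truncation at
    distance s from the tip is geometrically similar, scaling areas by
    (s/h)².
    """
    h = design.needle_height_um
    if not 0.0 <= s_um <= h:
        raise ValueError(f"s={s_um} outside [0, {h}] µm")
    w, l = design.needle_width_um, design.needle_length_um
    full = (l * math.sqrt(h * h + (w / 2.0) ** 2)
            + w * math.sqrt(h * h + (l / 2.0) ** 2))
    return full * (s_um / h) ** 2


def patch_area_for_dose(dose_mg: float, dose_loading_mg_cm2: float
                        ) -> tuple[float, float]:
    """Patch area (cm²) delivering ``dose_mg`` at the given loading.

    Returns ``(area_cm2, effective_needle_count)``; the needle count is
    area-scaled (fractional baseplates allowed) assuming the default 256
    needles per 0.49 cm² baseplate.
    """
    if dose_mg <= 0 or dose_loading_mg_cm2 <= 0:
        raise ValueError("dose and loading must be positive")
    area = dose_mg / dose_loading_mg_cm2
    design = MAPDesign()
    n_needles = area / design.baseplate_area_cm2 * design.needles_per_baseplate
    return area, n_needles


def skin_compartment_volumes(patch_area_cm2: float,
                             thicknesses_um: tuple[float, float, float],
                             subtract_needles: bool = False,
                             design: MAPDesign | None = None,
                             ) -> tuple[float, float, float]:
    """Skin-layer compartment volumes (mL) under a patch of the given area.

    V_layer = area × thickness; optionally the needle volume occupying the
    layer is subtracted (default: not subtracted).
    """
    if patch_area_cm2 <= 0:
        raise ValueError("patch_area must be positive")
    if any(t <= 0 for t in thicknesses_um):
        raise ValueError("layer thicknesses must be positive")
    # cm² × µm → mL: 1 cm² × 1 µm = 1e-4 cm³
    vols = [patch_area_cm2 * t * 1e-4 for t in thicknesses_um]
    if subtract_needles:
        geom = layer_partition(design or MAPDesign(), thicknesses_um,
                               patch_area_cm2=patch_area_cm2)
        vols = [v - geom.v_mn_ml[lay] for v, lay in zip(vols, LAYERS)]
    return tuple(vols)  # type: ignore[return-value]


def layer_partition(design: MAPDesign,
                    thicknesses_um: tuple[float, float, float],
                    patch_area_cm2: float | None = None,
                    dose_mg: float | None = None) -> LayerGeometry:
    """Partition the inserted needle volume and lateral area by skin layer.

    The inserted segment spans depths [0, d_ins] below the surface with the
    tip at d_ins = insertion_fraction × tip height; depth z corresponds to
    distance s = d_ins − z from the tip.  Layer boundaries are half-open
    [top, bottom).  Dose fractions are normalised over the inserted volume.

    ``patch_area_cm2`` defaults to one baseplate; alternatively pass
    ``dose_mg`` to size the patch from the design's dose loading.
    """
    if any(t <= 0 for t in thicknesses_um):
        raise ValueError("zero-thickness skin layer is degenerate")
    d_ins = design.insertion_depth_um
    if d_ins > sum(thicknesses_um):
        raise ValueError("insertion depth exceeds total skin thickness")

    if patch_area_cm2 is None:
        if dose_mg is not None:
            patch_area_cm2 = dose_mg / design.dose_loading_mg_cm2
        else:
            patch_area_cm2 = design.baseplate_area_cm2
    n_needles = (patch_area_cm2 / design.baseplate_area_cm2
                 * design.needles_per_baseplate)

    # depth boundaries of the three layers
    t_sc, t_ve, t_de = thicknesses_um
    bounds = [0.0, t_sc, t_sc + t_ve, t_sc + t_ve + t_de]

    v_total = pyramid_volume_from_tip(d_ins, design)
    v_mn: dict[str, float] = {}
    sa_mn: dict[str, float] = {}
    for lay, z0, z1 in zip(LAYERS, bounds[:-1], bounds[1:]):
        # clip layer to the inserted span; s decreases with depth
        z0c, z1c = min(z0, d_ins), min(z1, d_ins)
        s_hi, s_lo = d_ins - z0c, d_ins - z1c
        v = (pyramid_volume_from_tip(s_hi, design)
             - pyramid_volume_from_tip(s_lo, design))
        sa = (pyramid_lateral_area_from_tip(s_hi, design)
              - pyramid_lateral_area_from_tip(s_lo, design))
        v_mn[lay] = v * n_needles / UM3_PER_ML
        sa_mn[lay] = sa * n_needles / UM2_PER_CM2

    dose_fraction = {
        lay: v_mn[lay] / (v_total * n_needles / UM3_PER_ML) for lay in LAYERS
    }
    v_layer = dict(zip(LAYERS,
                       skin_compartment_volumes(patch_area_cm2,
                                                thicknesses_um)))
    return LayerGeometry(patch_area_cm2=patch_area_cm2, n_needles=n_needles,
                         v_mn_ml=v_mn, sa_mn_cm2=sa_mn,
                         dose_fraction=dose_fraction, v_layer_ml=v_layer)
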