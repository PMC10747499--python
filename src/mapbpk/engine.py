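"""Whole-body PBPK engine with intradermal microarray-patch compartments.

The model couples three groups of compartments:

* **MAP depot** — per skin layer x ∈ {SC, VE, DE}: nanoparticle drug ND_x
  releases at first order (K_NP) into released drug RD_x inside the needle,
  which enters the penetrating pool PD_x across the needle's lateral surface
  (permeability coefficient PC_x/W).  Penetrating drug moves unidirectionally
  SC → VE → DE at the volumetric skin rate K_SKIN scaled by the inter-layer
  partition coefficients; the dermis exchanges with blood via the dermal flow
  Q_DE (uptake from arterial blood, washout at R/TP_SKIN).
* **IM depot** — first-order release (K_NP) into venous blood.
* **Systemic disposition** — blood-flow-limited, well-stirred organs:
  dA_t/dt = Q_t·(C_art − A_t·R/(V_t·tp_t)); the lung sits between the venous
  and arterial pools and carries the full cardiac output.  Apparent clearance
  CL/F removes drug at first order from the venous *blood* concentration;
  reported plasma concentration is venous blood concentration divided by the
  blood:plasma ratio R.

All inter-dose dynamics are linear and time-invariant, so the default solver
propagates the exact matrix exponential on a uniform grid (machine-precision
mass balance); an adaptive stiff integrator is available for cross-checks.

Canonical units: µg, mL, h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .geometry import LAYERS, LayerGeometry, MAPDesign, layer_partition
from .parameters import DrugParameters
from .physiology import ORGANS, PartitionSet, Subject, TissueComposition, \
    tissue_plasma_partition

#: state labels for the MAP/IM depot block, in order
DEPOT_STATES = ("ND_SC", "ND_VE", "ND_DE", "RD_SC", "RD_VE", "RD_DE",
                "PD_SC", "PD_VE", "PD_DE", "IM_depot")


@dataclass(frozen=True)
class Regimen:
    """Dosing regimen: route, dose per administration, schedule and horizon."""

    route: str                      # "IM" or "MAP"
    dose_mg: float
    interval_h: float = 168.0
    n_doses: int = 1
    horizon_h: float = 672.0
    design: MAPDesign | None = None
    #: override the dose-loading-derived patch area (used by dose ladders to
    #: share one patch-skin interface so kinetics stay dose-independent)
    patch_area_cm2: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ("IM", "MAP"):
            raise ValueError("route must be 'IM' or 'MAP'")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        if self.n_doses < 1:
            raise ValueError("need at least one dose")
        if self.n_doses > 1 and self.interval_h <= 0:
            raise ValueError("multi-dose regimen needs a positive interval")
        if (self.n_doses - 1) * self.interval_h >= self.horizon_h:
            raise ValueError("horizon must cover the last dose")
        if self.route == "MAP" and self.design is None:
            object.__setattr__(self, "design", MAPDesign())

    @property
    def dose_times_h(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval_h


@dataclass
class ConcentrationSeries:
    """Plasma concentration–time series with optional compartment amounts."""

    times_h: np.ndarray
    conc_ug_ml: np.ndarray
    states: pd.DataFrame | None = None
    total_dosed_ug: float = 0.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_ug_ml = np.asarray(self.conc_ug_ml, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc_ug_ml < -1e-9):
            raise ValueError("negative concentrations")
        self.conc_ug_ml = np.maximum(self.conc_ug_ml, 0.0)

    def at(self, t_h: float) -> float:
        """Linearly interpolated plasma concentration (µg/mL)."""
        return float(np.interp(t_h, self.times_h, self.conc_ug_ml))

    def mass_balance_error(self) -> float:
        """Max relative deviation of Σ state amounts from the dosed amount
        (requires per-compartment trajectories)."""
        if self.states is None:
            raise ValueError("states were not retained")
        total = self.states.to_numpy().sum(axis=1)
        dosed = self.states.attrs["cum_dosed_ug"]
        return float(np.max(np.abs(total - dosed)
                            / np.maximum(dosed, 1e-300)))


@dataclass
class PBPKSystem:
    """Assembled linear system dx/dt = A·x with a per-administration dose
    increment vector and state labels."""

    A: np.ndarray
    dose_vector_per_ug: np.ndarray
    labels: tuple[str, ...]
    venous_index: int
    venous_volume_ml: float
    blood_plasma_ratio: float
    geometry: LayerGeometry | None = None
    partition: PartitionSet | None = None


def build_system(subject: Subject, drug: DrugParameters, regimen: Regimen,
                 composition: TissueComposition | None = None,
                 literal_eq9: bool = False) -> PBPKSystem:
    """Assemble the PBPK rate matrix for one subject, drug and route.

    ``literal_eq9`` switches the dermis–blood exchange to the as-printed
    reading of the dermis equation (venous amount in the washout term); that
    form does not conserve mass and exists for comparison only.
    """
    comp = composition or TissueComposition.for_species(subject.species)
    pset = tissue_plasma_partition(drug, comp, subject.organ_volumes_ml,
                                   vd_correction=subject.vd_correction)
    tp = {t: v * subject.vd_correction for t, v in pset.tp.items()}

    labels = list(DEPOT_STATES) + [f"A_{o}" for o in ORGANS] \
        + ["A_art", "A_ven", "A_elim"]
    ix = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    A = np.zeros((n, n))

    R = drug.blood_plasma_ratio
    co = subject.cardiac_output_ml_h
    v_art, v_ven = subject.arterial_volume_ml, subject.venous_volume_ml
    cl_ml_h = drug.clf_l_h * 1e3
    i_art, i_ven, i_elim = ix["A_art"], ix["A_ven"], ix["A_elim"]

    # systemic organs (lung receives venous blood, feeds arterial)
    q_sum = 0.0
    for organ in ORGANS:
        i_o = ix[f"A_{organ}"]
        q = subject.blood_flows_ml_h[organ]
        k_out = q * R / (subject.organ_volumes_ml[organ] * tp[organ])
        A[i_o, i_o] -= k_out
        if organ == "lung":
            A[i_o, i_ven] += co / v_ven
            A[i_art, i_o] += k_out
        else:
            A[i_o, i_art] += q / v_art
            A[i_ven, i_o] += k_out
            q_sum += q

    geom = None
    q_de = 0.0
    if regimen.route == "MAP":
        geom = layer_partition(regimen.design, subject.skin_thickness_um,
                               patch_area_cm2=regimen.patch_area_cm2,
                               dose_mg=regimen.dose_mg)
        q_de = subject.dermal_perfusion_ml_h_cm2 * geom.patch_area_cm2

    q_bypass = co - q_sum - q_de
    if q_bypass < 0:
        raise ValueError("organ + dermal blood flows exceed cardiac output")
    # arterial pool: everything that entered leaves (organs, dermis, bypass)
    A[i_art, i_art] -= co / v_art
    A[i_ven, i_art] += q_bypass / v_art
    # venous pool: to lung and to elimination (clearance on blood conc)
    A[i_ven, i_ven] -= (co + cl_ml_h) / v_ven
    A[i_elim, i_ven] += cl_ml_h / v_ven

    dose_vec = np.zeros(n)
    if regimen.route == "IM":
        # first-order release from the injection-site depot into venous blood
        i_dep = ix["IM_depot"]
        A[i_dep, i_dep] -= drug.knp_h
        A[i_ven, i_dep] += drug.knp_h
        dose_vec[i_dep] = 1.0
    else:
        pc_w = {"SC": drug.pc_sc_w, "VE": drug.pc_ve_w, "DE": drug.pc_de_w}
        pc_between = {"SC": drug.pc_sc_ve, "VE": drug.pc_ve_de}
        for lay in LAYERS:
            i_nd, i_rd, i_pd = ix[f"ND_{lay}"], ix[f"RD_{lay}"], ix[f"PD_{lay}"]
            # nanoparticle release inside the needle
            A[i_nd, i_nd] -= drug.knp_h
            A[i_rd, i_nd] += drug.knp_h
            # needle → skin across the lateral surface
            k_rd = pc_w[lay] * geom.sa_mn_cm2[lay] / geom.v_mn_ml[lay]
            A[i_rd, i_rd] -= k_rd
            A[i_pd, i_rd] += k_rd
            dose_vec[i_nd] = geom.dose_fraction[lay]
        # unidirectional trans-layer transport SC → VE → DE
        for lay, nxt in (("SC", "VE"), ("VE", "DE")):
            k = drug.kskin_cm3_h / (pc_between[lay] * geom.v_layer_ml[lay])
            A[ix[f"PD_{lay}"], ix[f"PD_{lay}"]] -= k
            A[ix[f"PD_{nxt}"], ix[f"PD_{lay}"]] += k
        # dermis ↔ blood exchange
        i_pd_de = ix["PD_DE"]
        v_de = geom.v_layer_ml["DE"]
        A[i_pd_de, i_art] += q_de / v_art
        A[i_art, i_art] -= 0.0  # arterial outflow to dermis already in CO
        if literal_eq9:
            # as-printed form: the washout term is driven by the *venous*
            # amount with a 1/1000 factor.  Routed into the venous pool to
            # keep total mass conserved, but because venous blood starts
            # empty the printed form provides no dermis → blood pathway at
            # all; it is retained only to demonstrate why the corrected
            # reading is required.
            k_lit = q_de * R * tp["skin"] / (v_de / 1e3)
            A[i_pd_de, i_ven] -= k_lit
            A[i_ven, i_ven] += k_lit
        else:
            k_de_out = q_de * R / (v_de * tp["skin"])
            A[i_pd_de, i_pd_de] -= k_de_out
            A[i_ven, i_pd_de] += k_de_out

    return PBPKSystem(A=A, dose_vector_per_ug=dose_vec, labels=tuple(labels),
                      venous_index=i_ven, venous_volume_ml=v_ven,
                      blood_plasma_ratio=R, geometry=geom, partition=pset)


def rhs(system: PBPKSystem, state: np.ndarray) -> np.ndarray:
    """State derivative dx/dt at ``state`` (µg/h per compartment).

    The depot, IM and systemic blocks are all assembled into the linear
    rate matrix by :func:`build_system`; this evaluates it directly, e.g.
    for coupling into external integrators.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    return system.A @ state


def simulate(subject: Subject, drug: DrugParameters, regimen: Regimen,
             grid_dt_h: float = 0.5, solver: str = "expm",
             rtol: float = 1e-8, atol: float = 1e-9,
             keep_states: bool = False,
             composition: TissueComposition | None = None,
             literal_eq9: bool = False) -> ConcentrationSeries:
    """Simulate a regimen for one subject on a uniform output grid.

    Dose events add the administered amount to the depot states (any MAP
    residue from earlier patches is retained).  ``solver='expm'`` uses the
    exact matrix-exponential propagator; ``solver='ivp'`` integrates with an
    adaptive stiff method at the given tolerances.
    """
    sys = build_system(subject, drug, regimen, composition=composition,
                       literal_eq9=literal_eq9)
    times = np.arange(0.0, regimen.horizon_h + grid_dt_h / 2, grid_dt_h)
    dose_steps = {}
    for t_d in regimen.dose_times_h:
        k = int(round(t_d / grid_dt_h))
        if abs(k * grid_dt_h - t_d) > 1e-9:
            raise ValueError("dose times must lie on the output grid")
        dose_steps[k] = dose_steps.get(k, 0.0) + regimen.dose_mg * 1e3

    n = len(sys.labels)
    xs = np.empty((len(times), n))
    cum_dosed = np.empty(len(times))
    x = np.zeros(n)
    dosed = 0.0

    if solver == "expm":
        M = expm(sys.A * grid_dt_h)
        for k in range(len(times)):
            if k in dose_steps:
                x = x + sys.dose_vector_per_ug * dose_steps[k]
                dosed += dose_steps[k]
            xs[k] = x
            cum_dosed[k] = dosed
            x = M @ x
    elif solver == "ivp":
        for k in range(len(times)):
            if k in dose_steps:
                x = x + sys.dose_vector_per_ug * dose_steps[k]
                dosed += dose_steps[k]
            xs[k] = x
            cum_dosed[k] = dosed
            if k < len(times) - 1:
                sol = solve_ivp(lambda t, y: sys.A @ y,
                                (0.0, grid_dt_h), x, method="BDF",
                                jac=lambda t, y: sys.A,
                                rtol=rtol, atol=atol)
                if not sol.success:
                    raise RuntimeError(
                        f"integration failed at t={times[k]:.3f} h: "
                        f"{sol.message}")
                x = sol.y[:, -1]
    else:
        raise ValueError(f"unknown solver {solver!r}")

    if not np.all(np.isfinite(xs)):
        raise RuntimeError("non-finite state encountered")

    conc = xs[:, sys.venous_index] / (sys.venous_volume_ml
                                      * sys.blood_plasma_ratio)
    states = None
    if keep_states:
        states = pd.DataFrame(xs, index=times, columns=sys.labels)
        states.attrs["cum_dosed_ug"] = cum_dosed
    return ConcentrationSeries(times_h=times, conc_ug_ml=conc, states=states,
                               total_dosed_ug=dosed)


def simulate_at(subject: Subject, drug: DrugParameters, regimen: Regimen,
                times_h: np.ndarray,
                composition: TissueComposition | None = None) -> np.ndarray:
    """Plasma concentrations at arbitrary times (exact propagation).

    Used as the forward model for curve-fitting: dose events are interleaved
    with the requested times and each gap is bridged with one matrix
    exponential.
    """
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0):
        raise ValueError("times must be non-negative")
    sys = build_system(subject, drug, regimen, composition=composition)
    events = sorted(set(regimen.dose_times_h.tolist())
                    | set(times_h.tolist()))
    dose_at = {float(t): regimen.dose_mg * 1e3
               for t in regimen.dose_times_h}
    conc_at: dict[float, float] = {}
    x = np.zeros(len(sys.labels))
    t_prev = 0.0
    cache: dict[float, np.ndarray] = {}
    for t in events:
        dt = t - t_prev
        if dt > 0:
            key = round(dt, 12)
            if key not in cache:
                cache[key] = expm(sys.A * dt)
            x = cache[key] @ x
        if t in dose_at:
            x = x + sys.dose_vector_per_ug * dose_at[t]
        conc_at[t] = x[sys.venous_index] / (sys.venous_volume_ml
                                            * sys.blood_plasma_ratio)
        t_prev = t
    return np.array([conc_at[float(t)] for t in times_h])
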