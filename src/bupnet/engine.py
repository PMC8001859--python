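"""Whole-body ODE assembly and simulation.

The model is a reduced whole-body PBPK system: venous and arterial plasma
pools, lung, and eleven systemic organs, each organ split into a vascular +
interstitial pool (plasma-like, fraction unbound ``fu`` applies) and an
intracellular pool governed by the tissue-to-plasma partition coefficient.
Exchange between the two pools is permeability-limited
(``PS = cellular permeability x surface-area proxy``), with the intracellular
unbound concentration defined as ``C_cell * fu / Kp`` so that the two pools
equilibrate at ``C_cell = Kp * C_plasma``.

Oral doses enter a Weibull-release depot feeding a chain of gut-lumen transit
segments; dissolved drug is absorbed bidirectionally into the gut-wall cell
pool and unabsorbed drug leaving the last segment is booked as feces.
Saturable enzyme processes (genotype-resolved CYP2B6, 11β-HSD, CYP2C19,
UGT2B7) drain intracellular unbound substrate and create metabolite moles 1:1;
per-process cumulative fluxes are carried as extra ODE states so the flux
ledger is exact to integrator tolerance. Perpetrators act through forcing
concentration profiles: competitive inhibition scales apparent KM values and
induction drives per-organ enzyme turnover pools.

All internal amounts are µmol and time is minutes; reported plasma
concentrations are ng/mL via the molar mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .absorption import FormulationSpec, weibull_release_rate
from .compounds import (
    Compound,
    EnzymeProcess,
    InductionSpec,
    InhibitionSpec,
    kon_from_binding,
    partition_coefficients,
)
from .config import ConfigurationError, load_defaults
from .physiology import SYSTEMIC_ORGANS, PhysiologyParameters

ORG_INDEX = {organ: i for i, organ in enumerate(SYSTEMIC_ORGANS)}
I_GUT = ORG_INDEX["gut_wall"]
I_LIVER = ORG_INDEX["liver"]
I_KIDNEY = ORG_INDEX["kidney"]
I_SPLEEN = ORG_INDEX["spleen"]


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the time of failure in the message."""


class IntegrityError(RuntimeError):
    """A state left its physical range beyond tolerance."""


@dataclass
class DoseEvent:
    """One administration of a victim compound."""

    compound: str
    amount_mg: float
    time_min: float = 0.0
    route: str = "oral"                       # oral | iv
    formulation: FormulationSpec | str | None = None

    def __post_init__(self):
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be > 0")
        if self.route not in ("oral", "iv"):
            raise ValueError(f"unknown route: {self.route!r}")


@dataclass
class PerpetratorRegimen:
    """Dosing schedule (or forcing profile) of one perpetrator drug."""

    compound: str
    doses: list[tuple[float, float]] = field(default_factory=list)  # (mg, time_min)
    mode: str = "model"                        # model | forcing_table
    forcing_times: np.ndarray | None = None    # min
    forcing_unbound: np.ndarray | None = None  # µmol/L

    def __post_init__(self):
        if self.mode not in ("model", "forcing_table"):
            raise ValueError(f"unknown perpetrator mode: {self.mode!r}")


@dataclass
class StudyProtocol:
    """Study design: victim dosing, genotype, perpetrators, sampling."""

    victim_doses: list[DoseEvent]
    duration_min: float
    genotype: str = "*1|*1"
    perpetrators: list[PerpetratorRegimen] = field(default_factory=list)
    observation_times_min: np.ndarray | None = None

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValueError("duration must be > 0")
        for dose in self.victim_doses:
            if not 0 <= dose.time_min <= self.duration_min:
                raise ValueError("dose times must lie within [0, duration]")
        if self.observation_times_min is not None:
            obs = np.asarray(self.observation_times_min, dtype=float)
            if obs.size and (obs.min() < 0 or obs.max() > self.duration_min):
                raise ValueError("observation times must lie within [0, duration]")
            self.observation_times_min = obs


@dataclass
class SimSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    max_negative: float = 1e-3      # µmol tolerated below zero (integrity guard)


@dataclass
class SimulationResult:
    """Output of one simulation: profiles, flux ledger, excretion."""

    times: np.ndarray                                    # min
    concentrations: dict[tuple[str, str], np.ndarray]    # (compound, compartment) -> µmol/L
    plasma_concentrations: dict[str, np.ndarray]         # compound -> ng/mL (venous plasma)
    flux_ledger: dict[str, np.ndarray]                   # process id -> cumulative µmol
    excreted: dict[str, dict[str, float]]                # compound -> route -> µmol
    dose_administered: dict[str, float]                  # compound -> µmol
    absorbed: dict[str, float]                           # compound -> µmol into gut wall (+iv)
    amount_remaining: dict[str, float]                   # compound -> µmol still in body
    mass_balance_rel_error: np.ndarray
    enzyme_pools: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


@dataclass
class PopulationResult:
    times: np.ndarray
    geo_mean: dict[str, np.ndarray]      # compound -> ng/mL
    geo_sd: dict[str, np.ndarray]        # unitless
    n: int


# ---------------------------------------------------------------------------
# Perpetrator exposure


class PerpetratorExposure:
    """Unbound plasma concentration of a perpetrator as a function of time."""

    def __init__(self, unbound_fn, kink_times=(), label=""):
        self._fn = unbound_fn
        self.kink_times = tuple(float(t) for t in kink_times)
        self.label = label

    def unbound(self, t):
        return self._fn(t)


def perpetrator_exposure(
    regimen: PerpetratorRegimen,
    compound_cfg: dict,
    duration_min: float,
    mode: str | None = None,
    settings: SimSettings | None = None,
) -> PerpetratorExposure:
    """Build the unbound-concentration forcing profile of a perpetrator.

    ``forcing_table`` mode interpolates the supplied series linearly and
    reproduces the supplied values exactly at the supplied times. ``model``
    mode integrates a reduced one-compartment oral model (first-order
    absorption and elimination) numerically and evaluates its dense solution.
    """
    mode = mode or regimen.mode
    if mode == "forcing_table":
        if regimen.forcing_times is None or regimen.forcing_unbound is None:
            raise ValueError("forcing_table mode requires forcing_times/forcing_unbound")
        times = np.asarray(regimen.forcing_times, dtype=float)
        values = np.asarray(regimen.forcing_unbound, dtype=float)
        if np.any(values < 0):
            raise ValueError("forcing concentrations must be >= 0")
        if times[0] > 0 or times[-1] < duration_min:
            raise ValueError("forcing table does not cover the simulation window")

        def fn(t, times=times, values=values):
            return float(np.interp(t, times, values))

        return PerpetratorExposure(fn, kink_times=(), label=regimen.compound)

    rm = compound_cfg.get("reduced_model")
    if rm is None:
        raise ConfigurationError(
            f"perpetrator {regimen.compound!r} has no reduced_model configuration"
        )
    ka, ke = float(rm["ka_per_min"]), float(rm["ke_per_min"])
    v, f_oral = float(rm["v_L"]), float(rm["f_oral"])
    fu = float(compound_cfg["fu"])
    mw = float(compound_cfg["mw"])

    dose_times = sorted(t for _, t in regimen.doses)
    boundaries = [0.0] + [t for t in dose_times if 0.0 < t < duration_min] + [duration_min]
    boundaries = sorted(set(boundaries))
    dose_at = {}
    for amount_mg, t in regimen.doses:
        if 0.0 <= t <= duration_min:
            dose_at[t] = dose_at.get(t, 0.0) + amount_mg / mw * 1000.0  # µmol

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    settings = settings or SimSettings()
    y = np.zeros(2)
    solutions = []
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        if t0 in dose_at:
            y = y + np.array([f_oral * dose_at[t0], 0.0])
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", dense_output=True,
            rtol=min(settings.rtol, 1e-10), atol=1e-14,
        )
        if not sol.success:
            raise IntegrationError(f"perpetrator model failed near t={sol.t[-1]:.3f} min")
        solutions.append((t0, t1, sol.sol))
        y = sol.y[:, -1]
    if boundaries[-1] in dose_at and boundaries[-1] == duration_min:
        pass  # dose exactly at the end of the window has no effect

    def fn(t, solutions=solutions, fu=fu, v=v):
        if np.ndim(t) > 0:
            return np.array([fn(ti) for ti in np.asarray(t, dtype=float).ravel()])
        t = float(t)
        if not solutions or t <= solutions[0][0]:
            return 0.0
        for t0, t1, interp in solutions:
            if t0 <= t <= t1:
                return fu * max(interp(t)[1], 0.0) / v
        _t0, t1, interp = solutions[-1]
        return fu * max(interp(t1)[1], 0.0) / v

    return PerpetratorExposure(fn, kink_times=dose_times, label=regimen.compound)


# ---------------------------------------------------------------------------
# Model assembly


@dataclass
class Interactions:
    inhibitions: list[InhibitionSpec] = field(default_factory=list)
    inductions: list[InductionSpec] = field(default_factory=list)
    perpetrator_configs: dict[str, dict] = field(default_factory=dict)


class ModelSystem:
    """Assembled state-vector layout + right-hand side for one scenario."""

    def __init__(
        self,
        compounds: list[Compound],
        physiology: PhysiologyParameters,
        processes: list[EnzymeProcess],
        interactions: Interactions | None = None,
        binding_capacities: dict[str, float] | None = None,
        defaults: dict | None = None,
    ):
        self.defaults = defaults or load_defaults()
        self.compounds = list(compounds)
        self.names = [c.name for c in self.compounds]
        self.cindex = {name: i for i, name in enumerate(self.names)}
        self.physiology = physiology
        self.processes = list(processes)
        self.interactions = interactions or Interactions()
        self.one_compartment_mode = False

        required = tuple({p.enzyme for p in self.processes})
        physiology.validate(required_enzymes=required)
        for proc in self.processes:
            if proc.substrate not in self.cindex:
                raise ConfigurationError(f"process substrate not declared: {proc.substrate!r}")
            if not proc.is_sink and proc.product not in self.cindex:
                raise ConfigurationError(
                    f"dangling product name {proc.product!r} in process {proc.process_id}"
                )

        abs_cfg = self.defaults["absorption"]
        self.n_seg = int(abs_cfg["n_segments"])
        self.transit_k = self.n_seg / float(abs_cfg["transit_time_min"])
        self.v_seg = float(abs_cfg["lumen_volume_L"]) / self.n_seg
        self.area_seg = float(abs_cfg["surface_area_cm2"]) / self.n_seg
        self.sa_per_L_cell = float(abs_cfg["cell_surface_area_cm2_per_L"])

        # Target binding (explicit bound pools, configured organs)
        self.binding_entries = []   # (compound index, organ index, kon, koff, capacity µmol/L)
        caps = binding_capacities if binding_capacities is not None else {
            organ: float(c) for organ, c in self.defaults["binding_capacities"].items()
        }
        for ci, compound in enumerate(self.compounds):
            if compound.binding is None:
                continue
            kon = kon_from_binding(compound.binding)
            organs = compound.binding.organs or caps
            for organ, capacity in organs.items():
                if organ not in ORG_INDEX:
                    raise ConfigurationError(f"binding organ {organ!r} not in organ set")
                self.binding_entries.append(
                    (ci, ORG_INDEX[organ], kon, compound.binding.koff, float(capacity))
                )

        # Enzyme turnover pools: one state per induced enzyme per expressing organ
        induced = sorted({spec.enzyme for spec in self.interactions.inductions})
        self.enzyme_pools = []       # (enzyme, organ index)
        for enzyme in induced:
            for (enz, organ) in sorted(physiology.enzyme_reference_concentrations):
                if enz == enzyme and organ in ORG_INDEX:
                    self.enzyme_pools.append((enzyme, ORG_INDEX[organ]))
        self.pool_index = {key: i for i, key in enumerate(self.enzyme_pools)}

        self._build_layout()
        self._precompute()

    # ------------------------------------------------------------------
    @classmethod
    def one_compartment(
        cls, compound: Compound, volume_L: float, clearance_L_per_min: float
    ) -> "ModelSystem":
        """Degenerate single-pool configuration with linear clearance.

        Shares the event/integration path of the full model; iv doses only.
        """
        system = cls.__new__(cls)
        system.defaults = load_defaults()
        system.compounds = [compound]
        system.names = [compound.name]
        system.cindex = {compound.name: 0}
        system.processes = []
        system.interactions = Interactions()
        system.binding_entries = []
        system.enzyme_pools = []
        system.pool_index = {}
        system.one_compartment_mode = True
        system.oc_volume = float(volume_L)
        system.oc_clearance = float(clearance_L_per_min)
        system.n_states = 2                      # central amount + cleared ledger
        system.nb = 1
        system.physiology = None
        return system

    # ------------------------------------------------------------------
    def _build_layout(self):
        no = len(SYSTEMIC_ORGANS)
        self.nb = 4 + 2 * no + 1 + self.n_seg + 1   # per-compound block
        self.i_ven, self.i_art, self.i_lung_v, self.i_lung_c = 0, 1, 2, 3
        self.sl_vasc = slice(4, 4 + no)
        self.sl_cell = slice(4 + no, 4 + 2 * no)
        self.i_und = 4 + 2 * no
        self.sl_lumen = slice(self.i_und + 1, self.i_und + 1 + self.n_seg)
        self.i_gall = self.i_und + self.n_seg + 1

        nc = len(self.compounds)
        self.off_bound = nc * self.nb
        self.off_pools = self.off_bound + len(self.binding_entries)
        self.off_ledger = self.off_pools + len(self.enzyme_pools)
        self.off_urine = self.off_ledger + len(self.processes)
        self.off_feces = self.off_urine + nc
        self.off_absorbed = self.off_feces + nc
        self.n_states = self.off_absorbed + nc

    @property
    def state_count(self) -> int:
        return self.n_states

    def layout(self) -> dict:
        """Human-readable audit of the deterministic state layout."""
        if self.one_compartment_mode:
            return {"mode": "one_compartment", "states": self.n_states}
        return {
            "compounds": self.names,
            "per_compound_block": self.nb,
            "organs": list(SYSTEMIC_ORGANS),
            "lumen_segments": self.n_seg,
            "bound_pools": len(self.binding_entries),
            "enzyme_pools": [(enz, SYSTEMIC_ORGANS[o]) for enz, o in self.enzyme_pools],
            "process_ledger": [p.process_id for p in self.processes],
            "states": self.n_states,
        }

    # ------------------------------------------------------------------
    def _precompute(self):
        phys = self.physiology
        nc, no = len(self.compounds), len(SYSTEMIC_ORGANS)
        hct = phys.hematocrit
        plasma = 1.0 - hct

        self.v_ven = phys.organ_volumes["venous_blood"] * plasma
        self.v_art = phys.organ_volumes["arterial_blood"] * plasma
        pool1 = phys.pool1_fractions
        v_lung = phys.organ_volumes["lung"]
        self.v_lung_v = v_lung * pool1["lung"]
        self.v_lung_c = v_lung * (1.0 - pool1["lung"])

        self.v_vasc = np.array(
            [phys.organ_volumes[o] * pool1[o] for o in SYSTEMIC_ORGANS]
        )
        self.v_cell = np.array(
            [phys.organ_volumes[o] * (1.0 - pool1[o]) for o in SYSTEMIC_ORGANS]
        )
        self.q = np.array([phys.blood_flows[o] * plasma for o in SYSTEMIC_ORGANS])
        self.co = self.q.sum()
        # liver outflow carries its arterial supply plus the portal inflow
        self.q_out = self.q.copy()
        self.q_out[I_LIVER] = self.q[I_LIVER] + self.q[I_GUT] + self.q[I_SPLEEN]
        self.arterial_organs = np.ones(no, dtype=bool)          # organs fed from arterial
        self.to_venous = np.ones(no, dtype=bool)
        self.to_venous[[I_GUT, I_SPLEEN]] = False               # portal organs drain to liver

        self.fu = np.array([c.fu for c in self.compounds])
        self.mw = np.array([c.mw for c in self.compounds])
        self.gfr_frac = np.array([c.gfr_fraction for c in self.compounds])
        self.peff = np.array([c.intestinal_permeability_cm_min for c in self.compounds])
        self.ehc_frac = np.array([c.ehc_continuous_fraction for c in self.compounds])

        from .compounds import load_tissue_composition

        composition = load_tissue_composition()
        aph = float(self.defaults["partitioning"]["aph_scale"])
        self.kp = np.ones((nc, no))
        for ci, compound in enumerate(self.compounds):
            kps = partition_coefficients(compound, composition, aph_scale=aph)
            for o, organ in enumerate(SYSTEMIC_ORGANS):
                if organ not in kps:
                    raise ConfigurationError(f"missing composition row for organ {organ!r}")
                self.kp[ci, o] = kps[organ]
        self.kp_lung = np.array(
            [partition_coefficients(c, composition, aph_scale=aph).get("lung", 1.0)
             for c in self.compounds]
        )

        perm = np.array([c.cellular_permeability_cm_min for c in self.compounds])
        self.ps = perm[:, None] * self.sa_per_L_cell * self.v_cell[None, :] / 1000.0
        self.ps_lung = perm * self.sa_per_L_cell * self.v_lung_c / 1000.0

        # per-process arrays: enzyme amounts per organ (µmol)
        self.proc_info = []
        for pi, proc in enumerate(self.processes):
            organs, amounts = [], []
            for (enz, organ), conc in sorted(phys.enzyme_reference_concentrations.items()):
                if enz == proc.enzyme and organ in ORG_INDEX:
                    o = ORG_INDEX[organ]
                    organs.append(o)
                    amounts.append(conc * self.v_cell[o] * proc.enzyme_fraction)
            if not organs:
                raise ConfigurationError(f"no organ expression for enzyme {proc.enzyme!r}")
            self.proc_info.append(
                {
                    "index": pi,
                    "cs": self.cindex[proc.substrate],
                    "cp": self.cindex.get(proc.product),
                    "organs": np.array(organs),
                    "e_amount": np.array(amounts),
                    "km": proc.km,
                    "kcat": proc.kcat,
                    "enzyme": proc.enzyme,
                    "pools": [self.pool_index.get((proc.enzyme, o)) for o in organs],
                }
            )

        self.inh_by_enzyme: dict[str, list[tuple[str, float]]] = {}
        for spec in self.interactions.inhibitions:
            self.inh_by_enzyme.setdefault(spec.enzyme, []).append((spec.perpetrator, spec.ki))
        self.ind_by_enzyme: dict[str, list[InductionSpec]] = {}
        for spec in self.interactions.inductions:
            self.ind_by_enzyme.setdefault(spec.enzyme, []).append(spec)

    # ------------------------------------------------------------------
    def _rhs_full(self, t, y, depots, exposures):
        nc, no = len(self.compounds), len(SYSTEMIC_ORGANS)
        blocks = y[: nc * self.nb].reshape(nc, self.nb)
        dy = np.zeros_like(y)
        dblocks = dy[: nc * self.nb].reshape(nc, self.nb)

        a_ven = blocks[:, self.i_ven]
        a_art = blocks[:, self.i_art]
        c_ven = a_ven / self.v_ven
        c_art = a_art / self.v_art
        c_lung_v = blocks[:, self.i_lung_v] / self.v_lung_v
        c_lung_c = blocks[:, self.i_lung_c] / self.v_lung_c
        c_vasc = blocks[:, self.sl_vasc] / self.v_vasc[None, :]
        c_cell = blocks[:, self.sl_cell] / self.v_cell[None, :]
        cu_cell = np.maximum(self.fu[:, None] * c_cell / self.kp, 0.0)

        # permeability-limited exchange vascular <-> cell
        j_ex = self.ps * (self.fu[:, None] * c_vasc - cu_cell)
        j_lung = self.ps_lung * (self.fu * c_lung_v - self.fu * c_lung_c / self.kp_lung)

        d_vasc = self.q[None, :] * c_art[:, None] - self.q_out[None, :] * c_vasc - j_ex
        # liver receives portal outflow in addition to its arterial supply
        d_vasc[:, I_LIVER] += (
            self.q_out[I_GUT] * c_vasc[:, I_GUT] + self.q_out[I_SPLEEN] * c_vasc[:, I_SPLEEN]
        )
        d_cell = j_ex.copy()

        d_ven = (self.q_out[None, :] * c_vasc)[:, self.to_venous].sum(axis=1) - self.co * c_ven
        d_lung_v = self.co * c_ven - self.co * c_lung_v - j_lung
        d_lung_c = j_lung
        d_art = self.co * c_lung_v - self.co * c_art

        # renal filtration from the kidney vascular pool
        v_ren = self.physiology.gfr * self.gfr_frac * self.fu * c_vasc[:, I_KIDNEY]
        d_vasc[:, I_KIDNEY] -= v_ren
        dy[self.off_urine : self.off_urine + nc] += v_ren

        # gut lumen: Weibull release, transit, absorption
        lumen = blocks[:, self.sl_lumen]
        release = np.zeros(nc)
        for ci, dose_umol, spec, t0 in depots:
            release[ci] += dose_umol * weibull_release_rate(t - t0, spec)
        dblocks[:, self.i_und] -= release
        d_lumen = np.zeros_like(lumen)
        d_lumen[:, 0] += release
        d_lumen -= self.transit_k * lumen
        d_lumen[:, 1:] += self.transit_k * lumen[:, :-1]
        dy[self.off_feces : self.off_feces + nc] += self.transit_k * lumen[:, -1]
        c_lumen = lumen / self.v_seg
        j_abs = self.peff[:, None] * self.area_seg / 1000.0 * (
            c_lumen - cu_cell[:, I_GUT][:, None]
        )
        d_lumen -= j_abs
        total_abs = j_abs.sum(axis=1)
        d_cell[:, I_GUT] += total_abs
        dy[self.off_absorbed : self.off_absorbed + nc] += total_abs

        # target binding pools
        for bi, (ci, o, kon, koff, capacity) in enumerate(self.binding_entries):
            bound = y[self.off_bound + bi]
            cap = capacity * self.v_cell[o]
            rate = kon * cu_cell[ci, o] * max(cap - bound, 0.0) - koff * bound
            dy[self.off_bound + bi] = rate
            d_cell[ci, o] -= rate

        # perpetrator forcing: unbound concentrations and modifiers
        iu = {name: exp.unbound(t) for name, exp in exposures.items()}
        inh_factor = {}
        for enzyme, entries in self.inh_by_enzyme.items():
            inh_factor[enzyme] = 1.0 + sum(iu.get(p, 0.0) / ki for p, ki in entries)

        # enzyme turnover pools
        pools = y[self.off_pools : self.off_pools + len(self.enzyme_pools)]
        for qi, (enzyme, _o) in enumerate(self.enzyme_pools):
            fold = 1.0
            for spec in self.ind_by_enzyme.get(enzyme, ()):
                conc = iu.get(spec.perpetrator, 0.0)
                fold += spec.emax * conc / (spec.ec50 + conc)
            kdeg = self.ind_by_enzyme[enzyme][0].kdeg if enzyme in self.ind_by_enzyme else 0.0
            dy[self.off_pools + qi] = kdeg * (fold - pools[qi])

        # saturable metabolism
        for info in self.proc_info:
            cs = info["cs"]
            km_eff = info["km"] * inh_factor.get(info["enzyme"], 1.0)
            cu = cu_cell[cs, info["organs"]]
            e_amt = info["e_amount"].copy()
            for slot, pool_id in enumerate(info["pools"]):
                if pool_id is not None:
                    e_amt[slot] *= pools[pool_id]
            v = info["kcat"] * e_amt * cu / (km_eff + cu)
            np.add.at(d_cell[cs], info["organs"], -v)
            if info["cp"] is not None:
                np.add.at(d_cell[info["cp"]], info["organs"], v)
            dy[self.off_ledger + info["index"]] = v.sum()

        dblocks[:, self.i_ven] = d_ven
        dblocks[:, self.i_art] = d_art
        dblocks[:, self.i_lung_v] = d_lung_v
        dblocks[:, self.i_lung_c] = d_lung_c
        dblocks[:, self.sl_vasc] += d_vasc
        dblocks[:, self.sl_cell] += d_cell
        dblocks[:, self.sl_lumen] += d_lumen
        return dy

    def _rhs_one_compartment(self, t, y, depots, exposures):
        compound = self.compounds[0]
        conc = y[0] / self.oc_volume
        cleared = self.oc_clearance * conc
        return np.array([-cleared, cleared])

    # ------------------------------------------------------------------
    def _resolve_formulation(self, formulation) -> FormulationSpec:
        if isinstance(formulation, FormulationSpec):
            return formulation
        if formulation is None:
            return FormulationSpec(kind="solution")
        cfg = self.defaults["formulations"].get(formulation)
        if cfg is None:
            raise ConfigurationError(f"unknown formulation label: {formulation!r}")
        return FormulationSpec.from_config(cfg)

    def simulate(
        self,
        protocol: StudyProtocol,
        individual: PhysiologyParameters | None = None,
        settings: SimSettings | None = None,
    ) -> SimulationResult:
        """Integrate the assembled system under one study protocol."""
        settings = settings or SimSettings(
            rtol=float(self.defaults["simulation"]["rtol"]),
            atol=float(self.defaults["simulation"]["atol"]),
            method=self.defaults["simulation"]["method"],
        )
        base_physiology = self.physiology
        if individual is not None and not self.one_compartment_mode:
            self.physiology = individual
            self._precompute()
        try:
            return self._simulate_inner(protocol, settings)
        finally:
            if individual is not None and not self.one_compartment_mode:
                self.physiology = base_physiology
                self._precompute()

    def _simulate_inner(self, protocol: StudyProtocol, settings: SimSettings):
        nc = len(self.compounds)
        duration = float(protocol.duration_min)
        obs = protocol.observation_times_min
        if obs is None:
            obs = np.linspace(0.0, duration, 501)
        obs = np.unique(np.asarray(obs, dtype=float))

        # perpetrator exposures (forcing)
        exposures: dict[str, PerpetratorExposure] = {}
        kinks: list[float] = []
        for regimen in protocol.perpetrators:
            cfg = self.interactions.perpetrator_configs.get(regimen.compound)
            if cfg is None:
                raise ConfigurationError(
                    f"no perpetrator model configured for {regimen.compound!r}"
                )
            exposure = perpetrator_exposure(regimen, cfg, duration, settings=settings)
            exposures[regimen.compound] = exposure
            kinks.extend(t for t in exposure.kink_times if 0.0 < t < duration)

        # dose bookkeeping
        dose_umol = {name: 0.0 for name in self.names}
        events: dict[float, list[tuple]] = {}
        depots: list[tuple] = []
        for dose in protocol.victim_doses:
            if dose.compound not in self.cindex:
                raise ConfigurationError(f"dose for undeclared compound {dose.compound!r}")
            ci = self.cindex[dose.compound]
            amount = dose.amount_mg / self.mw_of(ci) * 1000.0
            dose_umol[dose.compound] += amount
            events.setdefault(dose.time_min, []).append((ci, amount, dose))

        boundaries = sorted(set([0.0, duration]) | set(events) | set(kinks))

        y = np.zeros(self.n_states)
        if not self.one_compartment_mode:
            # enzyme pools start at baseline
            y[self.off_pools : self.off_pools + len(self.enzyme_pools)] = 1.0

        rhs_core = self._rhs_one_compartment if self.one_compartment_mode else self._rhs_full

        out_times: list[np.ndarray] = []
        out_states: list[np.ndarray] = []
        warnings: list[str] = []

        for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
            for ci, amount, dose in events.get(t0, ()):
                y = y.copy()
                if self.one_compartment_mode:
                    if dose.route != "iv":
                        raise ConfigurationError("one-compartment mode supports iv doses only")
                    y[0] += amount
                elif dose.route == "iv":
                    y[ci * self.nb + self.i_ven] += amount
                else:
                    spec = self._resolve_formulation(dose.formulation)
                    if spec.kind == "solution":
                        y[ci * self.nb + self.i_und + 1] += amount  # first lumen segment
                    else:
                        y[ci * self.nb + self.i_und] += amount
                        depots.append((ci, amount, spec, t0))
            seg_obs = obs[(obs >= t0) & (obs <= t1)]
            t_eval = np.unique(np.concatenate([seg_obs, [t1]]))
            t_eval = t_eval[t_eval >= t0]
            sol = solve_ivp(
                rhs_core,
                (t0, t1),
                y,
                method=settings.method,
                t_eval=t_eval,
                rtol=settings.rtol,
                atol=settings.atol,
                args=(depots, exposures),
            )
            if not sol.success:
                raise IntegrationError(
                    f"integrator failed near t={sol.t[-1] if sol.t.size else t0:.3f} min: "
                    f"{sol.message}"
                )
            keep = np.isin(sol.t, seg_obs)
            out_times.append(sol.t[keep])
            out_states.append(sol.y[:, keep])
            y = sol.y[:, -1]

        times = np.concatenate(out_times)
        states = np.concatenate(out_states, axis=1)
        # a sample falling on a dose time appears once per adjoining segment;
        # keep the post-dose state (last occurrence)
        _, first_rev = np.unique(times[::-1], return_index=True)
        idx = np.sort(times.size - 1 - first_rev)
        times, states = times[idx], states[:, idx]
        # physical amount states must stay nonnegative (the net-absorption
        # ledger may legitimately go negative under intestinal secretion)
        if not self.one_compartment_mode:
            physical = states[: self.off_pools]
            if np.min(physical) < -settings.max_negative:
                raise IntegrityError(
                    f"state fell below zero beyond tolerance (min {np.min(physical):.3e} µmol)"
                )

        if self.one_compartment_mode:
            conc = states[0] / self.oc_volume
            name = self.names[0]
            total_dose = dose_umol[name]
            total = states[0] + states[1]
            err = np.abs(total - _dose_given(times, events)) / max(total_dose, 1e-30)
            return SimulationResult(
                times=times,
                concentrations={(name, "central"): conc},
                plasma_concentrations={name: conc * self.compounds[0].mw},
                flux_ledger={"clearance": states[1]},
                excreted={name: {"cleared": float(states[1, -1])}},
                dose_administered=dose_umol,
                absorbed={name: total_dose},
                amount_remaining={name: float(states[0, -1])},
                mass_balance_rel_error=err,
            )

        return self._package_result(times, states, dose_umol, events, warnings)

    def mw_of(self, ci: int) -> float:
        return self.compounds[ci].mw

    # ------------------------------------------------------------------
    def _package_result(self, times, states, dose_umol, events, warnings):
        nc = len(self.compounds)
        blocks = states[: nc * self.nb].reshape(nc, self.nb, -1)

        concentrations: dict[tuple[str, str], np.ndarray] = {}
        plasma: dict[str, np.ndarray] = {}
        for ci, name in enumerate(self.names):
            concentrations[(name, "venous_plasma")] = blocks[ci, self.i_ven] / self.v_ven
            concentrations[(name, "arterial_plasma")] = blocks[ci, self.i_art] / self.v_art
            for o, organ in enumerate(SYSTEMIC_ORGANS):
                concentrations[(name, f"{organ}_cell")] = (
                    blocks[ci, self.sl_cell][o] / self.v_cell[o]
                )
            plasma[name] = concentrations[(name, "venous_plasma")] * self.compounds[ci].mw

        ledger = {
            proc.process_id: states[self.off_ledger + pi]
            for pi, proc in enumerate(self.processes)
        }
        if np.any(np.diff(states[self.off_ledger : self.off_urine], axis=1) < -1e-9):
            warnings.append("flux ledger transiently decreased beyond tolerance")

        excreted: dict[str, dict[str, float]] = {}
        absorbed: dict[str, float] = {}
        remaining: dict[str, float] = {}
        for ci, name in enumerate(self.names):
            sink = sum(
                float(states[self.off_ledger + pi, -1])
                for pi, proc in enumerate(self.processes)
                if proc.substrate == name and proc.is_sink
            )
            excreted[name] = {
                "urine": float(states[self.off_urine + ci, -1]),
                "feces": float(states[self.off_feces + ci, -1]),
                "glucuronide_sink": sink,
            }
            iv_amount = sum(
                amount
                for evs in events.values()
                for (eci, amount, dose) in evs
                if eci == ci and dose.route == "iv"
            )
            absorbed[name] = float(states[self.off_absorbed + ci, -1]) + iv_amount
            remaining[name] = float(blocks[ci, :, -1].sum()) + sum(
                float(states[self.off_bound + bi, -1])
                for bi, entry in enumerate(self.binding_entries)
                if entry[0] == ci
            )

        # molar mass balance across the network
        total = blocks.sum(axis=(0, 1))
        total = total + states[self.off_bound : self.off_pools].sum(axis=0)
        total = total + states[self.off_urine : self.off_absorbed].sum(axis=0)
        for pi, proc in enumerate(self.processes):
            if proc.is_sink:
                total = total + states[self.off_ledger + pi]
        given = _dose_given(times, events)
        scale = max(sum(dose_umol.values()), 1e-30)
        mb_err = np.abs(total - given) / scale

        enzyme_pools = {
            (enzyme, SYSTEMIC_ORGANS[o]): states[self.off_pools + qi]
            for qi, (enzyme, o) in enumerate(self.enzyme_pools)
        }

        return SimulationResult(
            times=times,
            concentrations=concentrations,
            plasma_concentrations=plasma,
            flux_ledger=ledger,
            excreted=excreted,
            dose_administered=dose_umol,
            absorbed=absorbed,
            amount_remaining=remaining,
            mass_balance_rel_error=mb_err,
            enzyme_pools=enzyme_pools,
            warnings=tuple(warnings),
        )

    # ------------------------------------------------------------------
    def simulate_population(
        self,
        protocol: StudyProtocol,
        population: list[PhysiologyParameters],
        settings: SimSettings | None = None,
    ) -> PopulationResult:
        """Geometric mean / geometric SD profiles over a virtual population."""
        if not population:
            raise ValueError("population must be nonempty")
        profiles: dict[str, list[np.ndarray]] = {name: [] for name in self.names}
        times = None
        for individual in population:
            result = self.simulate(protocol, individual=individual, settings=settings)
            times = result.times
            for name in self.names:
                profiles[name].append(result.plasma_concentrations[name])
        geo_mean, geo_sd = {}, {}
        for name, series in profiles.items():
            geo_mean[name], geo_sd[name] = geometric_summary(np.asarray(series))
        return PopulationResult(times=times, geo_mean=geo_mean, geo_sd=geo_sd, n=len(population))


def geometric_summary(profiles: np.ndarray, floor: float = 1e-12):
    """Per-time geometric mean and geometric SD over subject profiles.

    ``profiles`` has shape (n_subjects, n_times); values at or below the floor
    are treated as the floor inside the logs, and times where every subject is
    at the floor report a geometric mean of zero and a geometric SD of one.
    """
    arr = np.maximum(np.asarray(profiles, dtype=float), floor)
    logs = np.log(arr)
    geo_mean = np.exp(logs.mean(axis=0))
    geo_sd = np.exp(logs.std(axis=0, ddof=0))
    all_floor = np.all(np.asarray(profiles) <= floor, axis=0)
    geo_mean[all_floor] = 0.0
    geo_sd[all_floor] = 1.0
    return geo_mean, geo_sd


def _dose_given(times: np.ndarray, events: dict[float, list[tuple]]) -> np.ndarray:
    given = np.zeros_like(times)
    for t_dose, evs in events.items():
        amount = sum(a for _ci, a, _d in evs)
        given += np.where(times >= t_dose, amount, 0.0)
    return given


# ---------------------------------------------------------------------------
# Derived quantities


def fraction_metabolized(result: SimulationResult, parent: str) -> dict:
    """Fractions of total parent metabolism per pathway, from the flux ledger.

    Pathways are grouped by enzyme; fractions sum to 1. The fraction excreted
    unchanged, ``(urine + feces) / absorbed``, is reported separately. If less
    than 99.9% of the absorbed parent has been eliminated the result carries a
    warning flag rather than an error.
    """
    by_enzyme: dict[str, float] = {}
    total = 0.0
    for pid, series in result.flux_ledger.items():
        if f":{parent}->" not in pid:
            continue
        enzyme = pid.split("[")[0].split(":")[0]
        flux = float(series[-1])
        by_enzyme[enzyme] = by_enzyme.get(enzyme, 0.0) + flux
        total += flux
    if total <= 0:
        raise ValueError(f"no metabolic flux recorded for {parent!r}")
    fractions = {enzyme: flux / total for enzyme, flux in by_enzyme.items()}

    excreted = result.excreted.get(parent, {})
    unchanged = excreted.get("urine", 0.0) + excreted.get("feces", 0.0)
    absorbed = result.absorbed.get(parent, 0.0)
    remaining = result.amount_remaining.get(parent, 0.0)
    flags = []
    if absorbed > 0 and remaining / absorbed > 1e-3:
        flags.append("parent_elimination_incomplete")
    return {
        "fractions": fractions,
        "fraction_unchanged": unchanged / absorbed if absorbed > 0 else math.nan,
        "fraction_metabolized_total": total / absorbed if absorbed > 0 else math.nan,
        "flags": tuple(flags),
    }
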