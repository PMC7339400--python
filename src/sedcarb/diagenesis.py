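"""Two-layer riverbed sediment diagenesis with carbon resuspension.

The sediment column is split into a thin aerobic surface layer (default
1 mm) over a thicker anaerobic layer (default 10 cm).  Particulate organic
carbon settling out of the water column enters the anaerobic layer and is
split into three reactivity classes: labile (G1), slow-reacting (G2) and
non-reacting (G3).  G1 and G2 mineralize by first-order kinetics with
Arrhenius-style temperature correction; the mineralized carbon (the
"diagenesis flux"), less an optional denitrification sink, becomes
dissolved methane.  Methane above the dissolved-transport capacity of the
sediment escapes directly as bubbles; the dissolved remainder moves to the
aerobic layer where it is partly oxidized to CO2 and partly diffuses into
the overlying water.  All pools are additionally subject to resuspension
(proportional to the resuspended bulk-sediment flux) and the POC pools to
burial at a constant burial velocity.

Every operation works in areal flux units of gC m^-2 day^-1 and pool
concentrations of gC m^-3; each daily step conserves carbon exactly:
deposition = change in storage + resuspension + burial + inorganic release
+ denitrification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "LayerGeometry",
    "SedimentState",
    "DiagenesisParams",
    "DiagenesisFluxes",
    "partition_deposition",
    "poc_resuspension_flux",
    "poc_mineralization_flux",
    "poc_burial_flux",
    "step_anaerobic",
    "ch4_saturation",
    "ch4_transport_capacity",
    "methane_partition",
    "ch4_resuspension_flux",
    "step_aerobic_ch4",
    "step_sediment",
    "inorganic_release",
]

#: gO2 consumed per gC oxidized; reporting convenience only, the model
#: carries carbon units throughout.
O2_PER_C = 2.67


@dataclass(frozen=True)
class LayerGeometry:
    """Thicknesses of the two sediment layers (m).

    h1 : aerobic surface layer, default 1 mm.
    h2 : anaerobic layer, default 10 cm.
    """

    h1: float = 0.001
    h2: float = 0.1

    def __post_init__(self) -> None:
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("layer thicknesses must be positive")


@dataclass(frozen=True)
class SedimentState:
    """Sediment carbon pools.

    poc_g1/poc_g2/poc_g3 : organic C concentration in the anaerobic layer
    (gC m^-3 bulk sediment); ch4 : dissolved methane in the aerobic layer
    (gC m^-3).
    """

    poc_g1: float = 0.0
    poc_g2: float = 0.0
    poc_g3: float = 0.0
    ch4: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")

    @property
    def poc(self) -> tuple[float, float, float]:
        return (self.poc_g1, self.poc_g2, self.poc_g3)

    def storage(self, geom: LayerGeometry) -> float:
        """Total sediment carbon per unit bed area (gC m^-2)."""
        return (self.poc_g1 + self.poc_g2 + self.poc_g3) * geom.h2 + self.ch4 * geom.h1


@dataclass(frozen=True)
class DiagenesisParams:
    """Rate constants and closure parameters of the diagenesis model.

    The G-fraction split and mineralization rates follow the Di Toro /
    QUAL2K defaults for settled organic matter; the burial velocity is the
    6.85e-6 m day^-1 value used for riverbed sediments.  The methane
    closure (saturation, oxidation, diffusion) is parameterized by a
    saturation concentration at 20 degC, a temperature base, a first-order
    oxidation rate in the aerobic layer, and a sediment-water mass-transfer
    velocity.
    """

    f_g1: float = 0.65
    f_g2: float = 0.20
    f_g3: float = 0.15
    k_g1: float = 0.035  # day^-1 at 20 degC
    k_g2: float = 0.0018  # day^-1 at 20 degC
    theta_g1: float = 1.10
    theta_g2: float = 1.15
    w_bury: float = 6.85e-6  # m day^-1
    rho_sed: float = 1.0  # Mg m^-3 bulk bed sediment density
    ch4_sat_ref: float = 37.5  # gC m^-3 at 20 degC, zero depth
    theta_sat: float = 1.024
    k_ch4_ox: float = 100.0  # day^-1 at 20 degC
    theta_ch4_ox: float = 1.079
    v_diff: float = 0.1  # m day^-1 CH4 sediment-water transfer velocity

    def __post_init__(self) -> None:
        if abs(self.f_g1 + self.f_g2 + self.f_g3 - 1.0) > 1e-9:
            raise ValueError("G-fractions must sum to 1")
        if min(self.f_g1, self.f_g2, self.f_g3) < 0:
            raise ValueError("G-fractions must be nonnegative")
        for name in ("k_g1", "k_g2", "w_bury", "ch4_sat_ref", "k_ch4_ox", "v_diff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rho_sed <= 0:
            raise ValueError("rho_sed must be positive")
        if self.k_g1 <= self.k_g2:
            raise ValueError("k_g1 must exceed k_g2 (G1 is the labile pool)")


@dataclass(frozen=True)
class DiagenesisFluxes:
    """All sediment-water interface fluxes of one daily step (gC m^-2 day^-1).

    Per-pool tuples are ordered (G1, G2, G3).  j_c is the diagenesis flux
    (G1 + G2 mineralization); j_ch4_d the dissolved methane delivered to
    the aerobic layer; j_ch4_gas the anaerobic bubble flux; j_ch4_w the
    diffusive flux to the water column; j_ch4_r methane resuspension;
    j_ch4_o methane oxidized to CO2 (leaves the sediment as CO2 gas).
    """

    j_poc_dep: tuple[float, float, float] = (0.0, 0.0, 0.0)
    j_poc_res: tuple[float, float, float] = (0.0, 0.0, 0.0)
    j_poc_min: tuple[float, float, float] = (0.0, 0.0, 0.0)
    j_poc_bury: tuple[float, float, float] = (0.0, 0.0, 0.0)
    j_c: float = 0.0
    j_c_den: float = 0.0
    j_ch4_gas: float = 0.0
    j_ch4_d: float = 0.0
    j_ch4_w: float = 0.0
    j_ch4_r: float = 0.0
    j_ch4_o: float = 0.0

    @property
    def deposition_total(self) -> float:
        return sum(self.j_poc_dep)

    @property
    def resuspension_total(self) -> float:
        """Organic + porewater-methane carbon returned to the water column."""
        return sum(self.j_poc_res) + self.j_ch4_r

    @property
    def burial_total(self) -> float:
        return sum(self.j_poc_bury)

    def as_dict(self) -> dict[str, float]:
        d: dict[str, float] = {}
        for i, g in enumerate(("g1", "g2", "g3")):
            d[f"j_poc_dep_{g}"] = self.j_poc_dep[i]
            d[f"j_poc_res_{g}"] = self.j_poc_res[i]
            d[f"j_poc_min_{g}"] = self.j_poc_min[i]
            d[f"j_poc_bury_{g}"] = self.j_poc_bury[i]
        for name in ("j_c", "j_c_den", "j_ch4_gas", "j_ch4_d", "j_ch4_w",
                     "j_ch4_r", "j_ch4_o"):
            d[name] = getattr(self, name)
        return d


def partition_deposition(
    j_total: float, params: DiagenesisParams
) -> tuple[float, float, float]:
    """Split a settled organic-C flux into the G1/G2/G3 reactivity classes."""
    if j_total < 0:
        raise ValueError("deposition flux must be nonnegative")
    return (params.f_g1 * j_total, params.f_g2 * j_total, params.f_g3 * j_total)


def _resuspension_flux(
    conc: float,
    rho_sed: float,
    j_sed_r: float,
    available_mass: float = math.inf,
    dt: float = 1.0,
) -> float:
    if rho_sed <= 0:
        raise ValueError("rho_sed must be positive")
    if min(conc, j_sed_r, available_mass) < 0 or dt <= 0:
        raise ValueError("inputs must be nonnegative and dt positive")
    raw = conc / (rho_sed * 1e6) * j_sed_r
    return min(raw, available_mass / dt)


def poc_resuspension_flux(
    poc_gi: float,
    rho_sed: float,
    j_sed_r: float,
    available_mass: float = math.inf,
    dt: float = 1.0,
) -> float:
    """Organic C carried off the bed with resuspended sediment.

    The pool concentration (gC per m^3 of bulk sediment) divided by the
    bulk density (rho_sed Mg m^-3, i.e. rho_sed*1e6 g m^-3) gives the
    carbon content per gram of sediment, which multiplies the resuspended
    sediment mass flux.  Capped so no more carbon leaves than the pool
    holds (available_mass gC m^-2 over the step dt).
    """
    return _resuspension_flux(poc_gi, rho_sed, j_sed_r, available_mass, dt)


def ch4_resuspension_flux(
    ch4: float,
    rho_sed: float,
    j_sed_r: float,
    available_mass: float = math.inf,
    dt: float = 1.0,
) -> float:
    """Porewater methane carried off the bed with resuspended sediment."""
    return _resuspension_flux(ch4, rho_sed, j_sed_r, available_mass, dt)


def poc_mineralization_flux(
    poc_gi: float,
    k_gi: float,
    theta_gi: float,
    temp_c: float,
    h2: float,
    pool: int = 1,
) -> float:
    """First-order mineralization of a G pool, zero for the inert G3 pool."""
    if min(poc_gi, k_gi, theta_gi, h2) < 0:
        raise ValueError("inputs must be nonnegative")
    if pool == 3:
        return 0.0
    return k_gi * theta_gi ** (temp_c - 20.0) * poc_gi * h2


def poc_burial_flux(poc_gi: float, w_bury: float) -> float:
    """Loss of pool carbon below the active sediment layers."""
    if poc_gi < 0 or w_bury < 0:
        raise ValueError("inputs must be nonnegative")
    return w_bury * poc_gi


def _limit_sinks(available: float, sinks: list[float], dt: float) -> list[float]:
    """Proportionally rescale sink fluxes so their step mass <= available."""
    total = sum(sinks) * dt
    if total > available and total > 0:
        scale = available / total
        return [s * scale for s in sinks]
    return sinks


def step_anaerobic(
    state: SedimentState,
    dep_fluxes: tuple[float, float, float],
    j_sed_r: float,
    temp_c: float,
    params: DiagenesisParams,
    geom: LayerGeometry = LayerGeometry(),
    dt: float = 1.0,
) -> tuple[tuple[float, float, float], DiagenesisFluxes]:
    """Advance the three anaerobic POC pools one explicit-Euler step.

    Each pool obeys H2*dPOC/dt = J_dep - J_res - J_min - J_bury.  Sinks
    are evaluated at the start-of-step concentration and proportionally
    rescaled if they would overdraw the pool, so mass never goes negative
    and per-pool conservation J_dep*dt = dPOC*H2 + (J_res+J_min+J_bury)*dt
    holds exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if j_sed_r < 0:
        raise ValueError("j_sed_r must be nonnegative")
    ks = (params.k_g1, params.k_g2, 0.0)
    thetas = (params.theta_g1, params.theta_g2, 1.0)
    new_poc: list[float] = []
    res: list[float] = []
    mine: list[float] = []
    bury: list[float] = []
    for i, poc in enumerate(state.poc):
        j_min = poc_mineralization_flux(poc, ks[i], thetas[i], temp_c, geom.h2,
                                        pool=i + 1)
        j_res = poc_resuspension_flux(poc, params.rho_sed, j_sed_r)
        j_bury = poc_burial_flux(poc, params.w_bury)
        available = poc * geom.h2 + dep_fluxes[i] * dt
        j_res, j_min, j_bury = _limit_sinks(available, [j_res, j_min, j_bury], dt)
        poc_next = poc + (dt / geom.h2) * (dep_fluxes[i] - j_res - j_min - j_bury)
        # guard against roundoff-scale negatives only
        new_poc.append(max(poc_next, 0.0))
        res.append(j_res)
        mine.append(j_min)
        bury.append(j_bury)
    flx = DiagenesisFluxes(
        j_poc_dep=tuple(dep_fluxes),
        j_poc_res=tuple(res),
        j_poc_min=tuple(mine),
        j_poc_bury=tuple(bury),
        j_c=mine[0] + mine[1],
    )
    return tuple(new_poc), flx


def ch4_saturation(temp_c: float, params: DiagenesisParams) -> float:
    """Dissolved CH4 saturation (gC m^-3); solubility drops as water warms."""
    return params.ch4_sat_ref * params.theta_sat ** (20.0 - temp_c)


def ch4_transport_capacity(temp_c: float, params: DiagenesisParams) -> float:
    """Maximum dissolved-CH4 flux the sediment can deliver (gC m^-2 day^-1).

    Closure: the dissolved pathway saturates at v_diff * ch4_sat(T);
    diagenesis carbon beyond it leaves as bubbles.
    """
    return params.v_diff * ch4_saturation(temp_c, params)


def methane_partition(
    j_c: float, j_c_den: float, transport_capacity: float
) -> tuple[float, float]:
    """Split diagenesis carbon into dissolved CH4 and bubble CH4.

    Returns (j_ch4_d, j_ch4_gas) with j_ch4_d + j_ch4_gas = j_c - j_c_den
    exactly; bubbles form only for production above the dissolved-transport
    capacity.
    """
    if j_c_den < 0 or j_c_den > j_c:
        raise ValueError("need 0 <= j_c_den <= j_c")
    if transport_capacity < 0:
        raise ValueError("transport capacity must be nonnegative")
    production = j_c - j_c_den
    j_d = min(production, transport_capacity)
    return j_d, production - j_d


def step_aerobic_ch4(
    ch4: float,
    j_ch4_d: float,
    j_sed_r: float,
    temp_c: float,
    params: DiagenesisParams,
    geom: LayerGeometry = LayerGeometry(),
    dt: float = 1.0,
) -> tuple[float, float, float, float]:
    """Advance aerobic-layer methane one backward-Euler step.

    H1*dCH4/dt = J_d - J_w - J_r - J_o with diffusion J_w = v_diff*CH4,
    oxidation J_o = k_ox*theta^(T-20)*CH4*H1 and resuspension J_r as for
    POC.  Because the layer is thin (1 mm) the sink rates are stiff on a
    daily step, so the linear sinks are treated implicitly: the update is
    unconditionally stable, keeps CH4 nonnegative, shares the exact ODE
    fixed point, and conserves mass exactly:
    j_ch4_d*dt = dCH4*H1 + (J_w + J_r + J_o)*dt.

    Returns (new_ch4, j_ch4_w, j_ch4_r, j_ch4_o).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if min(ch4, j_ch4_d, j_sed_r) < 0:
        raise ValueError("inputs must be nonnegative")
    v_ox = params.k_ch4_ox * params.theta_ch4_ox ** (temp_c - 20.0) * geom.h1
    v_res = j_sed_r / (params.rho_sed * 1e6)
    rate = (params.v_diff + v_res + v_ox) / geom.h1  # day^-1
    ch4_next = (ch4 + (dt / geom.h1) * j_ch4_d) / (1.0 + dt * rate)
    j_w = params.v_diff * ch4_next
    j_r = v_res * ch4_next
    j_o = v_ox * ch4_next
    return ch4_next, j_w, j_r, j_o


def step_sediment(
    state: SedimentState,
    j_dep_total: float,
    j_sed_r: float,
    temp_c: float,
    params: DiagenesisParams,
    geom: LayerGeometry = LayerGeometry(),
    dt: float = 1.0,
    j_c_den: float = 0.0,
) -> tuple[SedimentState, DiagenesisFluxes]:
    """One coupled daily step of the whole sediment column.

    Orchestrates deposition partitioning, the anaerobic POC balance,
    methanogenesis partitioning and the aerobic methane balance, returning
    the advanced state and the complete flux set.
    """
    dep = partition_deposition(j_dep_total, params)
    new_poc, flx = step_anaerobic(state, dep, j_sed_r, temp_c, params, geom, dt)
    j_c_den = min(j_c_den, flx.j_c)
    capacity = ch4_transport_capacity(temp_c, params)
    j_ch4_d, j_ch4_gas = methane_partition(flx.j_c, j_c_den, capacity)
    new_ch4, j_w, j_r, j_o = step_aerobic_ch4(
        state.ch4, j_ch4_d, j_sed_r, temp_c, params, geom, dt
    )
    flx = replace(
        flx,
        j_c_den=j_c_den,
        j_ch4_d=j_ch4_d,
        j_ch4_gas=j_ch4_gas,
        j_ch4_w=j_w,
        j_ch4_r=j_r,
        j_ch4_o=j_o,
    )
    new_state = SedimentState(new_poc[0], new_poc[1], new_poc[2], new_ch4)
    return new_state, flx


def inorganic_release(flx: DiagenesisFluxes) -> float:
    """Total inorganic carbon leaving the sediment (gC m^-2 day^-1).

    Sum of dissolved CH4 diffusing to the water column, anaerobic CH4
    bubbles, and CO2 produced by aerobic CH4 oxidation (lost as gas).
    """
    return flx.j_ch4_w + flx.j_ch4_gas + flx.j_ch4_o
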