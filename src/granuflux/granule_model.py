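"""Domain types and flux laws for secretory-granule membrane energetics.

The model describes a single dense-core secretory granule as a spherical
capacitor whose lumen exchanges ions with an infinite cytosolic reservoir
through up to five pathways:

* the vacuolar H⁺-ATPase, pumping ``n_H`` protons into the lumen per ATP
  hydrolysed (unidirectional, stalls when the electrochemical proton
  gradient balances the free energy of ATP hydrolysis);
* a vesicular glutamate transporter (VGLUT), an electrogenic uniporter for
  glutamate⁻ driven by the membrane potential relative to the glutamate
  Nernst potential;
* EAAT2 operating in export mode: one cycle moves 1 glutamate⁻, 3 Na⁺ and
  1 H⁺ out of the lumen and 1 K⁺ in, i.e. two net positive charges leave
  the lumen per exported glutamate;
* an optional Cl⁻ conductance and an optional cation leak (both off by
  default).

Each carrier uses a thermodynamically consistent saturating rate law

    J = Jmax · tanh(ΔG / 2RT)

(clipped to the forward direction for the pump), which is exactly zero at
equilibrium, has the sign of its driving force everywhere, and is bounded
by Jmax.  Membrane potential is not an independent state: it is the
cumulative transported charge divided by the membrane capacitance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import FARADAY, R_GAS

__all__ = [
    "CONC_FLOOR_MM",
    "GranuleGeometry",
    "CytosolState",
    "LumenState",
    "Stoichiometry",
    "TransporterParams",
    "BufferModel",
    "EAAT2Flux",
    "nernst_potential",
    "atpase_driving_force",
    "atpase_flux",
    "vglut_flux",
    "eaat2_cycle_free_energy",
    "eaat2_flux",
    "passive_flux",
    "charge_to_potential",
    "stall_potential_mV",
]

#: Concentration floor (mM) applied inside logarithmic terms and
#: availability factors, so that flux laws stay finite when a luminal
#: species is fully depleted.  Steady states above the floor are unaffected.
CONC_FLOOR_MM = 1e-3


def _floored(c_mM: float) -> float:
    return c_mM if c_mM > CONC_FLOOR_MM else CONC_FLOOR_MM


def _availability(c_mM: float) -> float:
    """Smooth factor in [0, 1) damping efflux of a nearly depleted species.

    Equals c/(c + floor): ~1 well above the floor, → 0 as the pool empties,
    so reversible carriers cannot integrate a luminal concentration below
    zero.  Multiplying a flux by this factor preserves its sign and its
    zero at thermodynamic equilibrium.
    """
    if c_mM <= 0.0:
        return 0.0
    return c_mM / (c_mM + CONC_FLOOR_MM)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GranuleGeometry:
    """Spherical granule geometry; derived area, volume and capacitance."""

    radius_nm: float = 150.0
    specific_capacitance_uF_cm2: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("granule radius must be positive")
        if self.specific_capacitance_uF_cm2 <= 0:
            raise ValueError("specific capacitance must be positive")

    @property
    def membrane_area_um2(self) -> float:
        r_um = self.radius_nm * 1e-3
        return 4.0 * math.pi * r_um**2

    @property
    def membrane_area_m2(self) -> float:
        r_m = self.radius_nm * 1e-9
        return 4.0 * math.pi * r_m**2

    @property
    def volume_m3(self) -> float:
        r_m = self.radius_nm * 1e-9
        return (4.0 / 3.0) * math.pi * r_m**3

    @property
    def volume_L(self) -> float:
        return self.volume_m3 * 1e3

    @property
    def total_capacitance_F(self) -> float:
        # 1 µF/cm² = 1e-2 F/m²
        return self.specific_capacitance_uF_cm2 * 1e-2 * self.membrane_area_m2


@dataclass(frozen=True)
class CytosolState:
    """Cytosolic composition, held fixed (infinite reservoir contract).

    ``dG_ATP_kJ`` is the free energy of ATP hydrolysis under cellular
    conditions (negative, ~−57 kJ/mol).
    """

    pH: float = 7.2
    glu_mM: float = 3.0
    Na_mM: float = 15.0
    K_mM: float = 140.0
    Cl_mM: float = 40.0
    dG_ATP_kJ: float = -57.0
    T_K: float = 310.15

    def __post_init__(self) -> None:
        for name in ("glu_mM", "Na_mM", "K_mM", "Cl_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dG_ATP_kJ >= 0:
            raise ValueError("dG_ATP must be negative (hydrolysis releases energy)")
        if self.T_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LumenState:
    """Time-varying luminal composition and membrane potential.

    ``psi_mV`` is the potential of the lumen relative to the cytosol.
    """

    pH: float = 7.2
    glu_mM: float = 0.01
    Na_mM: float = 70.0
    K_mM: float = 30.0
    Cl_mM: float = 40.0
    psi_mV: float = 0.0

    @property
    def h_free_mM(self) -> float:
        """Free luminal [H⁺] in mM (10^(−pH) mol/L × 1000)."""
        return 1e3 * 10.0 ** (-self.pH)


@dataclass(frozen=True)
class Stoichiometry:
    """Fixed integer coupling ratios of the three active carriers."""

    eaat2_nNa: int = 3
    eaat2_nH: int = 1
    eaat2_nK: int = 1
    eaat2_nGlu: int = 1
    atpase_nH_per_ATP: int = 2
    vglut_zGlu: int = -1

    @property
    def eaat2_net_charge_out(self) -> int:
        """Net positive charge leaving the lumen per exported glutamate.

        3 Na⁺ + 1 H⁺ + 1 glu⁻ out, 1 K⁺ in → 3 + 1 − 1 − 1 = 2.
        """
        return (
            self.eaat2_nNa
            + self.eaat2_nH
            - self.eaat2_nGlu * abs(self.vglut_zGlu)
            - self.eaat2_nK
        )


@dataclass(frozen=True)
class TransporterParams:
    """Maximal rates (mol/s per granule) and conductance-like rates.

    ``cl_g`` and ``leak_g`` are linear rates in mol/s per mV of driving
    force; both default to zero so that the three published scenarios are
    unaffected by the optional pathways.  A disabled carrier contributes
    exactly zero flux.
    """

    pump_Jmax: float = 2e-20
    vglut_Jmax: float = 1.5e-21
    vglut_Km_glu_mM: float = 5.0
    eaat2_Jmax: float = 1e-20
    cl_g: float = 0.0
    leak_g: float = 0.0
    pump_enabled: bool = True
    vglut_enabled: bool = False
    eaat2_enabled: bool = False
    cl_enabled: bool = False
    leak_enabled: bool = False

    def __post_init__(self) -> None:
        for name in ("pump_Jmax", "vglut_Jmax", "eaat2_Jmax", "cl_g", "leak_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.vglut_Km_glu_mM <= 0:
            raise ValueError("vglut_Km_glu_mM must be positive")


@dataclass(frozen=True)
class BufferModel:
    """Luminal proton buffering capacity β, in mM of H⁺ per pH unit."""

    beta_mM_per_pH: float = 40.0

    def __post_init__(self) -> None:
        if self.beta_mM_per_pH <= 0:
            raise ValueError("buffering capacity must be positive")


@dataclass(frozen=True)
class EAAT2Flux:
    """Coupled species bookkeeping for one EAAT2 operating point.

    ``cycle_rate`` is the glutamate export rate v (mol/s, positive =
    export).  The ``*_into_lumen`` fields give the signed flux of each
    coupled species into the lumen and satisfy glu = −v, Na = −3v, H = −v,
    K = +v; ``charge_into_lumen`` is the implied net charge flux −2v (mol
    of elementary charge per second).
    """

    cycle_rate: float
    glu_into_lumen: float
    Na_into_lumen: float
    H_into_lumen: float
    K_into_lumen: float
    charge_into_lumen: float

    @classmethod
    def zero(cls) -> "EAAT2Flux":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# --------------------------------------------------------------------------
# flux laws
# --------------------------------------------------------------------------


def nernst_potential(z: int, c_lumen_mM: float, c_cyto_mM: float, T_K: float = 310.15) -> float:
    """Equilibrium (Nernst) potential in mV, lumen relative to cytosol.

    E = (RT / zF) ln(c_lumen / c_cyto).  Antisymmetric under swapping the
    two compartments and under z → −z.
    """
    if z == 0:
        raise ValueError("charge number z must be non-zero")
    if c_lumen_mM <= 0 or c_cyto_mM <= 0:
        raise ValueError("concentrations must be positive for a Nernst potential")
    return 1e3 * R_GAS * T_K / (z * FARADAY) * math.log(c_lumen_mM / c_cyto_mM)


def atpase_driving_force(
    lumen: LumenState, cyto: CytosolState, stoich: Stoichiometry
) -> float:
    """Net free energy (kJ/mol ATP) available for pumping n_H protons in.

    D = −ΔG_ATP − n_H (F ψ + RT ln([H⁺]_L/[H⁺]_c)).  Positive D drives
    pumping; D = 0 defines the stall point.
    """
    T = cyto.T_K
    psi_V = lumen.psi_mV * 1e-3
    # ln([H+]_L/[H+]_c) = ln(10) (pH_c − pH_L)
    ln_h = math.log(10.0) * (cyto.pH - lumen.pH)
    D_J = -cyto.dG_ATP_kJ * 1e3 - stoich.atpase_nH_per_ATP * (
        FARADAY * psi_V + R_GAS * T * ln_h
    )
    return D_J * 1e-3


def stall_potential_mV(
    cyto: CytosolState, stoich: Stoichiometry, pH_L: float | None = None
) -> float:
    """Membrane potential at which the pump's driving force vanishes.

    At equal pH this is the closed form −ΔG_ATP/(n_H F).
    """
    pH_L = cyto.pH if pH_L is None else pH_L
    ln_h = math.log(10.0) * (cyto.pH - pH_L)
    psi_V = (-cyto.dG_ATP_kJ * 1e3 / stoich.atpase_nH_per_ATP - R_GAS * cyto.T_K * ln_h) / FARADAY
    return psi_V * 1e3


def atpase_flux(
    lumen: LumenState,
    cyto: CytosolState,
    params: TransporterParams,
    stoich: Stoichiometry,
) -> float:
    """H⁺ flux into the lumen through the V-ATPase (mol/s, never negative)."""
    if not params.pump_enabled or params.pump_Jmax == 0.0:
        return 0.0
    D_J = atpase_driving_force(lumen, cyto, stoich) * 1e3
    if D_J <= 0.0:
        return 0.0
    return params.pump_Jmax * math.tanh(D_J / (2.0 * R_GAS * cyto.T_K))


def vglut_flux(
    lumen: LumenState,
    cyto: CytosolState,
    params: TransporterParams,
    stoich: Stoichiometry,
) -> float:
    """Glutamate⁻ flux into the lumen through VGLUT (mol/s, reversible).

    Electrogenic uniport: ΔG per mole = −zF(ψ − E_glu) with z = −1, zero
    exactly when ψ = E_glu; cytosolic substrate saturation
    glu_c/(glu_c + Km).
    """
    if not params.vglut_enabled or params.vglut_Jmax == 0.0:
        return 0.0
    T = cyto.T_K
    E_glu = nernst_potential(
        stoich.vglut_zGlu, _floored(lumen.glu_mM), _floored(cyto.glu_mM), T
    )
    # z = −1: ΔG = −zF(ψ − E) = +F(ψ − E)
    dG_J = -stoich.vglut_zGlu * FARADAY * (lumen.psi_mV - E_glu) * 1e-3
    sat = cyto.glu_mM / (cyto.glu_mM + params.vglut_Km_glu_mM)
    J = params.vglut_Jmax * sat * math.tanh(dG_J / (2.0 * R_GAS * T))
    if J < 0.0:
        J *= _availability(lumen.glu_mM)
    return J


def eaat2_cycle_free_energy(
    lumen: LumenState, cyto: CytosolState, stoich: Stoichiometry
) -> float:
    """ΔG (kJ/mol glutamate) for one EAAT2 export cycle.

    Export moves 3 Na⁺ + 1 H⁺ + 1 glu⁻ lumen→cytosol and 1 K⁺
    cytosol→lumen; the net charge leaving the lumen is +2, so a
    lumen-positive ψ contributes −2Fψ and favours export.  Negative ΔG
    means export proceeds.
    """
    for name, c in (
        ("Na_L", lumen.Na_mM),
        ("K_L", lumen.K_mM),
        ("glu_L", lumen.glu_mM),
        ("Na_c", cyto.Na_mM),
        ("K_c", cyto.K_mM),
        ("glu_c", cyto.glu_mM),
    ):
        if c <= 0:
            raise ValueError(f"coupled-ion concentration {name} must be positive")
    RT = R_GAS * cyto.T_K
    ln10 = math.log(10.0)
    dG_J = RT * (
        stoich.eaat2_nNa * math.log(cyto.Na_mM / lumen.Na_mM)
        + stoich.eaat2_nH * ln10 * (lumen.pH - cyto.pH)  # ln([H+]_c/[H+]_L)
        + stoich.eaat2_nGlu * math.log(cyto.glu_mM / lumen.glu_mM)
        + stoich.eaat2_nK * math.log(lumen.K_mM / cyto.K_mM)
    )
    dG_J -= stoich.eaat2_net_charge_out * FARADAY * lumen.psi_mV * 1e-3
    return dG_J * 1e-3


def eaat2_flux(
    lumen: LumenState,
    cyto: CytosolState,
    params: TransporterParams,
    stoich: Stoichiometry,
) -> EAAT2Flux:
    """Fully reversible EAAT2 cycle rate with coupled-species bookkeeping."""
    if not params.eaat2_enabled or params.eaat2_Jmax == 0.0:
        return EAAT2Flux.zero()
    guarded = LumenState(
        pH=lumen.pH,
        glu_mM=_floored(lumen.glu_mM),
        Na_mM=_floored(lumen.Na_mM),
        K_mM=_floored(lumen.K_mM),
        Cl_mM=lumen.Cl_mM,
        psi_mV=lumen.psi_mV,
    )
    dG_J = eaat2_cycle_free_energy(guarded, cyto, stoich) * 1e3
    v = params.eaat2_Jmax * math.tanh(-dG_J / (2.0 * R_GAS * cyto.T_K))
    if v > 0.0:  # export drains luminal glutamate and Na+
        v *= _availability(lumen.glu_mM) * _availability(lumen.Na_mM)
    elif v < 0.0:  # import drains luminal K+
        v *= _availability(lumen.K_mM)
    return EAAT2Flux(
        cycle_rate=v,
        glu_into_lumen=-stoich.eaat2_nGlu * v,
        Na_into_lumen=-stoich.eaat2_nNa * v,
        H_into_lumen=-stoich.eaat2_nH * v,
        K_into_lumen=+stoich.eaat2_nK * v,
        charge_into_lumen=-stoich.eaat2_net_charge_out * v,
    )


def passive_flux(
    lumen: LumenState,
    cyto: CytosolState,
    params: TransporterParams,
    species: str,
) -> float:
    """Linear-conductance flux of Cl⁻ or a leak cation into the lumen.

    J = g (ψ − E) for the anion (influx when ψ > E_Cl), J = −g (ψ − E) for
    the cation.  Both pathways default to disabled.
    """
    if species == "Cl":
        if not params.cl_enabled or params.cl_g == 0.0:
            return 0.0
        E = nernst_potential(-1, _floored(lumen.Cl_mM), _floored(cyto.Cl_mM), cyto.T_K)
        J = params.cl_g * (lumen.psi_mV - E)
        if J < 0.0:
            J *= _availability(lumen.Cl_mM)
        return J
    if species in ("K", "leak"):
        if not params.leak_enabled or params.leak_g == 0.0:
            return 0.0
        E = nernst_potential(+1, _floored(lumen.K_mM), _floored(cyto.K_mM), cyto.T_K)
        J = -params.leak_g * (lumen.psi_mV - E)
        if J < 0.0:
            J *= _availability(lumen.K_mM)
        return J
    raise ValueError(f"unknown passive species {species!r}")


def charge_to_potential(charge_C: float, geometry: GranuleGeometry) -> float:
    """Membrane potential (mV) from cumulative transported charge: ψ = Q/C."""
    return charge_C / geometry.total_capacitance_F * 1e3
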