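"""Time integration of the granule-membrane flux model.

The integrated state is

    y = [q, pH_L, glu_L, Na_L, K_L, Cl_L, n_pump, n_vglut, n_eaat2, n_cl, n_leak]

where ``q`` is the net transported charge expressed as a concentration of
elementary charge over the granule volume (mol/m³, numerically mM), so the
membrane potential is the derived quantity ψ = q·V·F / C and charge and
potential can never drift apart.  The trailing ``n_*`` states are the
cumulative moles moved by each pathway; they are integrated by the same
solver and make charge/mass bookkeeping checkable at every output point.

Concentrations are in mM (≡ mol/m³), time in s, fluxes in mol/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import FARADAY
from .granule_model import (
    BufferModel,
    CytosolState,
    EAAT2Flux,
    GranuleGeometry,
    LumenState,
    Stoichiometry,
    TransporterParams,
    atpase_flux,
    charge_to_potential,
    eaat2_flux,
    passive_flux,
    vglut_flux,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "Fluxes",
    "SCENARIO_NAMES",
    "make_scenario",
    "compute_fluxes",
    "derivatives",
    "integrate",
    "run_published_scenarios",
    "ordering_checks",
    "ordering_robustness_sweep",
]

SCENARIO_NAMES = ("atpase_only", "atpase_vglut", "atpase_vglut_eaat2")

_ENABLED_FLAGS: Mapping[str, dict] = {
    "atpase_only": dict(pump_enabled=True, vglut_enabled=False, eaat2_enabled=False),
    "atpase_vglut": dict(pump_enabled=True, vglut_enabled=True, eaat2_enabled=False),
    "atpase_vglut_eaat2": dict(pump_enabled=True, vglut_enabled=True, eaat2_enabled=True),
}


@dataclass(frozen=True)
class Fluxes:
    """Instantaneous pathway fluxes (mol/s) at one state."""

    pump_H: float
    vglut_glu: float
    eaat2: EAAT2Flux
    cl_Cl: float
    leak_K: float

    @property
    def species_into_lumen(self) -> dict:
        e = self.eaat2
        return {
            "H": self.pump_H + e.H_into_lumen,
            "glu": self.vglut_glu + e.glu_into_lumen,
            "Na": e.Na_into_lumen,
            "K": e.K_into_lumen + self.leak_K,
            "Cl": self.cl_Cl,
        }

    @property
    def charge_into_lumen(self) -> float:
        """Net charge flux into the lumen, mol elementary charge / s."""
        return (
            self.pump_H
            - self.vglut_glu
            + self.eaat2.charge_into_lumen
            - self.cl_Cl
            + self.leak_K
        )


@dataclass(frozen=True)
class Scenario:
    """One simulation setup: parameters, initial state and time grid.

    The three published scenarios differ only in which carriers are
    enabled; ``make_scenario`` builds them by name.
    """

    name: str
    params: TransporterParams
    cyto: CytosolState = CytosolState()
    stoich: Stoichiometry = Stoichiometry()
    geometry: GranuleGeometry = GranuleGeometry()
    buffer: BufferModel = BufferModel()
    initial_lumen: LumenState = field(default_factory=LumenState)
    t_end: float = 300.0
    n_out: int = 1001
    rtol: float = 1e-8
    atol: float = 1e-10


def make_scenario(
    name: str,
    t_end: float = 300.0,
    n_out: int = 1001,
    overrides: Mapping | None = None,
) -> Scenario:
    """Build a named scenario, optionally overriding any default.

    ``overrides`` may contain sub-dicts under the keys ``params``,
    ``cyto``, ``stoich``, ``geometry``, ``buffer`` and ``initial_lumen``
    (field name → value), plus scalar ``t_end``/``n_out``/``rtol``.
    For ``name="custom"`` the enabled flags come solely from overrides.
    """
    overrides = dict(overrides or {})
    if name in _ENABLED_FLAGS:
        flags = dict(_ENABLED_FLAGS[name])
    elif name == "custom":
        flags = {}
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES} or 'custom'")
    params = TransporterParams(**{**flags, **overrides.pop("params", {})})
    cyto = CytosolState(**overrides.pop("cyto", {}))
    stoich = Stoichiometry(**overrides.pop("stoich", {}))
    geometry = GranuleGeometry(**overrides.pop("geometry", {}))
    buffer = BufferModel(**overrides.pop("buffer", {}))
    initial = LumenState(**overrides.pop("initial_lumen", {}))
    t_end = overrides.pop("t_end", t_end)
    n_out = overrides.pop("n_out", n_out)
    rtol = overrides.pop("rtol", 1e-8)
    if overrides:
        raise ValueError(f"unrecognised override keys: {sorted(overrides)}")
    return Scenario(
        name=name,
        params=params,
        cyto=cyto,
        stoich=stoich,
        geometry=geometry,
        buffer=buffer,
        initial_lumen=initial,
        t_end=t_end,
        n_out=n_out,
        rtol=rtol,
    )


def compute_fluxes(
    lumen: LumenState,
    cyto: CytosolState,
    params: TransporterParams,
    stoich: Stoichiometry,
) -> Fluxes:
    """Evaluate all enabled pathway fluxes at one state."""
    return Fluxes(
        pump_H=atpase_flux(lumen, cyto, params, stoich),
        vglut_glu=vglut_flux(lumen, cyto, params, stoich),
        eaat2=eaat2_flux(lumen, cyto, params, stoich),
        cl_Cl=passive_flux(lumen, cyto, params, "Cl"),
        leak_K=passive_flux(lumen, cyto, params, "K"),
    )


def _lumen_from_state(y: np.ndarray, scn: Scenario) -> LumenState:
    V = scn.geometry.volume_m3
    psi_mV = charge_to_potential(y[0] * V * FARADAY, scn.geometry)
    # integration error can undershoot an exponentially decaying pool by
    # ~atol; the physical concentration is non-negative
    return LumenState(
        pH=y[1],
        glu_mM=max(y[2], 0.0),
        Na_mM=max(y[3], 0.0),
        K_mM=max(y[4], 0.0),
        Cl_mM=max(y[5], 0.0),
        psi_mV=psi_mV,
    )


def derivatives(t: float, y: np.ndarray, scn: Scenario) -> np.ndarray:
    """ODE right-hand side assembling the flux laws.

    Raises ``FloatingPointError`` with a state dump if any flux is not
    finite.
    """
    lumen = _lumen_from_state(y, scn)
    fl = compute_fluxes(lumen, scn.cyto, scn.params, scn.stoich)
    sp = fl.species_into_lumen
    vals = [fl.pump_H, fl.vglut_glu, fl.eaat2.cycle_rate, fl.cl_Cl, fl.leak_K]
    if not all(math.isfinite(v) for v in vals):
        raise FloatingPointError(
            f"non-finite flux at t={t:.6g}: fluxes={vals}, state={y.tolist()}"
        )
    V = scn.geometry.volume_m3
    beta = scn.buffer.beta_mM_per_pH
    dy = np.empty(11)
    dy[0] = fl.charge_into_lumen / V
    dy[1] = -(sp["H"] / V) / beta
    dy[2] = sp["glu"] / V
    dy[3] = sp["Na"] / V
    dy[4] = sp["K"] / V
    dy[5] = sp["Cl"] / V
    dy[6:11] = vals
    return dy


@dataclass
class Trajectory:
    """Simulated time course plus a steady-state summary.

    ``frame`` has one row per output time with the state, the derived
    membrane potential and free [H⁺], the instantaneous pathway fluxes and
    the cumulative per-pathway mole counters.  ``steady_state`` holds
    last-window means (final 10 % of t_end) and a convergence flag.
    """

    scenario: Scenario
    frame: pd.DataFrame
    steady_state: dict

    @property
    def steady_psi_mV(self) -> float:
        return self.steady_state["psi_mV"]


def _initial_state(scn: Scenario) -> np.ndarray:
    lum = scn.initial_lumen
    V = scn.geometry.volume_m3
    q0 = scn.geometry.total_capacitance_F * lum.psi_mV * 1e-3 / (V * FARADAY)
    return np.array(
        [q0, lum.pH, lum.glu_mM, lum.Na_mM, lum.K_mM, lum.Cl_mM, 0, 0, 0, 0, 0],
        dtype=float,
    )


def _frame_from_solution(scn: Scenario, t: np.ndarray, Y: np.ndarray) -> pd.DataFrame:
    rows = []
    for ti, yi in zip(t, Y.T):
        yi = yi.copy()
        yi[2:6] = np.maximum(yi[2:6], 0.0)
        lumen = _lumen_from_state(yi, scn)
        fl = compute_fluxes(lumen, scn.cyto, scn.params, scn.stoich)
        rows.append(
            dict(
                t=ti,
                q_mM=yi[0],
                psi_mV=lumen.psi_mV,
                pH_L=lumen.pH,
                H_mM=lumen.h_free_mM,
                glu_mM=lumen.glu_mM,
                Na_mM=lumen.Na_mM,
                K_mM=lumen.K_mM,
                Cl_mM=lumen.Cl_mM,
                J_pump=fl.pump_H,
                J_vglut=fl.vglut_glu,
                J_eaat2=fl.eaat2.cycle_rate,
                J_cl=fl.cl_Cl,
                J_leak=fl.leak_K,
                cum_pump_mol=yi[6],
                cum_vglut_mol=yi[7],
                cum_eaat2_mol=yi[8],
                cum_cl_mol=yi[9],
                cum_leak_mol=yi[10],
            )
        )
    return pd.DataFrame(rows)


def _steady_summary(scn: Scenario, frame: pd.DataFrame) -> dict:
    t_end = frame["t"].iloc[-1]
    window = frame[frame["t"] >= 0.9 * t_end] if t_end > 0 else frame
    means = window[["psi_mV", "pH_L", "H_mM", "glu_mM", "Na_mM", "K_mM", "Cl_mM"]].mean()
    # convergence: relative derivative of every state < 1e-6 /s at every
    # sampled point of the final window
    state_cols = ["q_mM", "pH_L", "glu_mM", "Na_mM", "K_mM", "Cl_mM"]
    scales = np.array([0.01, 1.0, 1.0, 1.0, 1.0, 1.0])
    converged = True
    for _, row in window.iterrows():
        y = np.concatenate([row[state_cols].to_numpy(dtype=float), np.zeros(5)])
        dy = derivatives(row["t"], y, scn)[:6]
        ref = np.maximum(np.abs(y[:6]), scales)
        if np.any(np.abs(dy) / ref >= 1e-6):
            converged = False
            break
    out = {k: float(v) for k, v in means.items()}
    out["converged"] = bool(converged)
    return out


def integrate(scn: Scenario) -> Trajectory:
    """Adaptive stiff integration of a scenario to ``t_end``.

    Deterministic given its inputs.  ``t_end = 0`` returns the initial
    state unchanged; a failed integration raises ``RuntimeError`` naming
    the last state reached.
    """
    y0 = _initial_state(scn)
    if scn.t_end == 0:
        frame = _frame_from_solution(scn, np.array([0.0]), y0[:, None])
        return Trajectory(scn, frame, _steady_summary(scn, frame))
    t_eval = np.linspace(0.0, scn.t_end, scn.n_out)
    # cumulative mole counters live on the 1e-20 mol scale; give them an
    # absolute tolerance far below their magnitude so the bookkeeping
    # identities hold to relative precision
    atol = np.concatenate([np.full(6, scn.atol), np.full(5, 1e-28)])
    sol = solve_ivp(
        derivatives,
        (0.0, scn.t_end),
        y0,
        args=(scn,),
        method="LSODA",
        t_eval=t_eval,
        rtol=scn.rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration of scenario {scn.name!r} failed ({sol.message}); "
            f"last state reached: {sol.y[:, -1].tolist() if sol.y.size else y0.tolist()}"
        )
    frame = _frame_from_solution(scn, sol.t, sol.y)
    return Trajectory(scn, frame, _steady_summary(scn, frame))


def run_published_scenarios(
    overrides: Mapping | None = None, t_end: float = 300.0
) -> tuple[dict, pd.DataFrame, dict]:
    """Run the three published scenarios and summarise the comparison.

    Returns (trajectories by name, steady-state table, ordering checks).
    """
    trajs = {
        name: integrate(make_scenario(name, t_end=t_end, overrides=dict(overrides or {})))
        for name in SCENARIO_NAMES
    }
    summary = pd.DataFrame(
        {name: tr.steady_state for name, tr in trajs.items()}
    ).T.reset_index(names="scenario")
    checks = ordering_checks({n: tr.steady_state for n, tr in trajs.items()})
    return trajs, summary, checks


def ordering_checks(steady: Mapping[str, Mapping]) -> dict:
    """Evaluate the qualitative orderings the model is expected to show.

    With only the pump, the membrane polarizes maximally and accumulates
    essentially no H⁺ or glutamate; adding VGLUT lowers ψ and accumulates
    both; adding EAAT2 lowers ψ further, raises [H⁺] further and strips
    the accumulated glutamate.
    """
    s1, s2, s3 = (steady[n] for n in SCENARIO_NAMES)
    return {
        "psi_order": bool(s1["psi_mV"] > s2["psi_mV"] > s3["psi_mV"]),
        "H_order": bool(s3["H_mM"] > s2["H_mM"] > s1["H_mM"]),
        "glu_vglut_over_10x_eaat2": bool(s2["glu_mM"] > 10.0 * s3["glu_mM"]),
        "atpase_only_glu_unchanged": bool(abs(s1["glu_mM"] - LumenState().glu_mM) < 0.05),
    }


def ordering_robustness_sweep(
    factors: tuple[float, ...] = (0.5, 1.5),
    rate_names: tuple[str, ...] = ("pump_Jmax", "vglut_Jmax", "eaat2_Jmax"),
    t_end: float = 300.0,
) -> list[dict]:
    """One-at-a-time ±50 % perturbation sweep of the maximal rates.

    Returns one record per (rate, factor) with the ordering checks of the
    three scenarios rerun under the perturbed rate.
    """
    base = TransporterParams()
    records = []
    for rate in rate_names:
        for f in factors:
            overrides = {"params": {rate: getattr(base, rate) * f}}
            _, _, checks = run_published_scenarios(overrides=overrides, t_end=t_end)
            records.append({"rate": rate, "factor": f, **checks})
    return records
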