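"""Anammox-plus-denitrification simulator and dual-isotope trajectory analysis.

Extends the anammox box model with two heterotrophic denitrification fluxes:

* ``NAR``    — nitrate reduction to nitrite, first order in [14NO3-], with
  identical N and O fractionation (default 15 per mil) so that pure
  denitrification moves residual nitrate up the canonical 1:1 line in
  delta-18O vs delta-15N space;
* ``DENNIR`` — nitrite reduction onward to gas, first order in [14NO2-]
  (default 5 per mil for N).

During NAR one O atom is lost to water ("branching"): the light O atom is
preferentially expelled, so the two atoms retained in nitrite are enriched
by the branching factor (default +25 per mil) on top of the kinetic NAR
effect.  Nitrite O can exchange with water O either not
at all, kinetically (rate ``k_exch``), or fully (nitrite delta-18O pinned
at ``d18_water + eps18_eq``).

The diagnostic output is the trajectory of residual nitrate in
delta-15N/delta-18O space: its regression slope and the endpoint anomaly
Delta(15,18) quantify how far concurrent nitrite oxidation (here by
anammox, with its strongly inverse 15N effect) pushes the system off the
denitrification line.  Runs stop once a set fraction (default 25%) of the
initial nitrite pool has been consumed (gross consumption, summed over all
nitrite-consuming fluxes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .anammox_ode import IDX, N_STATE, ModelParams, init_state, observables
from .isotope_core import delta_15_18_anomaly, permil_to_alpha

__all__ = [
    "DenitParams",
    "TrajectoryResult",
    "rhs_denit",
    "default_initial",
    "run_trajectory",
    "slope_and_anomaly",
    "run_sweep",
]

EXCHANGE_MODES = ("none", "kinetic", "full")


@dataclass
class DenitParams(ModelParams):
    """Anammox + denitrification parameters.

    ``eps1518_nar`` applies to both N and O of nitrate reduction;
    ``eps18_dennir`` defaults to ``eps15_dennir`` (no independently
    constrained value exists).  ``k_dennir=None`` balances the
    denitrification chain at t=0 (DENNIR(0) = NAR(0)).
    """

    k_nar: float = 0.05
    k_dennir: float | None = None
    eps1518_nar: float = 15.0
    eps15_dennir: float = 5.0
    eps18_dennir: float | None = None
    eps18_h2obrnar: float = 25.0
    exchange_mode: str = "none"

    def __post_init__(self):
        super().__post_init__()
        if self.exchange_mode not in EXCHANGE_MODES:
            raise ValueError(f"exchange_mode must be one of {EXCHANGE_MODES}")
        if self.k_nar < 0:
            raise ValueError("k_nar must be >= 0")

    def with_initial_rates(self, y0: np.ndarray, amx_to_nar: float) -> "DenitParams":
        """Fix k_amo14n (and k_dennir if unset) from the initial state.

        The anammox/denitrification ratio is defined on initial fluxes:
        ``AMX(0)/NAR(0) = amx_to_nar``.
        """
        if amx_to_nar < 0:
            raise ValueError("amx_to_nar must be >= 0")
        nar0 = self.k_nar * y0[IDX["no3_14"]]
        if nar0 <= 0:
            raise ValueError("initial NAR flux is zero; cannot set AMX/NAR ratio")
        nh4_0 = y0[IDX["nh4_14"]]
        k_amo = amx_to_nar * nar0 / nh4_0 if nh4_0 > 0 else 0.0
        if amx_to_nar > 0 and nh4_0 <= 0:
            raise ValueError("amx_to_nar > 0 requires ammonium in the initial state")
        k_dennir = self.k_dennir
        if k_dennir is None:
            no2_0 = y0[IDX["no2_14"]]
            if no2_0 <= 0:
                raise ValueError("initial nitrite pool required to set k_dennir")
            k_dennir = nar0 / no2_0
        return replace(self, k_amo14n=k_amo, k_dennir=k_dennir)


def rhs_denit(t: float, y: np.ndarray, params: DenitParams) -> np.ndarray:
    """Time derivative of the anammox + denitrification state vector."""
    if params.k_dennir is None:
        raise ValueError("k_dennir unset; call with_initial_rates() first")
    d = np.zeros(N_STATE)

    nh4_14, nh4_15 = y[IDX["nh4_14"]], y[IDX["nh4_15"]]
    no2_14, no2_15 = y[IDX["no2_14"]], y[IDX["no2_15"]]
    no3_14, no3_15 = y[IDX["no3_14"]], y[IDX["no3_15"]]
    no2_o16, no2_o18 = y[IDX["no2_o16"]], y[IDX["no2_o18"]]
    no3_o16, no3_o18 = y[IDX["no3_o16"]], y[IDX["no3_o18"]]

    amx = params.k_amo14n * nh4_14
    amxnir = amx
    nxr = amxnir * params.x / (1.0 - params.x)
    nar = params.k_nar * no3_14
    dennir = params.k_dennir * no2_14

    r_nh4 = nh4_15 / nh4_14 if nh4_14 > 0 else 0.0
    rn_no2 = no2_15 / no2_14 if no2_14 > 0 else 0.0
    rn_no3 = no3_15 / no3_14 if no3_14 > 0 else 0.0
    ro_no2 = no2_o18 / no2_o16 if no2_o16 > 0 else 0.0
    ro_no3 = no3_o18 / no3_o16 if no3_o16 > 0 else 0.0

    a15_amx = permil_to_alpha(params.eps15_amx)
    a15_nir = permil_to_alpha(params.eps15_amxnir)
    a15_nxr = permil_to_alpha(params.eps15_nxr)
    a18_nir = permil_to_alpha(params.eps18_amxnir)
    a18_nxr = permil_to_alpha(params.eps18_nxr)
    a18_h2onxr = permil_to_alpha(params.eps18_h2onxr)
    a_nar = permil_to_alpha(params.eps1518_nar)
    a15_den = permil_to_alpha(params.eps15_dennir)
    eps18_den = (
        params.eps15_dennir if params.eps18_dennir is None else params.eps18_dennir
    )
    a18_den = permil_to_alpha(eps18_den)
    a_br = permil_to_alpha(params.eps18_h2obrnar)

    # ammonium
    d[IDX["nh4_14"]] = -amx
    d[IDX["nh4_15"]] = -r_nh4 * amx / a15_amx

    # nitrite N
    no2_15_out = (
        rn_no2 * nxr / a15_nxr + rn_no2 * dennir / a15_den + rn_no2 * amxnir / a15_nir
    )
    d[IDX["no2_14"]] = -nxr + nar - dennir - amxnir
    d[IDX["no2_15"]] = -no2_15_out + rn_no3 * nar / a_nar

    # nitrite O
    d[IDX["no2_o16"]] = -2 * nxr + 2 * nar - 2 * dennir - 2 * amxnir
    if params.exchange_mode == "full":
        # delta-18O of nitrite pinned at equilibrium with water: the heavy
        # pool shadows the light pool at the fixed equilibrium ratio
        d[IDX["no2_o18"]] = d[IDX["no2_o16"]] * params.r_no2_eq
    else:
        # branching: the O atoms retained in nitrite are enriched by
        # eps18_h2obrnar relative to the NAR-fractionated nitrate O flux
        # (the light O atom is preferentially lost to water)
        d[IDX["no2_o18"]] = (
            -ro_no2 * 2 * nxr / a18_nxr
            + ro_no3 * 2 * nar * a_br / a_nar
            - ro_no2 * 2 * dennir / a18_den
            - ro_no2 * 2 * amxnir / a18_nir
        )
        if params.exchange_mode == "kinetic":
            exch = params.k_exch * (no2_o16 * params.r_no2_eq - no2_o18)
            d[IDX["no2_o16"]] -= exch
            d[IDX["no2_o18"]] += exch

    # nitrate
    d[IDX["no3_14"]] = nxr - nar
    d[IDX["no3_15"]] = rn_no2 * nxr / a15_nxr - rn_no3 * nar / a_nar
    d[IDX["no3_o16"]] = 3 * nxr - 3 * nar
    d[IDX["no3_o18"]] = (
        ro_no2 * 2 * nxr / a18_nxr
        + params.r_water_o * nxr / a18_h2onxr
        - ro_no3 * 3 * nar / a_nar
    )

    # gas sink (anammox N2 + denitrification products), closure only
    d[IDX["n2_14"]] = amx + amxnir + dennir
    d[IDX["n2_15"]] = (
        r_nh4 * amx / a15_amx + rn_no2 * amxnir / a15_nir + rn_no2 * dennir / a15_den
    )

    d[IDX["no2_cons"]] = (nxr + amxnir + dennir) + no2_15_out
    return d


@dataclass
class TrajectoryResult:
    """One simulated run: nitrate dual-isotope trajectory plus summaries."""

    df: pd.DataFrame
    slope: float
    delta_15_18_final: float
    t_end: float
    frac_no2_consumed: float
    amx_to_nar: float = np.nan
    exchange_mode: str = "none"
    d18_water: float = np.nan
    meta: dict = field(default_factory=dict)


def default_initial(params: DenitParams) -> np.ndarray:
    """Generic environmental initial state for the simulation exercise.

    10 mM each of ammonium, nitrite and nitrate; nitrate at 5 per mil in
    both delta-15N and delta-18O (so a pure-denitrification run follows the
    1:1 line exactly); nitrite delta-18O starts at isotopic equilibrium with
    the ambient water.
    """
    return init_state(
        {"nh4": 10.0, "no2": 10.0, "no3": 10.0},
        {
            "d15_nh4": 0.0,
            "d15_no2": 0.0,
            "d18_no2": params.d18_water + params.eps18_eq,
            "d15_no3": 5.0,
            "d18_no3": 5.0,
        },
    )


def slope_and_anomaly(df: pd.DataFrame) -> tuple[float, float]:
    """OLS slope of delta-18O on delta-15N of nitrate, and final Delta(15,18).

    Requires >= 3 trajectory points spanning more than 0.1 per mil in
    delta-15N (otherwise the slope is undefined).
    """
    d15 = np.asarray(df["d15_no3"], dtype=float)
    d18 = np.asarray(df["d18_no3"], dtype=float)
    ok = np.isfinite(d15) & np.isfinite(d18)
    d15, d18 = d15[ok], d18[ok]
    if len(d15) < 3:
        raise ValueError("need at least 3 finite trajectory points")
    if np.ptp(d15) <= 0.1:
        raise ValueError("delta-15N range <= 0.1 permil: slope undefined")
    slope = np.polyfit(d15, d18, 1)[0]
    anomaly = delta_15_18_anomaly(d15[-1], d15[0], d18[-1], d18[0], 1.0)
    return float(slope), float(anomaly)


def run_trajectory(
    params: DenitParams,
    amx_to_nar: float,
    initial: np.ndarray | None = None,
    stop_frac: float = 0.25,
    t_max: float = 1000.0,
    n_out: int = 60,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> TrajectoryResult:
    """Integrate until ``stop_frac`` of the initial nitrite pool is consumed.

    Consumption is gross (summed over NXR, AMXNIR and DENNIR), so the stop
    criterion is meaningful even when NAR replenishes nitrite faster than
    it is consumed.  The integration runs slightly past the event; the
    returned trajectory is sampled on a uniform grid ending exactly at the
    event time.
    """
    y0 = default_initial(params) if initial is None else np.asarray(initial, float)
    y0 = y0.copy()
    p = params.with_initial_rates(y0, amx_to_nar)
    if p.exchange_mode == "full":
        y0[IDX["no2_o18"]] = y0[IDX["no2_o16"]] * p.r_no2_eq

    no2_tot0 = y0[IDX["no2_14"]] + y0[IDX["no2_15"]]
    target = stop_frac * no2_tot0

    def hit(t, y, _p):
        return y[IDX["no2_cons"]] - target

    hit.terminal = True
    hit.direction = 1

    sol = solve_ivp(
        rhs_denit,
        (0.0, t_max),
        y0,
        args=(p,),
        events=hit,
        dense_output=True,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    if not sol.t_events[0].size:
        amx0 = p.k_amo14n * y0[IDX["nh4_14"]]
        raise RuntimeError(
            f"nitrite consumption did not reach {stop_frac:.0%} within "
            f"t_max={t_max} h (AMX(0)={amx0:.3g}, NAR(0)="
            f"{p.k_nar * y0[IDX['no3_14']]:.3g} mM/h); increase t_max or rates"
        )
    t_end = float(sol.t_events[0][0])
    t_grid = np.linspace(0.0, t_end, n_out)
    ys = sol.sol(t_grid).T
    df = observables(t_grid, ys)
    df["frac_no2_consumed"] = df["no2_consumed"] / no2_tot0
    slope, anomaly = slope_and_anomaly(df)
    return TrajectoryResult(
        df=df,
        slope=slope,
        delta_15_18_final=anomaly,
        t_end=t_end,
        frac_no2_consumed=float(df["frac_no2_consumed"].iloc[-1]),
        amx_to_nar=amx_to_nar,
        exchange_mode=p.exchange_mode,
        d18_water=p.d18_water,
    )


def run_sweep(
    amx_to_nar_values,
    exchange_modes=("none",),
    d18_water_values=(-8.0,),
    base_params: DenitParams | None = None,
    **run_kwargs,
) -> list[TrajectoryResult]:
    """Grid of trajectory runs over AMX/NAR ratio, exchange mode and water.

    Returns one :class:`TrajectoryResult` per grid cell, in itertools
    product order (ratio outermost).
    """
    base = base_params if base_params is not None else DenitParams()
    results = []
    for ratio, mode, d18w in itertools.product(
        amx_to_nar_values, exchange_modes, d18_water_values
    ):
        p = replace(base, exchange_mode=mode, d18_water=d18w)
        results.append(run_trajectory(p, ratio, **run_kwargs))
    return results


def sweep_table(results: list[TrajectoryResult]) -> pd.DataFrame:
    """Long-format summary of a sweep (one row per run)."""
    return pd.DataFrame(
        {
            "amx_to_nar": [r.amx_to_nar for r in results],
            "exchange_mode": [r.exchange_mode for r in results],
            "d18_water": [r.d18_water for r in results],
            "slope": [r.slope for r in results],
            "delta_15_18_final": [r.delta_15_18_final for r in results],
            "t_end_h": [r.t_end for r in results],
            "frac_no2_consumed": [r.frac_no2_consumed for r in results],
        }
    )
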