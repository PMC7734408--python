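"""Closed-system isotopologue box model of the anammox reaction network.

The model tracks light and heavy atom pools (mM of atoms) for ammonium,
nitrite, nitrate and the N2 produced, for both nitrogen (14N/15N) and the
oxygen atoms bound in nitrite and nitrate (16O/18O).  Three fluxes describe
anammox:

* ``AMX``    — ammonium oxidation to N2, first order in [14NH4+],
* ``AMXNIR`` — nitrite reduction to N2, stoichiometrically coupled 1:1
  to AMX,
* ``NXR``    — nitrite oxidation to nitrate, ``AMXNIR * x/(1-x)`` where the
  stoichiometric ratio ``x`` is nitrate produced per nitrite consumed
  (canonically 0.3/1.3 ~= 0.23, measured values 0.13-0.48).

Each heavy-isotope flux is the light flux times the substrate heavy/light
ratio divided by ``alpha = 1 + eps/1000``; an inverse effect (eps < 0,
alpha < 1) enhances the heavy flux.  Nitrate formed by NXR inherits two O
atoms from nitrite (fractionated by ``eps18_nxr``) and one from water
(fractionated by ``eps18_h2onxr``).  Nitrite O atoms can additionally
exchange with water O at first-order rate ``k_exch``, relaxing nitrite
delta-18O toward the equilibrium value ``d18_water + eps18_eq``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .isotope_core import R15_AIR, R18_VSMOW, delta_to_ratio, permil_to_alpha

__all__ = ["ModelParams", "SystemState", "fluxes", "rhs", "init_state", "simulate"]

# State-vector layout (mM of atoms).  no2_cons is the cumulative nitrite-N
# consumed by all pathways, used for stop criteria in downstream simulators.
IDX = {
    "nh4_14": 0,
    "nh4_15": 1,
    "no2_14": 2,
    "no2_15": 3,
    "no2_o16": 4,
    "no2_o18": 5,
    "no3_14": 6,
    "no3_15": 7,
    "no3_o16": 8,
    "no3_o18": 9,
    "n2_14": 10,
    "n2_15": 11,
    "no2_cons": 12,
}
N_STATE = 13


@dataclass
class ModelParams:
    """Rate constants and fractionation factors of the anammox model.

    Rates are per hour, eps values per mil.  Defaults for the assigned
    constants: ``eps18_eq = 13`` (nitrite-water O equilibrium enrichment at
    the incubation temperature and pH) and ``eps18_h2onxr = 10.0`` (water-O
    incorporation during nitrite oxidation).
    """

    k_amo14n: float = 0.05
    x: float = 0.3 / 1.3
    k_exch: float = 0.0
    eps15_amx: float = 0.0
    eps15_amxnir: float = 0.0
    eps15_nxr: float = 0.0
    eps18_amxnir: float = 0.0
    eps18_nxr: float = 0.0
    eps18_eq: float = 13.0
    eps18_h2onxr: float = 10.0
    d18_water: float = -8.0

    def __post_init__(self):
        if self.k_amo14n < 0 or self.k_exch < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0.0 <= self.x < 1.0:
            raise ValueError("stoichiometric ratio x must lie in [0, 1)")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    @property
    def r_water_o(self) -> float:
        """Absolute 18O/16O ratio of the water pool."""
        return delta_to_ratio(self.d18_water, R18_VSMOW)

    @property
    def r_no2_eq(self) -> float:
        """Nitrite 18O/16O ratio at isotopic equilibrium with water.

        The equilibrium point is additive in delta space
        (``d18O_NO2_eq = d18_water + eps18_eq``), matching the standard
        full-exchange limit.
        """
        return delta_to_ratio(self.d18_water + self.eps18_eq, R18_VSMOW)


class SystemState:
    """Thin view over the 13-element state vector with named accessors."""

    __slots__ = ("y",)

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATE,):
            raise ValueError(f"state vector must have length {N_STATE}")
        self.y = y

    def __getattr__(self, name):
        try:
            return self.y[IDX[name]]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def conc_nh4(self):
        return self.nh4_14 + self.nh4_15

    @property
    def conc_no2(self):
        return self.no2_14 + self.no2_15

    @property
    def conc_no3(self):
        return self.no3_14 + self.no3_15

    @property
    def conc_n2(self):
        return self.n2_14 + self.n2_15


def fluxes(y: np.ndarray, params: ModelParams) -> tuple[float, float, float]:
    """Light-isotope fluxes (AMX, AMXNIR, NXR) at state ``y`` (mM/h)."""
    amx = params.k_amo14n * y[IDX["nh4_14"]]
    amxnir = amx
    nxr = amxnir * params.x / (1.0 - params.x)
    return amx, amxnir, nxr


def _safe_ratio(heavy: float, light: float) -> float:
    return heavy / light if light > 0 else 0.0


def rhs(t: float, y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the anammox-only state vector."""
    d = np.zeros(N_STATE)
    amx, amxnir, nxr = fluxes(y, params)

    r_nh4 = _safe_ratio(y[IDX["nh4_15"]], y[IDX["nh4_14"]])
    r_no2_n = _safe_ratio(y[IDX["no2_15"]], y[IDX["no2_14"]])
    r_no2_o = _safe_ratio(y[IDX["no2_o18"]], y[IDX["no2_o16"]])

    a15_amx = permil_to_alpha(params.eps15_amx)
    a15_nir = permil_to_alpha(params.eps15_amxnir)
    a15_nxr = permil_to_alpha(params.eps15_nxr)
    a18_nir = permil_to_alpha(params.eps18_amxnir)
    a18_nxr = permil_to_alpha(params.eps18_nxr)
    a18_h2onxr = permil_to_alpha(params.eps18_h2onxr)

    # ammonium
    d[IDX["nh4_14"]] = -amx
    d[IDX["nh4_15"]] = -r_nh4 * amx / a15_amx

    # nitrite nitrogen
    d[IDX["no2_14"]] = -nxr - amxnir
    d[IDX["no2_15"]] = -r_no2_n * nxr / a15_nxr - r_no2_n * amxnir / a15_nir

    # nitrite oxygen (2 atoms per ion); kinetic exchange relaxes the O ratio
    # toward equilibrium with water while conserving nitrite O atoms
    exch = params.k_exch * (y[IDX["no2_o16"]] * params.r_no2_eq - y[IDX["no2_o18"]])
    d[IDX["no2_o16"]] = -2.0 * nxr - 2.0 * amxnir - exch
    d[IDX["no2_o18"]] = (
        -r_no2_o * 2.0 * nxr / a18_nxr - r_no2_o * 2.0 * amxnir / a18_nir + exch
    )

    # nitrate: 2 O atoms inherited from nitrite + 1 from water per NXR event
    d[IDX["no3_14"]] = nxr
    d[IDX["no3_15"]] = r_no2_n * nxr / a15_nxr
    d[IDX["no3_o16"]] = 3.0 * nxr
    d[IDX["no3_o18"]] = (
        r_no2_o * 2.0 * nxr / a18_nxr + params.r_water_o * nxr / a18_h2onxr
    )

    # N2 closure (diagnostic; no back-reaction)
    d[IDX["n2_14"]] = amx + amxnir
    d[IDX["n2_15"]] = r_nh4 * amx / a15_amx + r_no2_n * amxnir / a15_nir

    d[IDX["no2_cons"]] = (nxr + amxnir) + (
        r_no2_n * nxr / a15_nxr + r_no2_n * amxnir / a15_nir
    )
    return d


def init_state(
    conc: dict[str, float], deltas: dict[str, float] | None = None
) -> np.ndarray:
    """Build a state vector from species concentrations (mM) and deltas.

    ``conc`` keys: ``nh4``, ``no2``, ``no3`` (and optionally ``n2``);
    ``deltas`` keys: ``d15_nh4``, ``d15_no2``, ``d18_no2``, ``d15_no3``,
    ``d18_no3`` (``d15_n2``), defaulting to 0 per mil.  The heavy/light
    split uses the exact atom-fraction formula ``heavy = total * R/(1+R)``
    per atom; nitrite carries 2 O atoms per ion, nitrate 3.
    """
    deltas = dict(deltas or {})
    y = np.zeros(N_STATE)

    def split(total, delta, ref):
        r = delta_to_ratio(0.0 if delta is None else delta, ref)
        heavy = total * r / (1.0 + r)
        return total - heavy, heavy

    for sp, n_oxy in (("nh4", 0), ("no2", 2), ("no3", 3), ("n2", 0)):
        c = conc.get(sp, 0.0)
        if c < 0:
            raise ValueError(f"negative concentration for {sp}")
        if c == 0:
            for key in (f"d15_{sp}", f"d18_{sp}"):
                if deltas.get(key) is not None:
                    import warnings

                    warnings.warn(
                        f"{key} supplied for zero-concentration species; ignored"
                    )
            continue
        light, heavy = split(c, deltas.get(f"d15_{sp}"), R15_AIR)
        y[IDX[f"{sp}_14"]] = light
        y[IDX[f"{sp}_15"]] = heavy
        if n_oxy:
            o_light, o_heavy = split(n_oxy * c, deltas.get(f"d18_{sp}"), R18_VSMOW)
            y[IDX[f"{sp}_o16"]] = o_light
            y[IDX[f"{sp}_o18"]] = o_heavy
    return y


def observables(t: np.ndarray, ys: np.ndarray) -> pd.DataFrame:
    """Concentrations and deltas per species from a trajectory array.

    ``ys`` has shape (n_times, N_STATE).  Delta columns are NaN where the
    species is absent.
    """
    ys = np.atleast_2d(ys)
    df = pd.DataFrame({"time_h": np.asarray(t, dtype=float)})

    def delta_col(heavy, light, ref):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(light > 0, (heavy / light / ref - 1.0) * 1000.0, np.nan)

    for sp in ("nh4", "no2", "no3", "n2"):
        light = ys[:, IDX[f"{sp}_14"]]
        heavy = ys[:, IDX[f"{sp}_15"]]
        df[f"conc_{sp}"] = light + heavy
        df[f"d15_{sp}"] = delta_col(heavy, light, R15_AIR)
    for sp in ("no2", "no3"):
        df[f"d18_{sp}"] = delta_col(
            ys[:, IDX[f"{sp}_o18"]], ys[:, IDX[f"{sp}_o16"]], R18_VSMOW
        )
    df["no2_consumed"] = ys[:, IDX["no2_cons"]]
    return df


def _rk4(fun, t_grid, y0):
    """Classic fixed-step 4th-order Runge-Kutta on the given time grid."""
    y = np.empty((len(t_grid), len(y0)))
    y[0] = y0
    for i in range(len(t_grid) - 1):
        h = t_grid[i + 1] - t_grid[i]
        t, yi = t_grid[i], y[i]
        k1 = fun(t, yi)
        k2 = fun(t + h / 2, yi + h / 2 * k1)
        k3 = fun(t + h / 2, yi + h / 2 * k2)
        k4 = fun(t + h, yi + h * k3)
        y[i + 1] = yi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def simulate(
    initial: np.ndarray | dict,
    params: ModelParams,
    t_grid,
    deltas: dict | None = None,
    method: str = "adaptive",
    rtol: float = 1e-9,
    atol: float = 1e-12,
    rhs_fun=None,
    n_substeps: int = 20,
) -> pd.DataFrame:
    """Integrate the model and return observables on ``t_grid``.

    Parameters
    ----------
    initial : array or dict
        Either a full state vector or a concentration dict passed to
        :func:`init_state` (with ``deltas``).
    method : {"adaptive", "rk4"}
        Adaptive embedded Runge-Kutta (default) or classic fixed-step RK4
        with ``n_substeps`` internal steps per output interval.
    rhs_fun : callable, optional
        Alternative right-hand side with the same signature as :func:`rhs`
        (used by the anammox-denitrification extension).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if isinstance(initial, dict):
        y0 = init_state(initial, deltas)
    else:
        y0 = np.asarray(initial, dtype=float).copy()
    fun = rhs_fun or rhs

    if method == "rk4":
        fine = np.concatenate(
            [
                np.linspace(t_grid[i], t_grid[i + 1], n_substeps + 1)[:-1]
                for i in range(len(t_grid) - 1)
            ]
            + [t_grid[-1:]]
        )
        ys_fine = _rk4(lambda t, y: fun(t, y, params), fine, y0)
        idx = np.searchsorted(fine, t_grid)
        ys = ys_fine[idx]
    elif method == "adaptive":
        sol = solve_ivp(
            fun,
            (t_grid[0], t_grid[-1]),
            y0,
            t_eval=t_grid,
            args=(params,),
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        ys = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.any(ys[:, : IDX["n2_14"]] < -1e-9):
        raise RuntimeError("integration produced a negative pool; reduce step size")
    return observables(t_grid, ys)
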