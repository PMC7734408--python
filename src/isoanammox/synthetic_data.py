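"""Synthetic incubation experiments and steady-state reactor trains.

The incubation generator emulates anaerobic batch incubations of an
anammox-dominated biomass: first-order ammonium consumption with the
coupled anammox stoichiometry, isotope fractionation at specified epsilon
values, and independent Gaussian analytical noise at the stated precisions
(0.2 per mil for delta-15N of nitrite/nitrate, 0.5 per mil for delta-18O
and for delta-15N of ammonium).  One scenario uses 18O-labelled water
(delta-18O = +229 per mil) to make the nitrite-water O exchange rate
identifiable from nitrite delta-18O alone.

The reactor-train generator inverts the open-system steady-state algebra:
given target apparent isotope effects it constructs an NT/ANX reactor pair
from which the open-system calculators recover those targets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anammox_ode import ModelParams, init_state, simulate
from .fitting import DEFAULT_SD, ObservationSeries
from .open_system import ReactorState

__all__ = [
    "ScenarioSpec",
    "experiment_a_like",
    "experiment_c_like",
    "generate_incubation",
    "incubation_frame",
    "generate_plant_train",
]

CONC_KINDS = ("conc_nh4", "conc_no2", "conc_no3")
DELTA_KINDS = ("d15_nh4", "d15_no2", "d15_no3", "d18_no2", "d18_no3")


@dataclass
class ScenarioSpec:
    """Design of one synthetic batch incubation.

    ``params`` is the generating truth; noise applies to the sampled
    observations only.  A fixed seed gives byte-identical output.
    """

    name: str
    initial_conc: dict
    initial_deltas: dict
    params: ModelParams
    schedule: np.ndarray
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_SD))
    seed: int = 0

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("sampling schedule must be strictly increasing")


def experiment_a_like(seed: int = 0, noise: bool = True) -> ScenarioSpec:
    """Batch incubation in unlabelled water (delta-18O = -8 per mil).

    Generating truth uses the laboratory closed-system estimates for the
    five fractionation factors (32.5, 13.7, -77.8, 3.1, -20.6 per mil),
    a stoichiometric ratio x = 0.16, and a rate constant consuming ~70% of
    the ammonium over a 24 h, 10-point schedule.  Oxygen-atom exchange is
    negligible in this regime.
    """
    params = ModelParams(
        k_amo14n=0.05,
        x=0.16,
        k_exch=0.0,
        eps15_amx=32.5,
        eps15_amxnir=13.7,
        eps15_nxr=-77.8,
        eps18_amxnir=3.1,
        eps18_nxr=-20.6,
        d18_water=-8.0,
    )
    return ScenarioSpec(
        name="expA",
        initial_conc={"nh4": 3.0, "no2": 4.0, "no3": 0.05},
        initial_deltas={
            "d15_nh4": 0.0,
            "d15_no2": 0.0,
            "d18_no2": 3.0,
            "d15_no3": 5.0,
            "d18_no3": 3.0,
        },
        params=params,
        schedule=np.linspace(0.0, 24.0, 10),
        noise_sd=dict(DEFAULT_SD) if noise else {},
        seed=seed,
    )


def experiment_c_like(seed: int = 0, noise: bool = True) -> ScenarioSpec:
    """Batch incubation in 18O-labelled water (delta-18O = +229 per mil).

    The labelled water drives a large, rapid rise of nitrite delta-18O
    through O-atom exchange (truth k_exch = 0.02 per hour), the design that
    makes k_exch directly identifiable.
    """
    spec = experiment_a_like(seed=seed, noise=noise)
    return ScenarioSpec(
        name="expC",
        initial_conc=dict(spec.initial_conc),
        initial_deltas=dict(spec.initial_deltas),
        params=spec.params.replace(d18_water=229.0, k_exch=0.02),
        schedule=spec.schedule.copy(),
        noise_sd=dict(spec.noise_sd),
        seed=seed,
    )


def generate_incubation(spec: ScenarioSpec) -> dict[str, ObservationSeries]:
    """Simulate the scenario and sample noisy observations.

    Returns one :class:`ObservationSeries` per concentration and delta
    column.  Noise is independent Gaussian per observation at the per-kind
    sd from ``spec.noise_sd`` (kinds absent from the dict are noiseless).
    """
    y0 = init_state(spec.initial_conc, spec.initial_deltas)
    df = simulate(y0, spec.params, spec.schedule)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for kind in CONC_KINDS + DELTA_KINDS:
        truth = df[kind].to_numpy()
        sd = spec.noise_sd.get(kind, 0.0)
        values = truth + rng.normal(0.0, sd, size=truth.shape) if sd else truth.copy()
        out[kind] = ObservationSeries(
            kind=kind, times=spec.schedule.copy(), values=values,
            sd=sd if sd else None,
        )
    return out


def incubation_frame(series: dict[str, ObservationSeries]) -> pd.DataFrame:
    """Wide-format data frame (time_h + one column per series)."""
    first = next(iter(series.values()))
    df = pd.DataFrame({"time_h": first.times})
    for kind, s in series.items():
        df[kind] = s.values
    return df


def generate_plant_train(
    d15_amx: float,
    d15_nxr: float,
    d15_amxnir: float,
    e18_combined: float,
    conc: dict | None = None,
    d18_water: float = -8.0,
    d15_nh4_nt: float = 19.2,
    d15_no2_anx: float = -21.6,
    d18_no2_anx: float = 3.3,
) -> tuple[ReactorState, ReactorState]:
    """Construct an NT/ANX reactor pair realising the target apparent effects.

    The steady-state open-system algebra is inverted: the baseline deltas
    (NT ammonium, ANX nitrite) are free anchors, everything else follows
    from the targets.  ``d15_amxnir`` is taken in the substrate-minus-
    product convention (positive for normal fractionation).

    Default concentrations mirror a healthy anammox train (f_NH4 ~ 0.9,
    nitrite nearly exhausted, modest nitrate production).
    """
    c = {
        "nh4_nt": 18.7, "nh4_anx": 1.9,
        "no2_nt": 21.2, "no2_anx": 0.4,
        "no3_nt": 0.0, "no3_anx": 2.5,
    }
    c.update(conc or {})
    if c["nh4_nt"] <= c["nh4_anx"]:
        raise ValueError("need ammonium consumption: nh4_nt > nh4_anx")
    dno2 = c["no2_nt"] - c["no2_anx"]
    if dno2 <= 0:
        raise ValueError("need nitrite consumption: no2_nt > no2_anx")
    a = c["no2_anx"] / dno2
    b = (c["no3_anx"] - c["no3_nt"]) / dno2
    if abs(a + b - 1.0) < 1e-12:
        raise ValueError("infeasible targets: a + b = 1 (singular steady state)")

    f = (c["nh4_nt"] - c["nh4_anx"]) / c["nh4_nt"]
    d15_nh4_anx = d15_nh4_nt + d15_amx * f
    d15_no3_anx = d15_no2_anx - d15_nxr
    d15_n2_anx = d15_no2_anx - d15_amxnir
    d15_no2_nt = (
        (1.0 - a - b) * d15_n2_anx + a * d15_no2_anx + b * d15_no3_anx
    )
    d18_no3_anx = (2.0 / 3.0) * d18_no2_anx + (1.0 / 3.0) * d18_water - e18_combined

    nt = ReactorState(
        name="NT", nh4=c["nh4_nt"], no2=c["no2_nt"], no3=c["no3_nt"],
        d15_nh4=d15_nh4_nt, d15_no2=d15_no2_nt,
    )
    anx = ReactorState(
        name="ANX", nh4=c["nh4_anx"], no2=c["no2_anx"], no3=c["no3_anx"],
        d15_nh4=d15_nh4_anx, d15_no2=d15_no2_anx, d18_no2=d18_no2_anx,
        d15_no3=d15_no3_anx, d18_no3=d18_no3_anx, d15_n2=d15_n2_anx,
    )
    return nt, anx
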