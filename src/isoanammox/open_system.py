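"""Steady-state open-system apparent isotope effects for an anammox reactor train.

A full-scale anammox treatment train feeds partially nitritated wastewater
(the NT reactor: ammonium plus nitrite) into an anammox reactor (ANX) where
ammonium is oxidised by nitrite to N2 with a minor co-production of nitrate.
At steady state the influent/effluent differences in concentration and
isotopic composition yield *apparent* isotope effects for the three
branches of the anammox reaction:

* ``15Delta_AMX``   — ammonium oxidation to N2,
* ``15Delta_AMXNIR`` — nitrite reduction to N2,
* ``15Delta_NXR``   — nitrite oxidation to nitrate (inverse: the product
  nitrate is isotopically heavier than the substrate nitrite),
* ``18E_combined``  — the combined O isotope effect of nitrite oxidation and
  water-O incorporation, from the 2:1 O-atom inheritance of nitrate.

These are the open-system analogues of closed-system Rayleigh epsilons and
are not numerically interchangeable with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "ReactorState",
    "ApparentEffects",
    "fraction_reacted",
    "apparent_amx_15",
    "apparent_nxr_15",
    "mixing_coefficients",
    "apparent_amxnir_15",
    "apparent_amxnir_15_raw",
    "d15_n2_back_calculated",
    "apparent_combined_18",
    "stoichiometric_ratios",
    "plant_effects",
    "packaged_plant_train_path",
]


@dataclass
class ReactorState:
    """Concentrations (mM) and isotope deltas (per mil) for one reactor.

    Delta fields may be ``None`` when the species is absent or was not
    determined.
    """

    name: str
    nh4: float = 0.0
    no2: float = 0.0
    no3: float = 0.0
    d15_nh4: Optional[float] = None
    d15_no2: Optional[float] = None
    d18_no2: Optional[float] = None
    d15_no3: Optional[float] = None
    d18_no3: Optional[float] = None
    d15_n2: Optional[float] = None

    def __post_init__(self):
        for attr in ("nh4", "no2", "no3"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} concentration must be >= 0")


@dataclass
class ApparentEffects:
    """Apparent isotope effects of one NT->ANX steady state (per mil)."""

    d15_amx: float
    d15_nxr: float
    d15_amxnir: float
    e18_combined: float
    f_nh4: float
    a: float
    b: float
    d15_amxnir_raw: float = field(default=float("nan"))
    d15_n2: float = field(default=float("nan"))


def _require(reactor: ReactorState, *fields: str) -> None:
    missing = [f for f in fields if getattr(reactor, f) is None]
    if missing:
        raise ValueError(
            f"reactor {reactor.name!r}: missing required delta value(s) {missing}"
        )


def fraction_reacted(nt: ReactorState, anx: ReactorState) -> float:
    """Fraction of the NT ammonium pool consumed in the ANX reactor."""
    if nt.nh4 <= 0:
        raise ValueError("NT ammonium concentration must be positive")
    if anx.nh4 > nt.nh4:
        raise ValueError("ANX ammonium exceeds NT ammonium (negative consumption)")
    return (nt.nh4 - anx.nh4) / nt.nh4


def apparent_amx_15(nt: ReactorState, anx: ReactorState) -> float:
    """Apparent 15N effect of ammonium oxidation: (dANX - dNT) / f_NH4."""
    _require(nt, "d15_nh4")
    _require(anx, "d15_nh4")
    f = fraction_reacted(nt, anx)
    if f == 0:
        raise ValueError("no ammonium consumption between NT and ANX")
    return (anx.d15_nh4 - nt.d15_nh4) / f


def apparent_nxr_15(anx: ReactorState) -> float:
    """Apparent 15N effect of nitrite oxidation: d15N_NO2 - d15N_NO3 in ANX.

    Negative values mean the product nitrate is heavier than the substrate
    nitrite — an inverse isotope effect.
    """
    _require(anx, "d15_no2", "d15_no3")
    return anx.d15_no2 - anx.d15_no3


def mixing_coefficients(nt: ReactorState, anx: ReactorState) -> tuple[float, float]:
    """Branching coefficients of the ANX nitrite budget.

    ``a`` is residual nitrite and ``b`` nitrate production, each normalised
    to the nitrite consumed between NT and ANX; ``1 - a - b`` is the share
    reduced to N2.
    """
    dno2 = nt.no2 - anx.no2
    if dno2 <= 0:
        raise ValueError("degenerate train: no nitrite consumption between NT and ANX")
    a = anx.no2 / dno2
    b = (anx.no3 - nt.no3) / dno2
    if b < 0:
        raise ValueError("negative nitrate production across the ANX reactor")
    return a, b


def apparent_amxnir_15_raw(
    nt: ReactorState, anx: ReactorState, d15_nxr: Optional[float] = None
) -> float:
    """Raw steady-state quotient for the nitrite-reduction effect.

    ``[d15_NO2_ANX - d15_NO2_NT - b * 15Delta_NXR] / (a + b - 1)``, exposed
    for audit.  See :func:`apparent_amxnir_15` for the conventionally signed
    value.
    """
    _require(nt, "d15_no2")
    _require(anx, "d15_no2")
    if d15_nxr is None:
        d15_nxr = apparent_nxr_15(anx)
    a, b = mixing_coefficients(nt, anx)
    denom = a + b - 1.0
    if denom == 0:
        raise ValueError("singular system: a + b = 1")
    return (anx.d15_no2 - nt.d15_no2 - b * d15_nxr) / denom


def apparent_amxnir_15(
    nt: ReactorState, anx: ReactorState, d15_nxr: Optional[float] = None
) -> float:
    """Apparent 15N effect of nitrite reduction to N2, positive for normal.

    Reported under the substrate-minus-product convention
    ``15Delta_AMXNIR = d15N_NO2_ANX - d15N_N2_ANX`` (the same convention as
    the other apparent effects), which equals the negated raw steady-state
    quotient of :func:`apparent_amxnir_15_raw`.
    """
    return -apparent_amxnir_15_raw(nt, anx, d15_nxr)


def d15_n2_back_calculated(nt: ReactorState, anx: ReactorState) -> float:
    """delta-15N of the N2 produced in ANX, inferred from the steady state.

    N2 is not measured directly; the nitrite mixing balance
    ``d15_NO2_NT = (1-a-b) d15_N2 + a d15_NO2_ANX + b d15_NO3_ANX``
    is solved for ``d15_N2``.
    """
    _require(nt, "d15_no2")
    _require(anx, "d15_no2", "d15_no3")
    a, b = mixing_coefficients(nt, anx)
    denom = 1.0 - a - b
    if denom == 0:
        raise ValueError("singular system: a + b = 1")
    return (nt.d15_no2 - a * anx.d15_no2 - b * anx.d15_no3) / denom


def apparent_combined_18(anx: ReactorState, d18_water: float) -> float:
    """Combined apparent 18O effect of nitrite oxidation to nitrate.

    Nitrate inherits two O atoms from nitrite and one from water, so
    ``18E = 2/3 d18O_NO2 + 1/3 d18O_H2O - d18O_NO3`` lumps the kinetic O
    effect of nitrite oxidation with the water-incorporation effect.
    Negative values indicate a combined inverse effect.
    """
    _require(anx, "d18_no2", "d18_no3")
    return (2.0 / 3.0) * anx.d18_no2 + (1.0 / 3.0) * d18_water - anx.d18_no3


def stoichiometric_ratios(nt: ReactorState, anx: ReactorState) -> tuple[float, float]:
    """(dNO2/dNH4, dNO3/dNH4) consumption/production ratios across ANX.

    For a healthy anammox reactor these fall near the canonical 1.3 and 0.3
    (reported plant and culture ranges: 1.03-1.32 and 0.14-0.35).
    """
    dnh4 = nt.nh4 - anx.nh4
    if dnh4 <= 0:
        raise ValueError("no ammonium consumption between NT and ANX")
    return (nt.no2 - anx.no2) / dnh4, (anx.no3 - nt.no3) / dnh4


def plant_effects(
    nt: ReactorState, anx: ReactorState, d18_water: float = -8.0
) -> ApparentEffects:
    """All apparent effects for one NT->ANX pair.

    ``d18_water`` defaults to -8 per mil (a typical freshwater value, also
    used for the laboratory incubations in unlabelled water).
    """
    f = fraction_reacted(nt, anx)
    a, b = mixing_coefficients(nt, anx)
    d15_nxr = apparent_nxr_15(anx)
    raw = apparent_amxnir_15_raw(nt, anx, d15_nxr)
    return ApparentEffects(
        d15_amx=apparent_amx_15(nt, anx),
        d15_nxr=d15_nxr,
        d15_amxnir=-raw,
        e18_combined=apparent_combined_18(anx, d18_water),
        f_nh4=f,
        a=a,
        b=b,
        d15_amxnir_raw=raw,
        d15_n2=d15_n2_back_calculated(nt, anx),
    )


def packaged_plant_train_path():
    """Path to the packaged reactor-train fixture (plant mean chemistry).

    Five reactors (Influent, DN, BD, NT, ANX) with three-date mean DIN
    concentrations and isotope deltas from a full-scale anammox plant.
    """
    return resources.files("isoanammox.data") / "plant_train.csv"
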