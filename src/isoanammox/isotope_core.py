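"""Delta-notation arithmetic, fractionation factors, and closed-form oracles.

All isotope ratios are expressed relative to the conventional references:
atmospheric N2 for 15N/14N and VSMOW for 18O/16O.  Delta values are per-mil
deviations, ``delta = (R_sample/R_ref - 1) * 1000``.  Kinetic fractionation
factors ``eps`` (per mil) enter fluxes through the alpha form
``alpha = 1 + eps/1000``: the heavy-isotope flux of a reaction is the light
flux times the substrate ratio divided by alpha, so positive eps means the
light isotope reacts faster (a "normal" effect) and negative eps an
"inverse" effect.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "R15_AIR",
    "R18_VSMOW",
    "delta_to_ratio",
    "ratio_to_delta",
    "permil_to_alpha",
    "alpha_to_permil",
    "rayleigh_delta",
    "delta_15_18_anomaly",
]

#: 15N/14N of atmospheric N2 (the delta-15N reference).
R15_AIR = 0.0036765

#: 18O/16O of Vienna Standard Mean Ocean Water (the delta-18O reference).
R18_VSMOW = 0.0020052


def delta_to_ratio(delta, ref):
    """Convert a per-mil delta value to an absolute heavy/light atom ratio.

    Parameters
    ----------
    delta : float or array
        Per-mil deviation from the reference; must exceed -1000.
    ref : float
        Reference isotope ratio (e.g. ``R15_AIR``), > 0.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta must exceed -1000 permil (ratio must stay positive)")
    if ref <= 0:
        raise ValueError("reference ratio must be positive")
    out = ref * (1.0 + delta / 1000.0)
    return out if out.ndim else float(out)


def ratio_to_delta(r, ref):
    """Inverse of :func:`delta_to_ratio`; returns per mil."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be positive")
    out = (r / ref - 1.0) * 1000.0
    return out if out.ndim else float(out)


def permil_to_alpha(eps):
    """alpha = 1 + eps/1000 for eps in per mil (eps > -1000)."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= -1000.0):
        raise ValueError("eps must exceed -1000 permil")
    out = 1.0 + eps / 1000.0
    return out if out.ndim else float(out)


def alpha_to_permil(alpha):
    """Inverse of :func:`permil_to_alpha`."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    out = (alpha - 1.0) * 1000.0
    return out if out.ndim else float(out)


def rayleigh_delta(delta0, eps, f):
    """Residual-substrate delta after closed-system (Rayleigh) consumption.

    Under the divisor convention used throughout this package (heavy flux =
    R * light_flux / alpha) the exact closed form for a single substrate
    consumed by a single reaction is ``R/R0 = f**(1/alpha - 1)`` where ``f``
    is the fraction of the light-isotope pool remaining (indistinguishable
    from the total pool at natural abundance).

    Parameters
    ----------
    delta0 : float
        Initial delta of the substrate (per mil).
    eps : float
        Kinetic fractionation factor (per mil); positive = normal.
    f : float or array
        Fraction of substrate remaining, in (0, 1].

    Returns
    -------
    float or array — delta of the residual substrate, per mil.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("fraction remaining f must satisfy 0 < f <= 1")
    alpha = permil_to_alpha(eps)
    out = (1000.0 + delta0) * f ** (1.0 / alpha - 1.0) - 1000.0
    return out if out.ndim else float(out)


def delta_15_18_anomaly(d15, d15_init, d18, d18_init, ratio_18_15=1.0):
    """Dual-isotope anomaly of nitrate, Delta(15,18).

    ``Delta(15,18) = (d15 - d15_init) - ratio_18_15 * (d18 - d18_init)``.

    Pure dissimilatory nitrate reduction moves nitrate delta-18O and
    delta-15N up a line of slope ~1, so the anomaly stays at zero; concurrent
    nitrite re-oxidation (by anammox or nitrifiers) displaces the trajectory
    and yields a nonzero anomaly.  The default 18/15 ratio of 1 encodes the
    canonical denitrification slope.
    """
    d15 = np.asarray(d15, dtype=float)
    d18 = np.asarray(d18, dtype=float)
    out = (d15 - d15_init) - ratio_18_15 * (d18 - d18_init)
    return out if out.ndim else float(out)
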