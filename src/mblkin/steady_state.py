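"""Initial-rate extraction and Michaelis–Menten nonlinear regression.

Initial rates are taken as the least-squares slope of the early, linear part
of a progress curve (at most 10% conversion by default) and converted from
AU·s⁻¹ to µM·s⁻¹ via the chromophore's extinction coefficient and path
length.  The hyperbola v = Vmax·S/(Km + S) is then fitted by nonlinear least
squares; kcat = Vmax/[E] with [E] known from the assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from lmfit import Model

from .errors import InsufficientDataError
from .synthetic import MMDataset
from .traces import TimeSeries

__all__ = [
    "MichaelisMentenFit",
    "Efficiency",
    "initial_rate",
    "fit_michaelis_menten",
    "catalytic_efficiency",
]


@dataclass(frozen=True)
class MichaelisMentenFit:
    """kcat, Km and catalytic efficiency with standard errors."""

    kcat: float  # s⁻¹
    kcat_se: float
    km: float  # µM
    km_se: float
    vmax: float  # µM·s⁻¹
    vmax_se: float
    enzyme_uM: float
    rss: float
    converged: bool
    poorly_identified: bool = False

    @property
    def efficiency(self) -> float:
        """kcat/Km in µM⁻¹·s⁻¹."""
        return self.kcat / self.km


class Efficiency(NamedTuple):
    value: float  # µM⁻¹·s⁻¹
    stderr: float


def initial_rate(
    progress: TimeSeries,
    epsilon: float,
    path_length: float = 1.0,
    max_conversion: float = 0.1,
) -> float:
    """Initial hydrolysis rate (µM·s⁻¹) from an absorbance progress curve.

    Conversion is measured against the curve's full observed excursion, so
    the window is the leading stretch where |A(t) − A(0)| stays below
    ``max_conversion`` of that excursion.  The rate is returned positive for
    both product-formation (rising) and substrate-depletion (falling)
    curves.  A constant curve yields 0.
    """
    if epsilon <= 0 or path_length <= 0:
        raise ValueError("epsilon and path_length must be positive")
    if not 0 < max_conversion <= 1:
        raise ValueError("max_conversion must lie in (0, 1]")
    t, y = progress.times, progress.values
    excursion = np.abs(y - y[0])
    span = float(np.max(excursion))
    if span == 0.0:
        return 0.0
    beyond = np.nonzero(excursion > max_conversion * span)[0]
    n = int(beyond[0]) if beyond.size else t.size
    if n < 3:
        raise InsufficientDataError(
            f"only {n} points below {max_conversion:.0%} conversion; need at least 3"
        )
    slope = np.polyfit(t[:n], y[:n], 1)[0]
    return abs(float(slope)) / (epsilon * path_length)


def _mm_model(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(data: MMDataset) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = Vmax·S/(Km + S).

    Requires at least 4 distinct substrate concentrations.  The fit is
    flagged ``poorly_identified`` when Km falls outside the substrate grid
    or its standard error exceeds its value — the hallmark of a titration
    run entirely above or below Km.
    """
    s, v = data.substrate_uM, data.rates_uM_s
    if np.unique(s).size < 4:
        raise InsufficientDataError("need at least 4 distinct substrate concentrations")

    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    km0 = float(s[np.argmin(np.abs(v - half))])
    model = Model(_mm_model)
    params = model.make_params(vmax=max(vmax0, 1e-12), km=max(km0, 1e-6))
    params["vmax"].set(min=1e-15)
    params["km"].set(min=1e-9)
    fit = model.fit(v, params, s=s)

    vmax = float(fit.params["vmax"].value)
    km = float(fit.params["km"].value)
    vmax_se = fit.params["vmax"].stderr
    km_se = fit.params["km"].stderr
    vmax_se = float(vmax_se) if vmax_se is not None else math.nan
    km_se = float(km_se) if km_se is not None else math.nan
    converged = bool(fit.success) and vmax > 0 and km > 0
    poorly = converged and (
        not (s.min() <= km <= s.max()) or not math.isfinite(km_se) or km_se > km
    )
    return MichaelisMentenFit(
        kcat=vmax / data.enzyme_uM,
        kcat_se=vmax_se / data.enzyme_uM,
        km=km,
        km_se=km_se,
        vmax=vmax,
        vmax_se=vmax_se,
        enzyme_uM=data.enzyme_uM,
        rss=float(np.sum(fit.residual**2)),
        converged=converged,
        poorly_identified=poorly,
    )


def catalytic_efficiency(fit: MichaelisMentenFit) -> Efficiency:
    """kcat/Km with its standard error propagated in quadrature."""
    if not fit.converged:
        raise ValueError("catalytic efficiency requires a converged fit")
    value = fit.efficiency
    rel = math.hypot(fit.kcat_se / fit.kcat, fit.km_se / fit.km)
    return Efficiency(value, value * rel)
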