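"""Three-parameter dose-response (IC50) fitting and cross-form comparison.

Residual activity after pre-incubation with an inhibitor is modelled as

    a(c) = bottom + (top − bottom) / (1 + c / IC50)

a logistic in log-concentration with the Hill slope fixed at 1; the free
parameters are top, bottom and log10(IC50).  The IC50 standard error is
obtained by the delta method, σ_IC50 = ln(10)·IC50·σ_log10IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from lmfit import Model

from .errors import InsufficientDataError
from .synthetic import DoseResponseDataset

__all__ = ["DoseResponseFit", "FoldChange", "fit_ic50", "ic50_fold_change"]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted three-parameter dose-response curve."""

    log10_ic50: float
    log10_ic50_se: float
    top: float
    top_se: float
    bottom: float
    bottom_se: float
    rss: float
    converged: bool
    no_inhibition: bool = False

    @property
    def ic50(self) -> float:
        return 10.0**self.log10_ic50

    @property
    def ic50_se(self) -> float:
        """Delta-method standard error, ln(10)·IC50·SE(log10 IC50)."""
        return _LN10 * self.ic50 * self.log10_ic50_se


class FoldChange(NamedTuple):
    value: float
    stderr: float


def _model(c, top, bottom, log_ic50):
    return bottom + (top - bottom) / (1.0 + c / 10.0**log_ic50)


def fit_ic50(data: DoseResponseDataset) -> DoseResponseFit:
    """Fit the three-parameter dose-response model to residual-activity data.

    Requires ≥ 5 positive inhibitor concentrations spanning at least 2
    decades.  A curve whose activities never drop appreciably below the top
    plateau is flagged ``no_inhibition`` (its IC50 is not meaningful).
    """
    c, a = data.inhibitor, data.activity
    pos = c > 0
    if pos.sum() < 5:
        raise InsufficientDataError("need at least 5 positive inhibitor concentrations")
    if np.log10(c[pos].max() / c[pos].min()) < 2.0 - 1e-9:
        raise InsufficientDataError("inhibitor concentrations must span at least 2 decades")

    top0 = float(a[np.argmin(c)])
    bottom0 = float(np.min(a))
    half = (top0 + bottom0) / 2.0
    ic50_0 = float(c[pos][np.argmin(np.abs(a[pos] - half))])
    model = Model(_model)
    params = model.make_params(
        top=top0, bottom=bottom0, log_ic50=math.log10(max(ic50_0, 1e-12))
    )
    fit = model.fit(a, params, c=c)

    vals = {p: float(fit.params[p].value) for p in ("top", "bottom", "log_ic50")}
    errs = {
        p: (float(fit.params[p].stderr) if fit.params[p].stderr is not None else math.nan)
        for p in ("top", "bottom", "log_ic50")
    }
    span = vals["top"] - vals["bottom"]
    scale = max(abs(vals["top"]), 1e-12)
    no_inhibition = span < 0.05 * scale
    converged = bool(fit.success) and span >= 0 and math.isfinite(vals["log_ic50"])
    return DoseResponseFit(
        log10_ic50=vals["log_ic50"],
        log10_ic50_se=errs["log_ic50"],
        top=vals["top"],
        top_se=errs["top"],
        bottom=vals["bottom"],
        bottom_se=errs["bottom"],
        rss=float(np.sum(fit.residual**2)),
        converged=converged,
        no_inhibition=no_inhibition,
    )


def ic50_fold_change(a: DoseResponseFit, b: DoseResponseFit) -> FoldChange:
    """IC50 ratio b/a with the relative errors combined in quadrature."""
    if not (a.converged and b.converged):
        raise ValueError("fold change requires two converged fits")
    ratio = b.ic50 / a.ic50
    rel = math.hypot(a.ic50_se / a.ic50, b.ic50_se / b.ic50)
    return FoldChange(ratio, ratio * rel)
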