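"""Single-wavelength trace extraction, difference spectra and exponential fits.

Substrate depletion (390 nm) and product accumulation (485 nm) traces follow
single exponentials; the transient 665 nm intermediate feature accumulates
and then decays and is fitted with a difference of two saturating
exponentials, reporting a rise and a fall rate constant.  Non-convergence is
data, not an exception: an unfittable trace comes back with
``converged=False`` so tabulated results can show a dash, exactly as a bench
scientist would report an unfit trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import InsufficientDataError, RangeError
from .synthetic import StoppedFlowDataset

__all__ = [
    "TimeSeries",
    "DifferenceSpectrum",
    "ExponentialFitResult",
    "extract_wavelength",
    "difference_spectra",
    "find_lambda_max",
    "fit_single_exponential",
    "fit_double_exponential",
    "delta_abs_max",
]


@dataclass(frozen=True)
class TimeSeries:
    """A single-wavelength absorbance time course."""

    times: np.ndarray  # s
    values: np.ndarray  # AU
    wavelength: float  # nm actually used
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.shape != y.shape:
            raise ValueError("times and values differ in length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class DifferenceSpectrum:
    """ΔA(λ) = A(probe, λ) − A(baseline, λ)."""

    wavelengths: np.ndarray
    delta_a: np.ndarray
    probe_time: float
    baseline_time: float


@dataclass(frozen=True)
class ExponentialFitResult:
    """Observed rate constants and amplitudes from an exponential fit.

    For ``form == "double"`` the rates are ordered (rise, fall) with
    rise ≥ fall; amplitudes follow the same ordering.  Standard errors are
    NaN when the optimiser could not estimate them.
    """

    form: str  # "single" | "double"
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # s⁻¹
    offset: float
    amplitude_errors: tuple[float, ...]
    rate_errors: tuple[float, ...]
    offset_error: float
    rss: float
    converged: bool

    @property
    def k_obs(self) -> float:
        return self.rates[0]

    @property
    def k_rise(self) -> float:
        return self.rates[0]

    @property
    def k_fall(self) -> float:
        return self.rates[-1]

    @property
    def well_determined(self) -> bool:
        """True when every rate has a finite standard error smaller than itself."""
        return self.converged and all(
            np.isfinite(se) and se < abs(k) for k, se in zip(self.rates, self.rate_errors)
        )


def extract_wavelength(dataset: StoppedFlowDataset, wavelength: float) -> TimeSeries:
    """Nearest-grid-point single-wavelength trace; ties pick the lower neighbour."""
    wl = dataset.wavelengths
    if not (wl.min() <= wavelength <= wl.max()):
        raise RangeError(
            f"wavelength {wavelength} nm outside data range [{wl.min()}, {wl.max()}]"
        )
    i = int(np.argmin(np.abs(wl - wavelength)))
    meta = dict(dataset.metadata)
    meta["requested_wavelength_nm"] = wavelength
    return TimeSeries(dataset.times.copy(), dataset.absorbance[:, i].copy(), float(wl[i]), meta)


def _nearest_time_index(dataset: StoppedFlowDataset, t: float) -> int:
    times = dataset.times
    if not (times.min() <= t <= times.max()):
        raise RangeError(f"time {t} s outside data range [{times.min()}, {times.max()}]")
    return int(np.argmin(np.abs(times - t)))


def difference_spectra(
    dataset: StoppedFlowDataset, baseline_time: float, probe_times
) -> list[DifferenceSpectrum]:
    """Spectra at each probe time minus the spectrum at the baseline time."""
    ib = _nearest_time_index(dataset, baseline_time)
    baseline = dataset.absorbance[ib]
    out = []
    for tp in probe_times:
        ip = _nearest_time_index(dataset, tp)
        out.append(
            DifferenceSpectrum(
                dataset.wavelengths.copy(),
                dataset.absorbance[ip] - baseline,
                float(dataset.times[ip]),
                float(dataset.times[ib]),
            )
        )
    return out


def find_lambda_max(diff: DifferenceSpectrum, window: tuple[float, float]) -> float:
    """Wavelength of the largest |ΔA| within a window; ties pick the lowest λ."""
    lo, hi = window
    mask = (diff.wavelengths >= lo) & (diff.wavelengths <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no grid wavelengths")
    wl = diff.wavelengths[mask]
    mag = np.abs(diff.delta_a[mask])
    return float(wl[int(np.argmax(mag))])


def _failed(form: str, n_amp: int, rss: float = np.nan) -> ExponentialFitResult:
    nan = (np.nan,) * n_amp
    return ExponentialFitResult(
        form, nan, (np.nan,) * (n_amp), np.nan, nan, (np.nan,) * n_amp, np.nan, rss, False
    )


def _single_exp(t, a, k, c):
    return a * np.exp(-k * t) + c


def _guess_single_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Log-linearised slope of |y − y_end| over the first half of the trace."""
    resid = np.abs(y - y[-1])
    half = max(3, t.size // 2)
    tt, rr = t[:half], resid[:half]
    ok = rr > 1e-12 * max(np.max(resid), 1e-30)
    if ok.sum() >= 3 and np.ptp(tt[ok]) > 0:
        slope = np.polyfit(tt[ok], np.log(rr[ok]), 1)[0]
        if slope < 0:
            return -slope
    span = t[-1] - t[0]
    return 3.0 / span if span > 0 else 1.0


def fit_single_exponential(series: TimeSeries) -> ExponentialFitResult:
    """Fit A(t) = a·exp(−k·t) + c by nonlinear least squares.

    A decaying trace has a > 0; a rising one has a < 0 (equivalently
    A∞·(1 − exp(−k·t)) + c with A∞ = −a).  Requires ≥ 5 points.  Returns
    ``converged=False`` for flat or unfittable traces.
    """
    t, y = series.times, series.values
    if t.size < 5:
        raise InsufficientDataError("single-exponential fit needs at least 5 points")
    span = float(np.ptp(y))
    scale = max(np.max(np.abs(y)), 1.0)
    if span <= 1e-12 * scale:  # flat trace: amplitude indistinguishable from 0
        return _failed("single", 1, rss=float(np.sum((y - y.mean()) ** 2)))

    model = Model(_single_exp)
    params = model.make_params(
        a=y[0] - y[-1], k=_guess_single_rate(t, y), c=y[-1]
    )
    params["k"].set(min=1e-12)
    try:
        fit = model.fit(y, params, t=t)
    except Exception:
        return _failed("single", 1)
    k = float(fit.params["k"].value)
    converged = bool(fit.success) and k > 0
    se = {p: fit.params[p].stderr for p in ("a", "k", "c")}
    se = {p: (float(v) if v is not None else np.nan) for p, v in se.items()}
    return ExponentialFitResult(
        form="single",
        amplitudes=(float(fit.params["a"].value),),
        rates=(k,),
        offset=float(fit.params["c"].value),
        amplitude_errors=(se["a"],),
        rate_errors=(se["k"],),
        offset_error=se["c"],
        rss=float(np.sum(fit.residual**2)),
        converged=converged,
    )


def _double_exp(t, a1, a2, k_rise, k_fall, c):
    return a1 * (1.0 - np.exp(-k_rise * t)) - a2 * (1.0 - np.exp(-k_fall * t)) + c


def fit_double_exponential(series: TimeSeries) -> ExponentialFitResult:
    """Fit the rise-then-fall form A1·(1−e^(−k_rise·t)) − A2·(1−e^(−k_fall·t)) + c.

    Used for the transient 665 nm intermediate feature, which accumulates
    and then decays.  Rates are relabelled so k_rise ≥ k_fall.  Requires
    ≥ 8 points.  Shallow or flat traces return ``converged=False``; nearly
    equal rates converge with large standard errors (poorly identified).
    """
    t, y = series.times, series.values
    if t.size < 8:
        raise InsufficientDataError("double-exponential fit needs at least 8 points")
    span = float(np.ptp(y))
    scale = max(np.max(np.abs(y)), 1.0)
    if span <= 1e-12 * scale:
        return _failed("double", 2, rss=float(np.sum((y - y.mean()) ** 2)))

    rel = y - y[0]
    peak_idx = int(np.argmax(np.abs(rel)))
    peak = float(rel[peak_idx])
    t_peak = float(t[peak_idx]) if t[peak_idx] > 0 else float(t[-1]) / 10.0

    # fall-rate guess from the post-peak tail, rise-rate candidates from t_peak
    if peak_idx < t.size - 5:
        k_fall0 = _guess_single_rate(t[peak_idx:] - t[peak_idx], y[peak_idx:])
    else:
        k_fall0 = 1.0 / max(t[-1], 1e-9)
    best = None
    model = Model(_double_exp)
    for mult in (2.0, 5.0, 10.0):
        params = model.make_params(
            a1=1.5 * peak, a2=1.5 * peak, k_rise=mult / t_peak, k_fall=k_fall0, c=y[0]
        )
        params["k_rise"].set(min=1e-12)
        params["k_fall"].set(min=1e-12)
        try:
            fit = model.fit(y, params, t=t)
        except Exception:
            continue
        rss = float(np.sum(fit.residual**2))
        if fit.success and (best is None or rss < best[1]):
            best = (fit, rss)
    if best is None:
        return _failed("double", 2)
    fit, rss = best

    vals = {p: float(fit.params[p].value) for p in ("a1", "a2", "k_rise", "k_fall", "c")}
    errs = {
        p: (float(fit.params[p].stderr) if fit.params[p].stderr is not None else np.nan)
        for p in ("a1", "a2", "k_rise", "k_fall", "c")
    }
    a1, a2, kr, kf = vals["a1"], vals["a2"], vals["k_rise"], vals["k_fall"]
    se_a1, se_a2, se_kr, se_kf = errs["a1"], errs["a2"], errs["k_rise"], errs["k_fall"]
    if kr < kf:
        # swap channels; the model maps onto itself with negated amplitudes
        a1, a2 = -a2, -a1
        kr, kf = kf, kr
        se_a1, se_a2 = se_a2, se_a1
        se_kr, se_kf = se_kf, se_kr
    converged = bool(fit.success) and kr > 0 and kf > 0
    # shallow-gradient traces (signal under ~5x the noise floor) are not
    # reliably fittable; report them unfitted rather than with spurious rates
    noise_est = float(np.std(np.diff(y)) / np.sqrt(2.0))
    signal = float(np.max(np.abs(_double_exp(t, a1, a2, kr, kf, 0.0))))
    if signal < 5.0 * noise_est:
        converged = False
    return ExponentialFitResult(
        form="double",
        amplitudes=(a1, a2),
        rates=(kr, kf),
        offset=vals["c"],
        amplitude_errors=(se_a1, se_a2),
        rate_errors=(se_kr, se_kf),
        offset_error=errs["c"],
        rss=rss,
        converged=converged,
    )


def delta_abs_max(series: TimeSeries) -> float:
    """Maximum absorbance excursion above the starting value, max A(t) − A(0).

    Zero for traces that only decay from their initial value.
    """
    if series.values.size == 0:
        raise InsufficientDataError("empty series")
    return float(np.max(series.values) - series.values[0])
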