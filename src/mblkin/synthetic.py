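"""Synthetic stopped-flow, initial-rate and dose-response data generators.

These emulate the three assay formats used to characterise metal-substituted
BcII and VIM-2 with nitrocefin:

* stopped-flow photodiode-array acquisitions after 1:1 rapid mixing of
  enzyme with substrate (100 µM each pre-mix, so 50 µM each post-mix) at
  5 °C, recorded over 100 s on a 300–750 nm grid;
* plate-reader substrate titrations (two-fold serial dilution from 400 µM)
  read out as initial hydrolysis rates;
* residual-activity measurements after a 5 min pre-incubation with an
  inhibitor, at 10 µM nitrocefin.

Absorbance follows Beer–Lambert: A(t, λ) = Σ_s ε_s(λ)·c_s(t)·ℓ.  The
chromophore defaults place Gaussian bands (40 nm standard deviation) at the
assigned λ_max values — substrate 390 nm, ring-opened product 485 nm,
anionic intermediate 665 nm — with enzyme-bound ES and EI carrying the
substrate and intermediate spectra respectively.  Peak extinction
coefficients (0.0115 / 0.0175 / 0.030 µM⁻¹·cm⁻¹) are plausible defaults;
every rate-recovery analysis downstream is amplitude-agnostic.

Noise models: additive Gaussian in AU for stopped-flow traces (default
σ = 0.002 AU), multiplicative Gaussian for initial rates (default 2%), and
additive Gaussian on the activity fraction for dose-response data (default
0.02).  Identical arguments and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .schemes import (
    ConcentrationTrajectory,
    RateConstantSet,
    ReactionScheme,
    integrate,
)

__all__ = [
    "ChromophoreMap",
    "AssayConditions",
    "StoppedFlowDataset",
    "MMDataset",
    "DoseResponseDataset",
    "default_chromophores",
    "mm_substrate_grid",
    "dose_response_grid",
    "absorbance_from_trajectory",
    "simulate_stopped_flow",
    "simulate_mm_dataset",
    "simulate_dose_response",
]


@dataclass(frozen=True)
class ChromophoreMap:
    """Per-species extinction spectra ε(λ) in µM⁻¹·cm⁻¹ on a shared nm grid."""

    wavelengths: np.ndarray
    epsilon: Mapping[str, np.ndarray]
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        eps = {k: np.asarray(v, dtype=float) for k, v in self.epsilon.items()}
        object.__setattr__(self, "epsilon", eps)
        if self.path_length <= 0:
            raise ConfigurationError("path_length must be positive")
        for name, e in eps.items():
            if e.shape != wl.shape:
                raise ConfigurationError(f"epsilon grid mismatch for species {name!r}")
            if np.any(e < 0):
                raise ConfigurationError(f"negative extinction coefficient for {name!r}")

    def epsilon_at(self, species: str, wavelength: float) -> float:
        """ε of one species at the nearest grid wavelength."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.epsilon[species][i])


def default_chromophores(
    wavelengths: np.ndarray | None = None,
    peaks: Mapping[str, tuple[float, float]] | None = None,
    band_sd: float = 40.0,
    path_length: float = 1.0,
) -> ChromophoreMap:
    """Gaussian-band chromophores for the nitrocefin schemes.

    Bands default to S/ES at 390 nm (ε_max 0.0115), P at 485 nm (0.0175)
    and EI at 665 nm (0.030 µM⁻¹·cm⁻¹), each with ``band_sd`` nm standard
    deviation, on a 300–750 nm grid.
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 751.0, 5.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if peaks is None:
        peaks = {
            "S": (390.0, 0.0115),
            "ES": (390.0, 0.0115),
            "EI": (665.0, 0.030),
            "P": (485.0, 0.0175),
        }
    eps = {
        name: amp * np.exp(-0.5 * ((wavelengths - centre) / band_sd) ** 2)
        for name, (centre, amp) in peaks.items()
    }
    return ChromophoreMap(wavelengths, eps, path_length)


@dataclass(frozen=True)
class AssayConditions:
    """Post-mix stopped-flow assay conditions."""

    enzyme: str = "BcII"
    metal: str = "Fe(II)"
    pH: float = 7.5
    temperature_C: float = 5.0
    enzyme_uM: float = 50.0
    substrate_uM: float = 50.0

    @classmethod
    def from_premix(
        cls, enzyme_uM: float = 100.0, substrate_uM: float = 100.0, **kwargs
    ) -> "AssayConditions":
        """1:1 rapid mixing halves both pre-mix concentrations."""
        return cls(enzyme_uM=enzyme_uM / 2.0, substrate_uM=substrate_uM / 2.0, **kwargs)


@dataclass(frozen=True)
class StoppedFlowDataset:
    """Time × wavelength absorbance matrix with assay metadata."""

    times: np.ndarray  # s, starting at 0
    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # AU, shape (n_times, n_wavelengths)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", a)
        if a.shape != (t.size, wl.size):
            raise ConfigurationError(
                f"absorbance shape {a.shape} does not match axes ({t.size}, {wl.size})"
            )
        if t.size and t[0] != 0.0:
            raise ConfigurationError("times must start at 0")


@dataclass(frozen=True)
class MMDataset:
    """Initial rates (µM·s⁻¹) over a substrate grid (µM) at fixed [E]."""

    substrate_uM: np.ndarray
    rates_uM_s: np.ndarray
    enzyme_uM: float
    noise_rel: float
    seed: int | None

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_uM, dtype=float)
        v = np.asarray(self.rates_uM_s, dtype=float)
        object.__setattr__(self, "substrate_uM", s)
        object.__setattr__(self, "rates_uM_s", v)
        if np.any(s <= 0):
            raise ConfigurationError("substrate concentrations must be positive")
        if s.shape != v.shape:
            raise ConfigurationError("substrate and rate arrays differ in length")


@dataclass(frozen=True)
class DoseResponseDataset:
    """Residual activity fractions over an inhibitor grid including 0."""

    inhibitor: np.ndarray
    activity: np.ndarray
    noise_sigma: float
    seed: int | None

    def __post_init__(self) -> None:
        c = np.asarray(self.inhibitor, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "inhibitor", c)
        object.__setattr__(self, "activity", a)
        if c.shape != a.shape:
            raise ConfigurationError("inhibitor and activity arrays differ in length")
        if np.any(c < 0):
            raise ConfigurationError("inhibitor concentrations must be non-negative")


def absorbance_from_trajectory(
    traj: ConcentrationTrajectory, chrom: ChromophoreMap
) -> StoppedFlowDataset:
    """Noiseless Beer–Lambert forward model of a concentration trajectory."""
    missing = [name for name in traj.chromophoric if name not in chrom.epsilon]
    if missing:
        raise ConfigurationError(
            f"no extinction spectrum for chromophoric species: {', '.join(missing)}"
        )
    a = np.zeros((traj.times.size, chrom.wavelengths.size))
    for name in traj.species:
        if name in chrom.epsilon:
            a += np.outer(traj[name], chrom.epsilon[name]) * chrom.path_length
    return StoppedFlowDataset(
        traj.times.copy(),
        chrom.wavelengths.copy(),
        a,
        metadata={"scheme_id": traj.scheme_id, "noise_sigma": 0.0, "seed": None},
    )


def simulate_stopped_flow(
    scheme: ReactionScheme,
    k: RateConstantSet,
    chrom: ChromophoreMap,
    conditions: AssayConditions = AssayConditions(),
    duration: float = 100.0,
    n_times: int = 500,
    noise_sigma: float = 0.002,
    seed: int | None = 0,
) -> StoppedFlowDataset:
    """Simulate a photodiode-array stopped-flow acquisition.

    Integrates the scheme from post-mix concentrations (free enzyme and
    substrate only), applies Beer–Lambert and adds i.i.d. Gaussian noise.
    """
    if conditions.enzyme_uM <= 0 or conditions.substrate_uM <= 0:
        raise ValueError("post-mix enzyme and substrate concentrations must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    enzyme = scheme.species_with_role("enzyme")[0]
    substrate = scheme.species_with_role("substrate")[0]
    times = np.linspace(0.0, duration, n_times)
    traj = integrate(
        scheme, k, {enzyme: conditions.enzyme_uM, substrate: conditions.substrate_uM}, times
    )
    ds = absorbance_from_trajectory(traj, chrom)
    a = ds.absorbance
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sigma, size=a.shape)
    meta = {
        "enzyme": conditions.enzyme,
        "metal": conditions.metal,
        "pH": conditions.pH,
        "temperature_C": conditions.temperature_C,
        "enzyme_uM": conditions.enzyme_uM,
        "substrate_uM": conditions.substrate_uM,
        "scheme_id": scheme.id,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return StoppedFlowDataset(ds.times, ds.wavelengths, a, meta)


def mm_substrate_grid(top_uM: float = 400.0, n: int = 10, dilution: float = 2.0) -> np.ndarray:
    """Serial-dilution substrate grid, descending (default 400 → 0.78 µM)."""
    return top_uM / dilution ** np.arange(n)


def simulate_mm_dataset(
    kcat: float,
    km: float,
    enzyme_uM: float,
    substrate_grid: Sequence[float] | None = None,
    noise_rel: float = 0.02,
    seed: int | None = 0,
) -> MMDataset:
    """Initial-rate dataset from the Michaelis–Menten law with multiplicative noise.

    Expected rate v(S) = kcat·[E]·S / (Km + S); observed v·(1 + σ·Z).
    """
    if kcat <= 0 or km <= 0 or enzyme_uM <= 0:
        raise ValueError("kcat, Km and enzyme concentration must be positive")
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    s = mm_substrate_grid() if substrate_grid is None else np.asarray(substrate_grid, float)
    v = kcat * enzyme_uM * s / (km + s)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_rel * rng.standard_normal(s.size))
    return MMDataset(s, v, enzyme_uM, noise_rel, seed)


def dose_response_grid(ic50: float, span_decades: float = 2.0, n: int = 8) -> np.ndarray:
    """Log-spaced inhibitor grid spanning ``span_decades`` around the IC50, plus a 0 control."""
    half = span_decades / 2.0
    return np.concatenate(([0.0], ic50 * 10.0 ** np.linspace(-half, half, n)))


def simulate_dose_response(
    ic50: float,
    top: float = 1.0,
    bottom: float = 0.0,
    inhibitor_grid: Sequence[float] | None = None,
    noise_sigma: float = 0.02,
    seed: int | None = 0,
) -> DoseResponseDataset:
    """Residual-activity dataset from a three-parameter dose-response curve.

    Expected activity a(c) = bottom + (top − bottom) / (1 + c/IC50), i.e.
    a logistic in log-concentration with Hill slope fixed at 1.
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if bottom > top:
        raise ValueError("bottom must not exceed top")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    c = dose_response_grid(ic50) if inhibitor_grid is None else np.asarray(inhibitor_grid, float)
    a = bottom + (top - bottom) / (1.0 + c / ic50)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + noise_sigma * rng.standard_normal(c.size)
    return DoseResponseDataset(c, a, noise_sigma, seed)
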