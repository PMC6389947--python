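"""Seeded synthetic-data generators with embedded ground truth.

Every input the analysis chain consumes can be generated here with known
parameters, so each fitter can be tested as the (approximate) inverse of
the corresponding generator:

* dye-influx fluorescence traces — flat baseline, peptide addition at a
  stated time (default 248 s), saturating rise to F_eq < F_max on the
  ionophore-normalized scale, under either the saturating-exponential or
  the second-order pore-formation model;
* polarized band-spectrum pairs — overlapping pseudo-Voigt components
  with per-component dichroic ratios built in exactly (before noise);
* CD mixtures — f_bound-weighted combinations of a bound and a free
  spectrum.

All noise is additive i.i.d. Gaussian and every generator is a
deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cd import CDSpectrum
from .ftir import PolarizedSpectrumPair, R_from_order_parameter, band_profile
from .kinetics import FluorescenceTrace

__all__ = [
    "TraceScenario",
    "SpectrumComponent",
    "SpectrumScenario",
    "gen_trace",
    "gen_polarized_pair",
    "gen_cd_mixture",
    "cd_band_spectrum",
]


@dataclass(frozen=True)
class TraceScenario:
    """Parameters of a synthetic dye-influx trace.

    ``model`` selects the post-addition rise: ``"exponential"``
    (F_eq (1 - exp(-k_exp tau))) or ``"second_order"``
    (F_eq k_a [P_b] tau / (1 + k_a [P_b] tau)).  Defaults mirror the
    study conditions: addition at 248 s, 1 s sampling over 1500 s,
    ionophore maximum normalized to 1 and F_eq below it.
    """

    model: str = "exponential"
    f_eq: float = 0.6
    k_exp: float = 0.01  # s^-1, exponential model
    k_a: float = 1e5  # M^-1 s^-1, second-order model
    p_b: float = 2e-6  # M, second-order model
    t_add: float = 248.0
    duration: float = 1500.0
    dt: float = 1.0
    baseline: float = 0.0
    f_max: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "second_order"):
            raise ValueError(
                f'model must be "exponential" or "second_order", got {self.model!r}'
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.dt <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        if not 0.0 < self.f_eq <= 1.0:
            raise ValueError(f"F_eq must be in (0, 1] on the normalized scale")
        if self.f_max <= self.baseline:
            raise ValueError("f_max must exceed the baseline level")


def gen_trace(scenario: TraceScenario) -> FluorescenceTrace:
    """Generate a fluorescence trace; ground truth goes into ``meta``."""
    rng = np.random.default_rng(scenario.seed)
    time = np.arange(0.0, scenario.duration + scenario.dt / 2.0, scenario.dt)
    tau = np.clip(time - scenario.t_add, 0.0, None)
    if scenario.model == "exponential":
        rise = 1.0 - np.exp(-scenario.k_exp * tau)
    else:
        x = scenario.k_a * scenario.p_b * tau
        rise = x / (1.0 + x)
    amplitude = scenario.f_max - scenario.baseline
    clean = scenario.baseline + amplitude * scenario.f_eq * rise
    noisy = clean + rng.normal(0.0, scenario.noise_sigma, size=time.shape) if (
        scenario.noise_sigma > 0
    ) else clean
    return FluorescenceTrace(
        time=time,
        intensity=noisy,
        t_add=scenario.t_add,
        f_max=scenario.f_max,
        meta={"scenario": scenario, "ground_truth_clean": clean},
    )


@dataclass(frozen=True)
class SpectrumComponent:
    """One generated band: iso-area and dichroic ratio are exact.

    The per-polarization areas satisfy ``a_par / a_perp = R`` and the
    pseudo-isotropic combination ``a_par + 2 a_perp = 3 area_iso``.
    """

    label: str
    center: float  # cm^-1
    fwhm: float  # cm^-1
    area_iso: float
    R: float = 1.0
    lorentz_fraction: float = 0.0

    @property
    def area_perp(self) -> float:
        return 3.0 * self.area_iso / (self.R + 2.0)

    @property
    def area_par(self) -> float:
        return self.R * self.area_perp


@dataclass(frozen=True)
class SpectrumScenario:
    """Parameters of a synthetic polarized spectrum pair.

    ``noise_frac`` is the noise standard deviation as a fraction of the
    clean parallel-spectrum peak, applied independently per
    polarization.  The default grid is 1 cm^-1 over the requested range.
    """

    components: tuple[SpectrumComponent, ...]
    grid: tuple[float, float, float] = (1550.0, 1750.0, 1.0)  # start, stop, step
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError(f"invalid grid specification {self.grid}")
        if not self.components:
            raise ValueError("scenario needs at least one component")

    @classmethod
    def amide_i(
        cls,
        sheet_fraction: float = 0.4,
        r_sheet: float = 0.89,
        total_area: float = 1.0,
        noise_frac: float = 0.0,
        seed: int = 0,
    ) -> "SpectrumScenario":
        """Five-component amide I pair emulating measured film spectra.

        The sheet component carries ``sheet_fraction`` of the
        conformational (iso-combination) area and the stated dichroic
        ratio; turns, helix and irregular structure share the rest; a
        side-chain band sits below 1620 cm^-1 and is excluded from
        structure fractions downstream.
        """
        rest = (1.0 - sheet_fraction) / 3.0
        comps = (
            SpectrumComponent("turn", 1683.0, 22.0, rest * total_area, 1.05),
            SpectrumComponent("helix", 1657.0, 16.0, rest * total_area, 1.10),
            SpectrumComponent("irregular", 1643.0, 14.0, rest * total_area, 1.02),
            SpectrumComponent("sheet", 1629.0, 18.0, sheet_fraction * total_area, r_sheet),
            SpectrumComponent("side", 1610.0, 14.0, 0.10 * total_area, 1.00),
        )
        return cls(components=comps, noise_frac=noise_frac, seed=seed)

    @classmethod
    def ch2_stretch(
        cls,
        s_lipid: float = 0.6,
        total_area: float = 1.0,
        noise_frac: float = 0.0,
        seed: int = 0,
    ) -> "SpectrumScenario":
        """CH2 stretching doublet for a lipid chain order parameter.

        Both CH2 modes (transition dipoles perpendicular to the chain,
        alpha = 90 deg) get the dichroic ratio implied by ``s_lipid``
        under the default ATR fields.
        """
        r = R_from_order_parameter(s_lipid, alpha_deg=90.0)
        comps = (
            SpectrumComponent("ch2_antisym", 2922.0, 14.0, 0.65 * total_area, r),
            SpectrumComponent("ch2_sym", 2852.0, 12.0, 0.35 * total_area, r),
        )
        return cls(
            components=comps, grid=(2790.0, 3010.0, 1.0), noise_frac=noise_frac,
            seed=seed,
        )


def gen_polarized_pair(scenario: SpectrumScenario) -> PolarizedSpectrumPair:
    """Generate a || / perpendicular spectrum pair with exact
    per-component dichroic ratios before noise."""
    start, stop, step = scenario.grid
    nu = np.arange(start, stop + step / 2.0, step)
    par = np.zeros_like(nu)
    perp = np.zeros_like(nu)
    for c in scenario.components:
        par += band_profile(nu, c.center, c.fwhm, c.area_par, c.lorentz_fraction)
        perp += band_profile(nu, c.center, c.fwhm, c.area_perp, c.lorentz_fraction)
    if scenario.noise_frac > 0:
        rng = np.random.default_rng(scenario.seed)
        sigma = scenario.noise_frac * float(par.max())
        par = par + rng.normal(0.0, sigma, size=nu.shape)
        perp = perp + rng.normal(0.0, sigma, size=nu.shape)
    truth = {
        c.label: {"area_par": c.area_par, "area_perp": c.area_perp, "R": c.R,
                  "area_iso": c.area_iso, "center": c.center, "fwhm": c.fwhm}
        for c in scenario.components
    }
    return PolarizedSpectrumPair(
        wavenumber=nu,
        absorbance_par=par,
        absorbance_perp=perp,
        meta={"scenario": scenario, "ground_truth": truth},
    )


def cd_band_spectrum(
    wavelength: np.ndarray,
    bands: Sequence[tuple[float, float, float]],
    units: str = "a.u.",
) -> CDSpectrum:
    """Build a CD spectrum from Gaussian bands.

    ``bands`` is a sequence of ``(center_nm, fwhm_nm, peak_ellipticity)``
    tuples; negative peaks make dips (e.g. the n-pi* minimum).
    """
    wl = np.asarray(wavelength, dtype=float)
    y = np.zeros_like(wl)
    for center, fwhm, peak in bands:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y += peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return CDSpectrum(wavelength=wl, ellipticity=y, units=units)


def gen_cd_mixture(
    bound: CDSpectrum,
    free: CDSpectrum,
    f_bound: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """Population-weighted CD mixture
    ``f_bound * bound + (1 - f_bound) * free`` plus optional noise."""
    if not 0.0 <= f_bound <= 1.0:
        raise ValueError(f"f_bound must be in [0, 1], got {f_bound}")
    b, f = bound.ascending(), free.ascending()
    if b.wavelength.shape != f.wavelength.shape or not np.allclose(
        b.wavelength, f.wavelength
    ):
        raise ValueError("bound and free spectra must share one wavelength grid")
    y = f_bound * b.ellipticity + (1.0 - f_bound) * f.ellipticity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return CDSpectrum(
        wavelength=b.wavelength,
        ellipticity=y,
        units=bound.units,
        meta={"f_bound": f_bound, "noise_sigma": noise_sigma, "seed": seed},
    )
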