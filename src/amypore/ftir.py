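"""Polarized ATR-FTIR analysis: band decomposition and orientation.

Polarized attenuated-total-reflection infrared spectra of a
peptide/lipid film on a germanium internal-reflection element are
decomposed into overlapping band components.  In the amide I region the
component areas give secondary-structure fractions; the ratio of a
component's area at parallel vs perpendicular polarization (the dichroic
ratio R) encodes the orientation of its transition dipole relative to
the membrane normal.

Orientation formalism (uniaxial distribution, thick-film limit)
---------------------------------------------------------------
With relative interface field amplitudes (E_x, E_y, E_z) the dichroic
ratio of a transition dipole with order parameter S_d about the membrane
normal is

    R = [E_x^2 (1 - C)/2 + E_z^2 C] / [E_y^2 (1 - C)/2],   C = (2 S_d + 1)/3,

where C is the mean squared dipole projection on the normal.  The
molecular-axis order parameter follows from the transition-dipole angle
alpha off the molecular axis: S = 2 S_d / (3 cos^2(alpha) - 1).  Order
parameters are bounded by -0.5 (axis in the membrane plane) and 1.0
(axis along the normal); S = 0 is isotropic.

For a beta-barrel, orientational order factorizes along the nested axes
barrel -> strand -> amide I dipole:

    S_d = S(gamma) * S(beta) * S(theta_d),    S(x) = (3 cos^2 x - 1)/2,

with gamma the barrel-axis tilt from the membrane normal, beta the
strand tilt from the barrel axis, and theta_d the amide I dipole angle
from the strand axis (~90 deg).  Given a measured beta-sheet dichroic
ratio, the strand tilt beta is solved per assumed gamma; combinations
with no real solution are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PolarizedSpectrumPair",
    "BandComponent",
    "BandModel",
    "FittedBand",
    "BandComponentSet",
    "StructureFractions",
    "ATRGeometry",
    "OrderParameterResult",
    "OrientationResult",
    "gaussian_band",
    "band_profile",
    "baseline_correct",
    "BandFitter",
    "fit_bands",
    "structure_fractions",
    "dichroic_ratio",
    "order_parameter_from_R",
    "R_from_order_parameter",
    "lipid_order",
    "strand_tilt",
    "solve_strand_tilt_at",
    "solvable_gamma_limit",
]

#: Default amide I assignment windows (cm^-1).
AMIDE_I_WINDOWS = {
    "turn": (1670.0, 1700.0),
    "helix": (1654.0, 1660.0),
    "irregular": (1642.0, 1644.0),
    "sheet": (1628.0, 1630.0),
    "side": (1600.0, 1620.0),
}

#: Labels counted as peptide backbone conformations (side chains excluded).
CONFORMATION_LABELS = ("turn", "helix", "irregular", "sheet")

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
_MAGIC_ANGLE_TOL = 1e-6


@dataclass(frozen=True)
class PolarizedSpectrumPair:
    """Matched || and |_ absorbance spectra on one wavenumber grid."""

    wavenumber: np.ndarray  # cm^-1, monotone (ascending or descending)
    absorbance_par: np.ndarray
    absorbance_perp: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumber, dtype=float)
        par = np.asarray(self.absorbance_par, dtype=float)
        perp = np.asarray(self.absorbance_perp, dtype=float)
        object.__setattr__(self, "wavenumber", nu)
        object.__setattr__(self, "absorbance_par", par)
        object.__setattr__(self, "absorbance_perp", perp)
        if not (nu.shape == par.shape == perp.shape) or nu.ndim != 1:
            raise ValueError("both polarizations must share one 1-D wavenumber grid")
        d = np.diff(nu)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not (np.all(np.isfinite(par)) and np.all(np.isfinite(perp))):
            raise ValueError("absorbance values must be finite")

    def select(self, region: tuple[float, float]) -> "PolarizedSpectrumPair":
        """Restrict to a wavenumber window (bounds in any order)."""
        lo, hi = sorted(region)
        mask = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if not mask.any():
            raise ValueError(
                f"region {region} does not overlap the grid "
                f"[{self.wavenumber.min():g}, {self.wavenumber.max():g}] cm^-1"
            )
        return replace(
            self,
            wavenumber=self.wavenumber[mask],
            absorbance_par=self.absorbance_par[mask],
            absorbance_perp=self.absorbance_perp[mask],
        )


@dataclass(frozen=True)
class BandComponent:
    """One spectral component of a band model.

    ``center_window`` bounds the fitted peak position, ``width_bounds``
    the FWHM, and ``lorentz_fraction`` sets the Gaussian/Lorentzian
    mixing of the pseudo-Voigt line shape (0 = pure Gaussian).
    """

    label: str
    center_window: tuple[float, float]
    width_bounds: tuple[float, float] = (4.0, 40.0)
    lorentz_fraction: float = 0.0

    @property
    def center_init(self) -> float:
        return 0.5 * (self.center_window[0] + self.center_window[1])


@dataclass(frozen=True)
class BandModel:
    """An ordered set of band components to fit in one spectral region."""

    components: tuple[BandComponent, ...]

    @classmethod
    def amide_i_default(cls) -> "BandModel":
        """Standard five-component amide I model: beta/gamma-turns
        (1700-1670), alpha-helix (1660-1654), irregular (1644-1642),
        beta-sheet (1630-1628) and side-chain (1620-1600) bands."""
        return cls(
            components=tuple(
                BandComponent(label=label, center_window=(lo, hi))
                for label, (lo, hi) in AMIDE_I_WINDOWS.items()
            )
        )

    @classmethod
    def ch2_stretch_default(cls) -> "BandModel":
        """Lipid acyl-chain CH2 stretching doublet: antisymmetric
        (~2923-2921) and symmetric (~2853-2851 cm^-1) modes."""
        return cls(
            components=(
                BandComponent("ch2_antisym", (2915.0, 2930.0), (5.0, 30.0)),
                BandComponent("ch2_sym", (2845.0, 2860.0), (5.0, 30.0)),
            )
        )


def gaussian_band(
    x: np.ndarray, center: float, fwhm: float, area: float
) -> np.ndarray:
    """Area-normalized Gaussian line."""
    sigma = fwhm * _FWHM_TO_SIGMA
    return (
        area
        / (sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    )


def band_profile(
    x: np.ndarray,
    center: float,
    fwhm: float,
    area: float,
    lorentz_fraction: float = 0.0,
) -> np.ndarray:
    """Area-normalized pseudo-Voigt line (Gaussian/Lorentzian mix)."""
    g = gaussian_band(x, center, fwhm, area)
    if lorentz_fraction == 0.0:
        return g
    hwhm = fwhm / 2.0
    lor = area / math.pi * hwhm / ((x - center) ** 2 + hwhm**2)
    return (1.0 - lorentz_fraction) * g + lorentz_fraction * lor


def baseline_correct(
    x: np.ndarray, y: np.ndarray, method: str = "linear"
) -> np.ndarray:
    """Subtract a baseline: ``"none"``, ``"linear"`` (straight line
    through the region endpoints) or ``"rubberband"`` (lower convex
    hull)."""
    if method == "none":
        return y
    if method == "linear":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        return y - base
    if method == "rubberband":
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        hull = [0]
        for i in range(1, xs.size):
            while len(hull) >= 2:
                i1, i2 = hull[-2], hull[-1]
                cross = (xs[i2] - xs[i1]) * (ys[i] - ys[i1]) - (
                    xs[i] - xs[i1]
                ) * (ys[i2] - ys[i1])
                if cross <= 0:  # keep only the lower hull
                    hull.pop()
                else:
                    break
            hull.append(i)
        base_sorted = np.interp(xs, xs[hull], ys[hull])
        base = np.empty_like(base_sorted)
        base[order] = base_sorted
        return y - base
    raise ValueError(f'baseline method must be "none", "linear" or "rubberband", got {method!r}')


@dataclass(frozen=True)
class FittedBand:
    """One fitted component with per-polarization areas."""

    label: str
    center: float
    fwhm: float
    lorentz_fraction: float
    area_par: float
    area_perp: float

    @property
    def dichroic_ratio(self) -> float:
        return dichroic_ratio(self.area_par, self.area_perp)


@dataclass(frozen=True)
class BandComponentSet:
    """Fitted components of one region plus fit diagnostics."""

    bands: tuple[FittedBand, ...]
    rss: float
    redchi: float
    flagged: bool = False
    flags: tuple[str, ...] = ()

    def area(self, label: str, polarization: str) -> float:
        key = {"par": "area_par", "perp": "area_perp"}[polarization]
        total = sum(getattr(b, key) for b in self.bands if b.label == label)
        if not any(b.label == label for b in self.bands):
            raise KeyError(f"no component labelled {label!r}")
        return total

    def band(self, label: str) -> FittedBand:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(f"no component labelled {label!r}")


@dataclass(frozen=True)
class StructureFractions:
    """Secondary-structure fractions (side chains excluded); they sum
    to 1."""

    alpha: float
    beta: float
    turn: float
    irregular: float
    combination: str = "par_plus_2perp"

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "turn": self.turn,
            "irregular": self.irregular,
        }


class BandFitter(BaseEstimator):
    """Joint nonlinear least-squares decomposition of a polarized pair.

    Component centers and widths are shared between the two
    polarizations — required for the per-component areas to define
    meaningful dichroic ratios — while the areas are free per
    polarization.  ``fit(pair)`` stores the fitted ``components_``
    (a :class:`BandComponentSet`), the residual arrays and chi-square
    diagnostics.

    Parameters
    ----------
    model : BandModel
        Components, their center windows, width bounds and line shapes.
    region : (float, float)
        Wavenumber window to fit.
    baseline : {"linear", "none", "rubberband"}
        Baseline correction applied per polarization before fitting.
    max_nfev : int
        Optimizer evaluation budget.
    """

    def __init__(
        self,
        model: BandModel | None = None,
        region: tuple[float, float] = (1600.0, 1700.0),
        baseline: str = "linear",
        max_nfev: int = 20000,
    ):
        self.model = model
        self.region = region
        self.baseline = baseline
        self.max_nfev = max_nfev

    def fit(self, pair: PolarizedSpectrumPair) -> "BandFitter":
        model = self.model if self.model is not None else BandModel.amide_i_default()
        sub = pair.select(self.region)
        nu = sub.wavenumber
        a_par = baseline_correct(nu, sub.absorbance_par, self.baseline)
        a_perp = baseline_correct(nu, sub.absorbance_perp, self.baseline)

        params = lmfit.Parameters()
        comps = model.components
        peak_scale = max(float(np.max(a_par)), float(np.max(a_perp)), 1e-12)
        for i, c in enumerate(comps):
            lo, hi = sorted(c.center_window)
            wlo, whi = c.width_bounds
            params.add(f"c{i}_center", value=c.center_init, min=lo, max=hi)
            params.add(
                f"c{i}_fwhm",
                value=min(max(0.5 * (wlo + whi), wlo), whi),
                min=wlo,
                max=whi,
            )
            # initial area from the local spectrum height
            j = int(np.argmin(np.abs(nu - c.center_init)))
            for pol, spec in (("par", a_par), ("perp", a_perp)):
                height = max(float(spec[j]), 0.05 * peak_scale)
                params.add(
                    f"c{i}_area_{pol}",
                    value=height * 0.5 * (wlo + whi) * 1.064,
                    min=0.0,
                )

        def model_sum(p: lmfit.Parameters, pol: str) -> np.ndarray:
            total = np.zeros_like(nu)
            for i, c in enumerate(comps):
                total += band_profile(
                    nu,
                    p[f"c{i}_center"].value,
                    p[f"c{i}_fwhm"].value,
                    p[f"c{i}_area_{pol}"].value,
                    c.lorentz_fraction,
                )
            return total

        def residual(p: lmfit.Parameters) -> np.ndarray:
            return np.concatenate(
                [model_sum(p, "par") - a_par, model_sum(p, "perp") - a_perp]
            )

        out = lmfit.minimize(residual, params, max_nfev=self.max_nfev)
        if not out.success:
            raise RuntimeError(
                f"band fit did not converge ({out.message}); "
                f"starting values: {params.valuesdict()}"
            )
        flags: list[str] = []
        bands = []
        for i, c in enumerate(comps):
            fwhm = out.params[f"c{i}_fwhm"]
            if fwhm.value <= fwhm.min + 1e-6 or fwhm.value >= fwhm.max - 1e-6:
                flags.append(f"component {c.label!r} width at bound ({fwhm.value:.3g})")
            bands.append(
                FittedBand(
                    label=c.label,
                    center=float(out.params[f"c{i}_center"].value),
                    fwhm=float(fwhm.value),
                    lorentz_fraction=c.lorentz_fraction,
                    area_par=float(out.params[f"c{i}_area_par"].value),
                    area_perp=float(out.params[f"c{i}_area_perp"].value),
                )
            )
        self.components_ = BandComponentSet(
            bands=tuple(bands),
            rss=float(np.sum(out.residual**2)),
            redchi=float(out.redchi),
            flagged=bool(flags),
            flags=tuple(flags),
        )
        self.wavenumber_ = nu
        self.residual_par_ = model_sum(out.params, "par") - a_par
        self.residual_perp_ = model_sum(out.params, "perp") - a_perp
        self.result_ = out
        return self

    def predict(self, nu: np.ndarray, polarization: str = "par") -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        key = {"par": "area_par", "perp": "area_perp"}[polarization]
        total = np.zeros_like(nu)
        for b in self.components_.bands:
            total += band_profile(
                nu, b.center, b.fwhm, getattr(b, key), b.lorentz_fraction
            )
        return total


def fit_bands(
    pair: PolarizedSpectrumPair,
    model: BandModel | None = None,
    region: tuple[float, float] = (1600.0, 1700.0),
    baseline: str = "linear",
) -> BandComponentSet:
    """Decompose a polarized pair into band components (see BandFitter)."""
    return BandFitter(model=model, region=region, baseline=baseline).fit(pair).components_


def structure_fractions(
    components: BandComponentSet, combination: str = "par_plus_2perp"
) -> StructureFractions:
    """Secondary-structure fractions from amide I component areas.

    Each conformation's weight is its component area under the chosen
    polarization combination — ``"par_plus_2perp"`` (pseudo-isotropic
    a_|| + 2 a_perp, the default), ``"par"`` or ``"perp"`` — normalized
    over the four backbone conformations.  Side-chain components are
    excluded from the denominator.
    """
    if combination == "par_plus_2perp":
        weight = lambda b: b.area_par + 2.0 * b.area_perp
    elif combination == "par":
        weight = lambda b: b.area_par
    elif combination == "perp":
        weight = lambda b: b.area_perp
    else:
        raise ValueError(
            f'combination must be "par_plus_2perp", "par" or "perp", got {combination!r}'
        )
    totals = {label: 0.0 for label in CONFORMATION_LABELS}
    for b in components.bands:
        if b.label in totals:
            totals[b.label] += weight(b)
    denom = sum(totals.values())
    if denom <= 0:
        raise ValueError("total conformational band area is zero")
    return StructureFractions(
        alpha=totals["helix"] / denom,
        beta=totals["sheet"] / denom,
        turn=totals["turn"] / denom,
        irregular=totals["irregular"] / denom,
        combination=combination,
    )


def dichroic_ratio(area_par: float, area_perp: float) -> float:
    """R = a_|| / a_perp."""
    if area_perp == 0:
        raise ZeroDivisionError("perpendicular band area is zero; R is undefined")
    return area_par / area_perp


@dataclass(frozen=True)
class ATRGeometry:
    """ATR experiment geometry.

    ``e_x, e_y, e_z`` are the relative electric-field amplitudes at the
    internal-reflection interface; the defaults are the thick-film values
    for a germanium element at 45 deg incidence.  ``alpha_deg`` is the
    transition-dipole angle from the molecular axis and ``gamma_deg``
    the barrel-axis tilt from the membrane normal.
    """

    e_x: float = 1.398
    e_y: float = 1.516
    e_z: float = 0.629
    alpha_deg: float = 90.0
    gamma_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.e_x, self.e_y, self.e_z) <= 0:
            raise ValueError("field amplitudes must be positive")
        if not 0.0 <= self.alpha_deg <= 90.0:
            raise ValueError(f"alpha must be in [0, 90] degrees, got {self.alpha_deg}")
        if not 0.0 <= self.gamma_deg < 90.0:
            raise ValueError(f"gamma must be in [0, 90) degrees, got {self.gamma_deg}")

    @property
    def isotropic_ratio(self) -> float:
        """Dichroic ratio of an isotropic sample, (E_x^2 + E_z^2)/E_y^2."""
        return (self.e_x**2 + self.e_z**2) / self.e_y**2


@dataclass(frozen=True)
class OrderParameterResult:
    """Order parameters recovered from one dichroic ratio.

    ``attainable`` is False when R lies outside the range any uniaxial
    distribution can produce for the given fields; ``in_physical_range``
    is False when the molecular S falls outside [-0.5, 1] (reported, not
    clipped).
    """

    R: float
    S: float
    S_dipole: float
    attainable: bool = True
    in_physical_range: bool = True


@dataclass(frozen=True)
class OrientationResult:
    """Orientation analysis output: the dichroic ratio, the derived order
    parameter(s), and — for strand-tilt scans — the beta(gamma) table."""

    R: float
    S: float = float("nan")
    S_dipole: float = float("nan")
    in_physical_range: bool = True
    antisym_peak: float | None = None
    beta_of_gamma: pd.DataFrame | None = None


def _axis_order(angle_deg: float) -> float:
    """S(x) = (3 cos^2 x - 1)/2."""
    c = math.cos(math.radians(angle_deg))
    return (3.0 * c * c - 1.0) / 2.0


def _dipole_order_from_R(R: float, geometry: ATRGeometry) -> tuple[float, bool]:
    """Invert the thick-film dichroic-ratio relation for S_d.

    Returns (S_d, attainable); S_d is nan when no uniaxial distribution
    reproduces R with the given field amplitudes (R below E_x^2/E_y^2).
    """
    if R <= 0:
        raise ValueError(f"dichroic ratio must be positive, got {R}")
    a = (R * geometry.e_y**2 - geometry.e_x**2) / 2.0
    if a < -1e-9 * geometry.e_x**2:
        return float("nan"), False
    a = max(a, 0.0)  # R at the S_d = -0.5 boundary, up to rounding
    c = a / (a + geometry.e_z**2)
    return (3.0 * c - 1.0) / 2.0, True


def order_parameter_from_R(
    R: float, geometry: ATRGeometry | None = None, alpha_deg: float | None = None
) -> OrderParameterResult:
    """Molecular-axis order parameter from a measured dichroic ratio.

    Solves the thick-film relation for the transition-dipole order
    parameter S_d and converts to the molecular axis through
    S = 2 S_d / (3 cos^2(alpha) - 1).  At the magic angle
    (alpha = 54.7 deg) the molecular axis is undetermined and an error
    is raised.
    """
    geometry = geometry or ATRGeometry()
    alpha = geometry.alpha_deg if alpha_deg is None else alpha_deg
    denom = 3.0 * math.cos(math.radians(alpha)) ** 2 - 1.0
    if abs(denom) < _MAGIC_ANGLE_TOL:
        raise ValueError(
            "transition dipole at the magic angle (54.7 deg): the molecular "
            "order parameter is undetermined"
        )
    s_d, attainable = _dipole_order_from_R(R, geometry)
    if not attainable:
        return OrderParameterResult(
            R=R, S=float("nan"), S_dipole=float("nan"), attainable=False,
            in_physical_range=False,
        )
    s = 2.0 * s_d / denom
    return OrderParameterResult(
        R=R,
        S=s,
        S_dipole=s_d,
        attainable=True,
        in_physical_range=(-0.5 - 1e-9) <= s <= (1.0 + 1e-9),
    )


def R_from_order_parameter(
    S: float, geometry: ATRGeometry | None = None, alpha_deg: float | None = None
) -> float:
    """Forward relation: dichroic ratio produced by a molecular-axis
    order parameter S (inverse of :func:`order_parameter_from_R`)."""
    geometry = geometry or ATRGeometry()
    alpha = geometry.alpha_deg if alpha_deg is None else alpha_deg
    denom = 3.0 * math.cos(math.radians(alpha)) ** 2 - 1.0
    if abs(denom) < _MAGIC_ANGLE_TOL:
        raise ValueError("transition dipole at the magic angle: R is independent of S")
    s_d = S * denom / 2.0
    c = (2.0 * s_d + 1.0) / 3.0
    if not 0.0 <= c < 1.0:
        raise ValueError(
            f"S={S} with alpha={alpha} deg implies mean squared projection "
            f"{c:.3g} outside [0, 1)"
        )
    num = geometry.e_x**2 * (1.0 - c) / 2.0 + geometry.e_z**2 * c
    return num / (geometry.e_y**2 * (1.0 - c) / 2.0)


def lipid_order(
    pair: PolarizedSpectrumPair,
    geometry: ATRGeometry | None = None,
    region: tuple[float, float] = (2830.0, 2990.0),
    baseline: str = "linear",
) -> OrientationResult:
    """Lipid acyl-chain order parameter from the CH2 stretching bands.

    The antisymmetric (~2922) and symmetric (~2852 cm^-1) CH2 modes are
    fitted jointly in both polarizations; the lipid dichroic ratio
    R_L is the ratio of total CH2 areas, and S_L follows with the CH2
    transition dipoles perpendicular to the chain axis (alpha = 90 deg).
    The antisymmetric peak wavenumber, itself a fluidity marker, is
    reported alongside.
    """
    geometry = geometry or ATRGeometry(alpha_deg=90.0)
    lo, hi = sorted(region)
    nu_lo, nu_hi = pair.wavenumber.min(), pair.wavenumber.max()
    if nu_lo > 2860.0 or nu_hi < 2920.0:
        raise ValueError(
            f"CH2 stretching region ({lo:g}-{hi:g} cm^-1) not covered by the "
            f"grid [{nu_lo:g}, {nu_hi:g}] cm^-1"
        )
    comps = fit_bands(
        pair, model=BandModel.ch2_stretch_default(), region=region, baseline=baseline
    )
    a_par = comps.area("ch2_antisym", "par") + comps.area("ch2_sym", "par")
    a_perp = comps.area("ch2_antisym", "perp") + comps.area("ch2_sym", "perp")
    r_l = dichroic_ratio(a_par, a_perp)
    op = order_parameter_from_R(r_l, geometry, alpha_deg=90.0)
    return OrientationResult(
        R=r_l,
        S=op.S,
        S_dipole=op.S_dipole,
        in_physical_range=op.in_physical_range,
        antisym_peak=comps.band("ch2_antisym").center,
    )


def solve_strand_tilt_at(
    R_beta: float,
    gamma_deg: float,
    geometry: ATRGeometry | None = None,
    theta_d_deg: float = 90.0,
) -> float:
    """Strand tilt beta (deg) for one assumed barrel tilt gamma.

    Solves S_d(R_beta) = S(gamma) S(beta) S(theta_d) for beta.  Returns
    nan when the required S(beta) falls outside [-0.5, 1] (no real
    strand tilt reproduces the measured dichroic ratio at this gamma).
    """
    geometry = geometry or ATRGeometry()
    s_d, attainable = _dipole_order_from_R(R_beta, geometry)
    if not attainable:
        return float("nan")
    s_gamma = _axis_order(gamma_deg)
    s_theta = _axis_order(theta_d_deg)
    if abs(s_gamma) < 1e-12 or abs(s_theta) < 1e-12:
        raise ValueError(
            "barrel-axis or dipole angle at the magic angle: strand tilt is "
            "undetermined"
        )
    s_beta = s_d / (s_gamma * s_theta)
    cos2 = (2.0 * s_beta + 1.0) / 3.0
    if not 0.0 <= cos2 <= 1.0:
        return float("nan")
    return math.degrees(math.acos(math.sqrt(cos2)))


def solvable_gamma_limit(
    R_beta: float,
    geometry: ATRGeometry | None = None,
    theta_d_deg: float = 90.0,
) -> float:
    """Largest barrel tilt gamma (deg) still consistent with R_beta.

    Beyond this gamma the nested-order relation has no real strand-tilt
    solution: the required S(beta) would exceed 1 (beta = 0 is already
    the most upright strand).  Returns 0 if even gamma = 0 is
    unsolvable, and 90 if every gamma < 90 is solvable.
    """
    geometry = geometry or ATRGeometry()
    s_d, attainable = _dipole_order_from_R(R_beta, geometry)
    if not attainable:
        return 0.0
    s_theta = _axis_order(theta_d_deg)
    s_gamma_min = s_d / s_theta  # S(gamma) at which S(beta) = 1 is required
    if s_gamma_min > 1.0:
        return 0.0
    cos2 = (2.0 * s_gamma_min + 1.0) / 3.0
    if cos2 <= 0.0:
        return 90.0
    return math.degrees(math.acos(math.sqrt(cos2)))


def strand_tilt(
    R_beta: float,
    geometry: ATRGeometry | None = None,
    gamma_grid_deg: Sequence[float] = tuple(range(0, 21)),
    theta_d_deg: float = 90.0,
) -> OrientationResult:
    """Strand tilt beta versus assumed barrel tilt gamma.

    Scans gamma over ``gamma_grid_deg`` (restricted to 0-20 deg, the
    physically conceivable range for a transmembrane barrel) and solves
    the nested uniaxial-order relation for beta at each.  The result's
    ``beta_of_gamma`` table has columns ``gamma_deg``, ``beta_deg`` and
    ``solvable``.
    """
    geometry = geometry or ATRGeometry()
    grid = np.asarray(list(gamma_grid_deg), dtype=float)
    if grid.size == 0:
        raise ValueError("gamma grid is empty")
    if grid.min() < 0.0 or grid.max() > 20.0:
        raise ValueError("gamma grid must lie within [0, 20] degrees")
    betas = [solve_strand_tilt_at(R_beta, g, geometry, theta_d_deg) for g in grid]
    table = pd.DataFrame(
        {
            "gamma_deg": grid,
            "beta_deg": betas,
            "solvable": [not math.isnan(b) for b in betas],
        }
    )
    s_d, _ = _dipole_order_from_R(R_beta, geometry)
    return OrientationResult(R=R_beta, S_dipole=s_d, beta_of_gamma=table)
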