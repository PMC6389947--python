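"""Pore-formation kinetics from vesicle dye-influx traces.

A Ca2+-sensitive dye (Quin-2) entrapped in vesicles reports Ca2+ influx
through membrane pores as a rise in fluorescence F_t after peptide
addition at t_add.  The maximal fluorescence F_max is set by an
ionophore.  Two estimators are applied to a normalized trace:

* a single-exponential fit
  ``F_t = F_eq (1 - exp(-k_exp (t - t_add)))`` giving the saturation
  level F_eq (hence F_rel = F_eq/F_max) and the observed rate k_exp;

* the second-order pore-formation model, linearized as

  ``F_eq / ([P_b] (F_eq - F_t)) = 1/[P_b] + k_a t``

  with time measured from peptide addition, whose slope is the
  second-order rate constant k_a (M^-1 s^-1) and whose intercept must
  equal 1/[P_b] if the model holds.  [P_b] is the concentration of
  membrane-bound peptide particles, supplied from independent
  measurements.

From the two rate constants the in-membrane peptide-peptide affinity
K_p = k_a / k_exp follows, and the mean number of peptide units per pore
n is estimated from K_p and [P_b] under a pluggable association model
(default: isodesmic stepwise association).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceTrace",
    "MembraneCondition",
    "ExpFitResult",
    "PoreKineticsResult",
    "MissingReferenceError",
    "FitConvergenceError",
    "normalize_trace",
    "SingleExponentialFitter",
    "fit_single_exponential",
    "linearize_eq2",
    "SecondOrderRateFitter",
    "fit_ka",
    "initial_slope_ka",
    "affinity_constant",
    "estimate_n",
    "register_association_model",
    "analyze_trace",
]


class MissingReferenceError(ValueError):
    """The trace lacks the ionophore-induced maximum needed to normalize."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the initial guesses used."""

    def __init__(self, message: str, initial_guesses: dict, n_iter: int | None = None):
        super().__init__(message)
        self.initial_guesses = initial_guesses
        self.n_iter = n_iter


@dataclass(frozen=True)
class FluorescenceTrace:
    """A timed dye-influx record.

    Attributes
    ----------
    time : array, seconds, strictly increasing
    intensity : array, arbitrary fluorescence units
    t_add : peptide addition time, seconds
    f_max : ionophore-induced maximum (same units as intensity), or None
    meta : free-form metadata (e.g. generator ground truth)
    """

    time: np.ndarray
    intensity: np.ndarray
    t_add: float
    f_max: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or time.shape != intensity.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.count_nonzero(time >= self.t_add) < 10:
            raise ValueError("need at least 10 samples after the addition time")
        if self.f_max is not None and self.f_max <= 0:
            raise ValueError(f"f_max must be positive, got {self.f_max}")

    @property
    def post_addition(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, intensity) at and after t_add."""
        mask = self.time >= self.t_add
        return self.time[mask], self.intensity[mask]

    @property
    def baseline(self) -> float:
        """Mean intensity before t_add (0.0 if no pre-addition samples)."""
        pre = self.intensity[self.time < self.t_add]
        return float(pre.mean()) if pre.size else 0.0


@dataclass(frozen=True)
class MembraneCondition:
    """One membrane/peptide condition of a dye-influx experiment."""

    p_b: float  # molar concentration of membrane-bound peptide particles
    x_chol: float = 0.0  # cholesterol mole fraction
    peptide_to_lipid: float | None = None
    lipid_conc: float | None = None  # molar
    z: int = 1  # monomers per pre-formed oligomer

    def __post_init__(self) -> None:
        if self.p_b <= 0:
            raise ValueError(f"[P_b] must be positive, got {self.p_b}")
        if not 0.0 <= self.x_chol <= 1.0:
            raise ValueError(f"x_chol must be in [0, 1], got {self.x_chol}")
        if self.z < 1:
            raise ValueError(f"oligomer size z must be >= 1, got {self.z}")


@dataclass(frozen=True)
class ExpFitResult:
    """Single-exponential fit of a normalized trace."""

    f_eq: float
    k_exp: float  # s^-1
    f_rel: float  # = f_eq on the normalized scale
    rss: float
    se: dict
    flagged: bool = False
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PoreKineticsResult:
    """Second-order analysis for one membrane condition."""

    k_a: float  # M^-1 s^-1 (nan when not determined)
    intercept: float  # M^-1
    k_exp: float | None = None  # s^-1
    K_p: float | None = None  # M^-1
    n: float | None = None
    r2: float = float("nan")
    intercept_expected: float | None = None  # 1/[P_b]
    curvature: float | None = None  # normalized quadratic coefficient
    flagged: bool = False
    flags: tuple[str, ...] = ()


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Normalize to the ionophore maximum after subtracting the baseline.

    The pre-addition mean is subtracted from both the intensities and
    f_max, then intensities are divided by the corrected maximum, so the
    ionophore effect maps to 1.0 and the pre-addition level to ~0.
    """
    if trace.f_max is None:
        raise MissingReferenceError(
            "trace has no ionophore reference level: supply f_max, the maximal "
            "fluorescence induced by a Ca2+ ionophore (e.g. 4-Br-A23187), to "
            "put the trace on the F/F_max scale"
        )
    baseline = trace.baseline
    scale = trace.f_max - baseline
    if scale <= 0:
        raise ValueError(
            f"f_max ({trace.f_max}) does not exceed the baseline ({baseline})"
        )
    return replace(
        trace,
        intensity=(trace.intensity - baseline) / scale,
        f_max=1.0,
        meta={**trace.meta, "baseline_subtracted": baseline, "normalized": True},
    )


class SingleExponentialFitter(BaseEstimator):
    """Least-squares fit of ``F(t) = F_eq (1 - exp(-k_exp (t - t_add)))``.

    sklearn-style estimator over the post-addition part of a trace:
    ``fit(t, f)`` stores ``f_eq_``, ``k_exp_``, ``f_rel_``, ``rss_`` and
    per-parameter standard errors ``se_``.  Degenerate (near-zero) or
    negative estimates are flagged rather than raised.

    Parameters
    ----------
    t_add : float
        Time origin of the exponential rise (seconds).
    max_nfev : int
        Iteration budget for the optimizer.
    """

    def __init__(self, t_add: float = 0.0, max_nfev: int = 2000):
        self.t_add = t_add
        self.max_nfev = max_nfev

    def fit(self, t: np.ndarray, f: np.ndarray) -> "SingleExponentialFitter":
        t = np.asarray(t, dtype=float)
        f = np.asarray(f, dtype=float)
        mask = t >= self.t_add
        tau = t[mask] - self.t_add
        y = f[mask]
        if tau.size < 3:
            raise ValueError("need at least 3 post-addition samples to fit")

        f_eq0 = float(np.mean(y[-max(3, y.size // 10) :]))
        flags: list[str] = []
        if abs(f_eq0) < 1e-12 or np.ptp(y) < 1e-12:
            # flat/null signal: the rate is unidentifiable
            self._store(f_eq=float(np.mean(y)), k_exp=float("nan"),
                        rss=float(np.sum((y - np.mean(y)) ** 2)),
                        se={"f_eq": float("nan"), "k_exp": float("nan")},
                        flags=["degenerate: no post-addition signal"])
            return self
        # initial rate from the time to reach half of the plateau estimate
        above = np.nonzero(y >= 0.5 * f_eq0)[0]
        t_half = tau[above[0]] if above.size and tau[above[0]] > 0 else max(
            tau[-1] / 10.0, np.finfo(float).tiny
        )
        k0 = math.log(2.0) / t_half
        p0 = {"f_eq": f_eq0, "k_exp": k0}

        def model(tau: np.ndarray, f_eq: float, k: float) -> np.ndarray:
            return f_eq * (1.0 - np.exp(-k * tau))

        try:
            popt, pcov = optimize.curve_fit(
                model, tau, y, p0=[f_eq0, k0], maxfev=self.max_nfev
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"single-exponential fit did not converge: {exc}",
                initial_guesses=p0,
                n_iter=self.max_nfev,
            ) from exc
        f_eq, k_exp = (float(v) for v in popt)
        perr = np.sqrt(np.diag(pcov))
        if f_eq < 0:
            flags.append("negative F_eq estimate")
        if k_exp < 0:
            flags.append("negative k_exp estimate")
        if abs(f_eq) < 1e-9:
            flags.append("degenerate: F_eq ~ 0")
        resid = y - model(tau, f_eq, k_exp)
        self._store(
            f_eq=f_eq,
            k_exp=k_exp,
            rss=float(resid @ resid),
            se={"f_eq": float(perr[0]), "k_exp": float(perr[1])},
            flags=flags,
        )
        return self

    def _store(self, f_eq, k_exp, rss, se, flags) -> None:
        self.f_eq_ = f_eq
        self.k_exp_ = k_exp
        self.f_rel_ = f_eq  # on the normalized (F/F_max) scale
        self.rss_ = rss
        self.se_ = se
        self.flags_ = tuple(flags)
        self.flagged_ = bool(flags)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = np.clip(t - self.t_add, 0.0, None)
        if math.isnan(self.k_exp_):
            return np.full_like(tau, self.f_eq_)
        return self.f_eq_ * (1.0 - np.exp(-self.k_exp_ * tau))

    def result(self) -> ExpFitResult:
        return ExpFitResult(
            f_eq=self.f_eq_,
            k_exp=self.k_exp_,
            f_rel=self.f_rel_,
            rss=self.rss_,
            se=self.se_,
            flagged=self.flagged_,
            flags=self.flags_,
        )


def fit_single_exponential(trace: FluorescenceTrace) -> ExpFitResult:
    """Fit the saturating exponential to a (normalized) trace."""
    return SingleExponentialFitter(t_add=trace.t_add).fit(
        trace.time, trace.intensity
    ).result()


def linearize_eq2(
    trace: FluorescenceTrace,
    f_eq: float,
    p_b: float,
    floor: float = 0.0,
    exclusion_fraction: float = 0.99,
    saturated: str = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Transform a trace to the linear form of the second-order model.

    Returns ``(tau, y)`` with ``tau`` re-zeroed at t_add and
    ``y = F_eq / ([P_b] (F_eq - F_t))``.  Under the second-order model
    y is linear in tau with slope k_a and intercept 1/[P_b].

    Points with ``F_t >= exclusion_fraction * F_eq`` or with residual
    saturation ``F_eq - F_t`` below ``floor`` are dropped (and logged):
    there the transform divides by a vanishing quantity.  Points at or
    above F_eq violate the model; ``saturated="error"`` (default) raises
    naming them, ``saturated="drop"`` discards them, which is the
    appropriate mode for noisy traces whose plateau scatter crosses F_eq.
    """
    if p_b <= 0:
        raise ValueError(f"[P_b] must be positive, got {p_b}")
    if f_eq <= 0:
        raise ValueError(f"F_eq must be positive, got {f_eq}")
    if saturated not in ("error", "drop"):
        raise ValueError('saturated must be "error" or "drop"')
    t, f = trace.post_addition
    tau = t - trace.t_add

    over = f >= f_eq
    if over.any() and saturated == "error":
        times = np.round(t[over], 3).tolist()
        raise ValueError(
            f"F_eq ({f_eq}) does not exceed F_t at t = {times[:10]}"
            f"{'...' if len(times) > 10 else ''}; supply a larger F_eq or pass "
            'saturated="drop" to discard saturated points'
        )
    cut = max(float(floor), (1.0 - exclusion_fraction) * f_eq)
    keep = (f_eq - f) > cut
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "linearize_eq2: dropped %d/%d points with F_eq - F_t <= %.3g",
            n_dropped, keep.size, cut,
        )
    tau, f = tau[keep], f[keep]
    if tau.size == 0:
        raise ValueError("no points remain after exclusion; trace is saturated")
    y = f_eq / (p_b * (f_eq - f))
    return tau, y


class SecondOrderRateFitter(BaseEstimator):
    """Slope of the linearized second-order pore-formation plot.

    ``fit(tau, y)`` performs a straight-line fit of the transformed
    series, storing the second-order rate constant ``k_a_`` (slope,
    M^-1 s^-1), ``intercept_`` (compared with the model-implied
    1/[P_b]), ``r2_`` as a linearity diagnostic and ``curvature_``, the
    normalized quadratic coefficient of a parabola fit (positive =
    convex, as produced by exponential-model data).  A negative slope is
    flagged and ``k_a_`` reported as nan (not determined).

    Parameters
    ----------
    p_b : float
        Membrane-bound peptide particle concentration, molar.
    weights : None | "inverse_variance"
        Ordinary least squares by default.  With ``"inverse_variance"``
        and a known intensity noise ``sigma``, points are weighted by
        1/sigma_y^2 with sigma_y = y^2 [P_b] sigma / F_eq — the
        first-order noise propagation through the transform, which
        strongly amplifies near-saturation points.  The weights are
        computed from the straight-line prediction and refined by a few
        reweighting passes (IRLS), since weights taken from the observed
        y would correlate with the noise and bias the slope.
    sigma, f_eq : float
        Intensity noise and saturation level used only for the weights.
    n_reweight : int
        Number of IRLS passes after the initial OLS fit.
    """

    def __init__(
        self,
        p_b: float,
        weights: str | None = None,
        sigma: float | None = None,
        f_eq: float | None = None,
        n_reweight: int = 3,
    ):
        self.p_b = p_b
        self.weights = weights
        self.sigma = sigma
        self.f_eq = f_eq
        self.n_reweight = n_reweight

    def fit(self, tau: np.ndarray, y: np.ndarray) -> "SecondOrderRateFitter":
        tau = np.asarray(tau, dtype=float)
        y = np.asarray(y, dtype=float)
        if tau.size < 5:
            raise ValueError("need at least 5 points for the linear fit")
        if self.weights is None:
            res = stats.linregress(tau, y)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        elif self.weights == "inverse_variance":
            if self.sigma is None or self.f_eq is None:
                raise ValueError(
                    'weights="inverse_variance" requires sigma and f_eq'
                )
            ols = stats.linregress(tau, y)
            intercept, slope = float(ols.intercept), float(ols.slope)
            design = np.column_stack([np.ones_like(tau), tau])
            w = np.ones_like(y)
            for _ in range(max(self.n_reweight, 1)):
                yhat = np.maximum(intercept + slope * tau, 1e-300)
                sigma_y = yhat**2 * self.p_b * self.sigma / self.f_eq
                w = 1.0 / sigma_y**2
                sw = np.sqrt(w)
                coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
                intercept, slope = (float(c) for c in coef)
            yhat = intercept + slope * tau
            ybar = np.average(y, weights=w)
            ss_res = float(w @ (y - yhat) ** 2)
            ss_tot = float(w @ (y - ybar) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        else:
            raise ValueError(f"unknown weighting scheme {self.weights!r}")

        flags: list[str] = []
        if slope < 0:
            flags.append("negative slope: k_a not determined")
        if np.ptp(y) < 1e-15:
            flags.append("constant series")
        # convexity diagnostic: quadratic coefficient scaled to the data span
        quad = np.polyfit(tau, y, 2)[0] if tau.size >= 3 else 0.0
        span = np.ptp(tau) or 1.0
        self.curvature_ = float(quad * span**2 / (np.ptp(y) or 1.0))
        self.k_a_ = float("nan") if slope < 0 else float(slope)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.intercept_expected_ = 1.0 / self.p_b
        self.r2_ = float(r2)
        self.flags_ = tuple(flags)
        self.flagged_ = bool(flags)
        return self

    def predict(self, tau: np.ndarray) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(tau, dtype=float)

    def result(self) -> PoreKineticsResult:
        return PoreKineticsResult(
            k_a=self.k_a_,
            intercept=self.intercept_,
            r2=self.r2_,
            intercept_expected=self.intercept_expected_,
            curvature=self.curvature_,
            flagged=self.flagged_,
            flags=self.flags_,
        )


def fit_ka(
    tau: Sequence[float],
    y: Sequence[float],
    p_b: float,
    weights: str | None = None,
    sigma: float | None = None,
    f_eq: float | None = None,
) -> PoreKineticsResult:
    """Straight-line fit of a linearized series; slope is k_a."""
    return (
        SecondOrderRateFitter(p_b=p_b, weights=weights, sigma=sigma, f_eq=f_eq)
        .fit(np.asarray(tau, float), np.asarray(y, float))
        .result()
    )


def initial_slope_ka(
    traces: Sequence[FluorescenceTrace], window: float = 120.0
) -> list[float]:
    """Initial linear slope of F(t) over ``window`` seconds after addition.

    For slow second-order kinetics (k_a [P_b] << 1/window) the slope
    approximates F_eq k_a [P_b]; exposed as a cross-check of the
    linearization route.
    """
    slopes = []
    for trace in traces:
        t, f = trace.post_addition
        mask = t <= trace.t_add + window
        if mask.sum() < 3:
            raise ValueError(
                f"fewer than 3 points within {window} s of t_add={trace.t_add}"
            )
        res = stats.linregress(t[mask], f[mask])
        slopes.append(float(res.slope))
    return slopes


def affinity_constant(k_a: float, k_exp: float) -> float:
    """In-membrane peptide-peptide affinity K_p = k_a / k_exp (M^-1)."""
    if k_exp == 0:
        raise ZeroDivisionError(
            "k_exp is zero: the affinity K_p = k_a/k_exp is undefined; check "
            "that the exponential fit produced a positive rate constant"
        )
    return k_a / k_exp


def _isodesmic_n(K_p: float, p_b: float) -> float:
    # mean aggregate size of an isodesmic (equal-K stepwise) association
    return (1.0 + math.sqrt(1.0 + 4.0 * K_p * p_b)) / 2.0


_ASSOCIATION_MODELS: dict[str, Callable[[float, float], float]] = {
    "isodesmic": _isodesmic_n,
}


def register_association_model(
    name: str, fn: Callable[[float, float], float]
) -> None:
    """Register a custom ``n(K_p, [P_b])`` association model."""
    _ASSOCIATION_MODELS[name] = fn


def estimate_n(K_p: float, p_b: float, model: str = "isodesmic") -> float:
    """Mean number of peptide units per pore from K_p and [P_b].

    The default is the isodesmic stepwise-association closed form
    ``n = (1 + sqrt(1 + 4 K_p [P_b])) / 2`` — an explicit modelling
    assumption (the field offers several association schemes); other
    models can be registered.  n -> 1 as K_p [P_b] -> 0.
    """
    if K_p < 0:
        raise ValueError(f"K_p must be non-negative, got {K_p}")
    if p_b <= 0:
        raise ValueError(f"[P_b] must be positive, got {p_b}")
    try:
        fn = _ASSOCIATION_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown association model {model!r}; registered models: "
            f"{sorted(_ASSOCIATION_MODELS)}"
        ) from None
    return fn(K_p, p_b)


def analyze_trace(
    trace: FluorescenceTrace,
    p_b: float,
    normalize: bool = True,
    association_model: str = "isodesmic",
    saturated: str = "error",
) -> PoreKineticsResult:
    """Full per-condition chain: normalize, exponential fit, second-order
    linearization, K_p and the pore oligomer count n."""
    if normalize:
        trace = normalize_trace(trace)
    exp = fit_single_exponential(trace)
    tau, y = linearize_eq2(trace, f_eq=exp.f_eq, p_b=p_b, saturated=saturated)
    lin = fit_ka(tau, y, p_b=p_b)
    K_p = affinity_constant(lin.k_a, exp.k_exp) if not math.isnan(lin.k_a) else None
    n = estimate_n(K_p, p_b, association_model) if K_p is not None and K_p >= 0 else None
    return PoreKineticsResult(
        k_a=lin.k_a,
        intercept=lin.intercept,
        k_exp=exp.k_exp,
        K_p=K_p,
        n=n,
        r2=lin.r2,
        intercept_expected=lin.intercept_expected,
        curvature=lin.curvature,
        flagged=exp.flagged or lin.flagged,
        flags=exp.flags + lin.flags,
    )
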