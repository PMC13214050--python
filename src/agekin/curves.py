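"""Nonparametric ("black-box") analysis of steady-state wash-out labeling curves.

In a wash-out experiment a fully labeled steady-state system is switched to
unlabeled supply at t = 0 and the labeled fraction f(t) is followed over time.
The central identity is that 1 - f(t) equals the cumulative distribution of
the *metabolic age* A of the observed particles (the time since they entered
the system).  Every estimator here exploits that identity:

* age CDF         P_A(t) = 1 - f(t)
* age PDF         p_A(t) = -f'(t)
* mean age        Abar   = integral of f over [0, inf)  (area under the curve)
* residence time  survival 1 - P_T(t) = e^{mu t} f'(t) / f'(0)
* decay rate      kappa(A) = -f''(A)/f'(A) - mu

where mu is the balanced (exponential) growth rate of the culture; mu = 0
recovers the constant-size formulas.  Derivatives of discretely sampled,
noisy curves are estimated by local quadratic fits over a sliding window,
never by raw finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LabelingCurve",
    "GrowthModel",
    "AgeDistribution",
    "DecayRateCurve",
    "DynamicParameters",
    "DiagnosticsReport",
    "CurveError",
    "NonmonotoneError",
    "NoCrossingError",
    "FlatInitialSlopeError",
    "DelayedInputError",
    "TailExtrapolationError",
    "washout_from_stepup",
    "mean_age",
    "median_age",
    "age_distribution",
    "rtl_distribution",
    "residence_time_distribution",
    "decay_rate_function",
    "summary_parameters",
    "diagnose",
    "order_by_mean_age",
]

TailPolicy = Literal["exponential", "truncate"]

#: default additive noise scale (fraction units) used by tolerance checks
DEFAULT_NOISE_SD = 0.01


class CurveError(ValueError):
    """Base class for labeling-curve analysis errors."""


class NonmonotoneError(CurveError):
    """The curve increases beyond noise tolerance; system not at steady state."""


class NoCrossingError(CurveError):
    """The curve never crosses 1/2 within the sampled range."""


class FlatInitialSlopeError(CurveError):
    """f'(0) is indistinguishable from zero — signature of delayed input."""


class DelayedInputError(CurveError):
    """Residence-time survival is not monotone — signature of delayed input."""


class TailExtrapolationError(CurveError):
    """Terminal samples do not decay; exponential tail cannot be fitted."""


@dataclass(frozen=True)
class LabelingCurve:
    """Discrete samples of the labeled fraction f(t) for one molecular species.

    Parameters
    ----------
    species_id:
        Identifier of the molecular species (protein, metabolite pool, ...).
    times:
        Sampling times in minutes, strictly increasing, >= 0.
    values:
        Labeled fractions in [0, 1], one per time point.
    replicate:
        Optional replicate identifier.
    meta:
        Free-form provenance notes (e.g. "converted from step-up").
    """

    species_id: str
    times: np.ndarray
    values: np.ndarray
    replicate: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise CurveError("times and values must be 1-D arrays of equal length")
        if len(t) < 2:
            raise CurveError("a labeling curve needs at least 2 time points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise CurveError("times must be non-negative and strictly increasing")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise CurveError("labeled fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthModel:
    """Balanced-growth description: specific growth rate mu (per minute).

    mu = 0 encodes a non-growing (constant-size) system.
    """

    mu: float = 0.0
    source: Literal["fitted", "given"] = "given"
    residual_sd: float | None = None

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("growth rate mu must be >= 0")


NO_GROWTH = GrowthModel(0.0)


@dataclass(frozen=True)
class AgeDistribution:
    """A distribution over times (age, residence time, ...) on a discrete grid."""

    grid: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    kind: str = "age"

    def mean(self) -> float:
        """First moment by trapezoidal quadrature of the survival function."""
        return float(np.trapezoid(1.0 - self.cdf, self.grid))


@dataclass(frozen=True)
class DecayRateCurve:
    """Age-dependent decay rate kappa(A) evaluated on the sampling grid.

    Undefined ages (where |f'| falls below tolerance) carry NaN.
    """

    ages: np.ndarray
    values: np.ndarray

    def __call__(self, age):
        return np.interp(age, self.ages, self.values)


@dataclass(frozen=True)
class DynamicParameters:
    """Cumulative dynamic parameters of one species or system.

    All times in minutes, rates per minute.  NaN marks quantities that the
    data cannot define (e.g. slope-based rates under a flat initial slope).
    """

    mean_age: float                     # Abar: mean metabolic age
    half_life: float                    # t_1/2: median metabolic age
    expected_decay_rate: float          # kbar = -f'(0) - mu
    mean_residence_time: float          # Tbar
    mean_rtl: float                     # Lbar: mean residence time of the living
    mean_rrtl: float                    # Lbar_r: remaining part of Lbar
    conditioning_age: float = 0.0       # a (minutes); 0 = unconditioned
    conditioned_decay_rate: float = np.nan    # kbar_a = -f'(a)/f(a) - mu
    conditioned_residence_time: float = np.nan  # Tbar_a
    conditioned_escape_rate: float = np.nan     # total escape -f'(a)/f(a) (decay + growth)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Steady-state / delayed-input diagnostics for one labeling curve.

    Each raised flag carries the time interval where the criterion fired.
    """

    nonmonotone: bool = False
    nonmonotone_interval: tuple[float, float] | None = None
    nonconvex: bool = False
    nonconvex_interval: tuple[float, float] | None = None
    flat_initial_slope: bool = False
    slower_than_dilution: bool = False
    slower_than_dilution_interval: tuple[float, float] | None = None
    noise_tolerance_used: float = DEFAULT_NOISE_SD

    @property
    def any_flag(self) -> bool:
        return (self.nonmonotone or self.nonconvex
                or self.flat_initial_slope or self.slower_than_dilution)

    @property
    def delayed_input(self) -> bool:
        """Delayed-input evidence (flat slope, nonconvexity or sub-dilution wash-out)."""
        return self.nonconvex or self.flat_initial_slope or self.slower_than_dilution


# ---------------------------------------------------------------------------
# derivative machinery
# ---------------------------------------------------------------------------

def _local_quadratic(times: np.ndarray, values: np.ndarray, half_window: int = 2):
    """Smoothed f, f', f'' at each sample by local quadratic least squares.

    A quadratic is fitted over a window of up to 2*half_window + 1 points
    centred on each sample (shrunk near the edges, never below 3 points).
    Works on non-uniform grids.  Returns (f_hat, f1, f2).
    """
    n = len(times)
    if n < 3:
        raise CurveError("derivative estimation needs at least 3 points")
    f_hat = np.empty(n)
    f1 = np.empty(n)
    f2 = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        if hi - lo < 2 * half_window + 1:   # shifted (one-sided) edge window
            lo = max(0, hi - (2 * half_window + 1))
            hi = min(n, lo + 2 * half_window + 1)
        dt = times[lo:hi] - times[i]
        # one-sided quadratic derivatives carry O(h) bias; a cubic restores
        # O(h^2) accuracy at the edges
        deg = 3 if (hi - lo >= 5 and (i - lo < half_window or hi - 1 - i < half_window)) else 2
        c = np.polynomial.polynomial.polyfit(dt, values[lo:hi], deg)
        f_hat[i] = c[0]
        f1[i] = c[1]
        f2[i] = 2.0 * c[2]
    return f_hat, f1, f2


def _initial_slope(times: np.ndarray, values: np.ndarray) -> float:
    """f'(0): forward quadratic through the first three samples."""
    if len(times) < 3:
        return float((values[1] - values[0]) / (times[1] - times[0]))
    dt = times[:3] - times[0]
    c = np.polynomial.polynomial.polyfit(dt, values[:3], 2)
    return float(c[1])


def _flat_slope_threshold(times: np.ndarray, noise_sd: float) -> float:
    # |f'(0)| below 3*sigma over the span of the first three points is "flat"
    span = times[min(2, len(times) - 1)] - times[0]
    return 3.0 * noise_sd / span


def _check_monotone(curve: LabelingCurve, noise_sd: float) -> None:
    # standardized against the noise of a between-sample difference, with the
    # per-curve family-wise level held at the 3-sigma point across intervals
    inc = np.diff(curve.values)
    thr = _sidak_z(len(inc)) * np.sqrt(2.0) * noise_sd
    bad = np.nonzero(inc > thr)[0]
    if bad.size:
        i = bad[0]
        raise NonmonotoneError(
            f"curve {curve.species_id!r} increases by {inc[i]:.4f} on "
            f"[{curve.times[i]:g}, {curve.times[i + 1]:g}] min "
            f"(tolerance {thr:.4f}): not a steady-state wash-out")


def _tail_fit(times: np.ndarray, values: np.ndarray, n_tail: int = 3):
    """Log-linear fit to the last n_tail positive samples: (rate, value at T, T).

    rate > 0 for a decaying tail.  Returns (nan, 0, T) when the tail has
    already hit zero (no mass to extrapolate).
    """
    t_end = times[-1]
    mask = values > 0
    t_pos, v_pos = times[mask], values[mask]
    if len(t_pos) < 2:
        return np.nan, 0.0, t_end
    t_fit, v_fit = t_pos[-n_tail:], v_pos[-n_tail:]
    slope = np.polynomial.polynomial.polyfit(t_fit, np.log(v_fit), 1)[1]
    if values[-1] == 0.0:
        return np.nan, 0.0, t_end
    return -float(slope), float(values[-1]), float(t_end)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def washout_from_stepup(curve: LabelingCurve) -> LabelingCurve:
    """Convert a step-up labeling curve (label accumulating) to wash-out form.

    In a step-up experiment the system starts unlabeled and the labeled
    fraction rises; the complement 1 - f is exactly the wash-out readout, so
    all age-based estimators apply to it unchanged.
    """
    meta = dict(curve.meta)
    meta["converted"] = "step-up -> wash-out (values complemented)"
    return replace(curve, values=1.0 - curve.values, meta=meta)


def mean_age(curve: LabelingCurve, tail: TailPolicy = "exponential",
             noise_sd: float = DEFAULT_NOISE_SD) -> float:
    """Mean metabolic age Abar = area under the labeling curve, in minutes.

    The sampled range contributes by trapezoidal quadrature; the unobserved
    tail beyond the last sample is handled per ``tail``:

    * ``"exponential"`` (default): a log-linear fit to the last three positive
      samples supplies a decay rate r, adding f(T)/r analytically.  Raises
      :class:`TailExtrapolationError` if the terminal samples do not decay.
    * ``"truncate"``: no tail correction (biases Abar down for slow species).
    """
    if len(curve) < 3:
        raise CurveError("mean_age needs at least 3 time points")
    _check_monotone(curve, noise_sd)
    t, v = curve.times, curve.values
    area = float(np.trapezoid(v, t))
    if t[0] > 0:  # account for [0, t0] assuming full labeling at t = 0
        area += float(t[0] * (1.0 + v[0]) / 2.0)
    if tail == "truncate":
        return area
    rate, v_end, _ = _tail_fit(t, v)
    if v_end == 0.0:
        return area
    if not np.isfinite(rate) or rate <= 0:
        raise TailExtrapolationError(
            f"curve {curve.species_id!r}: terminal samples do not decay "
            f"(tail rate {rate:.3g}/min); cannot extrapolate the AUC tail")
    return area + v_end / rate


def median_age(curve: LabelingCurve) -> float:
    """Half-life t_1/2 = median metabolic age: first crossing of f = 1/2.

    Linear interpolation between the bracketing samples; with noisy multiple
    crossings the first one is used.
    """
    t, v = curve.times, curve.values
    below = np.nonzero(v <= 0.5)[0]
    if below.size == 0:
        raise NoCrossingError(
            f"curve {curve.species_id!r} never reaches 1/2 within the "
            f"sampled range (min value {v.min():.3f}): no crossing")
    i = below[0]
    if i == 0:
        return float(t[0])
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    return float(t0 + (v0 - 0.5) * (t1 - t0) / (v0 - v1))


def age_distribution(curve: LabelingCurve,
                     noise_sd: float = DEFAULT_NOISE_SD) -> AgeDistribution:
    """Metabolic age distribution: CDF = 1 - f, PDF = -f' (smoothed).

    Small negative PDF values produced by noise are clipped to zero with a
    warning; a confident increase of f raises :class:`NonmonotoneError`.
    """
    if len(curve) < 3:
        raise CurveError("age_distribution needs at least 3 points")
    _check_monotone(curve, noise_sd)
    _, f1, _ = _local_quadratic(curve.times, curve.values)
    pdf = -f1
    if np.any(pdf < 0):
        worst = pdf.min()
        if worst < -3.0 * noise_sd / max(np.diff(curve.times).min(), 1e-12):
            raise NonmonotoneError(
                f"curve {curve.species_id!r}: smoothed slope positive beyond "
                "noise tolerance")
        warnings.warn(
            f"curve {curve.species_id!r}: clipped small negative age-PDF "
            f"values (min {worst:.3g}) to 0", stacklevel=2)
        pdf = np.clip(pdf, 0.0, None)
    cdf = 1.0 - curve.values
    return AgeDistribution(grid=curve.times.copy(), pdf=pdf, cdf=cdf, kind="age")


def residence_time_distribution(curve: LabelingCurve,
                                growth: GrowthModel = NO_GROWTH,
                                noise_sd: float = DEFAULT_NOISE_SD) -> AgeDistribution:
    """Residence-time distribution from labeling dynamics.

    Survival 1 - P_T(t) = e^{mu t} f'(t)/f'(0); the PDF follows as
    -e^{mu t} (f''(t) + mu f'(t)) / f'(0).  Requires a clearly nonzero
    initial slope (otherwise the input is delayed and the residence-time
    distribution of the observed pool is not identifiable from f alone).
    """
    t, v = curve.times, curve.values
    _check_monotone(curve, noise_sd)
    f0p = _initial_slope(t, v)
    if abs(f0p) < _flat_slope_threshold(t, noise_sd):
        raise FlatInitialSlopeError(
            f"curve {curve.species_id!r}: flat initial slope "
            f"(f'(0) = {f0p:.3g}/min) — delayed input; residence times "
            "require delay compensation")
    if f0p >= 0:
        raise NonmonotoneError(f"curve {curve.species_id!r}: f'(0) > 0")
    mu = growth.mu
    _, f1, f2 = _local_quadratic(t, v)
    egt = np.exp(mu * t)
    survival = egt * f1 / f0p
    survival = np.clip(survival, 0.0, None)
    survival[0] = 1.0
    inc = np.diff(survival)
    slope_tol = 3.0 * noise_sd / max(np.diff(t).min(), 1e-12) / abs(f0p)
    if np.any(inc > slope_tol * np.diff(t)):
        i = int(np.nonzero(inc > slope_tol * np.diff(t))[0][0])
        raise DelayedInputError(
            f"curve {curve.species_id!r}: residence-time survival increases "
            f"on [{t[i]:g}, {t[i + 1]:g}] min — nonconvex labeling, delayed input")
    pdf = -egt * (f2 + mu * f1) / f0p
    pdf = np.clip(pdf, 0.0, None)
    return AgeDistribution(grid=t.copy(), pdf=pdf, cdf=1.0 - survival,
                           kind="residence_time")


def decay_rate_function(curve: LabelingCurve,
                        growth: GrowthModel = NO_GROWTH,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        clip_negative: bool = True) -> DecayRateCurve:
    """Age-dependent decay rate kappa(A) = -f''(A)/f'(A) - mu on the grid.

    Where |f'| falls below tolerance the ratio is undefined and NaN is
    reported.  Small negative rates from noise are clipped at 0 (with a
    warning) unless ``clip_negative`` is False.
    """
    t, v = curve.times, curve.values
    _, f1, f2 = _local_quadratic(t, v)
    tol = noise_sd / max(t[-1] - t[0], 1e-12)
    kappa = np.full_like(f1, np.nan)
    ok = np.abs(f1) > tol
    kappa[ok] = -f2[ok] / f1[ok] - growth.mu
    if clip_negative and np.any(kappa[ok] < 0):
        if np.nanmin(kappa) < -10 * tol:
            warnings.warn(
                f"curve {curve.species_id!r}: negative decay rates clipped "
                f"to 0 (min {np.nanmin(kappa):.3g}/min)", stacklevel=2)
        kappa[ok] = np.clip(kappa[ok], 0.0, None)
    return DecayRateCurve(ages=t.copy(), values=kappa)


def rtl_distribution(curve: LabelingCurve,
                     growth: GrowthModel = NO_GROWTH,
                     noise_sd: float = DEFAULT_NOISE_SD) -> AgeDistribution:
    """Distribution of the residence time of the living (RTL) on the grid.

    The RTL of the particles present at observation has PDF
    (e^{mu t} - 1)(f''(t) + mu f'(t)) / mu, reducing to t f''(t) for a
    constant-size system.  Its mean is Abar + Lbar_r (age plus remaining
    time); for mu = 0 that is exactly twice the mean age.
    """
    t, v = curve.times, curve.values
    _check_monotone(curve, noise_sd)
    _, f1, f2 = _local_quadratic(t, v)
    mu = growth.mu
    if mu > 0:
        pdf = np.expm1(mu * t) * (f2 + mu * f1) / mu
    else:
        pdf = t * f2
    pdf = np.clip(pdf, 0.0, None)
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(t) * (pdf[1:] + pdf[:-1]) / 2)])
    return AgeDistribution(grid=t.copy(), pdf=pdf, cdf=np.clip(cdf, 0.0, 1.0),
                           kind="rtl")


def _growth_weighted_integrals(t, v, f1, mu, tail_rate, v_end):
    """(I_f, I_fp) = (int e^{mu t} f dt, int e^{mu t} f' dt) incl. tails."""
    egt = np.exp(mu * t)
    I_f = float(np.trapezoid(egt * v, t))
    I_fp = float(np.trapezoid(egt * f1, t))
    if t[0] > 0:  # leading segment from a full-labeled start
        I_f += float(t[0] * (1.0 + egt[0] * v[0]) / 2.0)
        I_fp += float(t[0] * (egt[0] * f1[0] + f1[0]) / 2.0)
    if v_end > 0 and np.isfinite(tail_rate) and tail_rate > mu:
        # analytic tails for f ~ v_end e^{-r (t - T)}
        T = t[-1]
        I_f += v_end * np.exp(mu * T) / (tail_rate - mu)
        I_fp += -tail_rate * v_end * np.exp(mu * T) / (tail_rate - mu)
    return I_f, I_fp


def summary_parameters(curve: LabelingCurve,
                       growth: GrowthModel = NO_GROWTH,
                       conditioning_age: float = 0.0,
                       tail: TailPolicy = "exponential",
                       noise_sd: float = DEFAULT_NOISE_SD) -> DynamicParameters:
    """All cumulative dynamic parameters of one species from its curve.

    Age-based quantities (mean age, half-life) need no growth correction;
    the expected decay rate subtracts mu from the initial escape slope; the
    residence-time family uses the e^{mu t} weighting.  Slope-dependent
    fields come back NaN (with the flat-slope semantics) when the initial
    slope is indistinguishable from zero.
    """
    t, v = curve.times, curve.values
    mu = growth.mu
    abar = mean_age(curve, tail=tail, noise_sd=noise_sd)
    try:
        t_half = median_age(curve)
    except NoCrossingError:
        t_half = np.nan

    _, f1, _ = _local_quadratic(t, v)
    tail_rate, v_end, _ = _tail_fit(t, v)
    if tail == "truncate":
        tail_rate, v_end = np.nan, 0.0
    I_f, I_fp = _growth_weighted_integrals(t, v, f1, mu, tail_rate, v_end)

    lr = I_f                       # mean RRTL = int e^{mu t} f dt
    lbar = abar + lr               # mean RTL

    f0p = _initial_slope(t, v)
    flat = abs(f0p) < _flat_slope_threshold(t, noise_sd)
    if flat or f0p >= 0:
        kbar = tbar = np.nan
    else:
        kbar = -f0p - mu
        tbar = I_fp / f0p

    a = float(conditioning_age)
    k_a = t_a = esc_a = np.nan
    if a > 0:
        if a > t[-1]:
            raise CurveError(
                f"conditioning age {a:g} min beyond sampled range {t[-1]:g} min")
        f_a = float(np.interp(a, t, v))
        f1_a = float(np.interp(a, t, f1))
        if f_a > 0 and f1_a < 0:
            esc_a = -f1_a / f_a
            k_a = esc_a - mu
            mask = t >= a
            I_fp_a = float(np.trapezoid(np.exp(mu * t[mask]) * f1[mask], t[mask]))
            # close the [a, first sample >= a] gap and the tail
            t_first = t[mask][0]
            if t_first > a:
                I_fp_a += float((t_first - a)
                                * (np.exp(mu * a) * f1_a
                                   + np.exp(mu * t_first) * f1[mask][0]) / 2.0)
            if v_end > 0 and np.isfinite(tail_rate) and tail_rate > mu:
                I_fp_a += -tail_rate * v_end * np.exp(mu * t[-1]) / (tail_rate - mu)
            t_a = a + I_fp_a / (np.exp(mu * a) * f1_a)
    else:
        k_a, t_a, esc_a = kbar, tbar, (np.nan if np.isnan(kbar) else kbar + mu)

    return DynamicParameters(
        mean_age=abar, half_life=t_half, expected_decay_rate=kbar,
        mean_residence_time=tbar, mean_rtl=lbar, mean_rrtl=lr,
        conditioning_age=a, conditioned_decay_rate=k_a,
        conditioned_residence_time=t_a, conditioned_escape_rate=esc_a)


def _sidak_z(n_tests: int) -> float:
    """Threshold keeping the family-wise false-fire level at the 3-sigma point.

    A single 3-sigma test has one-sided level ~1.35e-3; scanning n_tests
    statistics per curve at that raw level would inflate the per-curve false
    rate n-fold, so the per-test threshold is raised to keep the *curve-wise*
    level at the 3-sigma point (Sidak correction).
    """
    from scipy.stats import norm
    alpha = float(norm.sf(3.0))
    return float(norm.isf(alpha / max(n_tests, 1)))


def _anchor_indices(n: int, max_anchors: int = 16) -> np.ndarray:
    """Comparison anchors for the convexity scan.

    Evenly spaced anchors plus a geometrically spaced early block: delayed-
    input signatures (growing slope magnitude) live at short times, which a
    purely linear subsample of a long dense grid can straddle and miss.
    """
    if n <= max_anchors:
        return np.arange(n)
    linear = np.round(np.linspace(0, n - 1, max_anchors)).astype(int)
    early = np.unique(np.geomspace(1, max(n // 4, 2), 8).astype(int))
    return np.unique(np.concatenate([[0], early, linear]))


def diagnose(curve: LabelingCurve,
             growth: GrowthModel = NO_GROWTH,
             noise_sd: float = DEFAULT_NOISE_SD) -> DiagnosticsReport:
    """Steady-state and delayed-input diagnostics (pure report, no errors).

    Every flag is a 3-sigma decision against the declared measurement noise,
    with the noise propagated into each test statistic and the per-curve
    family-wise level held at the 3-sigma point when several intervals are
    scanned — so flags only fire on departures noise alone cannot plausibly
    produce:

    * nonmonotone — a between-sample increase of f exceeding 3 sd of a
      sample difference: the system is not at steady state;
    * nonconvex — the secant-slope magnitude grows between an earlier and a
      later span (anchor triples over the grid): delayed input;
    * flat_initial_slope — f'(0) indistinguishable from 0: delayed input;
    * slower_than_dilution — f(t) > e^{-mu t}: delayed input (growing systems).
    """
    t, v = curve.times, curve.values
    mu = growth.mu
    rep: dict = {"noise_tolerance_used": noise_sd}

    # nonmonotone: increase beyond 3 sd of a between-sample difference
    inc = np.diff(v)
    thr = 3.0 * np.sqrt(2.0) * noise_sd
    bad = np.nonzero(inc > thr)[0]
    if bad.size:
        i = int(bad[0])
        rep["nonmonotone"] = True
        rep["nonmonotone_interval"] = (float(t[i]), float(t[i + 1]))

    # nonconvex: secant slope over a later span steeper than over an earlier
    # one; anchors bound the number of comparisons on dense grids
    if len(t) >= 3:
        idx = _anchor_indices(len(t))
        ta, va = t[idx], v[idx]
        m = len(ta)
        span = ta[:, None] - ta[None, :]            # span[j, i] = t_j - t_i
        with np.errstate(divide="ignore", invalid="ignore"):
            sec = (va[:, None] - va[None, :]) / span    # sec[j, i]: secant i->j
            inv = 1.0 / span
        # z[i, j, k] for i < j < k: earlier secant minus later secant
        # (> 0 when the curve steepens downward, i.e. nonconvex)
        P = inv.T                                   # P[i, j] = 1/(t_j - t_i) > 0 for i < j
        d = sec.T[:, :, None] - sec[None, :, :]     # sec(i,j) - sec(j,k)
        var = ((P[:, :, None] + P[None, :, :]) ** 2
               + P[:, :, None] ** 2 + P[None, :, :] ** 2)
        z = d / (noise_sd * np.sqrt(var))
        ii, jj, kk = np.meshgrid(np.arange(m), np.arange(m), np.arange(m),
                                 indexing="ij")
        valid = (ii < jj) & (jj < kk)
        z_thr = _sidak_z(int(valid.sum()))
        z = np.where(valid, z, -np.inf)
        best = np.unravel_index(np.argmax(z), z.shape)
        if z[best] > z_thr:
            rep["nonconvex"] = True
            rep["nonconvex_interval"] = (float(ta[best[0]]), float(ta[best[2]]))

        f0p = _initial_slope(t, v)
        if abs(f0p) < _flat_slope_threshold(t, noise_sd):
            rep["flat_initial_slope"] = True

    # slower than dilution: f above the growth-dilution bound e^{-mu t}
    if mu > 0:
        z_thr = _sidak_z(len(t) - 1)
        excess = (v - np.exp(-mu * t)) / noise_sd
        bad = np.nonzero(excess[1:] > z_thr)[0] + 1
        if bad.size:
            rep["slower_than_dilution"] = True
            rep["slower_than_dilution_interval"] = (float(t[bad[0]]),
                                                    float(t[bad[-1]]))

    return DiagnosticsReport(**rep)


def order_by_mean_age(curves: Sequence[LabelingCurve],
                      noise_sd: float = DEFAULT_NOISE_SD,
                      tail: TailPolicy = "exponential"):
    """Order species by increasing mean age (upstream pools first).

    In a metabolic chain the upstream pools are always younger and their
    curves are dominated (f_upstream <= f_downstream at every time), so the
    mean-age ranking recovers the chain order.  Besides the ranking, every
    ordered pair is checked for curve-wise dominance at the shared times
    (within 3 x noise_sd); pairs without dominance are flagged uncertain.

    Returns ``(ranking, pair_report)`` where ranking is a list of species
    ids (ties broken by id) and pair_report maps (id_younger, id_older) to
    a dict with ``dominant`` and ``tie`` flags.
    """
    if len(curves) < 2:
        raise CurveError("ordering needs at least 2 curves")
    ages = {}
    for c in curves:
        try:
            ages[c.species_id] = mean_age(c, tail=tail, noise_sd=noise_sd)
        except TailExtrapolationError:
            ages[c.species_id] = mean_age(c, tail="truncate", noise_sd=noise_sd)
    order = sorted(ages, key=lambda k: (ages[k], k))
    by_id = {c.species_id: c for c in curves}

    lo = max(c.times[0] for c in curves)
    hi = min(c.times[-1] for c in curves)
    grid = np.unique(np.concatenate([
        c.times[(c.times >= lo) & (c.times <= hi)] for c in curves]))

    report = {}
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = order[i], order[j]
            fa = np.interp(grid, by_id[a].times, by_id[a].values)
            fb = np.interp(grid, by_id[b].times, by_id[b].values)
            dominant = bool(np.all(fa <= fb + 3.0 * noise_sd))
            tie = abs(ages[a] - ages[b]) <= 3.0 * noise_sd * max(hi - lo, 1.0) / max(len(grid) - 1, 1)
            report[(a, b)] = {
                "dominant": dominant,
                "tie": tie,
                "mean_ages": (ages[a], ages[b]),
                "order_uncertain": (not dominant) and (not tie),
            }
    return order, report
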