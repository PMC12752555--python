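"""Force-dependent rate laws and rupture-force statistics.

Bell's model gives a single-exponential force dependence of a rate
constant, k(f) = k0 * exp(sign * f * x / kT), with x the distance to the
transition state along the pulling coordinate (sign +1 for unfolding,
-1 for folding).  Under a constant loading rate r the first-rupture force
then follows the Evans-Ritchie distribution, whose survival function is

    S(F) = exp[ (k0 kT)/(x r) * (1 - exp(F x / kT)) ].

This module provides the forward evaluations, exact sampling, and the
estimators used by the analysis pipeline (log-linear weighted fits of
rate-versus-force data, and maximum-likelihood / binned least-squares
fits of rupture-force distributions), plus the derived quantities:
most probable rupture force, critical (coexistence) force, and barrier
height from an assumed attempt rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit, minimize

from .polymer import KBT_ROOM, InvalidParameterError

__all__ = [
    "BellParams",
    "RateEstimate",
    "FitError",
    "bell_rate",
    "evans_ritchie_pdf",
    "evans_ritchie_cdf",
    "most_probable_force",
    "sample_rupture_forces",
    "fit_bell",
    "fit_ramp_distribution",
    "critical_force",
    "barrier_height",
]

UNFOLD = +1
FOLD = -1


@dataclass(frozen=True)
class BellParams:
    """Bell rate-law parameters.

    k0 : zero-force rate constant, 1/s (> 0)
    x  : transition distance, nm (> 0)
    sign : +1 if the rate grows with force (unfolding), -1 if it decays
        (folding)
    k0_err, x_err : optional 1-sigma uncertainties from a fit
    """

    k0: float
    x: float
    sign: int = UNFOLD
    k0_err: float | None = None
    x_err: float | None = None

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise InvalidParameterError("k0 must be > 0")
        if self.x <= 0:
            raise InvalidParameterError("x must be > 0")
        if self.sign not in (UNFOLD, FOLD):
            raise InvalidParameterError("sign must be +1 or -1")

    def with_(self, **kwargs) -> "BellParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RateEstimate:
    """A rate constant measured at one force."""

    force: float
    rate: float
    stderr: float | None = None
    n_events: int = 1

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")
        if self.n_events < 1:
            raise InvalidParameterError("n_events must be >= 1")


class FitError(RuntimeError):
    """Raised when an estimator cannot produce a valid fit."""


def bell_rate(force, params: BellParams, thermal_energy: float = KBT_ROOM):
    """Evaluate k(f) = k0 * exp(sign * f * x / kT).

    Computed in log space so that large exponents degrade gracefully to
    inf rather than raising.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("force must be >= 0")
    log_k = np.log(params.k0) + params.sign * f * params.x / thermal_energy
    with np.errstate(over="ignore"):
        out = np.exp(log_k)
    return float(out) if out.ndim == 0 else out


def _er_exponent(force, k0, x, r, kbt):
    """log of the Evans-Ritchie survival function."""
    return (k0 * kbt) / (x * r) * (1.0 - np.exp(force * x / kbt))


def evans_ritchie_pdf(rupture_force, params: BellParams, loading_rate: float,
                      thermal_energy: float = KBT_ROOM):
    """Density of first-rupture forces at constant loading rate.

    p(F) = k(F)/r * exp[(k0 kT)/(x r) * (1 - e^{F x / kT})], F >= 0.
    """
    if loading_rate <= 0:
        raise InvalidParameterError("loading_rate must be > 0")
    f = np.asarray(rupture_force, dtype=float)
    k0, x, kbt = params.k0, params.x, thermal_energy
    with np.errstate(over="ignore", under="ignore"):
        log_p = (np.log(k0) + f * x / kbt - np.log(loading_rate)
                 + _er_exponent(f, k0, x, loading_rate, kbt))
        out = np.where(f < 0, 0.0, np.exp(log_p))
    return float(out) if out.ndim == 0 else out


def evans_ritchie_cdf(rupture_force, params: BellParams, loading_rate: float,
                      thermal_energy: float = KBT_ROOM):
    """P(F_rupture <= F) for the Evans-Ritchie distribution."""
    if loading_rate <= 0:
        raise InvalidParameterError("loading_rate must be > 0")
    f = np.asarray(rupture_force, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        surv = np.exp(_er_exponent(f, params.k0, params.x, loading_rate,
                                   thermal_energy))
        out = np.where(f < 0, 0.0, 1.0 - surv)
    return float(out) if out.ndim == 0 else out


def most_probable_force(params: BellParams, loading_rate: float,
                        thermal_energy: float = KBT_ROOM) -> float:
    """Mode of the rupture-force distribution.

    F* = (kT/x) * ln( x r / (k0 kT) ), clamped at 0 when the argument of
    the logarithm is <= 1 (rupture is immediate at the ramp start).
    """
    if loading_rate <= 0:
        raise InvalidParameterError("loading_rate must be > 0")
    arg = params.x * loading_rate / (params.k0 * thermal_energy)
    if arg <= 1.0:
        return 0.0
    return (thermal_energy / params.x) * np.log(arg)


def sample_rupture_forces(n: int, params: BellParams, loading_rate: float,
                          seed: int | np.random.Generator,
                          thermal_energy: float = KBT_ROOM) -> np.ndarray:
    """Draw rupture forces by exact inversion of the survival function.

    F = (kT/x) * ln(1 - (x r)/(k0 kT) * ln U), U ~ Uniform(0, 1).
    Deterministic given the seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if loading_rate <= 0:
        raise InvalidParameterError("loading_rate must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    u = rng.uniform(size=n)
    k0, x, kbt = params.k0, params.x, thermal_energy
    return (kbt / x) * np.log1p(-(x * loading_rate) / (k0 * kbt) * np.log(u))


def fit_bell(rates: list[RateEstimate],
             thermal_energy: float = KBT_ROOM) -> BellParams:
    """Weighted log-linear fit of rate-versus-force data to Bell's model.

    ln k is regressed on force; weights follow from the delta method,
    var(ln k) = (stderr/rate)^2.  The slope sign fixes the branch
    (+: unfolding, -: folding); its magnitude times kT gives x.
    """
    if len(rates) < 3:
        raise FitError("need at least 3 rate estimates at distinct forces")
    f = np.array([r.force for r in rates], dtype=float)
    if len(np.unique(f)) < 3:
        raise FitError("need at least 3 distinct forces")
    y = np.log([r.rate for r in rates])
    var = np.array([
        (r.stderr / r.rate) ** 2 if (r.stderr is not None and r.stderr > 0)
        else 1.0
        for r in rates
    ])
    w = 1.0 / var
    design = np.column_stack([np.ones_like(f), f])
    xtw = design.T * w
    normal = xtw @ design
    try:
        cov = np.linalg.inv(normal)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise FitError("singular design matrix") from exc
    beta = cov @ (xtw @ y)
    intercept, slope = beta
    if slope == 0:
        raise FitError("zero slope: force dependence unresolved")
    sign = UNFOLD if slope > 0 else FOLD
    x = abs(slope) * thermal_energy
    k0 = float(np.exp(intercept))
    se_int, se_slope = np.sqrt(np.diag(cov))
    return BellParams(k0=k0, x=float(x), sign=sign,
                      k0_err=float(k0 * se_int),
                      x_err=float(se_slope * thermal_energy))


def _er_nll(theta, forces, loading_rate, kbt):
    log_k0, log_x = theta
    k0, x = np.exp(log_k0), np.exp(log_x)
    log_p = (log_k0 + forces * x / kbt - np.log(loading_rate)
             + _er_exponent(forces, k0, x, loading_rate, kbt))
    return -np.sum(log_p)


def _fit_ramp_mle(forces, loading_rate, kbt):
    # Moment initialization: the rupture-force law is Gumbel-like with
    # scale kT/x, so x0 from the sample s.d. and k0 from the mode formula
    sd = max(np.std(forces), 1e-3)
    x0 = kbt * np.pi / (np.sqrt(6.0) * sd)
    mode0 = max(np.mean(forces) - 0.5772 * kbt / x0, 0.5)
    k0_init = x0 * loading_rate / (kbt * np.exp(mode0 * x0 / kbt))
    res = minimize(_er_nll, x0=[np.log(k0_init), np.log(x0)],
                   args=(forces, loading_rate, kbt), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise FitError(f"rupture-distribution MLE did not converge: {res}")
    k0, x = np.exp(res.x)
    return float(k0), float(x)


def _fit_ramp_histogram(forces, loading_rate, kbt, bin_width):
    lo = np.floor(forces.min() / bin_width) * bin_width
    hi = np.ceil(forces.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(forces, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(f, log_k0, log_x):
        p = BellParams(k0=float(np.exp(log_k0)), x=float(np.exp(log_x)))
        return evans_ritchie_pdf(f, p, loading_rate, kbt)

    k0_init, x_init = _fit_ramp_mle(forces, loading_rate, kbt)
    try:
        popt, _ = curve_fit(model, centers, density,
                            p0=[np.log(k0_init), np.log(x_init)],
                            maxfev=10000)
    except RuntimeError as exc:
        raise FitError("histogram least-squares fit did not converge") from exc
    k0, x = np.exp(popt)
    return float(k0), float(x)


def fit_ramp_distribution(forces, loading_rate: float,
                          thermal_energy: float = KBT_ROOM,
                          method: str = "mle",
                          bin_width: float = 1.0,
                          n_bootstrap: int = 200,
                          seed: int | np.random.Generator = 0) -> BellParams:
    """Fit (k0, x) of the rupture-force distribution.

    method="mle" (default) maximizes the Evans-Ritchie likelihood in log
    parameters; method="histogram" least-squares fits the binned density
    (left-closed bins of ``bin_width`` pN).  Standard errors come from
    ``n_bootstrap`` nonparametric resamples (0 disables them).
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 20:
        raise FitError("need at least 20 rupture forces")
    if np.any(forces < 0):
        raise FitError("rupture forces must be >= 0")
    fitter = {"mle": _fit_ramp_mle,
              "histogram": lambda f, r, k: _fit_ramp_histogram(f, r, k,
                                                               bin_width)}
    if method not in fitter:
        raise ValueError(f"unknown method {method!r}")
    k0, x = fitter[method](forces, loading_rate, thermal_energy)
    k0_err = x_err = None
    if n_bootstrap > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        boot = []
        for _ in range(n_bootstrap):
            resample = rng.choice(forces, size=forces.size, replace=True)
            try:
                boot.append(fitter[method](resample, loading_rate,
                                           thermal_energy))
            except FitError:
                continue
        if len(boot) >= max(10, n_bootstrap // 2):
            boot = np.array(boot)
            k0_err = float(np.std(boot[:, 0], ddof=1))
            x_err = float(np.std(boot[:, 1], ddof=1))
    return BellParams(k0=k0, x=x, sign=UNFOLD, k0_err=k0_err, x_err=x_err)


def critical_force(unfold: BellParams, fold: BellParams,
                   thermal_energy: float = KBT_ROOM) -> float:
    """Force at which the folding and unfolding rate laws cross.

    f_c = kT * ln(k_f0 / k_u0) / (x_u + x_f).  Returns 0 with a warning
    when folding never outruns unfolding (k_f0 <= k_u0).
    """
    if fold.sign != FOLD or unfold.sign != UNFOLD:
        raise InvalidParameterError(
            "expected unfold.sign=+1 and fold.sign=-1")
    if fold.k0 <= unfold.k0:
        warnings.warn("k_f0 <= k_u0: no coexistence force, returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return thermal_energy * np.log(fold.k0 / unfold.k0) / (unfold.x + fold.x)


def barrier_height(k0: float, attempt_rate: float,
                   thermal_energy: float = KBT_ROOM) -> float:
    """Barrier height (k_B T units) from k0 = k* exp(-dG/kT).

    dG = ln(k*/k0).  ``thermal_energy`` is accepted for interface
    symmetry; the result is already expressed in k_B T.
    """
    if k0 <= 0:
        raise InvalidParameterError("k0 must be > 0")
    if k0 > attempt_rate:
        raise InvalidParameterError("k0 must not exceed the attempt rate")
    return float(np.log(attempt_rate / k0))
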