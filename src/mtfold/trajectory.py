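"""Bead-height trajectory analysis: state assignment and dwell kinetics.

The constant-force workflow mirrors the standard two-state analysis:
moving-average smoothing for display/histograms, a two-Gaussian occupancy
fit giving the unfolding probability, a two-state Gaussian hidden Markov
model (Baum-Welch + Viterbi, run on the raw samples) for the state path,
run-length dwell extraction with boundary censoring, and exponential
survival fits giving the rate constant at each force.  Ramps and jumps
use a two-window change-point detector for discrete extension steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .kinetics import RateEstimate
from .polymer import InvalidParameterError
from .simulate import STATE_N, STATE_U, Trajectory

__all__ = [
    "OccupancyFit",
    "DwellRecord",
    "StepEvent",
    "DegenerateFitError",
    "HmmConvergenceError",
    "smooth",
    "fit_occupancy",
    "hmm_segment",
    "extract_dwells",
    "survival_fit",
    "detect_steps",
]


class DegenerateFitError(RuntimeError):
    """Two-component fit collapsed onto a single population."""


class HmmConvergenceError(RuntimeError):
    """Baum-Welch failed to converge; carries the likelihood trace."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history or [])


@dataclass(frozen=True)
class OccupancyFit:
    """Two-Gaussian fit of the (smoothed) height histogram."""

    mean_N: float
    mean_U: float
    sigma_N: float
    sigma_U: float
    weight_U: float

    def __post_init__(self) -> None:
        if not self.mean_U > self.mean_N:
            raise InvalidParameterError("mean_U must exceed mean_N")
        if not 0.0 <= self.weight_U <= 1.0:
            raise InvalidParameterError("weight_U must be in [0, 1]")


@dataclass(frozen=True)
class DwellRecord:
    """One uninterrupted residence in a state."""

    state: str  # "N" or "U"
    duration: float
    force: float
    censored: bool = False


@dataclass(frozen=True)
class StepEvent:
    """A detected discrete height change."""

    time: float
    force: float
    size: float  # signed, nm
    index: int
    reliable: bool = True


def _heights(traj) -> np.ndarray:
    return traj.height if isinstance(traj, Trajectory) else np.asarray(traj,
                                                                      float)


def smooth(trajectory, window: int) -> np.ndarray:
    """Centered moving average; shrinking windows at the edges keep the
    output the same length as the input."""
    h = _heights(trajectory)
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    if window > len(h):
        raise InvalidParameterError("window exceeds trace length")
    if window == 1:
        return h.copy()
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    csum = np.concatenate([[0.0], np.cumsum(h)])
    n = len(h)
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _histogram_mode_init(h: np.ndarray) -> tuple[float, float]:
    """Locate the two highest well-separated histogram modes for EM
    initialization; falls back to the 25/75 percentiles."""
    counts, edges = np.histogram(h, bins=80)
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(counts)[::-1]
    first = centers[order[0]]
    min_sep = 0.15 * (h.max() - h.min())
    for j in order[1:]:
        if abs(centers[j] - first) >= min_sep and counts[j] > 0:
            return tuple(sorted((first, centers[j])))
    return tuple(np.percentile(h, [25, 75]))


def fit_occupancy(heights, min_separation_sigma: float = 0.5) -> OccupancyFit:
    """Two-component Gaussian mixture of (smoothed) heights by EM.

    The fraction in the upper component is the unfolding probability P_u.
    Raises ``DegenerateFitError`` when the components are not resolved
    (means closer than ``min_separation_sigma`` pooled sigmas).
    """
    from sklearn.mixture import GaussianMixture

    h = _heights(heights)
    if h.size < 1000:
        raise InvalidParameterError("need at least 1000 samples")
    m0, m1 = _histogram_mode_init(h)
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         means_init=np.array([[m0], [m1]]),
                         random_state=0, n_init=1, max_iter=500)
    gm.fit(h.reshape(-1, 1))
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    pooled = np.sqrt(0.5 * (sigmas[lo] ** 2 + sigmas[hi] ** 2))
    if (means[hi] - means[lo]) < min_separation_sigma * pooled or \
            min(weights) < 1e-4:
        raise DegenerateFitError(
            f"mixture collapsed: means {means[lo]:.3g}/{means[hi]:.3g}, "
            f"pooled sigma {pooled:.3g}, weights {weights}")
    # a genuine two-state population must be bimodal: the mixture density
    # needs a dip between the component means (a split single Gaussian
    # has none)
    grid = np.linspace(means[lo], means[hi], 200)
    dens = (weights[lo] / sigmas[lo]
            * np.exp(-0.5 * ((grid - means[lo]) / sigmas[lo]) ** 2)
            + weights[hi] / sigmas[hi]
            * np.exp(-0.5 * ((grid - means[hi]) / sigmas[hi]) ** 2))
    if dens[1:-1].min() > 0.95 * min(dens[0], dens[-1]):
        raise DegenerateFitError(
            "mixture density has no dip between components: population "
            "appears single-state")
    return OccupancyFit(mean_N=float(means[lo]), mean_U=float(means[hi]),
                        sigma_N=float(sigmas[lo]), sigma_U=float(sigmas[hi]),
                        weight_U=float(weights[hi]))


def hmm_segment(trajectory, n_iter: int = 500, tol: float = 1e-4):
    """Two-state Gaussian HMM on the raw heights.

    Emission and transition parameters are learned by Baum-Welch
    (initialized from the occupancy fit) and the most-likely state path
    is decoded by Viterbi.  States are ordered by emission mean, so 0 is
    always N (low) and 1 is U (high).

    Returns (state_path, info) where info carries the fitted means,
    sigmas and transition matrix.
    """
    from hmmlearn.hmm import GaussianHMM

    h = _heights(trajectory)
    # noiseless traces have (near-)zero within-state variance and break
    # EM; a midpoint threshold is then exact
    if np.unique(h).size <= 4:
        mid = 0.5 * (h.min() + h.max())
        path = (h > mid).astype(np.int8)
        info = {"means": np.array([h.min(), h.max()]),
                "sigmas": np.zeros(2), "transmat": None, "converged": True}
        return path, info
    try:
        occ = fit_occupancy(h if h.size >= 1000 else np.resize(h, 1000))
        means0 = np.array([occ.mean_N, occ.mean_U])
        sig0 = np.array([occ.sigma_N, occ.sigma_U])
    except DegenerateFitError:
        means0 = np.percentile(h, [30, 70])
        sig0 = np.full(2, np.std(h))
    model = GaussianHMM(n_components=2, covariance_type="diag",
                        n_iter=n_iter, tol=tol, init_params="",
                        params="stmc")
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.999, 0.001], [0.001, 0.999]])
    model.means_ = means0.reshape(-1, 1)
    model.covars_ = np.maximum(sig0, 1e-3).reshape(-1, 1) ** 2
    X = h.reshape(-1, 1)
    import logging

    hmm_log = logging.getLogger("hmmlearn.base")
    old_level = hmm_log.level
    hmm_log.setLevel(logging.ERROR)  # float-precision EM deltas are noise
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
    finally:
        hmm_log.setLevel(old_level)
    if not model.monitor_.converged:
        raise HmmConvergenceError(
            f"Baum-Welch did not converge in {n_iter} iterations",
            history=model.monitor_.history)
    path = model.predict(X)
    means = model.means_.ravel()
    order = np.argsort(means)
    remap = np.empty(2, dtype=np.int8)
    remap[order] = [STATE_N, STATE_U]
    path = remap[path]
    info = {
        "means": means[order],
        "sigmas": np.sqrt(model.covars_.ravel())[order],
        "transmat": model.transmat_[np.ix_(order, order)],
        "converged": True,
    }
    return path, info


def extract_dwells(state_path, sampling_rate: float, force: float,
                   min_duration: float = 0.0) -> list[DwellRecord]:
    """Run-length encode a decoded state path into dwell records.

    The first and last dwells touch the trace boundary and are flagged
    censored.  ``min_duration`` optionally drops shorter dwells.
    """
    path = np.asarray(state_path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    labels = np.array(["N", "U"])
    out = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        dur = (e - s) / sampling_rate
        censored = (i == 0) or (i == len(starts) - 1)
        if dur < min_duration and not censored:
            continue
        out.append(DwellRecord(state=str(labels[path[s]]), duration=dur,
                               force=force, censored=censored))
    return out


def survival_fit(dwells: list[DwellRecord], method: str = "mle",
                 include_censored: bool = False,
                 t_min: float = 0.0) -> RateEstimate:
    """Exponential rate from a set of dwells in one state at one force.

    Default is the closed-form MLE k = n / sum(t) on uncensored dwells
    with stderr k/sqrt(n).  method="cumulative" instead least-squares
    fits the empirical cumulative distribution to 1 - exp(-k t), the
    binned-survival convention.  ``include_censored=True`` switches to
    the censoring-aware MLE k = n_uncensored / sum(all t).

    When the dwells were extracted with a minimum-dwell filter, pass the
    same cutoff as ``t_min``: the memoryless property makes
    k = n / sum(t - t_min) the unbiased conditional MLE.
    """
    if not dwells:
        raise InvalidParameterError("no dwells supplied")
    states = {d.state for d in dwells}
    if len(states) > 1:
        raise InvalidParameterError(
            f"dwells mix states {states}; filter to one state first")
    uncens = [d for d in dwells if not d.censored]
    if not uncens:
        raise InvalidParameterError("all dwells are censored")
    if len(uncens) < 10:
        warnings.warn(f"only {len(uncens)} uncensored dwells; rate estimate "
                      "will be noisy", RuntimeWarning, stacklevel=2)
    t_unc = np.array([d.duration for d in uncens]) - t_min
    if np.any(t_unc < 0):
        raise InvalidParameterError("dwells shorter than t_min present")
    n = len(t_unc)
    total = (sum(d.duration - t_min for d in dwells) if include_censored
             else t_unc.sum())
    k_mle = n / total
    if method == "mle":
        k = k_mle
    elif method == "cumulative":
        ts = np.sort(t_unc)
        ecdf = np.arange(1, n + 1) / n

        def model(t, k):
            return 1.0 - np.exp(-k * t)

        popt, _ = curve_fit(model, ts, ecdf, p0=[k_mle], maxfev=5000)
        k = float(popt[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    force = float(np.mean([d.force for d in uncens]))
    return RateEstimate(force=force, rate=float(k),
                        stderr=float(k / np.sqrt(n)), n_events=n)


def detect_steps(trajectory: Trajectory, threshold_sigma: float = 5.0,
                 window: int = 20, refine_window: int = 100,
                 ) -> list[StepEvent]:
    """Two-window change-point detection of discrete height steps.

    The detection statistic at sample i is the mean over the next
    ``window`` samples minus the mean over the previous ``window``; its
    noise scale is sigma * sqrt(2/window) with sigma estimated robustly
    from first differences.  Peaks above ``threshold_sigma`` times that
    scale, separated by at least ``window`` samples, are events.  Step
    sizes are refined with means over up to ``refine_window`` samples on
    each side.  Events closer than ``window`` to a trace edge are flagged
    unreliable.
    """
    h = trajectory.height
    n = len(h)
    if n < 4:
        return []
    w = min(window, n // 2)
    sigma = 1.4826 * np.median(np.abs(np.diff(h))) / np.sqrt(2.0)
    sigma = max(sigma, 1e-12)
    csum = np.concatenate([[0.0], np.cumsum(h)])
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    hi = np.minimum(idx + w, n)
    n_before = np.maximum(idx - lo, 1)
    n_after = np.maximum(hi - idx, 1)
    mean_before = (csum[idx] - csum[lo]) / n_before
    mean_after = (csum[hi] - csum[idx]) / n_after
    d = mean_after - mean_before
    d[0] = d[-1] = 0.0
    # per-sample noise scale: edge windows are shorter and noisier
    local_sd = sigma * np.sqrt(1.0 / n_before + 1.0 / n_after)
    stat = np.abs(d) / local_sd
    peaks, _ = find_peaks(stat, height=threshold_sigma, distance=w)
    events: list[StepEvent] = []
    for j, p in enumerate(peaks):
        rw = refine_window
        left_lim = peaks[j - 1] if j > 0 else 0
        right_lim = peaks[j + 1] if j + 1 < len(peaks) else n
        a0 = max(p - rw, left_lim, 0)
        b1 = min(p + rw, right_lim, n)
        guard = 2
        before = h[a0:max(p - guard, a0 + 1)]
        after = h[min(p + guard, b1 - 1):b1]
        size = float(np.mean(after) - np.mean(before))
        reliable = (p >= w) and (p <= n - w) and len(before) >= w // 2 \
            and len(after) >= w // 2
        events.append(StepEvent(time=float(trajectory.time[p]),
                                force=float(trajectory.force[p]),
                                size=size, index=int(p), reliable=reliable))
    return events
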