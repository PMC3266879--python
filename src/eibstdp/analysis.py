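"""Estimators and summaries for the learning experiments.

Spike-triggered averages and the exponential-dip fit that extracts the
linear-response kernel, the temporal evolution of the weight density over
repeated runs, trailing-window asymptotic weights, excitation/inhibition
balance regressions, and the subgroup segregation index of excitatory
learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from .meanfield import GammaKernel

__all__ = [
    "STACurve",
    "DensityEvolution",
    "BalanceSummary",
    "spike_triggered_average",
    "fit_gamma",
    "weight_density_evolution",
    "count_modes",
    "asymptotic_weight",
    "balance_regression",
    "segregation_index",
]


@dataclass
class STACurve:
    """Conditional presynaptic rate around postsynaptic spikes.

    ``lags`` are lag-bin centres in ms; negative lags mean the presynaptic
    spike preceded the postsynaptic one.  ``conditional_rate`` is in
    spikes/s.
    """

    lags: np.ndarray
    conditional_rate: np.ndarray
    n_post_spikes: int
    pre_rate: float        # marginal presynaptic rate, spikes/s
    post_rate: float       # marginal postsynaptic rate, spikes/s

    def __post_init__(self):
        if np.any(self.conditional_rate < 0):
            raise ValueError("conditional rates must be non-negative")
        if not np.allclose(self.lags, -self.lags[::-1]):
            raise ValueError("lags must be symmetric around zero")


@dataclass
class DensityEvolution:
    """Weight probability density per (time, weight-bin)."""

    time_points: np.ndarray   # minutes
    bin_edges: np.ndarray     # len n_bins + 1, on [0, 1]
    density: np.ndarray       # (n_times, n_bins), integrates to 1 per slice

    def log_density(self, floor: float = 1e-3) -> np.ndarray:
        return np.log10(np.maximum(self.density, floor))


@dataclass
class BalanceSummary:
    """OLS summary of asymptotic inhibition against excitatory drive."""

    points: np.ndarray        # (n, 2): (drive, asymptotic weight)
    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple[float, float]
    n_in_range: int

    @property
    def drive_axis_intercept(self) -> float:
        """Drive at which the regression line crosses zero weight."""
        return -self.intercept / self.slope


def spike_triggered_average(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    duration: float,
    window: float = 100.0,
    bin_width: float = 1.0,
) -> STACurve:
    """Average presynaptic rate in lag bins around each postsynaptic spike.

    Parameters
    ----------
    pre_times, post_times
        Sorted spike times in ms.
    duration
        Recording length in ms (for marginal rates and edge handling).
    window
        Half-width of the lag window, ms.
    bin_width
        Lag resolution, ms.

    Post spikes whose window is truncated by the recording edges are
    excluded so every lag bin averages over the same number of triggers.
    """
    pre_times = np.asarray(pre_times, dtype=float)
    post_times = np.asarray(post_times, dtype=float)
    if post_times.size == 0:
        raise ValueError("no postsynaptic spikes: STA undefined")
    triggers = post_times[(post_times >= window) & (post_times <= duration - window)]
    if triggers.size == 0:
        raise ValueError("no postsynaptic spikes away from the edges")
    nb = int(round(2 * window / bin_width))
    edges = np.linspace(-window, window, nb + 1)
    counts = np.zeros(nb)
    lo = np.searchsorted(pre_times, triggers - window)
    hi = np.searchsorted(pre_times, triggers + window)
    for t, a, b in zip(triggers, lo, hi):
        d = pre_times[a:b] - t
        counts += np.histogram(d, bins=edges)[0]
    rate = counts / (triggers.size * bin_width / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return STACurve(
        lags=centers,
        conditional_rate=rate,
        n_post_spikes=int(triggers.size),
        pre_rate=pre_times.size / (duration / 1000.0),
        post_rate=post_times.size / (duration / 1000.0),
    )


def fit_gamma(sta: STACurve, w: float, max_latency: float = 10.0) -> GammaKernel:
    """Fit the inhibitory linear-response dip from an STA curve.

    The conditional *postsynaptic* rate a time s after an inhibitory
    presynaptic spike relates to the STA by Bayes' rule,
    ``sta(-s) = r_pre * (nu - w*Gamma(s)) / nu``, so the dip of the STA
    below ``r_pre`` at negative lags estimates ``w * Gamma``.  The latency
    is fixed at the zero-crossing of the dip nearest the trigger; the
    amplitude (per unit weight, in postsynaptic-rate units) and decay
    constant are then least-squares optimised.
    """
    if w <= 0:
        raise ValueError("fit requires a positive synaptic weight")
    neg = sta.lags < 0
    s = -sta.lags[neg][::-1]            # time since pre spike, ascending
    rate = sta.conditional_rate[neg][::-1]
    dip = sta.pre_rate - rate           # positive inside the dip
    if dip.max() <= 0:
        raise ValueError("no dip present: conditional rate never drops below r_pre")
    # latency fixed at the zero crossing nearest the trigger: the last
    # pre-peak sample indistinguishable from zero (2 x the noise floor of
    # the flat positive-lag side)
    pos = sta.conditional_rate[sta.lags > 0]
    noise = float(np.std(pos - sta.pre_rate)) if pos.size else 0.0
    guard = max(2.0 * noise, 0.02 * dip.max())
    k_peak = int(np.argmax(dip[: max(1, int(np.ceil(max_latency / (s[1] - s[0]))))]))
    latency = 0.0
    for k in range(k_peak, -1, -1):
        if dip[k] <= guard:
            latency = s[k]
            break

    def model(t, amp, tau):
        out = amp * np.exp(-(t - latency) / tau)
        return np.where(t >= latency, out, 0.0)

    # fit strictly inside the dip: the crossing sample itself straddles the
    # onset and would bias the amplitude down
    bin_w = s[1] - s[0]
    mask = (s > latency + 0.51 * bin_w) & (s <= latency + 200.0)
    try:
        p0 = (max(dip.max(), 1e-3), 10.0)
        (amp, tau), pcov = optimize.curve_fit(
            model, s[mask], dip[mask], p0=p0,
            bounds=((0.0, 0.1), (np.inf, 1000.0)), maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise ValueError(f"gamma fit did not converge: {err}") from err
    resid = float(np.sqrt(np.mean((model(s[mask], amp, tau) - dip[mask]) ** 2)))
    # convert the STA dip (presynaptic-rate units) to a postsynaptic rate
    # dip per unit weight
    amplitude = float(amp) * sta.post_rate / (sta.pre_rate * w)
    return GammaKernel(amplitude=amplitude, decay_tau=float(tau),
                       latency=float(latency), fit_residual=resid)


def weight_density_evolution(
    trajectories: np.ndarray,
    time_points: np.ndarray,
    n_bins: int = 100,
) -> DensityEvolution:
    """Normalised weight histogram per time point over repeated runs.

    ``trajectories`` has shape (n_runs, n_times); every time slice of the
    result integrates to one over [0, 1].
    """
    trajectories = np.asarray(trajectories, dtype=float)
    time_points = np.asarray(time_points, dtype=float)
    if trajectories.ndim != 2 or trajectories.shape[1] != time_points.size:
        raise ValueError("trajectories must be (n_runs, n_times) matching time_points")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    dens = np.empty((time_points.size, n_bins))
    for k in range(time_points.size):
        h, _ = np.histogram(np.clip(trajectories[:, k], 0, 1), bins=edges, density=True)
        dens[k] = h
    return DensityEvolution(time_points=time_points, bin_edges=edges, density=dens)


def count_modes(density_slice: np.ndarray, bin_edges: np.ndarray,
                bandwidth: float = 0.02) -> int:
    """Number of strict local maxima of a kernel-smoothed density slice.

    The histogram is smoothed with a Gaussian of width ``bandwidth`` (in
    weight units) before counting, so sampling noise does not create
    spurious modes.
    """
    bw_bins = bandwidth / (bin_edges[1] - bin_edges[0])
    sm = ndimage.gaussian_filter1d(density_slice.astype(float), bw_bins, mode="nearest")
    interior = (sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:])
    modes = int(np.count_nonzero(interior))
    # boundary bins can host a mode too (clipped weight piles up there)
    if sm[0] > sm[1]:
        modes += 1
    if sm[-1] > sm[-2]:
        modes += 1
    return modes


def asymptotic_weight(
    trajectory: np.ndarray, trailing_fraction: float = 0.25
) -> tuple[float, float]:
    """Mean and SD of a weight trajectory over its trailing window.

    The default window is the last quarter of the run (e.g. the last 600
    minutes of a 2400-minute simulation).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if not 0 < trailing_fraction <= 1:
        raise ValueError("trailing_fraction must lie in (0, 1]")
    n = trajectory.shape[-1]
    k = int(np.floor(n * trailing_fraction))
    if k < 1:
        raise ValueError("trailing window longer than trajectory")
    tail = trajectory[..., n - k:]
    return float(tail.mean()), float(tail.std())


def balance_regression(
    points: np.ndarray, fit_range: tuple[float, float] = (0.5, 0.85)
) -> BalanceSummary:
    """OLS of asymptotic inhibitory weight against excitatory drive.

    Only points whose *weight* lies inside ``fit_range`` enter the fit
    (outside it the integrate-and-fire nonlinearity bends the relation).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    lo, hi = fit_range
    sel = (points[:, 1] >= lo) & (points[:, 1] <= hi)
    if sel.sum() < 3:
        raise ValueError(
            f"only {int(sel.sum())} points inside fit range {fit_range}; need >= 3"
        )
    res = stats.linregress(points[sel, 0], points[sel, 1])
    return BalanceSummary(
        points=points,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        fit_range=(lo, hi),
        n_in_range=int(sel.sum()),
    )


def segregation_index(
    weights: np.ndarray, group_labels: np.ndarray
) -> tuple[float, float]:
    """Absolute difference between the two subgroup mean weights.

    ``weights`` is either a vector (one snapshot) or an array
    (n_synapses, n_times) of trailing-window samples; the SD is the
    dispersion of the per-time index over that window (0 for a snapshot).
    """
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly two subgroups required, got {uniq.size}")
    a = weights[labels == uniq[0]]
    b = weights[labels == uniq[1]]
    diff = np.abs(a.mean(axis=0) - b.mean(axis=0))
    if diff.ndim == 0:
        return float(diff), 0.0
    return float(diff.mean()), float(diff.std())
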