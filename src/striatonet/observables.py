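"""Macroscopic biomarkers of striatal network activity.

* mean network activity <a>_T: population spike count on a sliding T = 10 ms
  window, expressed as spikes per neuron per second (Hz);
* mean membrane voltage V(t) and its power spectrum |P(f)| = |X(f)|^2 with
  optional Gaussian smoothing — the rhythmicity biomarker (indirectly
  related to the LFP);
* gamma band fraction: spectral area in [30, 80] Hz over [0, 300] Hz;
* phase synchronisation index r_sync(t): modulus of the population mean of
  unit phasors built from linearly interpolated spike phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ActivityTrace",
    "Spectrum",
    "SyncTrace",
    "mean_activity",
    "mean_voltage",
    "power_spectrum",
    "band_fraction",
    "sync_index",
]


@dataclass
class ActivityTrace:
    """Mean network activity in Hz per neuron on T-ms windows."""

    t: np.ndarray  # left edges of windows, ms
    rate: np.ndarray  # Hz per neuron
    window: float  # T, ms
    n_neurons: int

    def time_mean(self) -> float:
        return float(self.rate.mean())


def mean_activity(
    spikes: list[np.ndarray],
    n_neurons: int,
    duration: float,
    window: float = 10.0,
    bin_width: float = 0.1,
) -> ActivityTrace:
    """Average network activation rate per T-ms window.

    Follows the two-step scaling of the rate definition: the population
    spike count per window is divided by the number of ``bin_width`` bins in
    the window (count per 0.1 ms bin), multiplied by 10,000 (per second),
    and divided by the population size (per neuron, Hz).  The time mean over
    the run therefore equals total spikes / (N * duration).
    """
    if n_neurons <= 0:
        raise ValueError("population size N must be positive")
    all_spikes = np.concatenate([np.asarray(s) for s in spikes]) if spikes else np.array([])
    if all_spikes.size and (all_spikes.min() < 0 or all_spikes.max() > duration + 1e-9):
        raise ValueError("spike times outside the run horizon")
    n_win = int(round(duration / window))
    edges = np.arange(n_win + 1) * window
    counts, _ = np.histogram(all_spikes, bins=edges)
    n_bins = window / bin_width  # 100 for the default 10 ms window
    per_bin = counts / n_bins
    rate = per_bin * (1000.0 / bin_width) / n_neurons
    return ActivityTrace(t=edges[:-1], rate=rate, window=window, n_neurons=n_neurons)


def mean_voltage(V_traces: np.ndarray) -> np.ndarray:
    """Arithmetic mean over neurons of aligned membrane traces (rows)."""
    V = np.asarray(V_traces, float)
    if V.ndim != 2:
        raise ValueError("expected a (neurons, time) array of aligned traces")
    return V.mean(axis=0)


@dataclass
class Spectrum:
    f: np.ndarray  # Hz
    power: np.ndarray  # |X(f)|^2, mean-removed signal
    smoothed: np.ndarray | None = None

    def peak_frequency(self, f_min: float = 1.0, f_max: float | None = None) -> float:
        """Argmax frequency of the (smoothed, if available) spectrum."""
        p = self.smoothed if self.smoothed is not None else self.power
        mask = self.f >= f_min
        if f_max is not None:
            mask &= self.f <= f_max
        return float(self.f[mask][np.argmax(p[mask])])


def power_spectrum(
    v_bar: np.ndarray,
    dt: float,
    smooth_width: float | None = 2.0,
    resolution: float = 0.01,
) -> Spectrum:
    """Power spectrum |X(f)|^2 of the mean-removed mean voltage.

    ``dt`` is the sampling step in ms.  The signal is zero-padded so the
    frequency partitioning reaches ``resolution`` Hz; ``smooth_width`` is
    the sigma (Hz) of an optional Gaussian smoothing kernel applied to |P|.
    """
    v = np.asarray(v_bar, float)
    if v.ndim != 1:
        raise ValueError("mean voltage must be a 1-D uniformly sampled series")
    fs = 1000.0 / dt  # Hz
    n_needed = int(np.ceil(fs / resolution))
    n_fft = max(len(v), n_needed)
    x = v - v.mean()
    X = np.fft.rfft(x, n=n_fft)
    f = np.fft.rfftfreq(n_fft, d=dt / 1000.0)
    power = np.abs(X) ** 2
    smoothed = None
    if smooth_width is not None and smooth_width > 0:
        df = f[1] - f[0]
        smoothed = gaussian_filter1d(power, sigma=smooth_width / df)
    return Spectrum(f=f, power=power, smoothed=smoothed)


def band_fraction(
    spec: Spectrum,
    band: tuple[float, float] = (30.0, 80.0),
    total: tuple[float, float] = (0.0, 300.0),
    use_smoothed: bool = False,
) -> float:
    """Trapezoidal AUC of |P| over ``band`` divided by AUC over ``total``."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty frequency band")
    if lo < total[0] or hi > total[1]:
        raise ValueError("band must lie inside the total range")
    p = spec.smoothed if (use_smoothed and spec.smoothed is not None) else spec.power
    in_band = (spec.f >= lo) & (spec.f <= hi)
    in_total = (spec.f >= total[0]) & (spec.f <= total[1])
    denom = np.trapezoid(p[in_total], spec.f[in_total])
    if denom == 0:
        return 0.0
    return float(np.trapezoid(p[in_band], spec.f[in_band]) / denom)


@dataclass
class SyncTrace:
    t: np.ndarray
    r: np.ndarray  # nan where too few neurons have a defined phase
    n_defined: np.ndarray

    @property
    def r_max(self) -> float:
        valid = np.isfinite(self.r)
        if not valid.any():
            raise ValueError("synchronisation index undefined: no neuron had >= 2 spikes")
        return float(np.nanmax(self.r))


def sync_index(
    spikes: list[np.ndarray],
    grid: np.ndarray,
    min_fraction: float = 0.1,
) -> SyncTrace:
    """Phase synchronisation order parameter r_sync(t).

    A neuron's phase advances linearly by 2 pi between consecutive spikes
    and is defined only between its first and last spike; neurons without a
    defined phase at t are excluded from the population mean (the divisor is
    the count of included neurons).  r is reported only where at least
    ``min_fraction`` of the population has a defined phase.
    """
    grid = np.asarray(grid, float)
    n = len(spikes)
    re = np.zeros(len(grid))
    im = np.zeros(len(grid))
    count = np.zeros(len(grid), dtype=int)
    any_defined = False
    for st in spikes:
        st = np.asarray(st, float)
        if len(st) < 2:
            continue
        any_defined = True
        inside = (grid >= st[0]) & (grid < st[-1])
        if not inside.any():
            continue
        tg = grid[inside]
        idx = np.searchsorted(st, tg, side="right") - 1
        frac = (tg - st[idx]) / (st[idx + 1] - st[idx])
        theta = 2 * np.pi * frac  # + 2 pi n, irrelevant modulo 2 pi
        re[inside] += np.cos(theta)
        im[inside] += np.sin(theta)
        count[inside] += 1
    if not any_defined:
        raise ValueError("synchronisation index undefined: no neuron had >= 2 spikes")
    r = np.full(len(grid), np.nan)
    ok = count >= max(1, int(np.ceil(min_fraction * n)))
    r[ok] = np.hypot(re[ok], im[ok]) / count[ok]
    return SyncTrace(t=grid, r=r, n_defined=count)
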