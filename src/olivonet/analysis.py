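"""Spike-train readouts: PSTH, instantaneous rates, response speed,
model comparison, and the eyeblink decoder.

The response *speed* quantifies how sharply a neuron's firing changes
after the climbing-fiber burst:

    speed_i = (max_rate_i - min_rate_i) / (t_max - t_min)

with the extrema of the Gaussian-smoothed instantaneous rate searched in
the 100 ms window starting 5 ms after the burst onset.  The denominator is
the signed interval from the maximum to the minimum, so a burst-then-pause
response (maximum first) has negative speed and a pause-then-burst
response positive speed.

The eyeblink motor output is decoded from deep-nuclei projection-neuron
spiking per microcomplex with an update/decay rule (update constant 1.0
per spike, exponential decay with a 10 ms time constant), smoothed by a
50-sample moving average, and combined across the two microcomplexes into
a net, baseline-subtracted response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "RateTrace",
    "SpeedResult",
    "EyeblinkTrace",
    "psth",
    "instantaneous_rate",
    "response_speed",
    "population_speeds",
    "compare_speeds",
    "decode_eyeblink",
    "plot_overview",
]


@dataclass
class RateTrace:
    """Firing-rate trace (Hz) on a regular time grid (ms)."""

    time: np.ndarray
    rate: np.ndarray
    sigma: float = 0.0


@dataclass(frozen=True)
class SpeedResult:
    """Extrema and signed rate-of-change of a response window."""

    speed: float        # Hz/ms, negative when the maximum precedes the minimum
    max_rate: float
    min_rate: float
    t_max: float
    t_min: float
    window: tuple[float, float]


@dataclass
class EyeblinkTrace:
    """Decoded per-microcomplex signals and the net motor response."""

    time: np.ndarray
    per_microcomplex: dict[int, np.ndarray]
    net: np.ndarray
    update: float = 1.0
    tau_decay: float = 10.0
    ma_window: int = 50


# ---------------------------------------------------------------------------

def psth(spike_times: np.ndarray, n_neurons: int,
         t_range: tuple[float, float], bin_ms: float = 5.0
         ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram as a population rate.

    Returns ``(edges, rate)`` where ``rate[k]`` (Hz) is the spike count in
    bin ``k`` divided by ``n_neurons`` and the bin duration.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if n_neurons <= 0:
        raise ValueError("PSTH of an empty population is undefined")
    t0, t1 = t_range
    edges = np.arange(t0, t1 + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(np.asarray(spike_times), bins=edges)
    rate = counts / (n_neurons * bin_ms / 1000.0)
    return edges, rate


def instantaneous_rate(spike_times: np.ndarray, sigma: float,
                       grid: np.ndarray) -> RateTrace:
    """Gaussian-kernel instantaneous rate (Hz) on a time grid.

    A unit-area Gaussian of width ``sigma`` ms is centred on every spike;
    kernels are truncated at +-4 sigma and renormalized by the kernel mass
    falling inside the grid span, so the trace integrates to the spike
    count regardless of edge effects.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = np.asarray(grid, dtype=float)
    st = np.asarray(spike_times, dtype=float)
    rate = np.zeros_like(grid)
    if st.size:
        g0, g1 = grid[0], grid[-1]
        mass = stats.norm.cdf((g1 - st) / sigma) - stats.norm.cdf((g0 - st) / sigma)
        mass = np.maximum(mass, 1e-12)
        lo = np.searchsorted(grid, st - 4 * sigma, side="left")
        hi = np.searchsorted(grid, st + 4 * sigma, side="right")
        for s, m, a, b in zip(st, mass, lo, hi):
            seg = grid[a:b]
            rate[a:b] += np.exp(-0.5 * ((seg - s) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi) * m)
    return RateTrace(time=grid, rate=rate * 1000.0, sigma=sigma)


def response_speed(trace: RateTrace, cf_onset: float,
                   window: tuple[float, float] = (5.0, 105.0)) -> SpeedResult:
    """Signed rate-of-change statistic in the post-burst window.

    Locates the maximum and minimum of the trace inside
    ``[cf_onset + window[0], cf_onset + window[1]]``; ties are broken by
    the earliest occurrence, and a flat trace has speed 0 by convention.
    """
    w0, w1 = cf_onset + window[0], cf_onset + window[1]
    if trace.time[0] > w0 or trace.time[-1] < w1:
        raise ValueError("trace does not cover the response window")
    m = (trace.time >= w0) & (trace.time <= w1)
    t, r = trace.time[m], trace.rate[m]
    i_max = int(np.argmax(r))
    i_min = int(np.argmin(r))
    if r[i_max] == r[i_min] or i_max == i_min:
        return SpeedResult(0.0, float(r[i_max]), float(r[i_min]),
                           float(t[i_max]), float(t[i_min]), (w0, w1))
    speed = (r[i_max] - r[i_min]) / (t[i_max] - t[i_min])
    return SpeedResult(float(speed), float(r[i_max]), float(r[i_min]),
                       float(t[i_max]), float(t[i_min]), (w0, w1))


def population_speeds(spikes: tuple[np.ndarray, np.ndarray],
                      neuron_ids: Sequence[int], sigma: float,
                      cf_onset: float, grid: np.ndarray,
                      window: tuple[float, float] = (5.0, 105.0)
                      ) -> np.ndarray:
    """Per-neuron response speeds of a recorded population subset."""
    ids, times = spikes
    out = np.empty(len(neuron_ids))
    for k, gid in enumerate(neuron_ids):
        tr = instantaneous_rate(np.sort(times[ids == gid]), sigma, grid)
        out[k] = response_speed(tr, cf_onset, window).speed
    return out


def compare_speeds(speeds_a: np.ndarray, speeds_b: np.ndarray):
    """Two-sample t-test between per-neuron speed distributions.

    Returns ``(t, df, p)``; a degenerate (zero-variance) comparison is
    reported as ``t = 0, p = nan`` rather than raised.
    """
    a = np.asarray(speeds_a, dtype=float)
    b = np.asarray(speeds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, a.size + b.size - 2, 1.0
        return 0.0, a.size + b.size - 2, float("nan")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def decode_eyeblink(spikes_per_mc: dict[int, np.ndarray], dt: float,
                    duration: float, *, update: float = 1.0,
                    tau_decay: float = 10.0, ma_window: int = 50,
                    mode: str = "sum",
                    baseline_window: Optional[tuple[float, float]] = None
                    ) -> EyeblinkTrace:
    """Decode the eyeblink motor response from DCNp spiking.

    Per microcomplex, spike counts per step drive a leaky accumulator
    (``x[k] = x[k-1] exp(-dt/tau_decay) + update * count[k]``), which is
    then filtered with a causal ``ma_window``-sample moving average.  The
    net response is the baseline-subtracted sum of the two microcomplex
    signals (``mode="sum"``), or their difference (``mode="diff"``,
    microcomplex 1 minus 2).
    """
    if mode not in ("sum", "diff"):
        raise ValueError("mode must be 'sum' or 'diff'")
    n = int(round(duration / dt))
    tgrid = (np.arange(n) + 1) * dt
    decay = np.exp(-dt / tau_decay)
    decoded: dict[int, np.ndarray] = {}
    for mc, times in spikes_per_mc.items():
        counts = np.bincount(
            np.clip((np.asarray(times) / dt).astype(np.int64) - 0, 0, n - 1),
            minlength=n)[:n].astype(float)
        x = signal.lfilter([update], [1.0, -decay], counts)
        decoded[mc] = signal.lfilter(np.full(ma_window, 1.0 / ma_window),
                                     [1.0], x)
    keys = sorted(decoded)
    if baseline_window is not None:
        bmask = (tgrid >= baseline_window[0]) & (tgrid < baseline_window[1])
    else:
        bmask = None
    def _base(sig: np.ndarray) -> float:
        return float(sig[bmask].mean()) if bmask is not None and bmask.any() else 0.0
    if mode == "sum":
        net = sum(decoded[k] - _base(decoded[k]) for k in keys)
    else:
        net = (decoded[keys[0]] - _base(decoded[keys[0]])) - \
              (decoded[keys[-1]] - _base(decoded[keys[-1]]))
    return EyeblinkTrace(time=tgrid, per_microcomplex=decoded, net=np.asarray(net),
                         update=update, tau_decay=tau_decay, ma_window=ma_window)


def plot_overview(net, rec, eyeblink: EyeblinkTrace, path: str,
                  raster_pops: Sequence[str] = ("PC", "DCNp", "DCNi", "IO"),
                  psth_bin: float = 5.0) -> None:
    """Summary figure: rasters, population PSTHs and the decoded eyeblink."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(raster_pops)
    fig, axes = plt.subplots(n + 2, 1, figsize=(9, 2.0 * (n + 2)),
                             sharex=True)
    for ax, pop in zip(axes[:n], raster_pops):
        ids, times = rec.spikes[pop]
        ax.plot(times, ids, ".", ms=1.5, color="k")
        ax.set_ylabel(pop)
    ids1 = net.ids("PC")[net.labels("PC") == 1]
    times = rec.population_times("PC", ids1)
    edges, rate = psth(times, ids1.size, (0.0, rec.T), psth_bin)
    axes[n].bar(edges[:-1], rate, width=psth_bin, align="edge", color="0.3")
    axes[n].set_ylabel("PC mc1 (Hz)")
    axes[n + 1].plot(eyeblink.time, eyeblink.net, color="C1")
    axes[n + 1].set_ylabel("eyeblink (a.u.)")
    axes[n + 1].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
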