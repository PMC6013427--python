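"""Morlet wavelet power, log/z transforms, band averages, and mean spectra.

Power is estimated by convolution with complex Morlet wavelets (wave number
5, i.e. five cycles under the Gaussian envelope) on a logarithmic frequency
grid, with generous buffers trimmed after convolution to control edge
effects.  Downstream statistics operate on natural-log power z-scored across
events within session x electrode x frequency (x time bin), the
normalization set being the union of encoding, navigation and baseline
events; empty-chest (no_item) events are transformed with the same group
statistics but never contribute to them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .preprocess import EpochSet, RaggedEpochSet

__all__ = [
    "FrequencyGrid",
    "ExplicitGrid",
    "BandDef",
    "DEFAULT_BANDS",
    "PowerTensor",
    "morlet_power",
    "event_power",
    "log_and_zscore",
    "band_power",
    "window_count",
    "baseline_normalize",
    "mean_spectrum",
]

NORMALIZATION_EVENTS = ("encoding", "navigation", "baseline")


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmically spaced analysis frequencies."""

    n: int = 50
    lo: float = 1.0
    hi: float = 200.0
    wavenumber: float = 5.0

    def __post_init__(self) -> None:
        if self.lo < 1.0:
            raise ValueError("minimum frequency must be >= 1 Hz")
        if self.hi <= self.lo or self.n < 2:
            raise ValueError("invalid frequency grid")

    @property
    def frequencies(self) -> np.ndarray:
        return np.logspace(np.log10(self.lo), np.log10(self.hi), self.n)


@dataclass(frozen=True)
class ExplicitGrid:
    """Arbitrary analysis frequencies (e.g. the decoder's 10+10 set)."""

    freqs: tuple
    wavenumber: float = 5.0

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @property
    def n(self) -> int:
        return len(self.freqs)

    @property
    def hi(self) -> float:
        return float(max(self.freqs))


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("band lo must be < hi")

    def member_mask(self, freqs: np.ndarray) -> np.ndarray:
        """Closed-interval membership [lo, hi] on the grid."""
        return (freqs >= self.lo - 1e-12) & (freqs <= self.hi + 1e-12)


DEFAULT_BANDS = {
    "low_theta": BandDef("low_theta", 1.0, 3.0),
    "theta": BandDef("theta", 3.0, 10.0),
    "hfa": BandDef("hfa", 40.0, 100.0),
    "classifier_low": BandDef("classifier_low", 1.0, 10.0),
}


@dataclass
class PowerTensor:
    """Events x channels x frequencies (x time bins) power with metadata.

    ``scale`` walks raw -> log -> z only.  ``events`` carries the event type
    tags used to pick the z normalization set.
    """

    values: np.ndarray
    freqs: np.ndarray
    events: pd.DataFrame
    channels: pd.DataFrame
    scale: str = "raw"
    time_bins_ms: np.ndarray | None = None  # bin centers, if time-resolved
    grouping: tuple = ()

    def copy_with(self, values: np.ndarray, scale: str) -> "PowerTensor":
        return PowerTensor(
            values=values,
            freqs=self.freqs,
            events=self.events,
            channels=self.channels,
            scale=scale,
            time_bins_ms=self.time_bins_ms,
            grouping=self.grouping,
        )


def _check_fs(fs: float, grid: FrequencyGrid) -> None:
    if fs < 2 * grid.hi:
        raise ValueError(
            f"fs={fs} Hz cannot resolve the grid maximum {grid.hi} Hz (Nyquist)"
        )


def morlet_wavelet(freq: float, fs: float, wavenumber: float = 5.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet: ``wavenumber`` cycles under the
    Gaussian envelope (sigma_t = wavenumber / (2 pi f)), support +-3.5 sigma.
    """
    sigma_t = wavenumber / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w -= w.mean()  # zero-mean correction, relevant at low wavenumbers
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_power(
    data: np.ndarray, fs: float, grid: FrequencyGrid, n_buffer: int = 0
) -> np.ndarray:
    """Per-sample Morlet power of (events x channels x samples) voltage.

    Convolution runs in 'same' mode, so epochs may be shorter than the
    wavelet; callers provide buffers and trim ``n_buffer`` samples from each
    end afterwards to keep edge effects out of the analysis window.  Returns
    events x channels x freqs x samples.
    """
    _check_fs(fs, grid)
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected events x channels x samples")
    n_ev, n_ch, n_t = x.shape
    out_t = n_t - 2 * n_buffer
    if out_t <= 0:
        raise ValueError("buffer longer than the epoch")
    freqs = grid.frequencies
    power = np.empty((n_ev, n_ch, freqs.size, out_t))
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, grid.wavenumber)
        conv = fftconvolve(x, w[None, None, :], mode="same", axes=-1)
        p = np.abs(conv) ** 2
        power[:, :, fi, :] = p[..., n_buffer : n_t - n_buffer]
    return power


def _time_mean_power(
    epochs: EpochSet | RaggedEpochSet, grid: FrequencyGrid
) -> np.ndarray:
    """Time-averaged raw power per event x channel x frequency.

    Rejected event x channel cells (from ``epochs.reject``) come back NaN so
    they drop out of all downstream nan-aware reductions.
    """
    if isinstance(epochs, EpochSet):
        p = morlet_power(epochs.data, epochs.fs, grid, n_buffer=epochs.n_buffer)
        out = p.mean(axis=-1)
    else:
        rows = []
        nb = epochs.n_buffer
        for arr in epochs.data:
            p = morlet_power(arr[None, :, :], epochs.fs, grid, n_buffer=nb)
            rows.append(p[0].mean(axis=-1))
        out = (
            np.stack(rows)
            if rows
            else np.empty((0, len(epochs.channels), grid.n))
        )
    if epochs.reject is not None and out.size:
        out = out.copy()
        out[epochs.reject] = np.nan
    return out


def event_power(
    epoch_sets: dict[str, EpochSet | RaggedEpochSet], grid: FrequencyGrid
) -> PowerTensor:
    """Raw time-averaged power for a mix of event types.

    ``epoch_sets`` maps event-type tags (encoding, no_item, navigation,
    baseline) to epoch sets sharing one channel table.  Event rows keep
    their tag in an ``event`` column.
    """
    blocks, frames = [], []
    channels = None
    for tag, es in epoch_sets.items():
        if es.n_events == 0:
            continue
        channels = es.channels if channels is None else channels
        blocks.append(_time_mean_power(es, grid))
        ev = es.events.copy()
        ev["event"] = tag
        frames.append(ev)
    if not blocks:
        raise ValueError("no events in any epoch set")
    return PowerTensor(
        values=np.concatenate(blocks, axis=0),
        freqs=grid.frequencies,
        events=pd.concat(frames, ignore_index=True),
        channels=channels,
        scale="raw",
    )


def log_and_zscore(power: PowerTensor, ddof: int = 0) -> PowerTensor:
    """Natural-log transform then z-score across events per group.

    Groups are channel x frequency (x time bin); statistics use only events
    whose type is in the normalization set (encoding, navigation, baseline).
    The population SD (ddof=0) is used, so a two-event group maps to -1, +1.
    Zero power cells are flagged NaN before the log; a zero group SD raises.
    """
    if power.scale != "raw":
        raise ValueError(f"expected raw power, got scale={power.scale!r}")
    vals = power.values.astype(float).copy()
    vals[vals == 0] = np.nan
    logp = np.log(vals)
    norm_mask = power.events["event"].isin(NORMALIZATION_EVENTS).to_numpy()
    if norm_mask.sum() < 2:
        raise ValueError("need >= 2 normalization events to z-score")
    ref = logp[norm_mask]
    mean = np.nanmean(ref, axis=0)
    sd = np.nanstd(ref, axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero group SD: degenerate normalization group")
    z = (logp - mean) / sd
    out = power.copy_with(z, "z")
    out.grouping = ("channel", "frequency") + (
        ("time_bin",) if power.time_bins_ms is not None else ()
    )
    return out


def band_power(
    z: PowerTensor,
    band: BandDef,
    interval_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """Mean z-power over time (if resolved) then over band frequencies.

    Returns events x channels.  ``interval_ms`` selects time bins whose
    centers fall inside the closed interval; omit for time-averaged tensors.
    """
    vals = z.values
    if z.time_bins_ms is not None:
        if interval_ms is not None:
            lo, hi = interval_ms
            tmask = (z.time_bins_ms >= lo) & (z.time_bins_ms <= hi)
            if not tmask.any():
                raise ValueError("interval contains no time bins")
            vals = vals[..., tmask]
        vals = np.nanmean(vals, axis=-1)
    fmask = band.member_mask(z.freqs)
    if not fmask.any():
        raise ValueError(f"band {band.name} contains no grid frequencies")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rejected cells
        return np.nanmean(vals[:, :, fmask], axis=2)


def window_count(span_ms: float, width_ms: float, step_ms: float):
    """Number and edges of fully contained overlapping windows.

    floor((span - width)/step) + 1 windows of ``width_ms`` stepped by
    ``step_ms`` across a span; e.g. 100-ms windows in 50-ms steps over the
    3500-ms peri-item span give 69 bins, and 500-ms windows in 100-ms steps
    over a 6000-ms span give 56.
    """
    if step_ms <= 0:
        raise ValueError("step must be positive")
    if width_ms > span_ms:
        raise ValueError("window width exceeds span")
    count = int(np.floor((span_ms - width_ms) / step_ms + 1e-9)) + 1
    starts = np.arange(count) * step_ms
    edges = np.column_stack([starts, starts + width_ms])
    return count, edges


def binned_log_power(
    epochs: EpochSet,
    grid: FrequencyGrid,
    span_ms: tuple[float, float],
    width_ms: float,
    step_ms: float,
) -> PowerTensor:
    """Log-power averaged into overlapping time bins (events x ch x f x bin).

    ``span_ms`` is relative to the epoch's analysis-window start; bins are
    the ``window_count`` layout over that span.
    """
    p = morlet_power(epochs.data, epochs.fs, grid, n_buffer=epochs.n_buffer)
    logp = np.log(p)
    a, b = span_ms
    _, edges = window_count(b - a, width_ms, step_ms)
    fs = epochs.fs
    w0 = epochs.window_ms[0]
    bins = []
    for lo, hi in edges:
        i0 = int(round((a + lo - w0) / 1000.0 * fs))
        i1 = int(round((a + hi - w0) / 1000.0 * fs))
        bins.append(logp[..., i0:i1].mean(axis=-1))
    vals = np.stack(bins, axis=-1)
    if epochs.reject is not None:
        vals[epochs.reject] = np.nan
    centers = a + edges.mean(axis=1)
    ev = epochs.events.copy()
    return PowerTensor(
        values=vals,
        freqs=grid.frequencies,
        events=ev,
        channels=epochs.channels,
        scale="log",
        time_bins_ms=centers,
    )


def zscore_binned(power: PowerTensor, ddof: int = 0) -> PowerTensor:
    """z-score a log-scale binned tensor per channel x frequency x bin."""
    if power.scale != "log":
        raise ValueError("expected log-scale tensor")
    vals = power.values
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero group SD: degenerate normalization group")
    return power.copy_with((vals - mean) / sd, "z")


def baseline_normalize(z: PowerTensor, baseline_tag: str = "baseline") -> PowerTensor:
    """Re-center z-power on the mean of the pre-trial baseline events."""
    if z.scale != "z":
        raise ValueError("expected z-scale tensor")
    mask = (z.events["event"] == baseline_tag).to_numpy()
    if not mask.any():
        raise ValueError("no baseline events to normalize against")
    base = np.nanmean(z.values[mask], axis=0)
    return z.copy_with(z.values - base, "z")


def mean_spectrum(
    power: PowerTensor,
    condition_mask: np.ndarray,
    freq_range: tuple[float, float] = (1.0, 50.0),
):
    """Per-electrode mean log-power spectrum for one condition.

    Averages natural-log power across the condition's events at each grid
    frequency inside ``freq_range``.  Returns (freqs, channels x freqs).
    """
    condition_mask = np.asarray(condition_mask, dtype=bool)
    if condition_mask.sum() == 0:
        raise ValueError("empty condition")
    fmask = (power.freqs >= freq_range[0] - 1e-12) & (power.freqs <= freq_range[1] + 1e-12)
    vals = power.values[condition_mask][:, :, fmask]
    if power.scale == "raw":
        vals = np.log(np.where(vals > 0, vals, np.nan))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(vals, axis=0)
    return power.freqs[fmask], out
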