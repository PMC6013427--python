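"""Referencing, filtering, epoching, and kurtosis-based artifact rejection."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .synthetic import Recording

__all__ = [
    "bipolar_reference",
    "notch_filter",
    "extract_epochs",
    "kurtosis_reject",
    "EpochSet",
    "RaggedEpochSet",
]

log = logging.getLogger(__name__)


def bipolar_reference(recording: Recording, montage: pd.DataFrame | None = None) -> Recording:
    """Re-reference to bipolar virtual channels.

    One virtual channel per pair of immediately adjacent contacts on the same
    probe (consecutive contact indices); signal = first minus second contact,
    location = midpoint of the pair.  Hemisphere/region labels are inherited
    when the parents agree, else set to "boundary".  Probes with a single
    contact contribute nothing (logged).
    """
    montage = recording.montage if montage is None else montage
    rows = []
    signals = []
    for probe, grp in montage.groupby("probe", sort=False):
        grp = grp.sort_values("contact")
        if len(grp) < 2:
            log.warning("probe %s has a single contact; no virtual channels", probe)
            continue
        idx = grp.index.to_numpy()
        contacts = grp["contact"].to_numpy()
        for a, b in zip(range(len(grp) - 1), range(1, len(grp))):
            if contacts[b] != contacts[a] + 1:
                continue  # non-adjacent physical contacts
            ra, rb = montage.loc[idx[a]], montage.loc[idx[b]]
            ia = montage.index.get_loc(idx[a])
            ib = montage.index.get_loc(idx[b])
            signals.append(recording.data[ia] - recording.data[ib])
            hemi = ra["hemisphere"] if ra["hemisphere"] == rb["hemisphere"] else "boundary"
            region = ra["region"] if ra["region"] == rb["region"] else "boundary"
            rows.append(
                {
                    "channel": f"{ra['channel']}-{rb['channel']}",
                    "probe": probe,
                    "contact": int(contacts[a]),
                    "parents": (ra["channel"], rb["channel"]),
                    "x": (ra["x"] + rb["x"]) / 2,
                    "y": (ra["y"] + rb["y"]) / 2,
                    "z": (ra["z"] + rb["z"]) / 2,
                    "hemisphere": hemi,
                    "region": region,
                    "soz": bool(ra["soz"] or rb["soz"]),
                }
            )
    return Recording(
        data=np.asarray(signals),
        fs=recording.fs,
        montage=pd.DataFrame(rows),
    )


def notch_filter(
    recording: Recording,
    stop_band: tuple[float, float] = (58.0, 62.0),
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-stop (default 58-62 Hz, 4th order)."""
    lo, hi = stop_band
    if recording.fs <= 2 * hi:
        raise ValueError(f"fs={recording.fs} too low for a {lo}-{hi} Hz stop band")
    sos = sp_signal.butter(order, [lo, hi], btype="bandstop", fs=recording.fs, output="sos")
    return Recording(
        data=sp_signal.sosfiltfilt(sos, recording.data, axis=-1),
        fs=recording.fs,
        montage=recording.montage,
    )


@dataclass
class EpochSet:
    """Fixed-window epochs: events x channels x samples, buffers attached.

    ``data`` covers ``window_ms`` widened by ``buffer_ms`` on each side; the
    analysis window is recovered by trimming ``n_buffer`` samples per side.
    """

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    buffer_ms: float
    events: pd.DataFrame
    channels: pd.DataFrame
    reject: np.ndarray | None = None  # events x channels bool

    @property
    def n_buffer(self) -> int:
        return int(round(self.buffer_ms / 1000.0 * self.fs))

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def core(self) -> np.ndarray:
        """Analysis-window samples (buffers trimmed)."""
        nb = self.n_buffer
        return self.data[..., nb : self.data.shape[-1] - nb]


@dataclass
class RaggedEpochSet:
    """Variable-length epochs (navigation / baseline), one array per event."""

    data: list  # of (channels x samples) arrays, buffers attached
    fs: float
    buffer_ms: float
    events: pd.DataFrame
    channels: pd.DataFrame
    reject: np.ndarray | None = None

    @property
    def n_buffer(self) -> int:
        return int(round(self.buffer_ms / 1000.0 * self.fs))

    @property
    def n_events(self) -> int:
        return len(self.data)

    def core(self, i: int) -> np.ndarray:
        nb = self.n_buffer
        return self.data[i][:, nb : self.data[i].shape[-1] - nb]


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] | None = (0.0, 1500.0),
    buffer_ms: float = 3000.0,
) -> EpochSet | RaggedEpochSet:
    """Slice buffered epochs around event onsets.

    ``window_ms=(a, b)`` extracts fixed windows a..b ms relative to onset;
    ``window_ms=None`` extracts each event's full onset..offset span (ragged,
    for variable-length navigation/baseline epochs).  Events whose buffered
    window falls outside the recording are dropped with a warning and flagged
    in the returned event table (``dropped`` column of the input index).
    """
    fs = recording.fs
    nb = int(round(buffer_ms / 1000.0 * fs))
    n = recording.n_samples
    kept_rows = []
    slices = []
    for _, row in events.iterrows():
        onset = int(round(row["onset_ms"] / 1000.0 * fs))
        if window_ms is None:
            a = onset - nb
            b = int(round(row["offset_ms"] / 1000.0 * fs)) + nb
        else:
            a = onset + int(round(window_ms[0] / 1000.0 * fs)) - nb
            b = onset + int(round(window_ms[1] / 1000.0 * fs)) + nb
        if a < 0 or b > n:
            warnings.warn(
                f"event at {row['onset_ms']:.0f} ms: buffered window outside recording; dropped",
                stacklevel=2,
            )
            continue
        kept_rows.append(row)
        slices.append(recording.data[:, a:b])
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    if window_ms is None:
        return RaggedEpochSet(
            data=slices, fs=fs, buffer_ms=buffer_ms, events=kept, channels=recording.montage
        )
    data = np.asarray(slices) if slices else np.empty((0, recording.data.shape[0], 0))
    return EpochSet(
        data=data,
        fs=fs,
        window_ms=tuple(window_ms),
        buffer_ms=buffer_ms,
        events=kept,
        channels=recording.montage,
    )


def _kurtosis(trace: np.ndarray) -> float:
    return float(sp_stats.kurtosis(trace, fisher=False, bias=True))


def kurtosis_reject(epochs: EpochSet | RaggedEpochSet, threshold: float = 5.0) -> np.ndarray:
    """Per event x channel exclusion mask by voltage-trace kurtosis.

    Kurtosis is the plain (non-excess) fourth standardized moment of the
    unbuffered analysis window, so a Gaussian trace sits near 3 and the
    default threshold 5 flags heavy-tailed (spike-contaminated) traces.
    Zero-variance traces are excluded and logged.  The mask is also stored on
    ``epochs.reject``.
    """
    n_ch = len(epochs.channels)
    mask = np.zeros((epochs.n_events, n_ch), dtype=bool)
    for i in range(epochs.n_events):
        core = epochs.core()[i] if isinstance(epochs, EpochSet) else epochs.core(i)
        for c in range(n_ch):
            trace = core[c]
            if trace.size < 4:
                raise ValueError("epoch too short for kurtosis (need >= 4 samples)")
            if trace.std() == 0:
                log.warning("zero-variance trace (event %d, channel %d): excluded", i, c)
                mask[i, c] = True
                continue
            mask[i, c] = _kurtosis(trace) > threshold
    epochs.reject = mask
    return mask


def rejection_report(epochs_list, channels: pd.DataFrame) -> pd.DataFrame:
    """Per-electrode fraction of excluded event windows across epoch sets."""
    masks = [e.reject for e in epochs_list if e.reject is not None and e.n_events]
    if not masks:
        raise ValueError("no rejection masks computed")
    stacked = np.concatenate(masks, axis=0)
    return pd.DataFrame(
        {
            "channel": channels["channel"].to_numpy(),
            "fraction_excluded": stacked.mean(axis=0),
        }
    )
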