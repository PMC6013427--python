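"""Synthetic treasure-hunt sessions and intracranial recordings.

The simulator emulates a hybrid navigation / spatial-memory task: on each
trial the subject navigates an open rectangular arena to a series of four
treasure chests, most of which reveal an object for 1500 ms whose location
must later be recalled from an elevated viewpoint at one of the arena's short
ends.  A full session has 40 trials and 160 chests, 100 holding objects and
60 empty, with two or three object chests per trial.

Recordings are multichannel voltage traces (microvolts) with a power-law
(1/f^k) background, 60-Hz line noise, occasional transient artifacts, and
Hann-windowed low-theta oscillatory bursts whose amplitude is modulated by
hemisphere-specific gains during successful encoding and during navigation.
Ground-truth memory outcomes are drawn first and behavioral responses are
generated conditional on them, so planted neural effects and behavioral
labels agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "ArenaConfig",
    "TaskConfig",
    "BehaviorModel",
    "NeuralModel",
    "TaskSession",
    "Recording",
    "default_montage",
    "generate_session",
    "generate_recording",
    "scaled_task",
]

CONFIDENCE_LEVELS = ("Yes", "Maybe", "No")


@dataclass(frozen=True)
class ArenaConfig:
    """Rectangular virtual arena; retrieval happens from the short ends."""

    width: float = 100.0
    height: float = 70.0
    response_circle_radius: float = 13.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if not 0 < self.response_circle_radius < min(self.width, self.height) / 2:
            raise ValueError("response_circle_radius out of range")

    @property
    def viewpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Two retrieval viewpoints at opposite short ends of the arena."""
        return ((0.0, self.height / 2), (self.width, self.height / 2))

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int = 40
    chests_per_trial: int = 4
    n_object_chests: int = 100
    n_empty_chests: int = 60
    item_display_ms: float = 1500.0
    movement_fraction: float = 0.96
    nav_median_s: float = 6.0
    nav_sigma: float = 0.4
    baseline_range_s: tuple[float, float] = (2.0, 6.0)
    inter_event_gap_ms: float = 500.0
    lead_in_ms: float = 6000.0
    lead_out_ms: float = 6000.0

    def __post_init__(self) -> None:
        if self.n_object_chests + self.n_empty_chests != self.n_trials * self.chests_per_trial:
            raise ValueError("object + empty chests must equal trials x chests_per_trial")
        if not 0 < self.movement_fraction <= 1:
            raise ValueError("movement_fraction must be in (0, 1]")
        # exactly solvable with 2-3 object chests per trial?
        n3 = self.n_object_chests - 2 * self.n_trials
        if not 0 <= n3 <= self.n_trials:
            raise ValueError(
                "infeasible balance: totals not reachable with 2-3 object chests per trial"
            )

    @property
    def n_three_object_trials(self) -> int:
        return self.n_object_chests - 2 * self.n_trials


def scaled_task(n_trials: int, **kwargs) -> TaskConfig:
    """Shorter session preserving the 2.5 objects-per-trial design ratio.

    ``n_trials`` must be even so the 3-object / 2-object trial split is exact.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even for an exact 100:60 design ratio")
    n_obj = n_trials * 5 // 2
    return TaskConfig(
        n_trials=n_trials,
        n_object_chests=n_obj,
        n_empty_chests=n_trials * 4 - n_obj,
        **kwargs,
    )


@dataclass(frozen=True)
class BehaviorModel:
    """Generative model of retrieval responses conditional on memory outcome.

    ``p_remember`` is the marginal probability that an object is encoded
    successfully (ground truth).  Remembered objects get a response scattered
    around the true location with per-axis SD ``error_sd``; forgotten objects
    respond uniformly at random with probability ``guess_rate`` and otherwise
    with a 4x wider scatter.  Confidence degrades with realized error via two
    soft thresholds with Gaussian slack.
    """

    error_sd: float = 13.0
    guess_rate: float = 0.85
    p_remember: float = 0.5
    confidence_slack_sd: float = 5.0
    yes_threshold: float = 15.0
    maybe_threshold: float = 35.0

    def __post_init__(self) -> None:
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        if not 0 <= self.guess_rate <= 1:
            raise ValueError("guess_rate must be in [0, 1]")
        if not 0 < self.p_remember < 1:
            raise ValueError("p_remember must be in (0, 1)")
        if not 0 < self.yes_threshold < self.maybe_threshold:
            raise ValueError("confidence thresholds must be increasing")


@dataclass(frozen=True)
class NeuralModel:
    """Planted effect structure of the synthetic recordings.

    Gains are multiplicative on burst amplitude: 1 means no condition effect.
    ``burst_amp`` is the microvolt amplitude of a baseline (gain-1) burst;
    set it to 0 for a pure power-law background.
    """

    background_exponent: float = 2.0
    background_rms: float = 10.0
    osc_freq_hz: float = 3.0
    burst_amp: float = 6.0
    burst_rate_hz: float = 3.0
    left_memory_gain: float = 1.0
    right_memory_gain: float = 1.0
    left_nav_gain: float = 1.0
    right_nav_gain: float = 1.0
    hfa_item_gain: float = 1.0
    hfa_amp: float = 5.0
    line_noise_amp: float = 5.0
    line_freq_hz: float = 60.0
    artifact_rate_per_min: float = 0.5
    artifact_amp: float = 300.0
    contact_gradient: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        gains = (
            self.left_memory_gain,
            self.right_memory_gain,
            self.left_nav_gain,
            self.right_nav_gain,
            self.hfa_item_gain,
        )
        if any(g < 0 for g in gains):
            raise ValueError("gains must be non-negative")
        if not 1 <= self.osc_freq_hz <= 50:
            raise ValueError("osc_freq_hz must lie in 1-50 Hz")
        if self.background_exponent < 0:
            raise ValueError("background_exponent must be non-negative")

    def memory_gain(self, hemisphere: str) -> float:
        return self.left_memory_gain if hemisphere == "L" else self.right_memory_gain

    def nav_gain(self, hemisphere: str) -> float:
        return self.left_nav_gain if hemisphere == "L" else self.right_nav_gain

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TaskSession:
    """One task session: timed events plus retrieval responses.

    ``events`` columns: event (encoding | no_item | navigation | baseline),
    trial, onset_ms, offset_ms, x, y, object_id, remembered (ground truth).
    ``responses`` columns: object_id, trial, true_x, true_y, response_x,
    response_y, confidence, remembered, viewpoint_x, viewpoint_y.
    """

    events: pd.DataFrame
    responses: pd.DataFrame
    arena: ArenaConfig
    task: TaskConfig
    duration_ms: float
    subject: str = "S00"
    session: int = 0

    @property
    def encoding_events(self) -> pd.DataFrame:
        return self.events[self.events["event"] == "encoding"]


@dataclass
class Recording:
    """Raw multichannel voltage (microvolts), contacts x samples."""

    data: np.ndarray
    fs: float
    montage: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


MONTAGE_COLUMNS = [
    "channel",
    "probe",
    "contact",
    "x",
    "y",
    "z",
    "hemisphere",
    "region",
    "soz",
]


def default_montage(
    contacts_per_probe: int = 5,
    probes: tuple[tuple[str, str, str], ...] = (
        ("LH", "L", "hippocampus"),
        ("RH", "R", "hippocampus"),
    ),
    spacing_mm: float = 10.0,
) -> pd.DataFrame:
    """Depth-probe montage: one linear probe per (name, hemisphere, region).

    Contacts are spaced ``spacing_mm`` apart along the probe's y axis, with
    the probe origin placed laterally by hemisphere.
    """
    rows = []
    for p_idx, (name, hemi, region) in enumerate(probes):
        x0 = -30.0 if hemi == "L" else 30.0
        for c in range(contacts_per_probe):
            rows.append(
                {
                    "channel": f"{name}{c + 1}",
                    "probe": name,
                    "contact": c + 1,
                    "x": x0,
                    "y": -25.0 + spacing_mm * c,
                    "z": -15.0 - 2.0 * p_idx,
                    "hemisphere": hemi,
                    "region": region,
                    "soz": False,
                }
            )
    montage = pd.DataFrame(rows, columns=MONTAGE_COLUMNS)
    if montage["channel"].duplicated().any():
        raise ValueError("duplicate channel ids in montage")
    return montage


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _draw_response(rng, true_xy, arena: ArenaConfig, behavior: BehaviorModel, remembered: bool):
    if remembered:
        sd = behavior.error_sd
        xy = true_xy + rng.normal(0.0, sd, size=2)
    elif rng.random() < behavior.guess_rate:
        xy = np.array([rng.uniform(0, arena.width), rng.uniform(0, arena.height)])
    else:
        xy = true_xy + rng.normal(0.0, 4 * behavior.error_sd, size=2)
    xy[0] = np.clip(xy[0], 0.0, arena.width)
    xy[1] = np.clip(xy[1], 0.0, arena.height)
    err = float(np.hypot(*(xy - true_xy)))
    score = err + rng.normal(0.0, behavior.confidence_slack_sd)
    if score < behavior.yes_threshold:
        conf = "Yes"
    elif score < behavior.maybe_threshold:
        conf = "Maybe"
    else:
        conf = "No"
    return xy, conf


def generate_session(
    task: TaskConfig | None = None,
    arena: ArenaConfig | None = None,
    behavior: BehaviorModel | None = None,
    seed: int | None = None,
    subject: str = "S00",
    session: int = 0,
) -> TaskSession:
    """Generate one deterministic task session from a seed.

    Per trial: a pre-trial baseline epoch, then four navigation-epoch /
    chest-event pairs, then retrieval responses for each object from the
    alternating short-end viewpoint.  All timestamps strictly increase.
    """
    task = task or TaskConfig()
    arena = arena or ArenaConfig()
    behavior = behavior or BehaviorModel()
    rng = np.random.default_rng(seed)

    # which trials carry 3 objects (remainder carry 2), shuffled by seed
    n3 = task.n_three_object_trials
    objects_per_trial = np.array([3] * n3 + [2] * (task.n_trials - n3))
    rng.shuffle(objects_per_trial)

    events: list[dict] = []
    responses: list[dict] = []
    t = float(task.lead_in_ms)
    gap = task.inter_event_gap_ms
    object_id = 0
    mu = np.log(task.nav_median_s)
    for trial in range(task.n_trials):
        b_lo, b_hi = task.baseline_range_s
        b_dur = rng.uniform(b_lo, b_hi) * 1000.0
        events.append(
            {"event": "baseline", "trial": trial, "onset_ms": t, "offset_ms": t + b_dur}
        )
        t += b_dur + gap

        k_obj = int(objects_per_trial[trial])
        object_slots = rng.choice(task.chests_per_trial, size=k_obj, replace=False)
        trial_objects = []
        for chest in range(task.chests_per_trial):
            nav_dur = float(np.clip(rng.lognormal(mu, task.nav_sigma), 2.0, 20.0)) * 1000.0
            events.append(
                {
                    "event": "navigation",
                    "trial": trial,
                    "onset_ms": t,
                    "offset_ms": t + nav_dur,
                }
            )
            t += nav_dur
            x = rng.uniform(1.0, arena.width - 1.0)
            y = rng.uniform(1.0, arena.height - 1.0)
            if chest in object_slots:
                remembered = bool(rng.random() < behavior.p_remember)
                events.append(
                    {
                        "event": "encoding",
                        "trial": trial,
                        "onset_ms": t,
                        "offset_ms": t + task.item_display_ms,
                        "x": x,
                        "y": y,
                        "object_id": object_id,
                        "remembered": remembered,
                    }
                )
                trial_objects.append((object_id, x, y, remembered))
                object_id += 1
            else:
                events.append(
                    {
                        "event": "no_item",
                        "trial": trial,
                        "onset_ms": t,
                        "offset_ms": t + task.item_display_ms,
                        "x": x,
                        "y": y,
                    }
                )
            t += task.item_display_ms + gap

        viewpoint = arena.viewpoints[trial % 2]
        for oid, x, y, remembered in trial_objects:
            xy, conf = _draw_response(rng, np.array([x, y]), arena, behavior, remembered)
            responses.append(
                {
                    "object_id": oid,
                    "trial": trial,
                    "true_x": x,
                    "true_y": y,
                    "response_x": float(xy[0]),
                    "response_y": float(xy[1]),
                    "confidence": conf,
                    "remembered": remembered,
                    "viewpoint_x": viewpoint[0],
                    "viewpoint_y": viewpoint[1],
                }
            )

    duration_ms = t + task.lead_out_ms
    ev = pd.DataFrame(events)
    ev["object_id"] = ev.get("object_id", pd.Series(dtype="float")).astype("Int64")
    onsets = ev["onset_ms"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise AssertionError("event onsets must strictly increase")
    return TaskSession(
        events=ev,
        responses=pd.DataFrame(responses),
        arena=arena,
        task=task,
        duration_ms=duration_ms,
        subject=subject,
        session=session,
    )


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng, n_samples: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    """Spectrally shaped white noise: amplitude ~ f^(-exponent/2), DC zeroed."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * shape
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _burst_waveform(rng, freq: float, fs: float) -> np.ndarray:
    """Hann-windowed sinusoid, random phase, 2-6 cycles of ``freq``.

    Shorter bursts make the voltage trace heavy-tailed enough to trip the
    kurtosis rejection on clean data; 2-6 cycles keeps epochs near-Gaussian
    while still producing a narrowband spectral peak.
    """
    cycles = rng.uniform(2.0, 6.0)
    n = max(int(round(cycles / freq * fs)), 4)
    tt = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    return np.hanning(n) * np.sin(2 * np.pi * freq * tt + phase)


def _epoch_gain(row: pd.Series, hemisphere: str, neural: NeuralModel) -> float:
    ev = row["event"]
    if ev == "encoding":
        if bool(row["remembered"]):
            return neural.memory_gain(hemisphere)
        return 1.0
    if ev == "navigation":
        return neural.nav_gain(hemisphere)
    # baseline and empty-chest displays carry baseline-amplitude bursts
    return 1.0


def generate_recording(
    session: TaskSession,
    montage: pd.DataFrame,
    neural: NeuralModel | None = None,
    fs: float = 500.0,
    seed: int | None = None,
) -> Recording:
    """Synthesize a contacts x samples voltage matrix covering the session.

    Each hemisphere receives a shared oscillatory burst train (amplitude
    scaled per epoch by the hemisphere's condition gain) projected onto its
    contacts with a fixed per-contact gradient, so bipolar differencing
    retains the oscillation while perfectly common signals cancel.
    Backgrounds, high-frequency item activity, and artifacts are independent
    per contact; line noise shares phase but varies slightly in amplitude.
    """
    neural = neural or NeuralModel()
    if fs < 400.0:
        raise ValueError(
            f"fs={fs} Hz too low: the 1-200 Hz analysis grid requires fs >= 400 Hz "
            "(Nyquist 200 Hz)"
        )
    rng = np.random.default_rng(seed)
    n_samples = int(np.ceil(session.duration_ms / 1000.0 * fs))
    n_contacts = len(montage)
    data = np.empty((n_contacts, n_samples))
    for i in range(n_contacts):
        data[i] = _powerlaw_noise(
            rng, n_samples, fs, neural.background_exponent, neural.background_rms
        )

    t = np.arange(n_samples) / fs

    # hemisphere burst trains with per-contact gradient
    lo, hi = neural.contact_gradient
    gradient = rng.uniform(lo, hi, size=n_contacts)
    hemi_of = montage["hemisphere"].to_numpy()
    if neural.burst_amp > 0:
        for hemi in ("L", "R"):
            idx = np.flatnonzero(hemi_of == hemi)
            if idx.size == 0:
                continue
            train = np.zeros(n_samples)
            for _, row in session.events.iterrows():
                dur_s = (row["offset_ms"] - row["onset_ms"]) / 1000.0
                n_bursts = rng.poisson(neural.burst_rate_hz * dur_s)
                amp = neural.burst_amp * _epoch_gain(row, hemi, neural)
                for _ in range(n_bursts):
                    w = _burst_waveform(rng, neural.osc_freq_hz, fs)
                    start = int(row["onset_ms"] / 1000.0 * fs) + rng.integers(
                        0, max(int(dur_s * fs) - w.size, 1)
                    )
                    stop = min(start + w.size, n_samples)
                    train[start:stop] += amp * w[: stop - start]
            data[idx] += gradient[idx, None] * train[None, :]

    # broadband 40-100 Hz activity during item displays (independent per contact)
    if neural.hfa_item_gain != 1.0:
        sos = sp_signal.butter(4, [40.0, 100.0], btype="bandpass", fs=fs, output="sos")
        amp = neural.hfa_amp * abs(neural.hfa_item_gain - 1.0)
        enc = session.events[session.events["event"] == "encoding"]
        for _, row in enc.iterrows():
            a = int(row["onset_ms"] / 1000.0 * fs)
            b = int(row["offset_ms"] / 1000.0 * fs)
            burst = sp_signal.sosfilt(sos, rng.normal(size=(n_contacts, b - a)), axis=1)
            sd = burst.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            data[:, a:b] += np.sign(neural.hfa_item_gain - 1.0) * amp * burst / sd

    if neural.line_noise_amp > 0:
        line = np.sin(2 * np.pi * neural.line_freq_hz * t + rng.uniform(0, 2 * np.pi))
        amps = neural.line_noise_amp * rng.uniform(0.8, 1.2, size=n_contacts)
        data += amps[:, None] * line[None, :]

    if neural.artifact_rate_per_min > 0:
        kernel = neural.artifact_amp * np.exp(-np.arange(int(0.02 * fs) or 1) / (0.005 * fs))
        minutes = n_samples / fs / 60.0
        for i in range(n_contacts):
            n_art = rng.poisson(neural.artifact_rate_per_min * minutes)
            for _ in range(n_art):
                start = rng.integers(0, n_samples - kernel.size)
                data[i, start : start + kernel.size] += rng.choice([-1, 1]) * kernel

    return Recording(data=data, fs=fs, montage=montage.reset_index(drop=True))
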