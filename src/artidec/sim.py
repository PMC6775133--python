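"""Synthetic high-density ECoG generator.

Produces continuous multichannel recordings with the statistical structure
the decoding pipeline assumes: a per-channel 1/f background, shared mains
(line) interference, and — during active trials — a band-limited (60–130 Hz)
amplitude increase whose magnitude falls off as a spatial Gaussian around a
class-specific grid location.  The trial design mirrors a cued movement
experiment: 4 movement classes and rest, 20 trials each, 1500 ms cues,
1500–2000 ms inter-trial intervals, electrodes on a rectangular grid with
3–4 mm pitch.

The class effect is injected as amplitude-modulated noise whose spectral
shape inside the high-frequency band matches the background, so the realized
high-frequency-band log-power rise at a class's center electrode equals the
configured ``effect_db`` (in dB) irrespective of the 1/f slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import fft as sfft

REST_LABEL = "rest"

__all__ = [
    "REST_LABEL",
    "GridLayout",
    "EventTable",
    "RecordingRun",
    "SimConfig",
    "generate_run",
    "inject_bad_channels",
    "permute_movement_labels",
    "save_run",
    "load_run",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridLayout:
    """Rectangular electrode grid; channels are numbered row-major."""

    n_rows: int
    n_cols: int
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, channel: int) -> tuple[int, int]:
        if not 0 <= channel < self.n_channels:
            raise ValueError(f"channel {channel} outside grid")
        return divmod(channel, self.n_cols)

    def positions_mm(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) positions in mm."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([rows, cols]).astype(float) * self.spacing_mm


@dataclass(frozen=True)
class EventTable:
    """Trial onsets, durations (cue period) and labels, in samples."""

    onset_sample: np.ndarray
    duration_samples: np.ndarray
    label: np.ndarray  # strings; REST_LABEL marks rest trials

    def __post_init__(self) -> None:
        onset = np.asarray(self.onset_sample, dtype=np.int64)
        dur = np.asarray(self.duration_samples, dtype=np.int64)
        lab = np.asarray(self.label, dtype=object)
        if not (len(onset) == len(dur) == len(lab)):
            raise ValueError("event columns must have equal length")
        if np.any(np.diff(onset) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(dur <= 0):
            raise ValueError("durations must be positive")
        object.__setattr__(self, "onset_sample", onset)
        object.__setattr__(self, "duration_samples", dur)
        object.__setattr__(self, "label", lab)

    def __len__(self) -> int:
        return len(self.onset_sample)

    @property
    def movement_mask(self) -> np.ndarray:
        return self.label != REST_LABEL

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.label[self.movement_mask]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": self.onset_sample,
                "duration_samples": self.duration_samples,
                "label": self.label,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTable":
        return cls(
            frame["onset_sample"].to_numpy(),
            frame["duration_samples"].to_numpy(),
            frame["label"].to_numpy(dtype=object),
        )


@dataclass(frozen=True)
class RecordingRun:
    """Continuous multichannel signal plus grid geometry and trial events."""

    signal: np.ndarray  # (n_channels, n_samples) float
    sampling_rate_hz: float
    layout: GridLayout
    events: EventTable

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 2:
            raise ValueError("signal must be 2-D (channels × samples)")
        if sig.shape[0] != self.layout.n_channels:
            raise ValueError("signal channel count does not match layout")
        if not np.isfinite(sig).all():
            raise ValueError("signal contains non-finite values")
        last_end = int(self.events.onset_sample[-1] + self.events.duration_samples[-1])
        if last_end > sig.shape[1]:
            raise ValueError("events extend past the end of the recording")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def with_signal(self, signal: np.ndarray) -> "RecordingRun":
        return replace(self, signal=signal)

    def with_events(self, events: EventTable) -> "RecordingRun":
        return replace(self, events=events)


def _default_centers(layout: GridLayout, n_classes: int) -> list[tuple[int, int]]:
    # spread class centers over the grid interior, one per quadrant-ish
    rows = np.linspace(0.25, 0.75, max(2, int(np.ceil(n_classes / 2)))) * (layout.n_rows - 1)
    cols = np.linspace(0.25, 0.75, 2) * (layout.n_cols - 1)
    centers = []
    for i in range(n_classes):
        r = int(round(rows[i // 2]))
        c = int(round(cols[i % 2]))
        centers.append((r, c))
    if len({tuple(c) for c in centers}) != n_classes:
        raise ValueError("grid too small for distinct default class centers")
    return centers


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated run.

    Defaults reproduce the densest common configuration of the emulated
    experiment: an 8×8 grid at 4 mm pitch sampled at 512 Hz, 4 movement
    classes × 20 trials plus 20 rest trials, 1500 ms cues and 1500 ms
    inter-trial intervals, 50 Hz mains.  ``effect_db`` (high-frequency-band
    log-power rise at a class's center electrode) and ``effect_sigma_mm``
    (spatial spread of the rise) are free parameters of the generator.
    """

    layout: GridLayout = field(default_factory=lambda: GridLayout(8, 8, 4.0))
    sampling_rate_hz: float = 512.0
    n_classes: int = 4
    trials_per_class: int = 20
    rest_trials: int = 20
    cue_duration_s: float = 1.5
    iti_s: float = 1.5
    line_freq_hz: float = 50.0
    line_amplitude: float = 1.0
    line_harmonics: int = 3
    class_centers: tuple[tuple[int, int], ...] | None = None
    effect_sigma_mm: float = 6.0
    effect_db: float = 6.0
    noise_exponent: float = 1.0
    onset_jitter_s: float = 0.2
    bad_channel_fraction: float = 0.0
    bad_channel_mode: str = "noisy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_class <= 0 or self.rest_trials < 0:
            raise ValueError("trial counts must be positive")
        if self.cue_duration_s <= 0 or self.iti_s <= 0:
            raise ValueError("cue_duration_s and iti_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not 0 <= self.bad_channel_fraction < 1:
            raise ValueError("bad_channel_fraction must be in [0, 1)")
        if self.onset_jitter_s < 0:
            raise ValueError("onset_jitter_s must be non-negative")
        centers = self.class_centers
        if centers is None:
            centers = tuple(_default_centers(self.layout, self.n_classes))
        else:
            centers = tuple(tuple(c) for c in centers)
        if len(centers) != self.n_classes:
            raise ValueError("class_centers must have one entry per class")
        for r, c in centers:
            if not (0 <= r < self.layout.n_rows and 0 <= c < self.layout.n_cols):
                raise ValueError(f"class center ({r}, {c}) outside grid")
        object.__setattr__(self, "class_centers", centers)

    @property
    def class_labels(self) -> list[str]:
        return [f"class_{i + 1}" for i in range(self.n_classes)]


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _one_over_f_weights(n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Amplitude weights for rfft bins giving power ∝ f^-exponent (DC = 0)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-exponent / 2.0)
    return w


def _shaped_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                  weights: np.ndarray) -> np.ndarray:
    """Independent per-channel Gaussian noise spectrally shaped by `weights`,
    normalized to unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = sfft.rfft(white, axis=1) * weights
    out = sfft.irfft(spec, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_run(config: SimConfig) -> RecordingRun:
    """Generate a seeded synthetic recording.

    The background on each channel is unit-variance 1/f^``noise_exponent``
    Gaussian noise plus a shared mains sinusoid (with harmonics).  During each
    active trial, band-limited (60–130 Hz) noise is added with a per-channel
    amplitude following a spatial Gaussian around the trial class's center,
    calibrated so the center channel's high-frequency-band log power rises by
    ``effect_db`` dB over rest.  Identical config (incl. seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    cue = int(round(config.cue_duration_s * fs))
    iti = int(round(config.iti_s * fs))
    pad = int(round(1.0 * fs))

    labels = np.array(
        [lab for lab in config.class_labels for _ in range(config.trials_per_class)]
        + [REST_LABEL] * config.rest_trials,
        dtype=object,
    )
    labels = labels[rng.permutation(len(labels))]
    n_trials = len(labels)
    onsets = pad + np.arange(n_trials) * (cue + iti)
    n_samples = int(onsets[-1] + cue + iti + pad)

    bg_weights = _one_over_f_weights(n_samples, fs, config.noise_exponent)
    signal = _shaped_noise(rng, config.layout.n_channels, n_samples, bg_weights)

    # shared mains interference with mild per-channel gain spread
    if config.line_amplitude > 0:
        t = np.arange(n_samples) / fs
        wave = np.zeros(n_samples)
        for h in range(1, config.line_harmonics + 1):
            f = config.line_freq_hz * h
            if f >= fs / 2:
                break
            wave += (config.line_amplitude / h) * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
            )
        gains = 1.0 + 0.05 * rng.standard_normal(config.layout.n_channels)
        signal += gains[:, None] * wave[None, :]

    # class effect: band-limited 1/f-shaped noise, spatial Gaussian amplitude
    band_weights = bg_weights.copy()
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    band_weights[(freqs < 60.0) | (freqs > 130.0)] = 0.0
    band_noise = _shaped_noise(rng, config.layout.n_channels, n_samples, band_weights)

    # expected fraction of background variance inside the 60–130 Hz band
    band_frac = float((band_weights**2).sum() / (bg_weights**2).sum())
    gain = np.sqrt(band_frac * (10.0 ** (config.effect_db / 10.0) - 1.0))

    positions = config.layout.positions_mm()
    center_pos = {
        lab: positions[config.layout.channel_index(r, c)]
        for lab, (r, c) in zip(config.class_labels, config.class_centers)
    }
    spatial = {}
    for lab, pos in center_pos.items():
        d2 = ((positions - pos) ** 2).sum(axis=1)
        spatial[lab] = np.exp(-d2 / (2.0 * config.effect_sigma_mm**2))

    jitter = rng.uniform(0.0, config.onset_jitter_s, size=n_trials)
    if config.effect_db != 0:
        for i in range(n_trials):
            lab = labels[i]
            if lab == REST_LABEL:
                continue
            start = int(onsets[i] + round(jitter[i] * fs))
            stop = min(start + cue, n_samples)
            amp = gain * spatial[lab]
            signal[:, start:stop] += amp[:, None] * band_noise[:, start:stop]

    events = EventTable(onsets, np.full(n_trials, cue, dtype=np.int64), labels)
    run = RecordingRun(signal, fs, config.layout, events)
    if config.bad_channel_fraction > 0:
        run, _ = inject_bad_channels(
            run, config.bad_channel_fraction, mode=config.bad_channel_mode,
            seed=int(rng.integers(2**31 - 1)),
        )
    return run


def inject_bad_channels(run: RecordingRun, fraction: float, mode: str = "noisy",
                        seed: int = 0) -> tuple[RecordingRun, list[int]]:
    """Corrupt a random subset of channels; returns the new run and the list
    of corrupted channel indices (ground truth).

    ``flat`` sets a channel to a constant; ``noisy`` scales its variance by
    100× and adds strong line interference.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if mode not in ("flat", "noisy"):
        raise ValueError("mode must be 'flat' or 'noisy'")
    n_bad = int(round(fraction * run.n_channels))
    if n_bad == 0:
        return run, []
    rng = np.random.default_rng(seed)
    bad = sorted(rng.choice(run.n_channels, size=n_bad, replace=False).tolist())
    sig = run.signal.copy()
    if mode == "flat":
        sig[bad, :] = 0.0
    else:
        t = np.arange(run.n_samples) / run.sampling_rate_hz
        strong_line = 10.0 * np.sin(2 * np.pi * 50.0 * t)
        for ch in bad:
            sig[ch] = sig[ch] * 10.0 + strong_line  # 100× variance + mains
    return run.with_signal(sig), bad


def permute_movement_labels(events: EventTable, seed: int) -> EventTable:
    """Randomly permute class labels among movement trials (rest fixed)."""
    rng = np.random.default_rng(seed)
    lab = events.label.copy()
    idx = np.flatnonzero(events.movement_mask)
    lab[idx] = lab[idx[rng.permutation(len(idx))]]
    return EventTable(events.onset_sample, events.duration_samples, lab)


# ---------------------------------------------------------------------------
# I/O: HDF5 signal + BIDS-events-like TSV + ground-truth JSON
# ---------------------------------------------------------------------------

def save_run(run: RecordingRun, h5_path, events_path, truth: dict | None = None,
             truth_path=None, dataset: str = "/signal") -> None:
    """Write signal to HDF5 (float32) with grid attributes, events to TSV,
    and optionally a ground-truth JSON sidecar."""
    with h5py.File(h5_path, "w") as f:
        ds = f.create_dataset(dataset, data=run.signal.astype(np.float32))
        ds.attrs["sampling_rate_hz"] = run.sampling_rate_hz
        ds.attrs["n_rows"] = run.layout.n_rows
        ds.attrs["n_cols"] = run.layout.n_cols
        ds.attrs["spacing_mm"] = run.layout.spacing_mm
    run.events.to_frame().to_csv(events_path, sep="\t", index=False)
    if truth is not None:
        if truth_path is None:
            raise ValueError("truth_path required when truth is given")
        with open(truth_path, "w") as f:
            json.dump(truth, f, indent=2, sort_keys=True)


def load_run(h5_path, events_path, dataset: str = "/signal") -> RecordingRun:
    with h5py.File(h5_path, "r") as f:
        ds = f[dataset]
        signal = ds[()].astype(np.float64)
        layout = GridLayout(
            int(ds.attrs["n_rows"]), int(ds.attrs["n_cols"]),
            float(ds.attrs["spacing_mm"]),
        )
        fs = float(ds.attrs["sampling_rate_hz"])
    frame = pd.read_csv(events_path, sep="\t")
    return RecordingRun(signal, fs, layout, EventTable.from_frame(frame))
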