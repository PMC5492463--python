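"""Synthetic labeled sEMG datasets for lower-limb activity monitoring.

The generator emulates the acquisition setting of a wearable four-channel
surface-EMG system: 1024 Hz sampling, a 20–450 Hz signal band, baseline noise
below 1.25 μV rms, 1.5 s epochs, and eight activity classes (seven activities
of daily living plus a trip-fall).  Each epoch is modelled as

    x_c(t) = baseline_noise_c(t) + e_c(t) * carrier_c(t)

where ``carrier`` is zero-mean Gaussian noise band-limited to the passband and
scaled to unit rms (the standard interference-pattern surrogate for surface
EMG), and ``e_c`` is an activity- and channel-specific trapezoidal burst
envelope.  The trip-fall class receives the sharpest-onset, highest-amplitude
burst across all channels.  Signal units are millivolts throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ACTIVITIES",
    "FALL_CLASS",
    "CHANNEL_NAMES",
    "GeneratorConfig",
    "SignalEpoch",
    "LabeledDataset",
    "generate_dataset",
    "bandpower_fraction",
    "default_envelope_matrix",
    "save_dataset",
    "load_dataset",
]

ACTIVITIES = (
    "stand-to-squat",
    "squat-to-stand",
    "stand-to-sit",
    "sit-to-stand",
    "stair-ascending",
    "stair-descending",
    "walking",
    "trip-fall",
)
FALL_CLASS = "trip-fall"

#: CH1–CH4: gastrocnemius, rectus femoris, tibialis anterior, semitendinosus
CHANNEL_NAMES = ("gastrocnemius", "rectus_femoris", "tibialis_anterior", "semitendinosus")


def default_envelope_matrix() -> np.ndarray:
    """Per-activity, per-channel burst descriptors.

    Returns an array of shape ``(8 activities, 4 channels, 3)`` whose last axis
    holds ``(onset fraction, duration fraction, peak amplitude in mV)``.  The
    amplitude patterns encode which lower-limb muscles dominate each movement:
    e.g. stand-to-sit loads channel 1 (the raw-signal lookalike of a fall),
    stair work loads rectus femoris / tibialis anterior, and the trip-fall is a
    short high burst on every channel.  Peaks are set so that bursts exceed the
    default Willison-amplitude threshold (0.05 mV) while staying below the
    ~7 mV ceiling typical of posture transitions.
    """
    rows = {
        #                      CH1                CH2                CH3                CH4
        "stand-to-squat":   [(0.20, 0.50, 1.0), (0.15, 0.55, 3.0), (0.25, 0.45, 0.8), (0.20, 0.50, 1.2)],
        "squat-to-stand":   [(0.25, 0.45, 1.2), (0.20, 0.50, 2.5), (0.30, 0.40, 0.6), (0.20, 0.50, 2.0)],
        "stand-to-sit":     [(0.15, 0.50, 3.5), (0.25, 0.45, 1.0), (0.30, 0.40, 0.5), (0.20, 0.45, 1.5)],
        "sit-to-stand":     [(0.20, 0.50, 1.5), (0.15, 0.55, 2.2), (0.25, 0.45, 1.0), (0.25, 0.45, 1.8)],
        "stair-ascending":  [(0.10, 0.60, 2.0), (0.10, 0.65, 2.8), (0.15, 0.60, 2.2), (0.20, 0.50, 1.0)],
        "stair-descending": [(0.15, 0.55, 1.8), (0.15, 0.55, 1.5), (0.10, 0.65, 2.5), (0.25, 0.45, 0.8)],
        "walking":          [(0.10, 0.70, 1.5), (0.15, 0.60, 1.2), (0.10, 0.70, 1.5), (0.15, 0.60, 1.2)],
        "trip-fall":        [(0.10, 0.25, 6.0), (0.10, 0.25, 5.0), (0.10, 0.25, 6.0), (0.10, 0.25, 5.0)],
    }
    return np.array([rows[a] for a in ACTIVITIES], dtype=float)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic sEMG generator.

    All defaults mirror the study conditions: 4 channels at 1024 Hz, 1.5 s
    epochs, a 20–450 Hz passband, baseline noise of 1.25 μV rms (1.25e-3 mV),
    at least 30 epochs per activity, 3 subjects, and 8 activity classes of
    which exactly one (the trip-fall) is flagged as the fall class.
    """

    n_channels: int = 4
    fs: float = 1024.0
    epoch_s: float = 1.5
    band: tuple[float, float] = (20.0, 450.0)
    baseline_rms: float = 1.25e-3
    activities: tuple[str, ...] = ACTIVITIES
    fall_class: str = FALL_CLASS
    envelope_matrix: np.ndarray = field(default_factory=default_envelope_matrix)
    separation: float = 1.0
    n_epochs_per_class: int = 30
    n_subjects: int = 3
    subject_jitter: float = 0.05
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.epoch_s)

    def validate(self) -> None:
        if self.epoch_s <= 0 or self.fs <= 0:
            raise ConfigError("fs and epoch_s must be positive")
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ConfigError(f"band must satisfy 0 < lo < hi < fs/2, got {self.band}")
        if self.n_channels < 1 or self.n_epochs_per_class < 1 or self.n_subjects < 1:
            raise ConfigError("counts must be positive")
        env = np.asarray(self.envelope_matrix, dtype=float)
        if env.shape != (len(self.activities), self.n_channels, 3):
            raise ConfigError(
                f"envelope_matrix shape {env.shape} != "
                f"({len(self.activities)}, {self.n_channels}, 3)"
            )
        if (env[..., 2] < 0).any():
            raise ConfigError("envelope peak amplitudes must be >= 0")
        if (env[..., 1] <= 0).any():
            raise ConfigError("burst duration fractions must be positive")
        if self.fall_class not in self.activities:
            raise ConfigError(f"fall class {self.fall_class!r} not among activities")
        if self.separation < 0 or self.subject_jitter < 0:
            raise ConfigError("separation and subject_jitter must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["envelope_matrix"] = np.asarray(self.envelope_matrix).tolist()
        d["band"] = list(self.band)
        d["activities"] = list(self.activities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "envelope_matrix" in d:
            d["envelope_matrix"] = np.asarray(d["envelope_matrix"], dtype=float)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "activities" in d:
            d["activities"] = tuple(d["activities"])
        return cls(**d)


@dataclass
class SignalEpoch:
    """One fixed-length window of multi-channel sEMG, in mV."""

    samples: np.ndarray  # (n_samples, n_channels)
    fs: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_channels)")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class LabeledDataset:
    """Collection of epochs with activity labels and subject identifiers."""

    epochs: list[SignalEpoch]
    labels: np.ndarray  # activity name per epoch
    subject_ids: np.ndarray  # subject index per epoch
    fall_flag: np.ndarray  # bool per epoch
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.fall_flag = np.asarray(self.fall_flag, dtype=bool)
        n = len(self.epochs)
        if not (len(self.labels) == len(self.subject_ids) == len(self.fall_flag) == n):
            raise ValueError("epochs, labels, subject_ids, fall_flag must be equal length")

    def __len__(self) -> int:
        return len(self.epochs)

    def signals(self) -> np.ndarray:
        """Stack all epochs into an (n_epochs, n_samples, n_channels) array."""
        return np.stack([e.samples for e in self.epochs])

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return LabeledDataset(
            epochs=[self.epochs[i] for i in idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            fall_flag=self.fall_flag[idx],
            config=self.config,
        )


def _trapezoid(n: int, onset_frac: float, dur_frac: float, peak: float) -> np.ndarray:
    """Trapezoidal burst envelope: 25% rise, 50% plateau, 25% fall."""
    env = np.zeros(n)
    start = int(round(onset_frac * n))
    width = max(int(round(dur_frac * n)), 4)
    stop = min(start + width, n)
    width = stop - start
    if width <= 0:
        return env
    ramp = max(width // 4, 1)
    shape = np.ones(width)
    shape[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    shape[width - ramp:] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    env[start:stop] = peak * shape
    return env


def _bandpass_sos(band: tuple[float, float], fs: float):
    return sps.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _effective_envelopes(cfg: GeneratorConfig) -> np.ndarray:
    """Pull per-class descriptors toward/away from the class mean by `separation`.

    separation = 0 collapses all classes onto the across-activity mean
    descriptor; 1 reproduces the configured matrix; > 1 exaggerates contrasts.
    """
    env = np.asarray(cfg.envelope_matrix, dtype=float)
    mean = env.mean(axis=0, keepdims=True)
    eff = mean + cfg.separation * (env - mean)
    eff[..., 2] = np.clip(eff[..., 2], 0.0, None)  # peaks stay non-negative
    eff[..., 1] = np.clip(eff[..., 1], 1e-3, 1.0)
    eff[..., 0] = np.clip(eff[..., 0], 0.0, 1.0 - eff[..., 1])
    return eff


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate a labeled synthetic sEMG dataset.

    Deterministic given ``config.seed``: one seed sequence is split into a
    per-subject jitter stream and one child stream per epoch.
    """
    config.validate()
    n = config.n_samples
    sos = _bandpass_sos(config.band, config.fs)
    env_eff = _effective_envelopes(config)

    ss = np.random.SeedSequence(config.seed)
    ss_jitter, ss_epochs = ss.spawn(2)
    jitter_rng = np.random.default_rng(ss_jitter)
    # multiplicative per-subject amplitude jitter, one factor per (subject, activity, channel)
    jitter = jitter_rng.normal(
        1.0, config.subject_jitter,
        size=(config.n_subjects, len(config.activities), config.n_channels),
    )
    jitter = np.clip(jitter, 0.0, None)

    n_total = config.n_subjects * len(config.activities) * config.n_epochs_per_class
    child_seeds = ss_epochs.spawn(n_total)

    channel_names = tuple(
        CHANNEL_NAMES[: config.n_channels]
        if config.n_channels <= len(CHANNEL_NAMES)
        else [f"CH{i + 1}" for i in range(config.n_channels)]
    )

    epochs: list[SignalEpoch] = []
    labels: list[str] = []
    subject_ids: list[int] = []
    fall_flag: list[bool] = []
    k = 0
    for subj in range(config.n_subjects):
        for ai, act in enumerate(config.activities):
            for _ in range(config.n_epochs_per_class):
                rng = np.random.default_rng(child_seeds[k])
                k += 1
                x = rng.normal(0.0, config.baseline_rms, size=(n, config.n_channels))
                for ch in range(config.n_channels):
                    onset, dur, peak = env_eff[ai, ch]
                    peak = peak * jitter[subj, ai, ch]
                    if peak <= 0:
                        continue
                    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
                    rms = np.sqrt(np.mean(carrier**2))
                    if rms > 0:
                        carrier = carrier / rms
                    x[:, ch] += _trapezoid(n, onset, dur, peak) * carrier
                epochs.append(SignalEpoch(x, fs=config.fs, channel_names=channel_names))
                labels.append(act)
                subject_ids.append(subj)
                fall_flag.append(act == config.fall_class)

    return LabeledDataset(
        epochs=epochs,
        labels=np.array(labels),
        subject_ids=np.array(subject_ids),
        fall_flag=np.array(fall_flag),
        config=config,
    )


def bandpower_fraction(epoch: SignalEpoch, band: tuple[float, float]) -> float:
    """Fraction of total spectral power inside ``band``, averaged over channels.

    Uses the one-sided periodogram; returns a value in [0, 1].
    """
    lo, hi = band
    if not (0 < lo < hi < epoch.fs / 2):
        raise ValueError(f"band must lie within (0, fs/2), got {band}")
    x = epoch.samples
    if x.size == 0:
        raise ValueError("empty signal")
    f, pxx = sps.periodogram(x, fs=epoch.fs, axis=0)
    total = pxx.sum(axis=0)
    if np.all(total == 0):
        raise ValueError("zero-power signal")
    sel = (f >= lo) & (f <= hi)
    return float(np.mean(pxx[sel].sum(axis=0) / total))


# ---------------------------------------------------------------------------
# dataset round-trip: long-format CSV + JSON sidecar
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, out_dir: str | Path) -> None:
    """Write one CSV per dataset plus a JSON sidecar with config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, ep in enumerate(dataset.epochs):
        n, c = ep.samples.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(dataset.subject_ids[i], n * c),
                    "label": np.repeat(dataset.labels[i], n * c),
                    "epoch_index": np.repeat(i, n * c),
                    "channel": np.tile(np.arange(c), n),
                    "sample_index": np.repeat(np.arange(n), c),
                    "value": ep.samples.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "dataset.csv", index=False, float_format="%.17g")
    sidecar = {
        "fs": dataset.epochs[0].fs if dataset.epochs else None,
        "channel_names": list(dataset.epochs[0].channel_names) if dataset.epochs else [],
        "fall_flag": dataset.fall_flag.astype(int).tolist(),
        "config": dataset.config.to_dict() if dataset.config is not None else None,
    }
    (out / "dataset.json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(in_dir: str | Path) -> LabeledDataset:
    """Read a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    meta = json.loads((src / "dataset.json").read_text())
    df = pd.read_csv(src / "dataset.csv")
    config = GeneratorConfig.from_dict(meta["config"]) if meta.get("config") else None
    channel_names = tuple(meta["channel_names"])
    fs = meta["fs"]
    epochs, labels, subjects = [], [], []
    for idx, g in df.groupby("epoch_index", sort=True):
        n = g["sample_index"].max() + 1
        c = g["channel"].max() + 1
        mat = np.empty((n, c))
        mat[g["sample_index"].to_numpy(), g["channel"].to_numpy()] = g["value"].to_numpy()
        epochs.append(SignalEpoch(mat, fs=fs, channel_names=channel_names))
        labels.append(g["label"].iloc[0])
        subjects.append(g["subject"].iloc[0])
    return LabeledDataset(
        epochs=epochs,
        labels=np.array(labels),
        subject_ids=np.array(subjects),
        fall_flag=np.array(meta["fall_flag"], dtype=bool),
        config=config,
    )
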