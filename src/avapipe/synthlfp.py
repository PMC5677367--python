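"""Synthetic multichannel LFP with known embedded negative deflections.

Generates band-limited (1-100 Hz) Gaussian background noise per channel plus
injected negative half-cosine deflections at inhomogeneous-Poisson times
following a trial-locked rate profile, returning the ground truth (per-channel
deflection times and amplitudes) so that threshold detection, adaptive
thresholding and synchrony measures can be validated event by event.

Amplitudes are expressed in units of the background SD: an amplitude of -4
means the deflection trough sits four background standard deviations below
the channel mean, comfortably beyond a -2 SD detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "LfpRecording",
    "GroundTruthEvents",
    "half_cosine_template",
    "generate_lfp",
    "generate_coupled_oscillation",
    "write_lfp_binary",
    "read_lfp_binary",
]


@dataclass
class LfpRecording:
    """Continuous multichannel LFP: channels x samples, plus trial marks."""

    samples: np.ndarray  # (n_channels, n_samples) float
    fs: float = 2000.0
    trial_marks: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.trial_marks = np.asarray(self.trial_marks, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        dur = self.samples.shape[1] / self.fs
        if self.trial_marks.size and (
            self.trial_marks.min() < 0 or self.trial_marks.max() > dur
        ):
            raise ValueError("trial marks outside the recording span")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs


@dataclass
class GroundTruthEvents:
    """Injected deflections: per-channel arrays of (center time, amplitude)."""

    times: list  # list over channels of float arrays (seconds)
    amplitudes: list  # list over channels of float arrays (negative, SD units)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.times))


def half_cosine_template(width: float, fs: float) -> np.ndarray:
    """Unit-depth negative half-cosine of the given width: minimum -1 at center."""
    n = max(int(round(width * fs)), 3)
    if n % 2 == 0:
        n += 1  # odd length -> unique central minimum
    tau = np.linspace(-0.5, 0.5, n)
    return -np.cos(np.pi * tau)


def _band_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise band-limited to ``band``, unit SD per channel."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")
    sos = signal.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n_channels, n_samples))
    y = signal.sosfiltfilt(sos, x, axis=1)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def generate_lfp(
    n_channels: int = 96,
    fs: float = 2000.0,
    n_trials: int = 20,
    trial_span: tuple[float, float] = (-0.8, 0.8),
    rate_profile=None,
    template_width: float = 0.020,
    amplitude_range: tuple[float, float] = (-4.5, -2.5),
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[LfpRecording, GroundTruthEvents]:
    """Synthesize trial-structured LFP with known nLFP-like deflections.

    ``rate_profile`` is a callable mapping trial time (seconds, within
    ``trial_span``) to the deflection rate per channel in events/s; ``None``
    means no deflections (pure background). Trials are laid out back to back;
    ``trial_marks`` gives the absolute time of each trial's alignment point
    (trial time 0). Deflection times are inhomogeneous Poisson (thinning);
    draws closer than the template width to the previous event on the same
    channel are discarded with a warning to keep deflections resolvable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    t0, t1 = trial_span
    trial_len = t1 - t0
    n_samples = int(round(n_trials * trial_len * fs))
    x = _band_noise(n_channels, n_samples, fs, (1.0, 100.0), rng) * noise_sd
    marks = (np.arange(n_trials) * trial_len) - t0  # absolute time of trial time 0

    tmpl = half_cosine_template(template_width, fs)
    half = len(tmpl) // 2
    gt_times: list[np.ndarray] = [np.empty(0) for _ in range(n_channels)]
    gt_amps: list[np.ndarray] = [np.empty(0) for _ in range(n_channels)]
    n_thinned = 0
    if rate_profile is not None:
        grid = np.linspace(t0, t1, 513)
        rates = np.asarray([rate_profile(t) for t in grid], dtype=float)
        if np.any(rates < 0):
            raise ValueError("rate_profile must be non-negative")
        rmax = rates.max()
        for ch in range(n_channels):
            ch_t, ch_a = [], []
            for tr in range(n_trials):
                if rmax <= 0:
                    continue
                n_cand = rng.poisson(rmax * trial_len)
                cand = np.sort(rng.uniform(t0, t1, n_cand))
                keep = rng.random(n_cand) < np.interp(cand, grid, rates) / rmax
                times = cand[keep]
                last = -np.inf
                for t in times:
                    if t - last < template_width:
                        n_thinned += 1
                        continue
                    last = t
                    amp = rng.uniform(*amplitude_range)
                    center = marks[tr] + t
                    idx = int(round(center * fs))
                    lo_i, hi_i = idx - half, idx + half + 1
                    if lo_i < 0 or hi_i > n_samples:
                        continue
                    x[ch, lo_i:hi_i] += (-amp * noise_sd) * tmpl[: hi_i - lo_i]
                    ch_t.append(center)
                    ch_a.append(amp)
            gt_times[ch] = np.asarray(ch_t)
            gt_amps[ch] = np.asarray(ch_a)
    if n_thinned:
        warnings.warn(
            f"rate profile denser than template width: {n_thinned} deflections thinned"
        )
    rec = LfpRecording(x, fs=fs, trial_marks=marks)
    return rec, GroundTruthEvents(gt_times, gt_amps)


def generate_coupled_oscillation(
    n_channels: int,
    fs: float = 2000.0,
    duration: float = 10.0,
    band: tuple[float, float] = (50.0, 100.0),
    coupling: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> LfpRecording:
    """Channels sharing a common band-limited signal with weight ``coupling``.

    Each channel is ``coupling * common + (1 - coupling) * independent``, all
    components band-limited Gaussian with unit SD, so coupling 1 gives
    identical channels (perfect downstream phase synchrony) and coupling 0
    gives independent ones.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    common = _band_noise(1, n_samples, fs, band, rng)
    indep = _band_noise(n_channels, n_samples, fs, band, rng)
    x = coupling * common + (1.0 - coupling) * indep
    return LfpRecording(x, fs=fs)


def generate_coupled_oscillation_profile(
    n_channels: int,
    fs: float = 2000.0,
    duration: float = 10.0,
    band: tuple[float, float] = (50.0, 100.0),
    coupling_profile=None,
    trial_marks: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> LfpRecording:
    """Coupled channels with a smoothly time-varying coupling weight.

    Like :func:`generate_coupled_oscillation`, but the weight of the common
    component is ``coupling_profile(t)`` evaluated per sample (values in
    [0, 1]). The common and independent components are continuous over the
    whole recording, so epoch-to-epoch coupling changes introduce no signal
    discontinuities.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    w = (
        np.full(n_samples, 0.5)
        if coupling_profile is None
        else np.asarray([coupling_profile(x) for x in t], dtype=float)
    )
    if w.min() < 0 or w.max() > 1:
        raise ValueError("coupling profile must stay within [0, 1]")
    common = _band_noise(1, n_samples, fs, band, rng)
    indep = _band_noise(n_channels, n_samples, fs, band, rng)
    x = w[None, :] * common + (1.0 - w[None, :]) * indep
    return LfpRecording(
        x, fs=fs, trial_marks=np.empty(0) if trial_marks is None else trial_marks
    )


def write_lfp_binary(rec: LfpRecording, data_path, header_path) -> None:
    """Channel-major little-endian float32 flat binary plus a text sidecar."""
    rec.samples.astype("<f4").tofile(data_path)
    with open(header_path, "w") as fh:
        fh.write(f"n_channels {rec.n_channels}\n")
        fh.write(f"n_samples {rec.samples.shape[1]}\n")
        fh.write(f"fs {rec.fs}\n")
        fh.write("trial_marks " + " ".join(f"{m:.6f}" for m in rec.trial_marks) + "\n")


def read_lfp_binary(data_path, header_path) -> LfpRecording:
    meta: dict[str, str] = {}
    with open(header_path) as fh:
        for line in fh:
            key, _, val = line.strip().partition(" ")
            meta[key] = val
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    x = np.fromfile(data_path, dtype="<f4").reshape(n_ch, n_s).astype(float)
    marks = np.array([float(v) for v in meta.get("trial_marks", "").split()])
    return LfpRecording(x, fs=float(meta["fs"]), trial_marks=marks)
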