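"""Synthetic neural recordings for end-to-end pipeline testing.

Two generators are provided.

``simulate_dataset1`` emulates an extracellular recording containing
action potentials from three distinct units plus background noise. Each
spike waveform is a cosine under a Gaussian envelope,

    V(t) = A * cos(2*pi*(t - tau_ph)/tau1) * exp(-(2.3548*t/tau2)**2),

sampled at 20 kHz. 2.3548 is the FWHM-to-sigma factor of a Gaussian, so
tau2 is the envelope's full width at half maximum. Units fire as
independent homogeneous Poisson processes at a mean rate of 3.3 Hz, with
a one-epoch dead time enforced across units so spike windows never
overlap. All three units share one recording; zero-mean Gaussian noise
is added at a target SNR, defined here as peak reference-template
amplitude over noise standard deviation (a common spike-sorting
convention; an RMS-based definition is selectable). By default the
noise is band-limited to the 3 kHz spike band before being rescaled to
the target standard deviation — extracellular background noise is a
superposition of distant spikes seen through a band-passed acquisition
chain, so its spectrum lives in the spike band, not at the 10 kHz
Nyquist edge; ``noise_bandwidth=None`` selects spectrally white noise
instead. The recording is then min-max normalized globally, which
preserves the between-unit amplitude ratios, and cut into 56-sample
epochs that are either spike-centered (labels 1-3) or drawn from
spike-free stretches (label 4).

Default template parameters produce three visually distinct biphasic
spikes with amplitude ratios 1 : 1.1 : 1.5 (unit 3 largest) and widths in
the 0.6-2.0 ms range typical of extracellular action potentials. They
mimic the qualitative class structure of simulated spike benchmarks, not
any specific published parameter set.

``simulate_eeg_surrogate`` produces Bonn-like EEG surrogates: 4096-sample
channels at 173.61 Hz in five condition classes that differ in amplitude
scale and autocorrelation, one of which is ictal-like (high-amplitude
rhythmic bursts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Epoch, TimeSeries, normalize_recording

__all__ = [
    "SpikeTemplateParams",
    "SimulationConfig",
    "DEFAULT_TEMPLATES",
    "spike_template",
    "generate_spike_times",
    "add_noise_at_snr",
    "simulate_dataset1",
    "simulate_eeg_surrogate",
]


@dataclass(frozen=True)
class SpikeTemplateParams:
    """Parameters of one unit's action-potential waveform (times in seconds)."""

    A: float
    tau1: float
    tau2: float
    tau_ph: float = 0.0
    class_id: int = 1

    def __post_init__(self) -> None:
        if not (self.A >= 0 and self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("require A >= 0 and tau1, tau2 > 0")


#: three biphasic units with amplitude ratios 1 : 1.1 : 1.5
DEFAULT_TEMPLATES = (
    SpikeTemplateParams(A=1.0, tau1=1.2e-3, tau2=0.6e-3, tau_ph=0.0, class_id=1),
    SpikeTemplateParams(A=1.1, tau1=1.6e-3, tau2=0.9e-3, tau_ph=1.0e-4, class_id=2),
    SpikeTemplateParams(A=1.5, tau1=2.0e-3, tau2=1.2e-3, tau_ph=2.0e-4, class_id=3),
)

#: label assigned to spike-free (noise) epochs
NOISE_CLASS = 4


@dataclass(frozen=True)
class SimulationConfig:
    sampling_rate: float = 20_000.0
    duration: float = 200.0
    firing_rate: float = 3.3
    snr: float = 2.0
    epoch_len: int = 56
    seed: int = 0
    templates: tuple[SpikeTemplateParams, ...] = DEFAULT_TEMPLATES
    n_per_class: int | None = None  # None = keep every realized epoch
    snr_mode: str = "peak"  # "peak" or "rms" noise-scale reference
    noise_bandwidth: float | None = 3000.0  # Hz low-pass; None = white noise

    def __post_init__(self) -> None:
        if not (
            self.sampling_rate > 0
            and self.duration > 0
            and self.firing_rate > 0
            and self.snr > 0
        ):
            raise ValueError("rates, duration and snr must be positive")
        if self.epoch_len < 2:
            raise ValueError("epoch_len must be at least 2")


def spike_template(
    p: SpikeTemplateParams, sampling_rate: float, support: float
) -> np.ndarray:
    """Sample V(t) on t in [-support/2, support/2) at the given rate."""
    if support <= 0:
        raise ValueError("support must be positive")
    n = int(round(support * sampling_rate))
    t = (np.arange(n) - n // 2) / sampling_rate
    return (
        p.A
        * np.cos(2 * np.pi * (t - p.tau_ph) / p.tau1)
        * np.exp(-((2.3548 * t / p.tau2) ** 2))
    )


def generate_spike_times(
    firing_rate: float, duration: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration), sorted."""
    if firing_rate <= 0 or duration < 0:
        raise ValueError("rate must be positive, duration non-negative")
    rng = np.random.default_rng(seed)
    # draw exponential gaps until past the horizon; expected count + slack
    n_guess = int(firing_rate * duration + 10 * np.sqrt(firing_rate * duration) + 10)
    gaps = rng.exponential(1.0 / firing_rate, size=n_guess)
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration:
        more = rng.exponential(1.0 / firing_rate, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(more)])
    return times[times < duration]


def add_noise_at_snr(
    signal: np.ndarray,
    snr: float,
    seed: int | np.random.Generator,
    sigma_ref: float | None = None,
    mode: str = "peak",
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise scaled to the target SNR.

    sigma = ref / snr, where ref is ``sigma_ref`` if given, else the
    signal's peak absolute amplitude (``mode="peak"``) or its RMS
    (``mode="rms"``).
    """
    signal = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be positive")
    if sigma_ref is None:
        if mode == "peak":
            sigma_ref = float(np.max(np.abs(signal)))
        elif mode == "rms":
            sigma_ref = float(np.sqrt(np.mean(signal**2)))
        else:
            raise ValueError(f"unknown snr mode {mode!r}")
    if sigma_ref <= 0:
        raise ValueError("signal has zero amplitude; SNR undefined")
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, sigma_ref / snr, size=signal.shape)


def _bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    sigma: float,
    sampling_rate: float,
    bandwidth: float,
) -> np.ndarray:
    """Gaussian noise low-passed at ``bandwidth`` and rescaled to exact sigma.

    Filtering is linear, so the result stays Gaussian; the rescale pins
    the realized standard deviation to the target.
    """
    from scipy.signal import butter, filtfilt

    white = rng.normal(0.0, 1.0, size=n)
    if bandwidth >= sampling_rate / 2:
        x = white
    else:
        b, a = butter(4, bandwidth / (sampling_rate / 2), btype="low")
        x = filtfilt(b, a, white)
    return x * (sigma / x.std())


def _thin_refractory(
    times: np.ndarray, labels: np.ndarray, dead_time: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedily drop events closer than ``dead_time`` to the last kept one."""
    keep_t, keep_l = [], []
    last = -np.inf
    for t, lab in zip(times, labels):
        if t - last >= dead_time:
            keep_t.append(t)
            keep_l.append(lab)
            last = t
    return np.array(keep_t), np.array(keep_l, dtype=int)


def simulate_dataset1(cfg: SimulationConfig) -> tuple[list[Epoch], dict]:
    """Simulate a multi-unit recording and return labeled spike/noise epochs.

    Returns ``(epochs, manifest)``; the manifest records the seed, noise
    sigma and per-class epoch counts. Epochs with labels 1-3 are centered
    on spikes of the corresponding unit; label-4 epochs come from
    stretches at least one epoch length away from every spike.
    """
    fs = cfg.sampling_rate
    n_total = int(round(cfg.duration * fs))
    n_ep = cfg.epoch_len
    if n_ep > n_total:
        raise ValueError("epoch length exceeds recording duration")
    support = n_ep / fs
    templates = [spike_template(p, fs, support) for p in cfg.templates]
    for p, tpl in zip(cfg.templates, templates):
        if tpl.size != n_ep:
            raise ValueError("template support does not match epoch length")

    root = np.random.default_rng(cfg.seed)
    child = root.spawn(len(cfg.templates) + 2)

    # per-unit Poisson trains, merged, with a one-epoch dead time across units
    all_t, all_l = [], []
    for k, p in enumerate(cfg.templates):
        t = generate_spike_times(cfg.firing_rate, cfg.duration, child[k])
        all_t.append(t)
        all_l.append(np.full(t.size, p.class_id, dtype=int))
    times = np.concatenate(all_t)
    labels = np.concatenate(all_l)
    order = np.argsort(times)
    times, labels = _thin_refractory(times[order], labels[order], n_ep / fs)

    # drop events whose window would clip the recording edges
    centers = np.round(times * fs).astype(int)
    half = n_ep // 2
    ok = (centers >= half) & (centers + (n_ep - half) <= n_total)
    centers, labels = centers[ok], labels[ok]

    recording = np.zeros(n_total)
    for c, lab in zip(centers, labels):
        recording[c - half : c - half + n_ep] += templates[lab - 1]

    sigma_ref = (
        cfg.templates[0].A
        if cfg.snr_mode == "peak"
        else float(np.sqrt(np.mean(templates[0] ** 2)))
    )
    sigma = sigma_ref / cfg.snr
    if cfg.noise_bandwidth is None:
        noisy = add_noise_at_snr(
            recording, cfg.snr, child[len(cfg.templates)], sigma_ref=sigma_ref
        )
    else:
        noisy = recording + _bandlimited_noise(
            np.random.default_rng(child[len(cfg.templates)]),
            n_total,
            sigma,
            fs,
            cfg.noise_bandwidth,
        )
    norm = normalize_recording(TimeSeries(noisy, fs, "sim")).samples

    # spike-free stretches for the noise class: stay >= one epoch away
    occupied = np.zeros(n_total, dtype=bool)
    for c in centers:
        lo = max(0, c - half - n_ep)
        hi = min(n_total, c - half + 2 * n_ep)
        occupied[lo:hi] = True
    free_starts = np.flatnonzero(~occupied[: n_total - n_ep])
    # keep starts whose whole window is free, then make them disjoint
    window_free = free_starts[
        ~occupied[np.minimum(free_starts + n_ep - 1, n_total - 1)]
    ]
    noise_starts = []
    last_end = -1
    for s in window_free:
        if s > last_end:
            noise_starts.append(s)
            last_end = s + n_ep - 1
    noise_starts = np.asarray(noise_starts, dtype=int)
    child[-1].shuffle(noise_starts)

    epochs: list[Epoch] = []
    counts: dict[int, int] = {}
    for c, lab in zip(centers, labels):
        if cfg.n_per_class is not None and counts.get(lab, 0) >= cfg.n_per_class:
            continue
        epochs.append(
            Epoch(q=norm[c - half : c - half + n_ep], index=len(epochs), label=int(lab))
        )
        counts[lab] = counts.get(lab, 0) + 1

    n_noise = cfg.n_per_class if cfg.n_per_class is not None else noise_starts.size
    if n_noise > noise_starts.size:
        raise ValueError(
            f"only {noise_starts.size} spike-free epochs available, "
            f"{n_noise} requested; increase duration"
        )
    for s in noise_starts[:n_noise]:
        epochs.append(Epoch(q=norm[s : s + n_ep], index=len(epochs), label=NOISE_CLASS))
    counts[NOISE_CLASS] = int(n_noise)

    if cfg.n_per_class is not None:
        short = {k: v for k, v in counts.items() if v < cfg.n_per_class}
        if short:
            raise ValueError(
                f"requested {cfg.n_per_class} epochs per class but realized "
                f"only {short}; increase duration"
            )

    manifest = {
        "seed": cfg.seed,
        "snr": cfg.snr,
        "snr_mode": cfg.snr_mode,
        "noise_sigma": sigma,
        "noise_bandwidth": cfg.noise_bandwidth,
        "sampling_rate": fs,
        "duration": cfg.duration,
        "firing_rate": cfg.firing_rate,
        "epoch_len": n_ep,
        "class_counts": {int(k): int(v) for k, v in sorted(counts.items())},
    }
    return epochs, manifest


# ---------------------------------------------------------------------------
# Bonn-like EEG surrogate

# (amplitude scale, AR(1) coefficient, burst amplitude) per condition class;
# class 5 is ictal-like: strong rhythmic bursts on top of colored noise
_EEG_CLASS_PARAMS = {
    1: (40.0, 0.90, 0.0),
    2: (60.0, 0.95, 0.0),
    3: (30.0, 0.85, 0.0),
    4: (80.0, 0.97, 0.0),
    5: (100.0, 0.90, 600.0),
}


def _ar1(rng: np.random.Generator, n: int, phi: float, scale: float) -> np.ndarray:
    eps = rng.normal(0.0, scale * np.sqrt(1 - phi**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, scale)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def simulate_eeg_surrogate(
    n_channels: int,
    n_samples: int = 4096,
    sampling_rate: float = 173.61,
    classes: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
) -> list[tuple[TimeSeries, int]]:
    """Surrogate EEG channels in five condition-like classes.

    Channels are assigned to ``classes`` round-robin. Each is AR(1)
    colored noise with a class-specific amplitude and autocorrelation;
    the ictal-like class additionally carries 3 Hz high-amplitude bursts.
    Returns ``(recording, class_id)`` pairs; recordings are raw (not
    normalized) and segment into ``n_samples // epoch_len`` epochs.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[TimeSeries, int]] = []
    t = np.arange(n_samples) / sampling_rate
    for ch in range(n_channels):
        cls = classes[ch % len(classes)]
        amp, phi, burst_amp = _EEG_CLASS_PARAMS[cls]
        x = _ar1(rng, n_samples, phi, amp)
        if burst_amp > 0:
            # rhythmic seizure-like bursts: 3 Hz carrier, smooth on/off
            n_bursts = rng.integers(3, 6)
            for _ in range(n_bursts):
                width = rng.uniform(1.0, 3.0)
                onset = rng.uniform(0, t[-1] - width)
                env = np.exp(-0.5 * ((t - onset - width / 2) / (width / 4)) ** 2)
                phase = rng.uniform(0, 2 * np.pi)
                x += burst_amp * env * np.sin(2 * np.pi * 3.0 * t + phase)
        out.append((TimeSeries(x, sampling_rate, f"ch{ch}"), int(cls)))
    return out
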