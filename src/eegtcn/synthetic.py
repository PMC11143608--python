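"""Seeded surrogate-EEG generator.

Two flavours are supported: 19-channel 500 Hz clinical-style recordings
(healthy background vs. recordings carrying interictal spike-and-wave
complexes and optional ictal bursts) and single-channel 173.61 Hz
benchmark-style records of 23.6 s.

The background model is 1/f^a Gaussian noise plus narrowband Gaussian
oscillations centred on the configured bands (so that no channel carries a
stationary phase that could fingerprint a subject).  Epileptiform events are a
stereotyped biphasic sharp transient followed by a half-sine slow wave,
repeated at ``event_freq`` (3 Hz by default), shared in time across
channels with a per-subject, per-channel amplitude scale.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import CHANNELS_1020, EP, HEALTHY, RawRecording

Event = Tuple[float, float]  # (onset seconds, duration seconds)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the surrogate generator; identical config+seed is bit-reproducible."""

    n_channels: int = 19
    rate: float = 500.0
    duration: float = 60.0
    background_bands: Tuple[Tuple[float, float], ...] = ((10.0, 20.0), (6.0, 10.0))
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    event_rate: float = 12.0          # events per minute
    event_freq: float = 3.0           # spike-wave repetition, Hz
    event_amplitude: float = 300.0    # µV at unit channel scale
    event_duration: Tuple[float, float] = (1.0, 2.0)
    ictal_free_fraction: float = 0.2  # fraction of EP subjects without an ictal burst
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.event_freq <= 0:
            raise ValueError("event_freq must be positive")
        if not 0.0 <= self.ictal_free_fraction <= 1.0:
            raise ValueError("ictal_free_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration * self.rate))


def _channel_names(n_channels: int) -> List[str]:
    if n_channels == len(CHANNELS_1020):
        return list(CHANNELS_1020)
    return [f"ch{i + 1}" for i in range(n_channels)]


def _subject_rng(config: SimulationConfig, subject_id: str, stream: int) -> np.random.Generator:
    # Stable per-subject stream keyed on the config seed and the id's CRC.
    return np.random.default_rng(
        [config.seed, stream, zlib.crc32(subject_id.encode("utf8"))]
    )


def simulate_background(
    config: SimulationConfig,
    subject_id: str = "sim",
    seed: Optional[int] = None,
) -> RawRecording:
    """Generate one healthy-background recording.

    ``seed`` overrides ``config.seed`` (used when generating cohorts so that
    each subject gets an independent, reproducible stream).
    """
    n = config.n_samples
    if n < 1:
        raise ValueError("duration x rate must yield at least one sample")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sig = np.zeros((config.n_channels, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    band_width = 0.5  # Hz, spectral half-width of each oscillatory band
    for c in range(config.n_channels):
        white = rng.standard_normal(n)
        pink = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
        sd = pink.std()
        if sd > 0:
            sig[c] += pink * (config.noise_scale / sd)
        for f0, amp in config.background_bands:
            bump = np.exp(-0.5 * ((freqs - f0) / band_width) ** 2)
            osc = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * bump, n=n)
            sd_osc = osc.std()
            if sd_osc > 0:
                # amp is the equivalent sinusoid amplitude (RMS = amp / sqrt(2))
                sig[c] += osc * (amp / np.sqrt(2.0) / sd_osc)
    return RawRecording(
        subject_id=subject_id,
        group=HEALTHY,
        rate=config.rate,
        channels=_channel_names(config.n_channels),
        signal=sig,
    )


def spike_wave_cycle(rate: float, event_freq: float) -> np.ndarray:
    """One unit-amplitude spike-and-wave period sampled at ``rate``.

    A ~60 ms biphasic sharp transient (peak +1, undershoot -0.3) followed by
    a 0.45-amplitude half-sine slow wave filling the rest of the period.
    """
    period = int(round(rate / event_freq))
    if period < 4:
        raise ValueError("rate too low for the requested event frequency")
    n_up = max(1, int(round(0.015 * rate)))
    n_down = max(1, int(round(0.015 * rate)))
    n_neg = max(1, int(round(0.030 * rate)))
    spike = np.concatenate([
        np.linspace(0.0, 1.0, n_up, endpoint=False),
        np.linspace(1.0, -0.3, n_down, endpoint=False),
        np.linspace(-0.3, 0.0, n_neg, endpoint=False),
    ])
    cycle = np.zeros(period)
    m = min(len(spike), period)
    cycle[:m] = spike[:m]
    if period > m:
        n_slow = period - m
        cycle[m:] = 0.45 * np.sin(np.linspace(0.0, np.pi, n_slow))
    return cycle


def inject_spike_wave(
    rec: RawRecording,
    events: Sequence[Event],
    config: SimulationConfig,
) -> RawRecording:
    """Return a copy of ``rec`` with additive spike-and-wave bursts.

    Each event contributes floor(duration x event_freq) complete cycles
    starting at its onset, shared across channels with a per-channel scale
    in [0.7, 1.0] drawn once per subject.  Samples outside the events are
    untouched.  An empty event list returns an identical copy.
    """
    total = rec.n_samples / rec.rate
    for onset, dur in events:
        if onset < 0 or dur < 0 or onset + dur > total + 1e-9:
            raise ValueError(
                f"event ({onset}, {dur}) outside recording of {total:.3f} s"
            )
    out = rec.copy()
    if not events:
        return out
    rng = _subject_rng(config, rec.subject_id, stream=1)
    scales = 0.7 + 0.3 * rng.random(rec.n_channels)
    cycle = spike_wave_cycle(rec.rate, config.event_freq)
    period = len(cycle)
    for onset, dur in events:
        n_cycles = int(math.floor(dur * config.event_freq))
        if n_cycles == 0:
            continue
        burst = np.tile(cycle, n_cycles)
        start = int(round(onset * rec.rate))
        # crop to the event window so samples outside it stay untouched
        stop = min(start + n_cycles * period,
                   start + int(round(dur * rec.rate)), rec.n_samples)
        burst = burst[: stop - start]
        out.signal[:, start:stop] += (
            config.event_amplitude * scales[:, None] * burst[None, :]
        )
    out.group = EP
    return out


def _draw_events(
    rng: np.random.Generator,
    duration: float,
    event_rate: float,
    event_duration: Tuple[float, float],
    window: Tuple[float, float] = (0.0, 1.0),
) -> List[Event]:
    """Non-overlapping events on a jittered regular grid inside a fractional window."""
    lo, hi = window
    span = (hi - lo) * duration
    n_ev = int(round(event_rate * duration / 60.0))
    if n_ev == 0 or span <= 0:
        return []
    slot = span / n_ev
    d_min, d_max = event_duration
    events: List[Event] = []
    for i in range(n_ev):
        dur = rng.uniform(d_min, min(d_max, slot)) if slot > d_min else slot * 0.9
        onset = lo * duration + i * slot + rng.uniform(0.0, max(slot - dur, 0.0))
        events.append((onset, dur))
    return events


def simulate_cohort(
    n_healthy: int,
    n_ep: int,
    config: SimulationConfig,
) -> List[RawRecording]:
    """Generate a cohort of ``n_healthy`` background-only and ``n_ep`` event-bearing subjects.

    EP subjects carry interictal spike-and-wave events spread over the whole
    recording; all but a configurable fraction additionally receive one
    longer ictal burst (interictal events overlapping the burst are dropped).
    """
    if n_healthy < 0 or n_ep < 0 or n_healthy + n_ep < 1:
        raise ValueError("cohort must contain at least one subject")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        n_healthy + n_ep, dtype=np.uint64
    )
    cohort: List[RawRecording] = []
    for i in range(n_healthy):
        cohort.append(
            simulate_background(config, subject_id=f"h{i + 1:02d}", seed=int(child_seeds[i]))
        )
    n_ictal_free = int(round(config.ictal_free_fraction * n_ep))
    selector = np.random.default_rng([config.seed, 2])
    ictal_free = set(selector.permutation(n_ep)[:n_ictal_free].tolist())
    for j in range(n_ep):
        sid = f"e{j + 1:02d}"
        rec = simulate_background(
            config, subject_id=sid, seed=int(child_seeds[n_healthy + j])
        )
        ev_rng = _subject_rng(config, sid, stream=3)
        burst: List[Event] = []
        if j not in ictal_free:
            b_dur = min(8.0, 0.15 * config.duration)
            b_on = ev_rng.uniform(0.0, config.duration - b_dur)
            burst = [(b_on, b_dur)]
        events = _draw_events(
            ev_rng, config.duration, config.event_rate, config.event_duration,
        )
        if burst:
            b_on, b_dur = burst[0]
            events = [
                (on, du) for on, du in events
                if on + du <= b_on or on >= b_on + b_dur
            ] + burst
        if not events:  # degenerate configs (event_rate 0) still label by intent
            events = [(0.0, 1.0 / config.event_freq)]
        cohort.append(inject_spike_wave(rec, events, config))
    return cohort


BONN_RATE = 173.61
BONN_DURATION = 23.6


def bonn_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Single-channel benchmark-style generator settings."""
    defaults = dict(
        n_channels=1,
        rate=BONN_RATE,
        duration=BONN_DURATION,
        background_bands=((9.0, 15.0), (4.0, 8.0)),
        noise_exponent=1.0,
        noise_scale=12.0,
        event_amplitude=400.0,
        event_freq=3.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def simulate_bonn_style(kind: str, n_segments: int, seed: int = 0) -> List[RawRecording]:
    """Generate single-channel 23.6 s records at 173.61 Hz.

    ``kind="healthy"`` yields background-only records; ``kind="ictal"``
    yields records dominated by continuous high-amplitude rhythmic
    spike-and-wave discharge.
    """
    if kind not in ("healthy", "ictal"):
        raise ValueError(f"unknown kind: {kind!r} (expected 'healthy' or 'ictal')")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    cfg = bonn_config(seed=seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_segments, dtype=np.uint64)
    records: List[RawRecording] = []
    prefix = "Z" if kind == "healthy" else "S"
    for i in range(n_segments):
        rec = simulate_background(
            cfg, subject_id=f"{prefix}{i + 1:03d}", seed=int(child_seeds[i])
        )
        if kind == "ictal":
            rec = inject_spike_wave(rec, [(0.2, BONN_DURATION - 0.4)], cfg)
        records.append(rec)
    return records
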