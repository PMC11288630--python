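"""Spike-train containers and first-order statistics.

This module turns raw voltage traces into spike times, spike times into
inter-spike-interval (ISI) summaries, and spike times into trial-averaged
peri-stimulus histograms (binned responses). Shorter median ISIs under a
treatment indicate burstier firing; the binned responses feed response
classification, population analyses and the behavioral decoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

CONTROL = "control"
SEROTONIN = "5HT"
CONDITIONS = (CONTROL, SEROTONIN)


class SpikeTimeError(ValueError):
    """Raised for spike times that violate the container invariants."""


def _count_bins(trial_duration: float, bin_width: float) -> int:
    n = trial_duration / bin_width
    n_round = round(n)
    if not math.isclose(n, n_round, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"bin_width {bin_width} does not evenly divide duration {trial_duration}"
        )
    return int(n_round)


def window_slice(
    window: tuple[float, float], bin_width: float, n_bins: int
) -> slice:
    """Slice of half-open bins fully inside ``window``."""
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= n_bins * bin_width + 1e-9):
        raise ValueError(f"window {window} not inside the binned trial")
    first = math.ceil(t0 / bin_width - 1e-9)
    last = math.floor(t1 / bin_width + 1e-9)
    if last <= first:
        raise ValueError(f"window {window} contains no whole bin")
    return slice(first, last)


class UndefinedMedianError(ValueError):
    """Raised when an ISI median is requested for a train with < 2 spikes."""


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane-potential trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in mV.
    sample_rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise SpikeTimeError("sample_rate must be positive")
        if samples.size == 0:
            raise SpikeTimeError("empty voltage trace")
        if not np.all(np.isfinite(samples)):
            raise SpikeTimeError("voltage trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron in one trial.

    ``times`` are seconds from trial start and must be strictly increasing.
    Identity metadata (neuron, odorant, condition, trial) travels with the
    train so that downstream grouping never relies on positional bookkeeping.
    """

    times: np.ndarray
    pn_id: str = "pn0"
    odor: str = ""
    condition: str = CONTROL
    trial: int = 0
    duration: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise SpikeTimeError("spike times must be a 1-d array")
        if times.size and not np.all(np.diff(times) > 0):
            raise SpikeTimeError("spike times must be strictly increasing")
        if times.size and times[0] < 0:
            raise SpikeTimeError("spike times must be non-negative")
        if self.duration is not None and times.size and times[-1] >= self.duration:
            raise SpikeTimeError("spike time at or beyond trial duration")

    def __len__(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Successive inter-spike intervals, seconds."""
        return np.diff(self.times)


@dataclass
class ISISummary:
    """Pooled ISIs of one neuron in one condition and their median."""

    pn_id: str
    condition: str
    isis: np.ndarray
    n_trains: int

    @property
    def median_isi(self) -> float:
        if self.isis.size == 0:
            raise UndefinedMedianError(
                f"no ISIs for {self.pn_id}/{self.condition}: need >= 2 spikes"
            )
        return float(np.median(self.isis))


@dataclass
class BinnedResponse:
    """Trial-averaged spike counts in non-overlapping time bins.

    ``counts[k]`` is the mean number of spikes in bin ``[k*Δ, (k+1)*Δ)``
    across trials; real-valued because of the averaging.
    """

    counts: np.ndarray
    bin_width: float
    n_trials: int
    pn_id: str = "pn0"
    odor: str = ""
    condition: str = CONTROL

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("binned counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def trial_duration(self) -> float:
        return self.n_bins * self.bin_width

    def window_slice(self, window: tuple[float, float]) -> slice:
        return window_slice(window, self.bin_width, self.n_bins)


def detect_spikes(
    trace: VoltageTrace,
    min_height_sd: float = 5.0,
    min_separation: float = 0.002,
) -> SpikeTrain:
    """Identify action potentials as threshold-crossing local maxima.

    The threshold is trace-relative: mean + ``min_height_sd`` standard
    deviations of the whole trace. Peaks closer than ``min_separation``
    (default 2 ms, a refractory floor) are resolved in favor of the larger
    peak.

    Returns
    -------
    SpikeTrain
        Peak times in seconds relative to ``trace.t0``.
    """
    v = trace.samples
    threshold = float(np.mean(v) + min_height_sd * np.std(v))
    distance = max(1, int(round(min_separation * trace.sample_rate)))
    idx, _ = find_peaks(v, height=threshold, distance=distance)
    times = idx / trace.sample_rate
    return SpikeTrain(times=times, duration=trace.duration + 1.0 / trace.sample_rate)


def render_voltage_trace(
    train: SpikeTrain,
    duration: float,
    sample_rate: float = 10_000.0,
    spike_height: float = 40.0,
    spike_width: float = 0.001,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Synthesize a voltage trace from spike times (triangular spike template
    on Gaussian noise). Inverse of :func:`detect_spikes` at high SNR; used to
    exercise the detection path without real recordings."""
    rng = rng or np.random.default_rng()
    n = int(round(duration * sample_rate))
    v = rng.normal(0.0, noise_sd, size=n)
    half = max(1, int(round(spike_width * sample_rate / 2)))
    template = spike_height * (1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1))
    for t in train.times:
        center = int(round(t * sample_rate))
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > n:
            continue
        v[lo:hi] += template
    return VoltageTrace(samples=v, sample_rate=sample_rate)


def compute_isis(train: SpikeTrain) -> ISISummary:
    """ISIs of a single train; raises :class:`UndefinedMedianError` for < 2
    spikes (a median would be undefined, and silence would hide it)."""
    if len(train) < 2:
        raise UndefinedMedianError(
            f"train {train.pn_id}/{train.condition} trial {train.trial} "
            f"has {len(train)} spikes; median ISI undefined"
        )
    return ISISummary(
        pn_id=train.pn_id,
        condition=train.condition,
        isis=train.isis(),
        n_trains=1,
    )


def pool_isis(trains: Iterable[SpikeTrain]) -> ISISummary:
    """Pool ISIs of one neuron across trials.

    Intervals are computed within each trial only — the inter-trial gap is
    not a physiological ISI. Trains with fewer than 2 spikes contribute no
    intervals.
    """
    trains = list(trains)
    if not trains:
        raise ValueError("no spike trains supplied")
    pn_ids = {t.pn_id for t in trains}
    conditions = {t.condition for t in trains}
    if len(pn_ids) > 1 or len(conditions) > 1:
        raise ValueError("pool_isis expects trains of one neuron and condition")
    isis = [t.isis() for t in trains if len(t) >= 2]
    pooled = np.concatenate(isis) if isis else np.empty(0)
    return ISISummary(
        pn_id=trains[0].pn_id,
        condition=trains[0].condition,
        isis=pooled,
        n_trains=len(trains),
    )


def bin_spikes(
    trains: Sequence[SpikeTrain],
    bin_width: float,
    trial_duration: float,
) -> BinnedResponse:
    """Trial-averaged histogram of spike counts in half-open bins.

    Every train is one trial of the same neuron/odor/condition; spikes must
    lie in ``[0, trial_duration)``.
    """
    if not trains:
        raise ValueError("no spike trains supplied")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = _count_bins(trial_duration, bin_width)
    total = np.zeros(n_bins)
    for train in trains:
        if len(train) and train.times[-1] >= trial_duration:
            raise SpikeTimeError(
                f"spike at {train.times[-1]:.4f}s >= trial_duration {trial_duration}s"
            )
        idx = np.floor(train.times / bin_width).astype(int)
        total += np.bincount(idx, minlength=n_bins)
    first = trains[0]
    return BinnedResponse(
        counts=total / len(trains),
        bin_width=bin_width,
        n_trials=len(trains),
        pn_id=first.pn_id,
        odor=first.odor,
        condition=first.condition,
    )


def peak_rate(binned: BinnedResponse, window: tuple[float, float]) -> float:
    """Maximum trial-averaged bin count over bins fully inside ``window``."""
    sl = binned.window_slice(window)
    return float(np.max(binned.counts[sl]))
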