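"""Trial structure of the odor-delivery experiment.

A trial is a fixed-length recording window containing a single odor pulse.
The analysis windows derived from it are used everywhere downstream:

* baseline (spontaneous) window: trial start up to odor onset,
* ON window: the odor pulse itself,
* OFF window: the interval of equal length immediately after odor offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class ProtocolError(ValueError):
    """Raised for stimulus protocols that cannot define the analysis windows."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of one odor-presentation trial.

    Defaults follow the standard locust preparation: 40 s trials with a 4 s
    odor pulse starting at the 10th second, five trials per odorant with 20 s
    between trials (electrophysiology); behavioral sessions use 10 trials.

    Parameters
    ----------
    trial_duration : float
        Length of one trial in seconds.
    odor_onset : float
        Time of odor-pulse onset within the trial, seconds.
    odor_duration : float
        Length of the odor pulse, seconds.
    n_trials : int
        Number of repeated trials per odorant.
    inter_trial_interval : float
        Gap between consecutive trials, seconds (metadata; no statistic in
        this package depends on it).
    """

    trial_duration: float = 40.0
    odor_onset: float = 10.0
    odor_duration: float = 4.0
    n_trials: int = 5
    inter_trial_interval: float = 20.0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0 or self.odor_duration <= 0:
            raise ProtocolError("durations must be positive")
        if self.odor_onset < 0:
            raise ProtocolError("odor_onset must be non-negative")
        if self.odor_onset + self.odor_duration > self.trial_duration:
            raise ProtocolError("odor pulse must end within the trial")
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be at least 1")
        if self.inter_trial_interval < 0:
            raise ProtocolError("inter_trial_interval must be non-negative")

    @property
    def baseline_window(self) -> tuple[float, float]:
        """Pre-stimulus window [0, odor_onset)."""
        return (0.0, self.odor_onset)

    @property
    def on_window(self) -> tuple[float, float]:
        """Odor-presentation window [onset, onset + duration)."""
        return (self.odor_onset, self.odor_onset + self.odor_duration)

    @property
    def off_window(self) -> tuple[float, float]:
        """Post-odor window of equal length, [offset, offset + duration)."""
        t0 = self.odor_onset + self.odor_duration
        return (t0, min(t0 + self.odor_duration, self.trial_duration))

    def n_bins(self, bin_width: float) -> int:
        """Number of non-overlapping bins of ``bin_width`` covering the trial."""
        if bin_width <= 0:
            raise ProtocolError("bin_width must be positive")
        n = self.trial_duration / bin_width
        n_round = round(n)
        if not math.isclose(n, n_round, rel_tol=0, abs_tol=1e-9):
            raise ProtocolError(
                f"bin_width {bin_width} does not evenly divide "
                f"trial_duration {self.trial_duration}"
            )
        return int(n_round)

    def window_bins(self, window: tuple[float, float], bin_width: float) -> slice:
        """Slice of bin indices fully inside ``window`` (half-open bins)."""
        t0, t1 = window
        if not (0.0 <= t0 < t1 <= self.trial_duration):
            raise ProtocolError(f"window {window} not inside the trial")
        first = math.ceil(t0 / bin_width - 1e-9)
        last = math.floor(t1 / bin_width + 1e-9)
        if last <= first:
            raise ProtocolError(f"window {window} contains no whole bin")
        return slice(first, last)


#: Behavioral sessions: 10 odor pulses per locust, ~1 min apart.
BEHAVIOR_PROTOCOL = StimulusProtocol(
    trial_duration=40.0,
    odor_onset=10.0,
    odor_duration=4.0,
    n_trials=10,
    inter_trial_interval=56.0,
)
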