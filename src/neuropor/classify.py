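"""ON/OFF response classification and response-robustness summaries.

A projection neuron counts as responsive to an odorant when its
trial-averaged binned activity exceeds a baseline-derived threshold —
the mean pre-stimulus bin count plus ``k_sd`` (default 6.5) baseline
standard deviations — in at least ``min_consecutive_bins`` bins of the ON
window (during the 4 s pulse) or the OFF window (the 4 s after offset).
Robustness across conditions is the fraction of neuron-odor pairs that keep
their control-condition label after treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .protocol import ProtocolError, StimulusProtocol
from .spikes import BinnedResponse


@dataclass(frozen=True)
class ResponseClass:
    """Responsiveness labels of one neuron-odor-condition with threshold
    provenance: ``threshold == baseline_mean + k_sd * baseline_sd`` is
    recomputable from the stored fields."""

    pn_id: str
    odor: str
    condition: str
    on_responsive: bool
    off_responsive: bool
    threshold: float
    baseline_mean: float
    baseline_sd: float
    k_sd: float
    degenerate_baseline: bool = False

    @property
    def label(self) -> str:
        """Single categorical label; ON takes precedence when both windows
        cross threshold (rare outside pathological inputs)."""
        if self.on_responsive:
            return "ON"
        if self.off_responsive:
            return "OFF"
        return "none"


@dataclass(frozen=True)
class RobustnessSummary:
    """Fractions of neuron-odor pairs keeping their control label after
    treatment, with the per-category denominators."""

    fraction_on_maintained: float
    fraction_off_maintained: float
    fraction_nonresponsive_maintained: float
    n_on: int
    n_off: int
    n_nonresponsive: int

    @property
    def n_pairs(self) -> int:
        return self.n_on + self.n_off + self.n_nonresponsive


def _window_exceeds(
    counts: np.ndarray, threshold: float, min_consecutive_bins: int
) -> bool:
    above = counts > threshold
    if min_consecutive_bins <= 1:
        return bool(above.any())
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= min_consecutive_bins:
            return True
    return False


def classify_response(
    binned: BinnedResponse,
    protocol: StimulusProtocol,
    k_sd: float = 6.5,
    min_consecutive_bins: int = 1,
) -> ResponseClass:
    """Label one neuron-odor-condition as ON and/or OFF responsive.

    Baseline statistics come from the trial-averaged bins of the
    pre-stimulus window ``[0, odor_onset)``. A zero baseline SD makes the
    threshold equal the baseline mean; the result is flagged
    ``degenerate_baseline`` since any activity then counts as a response.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    baseline_sl = protocol.window_bins(protocol.baseline_window, binned.bin_width)
    baseline = binned.counts[baseline_sl]
    if baseline.size < 2:
        raise ProtocolError("baseline window must contain >= 2 bins")
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std(ddof=0))
    threshold = baseline_mean + k_sd * baseline_sd
    on_counts = binned.counts[protocol.window_bins(protocol.on_window, binned.bin_width)]
    off_counts = binned.counts[protocol.window_bins(protocol.off_window, binned.bin_width)]
    return ResponseClass(
        pn_id=binned.pn_id,
        odor=binned.odor,
        condition=binned.condition,
        on_responsive=_window_exceeds(on_counts, threshold, min_consecutive_bins),
        off_responsive=_window_exceeds(off_counts, threshold, min_consecutive_bins),
        threshold=threshold,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        k_sd=k_sd,
        degenerate_baseline=baseline_sd == 0.0,
    )


def robustness_fractions(
    control: Iterable[ResponseClass],
    treated: Iterable[ResponseClass],
) -> RobustnessSummary:
    """Fraction of control-ON pairs still ON after treatment, and likewise
    for OFF and nonresponsive pairs. Both sets must cover the same
    (neuron, odor) keys."""
    ctrl = {(c.pn_id, c.odor): c for c in control}
    trt = {(c.pn_id, c.odor): c for c in treated}
    if set(ctrl) != set(trt):
        raise KeyError("control and treated sets must share (pn, odor) keys")
    kept = {"ON": 0, "OFF": 0, "none": 0}
    total = {"ON": 0, "OFF": 0, "none": 0}
    for key, c in ctrl.items():
        label = c.label
        total[label] += 1
        if trt[key].label == label:
            kept[label] += 1

    def frac(label: str) -> float:
        return kept[label] / total[label] if total[label] else float("nan")

    return RobustnessSummary(
        fraction_on_maintained=frac("ON"),
        fraction_off_maintained=frac("OFF"),
        fraction_nonresponsive_maintained=frac("none"),
        n_on=total["ON"],
        n_off=total["OFF"],
        n_nonresponsive=total["none"],
    )


def response_magnitude(
    binned: BinnedResponse, window: tuple[float, float]
) -> dict[str, float]:
    """Peak and mean trial-averaged bin count over a window (spikes/bin)."""
    sl = binned.window_slice(window)
    counts = binned.counts[sl]
    return {"peak": float(counts.max()), "mean": float(counts.mean())}
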