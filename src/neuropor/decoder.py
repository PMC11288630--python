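"""Signed linear decoder mapping population activity onto behavior.

The model assigns one signed weight per projection neuron and reads the
palp-opening probability out of the weighted sum of population activity:

    Y ≈ Wᵀ X,      W = argmin ‖Y − WᵀX‖²  (minimum-norm solution),

where X (units × odor-concatenated time bins, 50 ms trial-averaged counts)
is the design matrix and Y carries each odorant's mean-subtracted p(POR)
inside its stimulus bins and zeros elsewhere. The sign of the fitted weight
partitions the neurons into a promoting ("neuron") ensemble and a
suppressing ("anti-neuron") ensemble; a uniform multiplicative gain applied
to all evoked responses then shifts each odorant's predicted POR up or down
according to the net projection of its response onto W — the mechanism by
which a nonspecific amplification produces odor-specific behavioral change.

Usage follows the Model/Results convention::

    model = PORDecoder(design, target)
    res = model.fit()
    res.summary()
    res.predict_por(block)
    res.amplification_experiment(gain=1.5)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .protocol import StimulusProtocol
from .spikes import BinnedResponse, SpikeTrain, bin_spikes

POSITIVE, NEGATIVE, ZERO = "positive", "negative", "zero"


class DecoderError(ValueError):
    """Raised for inconsistent decoder inputs."""


@dataclass
class DesignMatrix:
    """Units × (odors × bins) trial-averaged spike counts.

    One block of ``n_bins_per_odor`` columns per odorant, concatenated in
    ``odors`` order (the study configuration is 89 units × 3 odors × 800
    bins of 50 ms = 89 × 2400).
    """

    X: np.ndarray
    odors: tuple[str, ...]
    unit_ids: tuple[str, ...]
    bin_width: float
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DecoderError("design matrix must be 2-d")
        if self.X.shape[0] != len(self.unit_ids):
            raise DecoderError("unit_ids length must match row count")
        if self.X.shape[1] % len(self.odors):
            raise DecoderError("column count must be a multiple of the odor count")
        if not np.all(np.isfinite(self.X)):
            raise DecoderError("design matrix must be finite")

    @property
    def n_units(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_bins_per_odor(self) -> int:
        return int(self.X.shape[1] // len(self.odors))

    def block(self, odor: str) -> np.ndarray:
        """Columns of one odorant's block (units × n_bins_per_odor)."""
        if odor not in self.odors:
            raise DecoderError(f"odor {odor!r} not in design")
        k = self.odors.index(odor)
        n = self.n_bins_per_odor
        return self.X[:, k * n : (k + 1) * n]

    def stimulus_bins(self) -> slice:
        """Within-block bin slice of the odor pulse (e.g. bins 200–279 for
        a 10–14 s pulse at 50 ms)."""
        return self.protocol.window_bins(self.protocol.on_window, self.bin_width)


@dataclass
class TargetVector:
    """Mean-subtracted p(POR) inside each odorant's stimulus bins, zero
    elsewhere."""

    y: np.ndarray
    stimulus_mask: np.ndarray
    grand_mean_por: float
    por_probs: dict[str, float]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.stimulus_mask = np.asarray(self.stimulus_mask, dtype=bool)
        if self.y.shape != self.stimulus_mask.shape:
            raise DecoderError("target and mask must have the same shape")
        if np.any(self.y[~self.stimulus_mask] != 0.0):
            raise DecoderError("target must be exactly zero outside stimulus bins")


def build_design(
    recordings: Mapping[str, Mapping[str, Sequence[SpikeTrain]]],
    odors: Sequence[str],
    bin_width: float = 0.05,
    protocol: StimulusProtocol | None = None,
) -> DesignMatrix:
    """Assemble the odor-concatenated design matrix from spike trains.

    Parameters
    ----------
    recordings : mapping
        ``{unit_id: {odor: [trial SpikeTrains]}}``; every unit must carry
        every odorant in ``odors``.
    odors : sequence of str
        Block concatenation order.
    bin_width : float
        Bin width in seconds (default 50 ms).
    """
    proto = protocol or StimulusProtocol()
    unit_ids = tuple(sorted(recordings))
    if not unit_ids:
        raise DecoderError("no recordings supplied")
    blocks = []
    for odor in odors:
        rows = []
        for unit_id in unit_ids:
            if odor not in recordings[unit_id]:
                raise DecoderError(f"unit {unit_id!r} missing odor {odor!r}")
            binned = bin_spikes(
                list(recordings[unit_id][odor]), bin_width, proto.trial_duration
            )
            rows.append(binned.counts)
        blocks.append(np.vstack(rows))
    return DesignMatrix(
        X=np.hstack(blocks),
        odors=tuple(odors),
        unit_ids=unit_ids,
        bin_width=bin_width,
        protocol=proto,
    )


def build_design_from_binned(
    binned: Mapping[str, Mapping[str, BinnedResponse]],
    odors: Sequence[str],
    protocol: StimulusProtocol | None = None,
) -> DesignMatrix:
    """Design matrix from pre-binned responses ``{unit: {odor: BinnedResponse}}``."""
    unit_ids = tuple(sorted(binned))
    if not unit_ids:
        raise DecoderError("no binned responses supplied")
    bin_width = next(iter(next(iter(binned.values())).values())).bin_width
    blocks = []
    for odor in odors:
        rows = []
        for unit_id in unit_ids:
            if odor not in binned[unit_id]:
                raise DecoderError(f"unit {unit_id!r} missing odor {odor!r}")
            resp = binned[unit_id][odor]
            if resp.bin_width != bin_width:
                raise DecoderError("all responses must share one bin width")
            rows.append(resp.counts)
        blocks.append(np.vstack(rows))
    proto = protocol or StimulusProtocol()
    return DesignMatrix(
        X=np.hstack(blocks),
        odors=tuple(odors),
        unit_ids=unit_ids,
        bin_width=bin_width,
        protocol=proto,
    )


def build_target(
    por_probs: Mapping[str, float],
    grand_mean: float,
    design: DesignMatrix,
) -> TargetVector:
    """Target vector for a design: each odor block's stimulus bins carry
    ``p(POR)_odor − grand_mean``; every other entry is exactly zero."""
    for odor, p in por_probs.items():
        if not 0.0 <= p <= 1.0:
            raise DecoderError(f"p(POR) for {odor!r} outside [0, 1]")
    missing = set(design.odors) - set(por_probs)
    if missing:
        raise DecoderError(f"missing p(POR) for odors: {sorted(missing)}")
    n = design.n_bins_per_odor
    stim = design.stimulus_bins()
    y = np.zeros(len(design.odors) * n)
    mask = np.zeros_like(y, dtype=bool)
    for k, odor in enumerate(design.odors):
        block = slice(k * n + stim.start, k * n + stim.stop)
        y[block] = por_probs[odor] - grand_mean
        mask[block] = True
    return TargetVector(
        y=y,
        stimulus_mask=mask,
        grand_mean_por=float(grand_mean),
        por_probs=dict(por_probs),
    )


class PORDecoder:
    """Linear POR decoder model: data in, :meth:`fit` out.

    Parameters
    ----------
    design : DesignMatrix
        Odor-concatenated trial-averaged population activity.
    target : TargetVector
        Mean-subtracted POR probabilities on the stimulus bins.
    """

    def __init__(self, design: DesignMatrix, target: TargetVector) -> None:
        if target.y.size != design.X.shape[1]:
            raise DecoderError("target length must equal design column count")
        self.design = design
        self.target = target

    @classmethod
    def from_recordings(
        cls,
        recordings: Mapping[str, Mapping[str, Sequence[SpikeTrain]]],
        por_probs: Mapping[str, float],
        grand_mean: float | None = None,
        bin_width: float = 0.05,
        protocol: StimulusProtocol | None = None,
    ) -> "PORDecoder":
        """Build design and target directly from spike trains and per-odor
        POR probabilities (grand mean defaults to the mean of the supplied
        probabilities)."""
        odors = tuple(por_probs)
        design = build_design(recordings, odors, bin_width, protocol)
        gm = float(np.mean(list(por_probs.values()))) if grand_mean is None else grand_mean
        return cls(design, build_target(por_probs, gm, design))

    def fit(self, rcond: float = 1e-10, ridge: float = 0.0) -> "DecoderResults":
        """Solve the normal equations for the per-unit weights.

        Minimum-norm least squares via SVD with relative singular-value
        cutoff ``rcond``; with ``ridge > 0`` the ridge-regularized normal
        equations ``(XXᵀ + ridge·I)W = XY`` are solved instead.
        """
        X, y = self.design.X, self.target.y
        if ridge < 0:
            raise DecoderError("ridge must be >= 0")
        if ridge > 0:
            gram = X @ X.T + ridge * np.eye(X.shape[0])
            weights = np.linalg.solve(gram, X @ y)
            s = np.linalg.svd(X, compute_uv=False)
            rank = int(np.sum(s > rcond * s[0]))
        else:
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            cutoff = rcond * s[0] if s.size else 0.0
            keep = s > cutoff
            rank = int(keep.sum())
            # min-norm solution of Xᵀ W ≈ y:  W = U diag(1/s) Vᵀ y  (kept SVs)
            weights = U[:, keep] @ ((Vt[keep] @ y) / s[keep])
        cond = float(s[0] / s[rank - 1]) if rank else np.inf
        return DecoderResults(
            model=self,
            weights=weights,
            rank=rank,
            singular_values=s,
            condition_number=cond,
            ill_conditioned=rank < X.shape[0],
            ridge=ridge,
        )


@dataclass
class DecoderResults:
    """Fitted decoder: weights, conditioning diagnostics and predictions."""

    model: PORDecoder
    weights: np.ndarray
    rank: int
    singular_values: np.ndarray
    condition_number: float
    ill_conditioned: bool
    ridge: float = 0.0

    @property
    def grand_mean_por(self) -> float:
        return self.model.target.grand_mean_por

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return self.model.design.unit_ids

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.weights @ self.model.design.X

    @property
    def resid(self) -> np.ndarray:
        return self.model.target.y - self.fittedvalues

    def ensembles(self) -> dict[str, tuple[str, ...]]:
        """Strict sign partition of the units by fitted weight."""
        sign = np.sign(self.weights)
        ids = np.asarray(self.unit_ids)
        return {
            POSITIVE: tuple(ids[sign > 0]),
            NEGATIVE: tuple(ids[sign < 0]),
            ZERO: tuple(ids[sign == 0]),
        }

    def ensemble_labels(self) -> np.ndarray:
        return np.where(
            self.weights > 0, POSITIVE, np.where(self.weights < 0, NEGATIVE, ZERO)
        )

    def _net_projection(self, block: np.ndarray) -> float:
        """Mean stimulus-bin weighted population activity of one odor block."""
        block = np.asarray(block, dtype=float)
        if block.shape[0] != self.weights.size:
            raise DecoderError("response block has wrong unit count")
        stim = self.model.design.stimulus_bins()
        return float(np.mean(self.weights @ block[:, stim]))

    def predict_por(self, block: np.ndarray) -> float:
        """Predicted p(POR): grand mean plus the mean stimulus-bin weighted
        population activity of the odor's response block."""
        return self.grand_mean_por + self._net_projection(block)

    def predicted_vs_observed(self) -> dict[str, tuple[float, float]]:
        """In-sample ``{odor: (predicted, observed)}`` on the training odors."""
        out = {}
        for odor in self.model.design.odors:
            pred = self.predict_por(self.model.design.block(odor))
            out[odor] = (pred, self.model.target.por_probs[odor])
        return out

    def amplification_experiment(
        self, gain: float, blocks: Mapping[str, np.ndarray] | None = None
    ) -> dict[str, float]:
        """Predicted POR change per odorant under uniform response gain.

        Scaling every response by ``gain`` changes the prediction by
        ``Δp = (gain − 1) × mean stimulus-bin WᵀX_odor``; the sign of Δp is
        the sign of the odor's net projection onto the weights, so a
        uniform amplification raises predicted POR for odorants loading on
        the positive ensemble and lowers it for those loading on the
        negative ensemble.
        """
        if gain < 1:
            raise DecoderError("gain must be >= 1 (the treatment only amplifies)")
        if blocks is None:
            blocks = {o: self.model.design.block(o) for o in self.model.design.odors}
        return {
            odor: (gain - 1.0) * self._net_projection(block)
            for odor, block in blocks.items()
        }

    def to_dict(self) -> dict:
        """JSON-serializable model record."""
        return {
            "unit_ids": list(self.unit_ids),
            "weights": self.weights.tolist(),
            "grand_mean_por": self.grand_mean_por,
            "ensemble_labels": self.ensemble_labels().tolist(),
            "rank": self.rank,
            "condition_number": self.condition_number,
            "ill_conditioned": bool(self.ill_conditioned),
            "ridge": self.ridge,
            "odors": list(self.model.design.odors),
            "por_probs": self.model.target.por_probs,
            "bin_width": self.model.design.bin_width,
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        ens = self.ensembles()
        lines = [
            "POR linear decoder",
            "==================",
            f"units: {len(self.unit_ids)}   design: "
            f"{self.model.design.X.shape[0]} x {self.model.design.X.shape[1]}",
            f"odors: {', '.join(self.model.design.odors)}",
            f"grand mean p(POR): {self.grand_mean_por:.3f}",
            f"rank: {self.rank}   condition number: {self.condition_number:.3g}"
            + ("   [ill-conditioned: minimum-norm solution]" if self.ill_conditioned else ""),
            f"ensembles: {len(ens[POSITIVE])} positive / {len(ens[NEGATIVE])} negative"
            f" / {len(ens[ZERO])} zero",
            "",
            "odor    predicted  observed",
        ]
        for odor, (pred, obs) in self.predicted_vs_observed().items():
            lines.append(f"{odor:<8}{pred:>8.3f}{obs:>10.3f}")
        return "\n".join(lines)

    def plot_weights(self, order: Sequence[int] | None = None, ax=None):
        """Bar plot of per-unit weights (optionally in a given unit order)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        w = self.weights if order is None else self.weights[np.asarray(order)]
        colors = np.where(w >= 0, "tab:red", "tab:blue")
        ax.bar(np.arange(w.size), w, color=colors)
        ax.set_xlabel("unit (ordered)")
        ax.set_ylabel("weight")
        return ax


def fit_weights(
    design: DesignMatrix,
    target: TargetVector,
    rcond: float = 1e-10,
    ridge: float = 0.0,
) -> DecoderResults:
    """Functional wrapper: ``PORDecoder(design, target).fit(...)``."""
    return PORDecoder(design, target).fit(rcond=rcond, ridge=ridge)


def segregate_ensembles(results: DecoderResults) -> dict[str, tuple[str, ...]]:
    """Sign partition of the fitted weights (see
    :meth:`DecoderResults.ensembles`)."""
    return results.ensembles()


def order_units_by_contrast(
    design: DesignMatrix, odor_a: str, odor_b: str
) -> np.ndarray:
    """Unit indices in descending order of (peak stimulus-window response to
    ``odor_a`` − peak to ``odor_b``); ties break by unit id."""
    stim = design.stimulus_bins()
    peak_a = design.block(odor_a)[:, stim].max(axis=1)
    peak_b = design.block(odor_b)[:, stim].max(axis=1)
    contrast = peak_a - peak_b
    # stable sort on unit id, then stable descending sort on contrast
    ids_order = np.argsort(np.asarray(design.unit_ids))
    order = ids_order[np.argsort(-contrast[ids_order], kind="stable")]
    return order
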