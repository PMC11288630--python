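"""Population-level analyses: stacked condition matrices, PCA trajectories
and the bin-by-bin correlation matrix.

The population matrix stacks the trial-averaged binned responses of every
neuron-odor combination in the control condition on top of the same
combinations after serotonin (82 combinations per condition → 164 rows of
200 bins at the default 200 ms binning of a 40 s trial). Each column is the
population activity vector of one time bin; columns are compared by Pearson
correlation, and the whole matrix is visualized by projecting the bin
vectors onto the top two eigenvectors of the response covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .protocol import StimulusProtocol
from .spikes import BinnedResponse, CONTROL, SEROTONIN


@dataclass
class PopulationMatrix:
    """Units × time-bins trial-averaged spike counts.

    Rows are (neuron-odor, condition) units in stacking order
    (all control rows first, then all treated rows); columns are time bins.
    """

    values: np.ndarray
    unit_labels: list[tuple[str, str]]  # (unit id, condition)
    bin_width: float
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("population matrix must be 2-d")
        if len(self.unit_labels) != self.values.shape[0]:
            raise ValueError("unit_labels length must match row count")

    @property
    def n_units(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[1])

    def condition_rows(self, condition: str) -> np.ndarray:
        return np.array([lab[1] == condition for lab in self.unit_labels])

    def window_slice(self, window: tuple[float, float]) -> slice:
        return self.protocol.window_bins(window, self.bin_width)


@dataclass
class Trajectory2D:
    """Per-bin coordinates on the top-2 principal axes, in time order."""

    coords: np.ndarray  # (n_bins, 2)
    explained_variance_ratio: np.ndarray  # (2,)
    components: np.ndarray  # (2, n_units) orthonormal eigenvectors
    bin_width: float

    def plot(self, ax=None, protocol: StimulusProtocol | None = None):
        """Closed-loop trajectory colored by analysis window (lazy import of
        matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        proto = protocol or StimulusProtocol()
        t = np.arange(self.coords.shape[0]) * self.bin_width
        on0, on1 = proto.on_window
        off0, off1 = proto.off_window
        seg = np.where(
            (t >= on0) & (t < on1), "ON", np.where((t >= off0) & (t < off1), "OFF", "spont")
        )
        colors = {"spont": "0.6", "ON": "tab:green", "OFF": "tab:purple"}
        for name, color in colors.items():
            mask = seg == name
            ax.plot(self.coords[mask, 0], self.coords[mask, 1], ".", color=color, label=name)
        ax.plot(self.coords[:, 0], self.coords[:, 1], "-", lw=0.5, color="0.8", zorder=0)
        ax.set_xlabel(f"PC1 ({self.explained_variance_ratio[0]:.0%})")
        ax.set_ylabel(f"PC2 ({self.explained_variance_ratio[1]:.0%})")
        ax.legend(frameon=False)
        return ax


@dataclass
class CorrelationMatrix:
    """Bins × bins Pearson correlations of population activity vectors.

    ``defined[i]`` is False when bin ``i`` has zero variance across units;
    its row/column of ``C`` is NaN (never silently zero).
    """

    C: np.ndarray
    sigma: np.ndarray
    defined: np.ndarray

    def mean_block(self, rows: slice, cols: slice) -> float:
        """Mean correlation over a block, ignoring undefined entries."""
        block = self.C[rows, cols]
        return float(np.nanmean(block))


def build_population_matrix(
    binned: Mapping[str, Mapping[str, BinnedResponse]],
    conditions: Sequence[str] = (CONTROL, SEROTONIN),
    protocol: StimulusProtocol | None = None,
) -> PopulationMatrix:
    """Stack trial-averaged responses condition-block by condition-block.

    Parameters
    ----------
    binned : mapping
        ``{unit_id: {condition: BinnedResponse}}`` where a unit is one
        neuron-odor combination. Every unit must be present in every
        requested condition.
    conditions : sequence of str
        Stacking order (control first by default).
    """
    if not binned:
        raise ValueError("no binned responses supplied")
    unit_ids = sorted(binned)
    rows, labels = [], []
    bin_widths = set()
    for condition in conditions:
        for unit_id in unit_ids:
            by_cond = binned[unit_id]
            if condition not in by_cond:
                raise KeyError(f"unit {unit_id!r} missing condition {condition!r}")
            resp = by_cond[condition]
            rows.append(resp.counts)
            labels.append((unit_id, condition))
            bin_widths.add(resp.bin_width)
    if len(bin_widths) != 1:
        raise ValueError("all responses must share one bin width")
    bin_width = bin_widths.pop()
    proto = protocol or StimulusProtocol(trial_duration=rows[0].size * bin_width)
    return PopulationMatrix(
        values=np.vstack(rows), unit_labels=labels, bin_width=bin_width, protocol=proto
    )


def pca_trajectories(pop: PopulationMatrix) -> Trajectory2D:
    """Project each time bin's population vector onto the top two
    eigenvectors of the response covariance matrix.

    Bins are observations and units variables; each unit is mean-centered
    across bins. Eigenvector signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    X = pop.values
    centered = X - X.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("population matrix has no variance across bins")
    cov = np.cov(centered, rowvar=True, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_comp = min(2, eigvec.shape[1])
    comps = eigvec[:, :n_comp].T.copy()
    for k in range(n_comp):
        lead = np.argmax(np.abs(comps[k]))
        if comps[k, lead] < 0:
            comps[k] *= -1
    coords = centered.T @ comps.T
    if n_comp < 2:  # degenerate single-unit case: pad with zeros
        coords = np.column_stack([coords, np.zeros(coords.shape[0])])
        comps = np.vstack([comps, np.zeros_like(comps)])
        eigval = np.append(eigval, 0.0)
    total = eigval[eigval > 0].sum()
    evr = np.maximum(eigval[:2], 0.0) / total if total > 0 else np.zeros(2)
    return Trajectory2D(
        coords=coords,
        explained_variance_ratio=evr,
        components=comps,
        bin_width=pop.bin_width,
    )


def _pearson_between_columns(A: np.ndarray, B: np.ndarray):
    """Pearson correlation between every column of A and every column of B
    (columns are population vectors over units)."""
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    n = A.shape[0]
    sa = Ac.std(axis=0, ddof=0)
    sb = Bc.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Ac.T @ Bc) / n / np.outer(sa, sb)
    defined_a, defined_b = sa > 0, sb > 0
    C[~defined_a, :] = np.nan
    C[:, ~defined_b] = np.nan
    return C, sa, sb, defined_a, defined_b


def binwise_correlation(pop: PopulationMatrix) -> CorrelationMatrix:
    """Bin-by-bin correlation matrix of the stacked population matrix.

    ``C[i, j]`` is the Pearson correlation between the population activity
    vectors of bins ``i`` and ``j``; ``sigma[i]`` is the SD of bin ``i``
    across units. Zero-variance bins are marked undefined (NaN).
    """
    if pop.n_units < 2:
        raise ValueError("binwise correlation needs >= 2 units")
    C, sa, _, defined, _ = _pearson_between_columns(pop.values, pop.values)
    return CorrelationMatrix(C=C, sigma=sa, defined=defined)


def cross_condition_correlation(
    pop: PopulationMatrix,
    condition_a: str = CONTROL,
    condition_b: str = SEROTONIN,
) -> CorrelationMatrix:
    """Correlation between bin vectors restricted to one condition's rows
    and bin vectors restricted to the other's.

    ``C[i, j]`` compares the condition-A population vector of bin ``i``
    against the condition-B vector of bin ``j`` — e.g. stimulus-window
    columns correlate strongly across conditions when treatment scales
    responses without changing tuning, while independent spontaneous
    activity decorrelates.
    """
    rows_a = pop.condition_rows(condition_a)
    rows_b = pop.condition_rows(condition_b)
    if rows_a.sum() < 2 or rows_b.sum() < 2:
        raise ValueError("each condition needs >= 2 units")
    C, sa, sb, defined_a, defined_b = _pearson_between_columns(
        pop.values[rows_a], pop.values[rows_b]
    )
    return CorrelationMatrix(C=C, sigma=sa, defined=defined_a & defined_b)
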