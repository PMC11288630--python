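"""Palp-opening response (POR) statistics.

The POR is a binary appetitive behavior: on each odor trial a locust either
opens its maxillary palps (1) or does not (0). A session is a locusts × trials
binary matrix per odorant and condition. The response probability is the
plain proportion

    p(POR) = (sum of all entries) / (n_locusts × n_trials),

and before/after-treatment comparisons use a one-tailed paired-sample t-test
on per-locust trial-summed POR counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class PORValidationError(ValueError):
    """Raised for POR matrices that are not rectangular binary arrays."""


@dataclass
class PORMatrix:
    """Binary palp-opening outcomes, locusts × trials, for one odorant in one
    condition.

    Parameters
    ----------
    values : ndarray of {0, 1}
        ``values[i, j]`` is 1 if locust ``i`` opened its palps on trial ``j``.
    odor, condition : str
        Labels for the odorant and the treatment condition.
    concentration : float
        Odor concentration in % v/v (metadata).
    locust_ids : sequence of str, optional
        Row labels; defaults to ``locust01..``.
    """

    values: np.ndarray
    odor: str = ""
    condition: str = "control"
    concentration: float = 1.0
    locust_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise PORValidationError("POR matrix must be non-empty and 2-d")
        if not np.isin(values, (0, 1)).all():
            raise PORValidationError("POR entries must be 0 or 1")
        self.values = values.astype(int)
        if not self.locust_ids:
            self.locust_ids = [f"locust{i + 1:02d}" for i in range(values.shape[0])]
        elif len(self.locust_ids) != values.shape[0]:
            raise PORValidationError("locust_ids length must match row count")

    @property
    def n_locusts(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_trials(self) -> int:
        return int(self.values.shape[1])

    def per_locust_scores(self) -> np.ndarray:
        """Trial-summed POR count per locust — the paired-test unit."""
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class PairedTestResult:
    """One-tailed paired-sample t-test on per-locust POR scores."""

    t_statistic: float
    p_value: float
    direction: str
    n: int
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (degenerate: zero-variance differences)" if self.degenerate else ""
        return (
            f"paired t-test ({self.direction}): t = {self.t_statistic:.3f}, "
            f"one-tailed p = {self.p_value:.4f}, n = {self.n}{flag}"
        )


def por_probability(matrix: PORMatrix) -> float:
    """Probability of palp opening: total PORs over locusts × trials."""
    return float(matrix.values.sum()) / (matrix.n_locusts * matrix.n_trials)


def paired_onetailed_ttest(
    before: np.ndarray,
    after: np.ndarray,
    direction: str = "greater",
) -> PairedTestResult:
    """One-tailed paired t-test on differences ``d = after − before``.

    ``direction="greater"`` tests whether scores increased after treatment,
    ``"less"`` whether they decreased. Zero-variance differences cannot
    support a t-statistic: all-zero differences give p = 0.5, and a constant
    nonzero shift gives the boundary p (0 or 1), both flagged ``degenerate``.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1-d vectors")
    n = before.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = d.mean()
        if mean == 0.0:
            return PairedTestResult(0.0, 0.5, direction, n, degenerate=True)
        favored = (mean > 0) == (direction == "greater")
        t = np.inf if mean > 0 else -np.inf
        return PairedTestResult(float(t), 0.0 if favored else 1.0, direction, n, degenerate=True)
    res = stats.ttest_rel(after, before, alternative=direction)
    return PairedTestResult(float(res.statistic), float(res.pvalue), direction, n)


def compare_conditions(
    before: PORMatrix, after: PORMatrix, direction: str = "greater"
) -> PairedTestResult:
    """Paired test between two POR matrices of the same locusts."""
    if before.values.shape != after.values.shape:
        raise PORValidationError("paired POR matrices must have the same shape")
    return paired_onetailed_ttest(
        before.per_locust_scores(), after.per_locust_scores(), direction
    )


def dose_response_table(
    matrices: Mapping[float, Mapping[str, PORMatrix]],
    direction: str = "greater",
) -> pd.DataFrame:
    """p(POR) by concentration × condition, with a paired test per
    concentration.

    Parameters
    ----------
    matrices : mapping
        ``{concentration: {"control": PORMatrix, "5HT": PORMatrix}}`` (any two
        condition keys; the first key in insertion order is "before").
    direction : str
        Tail of the per-concentration paired test.

    Returns
    -------
    DataFrame
        Tidy rows: concentration, condition, p_por, plus per-concentration
        t/p columns.
    """
    if not matrices:
        raise ValueError("no POR matrices supplied")
    rows = []
    for conc in sorted(matrices):
        by_cond = matrices[conc]
        if len(by_cond) < 1:
            raise ValueError(f"missing conditions at concentration {conc}")
        conds = list(by_cond)
        test = None
        if len(conds) >= 2:
            test = compare_conditions(by_cond[conds[0]], by_cond[conds[1]], direction)
        elif len(conds) != 1:
            raise ValueError(f"missing condition at concentration {conc}")
        for cond in conds:
            rows.append(
                {
                    "concentration": conc,
                    "condition": cond,
                    "p_por": por_probability(by_cond[cond]),
                    "t_statistic": test.t_statistic if test else np.nan,
                    "p_value": test.p_value if test else np.nan,
                }
            )
    return pd.DataFrame(rows)
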