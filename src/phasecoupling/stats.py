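"""Stage-comparison statistics: Friedman test and rank-based post hoc.

The repeated-measures design is subjects × protocol stages for one measure
(coupling strength sigma or similarity rho).  Stage differences are tested
with the non-parametric Friedman test; when significant, pairwise stage
differences are located with a Tukey-style comparison of within-subject
rank sums using studentized-range (Nemenyi-type) critical values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = ["StageMatrix", "friedman_test", "posthoc_pairwise"]


@dataclass
class StageMatrix:
    """Subjects × stages matrix of one scalar measure."""

    values: np.ndarray
    stage_labels: list[str]
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValidationError("stage matrix must be 2-D")
        n_sub, n_stage = self.values.shape
        if n_stage != len(self.stage_labels):
            raise ValidationError("one label per stage column required")
        if n_sub < 2 or n_stage < 2:
            raise ValidationError("need >= 2 subjects and >= 2 stages")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("stage matrix has missing cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.stage_labels)


def friedman_test(matrix: StageMatrix) -> tuple[float, float]:
    """Friedman chi-square test across stages (within-subject ranks).

    Returns ``(statistic, p_value)`` from the chi-square approximation with
    average ranks for ties.  Requires at least 3 stages (the approximation
    is invalid for two).
    """
    if matrix.n_stages < 3:
        raise ValidationError("Friedman chi-square needs >= 3 stages")
    if np.allclose(matrix.values, matrix.values[:, [0]]):
        # identical stages: zero statistic, p = 1 (scipy rejects this input)
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*matrix.values.T)
    return float(stat), float(p)


def posthoc_pairwise(matrix: StageMatrix, alpha: float = 0.05
                     ) -> set[tuple[str, str]]:
    """Tukey-style post hoc on within-subject rank sums after Friedman.

    Runs the Friedman test first; if its p-value is not below ``alpha`` the
    result is the empty set.  Otherwise stage pairs whose mean-rank
    difference exceeds the Nemenyi critical difference

        CD = q_{alpha, k, inf} / sqrt(2) * sqrt(k (k + 1) / (6 n))

    are reported as ``(label_i, label_j)`` with i < j in column order.
    """
    if alpha < 0 or alpha > 1:
        raise ValidationError("alpha must be in [0, 1]")
    if alpha == 0:
        return set()
    _, p = friedman_test(matrix)
    if not p < alpha:
        return set()
    ranks = sps.rankdata(matrix.values, axis=1)
    mean_ranks = ranks.mean(axis=0)
    k = matrix.n_stages
    n = matrix.n_subjects
    q = sps.studentized_range.ppf(1 - alpha, k, np.inf)
    cd = q / np.sqrt(2) * np.sqrt(k * (k + 1) / (6.0 * n))
    out: set[tuple[str, str]] = set()
    for i, j in combinations(range(k), 2):
        if abs(mean_ranks[i] - mean_ranks[j]) > cd:
            out.add((matrix.stage_labels[i], matrix.stage_labels[j]))
    return out
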