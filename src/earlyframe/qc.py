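"""Correlation-based cohort homogeneity QC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QcReport", "homogeneity_qc"]


@dataclass
class QcReport:
    """Per-subject mean pairwise correlation with the rest of the cohort and
    outlier flags (statistic below cohort mean minus 2 SD)."""

    table: pd.DataFrame  # columns: id, mean_corr, flagged
    cohort_mean: float
    cohort_sd: float

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "id"])


def homogeneity_qc(
    maps: np.ndarray,
    subject_ids: list[str] | None = None,
    include: np.ndarray | None = None,
) -> QcReport:
    """Flag subjects whose preprocessed map correlates poorly with the rest.

    ``maps`` is (n_subjects, n_vertices); the subject statistic is the mean
    of its off-diagonal row in the pairwise Pearson matrix over included
    vertices; flagged iff statistic < cohort mean - 2 * cohort SD.
    """
    x = np.asarray(maps, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("homogeneity QC needs at least 3 subjects")
    if include is not None:
        x = x[:, include]
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    corr = np.corrcoef(x)
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    stat = np.nanmean(off, axis=1)
    mean, sd = float(stat.mean()), float(stat.std(ddof=1))
    flagged = stat < mean - 2.0 * sd
    table = pd.DataFrame({"id": subject_ids, "mean_corr": stat, "flagged": flagged})
    return QcReport(table, mean, sd)
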