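"""Doubly standardized read-depth statistic alpha.

For sample i and chromosome j with mapped-read count n_ij,

    alpha_ij = n_ij * N / (row_sum_i * col_sum_j),

where N is the grand total.  alpha_ij > 1 means sample i carries more
reads on chromosome j than expected from its overall depth and the
chromosome's overall share — the visual signature of a dosage gain;
alpha_ij < 1 likewise flags a loss.  alpha is a diagnostic: the MCMC
model consumes raw counts, not alpha.

Because library amplification can distort per-chromosome capture,
alpha may also be computed within strata of PCR-cycle groups, each
stratum using its own totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .errors import DomainError


@dataclass(frozen=True)
class AlphaMatrix:
    """alpha values with the same shape/ordering as the source counts."""

    alpha: np.ndarray
    sample_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    group_label: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.alpha, index=list(self.sample_ids), columns=list(self.chromosomes)
        ).rename_axis("sample_id")


def alpha_matrix(counts: CountMatrix, group_label: str | None = None) -> AlphaMatrix:
    """Compute alpha for every cell of a count matrix.

    Raises
    ------
    DomainError
        If any sample (row) or chromosome (column) has zero total
        count: the standardization is undefined there.
    """
    n = counts.counts.astype(float)
    row = counts.row_totals.astype(float)
    col = counts.column_totals.astype(float)
    zero_rows = np.flatnonzero(row == 0)
    if zero_rows.size:
        bad = [counts.sample_ids[i] for i in zero_rows]
        raise DomainError(f"zero total depth for sample(s) {bad}; alpha undefined")
    zero_cols = np.flatnonzero(col == 0)
    if zero_cols.size:
        bad = [counts.chromosomes[j] for j in zero_cols]
        raise DomainError(f"zero total depth for chromosome(s) {bad}; alpha undefined")
    alpha = n * counts.N / np.outer(row, col)
    return AlphaMatrix(alpha, counts.sample_ids, counts.chromosomes, group_label)


def stratified_alpha(
    counts: CountMatrix, groups: Mapping[str, object]
) -> list[AlphaMatrix]:
    """alpha computed separately within each stratum.

    Each group's alpha uses only that group's rows — its own grand
    total, row sums and column sums — so group-specific capture or
    amplification profiles cancel within the group.

    Parameters
    ----------
    groups
        Map sample_id -> group label; every sample must be assigned.

    Returns
    -------
    One :class:`AlphaMatrix` per non-empty group, ordered by sorted
    group label.  A single-sample group triggers a warning (its alpha
    reflects only the within-sample chromosome profile and degenerates
    toward 1).
    """
    unassigned = [s for s in counts.sample_ids if s not in groups]
    if unassigned:
        raise DomainError(f"samples without a group assignment: {unassigned}")
    labels = sorted({str(groups[s]) for s in counts.sample_ids})
    out: list[AlphaMatrix] = []
    for label in labels:
        members = [s for s in counts.sample_ids if str(groups[s]) == label]
        if not members:  # pragma: no cover - labels derive from members
            warnings.warn(f"group {label!r} is empty; excluded from output")
            continue
        if len(members) == 1:
            warnings.warn(
                f"group {label!r} has a single sample; alpha within it is "
                "driven by the within-sample chromosome profile only"
            )
        out.append(alpha_matrix(counts.subset(members), group_label=label))
    return out
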