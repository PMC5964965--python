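"""Descriptor-matrix cleaning and lipophilicity-descriptor screening.

Molecular descriptor tables exported from prediction software routinely
contain columns that are useless for regression: values missing for some
compounds, non-numeric entries, or (near-)constant columns.
:func:`clean_descriptors` removes them in that fixed order and reports
exactly which column fell to which rule, so a 506-descriptor export can be
reduced to a clean numeric matrix reproducibly.

:func:`rank_lipophilicity_descriptors` screens candidate log P estimates
against measured HPLC retention times (an experimental lipophilicity proxy):
each candidate is scored by the Pearson correlation with retention time over
compounds where both are available, and candidates are ranked by |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CompoundTable
from .errors import InputError

__all__ = ["CleaningReport", "clean_descriptors", "rank_lipophilicity_descriptors"]


@dataclass
class CleaningReport:
    """Which descriptor columns were removed, and why.

    The four lists partition the input column names; ``retained`` are the
    survivors in their original order.
    """

    removed_incomplete: list = field(default_factory=list)
    removed_nonnumeric: list = field(default_factory=list)
    removed_low_variation: list = field(default_factory=list)
    retained: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_incomplete)
            + len(self.removed_nonnumeric)
            + len(self.removed_low_variation)
        )

    def to_dict(self) -> dict:
        return {
            "removed_incomplete": list(self.removed_incomplete),
            "removed_nonnumeric": list(self.removed_nonnumeric),
            "removed_low_variation": list(self.removed_low_variation),
            "retained": list(self.retained),
        }


def clean_descriptors(
    matrix: pd.DataFrame, variation_threshold: float = 1e-8
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove incomplete, non-numeric and (near-)constant descriptor columns.

    Rules apply in order: (1) any missing value -> removed_incomplete;
    (2) not coercible to numeric -> removed_nonnumeric; (3) sample standard
    deviation <= ``variation_threshold * |mean|`` (and exactly-constant
    columns regardless of threshold) -> removed_low_variation.

    Returns the cleaned numeric matrix and a :class:`CleaningReport`.
    Raises :class:`InputError` if the matrix is empty or nothing survives.
    """
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise InputError("descriptor matrix is empty")
    report = CleaningReport()
    kept: dict[str, np.ndarray] = {}
    for name in matrix.columns:
        col = matrix[name]
        if col.isna().any():
            report.removed_incomplete.append(name)
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():
            report.removed_nonnumeric.append(name)
            continue
        values = numeric.to_numpy(float)
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        if sd == 0.0 or sd <= variation_threshold * abs(float(np.mean(values))):
            report.removed_low_variation.append(name)
            continue
        report.retained.append(name)
        kept[name] = values
    if not kept:
        raise InputError("no descriptors retained after cleaning")
    cleaned = pd.DataFrame(kept, index=matrix.index)
    return cleaned, report


def rank_lipophilicity_descriptors(
    table: CompoundTable, candidates: pd.DataFrame
) -> list[tuple[str, float]]:
    """Rank candidate lipophilicity descriptors by |Pearson r| with RT.

    Correlations are computed pairwise-complete: compounds with missing
    retention time (or a missing candidate value) are dropped per candidate.
    Ties in |r| are broken alphabetically by descriptor name.
    """
    rt = table.data.set_index("compound_id")["rt_min"]
    if rt.notna().sum() < 3:
        raise InputError("need >= 3 compounds with measured retention time")
    scored = []
    for name in candidates.columns:
        col = pd.to_numeric(candidates[name], errors="coerce")
        col.index = col.index.astype(str)
        joined = pd.concat([rt.rename("rt"), col.rename("x")], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise InputError(
                f"descriptor {name!r}: fewer than 3 complete (rt, value) pairs"
            )
        r = float(np.corrcoef(joined["rt"], joined["x"])[0, 1])
        scored.append((str(name), r))
    scored.sort(key=lambda item: (-abs(item[1]), item[0]))
    return scored
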