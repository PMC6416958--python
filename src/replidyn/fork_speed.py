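"""Ratiometric EdU/PCNA nucleotide-incorporation-rate analysis.

Total nuclear PCNA is proportional to the number of active replisomes; total
incorporated nucleotide (EdU, short pulse) is proportional to the number of
replisomes times the replication fork speed.  The per-nucleus ratio
EdU/PCNA is therefore a proxy for relative fork speed: a higher normalized
ratio means more DNA synthesised per replisome during the pulse.  Ratios are
normalized to the median of the untreated early-S group and compared between
stage groups and treatment conditions with median fold changes and Wilcoxon
rank-sum tests, matching the box-plot framing of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reporting_stats import TestResult, wilcoxon_ranksum
from .types import RegionMask

__all__ = [
    "IncorporationRecord",
    "RecordDropped",
    "incorporation_ratio",
    "records_from_table",
    "group_ratios",
    "DEFAULT_CONTRASTS",
]

STAGE_GROUPS = ("early", "mid+late")

# The three contrasts reported for this analysis (A vs B -> median(A)/median(B)).
DEFAULT_CONTRASTS = (
    (("untreated", "mid+late"), ("untreated", "early")),
    (("treated", "early"), ("untreated", "early")),
    (("treated", "mid+late"), ("untreated", "mid+late")),
)


class RecordDropped(ValueError):
    """A nucleus cannot yield a valid incorporation record."""


@dataclass
class IncorporationRecord:
    """Per-nucleus EdU/PCNA totals and their ratio."""

    cell_id: str
    condition: str
    stage_group: str  # "early" or "mid+late"
    edu_total: float
    pcna_total: float

    def __post_init__(self) -> None:
        if self.pcna_total <= 0:
            raise RecordDropped(f"{self.cell_id}: nonpositive PCNA total")
        if self.stage_group not in STAGE_GROUPS:
            raise RecordDropped(f"{self.cell_id}: unknown stage group "
                                f"{self.stage_group!r}")

    @property
    def ratio(self) -> float:
        return self.edu_total / self.pcna_total


def stage_group(pattern: str) -> str:
    """Collapse a pattern label to the early vs mid+late grouping."""
    if pattern == "early":
        return "early"
    if pattern in ("mid", "late"):
        return "mid+late"
    raise RecordDropped(f"non-S pattern {pattern!r} has no stage group")


def incorporation_ratio(edu: np.ndarray, pcna: np.ndarray,
                        nucleus_mask: RegionMask | np.ndarray, *,
                        cell_id: str = "", condition: str = "",
                        pattern: str = "early",
                        background_subtract: bool = True) -> IncorporationRecord:
    """Integrate EdU and PCNA over the nucleus and form their ratio.

    Totals are taken over the whole nucleus mask after subtracting the
    per-image background (median of non-nuclear pixels, configurable off).
    Records with nonpositive PCNA after subtraction, and non-S cells, raise
    :class:`RecordDropped` with the reason.
    """
    nuc = nucleus_mask.mask if isinstance(nucleus_mask, RegionMask) else np.asarray(nucleus_mask, bool)
    edu = np.asarray(edu, dtype=float)
    pcna = np.asarray(pcna, dtype=float)
    if edu.shape != nuc.shape or pcna.shape != nuc.shape:
        raise ValueError("channel and mask dimensions differ")
    if not nuc.any():
        raise RecordDropped(f"{cell_id}: empty nucleus mask")
    grp = stage_group(pattern)  # raises for non-S cells

    def total(ch: np.ndarray) -> float:
        bg = float(np.median(ch[~nuc])) if (background_subtract and (~nuc).any()) else 0.0
        return float((ch[nuc] - bg).sum())

    return IncorporationRecord(cell_id=cell_id, condition=condition,
                               stage_group=grp, edu_total=total(edu),
                               pcna_total=total(pcna))


def records_from_table(table: pd.DataFrame) -> list[IncorporationRecord]:
    """Build records from a pre-measured per-nucleus table.

    Expects columns ``cell_id, condition, pattern, edu_total, pcna_total``
    (the population-table layout of the synthetic generator works directly).
    Non-S rows and rows with nonpositive PCNA are dropped with a warning.
    """
    out, dropped = [], 0
    for row in table.itertuples(index=False):
        try:
            out.append(IncorporationRecord(
                cell_id=str(row.cell_id), condition=str(row.condition),
                stage_group=stage_group(str(row.pattern)),
                edu_total=float(row.edu_total), pcna_total=float(row.pcna_total)))
        except RecordDropped:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} non-S or PCNA-negative records", stacklevel=2)
    return out


def group_ratios(records: list[IncorporationRecord],
                 reference: tuple[str, str] = ("untreated", "early"),
                 contrasts=DEFAULT_CONTRASTS) -> dict:
    """Per-group ratio distributions, normalized median fold changes and tests.

    All ratios are normalized to the median of the reference group (untreated
    early S).  For each requested contrast (A, B) the fold change
    ``median(A)/median(B)`` of normalized ratios and a Wilcoxon rank-sum test
    are reported.  The median is used as the location statistic throughout
    (robust; matches the box-plot presentation of this analysis).
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.condition, r.stage_group), []).append(r.ratio)
    if reference not in groups or not groups[reference]:
        raise ValueError(f"reference group {reference} is empty")
    ref_median = float(np.median(groups[reference]))
    norm = {g: np.asarray(v) / ref_median for g, v in groups.items()}

    summaries = {}
    for g, v in norm.items():
        if len(v) < 2:
            raise ValueError(f"group {g} has fewer than 2 records")
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        summaries["/".join(g)] = {"n": len(v), "median": float(q2),
                                  "q1": float(q1), "q3": float(q3)}

    folds: dict[str, float] = {}
    tests: dict[str, TestResult] = {}
    for a, b in contrasts:
        if a not in norm or b not in norm:
            continue
        key = f"{'/'.join(a)} vs {'/'.join(b)}"
        folds[key] = float(np.median(norm[a]) / np.median(norm[b]))
        tests[key] = wilcoxon_ranksum(norm[a], norm[b])
    return {"reference": "/".join(reference), "reference_median_raw": ref_median,
            "groups": summaries, "folds": folds, "tests": tests}
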