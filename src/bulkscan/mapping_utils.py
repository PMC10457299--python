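"""Small genetic-mapping calculations used alongside the genome scan.

Segregation goodness-of-fit tests (e.g. single-gene 1:3 ratios in an F2),
physical interval widths for fine-mapping narratives, and linkage-map
spacing summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SegregationCounts:
    """Observed class counts and the expected segregation ratio weights."""

    counts: list[int]
    ratio: list[float]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.ratio):
            raise ValueError("counts and ratio must have the same number of classes")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if sum(self.counts) <= 0:
            raise ValueError("total count must be positive")
        if any(w <= 0 for w in self.ratio):
            raise ValueError("ratio weights must be positive")


def chi_square_goodness_of_fit(
    obs: SegregationCounts, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of observed counts against a segregation ratio.

    Returns (statistic, degrees of freedom, p-value).  ``yates`` applies the
    continuity correction (two classes only); off by default.
    """
    counts = np.asarray(obs.counts, dtype=float)
    weights = np.asarray(obs.ratio, dtype=float)
    expected = counts.sum() * weights / weights.sum()
    df = counts.size - 1
    if yates:
        if counts.size != 2:
            raise ValueError("Yates correction applies to two classes only")
        stat = float(np.sum((np.abs(counts - expected) - 0.5) ** 2 / expected))
        p = float(stats.chi2.sf(stat, df))
    else:
        stat_, p_ = stats.chisquare(counts, f_exp=expected)
        stat, p = float(stat_), float(p_)
    return stat, df, p


def interval_width(start_mbp: float, end_mbp: float) -> float:
    """Physical interval width in Mbp, reported to 2 decimals."""
    if end_mbp < start_mbp:
        raise ValueError("end must be >= start")
    return round(end_mbp - start_mbp, 2)


@dataclass
class MarkerMap:
    """Marker positions (cM) on one linkage group."""

    positions_cm: list[float]

    def __post_init__(self) -> None:
        if len(self.positions_cm) < 2:
            raise ValueError("need at least two markers")


def marker_map_summary(marker_map: MarkerMap) -> tuple[float, float]:
    """(span in cM, mean adjacent-marker spacing in cM), both to 2 decimals.

    Spacing is span / (n − 1), the standard definition for n ordered markers.
    """
    pos = np.sort(np.asarray(marker_map.positions_cm, dtype=float))
    span = float(pos[-1] - pos[0])
    spacing = span / (pos.size - 1)
    return round(span, 2), round(spacing, 2)
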