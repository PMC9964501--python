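"""Atomic Sort scoring: normalized nearest-peak distances on HSQC peak lists.

Each peak of a reference compound is matched to the closest peak of a crude
extract's spectrum.  Distances are Euclidean after normalizing each
dimension by the chemical-shift range of the searched (extract) list, so a
distance is a fraction of the occupied chemical-shift space:

    d_AS = sqrt((Δδ¹H / range¹H)² + (Δδ¹³C / range¹³C)²)

The median over a compound's peaks (d̃_AS) scores how well the compound's
spectrum is contained in the extract's; sorting a database on d̃_AS ranks
candidate identifications.  Medians below 0.1 are read as the compound being
present, 0.1–0.2 as a related compound, and larger values as non-specific.
A peak counts as matched when its d_AS ≤ 0.25.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .peaks import PeakList, Peak2D, ReferenceCompound, ReferenceDatabase

__all__ = [
    "NormalizationRanges",
    "PeakMatch",
    "CompoundMatch",
    "MatchConfig",
    "shift_ranges",
    "peak_distance",
    "nearest_distance",
    "atomic_sort_match",
    "classify_match",
    "rank_compounds",
    "write_ranking_report",
    "DEFAULT_H_FLOOR",
    "DEFAULT_C_FLOOR",
]

# fallback normalization ranges for degenerate searched sets: the full
# spectral windows of a routine 1H-13C HSQC
DEFAULT_H_FLOOR = 10.0
DEFAULT_C_FLOOR = 160.0


@dataclass(frozen=True)
class NormalizationRanges:
    """Per-dimension chemical-shift ranges used to normalize distances."""

    h_range: float
    c_range: float

    def __post_init__(self) -> None:
        if self.h_range <= 0 or self.c_range <= 0:
            raise ValueError("normalization ranges must be > 0")


@dataclass(frozen=True)
class PeakMatch:
    """Nearest-extract-peak assignment for one compound peak."""

    query_index: int
    target_index: int
    d_as: float


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds for matching and classification.

    ``range_source`` selects which peak list supplies the normalization
    ranges: ``"extract"`` (the searched culture spectrum, the default) or
    ``"compound"`` (the query list).
    """

    match_threshold: float = 0.25
    present_threshold: float = 0.1
    related_threshold: float = 0.2
    range_source: str = "extract"

    def __post_init__(self) -> None:
        if not (0 < self.present_threshold <= self.related_threshold <= self.match_threshold):
            raise ValueError(
                "require 0 < present_threshold <= related_threshold <= match_threshold"
            )
        if self.range_source not in ("extract", "compound"):
            raise ValueError("range_source must be 'extract' or 'compound'")


@dataclass(frozen=True)
class CompoundMatch:
    """Atomic Sort result for one compound against one extract."""

    compound_name: str
    per_peak: tuple[PeakMatch, ...]
    median_das: float
    n_matched: int
    n_total: int
    label: str

    @property
    def fraction(self) -> str:
        return f"{self.n_matched}/{self.n_total}"

    def report_row(self) -> str:
        """Tabular cell in the conventional '0.056, 51/51' style."""
        return f"{self.median_das:.3f}, {self.fraction}"


def shift_ranges(
    peaks: PeakList | Sequence[Peak2D],
    floors: tuple[float, float] = (DEFAULT_H_FLOOR, DEFAULT_C_FLOOR),
) -> NormalizationRanges:
    """max−min of each shift dimension; ranges below 1e-6 ppm (degenerate
    sets, e.g. a single peak) are replaced by the floor values."""
    peaks = list(peaks)
    if not peaks:
        raise ValueError("cannot compute shift ranges of an empty peak list")
    h = [p.h_shift for p in peaks]
    c = [p.c_shift for p in peaks]
    h_range = max(h) - min(h)
    c_range = max(c) - min(c)
    if h_range < 1e-6:
        h_range = floors[0]
    if c_range < 1e-6:
        c_range = floors[1]
    return NormalizationRanges(h_range, c_range)


def peak_distance(query: Peak2D, target: Peak2D, ranges: NormalizationRanges) -> float:
    """Range-normalized Euclidean distance between two peaks."""
    dh = (query.h_shift - target.h_shift) / ranges.h_range
    dc = (query.c_shift - target.c_shift) / ranges.c_range
    return float(np.hypot(dh, dc))


def nearest_distance(
    query: Peak2D, targets: PeakList, ranges: NormalizationRanges
) -> PeakMatch:
    """Closest target peak to ``query``; ties resolve to the lowest index.

    Every target is always eligible — no exclusivity, so two query peaks may
    share the same target.
    """
    if len(targets) == 0:
        raise ValueError("empty target peak list")
    th = np.asarray(targets.h_shifts())
    tc = np.asarray(targets.c_shifts())
    d = np.hypot((query.h_shift - th) / ranges.h_range, (query.c_shift - tc) / ranges.c_range)
    idx = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return PeakMatch(query_index=0, target_index=idx, d_as=float(d[idx]))


def _all_nearest(
    compound_peaks: PeakList, extract: PeakList, ranges: NormalizationRanges
) -> list[PeakMatch]:
    qh = np.asarray(compound_peaks.h_shifts())[:, None]
    qc = np.asarray(compound_peaks.c_shifts())[:, None]
    th = np.asarray(extract.h_shifts())[None, :]
    tc = np.asarray(extract.c_shifts())[None, :]
    d = np.hypot((qh - th) / ranges.h_range, (qc - tc) / ranges.c_range)
    idx = d.argmin(axis=1)
    return [
        PeakMatch(query_index=i, target_index=int(j), d_as=float(d[i, j]))
        for i, j in enumerate(idx)
    ]


def atomic_sort_match(
    compound: ReferenceCompound,
    extract: PeakList,
    config: MatchConfig = MatchConfig(),
) -> CompoundMatch:
    """Score one reference compound against one extract spectrum.

    Direction is compound → extract: each compound peak is a query matched
    to the closest extract peak.  Normalization ranges come from the extract
    list by default (``config.range_source``).
    """
    if len(compound.peaks) == 0 or len(extract) == 0:
        raise ValueError("both peak lists must be nonempty")
    source = extract if config.range_source == "extract" else compound.peaks
    ranges = shift_ranges(source)
    matches = _all_nearest(compound.peaks, extract, ranges)
    d_values = [m.d_as for m in matches]
    median = float(statistics.median(d_values))  # even count -> mean of central pair
    n_matched = sum(d <= config.match_threshold for d in d_values)
    return CompoundMatch(
        compound_name=compound.name,
        per_peak=tuple(matches),
        median_das=median,
        n_matched=n_matched,
        n_total=len(compound.peaks),
        label=classify_match(median, config),
    )


def classify_match(median_das: float, config: MatchConfig = MatchConfig()) -> str:
    """Label a median distance: < present_threshold → ``present``;
    up to related_threshold (inclusive) → ``related``; else ``nonspecific``."""
    if median_das < 0:
        raise ValueError("median distance must be >= 0")
    if median_das < config.present_threshold:
        return "present"
    if median_das <= config.related_threshold:
        return "related"
    return "nonspecific"


def rank_compounds(
    db: ReferenceDatabase,
    extract: PeakList,
    config: MatchConfig = MatchConfig(),
) -> list[CompoundMatch]:
    """Score every database compound against the extract and sort ascending
    by d̃_AS; ties break by descending match fraction, then name."""
    if len(extract) == 0:
        raise ValueError("extract peak list is empty")
    results = [atomic_sort_match(c, extract, config) for c in db]
    results.sort(
        key=lambda m: (m.median_das, -(m.n_matched / m.n_total), m.compound_name)
    )
    return results


def write_ranking_report(matches: Sequence[CompoundMatch], path) -> None:
    """TSV report: compound, median_das (3 decimals), matched/total, label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound\tmedian_das\tmatched\tlabel\n")
        for m in matches:
            fh.write(f"{m.compound_name}\t{m.median_das:.3f}\t{m.fraction}\t{m.label}\n")
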