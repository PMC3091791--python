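"""Relative quantification of 14N/15N channel intensities.

A label-swap design measures each peptide twice: in replicate 1 the
knockout strain carries the light 14N label, in replicate 2 the labels are
reversed.  This module harmonizes both replicates onto a common
log2(KO/WT) scale (negative = lower in the knockout), pairs measurements
across replicates, fits a 95% agreement band to the inter-replicate
differences, and applies identification-score and fold-change thresholds.

The agreement band follows the replicate-scatter construction: with
d = r1 - r2 the difference of the two harmonized log2 ratios, the band is
|d| <= 1.96 * SD(d).  The SD is estimated robustly by default
(median absolute deviation scaled by 1.4826) because real ratio scatter
has heavy tails from mis-integrated isotope envelopes; the plain sample
SD is available via ``method="sd"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .io import QuantifiedPeptide

__all__ = [
    "LabelOrientation",
    "DEFAULT_ORIENTATION",
    "RatioPair",
    "ConfidenceBand",
    "filter_by_score",
    "log2_ko_wt_ratio",
    "compute_ratios",
    "pair_replicates",
    "fit_confidence_band",
    "classify_fold_change",
    "aggregate_protein_ratios",
]

#: Default score thresholds (identification-score units).
SCORE_MIN_REGULAR = 30.0
SCORE_MIN_PHOSPHO = 25.0


@dataclass(frozen=True)
class LabelOrientation:
    """Which channel (14N or 15N) the knockout strain carries, per replicate."""

    ko_channel: Mapping[int, str]

    def __post_init__(self) -> None:
        for rep, channel in self.ko_channel.items():
            if channel not in {"14N", "15N"}:
                raise ValueError(f"replicate {rep}: channel must be '14N' or '15N'")

    def ko_is_14n(self, replicate_id: int) -> bool:
        try:
            return self.ko_channel[replicate_id] == "14N"
        except KeyError:
            raise KeyError(f"no label orientation recorded for replicate {replicate_id}")


#: The study design: replicate 1 has KO on 14N, replicate 2 swaps the labels.
DEFAULT_ORIENTATION = LabelOrientation(ko_channel={1: "14N", 2: "15N"})


@dataclass
class RatioPair:
    """Harmonized log2(KO/WT) ratios of one peptide species across replicates."""

    key: tuple[str, str, str]  # (accession, peptide, modification signature)
    r1: Optional[float]
    r2: Optional[float]
    consistent: Optional[bool] = None

    @property
    def accession(self) -> str:
        return self.key[0]

    @property
    def peptide(self) -> str:
        return self.key[1]

    @property
    def modification(self) -> str:
        return self.key[2]

    @property
    def n_replicates(self) -> int:
        return (self.r1 is not None) + (self.r2 is not None)

    @property
    def mean_ratio(self) -> float:
        if self.r1 is not None and self.r2 is not None:
            return 0.5 * (self.r1 + self.r2)
        if self.r1 is not None:
            return self.r1
        if self.r2 is not None:
            return self.r2
        raise ValueError("RatioPair with no measurements")

    @property
    def difference(self) -> Optional[float]:
        if self.n_replicates == 2:
            return self.r1 - self.r2
        return None


@dataclass(frozen=True)
class ConfidenceBand:
    """95% agreement band for inter-replicate log2-ratio differences."""

    halfwidth: float
    sd_estimate: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.halfwidth < 0 or self.sd_estimate < 0:
            raise ValueError("band parameters must be non-negative")

    def contains(self, difference: float) -> bool:
        return abs(difference) <= self.halfwidth


def filter_by_score(
    peptides: Iterable[QuantifiedPeptide],
    regular_min: float = SCORE_MIN_REGULAR,
    phospho_min: float = SCORE_MIN_PHOSPHO,
) -> list[QuantifiedPeptide]:
    """Keep peptides passing the identification-score thresholds.

    Unmodified and N-acetylated peptides must reach ``regular_min``
    (default 30); phosphopeptides the laxer ``phospho_min`` (default 25).
    """
    kept = []
    for p in peptides:
        threshold = phospho_min if p.is_phospho else regular_min
        if p.score >= threshold:
            kept.append(p)
    return kept


def log2_ko_wt_ratio(
    peptide: QuantifiedPeptide,
    orientation: LabelOrientation = DEFAULT_ORIENTATION,
) -> Optional[float]:
    """log2(KO channel / WT channel) for one measurement, or None.

    Returns ``None`` when either channel is missing or non-positive — the
    identification stands but the row is unquantifiable.  Negative values
    mean the peptide is less abundant in the knockout.
    """
    if not peptide.quantifiable:
        return None
    if orientation.ko_is_14n(peptide.replicate_id):
        ko, wt = peptide.intensity_14N, peptide.intensity_15N
    else:
        ko, wt = peptide.intensity_15N, peptide.intensity_14N
    return math.log2(ko / wt)


def compute_ratios(
    peptides: Iterable[QuantifiedPeptide],
    orientation: LabelOrientation = DEFAULT_ORIENTATION,
) -> dict[tuple[str, str, str], float]:
    """Harmonized log2(KO/WT) per peptide key for one replicate.

    Peptides sharing a key within the replicate (e.g. re-identified in
    several fractions) are averaged.  Unquantifiable rows are skipped.
    """
    sums: dict[tuple[str, str, str], list[float]] = {}
    for p in peptides:
        r = log2_ko_wt_ratio(p, orientation)
        if r is None:
            continue
        sums.setdefault(p.key, []).append(r)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def pair_replicates(
    ratios_rep1: Mapping[tuple, float],
    ratios_rep2: Mapping[tuple, float],
) -> list[RatioPair]:
    """Join the two replicates' harmonized ratio maps on the peptide key.

    Keys present in both replicates give complete pairs; singletons are
    retained with ``n_replicates = 1`` (usable for descriptive outputs,
    excluded from band fitting).
    """
    keys = sorted(set(ratios_rep1) | set(ratios_rep2))
    return [
        RatioPair(key=k, r1=ratios_rep1.get(k), r2=ratios_rep2.get(k))
        for k in keys
    ]


def fit_confidence_band(
    pairs: Sequence[RatioPair],
    method: Literal["mad", "sd"] = "mad",
    min_pairs: int = 20,
) -> ConfidenceBand:
    """Fit the 95% replicate-agreement band and flag each complete pair.

    Pairs with ``|r1 - r2|`` beyond 1.96 x SD are flagged inconsistent
    (mutated in place: ``pair.consistent``).  Requires at least
    ``min_pairs`` complete pairs for a usable SD estimate.
    """
    diffs = np.array([p.difference for p in pairs if p.n_replicates == 2])
    if diffs.size < min_pairs:
        raise ValueError(
            f"only {diffs.size} complete pairs; need >= {min_pairs} to fit the band"
        )
    if method == "mad":
        sd = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs))))
    elif method == "sd":
        sd = float(np.std(diffs, ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}; use 'mad' or 'sd'")
    band = ConfidenceBand(halfwidth=1.96 * sd, sd_estimate=sd, n_pairs=int(diffs.size))
    for p in pairs:
        p.consistent = band.contains(p.difference) if p.n_replicates == 2 else None
    return band


def classify_fold_change(pair: RatioPair, fold: float = 3.0) -> str:
    """Label a pair 'up', 'down' or 'unchanged' at a fold-change cut.

    ``up`` iff mean log2 ratio >= log2(fold); ``down`` iff <= -log2(fold);
    boundaries inclusive.
    """
    if fold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    cut = math.log2(fold)
    m = pair.mean_ratio
    if m >= cut:
        return "up"
    if m <= -cut:
        return "down"
    return "unchanged"


def aggregate_protein_ratios(pairs: Sequence[RatioPair]) -> dict[str, float]:
    """Per-protein mean log2(KO/WT) from consistent unmodified peptides.

    Only unmodified peptides contribute (acetylated and phosphorylated
    species track their own regulation, not protein abundance).  Pairs
    flagged inconsistent are dropped; proteins left with no consistent
    pair are absent from the result.  Singleton pairs (never flagged)
    contribute.
    """
    per_protein: dict[str, list[float]] = {}
    for p in pairs:
        if p.modification != "unmod":
            continue
        if p.consistent is False:
            continue
        per_protein.setdefault(p.accession, []).append(p.mean_ratio)
    return {acc: float(np.mean(v)) for acc, v in per_protein.items()}
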