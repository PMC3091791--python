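"""Sequence-logo frequency matrices and category over-representation.

Two statistics drive the downstream-effect analysis.  First, position-wise
amino-acid frequency matrices of N-terminal peptide sets (the numeric
content of a sequence logo).  Second, normalized category contributions:
for a foreground set (e.g. phospho-sites elevated in the knockout) versus
a disjoint background (detected-but-unchanged sites), each category's
effect size is

    normalized contribution = foreground % / background %

and its significance a Pearson chi-square test (1 df, no continuity
correction by default) on the 2x2 membership table, with Bonferroni
correction over the tested categories (Benjamini-Hochberg optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "frequency_matrix",
    "category_contributions",
    "normalized_enrichment",
    "localization_profile",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    foreground_percent: float
    background_percent: float
    normalized_contribution: Optional[float]  # None when background % is 0
    chi2: float
    p: float
    p_corrected: float
    low_count: bool  # min expected cell < 5


def frequency_matrix(sequences: Iterable[str], k: int = 5) -> pd.DataFrame:
    """Relative amino-acid frequencies over the first ``k`` positions.

    Returns a (k x 20) DataFrame indexed by 1-based position; each row
    sums to 1 over the residues observed at that position.  Every input
    sequence must be at least ``k`` residues long.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot build a frequency matrix from an empty set")
    if k < 1:
        raise ValueError("k must be >= 1")
    for s in seqs:
        if len(s) < k:
            raise ValueError(f"sequence {s!r} shorter than k={k}")
    counts = pd.DataFrame(0.0, index=range(1, k + 1), columns=AMINO_ACIDS)
    for s in seqs:
        for pos in range(k):
            counts.loc[pos + 1, s[pos]] += 1
    freqs = counts.div(counts.sum(axis=1), axis=0)
    freqs.index.name = "position"
    return freqs


def category_contributions(
    item_to_categories: Mapping[Hashable, Iterable[str]],
    item_set: Iterable[Hashable],
) -> dict[str, float]:
    """Percent of items in each category (multi-membership counts per category)."""
    items = list(item_set)
    if not items:
        raise ValueError("empty item set")
    counts: dict[str, int] = {}
    for item in items:
        for cat in set(item_to_categories.get(item, ())):
            counts[cat] = counts.get(cat, 0) + 1
    return {cat: 100.0 * n / len(items) for cat, n in counts.items()}


def _chi2_2x2(fg_in: int, fg_n: int, bg_in: int, bg_n: int, yates: bool) -> tuple[float, float, bool]:
    table = np.array([[fg_in, fg_n - fg_in], [bg_in, bg_n - bg_in]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0, True
    chi2, p, _, expected = chi2_contingency(table, correction=yates)
    return float(chi2), float(p), bool(expected.min() < 5)


def normalized_enrichment(
    foreground: Iterable[Hashable],
    background: Iterable[Hashable],
    annotations: Mapping[Hashable, Iterable[str]],
    correction: Literal["bonferroni", "fdr_bh"] = "bonferroni",
    yates: bool = False,
) -> list[EnrichmentResult]:
    """Per-category over-representation of the foreground against the background.

    Foreground and background must be disjoint item sets (e.g. elevated
    vs unchanged phospho-sites).  Items without any annotation are
    excluded from both sets.  Categories absent from the background are
    omitted with a warning (their ratio is undefined).  Results are
    sorted by normalized contribution, descending.
    """
    if set(foreground) & set(background):
        raise ValueError("foreground and background sets must be disjoint")
    return _enrichment_core(foreground, background, annotations, correction, yates)


def _enrichment_core(
    foreground: Iterable[Hashable],
    background: Iterable[Hashable],
    annotations: Mapping[Hashable, Iterable[str]],
    correction: str,
    yates: bool,
) -> list[EnrichmentResult]:
    fg = [i for i in set(foreground) if annotations.get(i)]
    bg = [i for i in set(background) if annotations.get(i)]
    if not fg or not bg:
        raise ValueError("foreground and background must each contain annotated items")

    fg_pct = category_contributions(annotations, fg)
    bg_pct = category_contributions(annotations, bg)

    tested: list[tuple[str, float, float, float, float, bool]] = []
    for cat in sorted(set(fg_pct) | set(bg_pct)):
        if cat not in bg_pct:
            logger.warning("category %r absent from background; omitted", cat)
            continue
        f = fg_pct.get(cat, 0.0)
        b = bg_pct[cat]
        fg_in = round(f * len(fg) / 100.0)
        bg_in = round(b * len(bg) / 100.0)
        chi2, p, low = _chi2_2x2(fg_in, len(fg), bg_in, len(bg), yates)
        tested.append((cat, f, b, chi2, p, low))

    if not tested:
        return []
    p_corr = multipletests([t[4] for t in tested], method=correction)[1]
    results = [
        EnrichmentResult(
            category=cat,
            foreground_percent=f,
            background_percent=b,
            normalized_contribution=(f / b) if b > 0 else None,
            chi2=chi2,
            p=p,
            p_corrected=float(pc),
            low_count=low,
        )
        for (cat, f, b, chi2, p, low), pc in zip(tested, p_corr)
    ]
    results.sort(
        key=lambda r: (
            -(r.normalized_contribution if r.normalized_contribution is not None else -1),
            r.category,
        )
    )
    return results


def localization_profile(
    elevated_proteins: Iterable[Hashable],
    all_detected_proteins: Iterable[Hashable],
    localization_table: Mapping[Hashable, Iterable[str]],
    correction: Literal["bonferroni", "fdr_bh"] = "bonferroni",
    yates: bool = False,
) -> list[EnrichmentResult]:
    """Localization over/under-representation of elevated proteins.

    Unlike the kinase analysis, the reference here is the localization
    distribution of ALL detected proteins (elevated ones included), so
    the elevated-equals-detected degenerate case yields ratio 1.0 for
    every compartment.  The two-sided chi-square reports both directions
    — normalized contributions < 1 mark under-represented compartments.
    Proteins with no localization annotation drop out of both sets.
    """
    elevated = set(elevated_proteins)
    detected = set(all_detected_proteins)
    if not elevated <= detected:
        raise ValueError("elevated proteins must all be in the detected set")
    return _enrichment_core(
        elevated, detected, localization_table, correction, yates
    )
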