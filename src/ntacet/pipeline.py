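"""End-to-end wiring of the analysis stages.

Convenience drivers that chain score filtering, ratio harmonization,
replicate pairing, band fitting, terminus classification and substrate
calling; the CLI and batch scripts go through these, tests mostly target
the individual stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import quant
from .io import ProteinRecord, QuantifiedPeptide
from .nterm import classify_event
from .quant import ConfidenceBand, LabelOrientation, RatioPair
from .substrates import SubstrateCall, call_natb_substrates

__all__ = ["RatioAnalysis", "harmonize_replicates", "run_substrate_calling",
           "classify_phospho_sites"]


@dataclass
class RatioAnalysis:
    """Paired, band-checked ratios from a two-replicate label swap."""

    pairs: list[RatioPair]
    band: Optional[ConfidenceBand]


def harmonize_replicates(
    rep1: Sequence[QuantifiedPeptide],
    rep2: Sequence[QuantifiedPeptide],
    orientation: LabelOrientation = quant.DEFAULT_ORIENTATION,
    score_min_regular: float = quant.SCORE_MIN_REGULAR,
    score_min_phospho: float = quant.SCORE_MIN_PHOSPHO,
    ci_method: str = "mad",
    fit_band: bool = True,
) -> RatioAnalysis:
    """Score-filter both replicates, harmonize to log2(KO/WT), pair and band-check."""
    f1 = quant.filter_by_score(rep1, score_min_regular, score_min_phospho)
    f2 = quant.filter_by_score(rep2, score_min_regular, score_min_phospho)
    pairs = quant.pair_replicates(
        quant.compute_ratios(f1, orientation), quant.compute_ratios(f2, orientation)
    )
    band = quant.fit_confidence_band(pairs, method=ci_method) if fit_band else None
    return RatioAnalysis(pairs=pairs, band=band)


def run_substrate_calling(
    proteome: Sequence[ProteinRecord],
    rep1: Sequence[QuantifiedPeptide],
    rep2: Sequence[QuantifiedPeptide],
    fold: float = 3.0,
    require_both_replicates: bool = True,
    **harmonize_kwargs,
) -> tuple[list[SubstrateCall], RatioAnalysis]:
    """Full substrate-calling pipeline from raw replicate tables.

    Acetylated-terminus events are built from acetylated peptides with a
    recorded (or mappable) start; ambiguous multi-placement peptides are
    resolved by the recorded start only.
    """
    proteins = {p.accession: p for p in proteome}
    analysis = harmonize_replicates(rep1, rep2, **harmonize_kwargs)

    events = []
    seen: set[tuple[str, int]] = set()
    for peptide in list(rep1) + list(rep2):
        if not peptide.nterm_acetyl or peptide.start is None:
            continue
        key = (peptide.accession, peptide.start)
        if key in seen or peptide.accession not in proteins:
            continue
        seen.add(key)
        events.append(classify_event(proteins[peptide.accession], peptide.start))

    calls = call_natb_substrates(
        events,
        analysis.pairs,
        proteins,
        fold=fold,
        require_both_replicates=require_both_replicates,
    )
    return calls, analysis


def classify_phospho_sites(
    rep1: Sequence[QuantifiedPeptide],
    rep2: Sequence[QuantifiedPeptide],
    fold: float = 3.0,
    **harmonize_kwargs,
) -> dict[str, dict[str, str]]:
    """Per-site regulation labels from phosphopeptide tables.

    Site identifiers are ``{accession}_p{protein position}`` derived from
    the peptide start and the phospho offset; returns
    ``{"up"|"down"|"unchanged": {site_id: label}}``-style flat mapping
    ``site_id -> label``.
    """
    analysis = harmonize_replicates(rep1, rep2, **harmonize_kwargs)
    # map peptide key -> site ids from the identification rows
    key_to_sites: dict[tuple, set[str]] = {}
    for peptide in list(rep1) + list(rep2):
        if not peptide.phospho_positions or peptide.start is None:
            continue
        for offset in peptide.phospho_positions:
            key_to_sites.setdefault(peptide.key, set()).add(
                f"{peptide.accession}_p{peptide.start + offset - 1}"
            )
    labels: dict[str, str] = {}
    for pair in analysis.pairs:
        for site in key_to_sites.get(pair.key, ()):
            labels[site] = quant.classify_fold_change(pair, fold=fold)
    return labels
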