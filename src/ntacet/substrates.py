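"""NatB substrate calling.

A protein (or internal protein variant) is called a NatB substrate when
its acetylated N-terminal peptide carries the NatB consensus (retained
Met followed by D, E or N at the event position) and its harmonized
log2(KO/WT) ratio shows the acetylated form strongly depleted in the
knockout — the acetyl group cannot be attached without the enzyme, so
the acetylated peptide species collapses even where total protein
abundance is unchanged.

Internal consensus events passing the same cut indicate alternative
translation starts producing co-translationally acetylated variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import ProteinRecord
from .nterm import NTerminalEvent, natb_consensus
from .quant import RatioPair

__all__ = [
    "SubstrateCall",
    "call_natb_substrates",
    "unique_substrate_proteins",
    "overlap_with_known",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstrateCall:
    """One acetylated N-terminal peptide evaluated as a NatB substrate."""

    accession: str
    gene_name: Optional[str]
    sequence: str  # first five residues from the event position
    start: int
    mean_ratio: Optional[float]
    n_replicates: int
    alt_start: bool
    call: bool
    reason: str  # 'consensus+down' | 'consensus-only' | 'no-consensus'


def call_natb_substrates(
    events: Iterable[NTerminalEvent],
    ratio_pairs: Sequence[RatioPair],
    proteins: Mapping[str, ProteinRecord],
    fold: float = 3.0,
    require_both_replicates: bool = True,
) -> list[SubstrateCall]:
    """Evaluate acetylated N-terminal events as NatB substrates.

    ``call`` is true iff the two residues at the event position satisfy
    the NatB consensus AND the acetyl-peptide's mean log2(KO/WT) ratio is
    at or below -log2(fold), with quantification in both replicates when
    ``require_both_replicates``.  Consensus events missing the ratio cut
    are kept in the report as the 'consensus-only' tier.  Events on
    unknown proteins are skipped with a warning.  Output order: mean
    ratio ascending (ratio-less rows last), then accession.
    """
    if fold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    cut = -math.log2(fold)

    # Acetylated pairs indexed by (accession, first residues of the peptide)
    acetyl_pairs: dict[tuple[str, str], RatioPair] = {}
    for pair in ratio_pairs:
        if pair.modification.startswith("ac"):
            acetyl_pairs[(pair.accession, pair.peptide)] = pair

    calls: list[SubstrateCall] = []
    for event in events:
        if not event.acetylated:
            continue
        protein = proteins.get(event.accession)
        if protein is None:
            logger.warning("event at %s:%d has no protein record; skipped",
                           event.accession, event.start)
            continue
        local = protein.sequence[event.start - 1 : event.start + 4]
        first_two = protein.sequence[event.start - 1 : event.start + 1]
        consensus = len(first_two) == 2 and natb_consensus(first_two)

        pair = _match_pair(acetyl_pairs, event.accession, protein, event.start)

        mean_ratio = pair.mean_ratio if pair is not None else None
        n_rep = pair.n_replicates if pair is not None else 0

        if not consensus:
            call, reason = False, "no-consensus"
        elif (
            mean_ratio is not None
            and mean_ratio <= cut
            and (n_rep == 2 or not require_both_replicates)
        ):
            call, reason = True, "consensus+down"
        else:
            call, reason = False, "consensus-only"

        calls.append(
            SubstrateCall(
                accession=event.accession,
                gene_name=protein.gene_name,
                sequence=local,
                start=event.start,
                mean_ratio=mean_ratio,
                n_replicates=n_rep,
                alt_start=event.position_class == "internal" and event.alt_start_candidate,
                call=call,
                reason=reason,
            )
        )
    calls.sort(
        key=lambda c: (
            c.mean_ratio is None,
            c.mean_ratio if c.mean_ratio is not None else 0.0,
            c.accession,
        )
    )
    return calls


def _match_pair(
    acetyl_pairs: Mapping[tuple[str, str], RatioPair],
    accession: str,
    protein: ProteinRecord,
    start: int,
) -> Optional[RatioPair]:
    """Find the acetyl RatioPair whose peptide sits at this protein position."""
    for (acc, pep), pair in acetyl_pairs.items():
        if acc != accession:
            continue
        if protein.sequence[start - 1 : start - 1 + len(pep)] == pep:
            return pair
    return None


def unique_substrate_proteins(calls: Iterable[SubstrateCall]) -> tuple[int, list[str]]:
    """Deduplicate positive calls by accession.

    Returns (count, accessions) ordered by most-negative mean ratio,
    then accession.
    """
    best: dict[str, float] = {}
    for c in calls:
        if not c.call:
            continue
        r = c.mean_ratio if c.mean_ratio is not None else 0.0
        if c.accession not in best or r < best[c.accession]:
            best[c.accession] = r
    ordered = sorted(best, key=lambda acc: (best[acc], acc))
    return len(ordered), ordered


def overlap_with_known(
    calls: Iterable[SubstrateCall], known_list: Iterable[str]
) -> tuple[int, int, set[str]]:
    """Intersect called substrate accessions with a user-supplied known set."""
    known = set(known_list)
    called = {c.accession for c in calls if c.call}
    recovered = known & called
    return len(known), len(recovered), recovered


def calls_to_frame(calls: Sequence[SubstrateCall]) -> pd.DataFrame:
    """Substrate report mirroring the published substrate-table columns."""
    return pd.DataFrame(
        [
            {
                "accession": c.accession,
                "name": c.gene_name or "",
                "sequence": c.sequence,
                "start": c.start,
                "average_log2_ratio": c.mean_ratio,
                "n_replicates": c.n_replicates,
                "alt_start": c.alt_start,
                "call": c.call,
                "reason": c.reason,
            }
            for c in calls
        ]
    )
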