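"""In-silico digestion and N-terminal event classification.

Acetylated peptide N-termini are mapped onto protein coordinates and
classified by position (annotated start, post-Met-cleavage start, or
internal) and by the N-acetyltransferase whose recognition motif they
match.  NatB acetylates the retained initiator Met when the penultimate
residue is D, E or N (consensus MD/ME/MN); NatA acts after Met cleavage
on small N-terminal residues (S, A, T, V, G); NatC retains the Met with a
bulky hydrophobic penultimate residue (I, L, W, F).

Semi-specific digestion (one peptide terminus not conforming to the
protease rule) is what makes internal, non-annotated N-termini visible:
an acetylated semi-specific peptide whose free end is internal marks a
protein variant, possibly from an alternative translation start when the
event position is at or just after a methionine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

from .io import ProteinRecord

__all__ = [
    "DigestSpec",
    "NTerminalEvent",
    "digest",
    "map_peptide",
    "classify_event",
    "natb_consensus",
    "met_cleavage_variants",
    "theoretical_observability",
    "ObservabilitySummary",
]

NATB_SECOND = set("DEN")
NATA_FIRST = set("SATVG")
NATC_SECOND = set("ILWF")
#: Residues permitting initiator-Met cleavage by Met-aminopeptidases.
MAP_SMALL = set("ACGPSTV")


@dataclass(frozen=True)
class DigestSpec:
    """Protease, cleavage specificity and missed-cleavage allowance."""

    protease: Literal["trypsin", "lysn"] = "trypsin"
    specificity: Literal["full", "semi"] = "full"
    missed_cleavages: int = 1
    #: Suppress tryptic cleavage when the following residue is proline.
    no_cleave_before_proline: bool = True

    def __post_init__(self) -> None:
        if self.protease not in {"trypsin", "lysn"}:
            raise ValueError(f"unknown protease {self.protease!r}")
        if self.specificity not in {"full", "semi"}:
            raise ValueError(f"unknown specificity {self.specificity!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class NTerminalEvent:
    """An (acetylated or free) N-terminus mapped to a protein position."""

    accession: str
    start: int  # 1-based position of the (acetylated) residue
    acetylated: bool
    position_class: Literal["position1", "position2", "internal"]
    nat_class: Literal["NatB", "NatA-type", "NatC-type", "other"]
    alt_start_candidate: bool


def _cleavage_boundaries(sequence: str, spec: DigestSpec) -> list[int]:
    """0-based cut points (between sequence[:j] and sequence[j:]), termini included."""
    n = len(sequence)
    cuts = [0]
    for j in range(1, n):
        if spec.protease == "trypsin":
            if sequence[j - 1] in "KR" and not (
                spec.no_cleave_before_proline and sequence[j] == "P"
            ):
                cuts.append(j)
        else:  # lysn: cleaves N-terminal to lysine
            if sequence[j] == "K":
                cuts.append(j)
    cuts.append(n)
    return cuts


def digest(protein: ProteinRecord | str, spec: DigestSpec) -> list[tuple[str, int]]:
    """Enumerate peptides of an in-silico digest as (peptide, 1-based start).

    Fully-specific peptides span consecutive cleavage points with at most
    ``spec.missed_cleavages`` internal sites.  Semi-specific digestion
    additionally yields every proper prefix and suffix of each
    fully-specific peptide (one non-canonical terminus).  Duplicate
    (peptide, start) placements are reported once; output is sorted by
    start, then length.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    cuts = _cleavage_boundaries(sequence, spec)
    spans: set[tuple[int, int]] = set()
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + spec.missed_cleavages, len(cuts))):
            a, b = cuts[i], cuts[j]
            spans.add((a, b))
            if spec.specificity == "semi":
                for c in range(a + 1, b):
                    spans.add((a, c))  # canonical N-terminus, ragged C
                    spans.add((c, b))  # ragged N-terminus, canonical C
    peptides = [(sequence[a:b], a + 1) for a, b in spans]
    peptides.sort(key=lambda t: (t[1], len(t[0])))
    return peptides


def map_peptide(peptide: str, protein: ProteinRecord | str) -> list[int]:
    """All 1-based positions where ``peptide`` occurs in the protein (may overlap)."""
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not peptide:
        return []
    hits = []
    pos = sequence.find(peptide)
    while pos != -1:
        hits.append(pos + 1)
        pos = sequence.find(peptide, pos + 1)
    return hits


def natb_consensus(two_residues: str) -> bool:
    """True iff a two-residue N-terminus matches the NatB motif MD/ME/MN."""
    if len(two_residues) != 2:
        raise ValueError(f"expected exactly two residues, got {two_residues!r}")
    return two_residues[0] == "M" and two_residues[1] in NATB_SECOND


def classify_event(
    protein: ProteinRecord, start: int, acetylated: bool = True
) -> NTerminalEvent:
    """Classify an N-terminal event at a 1-based protein position.

    Position classes: ``position1`` (annotated initiator), ``position2``
    (post-Met-cleavage) and ``internal`` (position >= 3, a protein
    variant).  The Nat class describes co-translational acetylation of
    the annotated terminus, so NatB/NatC motifs are scored at position 1
    and the NatA rule at position 2 only; internal events are ``other``
    here even when their local sequence matches a motif (substrate
    calling re-checks the consensus at the event position via
    :func:`natb_consensus`).
    """
    if not 1 <= start <= len(protein):
        raise ValueError(
            f"start {start} outside 1..{len(protein)} for {protein.accession}"
        )
    if start == 1:
        position_class = "position1"
    elif start == 2:
        position_class = "position2"
    else:
        position_class = "internal"

    first = protein.residue(start)
    second = protein.residue(start + 1) if start < len(protein) else ""

    nat_class = "other"
    if position_class == "position1" and first == "M" and second:
        if second in NATB_SECOND:
            nat_class = "NatB"
        elif second in NATC_SECOND:
            nat_class = "NatC-type"
    elif position_class == "position2" and first in NATA_FIRST:
        nat_class = "NatA-type"

    alt_start = first == "M" or (start > 1 and protein.residue(start - 1) == "M")
    return NTerminalEvent(
        accession=protein.accession,
        start=start,
        acetylated=acetylated,
        position_class=position_class,
        nat_class=nat_class,
        alt_start_candidate=alt_start,
    )


def met_cleavage_variants(protein: ProteinRecord | str) -> set[int]:
    """Plausible mature N-terminal start positions after Met-aminopeptidase action.

    The initiator Met is cleaved only when the penultimate residue is
    small (A, C, G, P, S, T or V); both the uncleaved and cleaved forms
    are considered plausible.  Sequences not starting with M keep their
    annotated start.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    starts = {1}
    if sequence.startswith("M") and len(sequence) >= 2 and sequence[1] in MAP_SMALL:
        starts.add(2)
    return starts


class ObservabilitySummary(NamedTuple):
    n_observable: int
    n_observable_natb: int
    fraction_natb: float


def _nterm_peptide_lengths(sequence: str, spec: DigestSpec) -> list[int]:
    """Lengths of fully-specific N-terminal peptides with <= missed_cleavages sites."""
    cuts = _cleavage_boundaries(sequence, spec)
    return [cuts[j] for j in range(1, min(2 + spec.missed_cleavages, len(cuts)))]


def theoretical_observability(
    proteome: Sequence[ProteinRecord],
    min_len: int = 5,
    max_len: int = 45,
    missed_cleavages: int = 1,
) -> tuple[pd.DataFrame, ObservabilitySummary]:
    """Which protein N-termini the MS approach could theoretically detect.

    A protein's N-terminus is observable when at least one fully-specific
    N-terminal peptide — from trypsin or Lys-N, allowing up to
    ``missed_cleavages``, computed both with and without initiator-Met
    cleavage where the penultimate residue permits it — has a length
    within ``[min_len, max_len]`` (the MS-amenable window).  The summary
    counts observable termini and the subset carrying the NatB consensus
    at the annotated start.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if not proteome:
        raise ValueError("empty proteome")
    rows = []
    for protein in proteome:
        observable = False
        for mature_start in met_cleavage_variants(protein):
            mature = protein.sequence[mature_start - 1 :]
            for protease in ("trypsin", "lysn"):
                spec = DigestSpec(protease=protease, missed_cleavages=missed_cleavages)
                if any(
                    min_len <= length <= max_len
                    for length in _nterm_peptide_lengths(mature, spec)
                ):
                    observable = True
                    break
            if observable:
                break
        is_natb = len(protein.sequence) >= 2 and natb_consensus(protein.sequence[:2])
        rows.append(
            {
                "accession": protein.accession,
                "observable": observable,
                "natb_consensus": is_natb,
            }
        )
    df = pd.DataFrame(rows)
    n_obs = int(df["observable"].sum())
    n_natb = int((df["observable"] & df["natb_consensus"]).sum())
    fraction = n_natb / n_obs if n_obs else 0.0
    return df, ObservabilitySummary(n_obs, n_natb, fraction)
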