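"""Cross-species conservation of the NatB recognition motif.

Each identified substrate anchors an ortholog group: homologous protein
sequences from other eukaryotic species, tagged with a species identifier
in the FASTA header (``species|sequence_id``).  Conservation is scored in
two units.  Per species, the percentage of all its ortholog sequences
(pooled across groups, in-paralogs counted individually) that start with
MD, ME or MN.  Per protein (group), the percentage of represented species
with at least one motif-bearing member — in-paralogs collapse to
any-member here, since the question is whether the species conserves the
motif at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .nterm import natb_consensus

__all__ = [
    "OrthologGroup",
    "read_ortholog_groups",
    "species_conservation",
    "protein_conservation",
    "top_conserved",
]


@dataclass(frozen=True)
class OrthologGroup:
    """Species-tagged homologs of one yeast protein."""

    accession: str
    members: tuple[tuple[str, str], ...]  # (species, sequence)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"ortholog group {self.accession} has no members")

    @property
    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}


def _has_motif(sequence: str) -> bool:
    return len(sequence) >= 2 and natb_consensus(sequence[:2])


def read_ortholog_groups(manifest_path: str | Path) -> list[OrthologGroup]:
    """Load ortholog groups from a manifest TSV (``accession<TAB>fasta_path``).

    FASTA paths are resolved relative to the manifest; headers must be
    ``species|sequence_id``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("accession", "fasta_path"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    groups = []
    for row in manifest.itertuples(index=False):
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        members = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"header {rec.id!r} in {fasta} lacks 'species|id' format"
                )
            species = rec.id.split("|", 1)[0]
            members.append((species, str(rec.seq).upper()))
        groups.append(OrthologGroup(accession=row.accession, members=tuple(members)))
    return groups


def species_conservation(
    groups: Sequence[OrthologGroup],
    pooling: Literal["pooled", "per_group_mean"] = "pooled",
) -> dict[str, float]:
    """Percent of each species' ortholog sequences starting with MD/ME/MN.

    ``pooled`` (default) counts every sequence of the species across all
    groups; ``per_group_mean`` averages the per-group percentages
    instead.  Species contributing no sequences are absent.
    """
    if not groups:
        raise ValueError("no ortholog groups supplied")
    if pooling == "pooled":
        totals: dict[str, int] = {}
        hits: dict[str, int] = {}
        for group in groups:
            for species, seq in group.members:
                totals[species] = totals.get(species, 0) + 1
                hits[species] = hits.get(species, 0) + int(_has_motif(seq))
        return {sp: 100.0 * hits[sp] / totals[sp] for sp in totals}
    if pooling == "per_group_mean":
        per_species: dict[str, list[float]] = {}
        for group in groups:
            counts: dict[str, list[int]] = {}
            for species, seq in group.members:
                tot_hit = counts.setdefault(species, [0, 0])
                tot_hit[0] += 1
                tot_hit[1] += int(_has_motif(seq))
            for species, (tot, hit) in counts.items():
                per_species.setdefault(species, []).append(100.0 * hit / tot)
        return {sp: sum(v) / len(v) for sp, v in per_species.items()}
    raise ValueError(f"unknown pooling {pooling!r}")


def protein_conservation(group: OrthologGroup) -> float:
    """Percent of species in the group with >= 1 motif-bearing member."""
    conserving = {sp for sp, seq in group.members if _has_motif(seq)}
    return 100.0 * len(conserving) / len(group.species)


def top_conserved(
    groups: Sequence[OrthologGroup], k: int = 5
) -> tuple[list[str], dict[str, float]]:
    """The k most motif-conserved proteins, re-scored per species.

    Groups are ranked by :func:`protein_conservation` descending, ties
    broken by accession; the species-level conservation profile is then
    recomputed on just that subset (the published re-analysis of the
    most conserved substrates).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(groups):
        raise ValueError(f"k={k} exceeds the {len(groups)} available groups")
    ranked = sorted(groups, key=lambda g: (-protein_conservation(g), g.accession))
    subset = ranked[:k]
    return [g.accession for g in subset], species_conservation(subset)
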