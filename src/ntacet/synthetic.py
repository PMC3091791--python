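"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a two-replicate 15N label-swap experiment
comparing wild-type yeast to an N-acetyltransferase knockout: a protein
database whose N-termini reproduce the proteome-wide motif composition
(about 16% NatB consensus), peptide quantification tables with log-normal
intensity noise around power-law protein abundances, a planted set of
NatB substrates whose acetylated N-terminal peptides collapse in the
knockout, phospho-sites with planted up-regulation concentrated in
configured kinases and localizations, and ortholog groups with planted
highly-conserved proteins.  Every generated item is recorded in a
ground-truth manifest so recovery tests can score sensitivity and
precision.

All outputs are deterministic functions of ``SimulationConfig.seed``;
each generator draws from its own seed stream, so outputs do not depend
on call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, QuantifiedPeptide, write_fasta, write_quant_table
from .nterm import DigestSpec, MAP_SMALL, digest

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_quant_tables",
    "generate_phospho_table",
    "generate_ortholog_groups",
    "write_run_directory",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NATB_SECOND = list("DEN")
NATA_FIRST = list("SATVG")
NATC_SECOND = list("ILWF")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated experiment (defaults mirror the study's scale)."""

    seed: int = 0
    # proteome
    n_proteins: int = 4000
    fraction_natb_consensus: float = 0.16
    min_length: int = 50
    max_length: int = 600
    # planted NatB substrates
    n_natb_substrates: int = 60
    natb_effect_log2: float = -5.0
    # abundance / noise model
    protein_effect_sd: float = 0.3
    noise_sd: float = 0.5  # SD of one replicate's log2 ratio
    log10_abundance_mean: float = 5.0
    log10_abundance_sd: float = 0.7
    log10_peptide_sd: float = 0.4
    intensity_floor: float = 1e3  # identification floor on the stronger channel
    # acetylation prevalence outside the planted substrates
    p_acetylated_consensus: float = 0.8
    p_acetylated_other: float = 0.4
    # phospho layer
    n_phospho_sites: int = 2000
    fraction_phospho_up: float = 0.23
    phospho_up_log2: float = 2.5
    fraction_phospho_down: float = 0.035
    phospho_down_log2: float = -2.5
    kinases: Mapping[str, float] = field(
        default_factory=lambda: {
            "SNF1": 5.0,
            "CDC28": 1.0,
            "PKA1": 1.0,
            "HOG1": 1.0,
            "CKA1": 1.0,
            "PHO85": 1.0,
        }
    )
    localizations: Mapping[str, float] = field(
        default_factory=lambda: {
            "cytoplasm": 0.40,
            "nucleus": 0.25,
            "mitochondrion": 0.15,
            "ER": 0.10,
            "bud": 0.05,
            "vacuole": 0.05,
        }
    )
    localization_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"bud": 3.0, "cytoplasm": 0.5}
    )
    # ortholog layer
    n_ortholog_groups: int = 59
    n_species: int = 52
    n_top_conserved: int = 5
    baseline_conservation: float = 0.25
    species_presence: float = 0.8
    ortholog_length: int = 30

    def __post_init__(self) -> None:
        for name in (
            "fraction_natb_consensus",
            "fraction_phospho_up",
            "fraction_phospho_down",
            "p_acetylated_consensus",
            "p_acetylated_other",
            "baseline_conservation",
            "species_presence",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named seed stream."""
        return np.random.default_rng([self.seed, stream])


_STREAM_PROTEOME = 1
_STREAM_QUANT = 2
_STREAM_PHOSPHO = 3
_STREAM_ORTHOLOG = 4


@dataclass
class GroundTruth:
    """What was planted: the reference for recovery scoring."""

    protein_effects: dict[str, float] = field(default_factory=dict)
    natb_substrates: set[str] = field(default_factory=set)
    acetylated: dict[str, int] = field(default_factory=dict)  # accession -> event start
    phospho_sites: Optional[pd.DataFrame] = None
    conserved_top: list[str] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int, first_two: str) -> str:
    body = "".join(rng.choice(AMINO_ACIDS, size=length - 2))
    return first_two + body


def generate_proteome(config: SimulationConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random protein database with a controlled N-terminal motif mix.

    Every sequence starts with Met.  A ``fraction_natb_consensus`` of
    proteins get a D/E/N penultimate residue; the remainder are split
    among NatA-type (small penultimate, Met cleavable), NatC-type (bulky
    hydrophobic) and unclassified starts.  ``n_natb_substrates`` proteins
    are drawn from the consensus class and flagged as true substrates;
    every protein receives a true protein-level log2(KO/WT) effect drawn
    from N(0, protein_effect_sd) — substrate status perturbs the
    acetylated peptide species, not protein abundance.
    """
    if config.n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    rng = config.rng(_STREAM_PROTEOME)
    records: list[ProteinRecord] = []
    consensus_flags = rng.random(config.n_proteins) < config.fraction_natb_consensus
    lengths = rng.integers(config.min_length, config.max_length + 1, size=config.n_proteins)
    for i in range(config.n_proteins):
        if consensus_flags[i]:
            second = str(rng.choice(NATB_SECOND))
        else:
            u = rng.random()
            if u < 0.45:
                second = str(rng.choice(NATA_FIRST))
            elif u < 0.60:
                second = str(rng.choice(NATC_SECOND))
            else:
                others = [a for a in AMINO_ACIDS if a not in set("DEN")]
                second = str(rng.choice(others))
        seq = _random_sequence(rng, int(lengths[i]), "M" + second)
        records.append(ProteinRecord(accession=f"YSY{i:04d}W", sequence=seq))

    consensus_idx = np.flatnonzero(consensus_flags)
    if consensus_idx.size < config.n_natb_substrates:
        raise ValueError(
            f"only {consensus_idx.size} consensus proteins for "
            f"{config.n_natb_substrates} requested substrates"
        )
    substrate_idx = rng.choice(consensus_idx, size=config.n_natb_substrates, replace=False)
    substrates = {records[i].accession for i in substrate_idx}

    effects = rng.normal(0.0, config.protein_effect_sd, size=config.n_proteins)
    truth = GroundTruth(
        protein_effects={r.accession: float(e) for r, e in zip(records, effects)},
        natb_substrates=substrates,
    )
    # Acetylation status of the annotated N-terminus: all substrates, a
    # fraction of other proteins (about half the proteome is Nt-acetylated).
    for i, rec in enumerate(records):
        acetylated = rec.accession in substrates or (
            rng.random()
            < (config.p_acetylated_consensus if consensus_flags[i] else config.p_acetylated_other)
        )
        if acetylated:
            # Met-cleaved start for small penultimate residues (NatA territory)
            start = 2 if rec.sequence[1] in MAP_SMALL else 1
            truth.acetylated[rec.accession] = start
    return records, truth


def _nterm_acetyl_peptide(sequence: str, start: int) -> Optional[tuple[str, int]]:
    """Shortest MS-amenable fully-tryptic N-terminal peptide from ``start``."""
    mature = sequence[start - 1 :]
    for pep, pos in digest(mature, DigestSpec("trypsin", "full", missed_cleavages=1)):
        if pos == 1 and 5 <= len(pep) <= 45:
            return pep, start
    for pep, pos in digest(mature, DigestSpec("lysn", "full", missed_cleavages=1)):
        if pos == 1 and 5 <= len(pep) <= 45:
            return pep, start
    return None


def _emit_measurements(
    rng: np.random.Generator,
    config: SimulationConfig,
    peptide: str,
    accession: str,
    start: Optional[int],
    effect: float,
    log10_abundance: float,
    nterm_acetyl: bool = False,
    phospho_positions: tuple[int, ...] = (),
) -> list[Optional[QuantifiedPeptide]]:
    """One row per replicate (None where the peptide falls below the floor).

    Per-channel log2 noise has SD noise_sd/sqrt(2), so each replicate's
    log2 ratio carries SD ``noise_sd``.  Replicate 1 puts the knockout on
    the 14N channel; replicate 2 swaps the labels.
    """
    channel_sd = config.noise_sd / math.sqrt(2.0)
    base = 10.0 ** log10_abundance
    score_low = 26.0 if phospho_positions else 31.0
    rows: list[Optional[QuantifiedPeptide]] = []
    for replicate_id in (1, 2):
        wt = base * 2.0 ** rng.normal(0.0, channel_sd)
        ko = base * 2.0 ** (effect + rng.normal(0.0, channel_sd))
        if max(wt, ko) < config.intensity_floor:
            rows.append(None)
            continue
        if replicate_id == 1:
            i14, i15 = ko, wt
        else:
            i14, i15 = wt, ko
        rows.append(
            QuantifiedPeptide(
                sequence=peptide,
                accession=accession,
                start=start,
                nterm_acetyl=nterm_acetyl,
                phospho_positions=phospho_positions,
                score=float(rng.uniform(score_low, 120.0)),
                intensity_14N=float(i14),
                intensity_15N=float(i15),
                replicate_id=replicate_id,
            )
        )
    return rows


def generate_quant_tables(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[QuantifiedPeptide], list[QuantifiedPeptide]]:
    """Peptide quantification tables for the two label-swapped replicates.

    Each protein contributes 1-10 fully-tryptic unmodified peptides
    (length 6-30) whose KO channel is scaled by the protein's true
    effect, plus — when its N-terminus is acetylated — the acetylated
    N-terminal peptide, which for planted substrates carries
    ``natb_effect_log2`` instead.  Intensities are log-normal around a
    power-law protein abundance; peptides whose stronger channel falls
    below ``intensity_floor`` in a replicate are missing there, so
    singleton-replicate rows occur.
    """
    rng = config.rng(_STREAM_QUANT)
    rep1: list[QuantifiedPeptide] = []
    rep2: list[QuantifiedPeptide] = []
    spec = DigestSpec("trypsin", "full", missed_cleavages=0)
    for protein in proteome:
        effect = truth.protein_effects[protein.accession]
        log10_prot = rng.normal(config.log10_abundance_mean, config.log10_abundance_sd)
        candidates = [
            (pep, pos) for pep, pos in digest(protein, spec) if 6 <= len(pep) <= 30
        ]
        if candidates:
            n_pep = int(rng.integers(1, 11))
            chosen = rng.choice(len(candidates), size=min(n_pep, len(candidates)), replace=False)
            for ci in chosen:
                pep, pos = candidates[int(ci)]
                log10_pep = log10_prot + rng.normal(0.0, config.log10_peptide_sd)
                for row in _emit_measurements(
                    rng, config, pep, protein.accession, pos, effect, log10_pep
                ):
                    if row is not None:
                        (rep1 if row.replicate_id == 1 else rep2).append(row)

        event_start = truth.acetylated.get(protein.accession)
        if event_start is not None:
            nterm = _nterm_acetyl_peptide(protein.sequence, event_start)
            if nterm is not None:
                pep, start = nterm
                acetyl_effect = (
                    config.natb_effect_log2
                    if protein.accession in truth.natb_substrates
                    else effect
                )
                log10_pep = log10_prot + rng.normal(0.0, config.log10_peptide_sd)
                for row in _emit_measurements(
                    rng, config, pep, protein.accession, start,
                    acetyl_effect, log10_pep, nterm_acetyl=True,
                ):
                    if row is not None:
                        (rep1 if row.replicate_id == 1 else rep2).append(row)
    return rep1, rep2


def generate_phospho_table(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
) -> tuple[
    list[QuantifiedPeptide],
    list[QuantifiedPeptide],
    dict[str, list[str]],
    dict[str, list[str]],
    pd.DataFrame,
]:
    """Phosphopeptide tables plus site->kinase and protein->localization maps.

    Sites are S/T/Y residues on random tryptic peptides.  Each site gets
    a predicted kinase and (per protein) a localization; a
    ``fraction_phospho_up`` of sites receive ``phospho_up_log2`` on top
    of the protein effect, sampled with probability proportional to the
    kinase and localization multipliers, so configured kinases dominate
    the elevated subset.  Returns (replicate 1 rows, replicate 2 rows,
    site->kinases, protein->localizations, truth table).
    """
    rng = config.rng(_STREAM_PHOSPHO)
    if config.n_phospho_sites == 0:
        empty = pd.DataFrame(
            columns=["site_id", "accession", "position", "kinase", "localization",
                     "effect", "is_up"]
        )
        return [], [], {}, {}, empty

    kinase_names = list(config.kinases)
    loc_names = list(config.localizations)
    loc_probs = np.array([config.localizations[c] for c in loc_names], dtype=float)
    loc_probs /= loc_probs.sum()

    protein_loc = {
        p.accession: str(rng.choice(loc_names, p=loc_probs)) for p in proteome
    }
    protein_effects = truth.protein_effects if truth is not None else {}

    spec = DigestSpec("trypsin", "full", missed_cleavages=0)
    digest_cache: dict[str, list[tuple[str, int]]] = {}
    sites: list[dict] = []
    seen: set[str] = set()
    attempts = 0
    while len(sites) < config.n_phospho_sites and attempts < 50 * config.n_phospho_sites:
        attempts += 1
        protein = proteome[int(rng.integers(len(proteome)))]
        peptides = digest_cache.get(protein.accession)
        if peptides is None:
            peptides = [
                (pep, pos) for pep, pos in digest(protein, spec) if 6 <= len(pep) <= 30
            ]
            digest_cache[protein.accession] = peptides
        if not peptides:
            continue
        pep, pos = peptides[int(rng.integers(len(peptides)))]
        sty = [i for i, aa in enumerate(pep) if aa in "STY"]
        if not sty:
            continue
        offset = int(rng.choice(sty))
        site_pos = pos + offset
        site_id = f"{protein.accession}_p{site_pos}"
        if site_id in seen:
            continue
        seen.add(site_id)
        sites.append(
            {
                "site_id": site_id,
                "accession": protein.accession,
                "peptide": pep,
                "peptide_start": pos,
                "position": site_pos,
                "pep_offset": offset + 1,  # 1-based within peptide
                "kinase": str(rng.choice(kinase_names)),
                "localization": protein_loc[protein.accession],
            }
        )
    df = pd.DataFrame(sites)

    weights = np.array(
        [
            config.kinases[row.kinase]
            * config.localization_multipliers.get(row.localization, 1.0)
            for row in df.itertuples()
        ],
        dtype=float,
    )
    n_up = int(round(config.fraction_phospho_up * len(df)))
    up_idx = rng.choice(len(df), size=n_up, replace=False, p=weights / weights.sum())
    is_up = np.zeros(len(df), dtype=bool)
    is_up[up_idx] = True
    remaining = np.flatnonzero(~is_up)
    n_down = min(int(round(config.fraction_phospho_down * len(df))), remaining.size)
    down_idx = rng.choice(remaining, size=n_down, replace=False)
    is_down = np.zeros(len(df), dtype=bool)
    is_down[down_idx] = True

    df["is_up"] = is_up
    df["effect"] = [
        protein_effects.get(acc, 0.0)
        + (config.phospho_up_log2 if u else (config.phospho_down_log2 if d else 0.0))
        for acc, u, d in zip(df["accession"], is_up, is_down)
    ]

    rep1: list[QuantifiedPeptide] = []
    rep2: list[QuantifiedPeptide] = []
    for row in df.itertuples():
        log10_pep = rng.normal(config.log10_abundance_mean, config.log10_abundance_sd)
        for qp in _emit_measurements(
            rng, config, row.peptide, row.accession, row.peptide_start,
            float(row.effect), log10_pep, phospho_positions=(int(row.pep_offset),),
        ):
            if qp is not None:
                (rep1 if qp.replicate_id == 1 else rep2).append(qp)

    site_kinase = {row.site_id: [row.kinase] for row in df.itertuples()}
    protein_localization = {acc: [loc] for acc, loc in protein_loc.items()}
    truth_table = df[
        ["site_id", "accession", "position", "kinase", "localization", "effect", "is_up"]
    ].copy()
    return rep1, rep2, site_kinase, protein_localization, truth_table


def generate_ortholog_groups(
    config: SimulationConfig,
) -> tuple[list, GroundTruth]:
    """Ortholog groups with planted fully-conserved proteins.

    ``n_ortholog_groups`` groups over ``n_species`` species; each species
    is present in a group with probability ``species_presence`` and its
    member starts with MD/ME/MN with probability
    ``baseline_conservation`` — except in the ``n_top_conserved`` planted
    groups, where every member carries the motif.
    """
    from .conservation import OrthologGroup  # local import avoids a cycle

    rng = config.rng(_STREAM_ORTHOLOG)
    species = [f"species_{i:02d}" for i in range(config.n_species)]
    accessions = [f"YOG{i:04d}W" for i in range(config.n_ortholog_groups)]
    planted = sorted(
        str(a)
        for a in rng.choice(accessions, size=config.n_top_conserved, replace=False)
    )
    groups: list[OrthologGroup] = []
    non_motif_seconds = [a for a in AMINO_ACIDS if a not in set("DEN")]
    for acc in accessions:
        members = []
        for sp in species:
            if rng.random() >= config.species_presence:
                continue
            conserved = acc in planted or rng.random() < config.baseline_conservation
            if conserved:
                first_two = "M" + str(rng.choice(NATB_SECOND))
            else:
                first_two = "M" + str(rng.choice(non_motif_seconds))
            members.append((sp, _random_sequence(rng, config.ortholog_length, first_two)))
        if not members:  # force at least one member so the group is valid
            conserved = acc in planted
            first_two = "M" + str(rng.choice(NATB_SECOND if conserved else non_motif_seconds))
            members.append(
                (species[0], _random_sequence(rng, config.ortholog_length, first_two))
            )
        groups.append(OrthologGroup(accession=acc, members=tuple(members)))
    truth = GroundTruth(conserved_top=planted)
    return groups, truth


def write_run_directory(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``out_dir`` and return a manifest.

    Writes the proteome FASTA, the two replicate quant TSVs, phospho
    TSVs, annotation tables, ortholog FASTAs with their manifest, and
    the ground-truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    proteome, truth = generate_proteome(config)
    paths["proteome"] = out / "proteome.fasta"
    write_fasta(proteome, paths["proteome"])

    rep1, rep2 = generate_quant_tables(proteome, truth, config)
    paths["quant_rep1"] = out / "quant_rep1.tsv"
    paths["quant_rep2"] = out / "quant_rep2.tsv"
    write_quant_table(rep1, paths["quant_rep1"])
    write_quant_table(rep2, paths["quant_rep2"])

    p1, p2, site_kinase, protein_loc, phospho_truth = generate_phospho_table(
        proteome, config, truth
    )
    paths["phospho_rep1"] = out / "phospho_rep1.tsv"
    paths["phospho_rep2"] = out / "phospho_rep2.tsv"
    write_quant_table(p1, paths["phospho_rep1"])
    write_quant_table(p2, paths["phospho_rep2"])

    paths["site_kinase"] = out / "site_kinase.tsv"
    pd.DataFrame(
        [(s, k) for s, ks in site_kinase.items() for k in ks],
        columns=["site_id", "kinase"],
    ).to_csv(paths["site_kinase"], sep="\t", index=False)
    paths["protein_localization"] = out / "protein_localization.tsv"
    pd.DataFrame(
        [(p, loc) for p, locs in protein_loc.items() for loc in locs],
        columns=["accession", "localization"],
    ).to_csv(paths["protein_localization"], sep="\t", index=False)

    groups, ortho_truth = generate_ortholog_groups(config)
    ortho_dir = out / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for group in groups:
        fasta = ortho_dir / f"{group.accession}.fasta"
        with open(fasta, "w") as fh:
            for i, (sp, seq) in enumerate(group.members):
                fh.write(f">{sp}|{group.accession}_{i}\n{seq}\n")
        manifest_rows.append((group.accession, f"orthologs/{group.accession}.fasta"))
    paths["ortholog_manifest"] = out / "ortholog_manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["accession", "fasta_path"]).to_csv(
        paths["ortholog_manifest"], sep="\t", index=False
    )

    paths["truth_substrates"] = out / "truth_substrates.tsv"
    pd.DataFrame(
        sorted(
            (acc, eff, acc in truth.natb_substrates, truth.acetylated.get(acc, ""))
            for acc, eff in truth.protein_effects.items()
        ),
        columns=["accession", "protein_effect_log2", "natb_substrate", "acetyl_start"],
    ).to_csv(paths["truth_substrates"], sep="\t", index=False)
    paths["truth_phospho"] = out / "truth_phospho.tsv"
    phospho_truth.to_csv(paths["truth_phospho"], sep="\t", index=False)
    paths["truth_conserved"] = out / "truth_conserved.tsv"
    pd.DataFrame({"accession": ortho_truth.conserved_top}).to_csv(
        paths["truth_conserved"], sep="\t", index=False
    )
    return paths
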