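"""Reading and writing the pipeline's file formats.

Protein databases travel as FASTA (SGD-style headers, ``>ACCESSION GENE``),
peptide identification/quantification results as tab-separated tables with
one row per identified peptide per biological replicate, and annotation
tables (protein -> localization, phospho-site -> predicted kinase) as
two-column TSV.  All protein coordinates are 1-based and inclusive, with
position 1 the initiator methionine as annotated.

Missing channel intensities are kept distinct from zero: a peptide row with
an absent intensity is still an identification, it just cannot contribute a
ratio.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "QuantifiedPeptide",
    "read_fasta",
    "write_fasta",
    "read_quant_table",
    "write_quant_table",
    "read_annotation_table",
    "load_table1_fixture",
    "QUANT_COLUMNS",
]

#: Amino-acid alphabet accepted in protein sequences (X = unknown residue).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

#: Canonical column order of the quantification table.
QUANT_COLUMNS = [
    "peptide",
    "accession",
    "start",
    "nterm_acetyl",
    "phospho_positions",
    "score",
    "intensity_14N",
    "intensity_15N",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: accession, optional gene name, sequence."""

    accession: str
    sequence: str
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residues {sorted(bad)} in {self.accession!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"of {self.accession}"
            )
        return self.sequence[position - 1]


@dataclass
class QuantifiedPeptide:
    """One identified peptide in one biological replicate.

    ``intensity_14N``/``intensity_15N`` are MS1 channel intensities in
    arbitrary units; ``None`` means the channel was not quantified, which
    is distinct from an intensity of zero.  ``phospho_positions`` are
    1-based within the peptide.
    """

    sequence: str
    accession: str
    score: float
    replicate_id: int
    start: Optional[int] = None
    nterm_acetyl: bool = False
    phospho_positions: tuple[int, ...] = field(default_factory=tuple)
    intensity_14N: Optional[float] = None
    intensity_15N: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative score for {self.sequence}")
        for inten, name in (
            (self.intensity_14N, "intensity_14N"),
            (self.intensity_15N, "intensity_15N"),
        ):
            if inten is not None and inten < 0:
                raise ValueError(f"negative {name} for {self.sequence}")
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"phospho position {pos} outside peptide {self.sequence}"
                )

    @property
    def is_phospho(self) -> bool:
        return len(self.phospho_positions) > 0

    @property
    def quantifiable(self) -> bool:
        """Both channels present and strictly positive."""
        return (
            self.intensity_14N is not None
            and self.intensity_15N is not None
            and self.intensity_14N > 0
            and self.intensity_15N > 0
        )

    @property
    def modification_signature(self) -> str:
        """Stable string keying the modification state of this peptide."""
        parts = []
        if self.nterm_acetyl:
            parts.append("ac")
        if self.phospho_positions:
            parts.append("p" + ",".join(str(p) for p in self.phospho_positions))
        return "+".join(parts) if parts else "unmod"

    @property
    def key(self) -> tuple[str, str, str]:
        """(accession, peptide, modification signature) identity across replicates."""
        return (self.accession, self.sequence, self.modification_signature)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA database.

    The first whitespace-delimited header token is the accession; an
    optional second token is taken as the gene name.  Sequences are
    uppercased and trailing ``*`` stop symbols stripped.  Duplicate
    accessions and empty files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        tokens = rec.description.split()
        gene = tokens[1] if len(tokens) > 1 else None
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(accession=accession, sequence=seq, gene_name=gene))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write protein records as FASTA, wrapped at ``width`` columns."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            description=r.gene_name or "",
        )
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _parse_phospho(value) -> tuple[int, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(int(tok) for tok in text.split(","))


def read_quant_table(path: str | Path, replicate_id: int) -> list[QuantifiedPeptide]:
    """Read one replicate's peptide quantification TSV.

    Expected columns: ``peptide, accession, start, nterm_acetyl,
    phospho_positions, score, intensity_14N, intensity_15N``.  Empty
    intensity cells become ``None`` (channel not quantified); negative
    intensities are rejected with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in QUANT_COLUMNS]
    if unknown:
        raise ValueError(
            f"unknown column(s) {unknown} in {path}; accepted schema: {QUANT_COLUMNS}"
        )
    missing = [c for c in QUANT_COLUMNS if c not in df.columns and c != "start"]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")

    peptides: list[QuantifiedPeptide] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        def _intensity(name: str) -> Optional[float]:
            raw = getattr(row, name, "")
            if str(raw).strip() == "":
                return None
            value = float(raw)
            if value < 0:
                raise ValueError(f"negative {name} at line {idx} of {path}")
            return value

        start_raw = getattr(row, "start", "")
        start = int(float(start_raw)) if str(start_raw).strip() else None
        peptides.append(
            QuantifiedPeptide(
                sequence=row.peptide,
                accession=row.accession,
                start=start,
                nterm_acetyl=_parse_bool(row.nterm_acetyl),
                phospho_positions=_parse_phospho(row.phospho_positions),
                score=float(row.score),
                intensity_14N=_intensity("intensity_14N"),
                intensity_15N=_intensity("intensity_15N"),
                replicate_id=replicate_id,
            )
        )
    return peptides


def write_quant_table(peptides: Sequence[QuantifiedPeptide], path: str | Path) -> None:
    """Write peptides as a quantification TSV (inverse of :func:`read_quant_table`)."""
    rows = []
    for p in peptides:
        rows.append(
            {
                "peptide": p.sequence,
                "accession": p.accession,
                "start": "" if p.start is None else p.start,
                "nterm_acetyl": str(p.nterm_acetyl).lower(),
                "phospho_positions": ",".join(str(x) for x in p.phospho_positions),
                "score": p.score,
                "intensity_14N": "" if p.intensity_14N is None else repr(p.intensity_14N),
                "intensity_15N": "" if p.intensity_15N is None else repr(p.intensity_15N),
            }
        )
    pd.DataFrame(rows, columns=QUANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path, key: str, value: str) -> dict[str, list[str]]:
    """Read a two-column annotation TSV into ``key -> [values]``.

    Used for protein->localization and phospho-site->kinase tables; one
    row per (item, category) pair, items may recur with several categories.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (key, value):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    mapping: dict[str, list[str]] = {}
    for k, v in zip(df[key], df[value]):
        mapping.setdefault(k, []).append(v)
    return mapping


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged table of 59 detected NatB substrates.

    Columns: ``accession, name, score, sequence, start,
    average_log2_ratio``.  The ``sequence`` column holds the first five
    residues of the acetylated peptide; ``start`` is the 1-based protein
    position of the acetylated residue (four rows are internal termini,
    start > 1, from alternative translation starts).
    """
    resource = importlib.resources.files("ntacet.data").joinpath("natb_substrates.tsv")
    with importlib.resources.as_file(resource) as fp:
        df = pd.read_csv(fp, sep="\t", dtype={"name": str}, keep_default_na=False)
    df["score"] = df["score"].astype(int)
    df["start"] = df["start"].astype(int)
    df["average_log2_ratio"] = df["average_log2_ratio"].astype(float)
    return df
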