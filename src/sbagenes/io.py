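"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the types defined here: ``HmmHit``
records parsed from HMMER3 ``--tblout`` output, ``BlastRecord`` rows from
12-column tabular homology search output (BLAST ``-outfmt 6`` layout),
lineage tables, abundance tables and FASTA sequence files.

Tables are TSV with mandatory headers, UTF-8, '.' decimal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .families import FAMILIES


class ParseError(ValueError):
    """A malformed line or field in an external file; message names the line."""


# ---------------------------------------------------------------------------
# hmmsearch tblout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HmmHit:
    """One hmmsearch hit of a family profile against a genome's proteome.

    ``evalue`` and ``score`` are the full-sequence E-value and bit score.
    """

    family_id: str
    target_protein: str
    genome_id: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.family_id not in FAMILIES:
            raise ValueError(f"unknown gene family: {self.family_id!r}")
        if not self.evalue > 0:
            raise ValueError(f"E-value must be > 0, got {self.evalue!r}")


def parse_tblout(
    path: str | Path,
    protein_to_genome: Mapping[str, str] | None = None,
) -> list[HmmHit]:
    """Parse an HMMER3 ``--tblout`` file into :class:`HmmHit` records.

    The tblout dialect is whitespace-delimited with ``#``-prefixed comment
    lines; fields used are target name (column 1), query name (column 3,
    the family label), full-sequence E-value (column 5) and full-sequence
    score (column 6).

    Genome resolution: RefSeq tblout target names do not carry an assembly
    accession, so either pass an explicit ``protein_to_genome`` map keyed
    by target name, or encode the genome in the target name with the
    ``genome_id|protein_id`` compound convention.
    """
    hits: list[HmmHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 tblout columns, got {len(fields)}")
            target, family = fields[0], fields[2]
            if family not in FAMILIES:
                raise ParseError(f"{path}:{lineno}: unknown family label in query name: {family!r}")
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
            if protein_to_genome is not None:
                try:
                    genome = protein_to_genome[target]
                except KeyError:
                    raise ParseError(
                        f"{path}:{lineno}: target {target!r} absent from protein->genome map"
                    ) from None
                protein = target
            elif "|" in target:
                genome, protein = target.split("|", 1)
            else:
                raise ParseError(
                    f"{path}:{lineno}: cannot resolve genome for target {target!r}: "
                    "no map supplied and no 'genome|protein' convention"
                )
            hits.append(HmmHit(family_id=family, target_protein=protein, genome_id=genome, evalue=evalue, score=score))
    return hits


def write_tblout(hits: Iterable[HmmHit], path: str | Path) -> None:
    """Write hits in the (minimal) tblout dialect :func:`parse_tblout` reads.

    Targets are written with the ``genome|protein`` compound convention.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# target name  accession  query name  accession  E-value  score  bias\n")
        fh.write("#" + "-" * 70 + "\n")
        for h in hits:
            fh.write(
                f"{h.genome_id}|{h.target_protein} - {h.family_id} - {h.evalue:.6g} {h.score:.1f} 0.0\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class BlastRecord:
    """One row of 12-column tabular homology-search output."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"percent identity out of [0, 100]: {self.pident!r}")
        if not self.evalue > 0:
            raise ValueError(f"E-value must be > 0, got {self.evalue!r}")


def parse_blast_tab(path: str | Path) -> list[BlastRecord]:
    """Parse a 12-column tab-separated homology file into records."""
    records: list[BlastRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                rec = BlastRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=float(fields[2]),
                    length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_blast_tab(records: Iterable[BlastRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id, r.subject_id, r.pident, r.length, r.mismatch, r.gapopen,
                        r.qstart, r.qend, r.sstart, r.send, f"{r.evalue:.6g}", r.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; duplicate ids emit a warning but both records are kept."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id kept: {rec.id!r}", stacklevel=2)
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (SeqRecord or ``(id, sequence)`` pairs) as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rec = SeqRecord(Seq(rec[1]), id=rec[0], description="")
        out.append(rec)
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Lineage and abundance tables
# ---------------------------------------------------------------------------

LINEAGE_COLUMNS = ("genome_id", "species", "genus", "phylum", "kingdom")
_KINGDOMS = {"bacteria", "archaea", "fungi"}


def read_lineage(path: str | Path) -> pd.DataFrame:
    """Read a genome lineage TSV (genome_id, species, genus, phylum, kingdom)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_lineage(df)


def validate_lineage(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"lineage table missing required column(s): {', '.join(missing)}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ParseError(f"duplicate genome_id in lineage table: {dups}")
    if df["species"].isna().any() or (df["species"].astype(str).str.strip() == "").any():
        raise ParseError("lineage table has empty species names")
    bad = set(df["kingdom"]) - _KINGDOMS
    if bad:
        raise ParseError(f"unknown kingdom(s): {sorted(bad)}")
    return df.reset_index(drop=True)


def write_lineage(df: pd.DataFrame, path: str | Path) -> None:
    validate_lineage(df).to_csv(path, sep="\t", index=False)


@dataclass
class AbundanceTable:
    """A sample x feature matrix with group labels and optional pairing.

    ``kind`` is ``"species"`` (relative abundances; each sample sums to
    <= 1 + 1e-6) or ``"gene_rpkm"`` (non-negative RPKM values).
    ``groups`` maps sample -> "disease"/"control" (or cohort labels);
    ``pairs`` maps sample -> pairing key for paired designs.
    """

    values: pd.DataFrame
    kind: str
    groups: pd.Series
    pairs: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("species", "gene_rpkm"):
            raise ValueError(f"unknown abundance kind: {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.kind == "species":
            sums = self.values.sum(axis=1)
            if (sums > 1 + 1e-6).any():
                bad = sums[sums > 1 + 1e-6].index.tolist()
                raise ValueError(f"species relative abundances exceed 1 for sample(s): {bad}")
        if not self.groups.index.equals(self.values.index):
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                raise ValueError("every sample needs a group label")
        if self.pairs is not None and self.pairs.isna().all():
            self.pairs = None

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns


def read_abundance(path: str | Path, kind: str) -> AbundanceTable:
    """Read an abundance TSV: columns sample_id, group, [pair_id], features."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"abundance table missing required column: {col}")
    df = df.set_index("sample_id")
    groups = df.pop("group").astype(str)
    pairs = df.pop("pair_id").astype(str) if "pair_id" in df.columns else None
    values = df.astype(float)
    return AbundanceTable(values=values, kind=kind, groups=groups, pairs=pairs)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "group", table.groups)
    if table.pairs is not None:
        out.insert(1, "pair_id", table.pairs)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


@dataclass
class AbundanceStudy:
    """Paired species-abundance and gene-type-RPKM tables for one cohort."""

    species_abundance: AbundanceTable
    gene_rpkm: AbundanceTable
    design: str = "unpaired"  # "unpaired" (Mann-Whitney U) or "paired" (paired t)
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.design not in ("unpaired", "paired"):
            raise ValueError(f"unknown design: {self.design!r}")
        if not self.species_abundance.samples.equals(self.gene_rpkm.samples):
            raise ValueError("species and gene tables must share samples")
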