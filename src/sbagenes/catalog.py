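"""Catalog construction: hit filtering, seed supplementation, copy numbers.

An hmmsearch hit enters the catalog iff its full-sequence E-value is below
1e-65 (strict) and its full-sequence bit score reaches the per-family
cutoff (non-strict).  Seed proteins curated for sparsely detected families
(the Bai operon and 7bHSDH) can be supplemented; a seed duplicating a
retained hit is dropped in favour of the hit so score/E-value provenance
is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .families import EVALUE_MAX, FAMILIES, SCORE_CUTOFFS
from .io import HmmHit, validate_lineage


@dataclass(frozen=True)
class FamilyThresholds:
    """Per-family admission thresholds.

    ``evalue_max`` is global and strict (evalue < evalue_max); ``score_min``
    is per family and non-strict (score >= score_min), so a hit exactly at
    the published cutoff is retained.
    """

    evalue_max: float = EVALUE_MAX
    score_min: Mapping[str, float] = field(default_factory=lambda: dict(SCORE_CUTOFFS))

    def __post_init__(self) -> None:
        missing = [f for f in FAMILIES if f not in self.score_min]
        if missing:
            raise ValueError(f"score_min missing families: {missing}")
        bad = [f for f, s in self.score_min.items() if not s > 0]
        if bad:
            raise ValueError(f"score_min must be positive for: {bad}")


def filter_hits(hits: Sequence[HmmHit], thresholds: FamilyThresholds | None = None) -> list[HmmHit]:
    """Retain hits passing both admission criteria; order preserved, idempotent."""
    thresholds = thresholds or FamilyThresholds()
    unknown = sorted({h.family_id for h in hits} - set(thresholds.score_min))
    if unknown:
        raise KeyError(f"hits carry families absent from thresholds: {unknown}")
    return [
        h
        for h in hits
        if h.evalue < thresholds.evalue_max and h.score >= thresholds.score_min[h.family_id]
    ]


@dataclass(frozen=True)
class GeneRecord:
    """One catalog entry: a gene copy of one family in one genome."""

    family_id: str
    genome_id: str
    protein_accession: str
    kingdom: str
    phylum: str
    genus: str
    species: str
    origin: str = "hmm_hit"  # or "seed_supplement"
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.family_id not in FAMILIES:
            raise ValueError(f"unknown gene family: {self.family_id!r}")
        if self.origin not in ("hmm_hit", "seed_supplement"):
            raise ValueError(f"unknown origin: {self.origin!r}")
        if self.copy_index < 1:
            raise ValueError("copy_index is 1-based")


_CATALOG_COLUMNS = (
    "family_id",
    "genome_id",
    "protein_accession",
    "kingdom",
    "phylum",
    "genus",
    "species",
    "origin",
    "copy_index",
)


class Catalog:
    """An assembled set of :class:`GeneRecord` with derived count tables."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        keys = {(r.genome_id, r.family_id, r.protein_accession) for r in self.records}
        if len(keys) != len(self.records):
            raise ValueError("duplicate (genome, family, protein) records in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=_CATALOG_COLUMNS)

    def family_counts(self) -> pd.Series:
        """Genes per family; families with no record are absent."""
        df = self.to_frame()
        return df.groupby("family_id").size()

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Catalog":
        df = pd.read_csv(path, sep="\t", dtype={"copy_index": int})
        return cls(GeneRecord(**row) for row in df[list(_CATALOG_COLUMNS)].to_dict("records"))


def assemble_catalog(
    retained_hits: Sequence[HmmHit],
    lineage: pd.DataFrame,
    seed_genes: Sequence[GeneRecord] | None = None,
) -> Catalog:
    """Build the catalog from retained hits plus optional curated seeds.

    Records are deduplicated on (genome, family, protein accession) with
    hmm_hit taking precedence over seed_supplement; copy_index is assigned
    1-based by sorted protein accession within each (genome, family) pair.
    """
    lineage = validate_lineage(lineage)
    lin = lineage.set_index("genome_id")
    missing = sorted({h.genome_id for h in retained_hits} - set(lin.index))
    if missing:
        raise KeyError(f"hit genome(s) missing from lineage table: {missing}")

    by_key: dict[tuple[str, str, str], GeneRecord] = {}
    for h in retained_hits:
        row = lin.loc[h.genome_id]
        key = (h.genome_id, h.family_id, h.target_protein)
        by_key[key] = GeneRecord(
            family_id=h.family_id,
            genome_id=h.genome_id,
            protein_accession=h.target_protein,
            kingdom=row["kingdom"],
            phylum=row["phylum"],
            genus=row["genus"],
            species=row["species"],
            origin="hmm_hit",
        )
    for seed in seed_genes or ():
        key = (seed.genome_id, seed.family_id, seed.protein_accession)
        if key not in by_key:  # hmm_hit wins on duplicates
            by_key[key] = replace(seed, origin="seed_supplement")

    # deterministic copy indices: sorted protein accession within genome-family
    grouped: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in by_key.values():
        grouped.setdefault((rec.genome_id, rec.family_id), []).append(rec)
    out: list[GeneRecord] = []
    for (_genome, _family), recs in sorted(grouped.items()):
        for i, rec in enumerate(sorted(recs, key=lambda r: r.protein_accession), start=1):
            out.append(replace(rec, copy_index=i))
    return Catalog(out)


def dedupe_proteins(catalog: Catalog) -> dict[str, set[str]]:
    """Non-redundant protein accession set per family."""
    out: dict[str, set[str]] = {}
    for rec in catalog.records:
        out.setdefault(rec.family_id, set()).add(rec.protein_accession)
    return out


def copy_number_table(catalog: Catalog) -> pd.DataFrame:
    """Copies of each family per genome: columns genome_id, species, family_id, copies."""
    df = catalog.to_frame()
    return (
        df.groupby(["genome_id", "species", "family_id"], as_index=False)
        .size()
        .rename(columns={"size": "copies"})
        .sort_values(["genome_id", "family_id"], kind="stable")
        .reset_index(drop=True)
    )


def average_copy_number(catalog: Catalog) -> pd.DataFrame:
    """Average copy number per (species, family) over carrier genomes only.

    The denominator counts only genomes of the species that carry at least
    one copy of the family; species-family pairs with no carrier genome are
    absent from the output rather than reported as 0 or NaN.
    """
    per_genome = copy_number_table(catalog)
    return (
        per_genome.groupby(["species", "family_id"], as_index=False)["copies"]
        .mean()
        .rename(columns={"copies": "average_copy_number"})
        .round(6)
    )
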