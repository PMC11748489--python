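"""Map a global gene inventory onto the SBA protein catalog per habitat.

A gene from an inventory (e.g. a global unigene catalog tagged with habitat
of origin) is assigned to a gene family iff at least one homology hit
against the non-redundant SBA protein catalog passes the quality filter:
percent identity >= 70 (non-strict) and E-value < 1e-50 (strict).  Among
passing hits the best one (lowest E-value, then highest bit score, then
lexicographically smallest subject id) determines the family; each gene is
assigned at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .families import (
    CATEGORY_OF_FAMILY,
    FAMILIES,
    HOMOLOGY_MAX_EVALUE,
    HOMOLOGY_MIN_IDENTITY,
    round_half_up,
)
from .io import BlastRecord


@dataclass(frozen=True)
class HabitatAssignment:
    """One inventory gene assigned to one family in one habitat."""

    habitat: str
    gene_id: str
    family_id: str
    pident: float
    evalue: float

    def __post_init__(self) -> None:
        if self.pident < HOMOLOGY_MIN_IDENTITY or not self.evalue < HOMOLOGY_MAX_EVALUE:
            raise ValueError("assignment violates the quality filter")
        if self.family_id not in FAMILIES:
            raise ValueError(f"unknown gene family: {self.family_id!r}")


def passes_homology_filter(
    pident: float,
    evalue: float,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
) -> bool:
    """Quality filter shared with the Same/Similar/Unique classifier."""
    return pident >= min_identity and evalue < max_evalue


def classify_inventory(
    records: Sequence[BlastRecord],
    habitat_of: Mapping[str, str],
    family_of_subject: Mapping[str, str],
) -> list[HabitatAssignment]:
    """Assign inventory genes (queries) to families via their best passing hit."""
    passing: dict[str, BlastRecord] = {}
    for rec in records:
        if not passes_homology_filter(rec.pident, rec.evalue):
            continue
        if rec.subject_id not in family_of_subject:
            raise KeyError(
                f"passing hit for gene {rec.query_id!r} has unresolvable subject {rec.subject_id!r}"
            )
        best = passing.get(rec.query_id)
        if best is None or (rec.evalue, -rec.bitscore, rec.subject_id) < (
            best.evalue,
            -best.bitscore,
            best.subject_id,
        ):
            passing[rec.query_id] = rec
    out = []
    for gene_id in sorted(passing):
        rec = passing[gene_id]
        out.append(
            HabitatAssignment(
                habitat=habitat_of[gene_id],
                gene_id=gene_id,
                family_id=family_of_subject[rec.subject_id],
                pident=rec.pident,
                evalue=rec.evalue,
            )
        )
    return out


def habitat_proportions(
    assignments: Sequence[HabitatAssignment],
    habitat_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Per-habitat SBA gene counts and proportions of the habitat total.

    Proportions are percentages reported to 5 decimals; the category split
    groups the 13 families into BSH, Bai and HSDH.  Habitats present in
    ``habitat_totals`` but with no assignment are reported with count 0.
    """
    for habitat, total in habitat_totals.items():
        if total <= 0:
            raise ValueError(f"habitat {habitat!r} has non-positive total gene count")
    unknown = sorted({a.habitat for a in assignments} - set(habitat_totals))
    if unknown:
        raise KeyError(f"assignment habitat(s) without totals: {unknown}")
    rows = []
    for habitat in sorted(habitat_totals):
        here = [a for a in assignments if a.habitat == habitat]
        cats = {"BSH": 0, "Bai": 0, "HSDH": 0}
        for a in here:
            cats[CATEGORY_OF_FAMILY[a.family_id]] += 1
        total = habitat_totals[habitat]
        rows.append(
            {
                "habitat": habitat,
                "total_genes": total,
                "sba_genes": len(here),
                "percent": round_half_up(100.0 * len(here) / total, 5),
                "bsh_genes": cats["BSH"],
                "bai_genes": cats["Bai"],
                "hsdh_genes": cats["HSDH"],
            }
        )
    return pd.DataFrame(rows)
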