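"""Human-vs-animal-model resemblance of the SBA gene repertoire.

Every human gene of a scored family is classified against an animal
model's gene set: "Same" when the identical gene identifier occurs in both
sets (global unigene ids make this meaningful), otherwise "Similar" when a
homology hit reaches >= 70% identity with E-value < 1e-50, otherwise
"Unique" to humans.  Category ratios are fractions of the HUMAN gene count,
so animal-only genes never enter the score.

    gene score  = ratio_same + 0.7 * ratio_similar - ratio_unique
    overall     = sum_j W_j * gene_score_j        (weights sum to 1)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .families import FAMILY_WEIGHTS, GENE_TYPES
from .habitat import passes_homology_filter
from .io import BlastRecord

CATEGORIES = ("Same", "Similar", "Unique")


@dataclass(frozen=True)
class GeneCategory:
    """Classification of one human gene against one animal model."""

    gene_id: str
    family_id: str
    category: str
    evidence: str  # "shared_id" | "<subject id of best passing hit>" | "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")


def classify_genes(
    human_genes: Mapping[str, Sequence[str]],
    animal_genes: Mapping[str, Sequence[str]],
    blast_records: Iterable[BlastRecord],
) -> list[GeneCategory]:
    """Classify every human gene, per family, as Same/Similar/Unique.

    ``human_genes`` / ``animal_genes`` map family label -> gene id list;
    ``blast_records`` are human->animal homology hits indexed by query
    (human gene) id.  Shared-id membership is checked first and wins over
    any homology evidence; a human gene with several passing hits is
    Similar exactly once.
    """
    by_query: dict[str, list[BlastRecord]] = {}
    for rec in blast_records:
        by_query.setdefault(rec.query_id, []).append(rec)

    out: list[GeneCategory] = []
    for family, ids in human_genes.items():
        if len(set(ids)) != len(list(ids)):
            dups = sorted({g for g in ids if list(ids).count(g) > 1})
            raise ValueError(f"duplicate human gene ids in family {family!r}: {dups}")
        animal_set = set(animal_genes.get(family, ()))
        for gene_id in ids:
            if gene_id in animal_set:
                out.append(GeneCategory(gene_id, family, "Same", "shared_id"))
                continue
            passing = [
                r
                for r in by_query.get(gene_id, ())
                if passes_homology_filter(r.pident, r.evalue)
            ]
            if passing:
                best = min(passing, key=lambda r: (r.evalue, -r.bitscore, r.subject_id))
                out.append(GeneCategory(gene_id, family, "Similar", best.subject_id))
            else:
                out.append(GeneCategory(gene_id, family, "Unique", "none"))
    return out


def category_ratios(categories: Sequence[GeneCategory]) -> pd.DataFrame:
    """Per-family Same/Similar/Unique fractions of the human gene count.

    Returns columns family_id, n_human, ratio_same, ratio_similar,
    ratio_unique; the three ratios sum to 1 per family.
    """
    rows = []
    df = pd.DataFrame([vars(c) for c in categories])
    if df.empty:
        return pd.DataFrame(
            columns=["family_id", "n_human", "ratio_same", "ratio_similar", "ratio_unique"]
        )
    for family, grp in df.groupby("family_id", sort=False):
        n = len(grp)
        counts = grp["category"].value_counts()
        rows.append(
            {
                "family_id": family,
                "n_human": n,
                "ratio_same": counts.get("Same", 0) / n,
                "ratio_similar": counts.get("Similar", 0) / n,
                "ratio_unique": counts.get("Unique", 0) / n,
            }
        )
    return pd.DataFrame(rows)


def gene_score(ratio_same: float, ratio_similar: float, ratio_unique: float) -> float:
    """Category-weighted per-family similarity score in [-1, 1]."""
    total = ratio_same + ratio_similar + ratio_unique
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category ratios must sum to 1, got {total}")
    return ratio_same + 0.7 * ratio_similar - ratio_unique


def gene_scores(ratios: pd.DataFrame) -> pd.Series:
    """Gene score per family from a :func:`category_ratios` table."""
    return pd.Series(
        {
            row.family_id: gene_score(row.ratio_same, row.ratio_similar, row.ratio_unique)
            for row in ratios.itertuples()
        }
    )


def overall_score(
    scores: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Pathway-weighted sum of per-family gene scores; bounded in [-1, 1]."""
    weights = dict(FAMILY_WEIGHTS if weights is None else weights)
    if abs(sum(weights.values()) - 1.0) > 1e-12:
        raise ValueError("family weights must sum to 1")
    missing = [t for t in weights if t not in scores]
    if missing:
        raise KeyError(f"missing gene score(s) for: {missing}")
    return sum(w * scores[t] for t, w in weights.items())


@dataclass
class SimilarityResult:
    """Per-family and overall resemblance of one animal model to humans."""

    animal_model: str
    ratios: pd.DataFrame
    scores: pd.Series
    overall: float


def score_animal_model(
    animal_model: str,
    human_genes: Mapping[str, Sequence[str]],
    animal_genes: Mapping[str, Sequence[str]],
    blast_records: Iterable[BlastRecord],
    weights: Mapping[str, float] | None = None,
) -> SimilarityResult:
    """End-to-end classification and scoring of one animal model."""
    cats = classify_genes(human_genes, animal_genes, blast_records)
    ratios = category_ratios(cats)
    scores = gene_scores(ratios)
    missing_weighted = [t for t in (weights or FAMILY_WEIGHTS) if t not in scores.index]
    if missing_weighted:
        raise KeyError(f"no human genes for weighted gene type(s): {missing_weighted}")
    return SimilarityResult(
        animal_model=animal_model,
        ratios=ratios,
        scores=scores,
        overall=overall_score(scores, weights),
    )
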