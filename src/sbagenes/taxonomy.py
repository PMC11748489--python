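"""Composition, prevalence, multi-copy and multi-functionality summaries.

These are the counting operations behind the catalog overview figures:
how a family's genes distribute over phyla/genera/species, what fraction
of a species' genomes carry a family, which genomes hold duplicate genes,
and which genomes combine deconjugation (BSH) with downstream pathways.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .catalog import Catalog, copy_number_table
from .families import BAI_FAMILIES, percent

_RANKS = ("phylum", "genus", "species")


def compose_by_rank(catalog: Catalog, family: str, rank: str) -> pd.DataFrame:
    """Partition a family's genes by taxon at ``rank``.

    Returns columns family_id, rank, taxon, count, percent with percent =
    100*count/family_total rounded half-up to one decimal; rows sorted by
    count descending, ties broken by taxon name.
    """
    if rank not in _RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {_RANKS}")
    df = catalog.to_frame()
    fam = df[df["family_id"] == family]
    if fam.empty:
        raise ValueError(f"catalog has no records for family {family!r}")
    total = len(fam)
    counts = fam.groupby(rank).size().reset_index(name="count")
    counts["percent"] = [percent(c, total) for c in counts["count"]]
    counts = counts.sort_values(["count", rank], ascending=[False, True], kind="stable")
    counts.insert(0, "rank", rank)
    counts.insert(0, "family_id", family)
    return counts.rename(columns={rank: "taxon"}).reset_index(drop=True)


def species_prevalence(catalog: Catalog, genome_inventory: pd.DataFrame) -> pd.DataFrame:
    """Carrier-genome prevalence per (species, family).

    ``genome_inventory`` is a lineage table listing every genome of every
    species (carriers and non-carriers).  A carrier holds >= 1 copy.
    Species-family pairs with zero carriers are omitted.
    """
    inventory_genomes = set(genome_inventory["genome_id"])
    df = catalog.to_frame()
    missing = sorted(set(df["genome_id"]) - inventory_genomes)
    if missing:
        raise KeyError(f"catalog genome(s) absent from inventory: {missing}")
    totals = genome_inventory.groupby("species")["genome_id"].nunique()
    carriers = df.groupby(["species", "family_id"])["genome_id"].nunique().reset_index(name="carrier_genomes")
    carriers["total_genomes"] = carriers["species"].map(totals).astype(int)
    carriers["percent"] = [
        percent(c, t) for c, t in zip(carriers["carrier_genomes"], carriers["total_genomes"])
    ]
    return carriers.sort_values(["family_id", "species"], kind="stable").reset_index(drop=True)


def multicopy_summary(catalog: Catalog) -> pd.DataFrame:
    """Genomes with >= 2 copies of a family, stratified by species and copy count.

    Returns columns family_id, species, copies, n_genomes plus the fraction
    of the species' cataloged genomes that are multi-copy for that family
    (``species_multicopy_percent``, computed over the species' carrier
    genomes of that family).
    """
    per_genome = copy_number_table(catalog)
    multi = per_genome[per_genome["copies"] >= 2]
    if multi.empty:
        return pd.DataFrame(
            columns=["family_id", "species", "copies", "n_genomes", "species_multicopy_percent"]
        )
    strata = (
        multi.groupby(["family_id", "species", "copies"], as_index=False)
        .agg(n_genomes=("genome_id", "nunique"))
    )
    carriers = per_genome.groupby(["family_id", "species"])["genome_id"].nunique()
    multi_carriers = multi.groupby(["family_id", "species"])["genome_id"].nunique()
    frac = {
        key: percent(multi_carriers[key], carriers[key]) for key in multi_carriers.index
    }
    strata["species_multicopy_percent"] = [
        frac[(f, s)] for f, s in zip(strata["family_id"], strata["species"])
    ]
    return strata.sort_values(["family_id", "species", "copies"], kind="stable").reset_index(drop=True)


def multifunctional_genomes(catalog: Catalog) -> pd.DataFrame:
    """Genomes carrying BSH together with >= 1 Bai or HSDH family.

    Returns one row per qualifying genome with its species, the sorted
    family set carried, and a combination label such as ``BSH-12aHSDH``
    (BSH first, remaining families in canonical order).
    """
    from .families import FAMILIES

    df = catalog.to_frame()
    fam_sets = df.groupby(["genome_id", "species"])["family_id"].agg(set)
    rows = []
    for (genome, species), fams in fam_sets.items():
        if "BSH" in fams and len(fams - {"BSH"}) >= 1:
            ordered = [f for f in FAMILIES if f in fams]
            rows.append(
                {
                    "genome_id": genome,
                    "species": species,
                    "families": tuple(ordered),
                    "combination": "-".join(ordered),
                }
            )
    out = pd.DataFrame(rows, columns=["genome_id", "species", "families", "combination"])
    return out.sort_values("genome_id", kind="stable").reset_index(drop=True)


def complete_bai_genomes(
    catalog: Catalog, required_set: Sequence[str] = BAI_FAMILIES
) -> pd.DataFrame:
    """Genomes carrying every family in ``required_set`` (default: all 7 Bai)."""
    required = set(required_set)
    if not required:
        raise ValueError("required_set must be non-empty")
    if not required <= set(BAI_FAMILIES):
        raise ValueError(f"required_set must be Bai families, got {sorted(required)}")
    df = catalog.to_frame()
    fam_sets = df.groupby(["genome_id", "species"])["family_id"].agg(set)
    rows = [
        {"genome_id": genome, "species": species}
        for (genome, species), fams in fam_sets.items()
        if required <= fams
    ]
    out = pd.DataFrame(rows, columns=["genome_id", "species"])
    return out.sort_values("genome_id", kind="stable").reset_index(drop=True)
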