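"""Shared fixtures: compact catalog builders and seeded simulations."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from sbagenes.catalog import Catalog, GeneRecord
from sbagenes.simulate import SimConfig, simulate_genome_hits

_KINGDOM_OF = {"Euryarchaeota": "archaea", "Basidiomycola": "fungi"}


def build_catalog(entries) -> Catalog:
    """Build a catalog from (family, genome, species, genus, phylum[, n_copies]) tuples.

    Protein accessions are synthesized; copy indices follow the requested
    copy count.  Kingdom is inferred from the phylum (bacteria unless the
    phylum is archaeal/fungal).
    """
    counter = itertools.count(1)
    records = []
    for entry in entries:
        family, genome, species, genus, phylum = entry[:5]
        n_copies = entry[5] if len(entry) > 5 else 1
        for c in range(1, n_copies + 1):
            records.append(
                GeneRecord(
                    family_id=family,
                    genome_id=genome,
                    protein_accession=f"P{next(counter):06d}",
                    kingdom=_KINGDOM_OF.get(phylum, "bacteria"),
                    phylum=phylum,
                    genus=genus,
                    species=species,
                    copy_index=c,
                )
            )
    return Catalog(records)


def bulk_catalog(family_taxon_counts) -> Catalog:
    """Catalog with given (family, phylum, genus, species) gene counts.

    ``family_taxon_counts`` maps (family, phylum, genus, species) -> number
    of single-copy genes, each in its own genome.
    """
    counter = itertools.count(1)
    entries = []
    for (family, phylum, genus, species), n in family_taxon_counts.items():
        for _ in range(n):
            entries.append((family, f"G{next(counter):06d}", species, genus, phylum))
    return build_catalog(entries)


def lineage_frame(rows) -> pd.DataFrame:
    """Lineage table from (genome_id, species, genus, phylum, kingdom) tuples."""
    return pd.DataFrame(rows, columns=["genome_id", "species", "genus", "phylum", "kingdom"])


@pytest.fixture(scope="session")
def genome_sim():
    return simulate_genome_hits(SimConfig(rng_seed=7))


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(rng_seed=7)
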