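"""Composition, prevalence, multi-copy and multi-functionality arithmetic."""

import pytest

from sbagenes.catalog import assemble_catalog, filter_hits
from sbagenes.families import percent, round_half_up
from sbagenes.taxonomy import (
    complete_bai_genomes,
    compose_by_rank,
    multicopy_summary,
    multifunctional_genomes,
    species_prevalence,
)

from conftest import build_catalog, bulk_catalog, lineage_frame


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (1374, 1668, 82.4),  # BSH in Firmicutes
            (248, 1668, 14.9),  # BSH in Actinobacteria
            (655, 1668, 39.3),  # BSH in Enterococcus
            (281, 1668, 16.8),  # BSH in Listeria
            (157, 1668, 9.4),  # BSH in Lactiplantibacillus
            (176, 241, 73.0),  # Bai in Firmicutes
            (65, 241, 27.0),  # Bai in Actinobacteria
            (2642, 2770, 95.4),  # 7aHSDH in Proteobacteria
            (77, 136, 56.6),  # 3bHSDH in Bacteroidetes
            (183, 386, 47.4),  # 12aHSDH in Actinobacteria
        ],
    )
    def test_published_composition_pairs(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_ties(self):
        assert round_half_up(82.35, 1) == 82.4
        assert round_half_up(0.125, 2) == 0.13


class TestComposition:
    def test_phylum_split_reproduces_printed_percentages(self):
        catalog = bulk_catalog(
            {
                ("BSH", "Firmicutes", "Enterococcus", "Enterococcus faecium"): 1374,
                ("BSH", "Actinobacteria", "Collinsella", "Collinsella aerofaciens"): 248,
                ("BSH", "Euryarchaeota", "Methanobrevibacter", "Methanobrevibacter smithii"): 46,
            }
        )
        rows = compose_by_rank(catalog, "BSH", "phylum")
        assert rows["count"].sum() == 1668
        top = rows.iloc[0]
        assert (top["taxon"], top["count"], top["percent"]) == ("Firmicutes", 1374, 82.4)
        assert rows.set_index("taxon").loc["Actinobacteria", "percent"] == 14.9

    def test_single_taxon_family_is_100_percent(self):
        catalog = bulk_catalog({("BaiE", "Firmicutes", "Lachnoclostridium", "Clostridium scindens"): 12})
        rows = compose_by_rank(catalog, "BaiE", "phylum")
        assert len(rows) == 1 and rows["percent"].item() == 100.0

    def test_counts_partition_family_total(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        for family, total in catalog.family_counts().items():
            rows = compose_by_rank(catalog, family, "genus")
            assert rows["count"].sum() == total

    def test_genus_refines_phylum(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        df = catalog.to_frame()
        for family in catalog.family_counts().index:
            phyla = compose_by_rank(catalog, family, "phylum").set_index("taxon")["count"]
            genera = compose_by_rank(catalog, family, "genus")
            genus_to_phylum = df.drop_duplicates("genus").set_index("genus")["phylum"]
            summed = genera.assign(phylum=genera["taxon"].map(genus_to_phylum)).groupby("phylum")["count"].sum()
            assert summed.to_dict() == phyla.to_dict()

    def test_unknown_rank_errors(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        with pytest.raises(ValueError, match="rank"):
            compose_by_rank(catalog, "BSH", "kingdom2")


class TestPrevalence:
    def _inventory(self, species, n, prefix):
        return lineage_frame(
            [(f"{prefix}{i}", species, "Genus", "Phylum", "bacteria") for i in range(n)]
        )

    @pytest.mark.parametrize("carriers,total,expected", [(2203, 2250, 97.9), (3, 4, 75.0), (273, 276, 98.9)])
    def test_printed_carrier_total_pairs(self, carriers, total, expected):
        inventory = self._inventory("Escherichia coli", total, "G")
        catalog = build_catalog(
            [("7aHSDH", f"G{i}", "Escherichia coli", "Escherichia", "Proteobacteria") for i in range(carriers)]
        )
        rows = species_prevalence(catalog, inventory)
        assert rows["percent"].item() == expected
        assert rows["carrier_genomes"].item() == carriers

    def test_zero_carrier_species_omitted(self):
        inventory = self._inventory("Escherichia coli", 4, "G")
        extra = self._inventory("Listeria monocytogenes", 2, "L")
        catalog = build_catalog(
            [("BSH", "G0", "Escherichia coli", "Escherichia", "Proteobacteria")]
        )
        rows = species_prevalence(catalog, pd_concat(inventory, extra))
        assert set(rows["species"]) == {"Escherichia coli"}

    def test_catalog_genome_missing_from_inventory_errors(self):
        inventory = self._inventory("Escherichia coli", 1, "G")
        catalog = build_catalog([("BSH", "X1", "Escherichia coli", "Escherichia", "Proteobacteria")])
        with pytest.raises(KeyError, match="X1"):
            species_prevalence(catalog, inventory)


def pd_concat(a, b):
    import pandas as pd

    return pd.concat([a, b], ignore_index=True)


class TestMulticopy:
    def test_strata_and_species_fraction(self):
        # 194 multi-copy of 251 E. faecium carrier genomes -> 77.3%
        entries = [("BSH", f"G{i}", "Enterococcus faecium", "Enterococcus", "Firmicutes", 2) for i in range(186)]
        entries += [("BSH", f"H{i}", "Enterococcus faecium", "Enterococcus", "Firmicutes", 4) for i in range(8)]
        entries += [("BSH", f"S{i}", "Enterococcus faecium", "Enterococcus", "Firmicutes", 1) for i in range(57)]
        rows = multicopy_summary(build_catalog(entries))
        assert rows["species_multicopy_percent"].unique().tolist() == [77.3]
        four = rows[rows["copies"] == 4]
        assert four["n_genomes"].item() == 8  # the quadruplicated stratum

    def test_all_single_copy_gives_empty_summary(self):
        rows = multicopy_summary(
            build_catalog([("BSH", "G1", "Listeria monocytogenes", "Listeria", "Firmicutes", 1)])
        )
        assert rows.empty

    def test_matches_truth_copy_maxima(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        rows = multicopy_summary(catalog)
        truth = genome_sim.planted.groupby(["genome_id", "family_id"]).size()
        expected_multi = int((truth >= 2).sum())
        assert rows["n_genomes"].sum() == expected_multi


class TestMultifunctional:
    def test_requires_bsh_plus_other(self):
        entries = [
            ("BSH", "G1", "Sp a", "A", "Firmicutes"),  # BSH only -> excluded
            ("BSH", "G2", "Sp b", "B", "Firmicutes"),
            ("12aHSDH", "G2", "Sp b", "B", "Firmicutes"),  # BSH + 12aHSDH -> included
            ("7aHSDH", "G3", "Sp c", "C", "Proteobacteria"),  # no BSH -> excluded
        ]
        rows = multifunctional_genomes(build_catalog(entries))
        assert list(rows["genome_id"]) == ["G2"]
        assert rows["combination"].item() == "BSH-12aHSDH"

    def test_counts_match_truth_brute_force(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        rows = multifunctional_genomes(catalog)
        fams = genome_sim.planted.groupby("genome_id")["family_id"].agg(set)
        expected = {g for g, fs in fams.items() if "BSH" in fs and len(fs - {"BSH"}) >= 1}
        assert set(rows["genome_id"]) == expected
        # multifunctional set is a subset of BSH carriers
        bsh_carriers = {g for g, fs in fams.items() if "BSH" in fs}
        assert set(rows["genome_id"]) <= bsh_carriers


class TestCompleteBai:
    def test_full_set_membership(self):
        full = [(f, "G1", "Clostridium scindens", "Lachnoclostridium", "Firmicutes")
                for f in ("BaiA", "BaiB", "BaiCD", "BaiE", "BaiF", "BaiG", "BaiH")]
        missing_e = [(f, "G2", "Clostridium hylemonae", "Lachnoclostridium", "Firmicutes")
                     for f in ("BaiA", "BaiB", "BaiCD", "BaiF", "BaiG", "BaiH")]
        rows = complete_bai_genomes(build_catalog(full + missing_e))
        assert list(rows["genome_id"]) == ["G1"]

    def test_matches_set_intersection_oracle(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        required = {"BaiA", "BaiCD", "BaiE"}
        rows = complete_bai_genomes(catalog, sorted(required))
        fams = genome_sim.planted.groupby("genome_id")["family_id"].agg(set)
        expected = {g for g, fs in fams.items() if required <= fs}
        assert set(rows["genome_id"]) == expected

    def test_empty_required_set_errors(self, genome_sim):
        catalog = assemble_catalog(filter_hits(genome_sim.hits), genome_sim.lineage)
        with pytest.raises(ValueError):
            complete_bai_genomes(catalog, [])
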