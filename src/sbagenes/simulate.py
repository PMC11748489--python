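"""Seeded generators emulating every input the analysis chain assumes.

Four generators mirror the four data acquisitions the real study performed,
at desk scale and with machine-readable truth tables:

* :func:`simulate_genome_hits` — a planted taxonomy of complete genomes
  carrying 0-4 copies of the 13 gene families, emitted as an hmmsearch
  tblout file whose planted hits satisfy both admission criteria and whose
  decoys violate at least one (scores/E-values straddle the cutoffs).
* :func:`simulate_abundance_study` — a case/control cohort: species
  relative abundances (log-normal, rows sum to 1) and gene-type RPKM built
  as sum over carrier species of abundance x copy number x gain under
  multiplicative log-normal noise, with planted per-species fold changes.
* :func:`simulate_correspondence` — human and animal gene lists with
  configurable Same/Similar/Unique fractions and the homology table
  supporting them.
* :func:`simulate_habitat_inventory` — per-habitat gene totals and a
  homology table planting a known number of SBA genes per habitat.

Every generator is a pure function of its config (fixed seed gives
byte-identical files) and records truth sufficient to score downstream
recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .families import FAMILIES, GENE_TYPES, SCORE_CUTOFFS, gene_type_of
from .io import (
    AbundanceStudy,
    AbundanceTable,
    BlastRecord,
    HmmHit,
    write_blast_tab,
    write_lineage,
    write_tblout,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Planted taxonomy: species -> (genus, phylum, kingdom).
DEFAULT_SPECIES: Mapping[str, tuple[str, str, str]] = {
    "Enterococcus faecium": ("Enterococcus", "Firmicutes", "bacteria"),
    "Listeria monocytogenes": ("Listeria", "Firmicutes", "bacteria"),
    "Clostridium scindens": ("Lachnoclostridium", "Firmicutes", "bacteria"),
    "Ruminococcus gnavus": ("Ruminococcus", "Firmicutes", "bacteria"),
    "Collinsella aerofaciens": ("Collinsella", "Actinobacteria", "bacteria"),
    "Rhodococcus equi": ("Rhodococcus", "Actinobacteria", "bacteria"),
    "Escherichia coli": ("Escherichia", "Proteobacteria", "bacteria"),
    "Mesorhizobium opportunistum": ("Mesorhizobium", "Proteobacteria", "bacteria"),
    "Bacteroides xylanisolvens": ("Bacteroides", "Bacteroidetes", "bacteria"),
    "Elizabethkingia anophelis": ("Elizabethkingia", "Bacteroidetes", "bacteria"),
    "Methanobrevibacter smithii": ("Methanobrevibacter", "Euryarchaeota", "archaea"),
}

#: Host ranges: which planted species can carry each family.  Mirrors the
#: field's taxon structure (deconjugation in Firmicutes/Actinobacteria and
#: gut archaea, the Bai operon in a few Lachnospiraceae, 3bHSDH in
#: Bacteroidetes, 7aHSDH dominated by Proteobacteria, 7bHSDH in Ruminococcus
#: and Collinsella).
_BAI_HOSTS = ("Clostridium scindens", "Ruminococcus gnavus")
DEFAULT_FAMILY_HOSTS: Mapping[str, tuple[str, ...]] = {
    "BSH": (
        "Enterococcus faecium",
        "Listeria monocytogenes",
        "Clostridium scindens",
        "Ruminococcus gnavus",
        "Collinsella aerofaciens",
        "Methanobrevibacter smithii",
    ),
    **{f: _BAI_HOSTS for f in ("BaiA", "BaiB", "BaiCD", "BaiE", "BaiF", "BaiG", "BaiH")},
    "3aHSDH": ("Clostridium scindens", "Rhodococcus equi", "Mesorhizobium opportunistum"),
    "3bHSDH": ("Bacteroides xylanisolvens", "Elizabethkingia anophelis"),
    "7aHSDH": ("Escherichia coli", "Mesorhizobium opportunistum", "Bacteroides xylanisolvens"),
    "7bHSDH": ("Ruminococcus gnavus", "Collinsella aerofaciens"),
    "12aHSDH": (
        "Rhodococcus equi",
        "Enterococcus faecium",
        "Clostridium scindens",
        "Methanobrevibacter smithii",
    ),
}

#: Probability that a genome of a host species carries >= 1 copy.
DEFAULT_CARRIAGE_PROB: Mapping[str, float] = {
    "BSH": 0.9,
    "BaiA": 0.8,
    "BaiB": 0.8,
    "BaiCD": 0.8,
    "BaiE": 0.8,
    "BaiF": 0.8,
    "BaiG": 0.8,
    "BaiH": 0.8,
    "3aHSDH": 0.8,
    "3bHSDH": 0.9,
    "7aHSDH": 0.85,
    "7bHSDH": 0.6,
    "12aHSDH": 0.8,
}

#: Copies per carrier genome, probabilities over {1..4}.  Deconjugation and
#: the 7a/12a oxidations are frequently multi-copy; the Bai operon and
#: 7bHSDH are essentially single-copy.
_SINGLE = (1.0, 0.0, 0.0, 0.0)
DEFAULT_COPY_NUMBER_PROBS: Mapping[str, tuple[float, ...]] = {
    "BSH": (0.55, 0.25, 0.13, 0.07),
    "BaiA": _SINGLE,
    "BaiB": _SINGLE,
    "BaiCD": _SINGLE,
    "BaiE": _SINGLE,
    "BaiF": _SINGLE,
    "BaiG": _SINGLE,
    "BaiH": _SINGLE,
    "3aHSDH": (0.93, 0.07, 0.0, 0.0),
    "3bHSDH": (0.95, 0.05, 0.0, 0.0),
    "7aHSDH": (0.75, 0.15, 0.07, 0.03),
    "7bHSDH": _SINGLE,
    "12aHSDH": (0.65, 0.20, 0.10, 0.05),
}

#: Same/Similar/Unique target fractions per scored gene type (an animal
#: model broadly resembling the human repertoire).
DEFAULT_CORRESPONDENCE_FRACTIONS: Mapping[str, tuple[float, float, float]] = {
    "BSH": (0.35, 0.55, 0.10),
    "Bai": (0.20, 0.60, 0.20),
    "3aHSDH": (0.30, 0.60, 0.10),
    "3bHSDH": (0.10, 0.55, 0.35),
    "7aHSDH": (0.15, 0.70, 0.15),
    "7bHSDH": (0.50, 0.40, 0.10),
    "12aHSDH": (0.15, 0.75, 0.10),
}

DEFAULT_HABITAT_TOTALS: Mapping[str, int] = {
    "human gut": 120_000,
    "human oral": 60_000,
    "wastewater": 40_000,
    "soil": 80_000,
    "marine": 50_000,
}

#: Fraction of a habitat's genes that are planted SBA genes; the gut and
#: wastewater are SBA-rich, the marine habitat nearly devoid.
DEFAULT_HABITAT_SBA_RATE: Mapping[str, float] = {
    "human gut": 1.2e-4,
    "human oral": 2e-5,
    "wastewater": 1.5e-4,
    "soil": 5e-6,
    "marine": 1e-6,
}


@dataclass
class SimConfig:
    """Study conditions for all four generators.

    The defaults are the conditions used throughout the test suite and the
    reproduction script: 11 species x 4 genomes, 50 samples per group, unit
    log-normal spread between species, 0.5 log-sd within species and on
    RPKM noise, and no planted effects (a null cohort) unless
    ``fold_changes`` says otherwise.
    """

    rng_seed: int = 0
    # genomes / hits
    species: Mapping[str, tuple[str, str, str]] = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    n_genomes_per_species: int = 4
    family_hosts: Mapping[str, tuple[str, ...]] | None = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_HOSTS)
    )  # None = every species can carry every family
    carriage_prob: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CARRIAGE_PROB))
    copy_number_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COPY_NUMBER_PROBS)
    )  # copies per carrier genome, probs over {1..4}
    decoy_rate: float = 0.25  # expected decoy hits per (genome, family)
    # abundance study
    n_samples_per_group: int = 50
    paired: bool = False
    species_log_mu: float = 0.0
    species_log_sigma: float = 1.0
    sample_log_sigma: float = 0.5
    rpkm_log_sigma: float = 0.5
    rpkm_gain: float = 1000.0
    fold_changes: Mapping[str, float] = field(default_factory=dict)  # species -> disease fold
    # correspondence
    n_human_genes: int = 40
    correspondence_fractions: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CORRESPONDENCE_FRACTIONS)
    )
    # habitat inventory
    habitat_totals: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_HABITAT_TOTALS))
    habitat_sba_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_SBA_RATE)
    )

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species map must be non-empty")
        for fam, probs in self.copy_number_probs.items():
            probs = tuple(probs)
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"copy-number distribution for {fam} must be 4 probs over 1..4")
        for fam, p in self.carriage_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"carriage probability for {fam} out of [0, 1]")
        for fam, (s, m, u) in self.correspondence_fractions.items():
            if min(s, m, u) < 0 or abs(s + m + u - 1.0) > 1e-9:
                raise ValueError(f"Same/Similar/Unique fractions for {fam} must sum to 1")
        if not 0 <= self.decoy_rate:
            raise ValueError("decoy_rate must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent generator per logical stream, fixed by the seed."""
        return np.random.default_rng([int(self.rng_seed), stream])


# ---------------------------------------------------------------------------
# Genomes and hmmsearch hits
# ---------------------------------------------------------------------------


@dataclass
class GenomeSim:
    """A planted genome set: lineage, hmm hits (planted + decoys), truth."""

    lineage: pd.DataFrame
    hits: list[HmmHit]
    truth: pd.DataFrame  # genome_id, family_id, protein, copy_index, is_decoy, score, evalue

    @property
    def planted(self) -> pd.DataFrame:
        return self.truth[~self.truth["is_decoy"]].reset_index(drop=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_lineage(self.lineage, out / "lineage.tsv")
        write_tblout(self.hits, out / "hits.tblout")
        self.truth.to_csv(out / "genome_truth.tsv", sep="\t", index=False)


def simulate_genome_hits(config: SimConfig) -> GenomeSim:
    """Plant gene copies across a genome set and emit hits straddling the cutoffs.

    Planted hits draw score >= the family cutoff and E-value < 1e-65; every
    decoy violates at least one criterion (score strictly below the cutoff,
    E-value >= 1e-65, or both), so the admission filter recovers the
    planted truth exactly.
    """
    rng = config.rng(1)
    lineage_rows = []
    hits: list[HmmHit] = []
    truth_rows = []
    protein_counter = 0
    genome_counter = 0
    for species in config.species:
        genus, phylum, kingdom = config.species[species]
        for _ in range(config.n_genomes_per_species):
            genome_counter += 1
            genome = f"GCF_{genome_counter:06d}.1"
            lineage_rows.append(
                {"genome_id": genome, "species": species, "genus": genus, "phylum": phylum, "kingdom": kingdom}
            )
            for family in FAMILIES:
                hosts = None if config.family_hosts is None else config.family_hosts.get(family)
                copies = 0
                if (hosts is None or species in hosts) and rng.random() < config.carriage_prob[family]:
                    copies = 1 + int(rng.choice(4, p=config.copy_number_probs[family]))
                for copy_index in range(1, copies + 1):
                    protein_counter += 1
                    protein = f"WP_{protein_counter:08d}"
                    score = SCORE_CUTOFFS[family] * (1.0 + rng.uniform(0.02, 0.6))
                    evalue = 10.0 ** rng.uniform(-120.0, -66.0)
                    hits.append(HmmHit(family, protein, genome, evalue, round(score, 1)))
                    truth_rows.append(
                        {
                            "genome_id": genome,
                            "family_id": family,
                            "protein": protein,
                            "copy_index": copy_index,
                            "is_decoy": False,
                            "score": round(score, 1),
                            "evalue": evalue,
                        }
                    )
                # decoys straddle the cutoffs: near-misses on score, e-value or both
                for _ in range(rng.poisson(config.decoy_rate)):
                    protein_counter += 1
                    protein = f"WP_{protein_counter:08d}"
                    mode = rng.choice(["score", "evalue", "both"])
                    cutoff = SCORE_CUTOFFS[family]
                    if mode == "score":
                        score, evalue = cutoff * rng.uniform(0.3, 0.999), 10.0 ** rng.uniform(-120.0, -66.0)
                    elif mode == "evalue":
                        score, evalue = cutoff * (1.0 + rng.uniform(0.02, 0.6)), 10.0 ** rng.uniform(-64.9, -20.0)
                    else:
                        score, evalue = cutoff * rng.uniform(0.3, 0.999), 10.0 ** rng.uniform(-64.9, -20.0)
                    score = min(round(score, 1), cutoff - 0.1) if mode != "evalue" else round(score, 1)
                    hits.append(HmmHit(family, protein, genome, evalue, score))
                    truth_rows.append(
                        {
                            "genome_id": genome,
                            "family_id": family,
                            "protein": protein,
                            "copy_index": 0,
                            "is_decoy": True,
                            "score": score,
                            "evalue": evalue,
                        }
                    )
    lineage = pd.DataFrame(lineage_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["genome_id", "family_id", "protein", "copy_index", "is_decoy", "score", "evalue"],
    )
    return GenomeSim(lineage=lineage, hits=hits, truth=truth)


def depletion_folds(
    genomes: GenomeSim, family: str = "BSH", fold: float = 0.2
) -> dict[str, float]:
    """Fold changes planting a depletion of every carrier species of ``family``.

    A "strong depletion" of a gene type depletes the species that carry it;
    non-carrier species are untouched, so per-sample renormalization of the
    relative abundances preserves the planted signal.
    """
    if not 0 < fold:
        raise ValueError("fold must be positive")
    carriers = genomes.planted.merge(genomes.lineage[["genome_id", "species"]], on="genome_id")
    species = sorted(carriers.loc[carriers["family_id"] == family, "species"].unique())
    return {s: fold for s in species}


def truth_average_copy_number(sim: GenomeSim) -> pd.DataFrame:
    """Average copy number per (species, family) from the planted truth."""
    planted = sim.planted.merge(sim.lineage[["genome_id", "species"]], on="genome_id")
    per_genome = (
        planted.groupby(["species", "family_id", "genome_id"]).size().reset_index(name="copies")
    )
    return (
        per_genome.groupby(["species", "family_id"], as_index=False)["copies"]
        .mean()
        .rename(columns={"copies": "average_copy_number"})
    )


# ---------------------------------------------------------------------------
# Case/control abundance study
# ---------------------------------------------------------------------------


def simulate_abundance_study(config: SimConfig, genomes: GenomeSim) -> AbundanceStudy:
    """Generate a case/control cohort consistent with the planted genomes.

    Species abundances are log-normal with per-species location, normalized
    per sample to sum to 1; disease samples multiply each species named in
    ``config.fold_changes`` by its fold change before normalization.
    Gene-type RPKM is the carrier-weighted abundance-copy product scaled by
    ``rpkm_gain`` under multiplicative log-normal noise.
    """
    if config.n_samples_per_group < 3:
        raise ValueError("need >= 3 samples per group")
    rng = config.rng(2)
    species = list(config.species)
    n = config.n_samples_per_group
    mu = config.species_log_mu + config.species_log_sigma * rng.standard_normal(len(species))

    def draw_raw(base: np.ndarray | None = None) -> np.ndarray:
        dev = config.sample_log_sigma * rng.standard_normal(len(species))
        return np.exp(mu + dev) if base is None else base * np.exp(
            0.5 * config.sample_log_sigma * rng.standard_normal(len(species))
        )

    folds = np.array([config.fold_changes.get(s, 1.0) for s in species])
    rows, sample_ids, groups, pairs = [], [], [], []
    for i in range(n):
        if config.paired:
            base = draw_raw()
            control_raw = draw_raw(base)
            disease_raw = draw_raw(base) * folds
        else:
            control_raw = draw_raw()
            disease_raw = draw_raw() * folds
        for label, raw in (("control", control_raw), ("disease", disease_raw)):
            rows.append(raw / raw.sum())
            sample_ids.append(f"{label[0].upper()}{i + 1:03d}")
            groups.append(label)
            pairs.append(f"P{i + 1:03d}")
    abund = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=species)
    groups = pd.Series(groups, index=abund.index, name="group")
    pairs_s = pd.Series(pairs, index=abund.index, name="pair_id") if config.paired else None

    avg_copy = truth_average_copy_number(genomes)
    avg_copy["gene_type"] = [gene_type_of(f) for f in avg_copy["family_id"]]
    rpkm = pd.DataFrame(0.0, index=abund.index, columns=list(GENE_TYPES))
    for gene_type, grp in avg_copy.groupby("gene_type"):
        copy_of = grp.groupby("species")["average_copy_number"].max()
        carriers = [s for s in species if s in copy_of.index]
        if not carriers:
            continue
        signal = (abund[carriers] * copy_of[carriers]).sum(axis=1) * config.rpkm_gain
        noise = np.exp(config.rpkm_log_sigma * rng.standard_normal(len(signal)))
        rpkm[gene_type] = signal * noise

    truth = {
        "fold_changes": dict(config.fold_changes),
        "average_copy_number": avg_copy,
        "species_log_mu": dict(zip(species, mu)),
    }
    return AbundanceStudy(
        species_abundance=AbundanceTable(abund, "species", groups, pairs_s),
        gene_rpkm=AbundanceTable(rpkm, "gene_rpkm", groups.copy(), None if pairs_s is None else pairs_s.copy()),
        design="paired" if config.paired else "unpaired",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Human vs animal correspondence
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceSim:
    human_genes: dict[str, list[str]]
    animal_genes: dict[str, list[str]]
    records: list[BlastRecord]
    truth: pd.DataFrame  # gene_id, family_id, category

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_blast_tab(self.records, out / "human_vs_animal.blast.tsv")
        self.truth.to_csv(out / "correspondence_truth.tsv", sep="\t", index=False)
        for name, genes in (("human", self.human_genes), ("animal", self.animal_genes)):
            pd.DataFrame(
                [(f, g) for f, ids in genes.items() for g in ids],
                columns=["family_id", "gene_id"],
            ).to_csv(out / f"{name}_genes.tsv", sep="\t", index=False)


def _category_counts(fractions: tuple[float, float, float], n: int) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n genes to the three categories."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return tuple(counts)  # type: ignore[return-value]


def simulate_correspondence(config: SimConfig) -> CorrespondenceSim:
    """Plant Same/Similar/Unique fractions per gene type with supporting homology.

    "Same" genes share their identifier across the two lists; "Similar"
    genes get a passing homology record (identity >= 70, E-value < 1e-50);
    "Unique" genes get either no record or one failing a criterion.
    """
    rng = config.rng(3)
    human: dict[str, list[str]] = {}
    animal: dict[str, list[str]] = {}
    records: list[BlastRecord] = []
    truth_rows = []
    for gene_type in GENE_TYPES:
        fractions = config.correspondence_fractions[gene_type]
        n_same, n_similar, n_unique = _category_counts(tuple(fractions), config.n_human_genes)
        h_ids, a_ids = [], []
        for i in range(n_same):
            gid = f"HG_{gene_type}_{i:04d}"
            h_ids.append(gid)
            a_ids.append(gid)  # shared identifier across systems
            truth_rows.append({"gene_id": gid, "family_id": gene_type, "category": "Same"})
        for i in range(n_similar):
            gid = f"HG_{gene_type}_{n_same + i:04d}"
            subject = f"AG_{gene_type}_sim{i:04d}"
            h_ids.append(gid)
            a_ids.append(subject)
            records.append(
                _blast_record(
                    rng, gid, subject,
                    pident=float(rng.uniform(70.0, 100.0)),
                    evalue=10.0 ** float(rng.uniform(-120.0, -50.1)),
                )
            )
            truth_rows.append({"gene_id": gid, "family_id": gene_type, "category": "Similar"})
        for i in range(n_unique):
            gid = f"HG_{gene_type}_{n_same + n_similar + i:04d}"
            h_ids.append(gid)
            truth_rows.append({"gene_id": gid, "family_id": gene_type, "category": "Unique"})
            if i % 2 == 0:
                continue  # no homology evidence at all
            subject = f"AG_{gene_type}_far{i:04d}"
            a_ids.append(subject)
            if i % 4 == 1:  # identity fails
                pident, evalue = float(rng.uniform(30.0, 69.9)), 10.0 ** float(rng.uniform(-120.0, -50.1))
            else:  # e-value fails
                pident, evalue = float(rng.uniform(70.0, 100.0)), 10.0 ** float(rng.uniform(-49.9, -5.0))
            records.append(_blast_record(rng, gid, subject, pident=pident, evalue=evalue))
        # animal-only genes, never consulted by the human-denominator ratios
        for i in range(int(rng.integers(0, 5))):
            a_ids.append(f"AG_{gene_type}_own{i:04d}")
        human[gene_type] = h_ids
        animal[gene_type] = a_ids
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "family_id", "category"])
    return CorrespondenceSim(human_genes=human, animal_genes=animal, records=records, truth=truth)


def _blast_record(rng, query, subject, pident, evalue) -> BlastRecord:
    length = int(rng.integers(300, 1500))
    return BlastRecord(
        query_id=query, subject_id=subject, pident=round(pident, 2), length=length,
        mismatch=int(length * (100 - pident) / 100), gapopen=int(rng.integers(0, 5)),
        qstart=1, qend=length, sstart=1, send=length,
        evalue=evalue, bitscore=round(float(rng.uniform(150.0, 2500.0)), 1),
    )


# ---------------------------------------------------------------------------
# Habitat inventory
# ---------------------------------------------------------------------------


@dataclass
class HabitatSim:
    records: list[BlastRecord]
    habitat_of: dict[str, str]
    habitat_totals: dict[str, int]
    family_of_subject: dict[str, str]
    truth: pd.DataFrame  # habitat, family_id, n_genes

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_blast_tab(self.records, out / "inventory.blast.tsv")
        pd.DataFrame(sorted(self.habitat_of.items()), columns=["gene_id", "habitat"]).to_csv(
            out / "habitats.tsv", sep="\t", index=False
        )
        pd.DataFrame(sorted(self.habitat_totals.items()), columns=["habitat", "total_genes"]).to_csv(
            out / "totals.tsv", sep="\t", index=False
        )
        self.truth.to_csv(out / "habitat_truth.tsv", sep="\t", index=False)


def simulate_habitat_inventory(config: SimConfig) -> HabitatSim:
    """Plant a known number of SBA genes per habitat plus filter-failing decoys."""
    rng = config.rng(4)
    family_of_subject = {f"{fam}.ref{j}": fam for fam in FAMILIES for j in range(3)}
    subjects = sorted(family_of_subject)
    records: list[BlastRecord] = []
    habitat_of: dict[str, str] = {}
    truth_rows = []
    for habitat in config.habitat_totals:
        total = config.habitat_totals[habitat]
        slug = habitat.replace(" ", "_")
        n_sba = int(round(total * config.habitat_sba_rate.get(habitat, 0.0)))
        fam_counts: dict[str, int] = {}
        for i in range(n_sba):
            gene = f"{slug}.gene{i:06d}"
            subject = subjects[int(rng.integers(0, len(subjects)))]
            fam = family_of_subject[subject]
            fam_counts[fam] = fam_counts.get(fam, 0) + 1
            habitat_of[gene] = habitat
            records.append(
                _blast_record(
                    rng, gene, subject,
                    pident=float(rng.uniform(70.0, 100.0)),
                    evalue=10.0 ** float(rng.uniform(-120.0, -50.1)),
                )
            )
        # decoys: inventory genes whose best hit fails a criterion
        for i in range(max(1, n_sba // 2)):
            gene = f"{slug}.decoy{i:06d}"
            subject = subjects[int(rng.integers(0, len(subjects)))]
            habitat_of[gene] = habitat
            if i % 2 == 0:
                pident, evalue = float(rng.uniform(30.0, 69.9)), 10.0 ** float(rng.uniform(-120.0, -50.1))
            else:
                pident, evalue = float(rng.uniform(70.0, 100.0)), 10.0 ** float(rng.uniform(-49.9, -5.0))
            records.append(_blast_record(rng, gene, subject, pident=pident, evalue=evalue))
        for fam, count in sorted(fam_counts.items()):
            truth_rows.append({"habitat": habitat, "family_id": fam, "n_genes": count})
    truth = pd.DataFrame(truth_rows, columns=["habitat", "family_id", "n_genes"])
    return HabitatSim(
        records=records,
        habitat_of=habitat_of,
        habitat_totals=dict(config.habitat_totals),
        family_of_subject=family_of_subject,
        truth=truth,
    )
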