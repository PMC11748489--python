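"""Gene-family vocabulary and the fixed constants of the scoring system.

The catalog models 13 secondary bile acid (SBA) production gene families:
bile salt hydrolase (BSH, deconjugation), the seven bile acid-inducible
operon families (BaiA-BaiH, 7alpha-dehydroxylation) and five position- and
stereo-specific hydroxysteroid dehydrogenases (HSDHs, oxidation and
epimerization).  Downstream scoring pools the Bai subfamilies into a single
"Bai" gene type, giving seven weighted gene types.
"""

from __future__ import annotations

import decimal
from typing import Mapping

#: The 13 modeled gene families (closed set; order is canonical).
FAMILIES: tuple[str, ...] = (
    "BSH",
    "BaiA",
    "BaiB",
    "BaiCD",
    "BaiE",
    "BaiF",
    "BaiG",
    "BaiH",
    "3aHSDH",
    "3bHSDH",
    "7aHSDH",
    "7bHSDH",
    "12aHSDH",
)

BAI_FAMILIES: tuple[str, ...] = ("BaiA", "BaiB", "BaiCD", "BaiE", "BaiF", "BaiG", "BaiH")
HSDH_FAMILIES: tuple[str, ...] = ("3aHSDH", "3bHSDH", "7aHSDH", "7bHSDH", "12aHSDH")

#: Per-family full-sequence bit-score cutoffs used to admit an hmmsearch hit
#: into the catalog.  A hit is kept iff score >= cutoff (non-strict) and
#: e-value < EVALUE_MAX (strict).
SCORE_CUTOFFS: Mapping[str, float] = {
    "BSH": 400.0,
    "BaiA": 390.0,
    "BaiB": 1000.0,
    "BaiCD": 1090.0,
    "BaiE": 360.0,
    "BaiF": 1000.0,
    "BaiG": 950.0,
    "BaiH": 1400.0,
    "3aHSDH": 300.0,
    "3bHSDH": 340.0,
    "7aHSDH": 325.0,
    "7bHSDH": 580.0,
    "12aHSDH": 250.0,
}

#: Global candidate-selection e-value ceiling (strict: evalue < EVALUE_MAX).
EVALUE_MAX: float = 1e-65

#: Homology filter shared by habitat mapping and the Same/Similar/Unique
#: classification: percent identity >= 70 (non-strict) and e-value < 1e-50
#: (strict).
HOMOLOGY_MIN_IDENTITY: float = 70.0
HOMOLOGY_MAX_EVALUE: float = 1e-50

#: The seven scored gene types (Bai subfamilies pooled).
GENE_TYPES: tuple[str, ...] = ("BSH", "Bai", "3aHSDH", "3bHSDH", "7aHSDH", "7bHSDH", "12aHSDH")

#: Pathway-importance weights for the overall human-vs-animal similarity
#: score.  Deconjugation (BSH) is the gateway reaction and carries half the
#: weight; the four downstream modification pathways share the other half,
#: with the 3- and 7-position HSDH pairs splitting their pathway weight.
FAMILY_WEIGHTS: Mapping[str, float] = {
    "BSH": 0.5,
    "Bai": 0.125,
    "3aHSDH": 0.0625,
    "3bHSDH": 0.0625,
    "7aHSDH": 0.0625,
    "7bHSDH": 0.0625,
    "12aHSDH": 0.125,
}
assert sum(FAMILY_WEIGHTS.values()) == 1.0

#: Coarse category used in habitat composition summaries.
CATEGORY_OF_FAMILY: Mapping[str, str] = {
    **{"BSH": "BSH"},
    **{f: "Bai" for f in BAI_FAMILIES},
    **{f: "HSDH" for f in HSDH_FAMILIES},
}


def gene_type_of(family: str) -> str:
    """Map one of the 13 families to its scored gene type (Bai pooled)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown gene family: {family!r}")
    return "Bai" if family in BAI_FAMILIES else family


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), the convention used for
    every printed percentage in this package.

    Centralized so composition, prevalence and habitat summaries agree.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
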