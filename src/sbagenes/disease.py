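"""Case/control profiling of SBA genes and species, and the difference score.

The comparison works on two parallel views of a cohort: species relative
abundances weighted by each species' average per-carrier-genome copy number
(to undo the bias multi-copy genomes introduce into gene-derived
abundances), and gene-type RPKM values where BSH abundance is compared
directly while the remaining six types (Bai pooled, five HSDHs) are
compared as proportions of their pooled total.

Each comparison yields a p-value (two-tailed Mann-Whitney U for unpaired
designs, paired t for paired designs) and a rate of change of the group
means; both map to an ordinal significance level (SL), and the per-cohort
difference score aggregates the SLs:

    score = 0.5 * SL_BSH + 0.5 * sum_j SL_j * Proportion_j

over the six non-BSH gene types j.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, average_copy_number
from .families import BAI_FAMILIES, GENE_TYPES, gene_type_of
from .io import AbundanceStudy

NON_BSH_TYPES: tuple[str, ...] = tuple(t for t in GENE_TYPES if t != "BSH")

#: Largest per-group size for which the Mann-Whitney U p-value is computed
#: by exhaustive enumeration of rank splits; above this a tie-corrected
#: normal approximation is used.
_EXACT_MAX_N = 8


# ---------------------------------------------------------------------------
# Eqs 1-2: copy-number-weighted species abundance
# ---------------------------------------------------------------------------


def weighted_abundance(
    species_abundance: pd.DataFrame,
    avg_copy: pd.DataFrame,
    family: str,
) -> pd.DataFrame:
    """Species relative abundance times average copy number, per sample.

    ``avg_copy`` is the output of :func:`sbagenes.catalog.average_copy_number`
    (columns species, family_id, average_copy_number).  Only species
    carrying ``family`` appear in the result.
    """
    if (species_abundance.to_numpy() < 0).any():
        raise ValueError("negative species abundance")
    fam_copy = avg_copy[avg_copy["family_id"] == family].set_index("species")["average_copy_number"]
    carriers = [s for s in species_abundance.columns if s in fam_copy.index]
    return species_abundance[carriers] * fam_copy[carriers]


# ---------------------------------------------------------------------------
# Gene-type proportions
# ---------------------------------------------------------------------------


def pool_bai(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Collapse Bai subfamily columns into one pooled ``Bai`` column."""
    present_bai = [f for f in BAI_FAMILIES if f in rpkm.columns]
    if not present_bai and "Bai" in rpkm.columns:
        return rpkm
    out = rpkm.drop(columns=present_bai).copy()
    out["Bai"] = rpkm[present_bai].sum(axis=1) if present_bai else 0.0
    return out[[t for t in GENE_TYPES if t in out.columns]]


def gene_type_proportions(rpkm: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, pd.Index]:
    """Per-sample BSH abundance and non-BSH proportions.

    Returns ``(bsh, proportions, flagged)`` where ``bsh`` is the untouched
    BSH RPKM series, ``proportions`` holds each non-BSH type's share of the
    pooled non-BSH total (rows sum to 1 where the total is positive), and
    ``flagged`` indexes samples whose pooled total is zero (their
    proportions are NaN, not 0).
    """
    if (rpkm.to_numpy() < 0).any():
        raise ValueError("negative RPKM")
    pooled = pool_bai(rpkm)
    missing = [t for t in GENE_TYPES if t not in pooled.columns]
    if missing:
        raise KeyError(f"RPKM table missing gene type column(s): {missing}")
    bsh = pooled["BSH"]
    non_bsh = pooled[list(NON_BSH_TYPES)]
    totals = non_bsh.sum(axis=1)
    flagged = totals.index[totals == 0]
    proportions = non_bsh.div(totals.where(totals > 0), axis=0)
    return bsh, proportions, flagged


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p by exhaustive enumeration of rank splits.

    Handles ties exactly (midranks over all C(n1+n2, n1) group assignments).
    Two-sided p is the doubled smaller tail, clipped to 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = np.array(
        [sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2 for idx in itertools.combinations(range(n), n1)]
    )
    eps = 1e-9
    p_low = np.mean(us <= u_obs + eps)
    p_high = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 8 observations (correct
    under ties); otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # every split of a constant pool is equally extreme
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        return _exact_mwu_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed paired t-test p-value with degenerate-difference handling.

    When the paired differences have zero standard deviation the t statistic
    is undefined; a uniformly zero difference gives p = 1 (no evidence of
    change) and a uniformly nonzero difference gives p = 0 (the limit of the
    statistic as the spread vanishes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired design requires complete pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        return 1.0 if np.allclose(d, 0) else 0.0
    return float(stats.ttest_rel(x, y).pvalue)


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    rate_of_change: float  # percent; may be inf when the control mean is 0


def compare_groups(
    disease: Sequence[float],
    control: Sequence[float],
    design: str = "unpaired",
) -> GroupComparison:
    """Compare disease vs control values for one metric.

    ``rate_of_change`` is 100 * |mean(disease) - mean(control)| /
    mean(control); a zero control mean with a nonzero disease mean flags the
    rate as infinite (SL mapping then relies on the p-value alone).
    """
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(disease) < 3 or len(control) < 3:
        raise ValueError("need >= 3 samples per group")
    if design == "unpaired":
        p = mann_whitney_u(disease, control)
    elif design == "paired":
        p = paired_t(disease, control)
    else:
        raise ValueError(f"unknown design: {design!r}")
    md, mc = float(np.mean(disease)), float(np.mean(control))
    if mc == 0:
        rate = 0.0 if md == 0 else math.inf
    else:
        rate = 100.0 * abs(md - mc) / mc
    return GroupComparison(p_value=p, rate_of_change=rate)


# ---------------------------------------------------------------------------
# Eq 3: significance levels and the difference score
# ---------------------------------------------------------------------------


def significance_level(p_value: float, rate_of_change: float) -> float:
    """Ordinal significance level SL in {0, 0.5, 1, 2, 3, 4}.

    p < 1e-4 -> 4; p < 1e-3 -> 3; p < 0.01 -> 2; p < 0.05 -> 1;
    p >= 0.05 with a finite rate of change > 10% -> 0.5; otherwise 0.
    An infinite rate (zero control mean) contributes no SL on its own.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p_value!r}")
    if p_value < 1e-4:
        return 4.0
    if p_value < 1e-3:
        return 3.0
    if p_value < 1e-2:
        return 2.0
    if p_value < 0.05:
        return 1.0
    if math.isfinite(rate_of_change) and rate_of_change > 10.0:
        return 0.5
    return 0.0


@dataclass(frozen=True)
class ComparisonResult:
    """Group comparison of one gene type (metric: BSH abundance, others' proportion)."""

    gene_type: str
    metric: str  # "abundance" | "proportion"
    p_value: float
    rate_of_change: float
    sl: float
    proportion: float  # weight used in the difference score; 0 for BSH

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene type: {self.gene_type!r}")


def difference_score(comparisons: Sequence[ComparisonResult]) -> float:
    """0.5 * SL_BSH + 0.5 * sum over non-BSH types of SL * Proportion."""
    by_type = {c.gene_type: c for c in comparisons}
    if sum(c.gene_type == "BSH" for c in comparisons) != 1:
        raise ValueError("exactly one BSH comparison required")
    missing = [t for t in GENE_TYPES if t not in by_type]
    if missing:
        raise KeyError(f"missing gene type comparison(s): {missing}")
    other = sum(by_type[t].sl * by_type[t].proportion for t in NON_BSH_TYPES)
    return 0.5 * by_type["BSH"].sl + 0.5 * other


# ---------------------------------------------------------------------------
# Orchestration over a cohort
# ---------------------------------------------------------------------------


@dataclass
class DiseaseProfile:
    """Full comparison of one disease cohort against its controls."""

    comparisons: list[ComparisonResult]
    score: float
    major_species: dict[str, str | None]
    species_tests: pd.DataFrame


def profile_study(
    study: AbundanceStudy,
    catalog: Catalog,
    disease_label: str = "disease",
    control_label: str = "control",
    proportion_weighting: str = "pooled",
) -> DiseaseProfile:
    """Run the whole disease comparison for one cohort.

    ``proportion_weighting`` selects which samples' mean proportions weight
    the non-BSH terms of the difference score: "pooled" (both groups,
    default), "control" or "disease".
    """
    groups = study.gene_rpkm.groups
    d_idx = groups.index[groups == disease_label]
    c_idx = groups.index[groups == control_label]
    if study.design == "paired":
        pairs = study.gene_rpkm.pairs
        if pairs is None:
            raise ValueError("paired design requires pairing keys")
        # order both groups by pairing key so positions correspond
        d_idx = d_idx[np.argsort(pairs[d_idx].to_numpy(), kind="stable")]
        c_idx = c_idx[np.argsort(pairs[c_idx].to_numpy(), kind="stable")]
        if list(pairs[d_idx]) != list(pairs[c_idx]):
            raise ValueError("incomplete pairs between groups")

    bsh, proportions, flagged = gene_type_proportions(study.gene_rpkm.values)
    usable = proportions.index.difference(flagged)
    if proportion_weighting == "pooled":
        weight_idx = usable
    elif proportion_weighting in ("disease", "control"):
        weight_idx = usable.intersection(d_idx if proportion_weighting == "disease" else c_idx)
    else:
        raise ValueError(f"unknown proportion weighting: {proportion_weighting!r}")
    mean_props = proportions.loc[weight_idx].mean()

    comparisons = []
    cmp_bsh = compare_groups(bsh[d_idx], bsh[c_idx], study.design)
    comparisons.append(
        ComparisonResult(
            gene_type="BSH",
            metric="abundance",
            p_value=cmp_bsh.p_value,
            rate_of_change=cmp_bsh.rate_of_change,
            sl=significance_level(cmp_bsh.p_value, cmp_bsh.rate_of_change),
            proportion=0.0,
        )
    )
    for t in NON_BSH_TYPES:
        vals = proportions[t]
        du, cu = d_idx.intersection(usable), c_idx.intersection(usable)
        if study.design == "paired":
            # keep only complete usable pairs
            pairs = study.gene_rpkm.pairs
            common = set(pairs[du]) & set(pairs[cu])
            du = d_idx[[pairs[i] in common for i in d_idx]]
            cu = c_idx[[pairs[i] in common for i in c_idx]]
        cmp_t = compare_groups(vals[du], vals[cu], study.design)
        comparisons.append(
            ComparisonResult(
                gene_type=t,
                metric="proportion",
                p_value=cmp_t.p_value,
                rate_of_change=cmp_t.rate_of_change,
                sl=significance_level(cmp_t.p_value, cmp_t.rate_of_change),
                proportion=float(mean_props[t]),
            )
        )

    score = difference_score(comparisons)
    species_tests = _species_comparisons(study, catalog, d_idx, c_idx)
    directions = _gene_type_directions(study, bsh, proportions, d_idx, c_idx)
    major = {
        t: major_differential_species(
            species_tests[species_tests["gene_type"] == t], directions[t]
        )
        for t in GENE_TYPES
    }
    return DiseaseProfile(
        comparisons=comparisons, score=score, major_species=major, species_tests=species_tests
    )


def _gene_type_directions(study, bsh, proportions, d_idx, c_idx) -> dict[str, int]:
    out = {"BSH": int(np.sign(bsh[d_idx].mean() - bsh[c_idx].mean()))}
    for t in NON_BSH_TYPES:
        out[t] = int(np.sign(proportions[t][d_idx].mean(skipna=True) - proportions[t][c_idx].mean(skipna=True)))
    return out


def _species_comparisons(study, catalog, d_idx, c_idx) -> pd.DataFrame:
    """Per (gene type, carrier species) weighted-abundance comparison."""
    avg_copy = average_copy_number(catalog)
    avg_copy = avg_copy.assign(gene_type=[gene_type_of(f) for f in avg_copy["family_id"]])
    rows = []
    abund = study.species_abundance.values
    for t in GENE_TYPES:
        sub = avg_copy[avg_copy["gene_type"] == t]
        # a species carrying several subfamilies of a pooled type is compared once,
        # weighted by its highest average copy number for that type
        copy_of = sub.groupby("species")["average_copy_number"].max()
        for species, cn in copy_of.items():
            if species not in abund.columns:
                continue
            w = abund[species] * cn
            cmp_s = compare_groups(w[d_idx], w[c_idx], study.design)
            rows.append(
                {
                    "gene_type": t,
                    "species": species,
                    "p_value": cmp_s.p_value,
                    "direction": int(np.sign(w[d_idx].mean() - w[c_idx].mean())),
                    "mean_weighted_abundance": float(w.mean()),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_type", "species", "p_value", "direction", "mean_weighted_abundance"]
    )


def major_differential_species(species_tests: pd.DataFrame, direction: int) -> str | None:
    """The carrier species with the highest mean weighted abundance among
    significantly changed species whose direction matches the gene type's.

    Returns None when no carrier species is both significant (p < 0.05) and
    concordant; ties break lexicographically by species name.
    """
    if direction == 0:
        return None
    cand = species_tests[
        (species_tests["p_value"] < 0.05) & (species_tests["direction"] == direction)
    ]
    if cand.empty:
        return None
    cand = cand.sort_values(
        ["mean_weighted_abundance", "species"], ascending=[False, True], kind="stable"
    )
    return str(cand.iloc[0]["species"])
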