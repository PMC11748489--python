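"""Group tests, SL mapping, difference score and major-species selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sbagenes.disease import (
    ComparisonResult,
    NON_BSH_TYPES,
    compare_groups,
    difference_score,
    gene_type_proportions,
    major_differential_species,
    mann_whitney_u,
    paired_t,
    significance_level,
    weighted_abundance,
)
from sbagenes.families import GENE_TYPES


class TestWeightedAbundance:
    def test_elementwise_product(self):
        abund = pd.DataFrame({"sp1": [0.01, 0.02], "sp2": [0.1, 0.2]}, index=["s1", "s2"])
        avg = pd.DataFrame(
            {"species": ["sp1", "sp2"], "family_id": ["BSH", "BSH"], "average_copy_number": [3.0, 1.0]}
        )
        out = weighted_abundance(abund, avg, "BSH")
        assert out.loc["s1", "sp1"] == pytest.approx(0.03)  # 0.01 * 3
        # copy number 1 leaves the abundance unchanged
        assert out["sp2"].tolist() == abund["sp2"].tolist()

    def test_non_carriers_absent(self):
        abund = pd.DataFrame({"sp1": [0.01], "sp2": [0.1]}, index=["s1"])
        avg = pd.DataFrame(
            {"species": ["sp1"], "family_id": ["BSH"], "average_copy_number": [2.0]}
        )
        out = weighted_abundance(abund, avg, "BSH")
        assert list(out.columns) == ["sp1"]

    def test_negative_abundance_rejected(self):
        abund = pd.DataFrame({"sp1": [-0.01]}, index=["s1"])
        avg = pd.DataFrame({"species": ["sp1"], "family_id": ["BSH"], "average_copy_number": [2.0]})
        with pytest.raises(ValueError, match="negative"):
            weighted_abundance(abund, avg, "BSH")


class TestGeneTypeProportions:
    def test_two_active_types_split_evenly(self):
        rpkm = pd.DataFrame(
            {"BSH": [5.0], "BaiA": [2.0], "3aHSDH": [0.0], "3bHSDH": [0.0],
             "7aHSDH": [2.0], "7bHSDH": [0.0], "12aHSDH": [0.0]},
            index=["s1"],
        )
        bsh, props, flagged = gene_type_proportions(rpkm)
        assert bsh.item() == 5.0  # BSH passes through untouched
        assert props.loc["s1", "Bai"] == 0.5 and props.loc["s1", "7aHSDH"] == 0.5
        assert flagged.empty

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        rpkm = pd.DataFrame(
            rng.uniform(0.1, 5.0, size=(6, len(GENE_TYPES))), columns=list(GENE_TYPES)
        )
        _, props, flagged = gene_type_proportions(rpkm)
        assert flagged.empty
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_all_zero_sample_flagged_not_zeroed(self):
        rpkm = pd.DataFrame(
            {t: [0.0, 1.0] for t in GENE_TYPES}, index=["dead", "alive"]
        )
        _, props, flagged = gene_type_proportions(rpkm)
        assert list(flagged) == ["dead"]
        assert props.loc["dead"].isna().all()


class TestCompareGroups:
    def test_identical_groups_p_one_rate_zero(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.p_value == 1.0
        assert out.rate_of_change == 0.0

    def test_disjoint_small_groups_exact_p(self):
        # complete separation at n=3: doubled tail 2/C(6,3) = 0.1
        out = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert out.p_value == pytest.approx(0.1)

    def test_exact_matches_scipy_on_tiefree_data(self):
        # dual route: own enumeration vs scipy's exact recursion, n1,n2 <= 5
        rng = np.random.default_rng(42)
        for n1, n2 in itertools.product(range(3, 6), range(3, 6)):
            for _ in range(5):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
                assert mann_whitney_u(x, y) == pytest.approx(expected, abs=1e-12)

    def test_paired_t_matches_closed_form(self):
        x = np.array([3.1, 2.9, 3.4, 3.0, 3.3])
        y = np.array([2.5, 2.6, 2.8, 2.4, 2.9])
        d = x - y
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert paired_t(x, y) == pytest.approx(expected, rel=1e-12)

    def test_paired_constant_shift_degenerate_sd(self):
        # all deltas exactly +1: sd 0, the vanishing-spread limit is p -> 0
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert paired_t([b + 1 for b in base], base) == 0.0
        assert paired_t(base, base) == 1.0

    def test_zero_control_mean_flags_infinite_rate(self):
        out = compare_groups([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert math.isinf(out.rate_of_change)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSignificanceLevel:
    @pytest.mark.parametrize(
        "p,rate,expected",
        [
            (5e-5, 0.0, 4.0),
            (5e-4, 0.0, 3.0),
            (5e-3, 0.0, 2.0),
            (0.03, 5.0, 1.0),  # p < 0.05 wins regardless of rate
            (0.2, 12.0, 0.5),  # not significant but >10% shift
            (0.2, 3.0, 0.0),  # residual case
            (0.05, 3.0, 0.0),  # p = 0.05 is not significant
        ],
    )
    def test_mapping(self, p, rate, expected):
        assert significance_level(p, rate) == expected

    def test_infinite_rate_uses_p_only(self):
        assert significance_level(0.2, math.inf) == 0.0
        assert significance_level(0.03, math.inf) == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p1=st.floats(min_value=0.0, max_value=1.0),
        p2=st.floats(min_value=0.0, max_value=1.0),
        rate=st.floats(min_value=0.0, max_value=200.0),
    )
    def test_step_function_monotone_in_p(self, p1, p2, rate):
        lo, hi = sorted([p1, p2])
        assert significance_level(lo, rate) >= significance_level(hi, rate)


def comparison(gene_type, sl, proportion=0.0):
    return ComparisonResult(
        gene_type=gene_type,
        metric="abundance" if gene_type == "BSH" else "proportion",
        p_value=0.5,
        rate_of_change=0.0,
        sl=sl,
        proportion=proportion,
    )


def full_set(sl_bsh=0.0, sls=None, props=None):
    sls = sls or {}
    props = props or {}
    out = [comparison("BSH", sl_bsh)]
    for t in NON_BSH_TYPES:
        out.append(comparison(t, sls.get(t, 0.0), props.get(t, 0.0)))
    return out


class TestDifferenceScore:
    def test_formula_evaluation(self):
        comps = full_set(sl_bsh=1.0, sls={"Bai": 2.0}, props={"Bai": 1.0})
        assert difference_score(comps) == pytest.approx(1.5)  # 0.5*1 + 0.5*2*1

    def test_all_null_is_zero(self):
        assert difference_score(full_set()) == 0.0

    def test_maximum_reached_with_full_proportions(self):
        props = {"Bai": 0.5, "3aHSDH": 0.1, "3bHSDH": 0.1, "7aHSDH": 0.1, "7bHSDH": 0.1, "12aHSDH": 0.1}
        comps = full_set(sl_bsh=4.0, sls={t: 4.0 for t in NON_BSH_TYPES}, props=props)
        assert difference_score(comps) == pytest.approx(4.0)

    def test_missing_gene_type_named(self):
        comps = [c for c in full_set() if c.gene_type != "Bai"]
        with pytest.raises(KeyError, match="Bai"):
            difference_score(comps)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        sls=st.lists(st.sampled_from([0.0, 0.5, 1.0, 2.0, 3.0, 4.0]), min_size=7, max_size=7),
        bump=st.sampled_from([0.5, 1.0, 2.0]),
        which=st.integers(min_value=0, max_value=6),
    )
    def test_monotone_in_every_sl(self, sls, bump, which):
        props = {t: 1.0 / 6 for t in NON_BSH_TYPES}
        types = ("BSH",) + NON_BSH_TYPES
        base_sls = dict(zip(types, sls))
        raised = dict(base_sls)
        raised[types[which]] = min(4.0, raised[types[which]] + bump)
        score = difference_score(full_set(base_sls["BSH"], base_sls, props))
        score_up = difference_score(full_set(raised["BSH"], raised, props))
        assert score_up >= score
        assert 0.0 <= score <= 4.0


class TestMajorSpecies:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_type", "species", "p_value", "direction", "mean_weighted_abundance"]
        )

    def test_argmax_among_concordant_significant(self):
        frame = self._frame(
            [
                ("BSH", "sp low", 0.01, -1, 0.02),
                ("BSH", "sp high", 0.02, -1, 0.05),
                ("BSH", "sp discordant", 0.001, 1, 0.50),
                ("BSH", "sp ns", 0.50, -1, 0.90),
            ]
        )
        assert major_differential_species(frame, -1) == "sp high"

    def test_only_discordant_gives_null(self):
        frame = self._frame([("BSH", "sp1", 0.01, 1, 0.10)])
        assert major_differential_species(frame, -1) is None

    def test_tie_breaks_lexicographically(self):
        frame = self._frame(
            [("BSH", "b sp", 0.01, -1, 0.10), ("BSH", "a sp", 0.02, -1, 0.10)]
        )
        assert major_differential_species(frame, -1) == "a sp"
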