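"""Reporting arithmetic: prevalence, multi-morbidity distributions,
percent change and the mental ill-health overlap."""

import numpy as np
import pandas as pd
import pytest

from morbisim import (DISEASES_AND_IMPAIRMENTS, DISEASES_ONLY,
                      mental_illhealth_overlap, multimorbidity_table,
                      percent_change, prevalence_table)
from morbisim.errors import InputError
from morbisim.state import DISEASES
from morbisim.tables import MM_CATEGORIES, round1, round_count

from conftest import make_cohort


def random_snapshot(n=400, seed=0):
    rng = np.random.default_rng(seed)
    snap = make_cohort(n, age_years=65)
    snap["age_months"] = rng.integers(65, 100, n) * 12
    for cond in DISEASES + ("hearing", "vision"):
        snap[cond] = rng.integers(0, 2, n)
    snap["mmse"] = rng.integers(0, 31, n)
    return snap


class TestPercentChange:
    def test_zero_change(self):
        assert percent_change(100, 100) == 0.0

    def test_rounding_half_away_from_zero(self):
        assert percent_change(1000, 1245) == 24.5
        assert percent_change(1000, 755) == -24.5
        assert round1(0.05) == 0.1
        assert round1(-0.05) == -0.1
        assert round_count(149) == 100
        assert round_count(150) == 200

    def test_undefined_for_zero_start(self):
        with pytest.raises(InputError):
            percent_change(0, 10)

    def test_antisymmetry_identity(self):
        """percent_change(a,b) = -percent_change(b,a) * a/b to rounding."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.integers(100, 10_000_000, 2)
            lhs = percent_change(a, b)
            rhs = -percent_change(b, a) * b / a
            # each side carries at most 0.05 rounding, scaled by b/a
            assert abs(lhs - rhs) <= 0.05 + 0.05 * b / a + 1e-9


class TestPrevalenceTable:
    def test_direct_arithmetic(self):
        snap = make_cohort(10, age_years=70)
        snap.loc[:2, "stroke"] = 1  # 3 of 10
        tab = prevalence_table({2015: snap}, ["stroke"], scale_factor=100)
        row = tab[(tab.age_group == "65+") & (tab.condition == "stroke")]
        assert row["prevalence_pct"].iloc[0] == 30.0
        assert row["count"].iloc[0] == 300
        assert row["stratum_count"].iloc[0] == 1000

    def test_absent_condition_zero(self):
        snap = make_cohort(50, age_years=70)
        tab = prevalence_table({2015: snap}, ["cancer"])
        assert (tab[tab.age_group == "65+"]["prevalence_pct"] == 0.0).all()

    def test_empty_stratum_warns_not_divides(self):
        snap = make_cohort(20, age_years=70)  # nobody 85+
        with pytest.warns(UserWarning, match="empty stratum"):
            tab = prevalence_table({2015: snap}, ["stroke"])
        row = tab[tab.age_group == "85+"]
        assert row["prevalence_pct"].isna().all()

    def test_matches_groupby_recount(self):
        snap = random_snapshot(seed=3)
        tab = prevalence_table({2015: snap}, ["arthritis", "cind"])
        ages = snap["age_months"] // 12
        for label, (lo, hi) in (("65-74", (65, 75)), ("85+", (85, 200))):
            sub = snap[(ages >= lo) & (ages < hi)]
            for cond in ("arthritis", "cind"):
                if cond == "cind":
                    present = ((sub["mmse"] <= 20)
                               & (sub["dementia"] == 0)).sum()
                else:
                    present = sub[cond].sum()
                row = tab[(tab.age_group == label) & (tab.condition == cond)]
                assert row["prevalence_pct"].iloc[0] == round1(
                    100 * present / len(sub))


class TestMultimorbidityTable:
    def test_everyone_one_disease(self):
        snap = make_cohort(30, age_years=70)
        snap["stroke"] = 1
        tab = multimorbidity_table({2015: snap}, DISEASES_ONLY)
        sel = tab[tab.age_group == "65+"].set_index("category")
        assert sel.loc["1", "prevalence_pct"] == 100.0
        assert sel.loc["2+", "prevalence_pct"] == 0.0

    def test_complement_identity(self):
        snap = random_snapshot(seed=4)
        tab = multimorbidity_table({2015: snap}, DISEASES_ONLY)
        for label in ("65-74", "75-84", "85+", "65+"):
            sel = tab[tab.age_group == label].set_index("category")
            two_plus = sel.loc["2+", "prevalence_pct"]
            complement = 100 - (sel.loc["0", "prevalence_pct"]
                                + sel.loc["1", "prevalence_pct"])
            assert abs(two_plus - complement) < 0.2  # rounding only

    def test_category_percentages_sum_to_100(self):
        snap = random_snapshot(seed=5)
        tab = multimorbidity_table({2015: snap}, DISEASES_AND_IMPAIRMENTS)
        for label in ("65-74", "65+"):
            sel = tab[(tab.age_group == label)
                      & (tab.category.isin(MM_CATEGORIES))]
            assert abs(sel["prevalence_pct"].sum() - 100.0) <= 0.1

    def test_scaled_counts_conserve_total(self):
        snap = random_snapshot(seed=6)
        tab = multimorbidity_table({2015: snap}, DISEASES_ONLY,
                                   scale_factor=100)
        for label in ("65-74", "75-84", "85+", "65+"):
            sel = tab[(tab.age_group == label)
                      & (tab.category.isin(MM_CATEGORIES))]
            # counts are rounded to the nearest 100 per cell
            total = sel["stratum_count"].iloc[0]
            assert abs(sel["count"].sum() - total) <= 100 * len(sel) / 2

    def test_matches_brute_force_recount(self):
        snap = random_snapshot(seed=7)
        tab = multimorbidity_table({2015: snap}, DISEASES_ONLY)
        ages = snap["age_months"] // 12
        sub = snap[(ages >= 75) & (ages < 85)]
        counts = np.zeros(len(sub), dtype=int)
        for d in DISEASES:
            counts += sub[d].to_numpy()
        sel = tab[tab.age_group == "75-84"].set_index("category")
        for i, cat in enumerate(MM_CATEGORIES):
            expected = (np.minimum(counts, 4) == i).mean() * 100
            assert sel.loc[cat, "prevalence_pct"] == round1(expected)


class TestMentalIllHealthOverlap:
    def test_no_mental_conditions_gives_zero(self):
        snap = make_cohort(100, age_years=70)
        snap["arthritis"] = 1
        snap["cancer"] = np.arange(100) % 2
        tab = mental_illhealth_overlap(snap, DISEASES_AND_IMPAIRMENTS)
        sel = tab[tab.n > 0]
        assert (sel["mental_pct"] == 0.0).all()

    def test_all_four_plus_have_depression(self):
        snap = make_cohort(60, age_years=70)
        for c in ("arthritis", "cancer", "chd", "depression", "stroke"):
            snap[c] = 1
        tab = mental_illhealth_overlap(snap, DISEASES_ONLY)
        assert tab.set_index("category").loc["4+", "mental_pct"] == 100.0

    def test_matches_cross_tabulation(self):
        snap = random_snapshot(seed=8)
        tab = mental_illhealth_overlap(snap, DISEASES_AND_IMPAIRMENTS)
        counts = np.zeros(len(snap), dtype=int)
        for m in DISEASES_AND_IMPAIRMENTS.members:
            if m == "cind":
                counts += ((snap["mmse"] <= 20)
                           & (snap["dementia"] == 0)).to_numpy()
            else:
                counts += snap[m].to_numpy()
        mental = (snap["dementia"].astype(bool)
                  | snap["depression"].astype(bool)
                  | ((snap["mmse"] <= 20) & (snap["dementia"] == 0)))
        capped = np.minimum(counts, 4)
        for i, cat in enumerate(MM_CATEGORIES):
            in_cat = capped == i
            if in_cat.sum() == 0:
                continue
            expected = round1(100 * mental[in_cat].mean())
            assert tab.set_index("category").loc[cat, "mental_pct"] \
                == expected

    def test_exclude_mental_from_count_toggle(self):
        snap = make_cohort(10, age_years=70)
        snap["depression"] = 1
        snap["arthritis"] = 1
        incl = mental_illhealth_overlap(snap, DISEASES_ONLY,
                                        include_mental_in_count=True)
        excl = mental_illhealth_overlap(snap, DISEASES_ONLY,
                                        include_mental_in_count=False)
        # with depression counted everyone has 2 conditions; without, 1
        assert incl.set_index("category").loc["2", "n"] == 10
        assert excl.set_index("category").loc["1", "n"] == 10
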