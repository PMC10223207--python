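"""Composition module: quantification, similarity, variability, breadth."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from venomics import datasets
from venomics.composition import (
    AbundanceTable,
    Fraction,
    ProteinSet,
    QuantInput,
    aggregate_families,
    band_relative_abundance,
    cv_profile,
    dominant_sum,
    family_summary,
    filter_signal_traits,
    fold_ratio,
    levins_breadth,
    psc,
    psc_matrix,
    round_half_away,
    upper_triangle_mean,
)
from venomics.errors import InvalidInputError, ValidationError


# ---------------------------------------------------------------------------
# band quantification
# ---------------------------------------------------------------------------


class TestBandRelativeAbundance:
    def test_single_whole_fraction_is_everything(self):
        q = QuantInput((Fraction("f1", 5.0, (), ("SVMP",)),))
        out = band_relative_abundance(q)
        assert [(b.fraction_id, b.band_index, b.family, b.percent) for b in out] == [
            ("f1", 0, "SVMP", 100.0)
        ]

    def test_two_fractions_with_band_split(self):
        q = QuantInput(
            (
                Fraction("f1", 3.0, (), ("SVMP",)),
                Fraction("f2", 1.0, (1.0, 1.0), ("PLA2", "SVSP")),
            )
        )
        assert [b.percent for b in band_relative_abundance(q)] == [75.0, 12.5, 12.5]

    def test_four_fraction_spreadsheet_example(self):
        # areas 10/20/30/40; third split by densities 2:3:5 -> 6, 9, 15
        q = QuantInput(
            (
                Fraction("f1", 10.0, (), ("A",)),
                Fraction("f2", 20.0, (), ("B",)),
                Fraction("f3", 30.0, (2.0, 3.0, 5.0), ("A", "B", "C")),
                Fraction("f4", 40.0, (), ("C",)),
            )
        )
        by_fraction = {
            (b.fraction_id, b.band_index): b.percent for b in band_relative_abundance(q)
        }
        assert by_fraction[("f3", 0)] == pytest.approx(6.0)
        assert by_fraction[("f3", 1)] == pytest.approx(9.0)
        assert by_fraction[("f3", 2)] == pytest.approx(15.0)

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fractions = []
            for i in range(int(rng.integers(1, 8))):
                if rng.random() < 0.4:
                    fractions.append(
                        Fraction(f"f{i}", float(rng.uniform(0.1, 9)), (), ("X",))
                    )
                else:
                    k = int(rng.integers(1, 5))
                    fractions.append(
                        Fraction(
                            f"f{i}",
                            float(rng.uniform(0.1, 9)),
                            tuple(rng.uniform(0.1, 2, k)),
                            tuple("ABCD"[: k]),
                        )
                    )
            total = sum(b.percent for b in band_relative_abundance(QuantInput(tuple(fractions))))
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_areas_rejected(self):
        with pytest.raises(InvalidInputError):
            QuantInput((Fraction("f1", 0.0, (), ("A",)),))

    def test_zero_lane_densities_names_fraction(self):
        q = QuantInput(
            (
                Fraction("f1", 1.0, (), ("A",)),
                Fraction("f2", 1.0, (0.0, 0.0), ("A", "B")),
            )
        )
        with pytest.raises(InvalidInputError, match="f2"):
            band_relative_abundance(q)

    def test_mismatched_bands_rejected(self):
        with pytest.raises(ValidationError):
            Fraction("f1", 1.0, (1.0, 2.0), ("A",))


class TestAggregateFamilies:
    def test_same_family_accumulates(self):
        q = QuantInput(
            (
                Fraction("f1", 60.0, (), ("SVMP",)),
                Fraction("f2", 40.0, (), ("SVMP",)),
            )
        )
        assert aggregate_families(band_relative_abundance(q)) == {"SVMP": 100.0}

    def test_additivity_across_families(self):
        q = QuantInput(
            (
                Fraction("f1", 30.0, (), ("SVMP",)),
                Fraction("f2", 20.0, (), ("SVMP",)),
                Fraction("f3", 50.0, (), ("PLA2",)),
            )
        )
        agg = aggregate_families(band_relative_abundance(q))
        assert agg == pytest.approx({"SVMP": 50.0, "PLA2": 50.0})

    def test_matches_hand_grouping_of_banded_input(self):
        q = QuantInput(
            (
                Fraction("f1", 10.0, (), ("A",)),
                Fraction("f2", 20.0, (), ("B",)),
                Fraction("f3", 30.0, (2.0, 3.0, 5.0), ("A", "B", "C")),
                Fraction("f4", 40.0, (), ("C",)),
            )
        )
        agg = aggregate_families(band_relative_abundance(q))
        assert agg == pytest.approx({"A": 16.0, "B": 29.0, "C": 55.0})
        assert sum(agg.values()) == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# table statistics on the packaged habu data
# ---------------------------------------------------------------------------


class TestFamilySummary:
    @pytest.mark.parametrize(
        "family, mean, sd",
        [("SVMP", 32.56, 13.94), ("PLA2", 22.93, 9.26), ("SVSP", 16.27, 4.79)],
    )
    def test_dominant_family_means(self, habu_table, family, mean, sd):
        s = family_summary(habu_table, datasets.CURRENT_STUDY_ADULTS, family)
        assert round_half_away(s.mean, 2) == mean
        assert round_half_away(s.sd, 2) == sd
        assert s.n == 5

    def test_constant_column(self):
        t = AbundanceTable(
            pd.DataFrame({"F": [5.0, 5.0, 5.0]}, index=["a", "b", "c"])
        )
        s = family_summary(t, ["a", "b", "c"], "F")
        assert (s.mean, s.sd) == (5.0, 0.0)

    def test_unknown_labels_raise_key_error(self, habu_table):
        with pytest.raises(KeyError):
            family_summary(habu_table, ["nope"], "SVMP")
        with pytest.raises(KeyError):
            family_summary(habu_table, datasets.CURRENT_STUDY_ADULTS, "nope")


class TestDominantSum:
    @pytest.mark.parametrize(
        "taxon, expected",
        [("P. mucrosquamatus", 79.88), ("P. flavoviridis", 87.92)],
    )
    def test_dominant_triple(self, habu_table, taxon, expected):
        assert dominant_sum(habu_table, taxon, ["SVMP", "SVSP", "PLA2"]) == pytest.approx(
            expected
        )

    def test_empty_family_set(self, habu_table):
        assert dominant_sum(habu_table, "P. cornutus", []) == 0.0


class TestFoldRatio:
    @pytest.mark.parametrize(
        "num, den, expected", [(29.93, 1.44, 20.8), (58.0, 1.23, 47.2), (3.3, 3.3, 1.0)]
    )
    def test_reported_ratios(self, num, den, expected):
        assert fold_ratio(num, den, 1) == expected

    def test_zero_denominator(self):
        with pytest.raises(InvalidInputError):
            fold_ratio(1.0, 0.0)

    def test_round_half_away_from_zero(self):
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(-0.25, 1) == -0.3


class TestCVProfile:
    def test_habu_range_and_group_means(self, habu_table):
        prof = cv_profile(
            habu_table,
            datasets.ADULT_TAXA,
            families=datasets.PROTEIN_FAMILIES,
            groups={
                "abundant": datasets.ABUNDANT_FAMILIES,
                "trace": datasets.TRACE_FAMILIES,
            },
        )
        assert round_half_away(prof.cv_min, 1) == 32.5
        assert min(prof.cv, key=prof.cv.get) == "SVMP"
        assert round_half_away(prof.cv_max, 1) == 233.0
        assert max(prof.cv, key=prof.cv.get) == "QC"
        assert round_half_away(prof.group_means["abundant"], 1) == 47.8
        assert round_half_away(prof.group_means["trace"], 1) == 206.6

    def test_identical_rows_give_zero_cv(self):
        t = AbundanceTable(
            pd.DataFrame({"A": [10.0, 10.0], "B": [20.0, 20.0]}, index=["x", "y"])
        )
        prof = cv_profile(t, ["x", "y"])
        assert prof.cv == {"A": 0.0, "B": 0.0}

    def test_single_taxon_rejected(self, habu_table):
        with pytest.raises(InvalidInputError):
            cv_profile(habu_table, ["P. cornutus"])

    def test_all_zero_family_reported_undefined(self):
        t = AbundanceTable(
            pd.DataFrame({"A": [10.0, 20.0], "Z": [0.0, 0.0]}, index=["x", "y"])
        )
        prof = cv_profile(t, ["x", "y"])
        assert "Z" in prof.undefined and "Z" not in prof.cv

    def test_scale_invariance(self, habu_table):
        scaled = AbundanceTable(habu_table.data[["SVMP"]] * 0.5)
        a = cv_profile(habu_table, datasets.ADULT_TAXA, families=["SVMP"])
        b = cv_profile(scaled, datasets.ADULT_TAXA, families=["SVMP"])
        assert a.cv["SVMP"] == pytest.approx(b.cv["SVMP"], rel=1e-12)


# ---------------------------------------------------------------------------
# protein similarity coefficient
# ---------------------------------------------------------------------------


class TestPSC:
    def test_identical_and_disjoint(self):
        a = ProteinSet.from_iterable("a", ["x", "y", "z"])
        assert psc(a, a) == 100.0
        b = ProteinSet.from_iterable("b", ["u", "v"])
        assert psc(a, b) == 0.0

    def test_worked_example(self):
        a = ProteinSet.from_iterable("a", ["x", "y", "z"])
        b = ProteinSet.from_iterable("b", ["x", "y", "w", "v"])
        assert psc(a, b) == pytest.approx(2 * 2 / 7 * 100)

    def test_empty_set_rejected(self):
        a = ProteinSet.from_iterable("a", ["x"])
        with pytest.raises(InvalidInputError):
            psc(a, ProteinSet("b", frozenset()))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    def test_agrees_with_brute_force_and_is_symmetric(self, a, b):
        pa = ProteinSet.from_iterable("a", map(str, a))
        pb = ProteinSet.from_iterable("b", map(str, b))
        shared = sum(1 for p in a if p in b)  # brute-force count
        expected = 200.0 * shared / (len(a) + len(b))
        assert psc(pa, pb) == pytest.approx(expected)
        assert psc(pb, pa) == psc(pa, pb)
        assert 0.0 <= psc(pa, pb) <= 100.0
        assert (psc(pa, pb) == 100.0) == (a == b)
        assert (psc(pa, pb) == 0.0) == (not a & b)

    def test_identity_key_injection(self):
        a = ProteinSet.from_iterable("a", ["SVMP_1a"])
        b = ProteinSet.from_iterable("b", ["SVMP_1b"])
        assert psc(a, b) == 0.0
        assert psc(a, b, key=lambda p: p[:-1]) == 100.0


class TestPSCMatrix:
    def test_habu_mean(self):
        assert round_half_away(upper_triangle_mean(datasets.habu_psc_matrix()), 1) == 17.7

    def test_two_identical_sets(self):
        sets = [
            ProteinSet.from_iterable("a", ["x", "y"]),
            ProteinSet.from_iterable("b", ["x", "y"]),
        ]
        m = psc_matrix(sets)
        assert m.matrix.loc["a", "b"] == 100.0
        assert math.isnan(m.matrix.loc["a", "a"])
        assert m.mean == 100.0

    def test_mean_of_three_pairwise_values(self):
        sets = [
            ProteinSet.from_iterable("a", ["x"]),
            ProteinSet.from_iterable("b", ["y"]),
            ProteinSet.from_iterable("c", ["y"]),
        ]
        # pairwise PSC: ab=0, ac=0, bc=100 -> mean 33.33
        assert psc_matrix(sets).mean == pytest.approx(100 / 3)

    def test_duplicate_taxa_rejected(self):
        s = ProteinSet.from_iterable("a", ["x"])
        with pytest.raises(InvalidInputError):
            psc_matrix([s, s])


# ---------------------------------------------------------------------------
# venom breadth
# ---------------------------------------------------------------------------


class TestLevinsBreadth:
    def test_uniform_profile_is_maximally_even(self):
        r = levins_breadth({"a": 25.0, "b": 25.0, "c": 25.0, "d": 25.0})
        assert r.breadth_std == pytest.approx(1.0)

    def test_single_family_is_minimally_even(self):
        r = levins_breadth({"a": 100.0, "b": 0.0, "c": 0.0})
        assert r.breadth_std == pytest.approx(0.0)

    def test_worked_example(self):
        r = levins_breadth({"a": 0.5, "b": 0.3, "c": 0.2})
        assert r.breadth_raw == pytest.approx(1 / 0.38)
        assert r.breadth_std == pytest.approx((1 / 0.38 - 1) / 2)

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=10),
        scale=st.floats(0.01, 50.0),
    )
    def test_rescaling_invariance_and_bounds(self, values, scale):
        prof = {f"f{i}": v for i, v in enumerate(values)}
        scaled = {k: v * scale for k, v in prof.items()}
        r1, r2 = levins_breadth(prof), levins_breadth(scaled)
        assert r1.breadth_std == pytest.approx(r2.breadth_std, rel=1e-9)
        assert 0.0 <= r1.breadth_std <= 1.0 + 1e-12
        assert r1.breadth_std == pytest.approx(
            (r1.breadth_raw - 1) / (r1.n_categories - 1)
        )

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            levins_breadth({"a": 0.0, "b": 0.0})


# ---------------------------------------------------------------------------
# trait filter
# ---------------------------------------------------------------------------


class TestFilterSignalTraits:
    def test_habu_eight_families(self, habu_table):
        kept = filter_signal_traits(habu_table, taxa=datasets.SIGNAL_TAXA)
        assert kept == [
            "SVMP", "SVSP", "PLA2", "CRISP", "Disintegrin", "BPP/CNP", "CTL", "LAAO",
        ]

    def test_zero_thresholds_keep_everything(self, habu_table):
        kept = filter_signal_traits(habu_table, min_abundance=0.0, min_taxa=0)
        assert kept == habu_table.families

    def test_boundary_is_strict(self):
        t = AbundanceTable(
            pd.DataFrame({"F": [1.0, 1.0, 1.0, 1.0, 1.0]}, index=list("abcde"))
        )
        assert filter_signal_traits(t, min_abundance=1.0, min_taxa=5) == []


# ---------------------------------------------------------------------------
# table validation and I/O
# ---------------------------------------------------------------------------


class TestAbundanceTable:
    def test_sum_over_100_rejected(self):
        with pytest.raises(ValidationError):
            AbundanceTable(pd.DataFrame({"A": [60.0], "B": [41.0]}, index=["x"]))

    def test_missing_entries_allowed_and_round_trip(self, tmp_path, habu_table):
        path = tmp_path / "t.csv"
        habu_table.to_csv(path)
        back = AbundanceTable.read_csv(path)
        pd.testing.assert_frame_equal(back.data, habu_table.data)

    def test_duplicate_taxa_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2.0]}, index=["x", "x"])
        with pytest.raises(ValidationError):
            AbundanceTable(df)


class TestQuantInputIO:
    def test_csv_round_trip(self, tmp_path):
        q = QuantInput(
            (
                Fraction("f1", 10.0, (), ("SVMP",)),
                Fraction("f2", 30.0, (2.0, 3.0), ("PLA2", "SVSP")),
            )
        )
        path = tmp_path / "q.csv"
        q.to_csv(path)
        back = QuantInput.read_csv(path)
        assert back == q
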