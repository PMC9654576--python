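"""Index formulas against frozen hand-computed values and scikit-bio oracles."""

import math

import pytest
import skbio.diversity.alpha as skbio_alpha

from ethodiv import (
    BVIInput,
    CountVector,
    Ethogram,
    bvi,
    bvi_from_sets,
    chao1,
    compute_all,
    margalef,
    menhinick,
    richness,
    shannon,
    simpson_d,
    simpson_diversity,
    simpson_reciprocal,
)


class TestRichness:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({f"b{i}": 3 for i in range(8)}, 8),  # eight behaviors seen -> 8
            ({}, 0),
            ({"a": 1, "b": 0, "c": 5}, 2),
        ],
    )
    def test_counts_observed_categories(self, counts, expected):
        assert richness(counts).value == expected


class TestShannon:
    def test_single_behavior_gives_zero(self):
        assert shannon({"rest": 25}).value == 0.0

    def test_equal_abundance_reaches_log_richness(self):
        assert shannon({c: 7 for c in "abcd"}).value == pytest.approx(math.log(4))

    def test_frozen_hand_value(self):
        # p = (0.5, 0.25, 0.25): -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397207708...
        assert shannon({"a": 2, "b": 1, "c": 1}).value == pytest.approx(1.039720770839918)

    def test_accepts_proportion_input(self):
        by_counts = shannon({"a": 2, "b": 1, "c": 1}).value
        by_props = shannon({"a": 0.5, "b": 0.25, "c": 0.25}, proportions=True).value
        assert by_props == pytest.approx(by_counts)

    def test_proportion_input_contract(self):
        with pytest.raises(ValueError, match="sum to 1"):
            shannon({"a": 0.5, "b": 0.4}, proportions=True)
        with pytest.raises(ValueError, match="non-negative"):
            shannon({"a": 1.5, "b": -0.5}, proportions=True)

    def test_no_observations_is_undefined_not_an_error(self):
        res = shannon({})
        assert not res.is_defined and "N=0" in res.notes[0]


class TestSimpsonFamily:
    def test_single_behavior_is_lowest_diversity(self):
        assert simpson_d({"rest": 10}).value == 1.0
        assert simpson_diversity({"rest": 10}).value == 0.0
        assert simpson_reciprocal({"rest": 10}).value == 1.0

    def test_frozen_two_behavior_values(self):
        # {5,5}: matching pairs 2*5*4, total pairs 10*9 -> 40/90
        assert simpson_d({"a": 5, "b": 5}).value == pytest.approx(40 / 90)
        assert simpson_diversity({"a": 5, "b": 5}).value == pytest.approx(50 / 90)
        assert simpson_reciprocal({"a": 5, "b": 5}).value == pytest.approx(2.25)

    def test_two_singletons_have_no_matching_pairs(self):
        assert simpson_d({"a": 1, "b": 1}).value == 0.0
        assert simpson_diversity({"a": 1, "b": 1}).value == 1.0

    def test_reciprocal_diverges_at_zero_dominance(self):
        res = simpson_reciprocal({"a": 1, "b": 1})
        assert not res.is_defined and "diverges" in res.notes[0]

    def test_undefined_below_two_observations(self):
        for fn in (simpson_d, simpson_diversity, simpson_reciprocal):
            res = fn({"a": 1})
            assert not res.is_defined and "insufficient" in res.notes[0]


class TestMenhinick:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"a": 2, "b": 2}, 1.0),  # S=2, N=4
            ({"a": 3, "b": 3, "c": 3}, 1.0),  # S=3, N=9
            ({"a": 1}, 1.0),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert menhinick(counts).value == pytest.approx(expected)

    def test_undefined_without_observations(self):
        assert not menhinick({}).is_defined


class TestMargalef:
    def test_single_behavior_gives_zero(self):
        assert margalef({"rest": 17}).value == 0.0

    def test_frozen_value(self):
        cv = {f"b{i}": 20 for i in range(5)}  # S=5, N=100
        assert margalef(cv).value == pytest.approx(4 / math.log(100))

    def test_strictly_decreasing_in_effort_at_fixed_richness(self):
        values = [margalef({"a": m, "b": m, "c": m}).value for m in (1, 2, 3, 5, 10, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_undefined_at_or_below_one_observation(self):
        assert not margalef({"a": 1}).is_defined
        assert not margalef({}).is_defined


class TestChao1:
    def test_equals_richness_without_singletons(self):
        cv = {f"b{i}": 2 + i % 3 for i in range(10)}  # all counts >= 2
        res = chao1(cv)
        assert res.value == 10.0

    def test_frozen_bias_corrected_value(self):
        # Sobs=10, F1=3, F2=2 -> 10 + 3*2/(2*3) = 11
        counts = {"a": 5, "b": 5, "c": 1, "d": 1, "e": 1, "f": 2, "g": 2, "h": 3, "i": 3, "j": 4}
        assert chao1(counts).value == pytest.approx(11.0)

    @pytest.mark.parametrize("s", [2, 3, 5, 8])
    def test_all_singletons_closed_form(self, s):
        cv = {f"b{i}": 1 for i in range(s)}
        assert chao1(cv).value == pytest.approx(s + s * (s - 1) / 2)

    def test_classic_variant(self):
        counts = {"a": 5, "b": 5, "c": 1, "d": 1, "e": 1, "f": 2, "g": 2, "h": 3, "i": 3, "j": 4}
        # classic: 10 + 9/(2*2) = 12.25
        assert chao1(counts, bias_corrected=False).value == pytest.approx(12.25)
        undefined = chao1({"a": 1, "b": 3}, bias_corrected=False)
        assert not undefined.is_defined  # F1>0, F2=0

    def test_empty_vector_is_undefined(self):
        assert not chao1({}).is_defined


class TestBVI:
    @pytest.mark.parametrize(
        "ob, ex, expected", [(12, 12, 100.0), (0, 20, 0.0), (7, 20, 35.0)]
    )
    def test_percentage_of_expected_repertoire(self, ob, ex, expected):
        assert bvi(BVIInput(ob, ex)).value == expected

    def test_zero_expected_is_an_error(self):
        with pytest.raises(ValueError):
            BVIInput(5, 0)

    def test_observed_beyond_expected_is_flagged_not_rejected(self):
        res = bvi(observed=12, expected=10)
        assert res.value == pytest.approx(120.0)
        assert any("exceeds" in n for n in res.notes)

    def test_from_sets_ignores_labels_outside_the_repertoire(self):
        res = bvi_from_sets({"rest", "feed", "pace"}, {"rest", "feed", "play", "dig"})
        assert res.value == pytest.approx(50.0)  # Ob=2 of Ex=4
        assert any("pace" in n for n in res.notes)


class TestComputeAll:
    def test_full_roster_with_expected_repertoire(self, uneven_cv):
        eth = Ethogram(
            ["rest", "feed", "groom", "play", "dig"],
            expected_categories=["rest", "feed", "groom", "play", "dig", "swim"],
        )
        results = compute_all(uneven_cv, eth)
        assert len(results) == 9
        assert all(r.is_defined for r in results)

    def test_degenerate_input_reports_undefined_entries(self):
        results = {r.index_name: r for r in compute_all({"a": 1})}
        assert len(results) == 8  # no BVI without a repertoire
        assert results["richness"].value == 1
        for name in ("simpson_d", "simpson_diversity", "simpson_reciprocal", "margalef"):
            assert not results[name].is_defined
            assert results[name].notes

    def test_matches_individual_operations(self, uneven_cv):
        battery = {r.index_name: r.value for r in compute_all(uneven_cv)}
        singles = {
            "richness": richness(uneven_cv).value,
            "shannon": shannon(uneven_cv).value,
            "simpson_d": simpson_d(uneven_cv).value,
            "simpson_diversity": simpson_diversity(uneven_cv).value,
            "simpson_reciprocal": simpson_reciprocal(uneven_cv).value,
            "menhinick": menhinick(uneven_cv).value,
            "margalef": margalef(uneven_cv).value,
            "chao1": chao1(uneven_cv).value,
        }
        assert battery == singles

    def test_inputs_summary_matches_source_vector(self, uneven_cv):
        for res in compute_all(uneven_cv):
            assert res.inputs_summary == uneven_cv.summary()


class TestScikitBioCrossChecks:
    """Independent reference values from skbio.diversity.alpha."""

    VECTORS = [
        {"a": 2, "b": 1, "c": 1},
        {"rest": 11, "feed": 3, "groom": 2, "play": 1, "dig": 1},
        {f"b{i}": c for i, c in enumerate([9, 7, 5, 3, 1, 1, 1, 2, 2, 40])},
        {"x": 100},
    ]

    @pytest.mark.parametrize("counts", VECTORS)
    def test_shannon_matches(self, counts):
        arr = list(counts.values())
        assert shannon(counts).value == pytest.approx(skbio_alpha.shannon(arr, base=math.e))

    @pytest.mark.parametrize("counts", VECTORS)
    def test_menhinick_matches(self, counts):
        arr = list(counts.values())
        assert menhinick(counts).value == pytest.approx(skbio_alpha.menhinick(arr))

    @pytest.mark.parametrize("counts", VECTORS[:3])
    def test_margalef_matches(self, counts):
        arr = list(counts.values())
        assert margalef(counts).value == pytest.approx(skbio_alpha.margalef(arr))

    @pytest.mark.parametrize("counts", VECTORS)
    @pytest.mark.parametrize("bias_corrected", [True, False])
    def test_chao1_matches(self, counts, bias_corrected):
        arr = list(counts.values())
        ours = chao1(counts, bias_corrected=bias_corrected)
        if not ours.is_defined:
            return  # classic variant undefined at F2=0; skbio returns inf there
        assert ours.value == pytest.approx(
            skbio_alpha.chao1(arr, bias_corrected=bias_corrected)
        )
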