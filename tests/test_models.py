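"""Prediction formulas: worked values, algebraic identities, dataset-level runs."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairscreen import (
    Cocktail,
    DegenerateInputError,
    MissingInputError,
    ModelSpec,
    UnsupportedOrderError,
    ValidationError,
    predict_bliss,
    predict_dataset,
    predict_isserlis,
    predict_loglinear,
    predict_pairs,
    predict_regression,
)

ABC = Cocktail.parse("A+B+C")
viability = st.floats(min_value=0.05, max_value=1.0)


def bliss_pairs(singles: dict) -> dict:
    """Pairs exactly consistent with Bliss independence of the singles."""
    drugs = sorted(singles)
    return {
        f"{a}+{b}": singles[a] * singles[b]
        for i, a in enumerate(drugs)
        for b in drugs[i + 1:]
    }


class TestWorkedValues:
    def test_bliss_is_product_of_singles(self):
        pred = predict_bliss({"CPT": 0.77, "CISPT": 0.82}, Cocktail.parse("CPT+CisPt"))
        assert pred.value == pytest.approx(0.6314)

    @pytest.mark.parametrize(
        "singles, expected",
        [({"A": 1.0, "B": 1.0}, 1.0), ({"A": 0.5, "B": 0.0}, 0.0)],
    )
    def test_bliss_identity_and_absorbing_zero(self, singles, expected):
        assert predict_bliss(singles, Cocktail.parse("A+B")).value == expected

    def test_pairs_model_triplet_is_sqrt_of_pair_product(self):
        pairs = {"CISPT+CPT": 0.67, "CBPT+CPT": 0.58, "CBPT+CISPT": 0.73}
        pred = predict_pairs(pairs, Cocktail.parse("CPT+CisPt+CbPt"))
        assert pred.value == pytest.approx(math.sqrt(0.67 * 0.58 * 0.73))
        assert pred.value == pytest.approx(0.5326, abs=1e-4)

    def test_pairs_model_m2_returns_the_pair(self):
        assert predict_pairs({"A+B": 0.42}, Cocktail.parse("A+B")).value == 0.42

    def test_regression_triplet(self):
        singles = {"A": 0.8, "B": 0.8, "C": 0.8}
        pairs = {k: 0.5 for k in ("A+B", "A+C", "B+C")}
        pred = predict_regression(singles, pairs, ABC)
        assert pred.value == pytest.approx(0.125 / 0.512)

    def test_isserlis_triplet(self):
        singles = {"A": 0.8, "B": 0.8, "C": 0.8}
        pairs = {k: 0.7 for k in ("A+B", "A+C", "B+C")}
        pred = predict_isserlis(singles, pairs, ABC)
        assert pred.value == pytest.approx(3 * 0.8 * 0.7 - 2 * 0.512)
        assert not pred.clamped

    def test_isserlis_negative_output_clamped_with_flag(self):
        singles = {"A": 0.9, "B": 0.9, "C": 0.9}
        pairs = {k: 0.01 for k in ("A+B", "A+C", "B+C")}
        pred = predict_isserlis(singles, pairs, ABC)
        assert pred.value == 0.0
        assert pred.clamped

    def test_loglinear_half_alpha_triplet(self):
        singles = {d: 0.9 for d in "ABC"}
        pairs = {k: 0.8 for k in ("A+B", "A+C", "B+C")}
        pred = predict_loglinear(singles, pairs, ABC, alpha=0.5)
        assert pred.value == pytest.approx(0.512**0.5)


class TestErrors:
    def test_bliss_missing_single_names_the_drug(self):
        with pytest.raises(MissingInputError, match="B"):
            predict_bliss({"A": 0.9}, Cocktail.parse("A+B"))

    def test_pairs_missing_pair_listed(self):
        with pytest.raises(MissingInputError) as err:
            predict_pairs({"A+B": 0.5}, ABC)
        assert set(err.value.missing) == {"A+C", "B+C"}

    def test_negative_pair_rejected(self):
        with pytest.raises(ValidationError):
            predict_pairs({"A+B": -0.1, "A+C": 0.5, "B+C": 0.5}, ABC)

    def test_regression_degenerate_single_raises_not_clamps(self):
        singles = {"A": 0.0, "B": 0.8, "C": 0.8}
        pairs = {k: 0.5 for k in ("A+B", "A+C", "B+C")}
        with pytest.raises(DegenerateInputError, match="A"):
            predict_regression(singles, pairs, ABC)

    @pytest.mark.parametrize("name", ["A+B", "A+B+C+D+E"])
    def test_isserlis_only_defined_for_triplets_and_quadruplets(self, name):
        cocktail = Cocktail.parse(name)
        with pytest.raises(UnsupportedOrderError):
            predict_isserlis({d: 0.8 for d in cocktail.drugs}, {}, cocktail)


class TestAlgebraicIdentities:
    """Property tests over random Bliss-consistent and generic inputs."""

    @given(st.lists(viability, min_size=2, max_size=6))
    @settings(max_examples=200, derandomize=True)
    def test_bliss_conservation(self, values):
        drugs = [chr(65 + i) for i in range(len(values))]
        singles = dict(zip(drugs, values))
        pairs = bliss_pairs(singles)
        cocktail = Cocktail(tuple(drugs))
        expected = math.prod(values)
        assert predict_pairs(pairs, cocktail).value == pytest.approx(expected, rel=1e-12)
        for alpha in (0.0, 0.3, 1.0 / (len(values) - 1) if len(values) > 1 else 1.0, 1.0):
            got = predict_loglinear(singles, pairs, cocktail, alpha).value
            assert got == pytest.approx(expected, rel=1e-12)
        if len(values) >= 3:
            assert predict_regression(singles, pairs, cocktail).value == pytest.approx(
                expected, rel=1e-12
            )
        if len(values) in (3, 4):
            assert predict_isserlis(singles, pairs, cocktail).value == pytest.approx(
                expected, rel=1e-12
            )

    @given(
        st.lists(viability, min_size=3, max_size=5),
        st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_loglinear_endpoints(self, values, data):
        drugs = [chr(65 + i) for i in range(len(values))]
        singles = dict(zip(drugs, values))
        # generic (non-Bliss) pairs
        pairs = {
            k: data.draw(viability, label=k) for k in bliss_pairs(singles)
        }
        cocktail = Cocktail(tuple(drugs))
        M = cocktail.order
        assert predict_loglinear(singles, pairs, cocktail, 0.0).value == pytest.approx(
            predict_bliss(singles, cocktail).value, rel=1e-12
        )
        assert predict_loglinear(singles, pairs, cocktail, 1.0).value == pytest.approx(
            predict_regression(singles, pairs, cocktail).value, rel=1e-12
        )
        assert predict_loglinear(singles, pairs, cocktail, 1.0 / (M - 1)).value == pytest.approx(
            predict_pairs(pairs, cocktail).value, rel=1e-12
        )

    def test_permutation_invariance(self):
        singles = {"A": 0.9, "B": 0.7, "C": 0.6}
        pairs = {"A+B": 0.6, "A+C": 0.5, "B+C": 0.4}
        for name in ("A+B+C", "C+B+A", "B+A+C"):
            cocktail = Cocktail.parse(name)
            assert predict_pairs(pairs, cocktail).value == pytest.approx(
                predict_pairs(pairs, Cocktail.parse("A+B+C")).value
            )
            assert predict_isserlis(singles, pairs, cocktail).value == pytest.approx(
                predict_isserlis(singles, pairs, Cocktail.parse("A+B+C")).value
            )

    @given(viability, viability)
    @settings(max_examples=100, derandomize=True)
    def test_pairs_model_monotone_in_each_pair(self, low, high):
        low, high = sorted((low, high))
        base = {"A+B": 0.5, "A+C": 0.5, "B+C": low}
        bumped = {**base, "B+C": high}
        assert predict_pairs(bumped, ABC).value >= predict_pairs(base, ABC).value


class TestPredictDataset:
    def test_h1299_pairs_model_covers_all_42_high_order_cocktails(self, screen):
        result = predict_dataset(screen, "H1299", ModelSpec("pairs"))
        assert len(result) == 42
        assert result.skipped == []

    def test_hela_skips_exactly_the_cocktails_with_the_missing_pair(self, screen):
        result = predict_dataset(screen, "HeLa", ModelSpec("pairs"))
        assert result.skipped
        for s in result.skipped:
            assert "CBPT" in s.cocktail and "NCZ" in s.cocktail
        assert len(result) + len(result.skipped) == 42

    def test_isserlis_order_restriction_lands_in_skip_list(self, screen):
        result = predict_dataset(screen, "H1299", ModelSpec("isserlis"))
        assert len(result) == 35  # 20 triplets + 15 quadruplets
        assert all(s.cocktail.order >= 5 for s in result.skipped)

    def test_empty_dataset_predicts_nothing(self):
        from pairscreen import CombinationDataset

        result = predict_dataset(CombinationDataset(), "X", ModelSpec("pairs"))
        assert list(result) == []

    def test_unknown_cell_line_rejected(self, screen):
        with pytest.raises(ValidationError, match="unknown cell line"):
            predict_dataset(screen, "HEK293", ModelSpec("pairs"))
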