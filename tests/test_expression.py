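"""RPKM arithmetic and expression-pattern classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aatkit import expression

TISSUES = [f"t{i}" for i in range(11)]


def _series(values):
    return pd.Series(values, index=TISSUES[: len(values)])


def _matrix(counts_dict, lengths=None, libs=None):
    counts = pd.DataFrame(counts_dict).T
    counts.columns = TISSUES[: counts.shape[1]]
    lengths = lengths or {g: 1000 for g in counts.index}
    libs = libs if libs is not None else pd.Series(
        [1e6] * counts.shape[1], index=counts.columns)
    return expression.rpkm(counts, pd.Series(lengths), libs)


class TestRpkm:
    @pytest.mark.parametrize("count,length,lib,expected", [
        (10, 1000, 1e6, 10.0),
        (0, 1000, 1e6, 0.0),
        (5, 500, 2e6, 5.0),
    ])
    def test_unit_cases(self, count, length, lib, expected):
        counts = pd.DataFrame({"t0": [count]}, index=["g"])
        matrix = expression.rpkm(counts, pd.Series({"g": length}),
                                 pd.Series({"t0": lib}))
        assert matrix.rpkm.loc["g", "t0"] == pytest.approx(expected)

    def test_negative_count_rejected(self):
        counts = pd.DataFrame({"t0": [-1]}, index=["g"])
        with pytest.raises(ValueError):
            expression.rpkm(counts, pd.Series({"g": 100}), pd.Series({"t0": 1e6}))

    @given(st.integers(1, 1000), st.integers(1, 20))
    @settings(max_examples=30, deadline=None)
    def test_scale_consistency(self, count, factor):
        counts = pd.DataFrame({"t0": [count]}, index=["g"])
        base = expression.rpkm(counts, pd.Series({"g": 500}),
                               pd.Series({"t0": 1e6}))
        scaled = expression.rpkm(counts * factor, pd.Series({"g": 500}),
                                 pd.Series({"t0": 1e6 * factor}))
        assert scaled.rpkm.loc["g", "t0"] == pytest.approx(
            base.rpkm.loc["g", "t0"], abs=1e-12)


class TestClassifyRegulation:
    def test_all_below_threshold_is_silent(self):
        cls = expression.classify_regulation("g", _series([0.3] * 11))
        assert cls.status == "silent"
        assert cls.preferred_tissues == ()

    def test_twofold_boundary_uniform(self):
        profile = _series([5.0, 5.5, 9.9, 6.0, 7.0])
        cls = expression.classify_regulation("g", profile)
        assert cls.status == "uniform"
        assert cls.fold_range == pytest.approx(1.98)

    def test_spiked_tissue_is_regulated_and_preferred(self):
        values = [4.0] * 10 + [40.0]
        cls = expression.classify_regulation("g", _series(values))
        assert cls.status == "regulated"
        assert cls.preferred_tissues == (TISSUES[10],)

    def test_rescaling_preserves_fold_range(self):
        profile = _series([2.0, 3.0, 5.0, 8.0])
        a = expression.classify_regulation("g", profile)
        b = expression.classify_regulation("g", profile * 7)
        assert b.fold_range == pytest.approx(a.fold_range)


class TestPairDivergence:
    def test_identical_profiles_type_one(self):
        p = _series([1.0, 5.0, 20.0, 3.0, 8.0])
        call = expression.classify_pair_divergence("p", p, p)
        assert call.divergence_type == "I_same_pattern"

    def test_uniform_fourfold_shift_type_two(self):
        a = _series([2.0, 8.0, 32.0, 4.0, 16.0])
        call = expression.classify_pair_divergence("p", a, a * 4)
        assert call.divergence_type == "II_magnitude_shift"
        assert call.higher_member == "b"

    def test_complementary_profiles_type_three(self):
        a = _series([20.0, 0.2, 20.0, 0.2, 20.0])
        b = _series([0.2, 20.0, 0.2, 20.0, 0.2])
        call = expression.classify_pair_divergence("p", a, b)
        assert call.divergence_type == "III_divergent"

    def test_type_one_and_three_symmetric(self):
        a = _series([1.0, 5.0, 20.0, 3.0, 8.0])
        b = _series([20.0, 1.0, 2.0, 30.0, 0.5])
        ab = expression.classify_pair_divergence("p", a, b)
        ba = expression.classify_pair_divergence("p", b, a)
        assert ab.divergence_type == ba.divergence_type == "III_divergent"

    def test_type_two_records_higher_member(self):
        a = _series([2.0, 8.0, 32.0, 4.0, 16.0])
        ab = expression.classify_pair_divergence("p", a, a * 4,
                                                 member_a="x", member_b="y")
        ba = expression.classify_pair_divergence("p", a * 4, a,
                                                 member_a="x", member_b="y")
        assert ab.higher_member == "y"
        assert ba.higher_member == "x"

    def test_zero_variance_profile_falls_through(self):
        flat = _series([5.0] * 5)
        call = expression.classify_pair_divergence("p", flat, flat * 4)
        assert call.correlation is None
        assert call.divergence_type == "II_magnitude_shift"

    def test_silent_member_flagged(self):
        a = _series([0.1] * 5)
        b = _series([5.0, 8.0, 2.0, 9.0, 4.0])
        call = expression.classify_pair_divergence("p", a, b)
        assert call.silent_member

    def test_mismatched_tissue_order_rejected(self):
        a = _series([1.0, 2.0])
        b = pd.Series([1.0, 2.0], index=["t1", "t0"])
        with pytest.raises(ValueError):
            expression.classify_pair_divergence("p", a, b)


class TestSummary:
    def test_status_counts_sum_to_total(self):
        matrix = _matrix({
            "g1": [0.1] * 5, "g2": [5.0] * 5, "g3": [2.0, 2.0, 40.0, 2.0, 2.0],
        })
        summary = expression.summarize_family_expression(
            matrix, {"g1": "AAP", "g2": "AAP", "g3": "CAT"}, [])
        assert sum(summary.status_counts.values()) == 3
        assert summary.status_counts["silent"] == 1

    def test_all_silent_input(self):
        matrix = _matrix({"g1": [0.0] * 4, "g2": [0.2] * 4})
        summary = expression.summarize_family_expression(
            matrix, {"g1": "AAP", "g2": "AAP"}, [])
        assert summary.status_counts == {"silent": 2, "uniform": 0, "regulated": 0}

    def test_subfamily_means_shape(self):
        matrix = _matrix({"g1": [1.0] * 4, "g2": [3.0] * 4, "g3": [5.0] * 4})
        summary = expression.summarize_family_expression(
            matrix, {"g1": "AAP", "g2": "AAP", "g3": "CAT"}, [])
        assert summary.subfamily_means.loc["AAP"].tolist() == [2.0] * 4

    def test_unknown_gene_rejected(self):
        matrix = _matrix({"g1": [1.0] * 4})
        with pytest.raises(ValueError, match="missing"):
            expression.summarize_family_expression(matrix, {"nope": "AAP"}, [])

    def test_planted_pair_types_recovered(self):
        """30 simulated pairs (10 per type) classified with >= 9/10 per-type
        accuracy at the default thresholds."""
        rng = np.random.default_rng(0)
        counts = {}
        pairs = []
        want = {}
        for i in range(30):
            kind = ["I", "II", "III"][i % 3]
            raw = rng.normal(0, 1, 11)
            shape = 3.0 + 1.5 * (raw - raw.mean()) / raw.std()
            a = 2.0 ** shape
            if kind == "I":
                b = a.copy()
            elif kind == "II":
                b = a * 4.0
            else:
                b = 2.0 ** (2 * shape.mean() - shape)
            noise = lambda: np.exp(rng.normal(0, 0.25, 11))
            ga, gb = f"a{i}", f"b{i}"
            counts[ga] = np.round(a * noise() * 5)
            counts[gb] = np.round(b * noise() * 5)
            pairs.append((f"p{i}", ga, gb))
            want[f"p{i}"] = {"I": "I_same_pattern", "II": "II_magnitude_shift",
                             "III": "III_divergent"}[kind]
        matrix = _matrix(counts, lengths={g: 1000 for g in counts},
                         libs=pd.Series([5e6] * 11, index=TISSUES))
        summary = expression.summarize_family_expression(
            matrix, {g: "AAP" for g in counts}, pairs)
        correct = {"I_same_pattern": 0, "II_magnitude_shift": 0, "III_divergent": 0}
        for call in summary.pair_types:
            if call.divergence_type == want[call.pair_id]:
                correct[call.divergence_type] += 1
        assert all(v >= 9 for v in correct.values()), correct
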