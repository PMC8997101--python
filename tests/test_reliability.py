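"""Weighted kappa: frozen examples, invariances and the observer gate."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clawbench.reliability import (
    KappaResult,
    gate_observers,
    kappa_from_counts,
    landis_koch_label,
    merge_and_rate,
    observer_kappas,
    weighted_kappa,
)
from clawbench.simulate import simulate_raters, identity_confusion


def brute_force_kappa(table, weights="linear"):
    """Independent oracle: explicit O/E cell enumeration in plain Python."""
    k = len(table)
    n = sum(sum(row) for row in table)
    row_m = [sum(table[i][j] for j in range(k)) / n for i in range(k)]
    col_m = [sum(table[i][j] for i in range(k)) / n for j in range(k)]
    d_obs = d_exp = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1) if k > 1 else 0.0
            if weights == "quadratic":
                w = w * w
            d_obs += w * table[i][j] / n
            d_exp += w * row_m[i] * col_m[j]
    if d_exp == 0.0:
        return 1.0 if d_obs == 0.0 else float("nan")
    return 1.0 - d_obs / d_exp


class TestWeightedKappa:
    def test_perfect_agreement_is_exactly_one(self):
        res = weighted_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.kappa == 1.0
        assert not res.degenerate

    def test_two_category_textbook_table(self):
        # counts ((45,15),(25,15)): po=0.60, pe=0.7*0.6+0.3*0.4=0.54
        res = kappa_from_counts(np.array([[45, 15], [25, 15]]))
        assert res.kappa == pytest.approx((0.60 - 0.54) / (1 - 0.54), abs=1e-12)
        assert res.kappa == pytest.approx(brute_force_kappa([[45, 15], [25, 15]]),
                                          abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_oracle_on_random_tables(self, weights):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            table = rng.integers(0, 6, size=(k, k))
            if table.sum() == 0:
                continue
            mine = kappa_from_counts(table, weights).kappa
            oracle = brute_force_kappa(table.tolist(), weights)
            if np.isnan(oracle):
                assert np.isnan(mine) or mine == 1.0
            else:
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_linear_weights(self):
        cohen_kappa_score = pytest.importorskip(
            "sklearn.metrics").cohen_kappa_score
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.integers(1, 6, 60)
            b = rng.integers(1, 6, 60)
            cats = sorted(set(a) | set(b))
            mine = weighted_kappa(a, b, categories=cats).kappa
            assert mine == pytest.approx(
                cohen_kappa_score(a, b, weights="linear"), abs=1e-12)

    def test_degenerate_constant_raters(self):
        res = weighted_kappa([2, 2, 2], [2, 2, 2])
        assert res.kappa == 1.0 and res.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            weighted_kappa([1, 2], [1])
        with pytest.raises(ValueError):
            weighted_kappa([], [])

    def test_rating_outside_declared_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            weighted_kappa([1, 6], [1, 2], categories=[1, 2, 3, 4, 5])

    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    min_size=1, max_size=60))
    def test_kappa_bounded_and_relabel_invariant(self, pairs):
        """kappa lies in [-1, 1] and is invariant under any order-preserving
        relabeling applied to both raters."""
        r1 = [p[0] for p in pairs]
        r2 = [p[1] for p in pairs]
        res = weighted_kappa(r1, r2, categories=[1, 2, 3, 4, 5])
        assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
        relabel = {1: 10, 2: 20, 3: 30, 4: 40, 5: 50}
        res2 = weighted_kappa([relabel[r] for r in r1], [relabel[r] for r in r2],
                              categories=[10, 20, 30, 40, 50])
        assert res2.kappa == pytest.approx(res.kappa, abs=1e-12)


class TestMerging:
    def test_blockmates_agree_after_merge(self):
        # scores 1 and 2 fall into the same block of the (12)(3)(45) merge
        res = merge_and_rate([1, 2], [2, 1], "12|3|45", categories=[1, 2, 3, 4, 5])
        assert res.kappa == 1.0

    def test_identity_partition_changes_nothing(self):
        r1 = [1, 2, 3, 4, 5, 2, 3, 1]
        r2 = [2, 2, 3, 5, 4, 1, 3, 1]
        plain = weighted_kappa(r1, r2, categories=[1, 2, 3, 4, 5])
        merged = merge_and_rate(r1, r2, "1|2|3|4|5", categories=[1, 2, 3, 4, 5])
        assert merged.kappa == pytest.approx(plain.kappa, abs=1e-12)

    def test_overlapping_or_incomplete_partition_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            merge_and_rate([1, 2], [1, 2], "12|23|45", categories=[1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="missing"):
            merge_and_rate([1, 2], [1, 2], "12|3", categories=[1, 2, 3, 4, 5])

    def test_within_type_confusions_vanish_on_aggregation(self):
        """Merging categories of the same lesion type cannot lower agreement
        when all confusions are within-type: the merged table is perfect."""
        r1 = [1, 2, 1, 2, 3, 4, 3, 4]
        r2 = [2, 1, 1, 2, 4, 3, 3, 4]  # confusions only within {1,2} and {3,4}
        unmerged = weighted_kappa(r1, r2, categories=[1, 2, 3, 4])
        merged = merge_and_rate(r1, r2, "12|34", categories=[1, 2, 3, 4])
        assert merged.kappa == 1.0 >= unmerged.kappa


class TestGate:
    def test_threshold_is_inclusive(self):
        passed, failed = gate_observers(
            {"a": 0.61, "b": 0.55, "c": 1.0, "d": float("nan")}, threshold=0.61)
        assert passed == {"a", "c"}
        assert failed == {"b", "d"}

    def test_empty_input_gives_empty_sets(self):
        assert gate_observers({}) == (set(), set())

    def test_gate_accepts_kappa_results(self):
        res = KappaResult(0.7, 0.9, 0.6, "linear", 10)
        passed, _ = gate_observers({"a": res})
        assert passed == {"a"}


class TestObserverTable:
    def test_identity_confusion_gives_perfect_panel(self):
        table = simulate_raters(3, 30, identity_confusion(5), seed=4)
        panel = observer_kappas(table, categories=[1, 2, 3, 4, 5])
        assert (panel["kappa"] == 1.0).all()
        assert len(panel) == 3

    def test_merge_option_matches_direct_call(self):
        table = simulate_raters(2, 50, identity_confusion(5), seed=6)
        merged = observer_kappas(table, merge="12|3|45", categories=[1, 2, 3, 4, 5])
        assert (merged["kappa"] == 1.0).all()

    def test_missing_columns_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="reference"):
            observer_kappas(pd.DataFrame({"observer_id": [], "rating": []}))


@pytest.mark.parametrize("kappa,label", [
    (-0.2, "poor"), (0.1, "slight"), (0.3, "fair"), (0.5, "moderate"),
    (0.61, "substantial"), (0.9, "almost perfect"),
])
def test_landis_koch_labels(kappa, label):
    assert landis_koch_label(kappa) == label
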