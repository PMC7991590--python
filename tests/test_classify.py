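import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutsense.classify import (
    FLAG_AMBIGUOUS,
    FLAG_EXCLUDED,
    CombinedScoreTable,
    assign_classes,
    burial_truth_from_structure,
    call_class,
    combine,
    standardize,
)
from mutsense.dms_io import AccessibilityTable
from mutsense.errors import DegenerateDataError, InsufficientDataError
from mutsense.rescale_aggregate import PositionProfile


def profiles_from(sens_by_pos):
    return [PositionProfile(position=p, mean_rescaled=-s, n_mutants=19) for p, s in sens_by_pos.items()]


def brute_force_assign(z_sens, z_acc, k=1.0, exclusions=()):
    """Re-derive the three-class calls from first principles, pure Python."""
    n = len(z_sens)
    sa = [z_sens[i] + z_acc[i] for i in range(n)]
    sb = [z_sens[i] - z_acc[i] for i in range(n)]

    def stats(xs):
        mean = sum(xs) / len(xs)
        sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / len(xs))
        return mean, sd

    ma, sda = stats(sa)
    mb, sdb = stats(sb)
    out = []
    for i in range(n):
        active = sa[i] > ma + k * sda
        buried = sb[i] > mb + k * sdb and (i + 1) not in exclusions
        if active and buried:
            da = (sa[i] - ma) / sda
            db = (sb[i] - mb) / sdb
            out.append("active_site" if da >= db else "buried")
        elif active:
            out.append("active_site")
        elif buried:
            out.append("buried")
        else:
            out.append("exposed_nonactive")
    return out


class TestStandardize:
    def test_hand_computed(self):
        out = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.224745, 0.0, 1.224745], atol=1e-6)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
    @settings(max_examples=200)
    def test_mean_zero_sd_one(self, values):
        if np.std(values) < 1e-6:
            return
        out = standardize(values)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateDataError):
            standardize([2.0, 2.0, 2.0])

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            standardize([1.0])


class TestCombine:
    def test_intersection_of_positions(self):
        profiles = profiles_from({p: p / 10 for p in range(1, 6)})
        acc = AccessibilityTable(records=[(p, 10.0 * p) for p in range(2, 7)],
                                 source="sequence_predicted")
        combined = combine(profiles, acc)
        assert combined.positions.tolist() == [2, 3, 4, 5]

    def test_structure_source_rejected(self):
        profiles = profiles_from({1: 0.1, 2: 0.5, 3: 0.9})
        acc = AccessibilityTable(records=[(1, 1.0), (2, 2.0), (3, 3.0)], source="structure")
        with pytest.raises(ValueError, match="sequence-predicted"):
            combine(profiles, acc)

    def test_small_intersection_raises(self):
        profiles = profiles_from({1: 0.1, 2: 0.5})
        acc = AccessibilityTable(records=[(1, 1.0), (2, 2.0)], source="sequence_predicted")
        with pytest.raises(InsufficientDataError):
            combine(profiles, acc)

    def test_elementwise_scores(self):
        table = CombinedScoreTable(
            positions=np.array([1, 2, 3, 4]),
            z_sens=np.array([2.0, 0.0, -1.0, -1.0]),
            z_acc=np.array([1.5, 0.5, -1.0, -1.0]),
        )
        np.testing.assert_allclose(table.score_active, [3.5, 0.5, -2.0, -2.0])
        np.testing.assert_allclose(table.score_buried, [0.5, -0.5, 0.0, 0.0])
        np.testing.assert_allclose(table.score_active - table.score_buried, 2 * table.z_acc)

    def test_max_sensitive_max_exposed_has_max_active_score(self):
        profiles = profiles_from({1: 1.0, 2: 0.3, 3: 0.1, 4: 0.0})
        acc = AccessibilityTable(records=[(1, 95.0), (2, 40.0), (3, 20.0), (4, 5.0)],
                                 source="sequence_predicted")
        combined = combine(profiles, acc)
        assert int(np.argmax(combined.score_active)) == 0

    def test_z_scores_standardized_over_intersection(self):
        profiles = profiles_from({p: p / 7 for p in range(1, 8)})
        acc = AccessibilityTable(records=[(p, 3.0 * p + 1) for p in range(3, 10)],
                                 source="sequence_predicted")
        combined = combine(profiles, acc)
        for z in (combined.z_sens, combined.z_acc):
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1.0) < 1e-9


class TestCallClass:
    def test_hand_computed_cutoff(self):
        scores = [3.5, 0.5, -2.0, -2.0]
        # mean 0, population SD sqrt(20.5/4) = 2.2638; only 3.5 exceeds it
        called = call_class(scores, k=1.0)
        assert called.tolist() == [0]
        assert np.std(scores) == pytest.approx(2.2638, abs=1e-4)

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateDataError):
            call_class([1.0, 1.0, 1.0])

    def test_huge_k_empty(self):
        assert call_class([3.5, 0.5, -2.0, -2.0], k=1e9).size == 0


class TestAssignClasses:
    @staticmethod
    def _table(z_sens, z_acc):
        n = len(z_sens)
        return CombinedScoreTable(
            positions=np.arange(1, n + 1),
            z_sens=np.asarray(z_sens, dtype=float),
            z_acc=np.asarray(z_acc, dtype=float),
        )

    def test_three_way_partition(self):
        table = self._table([2.0, 0.0, -1.0, -0.5, -0.5], [1.5, 0.5, -1.0, -0.5, -0.5])
        pred = assign_classes(table)
        assert set(pred.predicted_class) <= {"active_site", "buried", "exposed_nonactive"}
        assert len(pred.predicted_class) == 5

    def test_residue_in_neither_set_is_exposed(self):
        table = self._table([3.0, 0.0, 0.0, 0.0], [2.5, 0.1, -0.1, 0.0])
        pred = assign_classes(table)
        assert pred.predicted_class[1] == "exposed_nonactive"
        assert pred.flags[1] == set()

    def test_dual_call_tiebreak_by_sd_margin(self):
        # residue 1 exceeds both cutoffs; its active margin is larger
        z_sens = [4.0, 0.1, -0.2, 0.0, -0.1, 0.2]
        z_acc = [1.0, -0.3, 0.4, -0.2, 0.3, -0.2]
        table = self._table(z_sens, z_acc)
        pred = assign_classes(table)
        expected = brute_force_assign(z_sens, z_acc)
        assert pred.predicted_class == expected
        assert pred.predicted_class[0] == "active_site"
        assert FLAG_AMBIGUOUS in pred.flags[0]

    def test_exclusions_only_affect_buried(self):
        z_sens = [3.0, 0.0, 0.1, -0.1, 0.0]
        z_acc = [-3.0, 0.0, 0.1, -0.1, 0.0]
        table = self._table(z_sens, z_acc)
        baseline = assign_classes(table)
        assert baseline.predicted_class[0] == "buried"
        excluded = assign_classes(table, exclusions={1})
        assert excluded.predicted_class[0] == "exposed_nonactive"
        assert FLAG_EXCLUDED in excluded.flags[0]

    def test_scale_invariance_before_standardization(self):
        sens = {p: p / 11 for p in range(1, 12)}
        rel = [(p, 9.0 * ((p * 7) % 11) + 1) for p in range(1, 12)]
        acc1 = AccessibilityTable(records=rel, source="sequence_predicted")
        acc5 = AccessibilityTable(records=[(p, 5.0 * v) for p, v in rel], source="sequence_predicted")
        pred1 = assign_classes(combine(profiles_from(sens), acc1))
        pred5 = assign_classes(combine(profiles_from(sens), acc5))
        assert pred1.predicted_class == pred5.predicted_class

    def test_oracle_equivalence_100_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            z_sens = standardize(rng.normal(size=n)).tolist()
            z_acc = standardize(rng.normal(size=n)).tolist()
            exclusions = set(int(p) for p in rng.choice(np.arange(1, n + 1),
                                                        size=rng.integers(0, 3), replace=False))
            table = self._table(z_sens, z_acc)
            pred = assign_classes(table, exclusions=exclusions)
            assert pred.predicted_class == brute_force_assign(z_sens, z_acc, exclusions=exclusions)

    def test_monotonicity_of_active_call(self):
        rng = np.random.default_rng(5)
        sens = rng.uniform(0, 1, 10)
        rel = rng.uniform(6, 100, 10)
        rel[0] = 95.0  # positive accessibility z-score for the focal residue
        acc = AccessibilityTable(records=[(i + 1, float(v)) for i, v in enumerate(rel)],
                                 source="sequence_predicted")
        calls = []
        for bump in np.linspace(0.0, 3.0, 13):
            s = sens.copy()
            s[0] = sens[0] + bump
            profs = profiles_from({i + 1: float(v) for i, v in enumerate(s)})
            calls.append(assign_classes(combine(profs, acc)).predicted_class[0])
        # once the focal residue enters the active set it never leaves
        first_active = calls.index("active_site")
        assert all(c == "active_site" for c in calls[first_active:])


class TestBurialTruth:
    def test_cutoff_is_inclusive(self):
        acc = AccessibilityTable(records=[(1, 5.0), (2, 5.1), (3, 0.0)], source="structure")
        labels = burial_truth_from_structure(acc)
        assert labels == {1: "buried", 2: "exposed", 3: "buried"}

    def test_requires_structure_source(self):
        acc = AccessibilityTable(records=[(1, 5.0)], source="sequence_predicted")
        with pytest.raises(ValueError):
            burial_truth_from_structure(acc)
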