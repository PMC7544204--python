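import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from capscreen import differential as diff
from .conftest import make_matrix


def bh_oracle(p):
    """Brute-force step-up: adj_i = min over ranks j>=i of p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(pos, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


def welch_oracle(x, y):
    """Hand-computed Welch statistic and two-sided p for two samples."""
    x, y = np.asarray(x), np.asarray(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestWelch:
    CASE = np.array([10.0, 10.2, 9.8, 10.0])
    CONTROL = np.array([6.0, 6.1, 5.9, 6.0])

    def test_against_hand_computed_value(self):
        fc, p = diff.welch_ttest(self.CASE[None, :], self.CONTROL[None, :])
        assert fc[0] == pytest.approx(4.0)
        assert p[0] == pytest.approx(welch_oracle(self.CASE, self.CONTROL), rel=1e-12)

    def test_null_identity(self):
        fc, p = diff.welch_ttest(self.CASE[None, :], self.CASE[None, :])
        assert fc[0] == 0.0
        assert p[0] == 1.0

    def test_label_swap_symmetry(self):
        fc_a, p_a = diff.welch_ttest(self.CASE[None, :], self.CONTROL[None, :])
        fc_b, p_b = diff.welch_ttest(self.CONTROL[None, :], self.CASE[None, :])
        assert fc_a[0] == -fc_b[0]
        assert p_a[0] == pytest.approx(p_b[0])

    def test_degenerate_rows(self):
        same = np.array([[5.0, 5.0]])
        other = np.array([[7.0, 7.0]])
        _, p_eq = diff.welch_ttest(same, same)
        _, p_ne = diff.welch_ttest(same, other)
        assert p_eq[0] == 1.0 and p_ne[0] == 0.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            diff.welch_ttest(np.array([[1.0]]), np.array([[1.0, 2.0]]))


class TestTestCondition(object):
    def test_per_condition_frame(self, toy_design):
        vals = pd.DataFrame(
            {
                "e1": [10.0, 5.0],
                "e2": [10.2, 5.2],
                "c1": [6.0, 5.1],
                "c2": [6.1, 4.9],
            },
            index=["HIT", "FLAT"],
        )
        out = diff.test_condition(make_matrix(vals), toy_design, "NCBP1", "7")
        assert out.loc["HIT", "log2FC"] == pytest.approx(4.05)
        assert out.loc["HIT", "p"] < out.loc["FLAT", "p"]


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            diff.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_and_tied_inputs(self):
        assert diff.bh_adjust([0.2]).tolist() == [0.2]
        np.testing.assert_allclose(diff.bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(diff.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_oracle_property_and_bounds(self, p):
        adj = diff.bh_adjust(np.asarray(p))
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0)).all()


class TestStabilityFilter:
    @pytest.mark.parametrize("n_sig, passes", [(60, True), (59, False), (100, True)])
    def test_min_trials_boundary(self, n_sig, passes):
        n_trials = 100
        fc = np.full((1, n_trials), 3.0)
        adjp = np.full((1, n_trials), 0.5)
        adjp[0, :n_sig] = 0.01
        out = diff.stability_filter(fc, adjp)
        assert out["n_significant_trials"].iloc[0] == n_sig
        assert bool(out["pass"].iloc[0]) is passes

    def test_both_thresholds_required_per_trial(self):
        fc = np.array([[3.0, 0.5, 3.0]])
        adjp = np.array([[0.01, 0.01, 0.2]])
        out = diff.stability_filter(fc, adjp, diff.DifferentialParams(min_trials=1))
        assert out["n_significant_trials"].iloc[0] == 1

    def test_trial_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            diff.stability_filter(np.zeros((2, 5)), np.zeros((2, 4)))

    def test_monotone_in_min_trials(self):
        rng = np.random.default_rng(1)
        fc = rng.normal(1.0, 1.0, size=(50, 100))
        adjp = rng.uniform(size=(50, 100))
        passes = {
            k: set(
                np.nonzero(
                    diff.stability_filter(
                        fc, adjp, diff.DifferentialParams(min_trials=k)
                    )["pass"].to_numpy()
                )[0]
            )
            for k in (59, 60, 61)
        }
        assert passes[61] <= passes[60] <= passes[59]


class TestCollate:
    def frame(self):
        return pd.DataFrame(
            {
                "protein_id": ["A", "A", "B", "C"],
                "target_set": ["T1", "T2", "T1", "T1"],
                "condition_id": ["7", "7", "7", "10"],
                "pass": [True, True, True, False],
            }
        )

    def test_union_and_tally(self):
        tally = diff.collate_significant(self.frame())
        assert set(tally["protein_id"]) == {"A", "B"}
        assert tally.set_index("protein_id").loc["A", "n_tests_passed"] == 2
        assert tally.set_index("protein_id").loc["B", "n_tests_passed"] == 1

    def test_never_passing_protein_excluded(self):
        tally = diff.collate_significant(self.frame())
        assert "C" not in set(tally["protein_id"])

    def test_significant_proteins_by_target(self):
        assert diff.significant_proteins(self.frame(), "T2") == {"A"}
        assert diff.significant_proteins(self.frame()) == {"A", "B"}
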