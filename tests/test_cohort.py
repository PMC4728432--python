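"""Cohort analysis: filtering, clustering, survival, DARs, DAPs, CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxscape import (
    dap_report,
    find_dars,
    group_daps,
    identify_poor_cluster,
    km_logrank,
    kmeans_cluster,
    select_k,
    variable_reactions,
    wilson_ci,
)
from fluxscape.cohort import ClusterAssignment, dar_tests
from fluxscape.exceptions import ValidationError


def _matrix(values, samples=None, reactions=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    reactions = reactions or [f"r{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=samples, columns=reactions)


class TestVariableReactions:
    def test_constant_columns_excluded(self):
        m = _matrix([[-1, 0], [-1, -1]])
        assert variable_reactions(m) == ["r1"]

    def test_single_deviant_sample_included(self):
        m = _matrix([[-1], [-1], [0]])
        assert variable_reactions(m) == ["r0"]

    def test_all_constant_gives_empty(self):
        assert variable_reactions(_matrix([[-1, 0], [-1, 0]])) == []


class TestKMeans:
    def test_orthogonal_prototypes_perfectly_separated(self):
        proto_a = [-1, -1, 0, 0]
        proto_b = [0, 0, -1, -1]
        m = _matrix([proto_a] * 5 + [proto_b] * 5)
        res = kmeans_cluster(m, k=2, seed=0)
        labels = res.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_zero_inertia(self):
        m = _matrix([[-1, 0], [0, -1], [-1, -1]])
        res = kmeans_cluster(m, k=3, seed=0)
        assert res.inertia == pytest.approx(0.0)
        assert sorted(res.labels) == [1, 2, 3]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.choice([-1, 0], size=(30, 6)))
        a = kmeans_cluster(m, k=3, seed=5).labels
        b = kmeans_cluster(m, k=3, seed=5).labels
        assert a.equals(b)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_cluster(_matrix([[-1], [0]]), k=3)


def _survival(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events},
                        index=pd.Index(samples, name="sample_id"))


def _assignment(labels, samples=None):
    samples = samples or [f"s{i}" for i in range(len(labels))]
    series = pd.Series(labels, index=samples, name="cluster")
    return ClusterAssignment(k=int(max(labels)), labels=series, inertia=0.0)


class TestKMLogrank:
    def test_identical_groups_null_statistic(self):
        surv = _survival([5, 8, 12, 5, 8, 12], [1, 1, 0, 1, 1, 0])
        res = km_logrank(_assignment([1, 1, 1, 2, 2, 2]), surv)
        assert res.overall_stat == pytest.approx(0.0, abs=1e-12)
        assert res.overall_p == pytest.approx(1.0)

    def test_km_curve_drops_to_zero_after_only_death(self):
        surv = _survival([1, 5], [1, 0])
        res = km_logrank(_assignment([1, 2]), surv)
        curve = res.curves[1]
        assert curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0]
        surv = _survival(times + [9.9], [1, 1, 1, 1, 0])
        res = km_logrank(_assignment([1, 1, 1, 1, 2]), surv)
        curve = res.curves[1].set_index("time")["survival"]
        for i, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1 - (i + 1) / 4)

    def test_logrank_detects_strong_hazard_ratio(self):
        """Exponential survival with hazard ratio 3 is detected at n=200/arm."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t_a = rng.exponential(1 / 3.0, size=200)
            t_b = rng.exponential(1.0, size=200)
            surv = _survival(np.concatenate([t_a, t_b]), np.ones(400, dtype=int))
            res = km_logrank(_assignment([1] * 200 + [2] * 200), surv)
            hits += res.overall_p < 0.001
        assert hits >= 19

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        surv = _survival(rng.exponential(1, 40), rng.integers(0, 2, 40))
        labels = list(rng.integers(1, 3, 40))
        a = km_logrank(_assignment(labels), surv)
        b = km_logrank(_assignment([3 - l for l in labels]), surv)
        assert a.overall_p == pytest.approx(b.overall_p)
        assert 0 <= a.overall_p <= 1

    def test_missing_survival_record_named(self):
        surv = _survival([1, 2], [1, 1], samples=["s0", "s1"])
        with pytest.raises(ValidationError, match="s2"):
            km_logrank(_assignment([1, 2, 2], samples=["s0", "s1", "s2"]), surv)


class TestSelectK:
    def test_single_k_range_returns_that_k(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.choice([-1, 0], size=(20, 5)))
        surv = _survival(rng.exponential(1, 20), np.ones(20, dtype=int))
        sel = select_k(m, surv, k_range=[4], restarts=5, seed=0)
        assert sel.best_k == 4
        assert set(sel.p_by_k) == {4}


class TestIdentifyPoorCluster:
    def test_planted_high_hazard_cluster_found(self):
        rng = np.random.default_rng(2)
        times = np.concatenate([rng.exponential(1 / 3.0, 30),
                                rng.exponential(3.0, 60)])
        surv = _survival(times, np.ones(90, dtype=int))
        res = identify_poor_cluster(_assignment([1] * 30 + [2] * 60), surv)
        assert res.cluster == 1

    def test_identical_survival_flags_no_cluster(self):
        surv = _survival([5, 8, 12, 5, 8, 12], [1, 1, 0, 1, 1, 0])
        res = identify_poor_cluster(_assignment([1, 1, 1, 2, 2, 2]), surv)
        assert res.cluster is None and not res.found

    def test_most_significant_adverse_cluster_wins(self):
        """Among two significant adverse clusters, the stronger association wins."""
        rng = np.random.default_rng(3)
        times = np.concatenate([
            rng.exponential(0.2, 40),   # clearly poor, strong evidence
            rng.exponential(1.0, 15),   # mildly poor
            rng.exponential(5.0, 100),  # good prognosis
        ])
        surv = _survival(times, np.ones(155, dtype=int))
        res = identify_poor_cluster(_assignment([1] * 40 + [2] * 15 + [3] * 100), surv)
        assert res.cluster == 1


class TestDARs:
    def test_perfectly_separating_reaction(self):
        """Active in all poor, absent in all rest: huge t, means 0 and -1."""
        poor = np.zeros(500, dtype=bool)
        poor[:50] = True
        col = np.where(poor, 0, -1)
        noise = np.tile([-1, 0], 250)  # uninformative second column
        m = _matrix(np.column_stack([col, noise]))
        dars = find_dars(m, poor)
        assert dars["reaction_id"].tolist() == ["r0"]
        row = dars.iloc[0]
        assert row["mean_poor"] == 0.0 and row["mean_rest"] == -1.0
        assert row["adjusted_p"] < 1e-50

    def test_identical_distribution_not_a_dar(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.choice([-1, 0], size=(100, 5)))
        poor = np.zeros(100, dtype=bool)
        poor[:20] = True
        rng.shuffle(poor)
        # no association planted: nothing should survive Bonferroni
        assert len(find_dars(m, poor)) == 0

    def test_bonferroni_is_multiplication_capped_at_one(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.choice([-1, 0], size=(60, 100)))
        poor = np.zeros(60, dtype=bool)
        poor[:25] = True
        tests = dar_tests(m, poor)
        assert np.allclose(tests["adjusted_p"],
                           np.minimum(1.0, tests["raw_p"] * 100))
        assert (tests["adjusted_p"] >= tests["raw_p"]).all()

    def test_constant_reaction_gets_p_one(self):
        m = _matrix(np.full((40, 1), -1))
        poor = np.zeros(40, dtype=bool)
        poor[:10] = True
        tests = dar_tests(m, poor)
        assert tests["raw_p"].iloc[0] == 1.0

    def test_tiny_group_rejected(self):
        m = _matrix(np.zeros((5, 2)))
        poor = np.array([True, False, False, False, False])
        with pytest.raises(ValidationError):
            dar_tests(m, poor)

    def test_type_one_error_controlled_under_permutation(self):
        """Raw p<0.05 rate on label-permuted data stays near nominal."""
        rng = np.random.default_rng(4)
        m = _matrix(rng.choice([-1, 0], size=(120, 50)))
        poor = np.zeros(120, dtype=bool)
        poor[:30] = True
        rates = []
        for _ in range(100):
            perm = rng.permutation(poor)
            rates.append((dar_tests(m, perm)["raw_p"] < 0.05).mean())
        assert np.mean(rates) <= 0.06


class TestDAPs:
    def test_identical_columns_grouped(self):
        poor = np.array([True] * 10 + [False] * 30)
        coupled = np.where(poor, 0, -1)
        other = np.concatenate([[0] * 9, [-1], np.where(poor[10:], 0, -1)])
        m = _matrix(np.column_stack([coupled, coupled, other]),
                    reactions=["a", "b", "c"])
        dars = find_dars(m, poor)
        daps = group_daps(dars, m)
        sizes = sorted(len(d) for d in daps)
        assert sizes == [1, 2]
        big = next(d for d in daps if len(d) == 2)
        assert set(big.reaction_ids) == {"a", "b"}

    def test_columns_differing_in_one_sample_split(self):
        col_a = np.array([-1, -1, 0, 0])
        col_b = np.array([-1, 0, 0, 0])
        m = _matrix(np.column_stack([col_a, col_b]))
        dars = pd.DataFrame({"reaction_id": ["r0", "r1"],
                             "adjusted_p": [0.01, 0.01]})
        assert len(group_daps(dars, m)) == 2


class TestWilsonCI:
    @pytest.mark.parametrize("successes,n,lo_pct,hi_pct", [
        (106, 134, 71, 85),
        (96, 863, 9, 13),
        (82, 134, 53, 69),
    ])
    def test_rounds_to_published_style_intervals(self, successes, n, lo_pct, hi_pct):
        lo, hi = wilson_ci(successes, n)
        assert round(100 * lo) == lo_pct
        assert round(100 * hi) == hi_pct

    def test_closed_form_oracle(self):
        """Match the closed-form Wilson score interval."""
        z = stats.norm.ppf(0.975)
        for successes, n in [(106, 134), (0, 10), (7, 7), (3, 100)]:
            p = successes / n
            denom = 1 + z**2 / n
            center = (p + z**2 / (2 * n)) / denom
            half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
            lo, hi = wilson_ci(successes, n)
            assert lo == pytest.approx(max(0.0, center - half), abs=1e-10)
            assert hi == pytest.approx(min(1.0, center + half), abs=1e-10)

    def test_zero_successes_lower_bound_zero(self):
        lo, _ = wilson_ci(0, 10)
        assert lo == pytest.approx(0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            wilson_ci(5, 4)
        with pytest.raises(ValidationError):
            wilson_ci(-1, 4)


class TestDAPReport:
    def test_published_style_row_formatting(self):
        """106/134 vs 96/863 active renders as 79% (71–85%) | 11% (9–13%)."""
        from fluxscape.cohort import DAPGroup

        poor = np.zeros(997, dtype=bool)
        poor[:134] = True
        activity = np.full(997, -1, dtype=np.int8)
        activity[:106] = 0          # 106 active among the 134 poor
        activity[134:134 + 96] = 0  # 96 active among the 863 rest
        dap = DAPGroup(reaction_ids=("rx1",), activity=activity, adjusted_p=1e-70)
        report = dap_report([dap], poor)
        row = report.iloc[0]
        assert row["poor_pct_ci"] == "79% (71–85%)"
        assert row["rest_pct_ci"] == "11% (9–13%)"

    def test_fully_active_dap_hits_100(self):
        from fluxscape.cohort import DAPGroup

        poor = np.array([True] * 5 + [False] * 15)
        dap = DAPGroup(reaction_ids=("r",), activity=np.zeros(20, dtype=np.int8),
                       adjusted_p=0.01)
        row = dap_report([dap], poor).iloc[0]
        assert row["poor_pct_ci"].startswith("100%")
        assert row["rest_pct_ci"].endswith("100%)")

    def test_empty_dap_list_empty_table(self):
        assert dap_report([], np.array([True, False])).empty

    def test_sorted_by_adjusted_p(self):
        from fluxscape.cohort import DAPGroup

        poor = np.array([True] * 5 + [False] * 5)
        act = np.zeros(10, dtype=np.int8)
        daps = [DAPGroup(("a",), act, 0.04), DAPGroup(("b",), act, 0.001)]
        report = dap_report(daps, poor)
        assert report["reactions"].tolist() == ["b", "a"]
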