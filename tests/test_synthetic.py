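"""Synthetic cohort generator: network structure, detection noise, survival."""

import numpy as np
import pandas as pd
import pytest

from fluxscape import (
    CohortConfig,
    gebra_landscape,
    make_cohort,
    make_toy_gsmn,
    reaction_states,
    simulate_detection,
    simulate_survival,
)
from fluxscape.calls import call_presence
from fluxscape.exceptions import ValidationError
from fluxscape.synthetic import (
    MARKER_GATE_GENE,
    detection_to_frame,
    marker_reaction_ids,
)


class TestToyGSMN:
    def test_default_model_valid_and_feasible(self):
        from fluxscape import max_congruency_milp

        model = make_toy_gsmn()
        assert model.genes  # GPRs present
        # feasible with nothing silenced
        res = max_congruency_milp(model, [])
        assert res.status == "optimal"

    def test_marker_gate_absent_blocks_whole_chain(self):
        model = make_toy_gsmn()
        states = reaction_states(model, {MARKER_GATE_GENE: False})
        scape = gebra_landscape(model, states)
        by_id = dict(zip(model.reaction_ids, scape.states))
        for rid in marker_reaction_ids(5):
            assert by_id[rid] == -1
        # supply routes and maintenance unaffected
        assert by_id["DM_E"] == 0

    def test_marker_gate_present_chain_active(self):
        model = make_toy_gsmn()
        states = reaction_states(model, {MARKER_GATE_GENE: True})
        scape = gebra_landscape(model, states)
        by_id = dict(zip(model.reaction_ids, scape.states))
        assert all(by_id[rid] == 0 for rid in marker_reaction_ids(5))

    def test_route_silencing_switches_coupled_route(self):
        # both isozymes of one step absent -> the whole coupled route blocks
        model = make_toy_gsmn()
        states = reaction_states(
            model, {"g_pathEa_2": False, "g_pathEb_2": False})
        scape = gebra_landscape(model, states)
        by_id = dict(zip(model.reaction_ids, scape.states))
        assert (by_id["EX_N2"], by_id["TR2"], by_id["ACT2"], by_id["CONV2"]) \
            == (-1, -1, -1, -1)
        assert by_id["DM_E"] == 0

    def test_single_isozyme_absence_does_not_silence_route(self):
        model = make_toy_gsmn()
        states = reaction_states(model, {"g_pathEa_2": False})
        assert not states.states.any()

    def test_excessive_maintenance_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            make_toy_gsmn(n_pathways=2, maintenance_lb=1e6)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"poor_fraction": 0.0},
        {"poor_fraction": 1.0},
        {"presence_noise": 0.5},
        {"hazard_poor": 0.0},
        {"n_pathways": 1},
        {"marker_pathway_length": 1},
    ])
    def test_out_of_range_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CohortConfig(**kwargs)


class TestDetection:
    def test_zero_noise_labels_recoverable_from_gate_gene(self):
        config = CohortConfig(presence_noise=0.0, seed=3)
        model = make_toy_gsmn()
        samples, groups = simulate_detection(model, config)
        for sample, group in zip(samples, groups):
            present = call_presence(sample.detection_p)[MARKER_GATE_GENE]
            assert present == (group == 0)

    def test_same_seed_identical_cohort(self):
        config = CohortConfig(seed=11)
        model = make_toy_gsmn()
        a, ga = simulate_detection(model, config)
        b, gb = simulate_detection(model, config)
        assert np.array_equal(ga, gb)
        for sa, sb in zip(a, b):
            assert sa.detection_p == sb.detection_p

    def test_maximal_noise_decouples_gate_from_labels(self):
        """Near noise 0.5 the gate-gene call carries ~no label information."""
        model = make_toy_gsmn()
        agreements = []
        for seed in range(10):
            config = CohortConfig(presence_noise=0.499, seed=seed)
            samples, groups = simulate_detection(model, config)
            calls = np.array([call_presence(s.detection_p)[MARKER_GATE_GENE]
                              for s in samples])
            agreements.append((calls == (groups == 0)).mean())
        assert abs(np.mean(agreements) - 0.5) < 0.05

    def test_zero_noise_state_fractions_match_planted_program(self):
        """Transcript-derived -1 states are exactly the planted silencing."""
        from fluxscape import reaction_states
        from fluxscape.calls import call_presence

        config = CohortConfig(n_samples=30, presence_noise=0.0, seed=6)
        model = make_toy_gsmn()
        samples, groups = simulate_detection(model, config)
        for sample, group in zip(samples, groups):
            calls = call_presence(sample.detection_p)
            states = reaction_states(model, calls, sample.sample_id)
            # own route: TR and CONV carry GPRs (2 reactions); marker gate
            # reaction adds one more -1 for non-poor samples
            expected = 2 if group == 0 else 3
            assert (states.states == -1).sum() == expected

    def test_poor_group_count_matches_fraction(self):
        config = CohortConfig(n_samples=300, poor_fraction=0.13, seed=0)
        _, groups = simulate_detection(make_toy_gsmn(), config)
        assert (groups == 0).sum() == 39


class TestSurvival:
    def test_zero_censor_time_censors_everything(self):
        config = CohortConfig(censor_time=0.0, seed=0)
        surv = simulate_survival(np.array([True, False, False, False]), config)
        assert (surv["time"] == 0).all()
        assert (surv["event"] == 0).all()

    def test_median_ratio_tracks_hazard_ratio(self):
        """Exponential medians scale as 1/hazard: ratio ~= 1/3 at HR 3."""
        config = CohortConfig(hazard_poor=0.03, hazard_rest=0.01,
                              censor_time=1e9, seed=0)
        ratios = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            poor = np.array([True] * 200 + [False] * 200)
            surv = simulate_survival(poor, config, rng=rng)
            ratios.append(np.median(surv["time"][poor.tolist()])
                          / np.median(surv["time"][(~poor).tolist()]))
        assert abs(np.mean(ratios) - 1 / 3) < 0.05

    def test_null_hazards_give_uniform_logrank_p(self):
        """Equal hazards: log-rank p over replicates is ~Uniform(0,1)."""
        from scipy import stats

        from fluxscape import km_logrank
        from fluxscape.cohort import ClusterAssignment

        config = CohortConfig(hazard_poor=0.01, hazard_rest=0.01, seed=0)
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            poor = np.zeros(60, dtype=bool)
            poor[:20] = True
            surv = simulate_survival(poor, config, rng=rng)
            labels = pd.Series(np.where(poor, 1, 2), index=surv.index)
            assignment = ClusterAssignment(k=2, labels=labels, inertia=0.0)
            pvals.append(km_logrank(assignment, surv).overall_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMakeCohort:
    def test_bundle_written_to_disk(self, tmp_path):
        config = CohortConfig(n_samples=20, seed=5)
        model, samples, survival, groups = make_cohort(config, out_dir=tmp_path)
        assert (tmp_path / "model.tsv").exists()
        assert (tmp_path / "detection_p.tsv").exists()
        assert (tmp_path / "survival.tsv").exists()
        assert (tmp_path / "truth_labels.tsv").exists()
        config_echo = (tmp_path / "config.txt").read_text()
        assert "poor_fraction=0.13" in config_echo
        assert len(samples) == 20 == len(survival)

    def test_seed_changes_pvalues_not_model(self):
        a = make_cohort(CohortConfig(n_samples=10, seed=1))
        b = make_cohort(CohortConfig(n_samples=10, seed=2))
        assert a[0].reaction_ids == b[0].reaction_ids
        assert not detection_to_frame(a[1]).equals(detection_to_frame(b[1]))
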