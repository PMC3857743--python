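"""Goal-selectivity regression, F-I classification, epoch contrasts, waveforms."""

import numpy as np
import pandas as pd
import pytest

from spikestab.selectivity import (
    FIIndexTrace,
    NeuronLabel,
    SelectivityTrace,
    TrialDataset,
    classify_neuron,
    classify_waveform,
    epoch_variability,
    fi_index_trace,
    goal_selectivity_trace,
)
from spikestab.synth import CohortSpec, NeuronProfile, make_cohort, make_fi_neuron


def dataset_for(profile, trials, seed):
    spikes = make_fi_neuron(profile, trials, np.random.default_rng(seed))
    return TrialDataset(trials=trials, spikes=spikes)


class TestGoalSelectivityTrace:
    def test_final_goal_driven_neuron_scores_fgs_not_igs(self, trial_table):
        ds = dataset_for(
            NeuronProfile("n", "final-goal", amplitude=10.0, preferred_final=(1, 1)),
            trial_table, seed=1,
        )
        sel = goal_selectivity_trace(ds, "n")
        assert np.max(sel.fgs) > 1.0
        assert np.mean(sel.fgs >= 1.0) > 0.5
        assert np.mean(sel.igs >= 1.0) < 0.2

    def test_null_neuron_exceedance_is_calibrated_to_5_percent(self, trial_table):
        """Normalisation check: under no selectivity, P(FGS or IGS >= 1) ~ 5% per bin."""
        exceed = []
        for seed in range(12):
            ds = dataset_for(
                NeuronProfile(f"n{seed}", "unselective", amplitude=0.0), trial_table, seed
            )
            sel = goal_selectivity_trace(ds, f"n{seed}")
            exceed.extend([sel.fgs >= 1.0, sel.igs >= 1.0])
        rate = np.mean(np.concatenate(exceed))
        assert 0.025 < rate < 0.085

    def test_zero_spikes_give_zero_selectivity(self, trial_table):
        ds = TrialDataset(
            trials=trial_table,
            spikes=pd.DataFrame(
                dict(neuron_id=["n"], trial_id=[trial_table["trial_id"].iloc[0]],
                     spike_time_ms=[-900.0])
            ),
        )
        sel = goal_selectivity_trace(ds, "missing-neuron")
        assert np.all(sel.fgs == 0.0) and np.all(sel.igs == 0.0)

    def test_confounded_goals_raise_diagnostic(self, trial_table):
        trials = trial_table.copy()
        trials["imm_goal_h"] = trials["final_goal_h"]  # perfectly collinear
        ds = dataset_for(NeuronProfile("n", "unselective", amplitude=0.0), trials, 3)
        with pytest.raises(ValueError, match="final_goal_h.*imm_goal_h"):
            goal_selectivity_trace(ds, "n")

    def test_single_category_factor_rejected(self, trial_table):
        trials = trial_table.copy()
        trials["final_goal_v"] = 1
        ds = TrialDataset(trials=trials, spikes=pd.DataFrame(
            dict(neuron_id=["n"], trial_id=[trials["trial_id"].iloc[0]],
                 spike_time_ms=[0.0])))
        with pytest.raises(ValueError, match="final_goal_v"):
            goal_selectivity_trace(ds, "n")


class TestFIIndex:
    def test_pure_cases(self):
        centers = np.array([50.0, 150.0, 250.0])
        trace = SelectivityTrace(
            bin_centers=centers,
            fgs=np.array([2.0, 0.0, 1.5]),
            igs=np.array([0.0, 2.0, 1.5]),
        )
        fi = fi_index_trace(trace)
        assert fi.index[0] == -1.0 and fi.index[1] == 1.0 and fi.index[2] == 0.0

    def test_undefined_where_both_zero_and_always_bounded(self, trial_table):
        trace = SelectivityTrace(
            bin_centers=np.array([50.0]), fgs=np.zeros(1), igs=np.zeros(1)
        )
        assert np.isnan(fi_index_trace(trace).index[0])
        for seed in range(5):
            ds = dataset_for(
                NeuronProfile("n", "F-I", transition_ms=1400.0), trial_table, seed
            )
            fi = fi_index_trace(goal_selectivity_trace(ds, "n"))
            finite = fi.index[np.isfinite(fi.index)]
            assert np.all(finite >= -1.0) and np.all(finite <= 1.0)


class TestClassifyNeuron:
    def test_fi_neuron_recovered_with_transition_inside_one_bin(self, trial_table):
        errors = []
        for seed in range(10):
            ds = dataset_for(
                NeuronProfile("n", "F-I", transition_ms=1400.0,
                              preferred_final=(1, 1), preferred_imm=(-1, 1)),
                trial_table, seed,
            )
            sel = goal_selectivity_trace(ds, "n")
            label = classify_neuron(sel, fi_index_trace(sel), "n")
            assert label.functional_class == "F-I"
            errors.append(abs(label.transition_time_ms - 1400.0))
        assert np.median(errors) <= 100.0

    def test_sustained_final_goal_neuron_recovered(self, trial_table):
        hits = 0
        for seed in range(10):
            ds = dataset_for(
                NeuronProfile("n", "final-goal", preferred_final=(-1, -1)), trial_table, seed
            )
            sel = goal_selectivity_trace(ds, "n")
            hits += classify_neuron(sel, fi_index_trace(sel), "n").functional_class == "final-goal"
        assert hits >= 9

    def test_unselective_neurons_are_other_in_95_percent_of_runs(self, trial_table):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            ds = dataset_for(
                NeuronProfile("n", "unselective", amplitude=0.0), trial_table, seed
            )
            sel = goal_selectivity_trace(ds, "n")
            hits += classify_neuron(sel, fi_index_trace(sel), "n").functional_class == "other"
        assert hits / n_runs >= 0.95

    def test_never_both_fi_and_final_goal_and_label_invariant(self):
        with pytest.raises(ValueError):
            NeuronLabel("n", "final-goal", transition_time_ms=100.0)
        with pytest.raises(ValueError):
            NeuronLabel("n", "F-I", transition_time_ms=None)

    def test_unequal_traces_rejected(self):
        sel = SelectivityTrace(np.array([50.0]), np.zeros(1), np.zeros(1))
        fi = FIIndexTrace(np.array([50.0, 150.0]), np.zeros(2))
        with pytest.raises(ValueError):
            classify_neuron(sel, fi)


class TestEpochVariability:
    @pytest.fixture(scope="class")
    def fi_cohort(self):
        """148 F-I neurons with the kappa dip confined to the pre-transition window."""
        ds, truth, _ = make_cohort(
            CohortSpec(n_fi=148, n_final_goal=0, n_unselective=0, n_trials=200, seed=11)
        )
        labels = [
            NeuronLabel(r.neuron_id, "F-I", transition_time_ms=r.transition_ms)
            for r in truth.itertuples()
        ]
        return ds, labels

    def test_pre_transition_elevation_and_post_transition_drop(self, fi_cohort):
        ds, labels = fi_cohort
        res = epoch_variability(ds, labels)
        pop = res["population"]
        assert pop["delay_before_transition"]["mean_delta"] > 0
        assert (
            pop["delay_before_transition"]["mean_delta"]
            > pop["delay_after_transition"]["mean_delta"]
        )
        assert res["contrasts"]["start_display_vs_delay_before_transition"]["p_value"] < 0.01
        assert (
            res["contrasts"]["delay_before_transition_vs_delay_after_transition"]["p_value"]
            < 0.01
        )

    def test_constant_kappa_cohort_shows_no_elevation(self):
        """Null schedule: the pre-transition contrast is not significantly positive."""
        from scipy import stats

        flat = 0
        for seed in (21, 22, 23):
            ds, truth, _ = make_cohort(
                CohortSpec(n_fi=40, n_final_goal=0, n_unselective=0, n_trials=120,
                           seed=seed, kappa_dip=None)
            )
            labels = [
                NeuronLabel(r.neuron_id, "F-I", transition_time_ms=r.transition_ms)
                for r in truth.itertuples()
            ]
            res = epoch_variability(ds, labels)
            table = res["per_neuron"][["start_display", "delay_before_transition"]].dropna()
            p = stats.ttest_rel(
                table["delay_before_transition"], table["start_display"],
                alternative="greater",
            ).pvalue
            flat += p > 0.05
        assert flat >= 2

    def test_neurons_without_transition_are_excluded_with_count(self, fi_cohort):
        ds, labels = fi_cohort
        mixed = labels[:5] + [NeuronLabel("ghost", "other")]
        res = epoch_variability(ds, mixed)
        assert res["n_excluded"] == 1
        assert np.isnan(res["per_neuron"].loc["ghost", "delay_after_transition"])

    def test_empty_epoch_yields_missing_value_not_crash(self, fi_cohort):
        ds, labels = fi_cohort
        res = epoch_variability(ds, labels[:3], epochs={"pre_task": (-5000.0, -4900.0)})
        assert res["per_neuron"]["pre_task"].isna().all()


class TestClassifyWaveform:
    def test_bimodal_norms_classified_correctly(self):
        rng = np.random.default_rng(5)
        n = 200
        inhibitory = rng.random(n) < 0.3
        norms = np.where(inhibitory, rng.normal(0.3, 0.03, n), rng.normal(0.8, 0.05, n))
        angle = rng.normal(np.pi / 4, 0.05, n)
        features = pd.DataFrame(
            dict(trough_peak_ms=norms * np.cos(angle), onset_return_ms=norms * np.sin(angle))
        )
        res = classify_waveform(features)
        predicted_inh = res["labels"] == "inhibitory"
        assert np.mean(predicted_inh == inhibitory) >= 0.99
        assert not res["low_separation"]

    def test_two_waveforms_split_one_per_class(self):
        features = pd.DataFrame(
            dict(trough_peak_ms=[0.14, 0.7], onset_return_ms=[0.14, 0.7])
        )
        res = classify_waveform(features)
        assert sorted(res["labels"]) == ["excitatory", "inhibitory"]

    def test_overlapping_norms_warn_low_separation(self):
        rng = np.random.default_rng(6)
        norms = rng.normal(0.5, 0.05, 100)
        features = pd.DataFrame(
            dict(trough_peak_ms=norms * 0.7, onset_return_ms=norms * 0.7)
        )
        res = classify_waveform(features)
        assert res["low_separation"]

    def test_identical_norms_rejected(self):
        features = pd.DataFrame(dict(trough_peak_ms=[0.5] * 3, onset_return_ms=[0.5] * 3))
        with pytest.raises(ValueError):
            classify_waveform(features)
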