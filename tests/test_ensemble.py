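"""Population matrix stacking, PCA trajectories and bin-by-bin correlations."""

import numpy as np
import pytest
from scipy import stats

from neuropor import (
    BinnedResponse,
    PopulationMatrix,
    StimulusProtocol,
    binwise_correlation,
    build_population_matrix,
    cross_condition_correlation,
    pca_trajectories,
)

PROTO = StimulusProtocol()


def _resp(counts, condition):
    return BinnedResponse(counts=counts, bin_width=0.2, n_trials=5, condition=condition)


def _stacked(rng, n_units=82, n_bins=200):
    binned = {}
    for i in range(n_units):
        binned[f"u{i:03d}"] = {
            "control": _resp(rng.poisson(1.0, n_bins).astype(float), "control"),
            "5HT": _resp(rng.poisson(1.0, n_bins).astype(float), "5HT"),
        }
    return build_population_matrix(binned, protocol=PROTO)


class TestBuildPopulationMatrix:
    def test_study_dimensions(self, rng):
        # 82 neuron-odor combinations x 2 conditions, 200 bins of 200 ms
        pop = _stacked(rng)
        assert pop.values.shape == (164, 200)
        assert [lab[1] for lab in pop.unit_labels[:82]] == ["control"] * 82
        assert [lab[1] for lab in pop.unit_labels[82:]] == ["5HT"] * 82

    def test_single_unit_single_condition(self, rng):
        binned = {"u0": {"control": _resp(rng.poisson(1.0, 200).astype(float), "control")}}
        pop = build_population_matrix(binned, conditions=("control",), protocol=PROTO)
        assert pop.values.shape == (1, 200)

    def test_missing_condition_rejected(self, rng):
        binned = {"u0": {"control": _resp(np.zeros(200), "control")}}
        with pytest.raises(KeyError):
            build_population_matrix(binned, protocol=PROTO)

    def test_column_sums_conserve_spikes(self, small_experiment, small_config):
        from neuropor import bin_spikes

        proto = small_config.protocol
        binned = {}
        totals = {"control": 0, "5HT": 0}
        for condition in ("control", "5HT"):
            for (pn, odor), trains in small_experiment.recordings(condition).items():
                binned.setdefault(f"{pn}|{odor}", {})[condition] = bin_spikes(
                    trains, 0.2, proto.trial_duration
                )
                totals[condition] += sum(len(t) for t in trains)
        pop = build_population_matrix(binned, protocol=proto)
        for condition in ("control", "5HT"):
            rows = pop.condition_rows(condition)
            assert pop.values[rows].sum() * proto.n_trials == pytest.approx(
                totals[condition]
            )


class TestPCATrajectories:
    def test_rank_one_matrix(self):
        u = np.array([1.0, 2.0, 3.0])
        t = np.linspace(0, 1, 8)
        pop = PopulationMatrix(
            values=np.outer(u, t), unit_labels=[("a", "c"), ("b", "c"), ("c", "c")],
            bin_width=0.125, protocol=StimulusProtocol(trial_duration=1.0,
                                                       odor_onset=0.25,
                                                       odor_duration=0.25),
        )
        traj = pca_trajectories(pop)
        assert traj.explained_variance_ratio[0] == pytest.approx(1.0)
        assert traj.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_oracle_up_to_sign(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(5, 8))
        pop = PopulationMatrix(
            values=X, unit_labels=[(f"u{i}", "c") for i in range(5)], bin_width=0.1,
            protocol=StimulusProtocol(trial_duration=0.8, odor_onset=0.2,
                                      odor_duration=0.2),
        )
        traj = pca_trajectories(pop)
        oracle = PCA(n_components=2).fit(X.T)
        coords = oracle.transform(X.T)
        for k in range(2):
            sign = np.sign(np.dot(coords[:, k], traj.coords[:, k]))
            np.testing.assert_allclose(traj.coords[:, k], sign * coords[:, k],
                                       atol=1e-10)
        np.testing.assert_allclose(
            traj.explained_variance_ratio, oracle.explained_variance_ratio_[:2],
            atol=1e-12,
        )

    def test_duplicating_rows_preserves_trajectory_shape(self, rng):
        X = rng.normal(size=(6, 10))
        def traj_of(values):
            labels = [(f"u{i}", "c") for i in range(values.shape[0])]
            pop = PopulationMatrix(
                values=values, unit_labels=labels, bin_width=0.1,
                protocol=StimulusProtocol(trial_duration=1.0, odor_onset=0.2,
                                          odor_duration=0.2),
            )
            return pca_trajectories(pop).coords

        # direction of the trajectory is invariant; scale may change
        a = traj_of(X)
        b = traj_of(np.vstack([X, X]))
        for k in range(2):
            ca = a[:, k] / np.linalg.norm(a[:, k])
            cb = b[:, k] / np.linalg.norm(b[:, k])
            assert abs(np.dot(ca, cb)) == pytest.approx(1.0, abs=1e-10)

    def test_rank_zero_rejected(self):
        pop = PopulationMatrix(
            values=np.ones((3, 8)), unit_labels=[(f"u{i}", "c") for i in range(3)],
            bin_width=0.1, protocol=StimulusProtocol(trial_duration=0.8,
                                                     odor_onset=0.2,
                                                     odor_duration=0.2),
        )
        with pytest.raises(ValueError):
            pca_trajectories(pop)


class TestBinwiseCorrelation:
    def test_identical_and_anticorrelated_bins(self, rng):
        x = rng.normal(size=10)
        values = np.column_stack([x, x, -x + 3.0])
        pop = PopulationMatrix(
            values=values, unit_labels=[(f"u{i}", "c") for i in range(10)],
            bin_width=0.1, protocol=StimulusProtocol(trial_duration=0.3,
                                                     odor_onset=0.1,
                                                     odor_duration=0.1),
        )
        corr = binwise_correlation(pop)
        assert corr.C[0, 1] == pytest.approx(1.0)
        assert corr.C[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr.C), 1.0)

    def test_matches_pearson_oracle(self, rng):
        values = rng.poisson(2.0, size=(82, 10)).astype(float)
        pop = PopulationMatrix(
            values=values, unit_labels=[(f"u{i}", "c") for i in range(82)],
            bin_width=0.1, protocol=StimulusProtocol(trial_duration=1.0,
                                                     odor_onset=0.2,
                                                     odor_duration=0.2),
        )
        corr = binwise_correlation(pop)
        for i in range(10):
            for j in range(10):
                expected = stats.pearsonr(values[:, i], values[:, j]).statistic
                assert corr.C[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(corr.C, corr.C.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(corr.C)
        assert eigvals.min() > -1e-8

    def test_zero_variance_bin_marked_undefined(self, rng):
        values = rng.normal(size=(8, 4))
        values[:, 2] = 5.0
        pop = PopulationMatrix(
            values=values, unit_labels=[(f"u{i}", "c") for i in range(8)],
            bin_width=0.1, protocol=StimulusProtocol(trial_duration=0.4,
                                                     odor_onset=0.1,
                                                     odor_duration=0.1),
        )
        corr = binwise_correlation(pop)
        assert not corr.defined[2]
        assert np.isnan(corr.C[2, :]).all() and np.isnan(corr.C[:, 2]).all()
        assert corr.defined[[0, 1, 3]].all()

    def test_needs_two_units(self):
        pop = PopulationMatrix(
            values=np.ones((1, 4)), unit_labels=[("u0", "c")], bin_width=0.1,
            protocol=StimulusProtocol(trial_duration=0.4, odor_onset=0.1,
                                      odor_duration=0.1),
        )
        with pytest.raises(ValueError):
            binwise_correlation(pop)


class TestCrossConditionStructure:
    def test_shared_tuning_correlates_on_window_not_spontaneous(self, rng):
        # treatment scales a shared evoked pattern; spontaneous activity is
        # independent noise -> ON-ON blocks correlate, spontaneous blocks do not
        n_units, n_bins = 60, 200
        tuning = rng.gamma(2.0, 2.0, size=n_units)
        on_sl = PROTO.window_bins(PROTO.on_window, 0.2)
        binned = {}
        for i in range(n_units):
            ctrl = rng.normal(0, 0.3, n_bins).clip(0)
            treat = rng.normal(0, 0.3, n_bins).clip(0)
            ctrl[on_sl] += tuning[i]
            treat[on_sl] += 1.5 * tuning[i]
            binned[f"u{i:02d}"] = {
                "control": _resp(ctrl, "control"),
                "5HT": _resp(treat, "5HT"),
            }
        pop = build_population_matrix(binned, protocol=PROTO)
        xcorr = cross_condition_correlation(pop)
        base_sl = PROTO.window_bins(PROTO.baseline_window, 0.2)
        assert xcorr.mean_block(on_sl, on_sl) > 0.8
        assert abs(xcorr.mean_block(base_sl, base_sl)) < 0.1
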