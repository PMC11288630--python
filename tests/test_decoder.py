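"""Signed linear decoder: design/target assembly, least-squares fit,
ensemble segregation, prediction and the uniform-amplification experiment."""

import numpy as np
import pytest
from scipy import linalg

from neuropor import (
    DesignMatrix,
    PORDecoder,
    StimulusProtocol,
    SyntheticConfig,
    build_design_from_binned,
    build_target,
    fit_weights,
    generate_experiment,
    order_units_by_contrast,
    segregate_ensembles,
)
from neuropor.decoder import DecoderError, TargetVector
from neuropor.spikes import BinnedResponse
from neuropor.synth import ON, expected_stimulus_counts

PROTO = StimulusProtocol()


def _design_from_arrays(blocks_by_odor, bin_width=0.05, protocol=PROTO):
    """blocks_by_odor: {odor: units x bins array}"""
    odors = tuple(blocks_by_odor)
    n_units = next(iter(blocks_by_odor.values())).shape[0]
    binned = {
        f"u{i:03d}": {
            odor: BinnedResponse(counts=blocks_by_odor[odor][i], bin_width=bin_width,
                                 n_trials=5, odor=odor)
            for odor in odors
        }
        for i in range(n_units)
    }
    return build_design_from_binned(binned, odors, protocol=protocol)


def _random_design(rng, n_units=6, odors=("HEX", "BZA", "LOOL")):
    blocks = {o: rng.poisson(1.0, size=(n_units, 800)).astype(float) for o in odors}
    return _design_from_arrays(blocks), blocks


class TestBuildDesign:
    def test_study_dimensions(self, rng):
        design, _ = _random_design(rng, n_units=89)
        assert design.X.shape == (89, 2400)
        assert design.n_bins_per_odor == 800

    def test_small_cardinality(self, rng):
        blocks = {"HEX": rng.poisson(1.0, size=(2, 800)).astype(float)}
        design = _design_from_arrays(blocks)
        assert design.X.shape == (2, 800)

    def test_block_slices_equal_single_odor_matrices(self, rng):
        design, blocks = _random_design(rng)
        for odor, block in blocks.items():
            np.testing.assert_array_equal(design.block(odor), block)

    def test_unit_mismatch_rejected(self, rng):
        binned = {
            "u0": {"HEX": BinnedResponse(counts=np.zeros(800), bin_width=0.05, n_trials=5)},
            "u1": {"BZA": BinnedResponse(counts=np.zeros(800), bin_width=0.05, n_trials=5)},
        }
        with pytest.raises(DecoderError):
            build_design_from_binned(binned, ("HEX", "BZA"))


class TestBuildTarget:
    def test_centered_null_is_all_zero(self, rng):
        design, _ = _random_design(rng)
        target = build_target({o: 0.43 for o in design.odors}, 0.43, design)
        assert not target.y.any()

    def test_study_probabilities_give_block_offsets(self, rng):
        design, _ = _random_design(rng)
        probs = {"HEX": 0.62, "BZA": 0.40, "LOOL": 0.29}
        target = build_target(probs, 0.43, design)
        stim = design.stimulus_bins()
        for k, (odor, offset) in enumerate(
            [("HEX", 0.19), ("BZA", -0.03), ("LOOL", -0.14)]
        ):
            block = target.y[k * 800 : (k + 1) * 800]
            np.testing.assert_allclose(block[stim], offset, atol=1e-12)
            outside = np.ones(800, bool)
            outside[stim] = False
            assert not block[outside].any()

    def test_nonzero_count_is_stimulus_mask_size(self, rng):
        design, _ = _random_design(rng)
        target = build_target({"HEX": 0.6, "BZA": 0.5, "LOOL": 0.3}, 0.43, design)
        # 3 odors x 4 s pulse / 50 ms bins
        assert np.count_nonzero(target.y) == 3 * 80
        assert target.stimulus_mask.sum() == 3 * 80

    def test_probability_bounds_enforced(self, rng):
        design, _ = _random_design(rng)
        with pytest.raises(DecoderError):
            build_target({o: 1.2 for o in design.odors}, 0.43, design)


class TestFitWeights:
    def test_null_target_gives_null_weights(self, rng):
        design, _ = _random_design(rng)
        target = build_target({o: 0.43 for o in design.odors}, 0.43, design)
        res = fit_weights(design, target)
        np.testing.assert_allclose(res.weights, 0.0, atol=1e-12)

    def test_orthogonal_rows_isolate_coefficients(self):
        X = np.zeros((3, 12))
        X[0, 0:4] = 1.0
        X[1, 4:8] = 1.0
        X[2, 8:12] = 1.0
        y = 3.0 * X[1]
        proto = StimulusProtocol(trial_duration=0.6, odor_onset=0.1, odor_duration=0.2)
        design = DesignMatrix(X=X, odors=("A",), unit_ids=("u0", "u1", "u2"),
                              bin_width=0.05, protocol=proto)
        target = TargetVector(y=y, stimulus_mask=y != 0, grand_mean_por=0.5,
                              por_probs={"A": 0.5})
        res = fit_weights(design, target)
        np.testing.assert_allclose(res.weights, [0.0, 3.0, 0.0], atol=1e-10)

    def test_matches_svd_oracle_on_random_systems(self, rng):
        for _ in range(50):
            n_units = rng.integers(2, 8)
            n_cols = rng.integers(n_units, 30)
            X = rng.normal(size=(n_units, n_cols))
            y = rng.normal(size=n_cols)
            proto = StimulusProtocol(trial_duration=n_cols * 0.05,
                                     odor_onset=0.05, odor_duration=0.05)
            design = DesignMatrix(X=X, odors=("A",),
                                  unit_ids=tuple(f"u{i}" for i in range(n_units)),
                                  bin_width=0.05, protocol=proto)
            target = TargetVector(y=y, stimulus_mask=np.ones_like(y, bool),
                                  grand_mean_por=0.5, por_probs={"A": 0.5})
            res = fit_weights(design, target)
            oracle, *_ = linalg.lstsq(X.T, y, lapack_driver="gelsd")
            assert np.linalg.norm(res.weights - oracle) <= 1e-10 * max(
                1.0, np.linalg.norm(oracle)
            )

    def test_residual_orthogonality(self, rng):
        design, _ = _random_design(rng, n_units=8)
        target = build_target({"HEX": 0.62, "BZA": 0.40, "LOOL": 0.29}, 0.43, design)
        res = fit_weights(design, target)
        grad = design.X @ res.resid
        scale = np.linalg.norm(design.X @ target.y)
        assert np.linalg.norm(grad) <= 1e-8 * max(scale, 1.0)

    def test_dimension_mismatch_rejected(self, rng):
        design, _ = _random_design(rng)
        target = TargetVector(y=np.zeros(10), stimulus_mask=np.zeros(10, bool),
                              grand_mean_por=0.4, por_probs={})
        with pytest.raises(DecoderError):
            PORDecoder(design, target)


class TestEnsemblesAndPrediction:
    def _fitted(self, rng):
        design, _ = _random_design(rng, n_units=8)
        target = build_target({"HEX": 0.62, "BZA": 0.40, "LOOL": 0.29}, 0.43, design)
        return fit_weights(design, target)

    def test_sign_partition(self, rng):
        res = self._fitted(rng)
        res.weights = np.array([1.0, -2.0, 0.0, 0.5, -0.5, 0.0, 3.0, -1.0])
        ens = segregate_ensembles(res)
        assert set(ens["positive"]) == {"u000", "u003", "u006"}
        assert set(ens["negative"]) == {"u001", "u004", "u007"}
        assert set(ens["zero"]) == {"u002", "u005"}

    def test_flipping_target_flips_ensembles(self, rng):
        design, _ = _random_design(rng, n_units=8)
        probs = {"HEX": 0.62, "BZA": 0.40, "LOOL": 0.29}
        flipped = {o: 2 * 0.43 - p for o, p in probs.items()}  # mirror around mean
        res = fit_weights(design, build_target(probs, 0.43, design))
        res_f = fit_weights(design, build_target(flipped, 0.43, design))
        np.testing.assert_allclose(res_f.weights, -res.weights, atol=1e-10)

    def test_zero_weights_predict_grand_mean(self, rng):
        res = self._fitted(rng)
        res.weights = np.zeros_like(res.weights)
        block = res.model.design.block("HEX")
        assert res.predict_por(block) == pytest.approx(0.43)

    def test_prediction_linear_in_response(self, rng):
        res = self._fitted(rng)
        block = res.model.design.block("HEX")
        base = res.predict_por(block) - res.grand_mean_por
        scaled = res.predict_por(2.5 * block) - res.grand_mean_por
        assert scaled == pytest.approx(2.5 * base)

    def test_in_sample_prediction_matches_up_to_residual(self, rng):
        res = self._fitted(rng)
        stim = res.model.design.stimulus_bins()
        for k, odor in enumerate(res.model.design.odors):
            pred, obs = res.predicted_vs_observed()[odor]
            block_resid = res.resid[k * 800 : (k + 1) * 800][stim]
            assert pred - obs == pytest.approx(-np.mean(block_resid), abs=1e-12)


class TestAmplification:
    def _fitted(self, rng):
        design, _ = _random_design(rng, n_units=8)
        target = build_target({"HEX": 0.62, "BZA": 0.40, "LOOL": 0.29}, 0.43, design)
        return fit_weights(design, target)

    def test_identity_gain_changes_nothing(self, rng):
        res = self._fitted(rng)
        deltas = res.amplification_experiment(1.0)
        assert all(d == 0.0 for d in deltas.values())

    def test_linear_in_gain_minus_one(self, rng):
        res = self._fitted(rng)
        d15 = res.amplification_experiment(1.5)
        d20 = res.amplification_experiment(2.0)
        for odor in d15:
            assert d20[odor] == pytest.approx(2.0 * d15[odor])

    def test_sign_equals_net_projection(self, rng):
        res = self._fitted(rng)
        for odor, delta in res.amplification_experiment(1.5).items():
            proj = res._net_projection(res.model.design.block(odor))
            assert np.sign(delta) == np.sign(proj)

    def test_shrinking_gain_rejected(self, rng):
        res = self._fitted(rng)
        with pytest.raises(DecoderError):
            res.amplification_experiment(0.9)


class TestOrderUnitsByContrast:
    def test_simple_and_tie_cases(self):
        blocks = {"HEX": np.zeros((3, 800)), "LOOL": np.zeros((3, 800))}
        stim = slice(200, 280)
        blocks["HEX"][0, stim] = 3.0
        blocks["LOOL"][1, stim] = 1.0
        # contrasts: u0 = +3, u1 = -1, u2 = 0 -> order u0, u2, u1
        design = _design_from_arrays(blocks)
        order = order_units_by_contrast(design, "HEX", "LOOL")
        assert list(order) == [0, 2, 1]

    def test_ties_break_by_unit_id(self, rng):
        blocks = {"HEX": np.ones((4, 800)), "LOOL": np.ones((4, 800))}
        design = _design_from_arrays(blocks)
        order = order_units_by_contrast(design, "HEX", "LOOL")
        assert list(order) == [0, 1, 2, 3]

    def test_matches_bruteforce_sort(self, rng):
        design, blocks = _random_design(rng, n_units=12)
        stim = design.stimulus_bins()
        contrast = blocks["HEX"][:, stim].max(axis=1) - blocks["LOOL"][:, stim].max(axis=1)
        order = order_units_by_contrast(design, "HEX", "LOOL")
        expected = sorted(range(12), key=lambda i: (-contrast[i], design.unit_ids[i]))
        assert list(order) == expected

    def test_missing_odor_rejected(self, rng):
        design, _ = _random_design(rng)
        with pytest.raises(DecoderError):
            order_units_by_contrast(design, "HEX", "AMN")


class TestParameterRecovery:
    def test_noiseless_expected_rates_recover_true_probabilities(self):
        cfg = SyntheticConfig(seed=17)
        from neuropor import build_ground_truth

        truth = build_ground_truth(cfg)
        # noiseless design: every stimulus bin carries the expected count,
        # every other bin the baseline count
        R = expected_stimulus_counts(cfg, truth.response_type_map, truth.base_rates)
        base = truth.base_rates * cfg.decoder_bin_width
        blocks = {}
        stim = PROTO.window_bins(PROTO.on_window, cfg.decoder_bin_width)
        for j, odor in enumerate(cfg.odor_names):
            block = np.tile(base[:, None], (1, 800))
            block[:, stim] = R[:, j][:, None]
            blocks[odor] = block
        design = _design_from_arrays(blocks, bin_width=cfg.decoder_bin_width)
        probs = {o.name: o.target_por for o in cfg.odor_set}
        res = fit_weights(design, build_target(probs, cfg.grand_mean_por, design))
        preds = {o: res.predicted_vs_observed()[o][0] for o in cfg.odor_names}
        rmse = np.sqrt(np.mean([(preds[o] - probs[o]) ** 2 for o in cfg.odor_names]))
        assert rmse < 0.02

    def test_sign_recovery_on_sampled_data(self, small_config):
        exp = generate_experiment(small_config, conditions=("control",))
        recs = {}
        for (pn, odor), trains in exp.recordings("control").items():
            recs.setdefault(pn, {})[odor] = trains
        from neuropor import por_probability

        probs = {o: por_probability(exp.por[(o, "control")]) for o in
                 small_config.odor_names}
        res = PORDecoder.from_recordings(
            recs, probs, grand_mean=small_config.grand_mean_por,
            protocol=small_config.protocol,
        ).fit()
        w_true = exp.truth.true_weights
        strong = np.abs(w_true) > np.median(np.abs(w_true))
        agreement = np.mean(np.sign(res.weights[strong]) == np.sign(w_true[strong]))
        assert agreement >= 0.8
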