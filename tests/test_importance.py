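"""Permutation importance, raw-pair attribution, network averages, voxel maps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gbmsurv.classifier import ClassifierConfig, train_nested_cv
from gbmsurv.connectome import ProbabilityMap, pair_labels
from gbmsurv.encoder import AutoencoderModel
from gbmsurv.errors import SchemaError, ShapeError
from gbmsurv.importance import (
    attribute_encoded_to_raw,
    network_average_weights,
    permutation_importance,
    project_to_voxels,
    raw_pair_importance,
)
from gbmsurv.synthetic import CLASSES


def one_informative_feature(n=90, seed=0):
    """Class fully determined by column 'age'; everything else is noise."""
    rng = np.random.default_rng(seed)
    per = n // 3
    labels = [cls for cls in CLASSES for _ in range(per)]
    age = np.concatenate([10.0 * g + rng.normal(0, 0.3, per) for g in range(3)])
    X = pd.DataFrame({
        "age": age,
        "sex": rng.integers(0, 2, n),
        "noise1": rng.standard_normal(n),
        "noise2": rng.standard_normal(n),
    }, index=pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject_id"))
    y = pd.Series(labels, index=X.index, name="survival_class")
    return X, y


FAST = ClassifierConfig(outer_folds=4, inner_folds=0, holdout_size=6,
                        alpha_grid=(1e-4,))


@pytest.fixture(scope="module")
def informative_run():
    X, y = one_informative_feature()
    ens = train_nested_cv(X, y, FAST, rng=0)
    return ens, X, y


def toy_encoder(W_enc, kept=None):
    h, d = W_enc.shape
    return AutoencoderModel(
        input_dim=d, hidden_dim=h,
        W_enc=np.asarray(W_enc, float), b_enc=np.zeros(h),
        W_dec=np.zeros((d, h)), b_dec=np.zeros(d),
        input_mean=np.zeros(d), input_sd=np.ones(d),
        training_log=[], best_epoch=0,
        kept_features=kept,
    )


class TestPermutationImportance:
    def test_informative_feature_dominates(self, informative_run):
        ens, X, y = informative_run
        imp = permutation_importance(ens, X, y, repeats=20, rng=0)
        assert imp["age"] > 0.4  # near baseline-minus-chance for a label-defining feature
        assert imp["age"] > 5 * max(imp["noise1"], imp["noise2"], 1e-6)

    def test_pure_noise_feature_near_zero(self, informative_run):
        ens, X, y = informative_run
        repeats = 200
        imp = permutation_importance(ens, X, y, repeats=repeats, rng=1)
        # permuting noise flips a handful of predictions at most; SE measured
        # across members' fold accuracies
        assert abs(imp["noise1"]) < 0.05

    def test_more_repeats_reduce_variance(self, informative_run):
        ens, X, y = informative_run
        few = [permutation_importance(ens, X, y, repeats=1, rng=s)["age"]
               for s in range(8)]
        many = [permutation_importance(ens, X, y, repeats=30, rng=s)["age"]
                for s in range(8)]
        assert np.mean(few) == pytest.approx(np.mean(many), abs=0.1)
        assert np.std(many) <= np.std(few) + 1e-9

    def test_feature_count_mismatch_rejected(self, informative_run):
        ens, X, y = informative_run
        with pytest.raises(ShapeError):
            permutation_importance(ens, X.iloc[:, :3], y, repeats=1, rng=0)


class TestAttribution:
    def test_one_hot_loading_routes_all_weight(self):
        labels = pair_labels(("SMD", "SMI", "CON"))  # 6 pairs
        W = np.zeros((2, 6))
        W[0, labels.index("SMDxCON")] = 0.7
        model = toy_encoder(W, kept=(0,))
        per_feature = pd.Series({"FC1": 0.2, "age": 0.5})
        pairw = attribute_encoded_to_raw(model, per_feature, labels)
        assert pairw["SMDxCON"] == pytest.approx(1.0)
        assert pairw.drop("SMDxCON").abs().max() == 0.0

    def test_uniform_weights_give_uniform_pairs(self):
        labels = pair_labels(("SMD", "SMI", "CON"))
        model = toy_encoder(np.full((3, 6), 0.5), kept=(0, 1, 2))
        per_feature = pd.Series({"FC1": 0.1, "FC2": 0.3, "FC3": 0.2})
        pairw = attribute_encoded_to_raw(model, per_feature, labels)
        np.testing.assert_allclose(pairw.to_numpy(), 1 / 6, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        labels = pair_labels(("SMD", "SMI", "CON", "AUD"))  # 10 pairs
        W = rng.standard_normal((5, 10))
        kept = (0, 2, 4)
        model = toy_encoder(W, kept=kept)
        imp = {f"FC{i + 1}": v for i, v in enumerate(rng.uniform(0, 1, 3))}
        pairw = attribute_encoded_to_raw(model, pd.Series(imp), labels)
        expected = np.zeros(10)
        for out_i, unit in enumerate(kept):
            for p in range(10):
                expected[p] += imp[f"FC{out_i + 1}"] * abs(W[unit, p])
        expected /= expected.sum()
        np.testing.assert_allclose(pairw.to_numpy(), expected, atol=1e-12)

    def test_missing_encoded_feature_is_schema_error(self):
        labels = pair_labels(("SMD", "SMI"))
        model = toy_encoder(np.ones((2, 3)), kept=(0, 1))
        with pytest.raises(SchemaError):
            attribute_encoded_to_raw(model, pd.Series({"FC1": 0.1}), labels)


@pytest.fixture(scope="module")
def encoded_run():
    # 6 raw "pairs"; pair SMDxCON (index 2) alone determines the class;
    # identity-like encoder exposes each pair as one code unit
    rng = np.random.default_rng(0)
    labels = pair_labels(("SMD", "SMI", "CON"))
    n = 90
    per = n // 3
    raw = rng.uniform(0.2, 0.4, (n, 6))
    raw[:, 2] = np.concatenate(
        [0.3 * g + rng.normal(0, 0.01, per) for g in range(3)]
    )
    conn = pd.DataFrame(
        raw, columns=labels,
        index=pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject_id"),
    )
    model = toy_encoder(np.eye(6), kept=tuple(range(6)))
    model.input_sd = raw.std(axis=0)
    model.input_mean = raw.mean(axis=0)
    y = pd.Series([cls for cls in CLASSES for _ in range(per)],
                  index=conn.index, name="survival_class")
    from gbmsurv.encoder import encode

    X = pd.DataFrame(encode(model, raw), index=conn.index,
                     columns=model.feature_names)
    X.insert(0, "sex", rng.integers(0, 2, n))
    X.insert(0, "age", rng.normal(60, 5, n))
    ens = train_nested_cv(X, y, FAST, rng=0)
    return ens, X, y, model, conn


class TestRawPairImportance:
    """Direct route: permute a raw pair, re-encode, re-score."""

    def test_informative_pair_takes_all_weight(self, encoded_run):
        ens, X, y, model, conn = encoded_run
        w = raw_pair_importance(ens, X, y, model, conn, repeats=5, rng=0)
        assert w.idxmax() == "SMDxCON"
        assert w["SMDxCON"] > 0.8  # weights normalized over pairs
        assert w.sum() == pytest.approx(1.0)

    def test_weights_nonnegative_and_normalized(self, encoded_run):
        ens, X, y, model, conn = encoded_run
        w = raw_pair_importance(ens, X, y, model, conn, repeats=2, rng=1)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0)

    def test_connectome_dimension_mismatch_rejected(self, encoded_run):
        ens, X, y, model, conn = encoded_run
        with pytest.raises(SchemaError):
            raw_pair_importance(ens, X, y, model, conn.iloc[:, :5], repeats=1, rng=0)


class TestNetworkAverages:
    def test_constant_field_gives_constant_means(self):
        labels = pair_labels()
        pairw = pd.Series(0.37, index=labels)
        nets = network_average_weights(pairw)
        np.testing.assert_allclose(nets["mean"], 0.37, atol=1e-12)
        np.testing.assert_allclose(nets["sd"], 0.0, atol=1e-12)

    def test_single_self_pair_weight_spreads_correctly(self):
        labels = pair_labels()
        pairw = pd.Series(0.0, index=labels)
        pairw["SMDxSMD"] = 1.0
        nets = network_average_weights(pairw)
        assert nets.loc["SMD", "mean"] == pytest.approx(1 / 15)
        assert nets.drop("SMD")["mean"].abs().max() == 0.0

    def test_matches_label_parsing_oracle(self):
        rng = np.random.default_rng(1)
        labels = pair_labels()
        pairw = pd.Series(rng.uniform(0, 1, len(labels)), index=labels)
        nets = network_average_weights(pairw)
        for net in nets.index:
            incident = [w for lbl, w in pairw.items()
                        if net in lbl.split("x")]
            assert nets.loc[net, "mean"] == pytest.approx(np.mean(incident))
            assert nets.loc[net, "sd"] == pytest.approx(np.std(incident))

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = pair_labels()
        pairw = pd.Series(rng.uniform(0, 1, len(labels)), index=labels)
        shuffled = pairw.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            network_average_weights(pairw), network_average_weights(shuffled)
        )

    def test_missing_pair_is_schema_error(self):
        labels = pair_labels()
        pairw = pd.Series(0.1, index=labels).drop("SMDxSMI")
        with pytest.raises(SchemaError):
            network_average_weights(pairw)


class TestVoxelProjection:
    def _maps(self, rng, n_vox=100):
        nets = ("SMD", "SMI", "CON")
        return [ProbabilityMap(n, rng.uniform(0, 1, n_vox)) for n in nets]

    def test_one_hot_weights_recover_single_map(self):
        rng = np.random.default_rng(0)
        maps = self._maps(rng)
        w = pd.Series({"SMD": 0.0, "SMI": 1.0, "CON": 0.0})
        np.testing.assert_allclose(project_to_voxels(w, maps), maps[1].values)

    def test_zero_weights_annihilate(self):
        rng = np.random.default_rng(1)
        maps = self._maps(rng)
        w = pd.Series({"SMD": 0.0, "SMI": 0.0, "CON": 0.0})
        assert np.all(project_to_voxels(w, maps) == 0.0)

    def test_matches_per_voxel_loop_and_is_linear(self):
        rng = np.random.default_rng(2)
        maps = self._maps(rng)
        w1 = pd.Series(rng.uniform(0, 1, 3), index=["SMD", "SMI", "CON"])
        w2 = pd.Series(rng.uniform(0, 1, 3), index=["SMD", "SMI", "CON"])
        expected = np.array([
            sum(w1[m.network] * m.values[v] for m in maps) for v in range(100)
        ])
        np.testing.assert_allclose(project_to_voxels(w1, maps), expected, atol=1e-12)
        np.testing.assert_allclose(
            project_to_voxels(w1 + w2, maps),
            project_to_voxels(w1, maps) + project_to_voxels(w2, maps),
            atol=1e-12,
        )

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        maps = self._maps(rng)
        maps[1] = ProbabilityMap("SMI", rng.uniform(0, 1, 50))
        w = pd.Series({"SMD": 1.0, "SMI": 1.0, "CON": 1.0})
        with pytest.raises(ShapeError):
            project_to_voxels(w, maps)
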