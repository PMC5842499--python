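"""Base learner configuration and the weighted probability-averaging ensemble."""

import numpy as np
import pandas as pd
import pytest

from sharketho.dataset import LabelledDataset
from sharketho.ensemble import (
    BaseLearnerSpec,
    FittedLearner,
    TrainedEnsemble,
    default_specs,
    make_base_learner,
    select_members,
    train_all,
)
from sharketho.metrics import confusion, metrics


def _toy_dataset(n_per_class=40, seed=0, sd=0.05):
    """Linearly separable 2-feature five-class set (oracle by construction)."""
    rng = np.random.default_rng(seed)
    centres = {
        "swim": (0, 0), "headshake": (3, 0), "rest": (0, 3),
        "chafe": (3, 3), "burst": (-3, 1.5),
    }
    rows, labels = [], []
    for cls, (cx, cy) in centres.items():
        rows.append(np.column_stack([
            rng.normal(cx, sd, n_per_class), rng.normal(cy, sd, n_per_class)
        ]))
        labels += [cls] * n_per_class
    frame = pd.DataFrame(np.vstack(rows), columns=["f1", "f2"])
    return LabelledDataset(features=frame, labels=np.array(labels, dtype=object))


class TestMakeBaseLearner:
    def test_gb_has_100_trees_of_depth_3(self):
        est = make_base_learner(BaseLearnerSpec("GB", seed=0))
        assert est.n_estimators == 100
        assert est.max_depth == 3

    def test_ann_has_one_hidden_layer_of_100_nodes(self):
        pipe = make_base_learner(BaseLearnerSpec("ANN", seed=0))
        assert pipe["model"].hidden_layer_sizes == (100,)
        assert pipe["model"].activation == "relu"

    def test_random_forests_differ_only_in_criterion(self):
        rfg = make_base_learner(BaseLearnerSpec("RFG", seed=1))
        rfe = make_base_learner(BaseLearnerSpec("RFE", seed=1))
        assert rfg.criterion == "gini"
        assert rfe.criterion == "entropy"
        pg, pe = rfg.get_params(), rfe.get_params()
        assert {k: v for k, v in pg.items() if k != "criterion"} == \
               {k: v for k, v in pe.items() if k != "criterion"}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            BaseLearnerSpec("SVM")


class TestTrainAll:
    def test_probabilities_row_stochastic_on_held_out(self, trained_members,
                                                      session_splits):
        _, _, test = session_splits
        for m in trained_members:
            proba = m.predict_proba(test.features)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
            assert proba.min() >= 0

    def test_training_is_deterministic_under_seeds(self):
        data = _toy_dataset()
        specs = default_specs(seed=4)
        p1 = train_all(specs, data)[1].predict_proba(data.features)
        p2 = train_all(specs, data)[1].predict_proba(data.features)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_toy_set_recalled_by_all_learners(self):
        data = _toy_dataset()
        for m in train_all(default_specs(0), data):
            pred = np.array(
                [m.class_order[i]
                 for i in np.argmax(m.predict_proba(data.features), axis=1)],
                dtype=object,
            )
            rep = metrics(confusion(data.labels, pred))
            assert (rep.per_class["recall"] >= 0.95).all(), m.spec.kind

    def test_single_class_training_rejected(self):
        data = _toy_dataset()
        sub = data.subset(np.arange(40))
        with pytest.raises(ValueError, match="class"):
            train_all(default_specs(0), sub)


class _StubLearner:
    """Duck-typed member returning fixed class probabilities."""

    def __init__(self, proba, kind="GB"):
        self._proba = np.asarray(proba, dtype=float)
        self.spec = BaseLearnerSpec(kind)
        self.class_order = ("swim", "headshake")

    def predict_proba(self, features):
        return np.tile(self._proba, (len(features), 1))


def test_weighted_average_hand_computation():
    # members A..E give class-2 probabilities (0,0,0,0,1); weights (1,1,1,1,3)
    members = [_StubLearner([1.0, 0.0]) for _ in range(4)] + [_StubLearner([0.0, 1.0])]
    ens = TrainedEnsemble(members=members, weights=np.array([1, 1, 1, 1, 3.0]),
                          class_order=("swim", "headshake"))
    proba = ens.predict_proba(pd.DataFrame({"f": [0.0]}))
    assert proba[0, 1] == pytest.approx(3 / 7)
    assert proba[0, 0] == pytest.approx(4 / 7)
    # 4/7 > 3/7: the four agreeing members override the weighted one
    assert ens.predict(pd.DataFrame({"f": [0.0]}))[0] == "swim"


def test_weight_rescaling_leaves_predictions_unchanged(trained_ensemble,
                                                       session_splits):
    _, _, test = session_splits
    scaled = TrainedEnsemble(
        members=trained_ensemble.members,
        weights=trained_ensemble.weights * 10.0,
        class_order=trained_ensemble.class_order,
    )
    np.testing.assert_allclose(
        trained_ensemble.predict_proba(test.features),
        scaled.predict_proba(test.features),
        atol=1e-12,
    )


def test_uniform_probability_tie_breaks_to_swim():
    members = [_StubLearner([0.5, 0.5])]
    ens = TrainedEnsemble(members=members, weights=np.array([1.0]),
                          class_order=("swim", "headshake"))
    assert ens.predict(pd.DataFrame({"f": [0.0]}))[0] == "swim"


def test_single_member_ensemble_is_identity(trained_members, session_splits):
    _, _, test = session_splits
    member = trained_members[4]
    ens = TrainedEnsemble(members=[member], weights=np.array([1.0]))
    np.testing.assert_array_equal(
        ens.predict_proba(test.features), member.predict_proba(test.features)
    )


def test_all_weight_on_gb_matches_gb_argmax(trained_members, session_splits):
    _, _, test = session_splits
    gb = next(m for m in trained_members if m.spec.kind == "GB")
    ens = TrainedEnsemble(
        members=trained_members,
        weights=np.array([1e9 if m.spec.kind == "GB" else 1e-9
                          for m in trained_members]),
    )
    gb_pred = [gb.class_order[i]
               for i in np.argmax(gb.predict_proba(test.features), axis=1)]
    np.testing.assert_array_equal(ens.predict(test.features), np.array(gb_pred, dtype=object))


class TestSelectMembers:
    def test_best_member_gets_weight_three(self, trained_ensemble):
        assert trained_ensemble.weights[0] == 3.0
        assert set(trained_ensemble.weights[1:]) == {1.0}
        best_kind = trained_ensemble.members[0].spec.kind
        scores = trained_ensemble.validation_macro_f
        assert scores[best_kind] == max(scores.values())

    def test_floor_excludes_weak_members(self, trained_members, session_splits):
        _, validation, _ = session_splits
        ens = select_members(trained_members, validation, macro_f_floor=0.0)
        assert len(ens.members) == 5  # default floor keeps all five members

    def test_impossible_floor_raises(self, trained_members, session_splits):
        _, validation, _ = session_splits
        with pytest.raises(ValueError, match="floor"):
            select_members(trained_members, validation, macro_f_floor=1.01)


class TestFeatureImportance:
    def test_importances_normalised(self, trained_ensemble):
        imp = trained_ensemble.feature_importance()
        assert set(imp.columns) <= {"RFG", "RFE", "GB"}
        np.testing.assert_allclose(imp.sum(axis=0), 1.0, atol=1e-9)

    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        n = 120
        labels = np.array(["swim"] * n + ["rest"] * n, dtype=object)
        frame = pd.DataFrame({
            "ODBA": np.r_[rng.normal(0.3, 0.05, n), rng.normal(0.01, 0.005, n)],
            "noise1": rng.normal(size=2 * n),
            "noise2": rng.normal(size=2 * n),
        })
        data = LabelledDataset(features=frame, labels=labels)
        fitted = train_all([BaseLearnerSpec("GB", 0), BaseLearnerSpec("RFG", 0)], data)
        ens = TrainedEnsemble(members=fitted, weights=np.ones(2))
        imp = ens.feature_importance()
        assert (imp.idxmax(axis=0) == "ODBA").all()

    def test_no_tree_member_raises(self):
        members = [_StubLearner([0.5, 0.5], kind="LR")]
        ens = TrainedEnsemble(members=members, weights=np.array([1.0]),
                              class_order=("swim", "headshake"))
        with pytest.raises(ValueError, match="tree"):
            ens.feature_importance()


def test_column_mismatch_rejected(trained_ensemble, session_splits):
    _, _, test = session_splits
    broken = test.features.rename(columns={"ODBA": "odba_wrong"})
    with pytest.raises(ValueError, match="columns"):
        trained_ensemble.predict_proba(broken)


def test_save_load_round_trip(tmp_path, trained_ensemble, session_splits):
    _, _, test = session_splits
    trained_ensemble.save(tmp_path / "bundle")
    back = TrainedEnsemble.load(tmp_path / "bundle")
    np.testing.assert_array_equal(
        trained_ensemble.predict(test.features), back.predict(test.features)
    )
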