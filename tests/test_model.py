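"""Model assembly: classic/augmented forms, groups, prediction, comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from qsrrkit import (
    DescriptorMatrix,
    QSRR,
    RetentionTable,
    SimulationConfig,
    build_augmented_model,
    build_classic_model,
    build_group_models,
    compare_models,
    load_results,
    simulate_dataset,
)
from qsrrkit.model import REFERENCE_TERM
from qsrrkit.regression import fit_ols


@pytest.fixture
def shared_dataset():
    cfg = SimulationConfig(seed=11)
    return simulate_dataset(cfg)


class TestClassic:
    def test_exact_single_descriptor_recovered(self, rng):
        frame = pd.DataFrame(
            rng.standard_normal((12, 8)),
            index=[f"S{i}" for i in range(12)],
            columns=[f"MD{j + 1}" for j in range(8)],
        )
        y = 2.0 * frame["MD7"]
        y = y - y.min() + 1.0  # positive retention; offset absorbed by intercept
        rt = RetentionTable(pd.DataFrame({"tR_A": y}))
        res = build_classic_model(
            DescriptorMatrix(frame), rt, "tR_A",
            mode="forward", include_intercept=True,
        )
        assert res.descriptor_names == ["MD7"]
        assert res.params["MD7"] == pytest.approx(2.0, rel=1e-8)
        assert res.fit_report.see == pytest.approx(0.0, abs=1e-8)

    def test_enter_mode_equals_direct_ols(self, small_dm, small_rt):
        res = build_classic_model(
            small_dm, small_rt, "tR_A", mode="enter",
            descriptor_names=["MD1", "MD2"],
        )
        direct = fit_ols(
            small_dm.frame[["MD1", "MD2"]].to_numpy(),
            small_rt.frame["tR_A"].to_numpy(),
            names=["MD1", "MD2"],
        )
        np.testing.assert_allclose(res.params.to_numpy(), direct.params)
        np.testing.assert_allclose(res.bse.to_numpy(), direct.bse)

    def test_empty_forward_selection_warns_not_crashes(self, rng):
        frame = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0, 1.0, -1.0]},
                             index=[f"S{i}" for i in range(6)])
        rt = RetentionTable(
            pd.DataFrame({"tR_A": [2.0, 2.0, 3.0, 3.0, 2.5, 2.5]},
                         index=frame.index)
        )
        with pytest.warns(UserWarning, match="no descriptor"):
            res = build_classic_model(DescriptorMatrix(frame), rt, "tR_A")
        assert res.descriptor_names == []

    def test_enter_mode_requires_descriptors(self, small_dm, small_rt):
        with pytest.raises(ValueError, match="enter mode"):
            QSRR(small_dm, small_rt, "tR_A", mode="enter")


class TestAugmented:
    def test_reference_identical_to_target_degenerate_b_one(self, small_dm, small_rt):
        frame = small_rt.frame.assign(tR_B=small_rt.frame["tR_A"])
        rt2 = RetentionTable(frame)
        res = build_augmented_model(
            small_dm, rt2, "tR_A", "tR_B",
            mode="enter", descriptor_names=["MD1", "MD2"],
        )
        b, _ = res.reference_coefficient
        assert b == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.params[["MD1", "MD2"]], 0.0, atol=1e-8)
        assert res.fit_report.see == pytest.approx(0.0, abs=1e-8)
        assert res.degenerate

    def test_reference_equal_to_target_label_rejected(self, small_dm, small_rt):
        with pytest.raises(ValueError, match="differ"):
            QSRR(small_dm, small_rt, "tR_A", reference="tR_A")

    def test_b_recovered_within_three_se(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names, include_intercept=True,
        )
        b, se = res.reference_coefficient
        assert abs(b - truth.true_b) < 3 * se

    def test_reference_term_is_forced_in_forward_mode(self, shared_dataset):
        _, dm, rt, _ = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="forward", include_intercept=True
        )
        assert res.trace.steps[0].name == REFERENCE_TERM
        assert res.trace.steps[0].forced
        assert REFERENCE_TERM in res.params.index

    def test_augmented_sse_never_above_classic_same_descriptors(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        names = truth.active_names
        classic = build_classic_model(
            dm, rt, "tR_A", mode="enter", descriptor_names=names
        )
        augmented = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter", descriptor_names=names
        )
        assert augmented.sse <= classic.sse + 1e-9


class TestPredict:
    def test_training_set_self_consistency(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names, include_intercept=True,
        )
        pred = res.predict(dm, reference_retention=rt.frame["tR_R"])
        mae = float(np.mean(np.abs(rt.frame["tR_A"] - pred)))
        assert mae == pytest.approx(res.fit_report.mae, rel=1e-10)

    def test_zero_descriptor_row_predicts_zero_without_intercept(self, small_dm, small_rt):
        res = build_classic_model(
            small_dm, small_rt, "tR_A", mode="enter",
            descriptor_names=["MD1", "MD2"],
        )
        new = pd.DataFrame({"MD1": [0.0], "MD2": [0.0], "MD3": [5.0]}, index=["Z"])
        assert res.predict(new).loc["Z"] == 0.0

    def test_duplicate_descriptor_rows_predict_identically(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        row = dm.frame.iloc[[0]]
        twin = pd.concat([row, row.set_axis(["copy"])])
        ref = pd.Series([rt.frame["tR_R"].iloc[0]] * 2, index=twin.index)
        pred = res.predict(twin, reference_retention=ref)
        assert pred.iloc[0] == pred.iloc[1]

    def test_missing_descriptor_column_named(self, small_dm, small_rt):
        res = build_classic_model(
            small_dm, small_rt, "tR_A", mode="enter", descriptor_names=["MD1"]
        )
        with pytest.raises(KeyError, match="MD1"):
            res.predict(pd.DataFrame({"other": [1.0]}))

    def test_augmented_predict_requires_reference(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        with pytest.raises(ValueError, match="reference_retention"):
            res.predict(dm)


class TestGroups:
    def test_each_group_selects_its_own_descriptor(self):
        cfg = SimulationConfig(
            n_solutes=120,
            n_descriptors=10,
            group_structure={"g1": (0,), "g2": (4,)},
            true_b=0.5,
            noise_sd_target=0.2,
            noise_sd_reference=0.2,
            seed=21,
        )
        solutes, dm, rt, truth = simulate_dataset(cfg)
        groups = pd.Series({s.id: s.group for s in solutes})
        models = build_group_models(
            dm, rt, "tR_A", "tR_R", groups, include_intercept=True
        )
        assert set(models) == {"g1", "g2"}
        for label, (classic, augmented) in models.items():
            assert truth.group_active[label][0] in classic.descriptor_names
            assert augmented.reference_coefficient is not None

    def test_undersized_group_skipped_with_warning(self, shared_dataset):
        solutes, dm, rt, _ = shared_dataset
        groups = pd.Series("big", index=dm.frame.index, dtype=object)
        groups.iloc[:3] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            models = build_group_models(dm, rt, "tR_A", "tR_R", groups,
                                        include_intercept=True)
        assert "tiny" not in models
        assert "big" in models


class TestComparison:
    def test_same_model_twice_gives_zero_deltas(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_classic_model(
            dm, rt, "tR_A", mode="enter", descriptor_names=truth.active_names
        )
        cmp_ = compare_models(res, res)
        assert cmp_.delta_mae == 0 and cmp_.delta_max_ae == 0 and cmp_.delta_see == 0
        assert cmp_.b is None

    def test_true_transfer_signal_flagged_significant(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        classic = build_classic_model(
            dm, rt, "tR_A", mode="enter", descriptor_names=truth.active_names
        )
        augmented = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        cmp_ = compare_models(classic, augmented)
        assert cmp_.b_significant
        assert cmp_.delta_see < 0

    def test_pure_noise_reference_adds_nothing(self):
        # Independent reference with b = 0: the reference column carries
        # no information about the target.
        cfg = SimulationConfig(
            true_b=0.0, reference_model="independent", seed=303,
            noise_sd_target=0.3,
        )
        _, dm, rt, truth = simulate_dataset(cfg)
        classic = build_classic_model(
            dm, rt, "tR_A", mode="enter",
            descriptor_names=truth.active_names, include_intercept=True,
        )
        augmented = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names, include_intercept=True,
        )
        cmp_ = compare_models(classic, augmented)
        assert not cmp_.b_significant
        assert abs(cmp_.delta_see) < 0.05 * classic.fit_report.see

    def test_mismatched_solute_sets_rejected(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        full = build_classic_model(
            dm, rt, "tR_A", mode="enter", descriptor_names=truth.active_names
        )
        sub_dm = DescriptorMatrix(dm.frame.iloc[:50].copy(), dict(dm.provenance))
        part = build_classic_model(
            sub_dm, rt, "tR_A", mode="enter", descriptor_names=truth.active_names
        )
        with pytest.raises(ValueError, match="solute sets"):
            compare_models(full, part)


class TestMutualReference:
    def test_each_column_can_reference_the_other(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        a_on_b = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        b_on_a = build_augmented_model(
            dm, rt, "tR_R", "tR_A", mode="enter",
            descriptor_names=truth.active_names,
        )
        assert a_on_b.reference_coefficient is not None
        assert b_on_a.reference_coefficient is not None

    def test_b_invariant_to_row_permutation(self, shared_dataset):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        perm = np.random.default_rng(1).permutation(len(dm.frame))
        dm2 = DescriptorMatrix(dm.frame.iloc[perm].copy(), dict(dm.provenance))
        res2 = build_augmented_model(
            dm2, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names,
        )
        assert res.reference_coefficient[0] == pytest.approx(
            res2.reference_coefficient[0], rel=1e-10
        )


class TestSerialization:
    def test_json_round_trip_predictions_bitwise_identical(
        self, tmp_path, shared_dataset
    ):
        _, dm, rt, truth = shared_dataset
        res = build_augmented_model(
            dm, rt, "tR_A", "tR_R", mode="enter",
            descriptor_names=truth.active_names, include_intercept=True,
        )
        path = tmp_path / "model.json"
        res.save(path)
        loaded = load_results(path)
        p1 = res.predict(dm, reference_retention=rt.frame["tR_R"])
        p2 = loaded.predict(dm, reference_retention=rt.frame["tR_R"])
        assert (p1.to_numpy() == p2.to_numpy()).all()

    def test_saved_document_carries_trace_and_digest(self, tmp_path, shared_dataset):
        import json

        _, dm, rt, _ = shared_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = build_classic_model(dm, rt, "tR_A", mode="forward",
                                      include_intercept=True)
        path = tmp_path / "m.json"
        res.save(path)
        doc = json.loads(path.read_text())
        assert doc["format"] == "qsrrkit-model"
        assert doc["trace"]["alpha"] == 0.05
        assert len(doc["input_digest"]) == 16
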