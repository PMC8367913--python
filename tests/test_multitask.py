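"""Task assembly, masked loss, helper tasks, training contracts."""

import numpy as np
import pytest

from conftest import make_records
from lipotask import (
    MoleculeRecord,
    TargetMatrix,
    TaskSpec,
    assemble_tasks,
    attach_helper_tasks,
    masked_loss,
    predict_primary,
    train,
)
from lipotask.dmpnn import ModelParams, batch_graphs, forward
from lipotask.multitask import (
    TrainedModel,
    build_target_matrix,
    check_task_specs,
    masked_loss_grad,
)


class TestTaskSpecs:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            check_task_specs([TaskSpec("a"), TaskSpec("a")])

    def test_at_least_one_primary(self):
        with pytest.raises(ValueError, match="primary"):
            check_task_specs([TaskSpec("a", "helper")])

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("a", role="auxiliary")


class TestTargetMatrix:
    def test_mask_must_match_finiteness(self):
        with pytest.raises(ValueError, match="mask"):
            TargetMatrix(values=np.array([[1.0, np.nan]]), mask=np.array([[True, True]]))

    def test_all_missing_row_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            TargetMatrix(
                values=np.array([[1.0], [np.nan]]),
                mask=np.array([[True], [False]]),
            )


class TestAssembleTasks:
    def _datasets(self, overlap=0):
        a = [MoleculeRecord("CCO", values={"logp": 1.0}),
             MoleculeRecord("CCC", values={"logp": 2.0}),
             MoleculeRecord("CCN", values={"logp": 0.5})]
        b_smiles = ["c1ccccc1", "Cc1ccccc1", "CCCC"]
        b = [MoleculeRecord(s, values={"logp": float(i)}) for i, s in enumerate(b_smiles)]
        for i in range(overlap):
            b.append(MoleculeRecord(a[i].smiles, values={"logp": 5.0 + i}))
        return [("opera", a), ("chembl", b)]

    def test_separate_mode_disjoint(self):
        records, specs, tm = assemble_tasks(self._datasets(), mode="separate")
        assert [s.name for s in specs] == ["opera", "chembl"]
        assert tm.values.shape == (6, 2)
        assert np.all(tm.mask.sum(axis=1) == 1)

    def test_merged_mode_single_column(self):
        records, specs, tm = assemble_tasks(self._datasets(), mode="merged")
        assert len(specs) == 1
        assert tm.values.shape == (6, 1)
        assert tm.mask.all()

    def test_overlapping_molecules_collapse_to_multi_observed_rows(self):
        records, specs, tm = assemble_tasks(self._datasets(overlap=3), mode="separate")
        assert tm.values.shape == (6, 2)  # no new rows: overlap collapses
        assert int((tm.mask.sum(axis=1) == 2).sum()) == 3

    def test_duplicates_within_dataset_resolved_by_median(self):
        ds = [("d", [
            MoleculeRecord("CCO", values={"x": 1.0}),
            MoleculeRecord("OCC", values={"x": 2.0}),  # same molecule
            MoleculeRecord("CCO", values={"x": 10.0}),
        ])]
        records, specs, tm = assemble_tasks(ds)
        assert len(records) == 1
        assert tm.values[0, 0] == pytest.approx(2.0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assemble_tasks([("a", [])])


class TestHelperTasks:
    def test_constant_provider(self):
        recs = [MoleculeRecord("CCO", values={"logp": 1.0})]
        out, specs = attach_helper_tasks(recs, lambda s: {"h": 0.0})
        assert specs == [TaskSpec("h", "helper", "external_predictor")]
        assert out[0].values["h"] == 0.0

    def test_no_provider_is_identity(self):
        recs = [MoleculeRecord("CCO", values={"logp": 1.0})]
        out, specs = attach_helper_tasks(recs, None)
        assert specs == []
        assert out[0].values == recs[0].values

    def test_provider_failure_masks_entry(self):
        recs = [MoleculeRecord("CCO", values={"logp": 1.0}),
                MoleculeRecord("CCC", values={"logp": 2.0})]

        def flaky(smiles):
            if smiles == "CCC":
                raise RuntimeError("predictor down")
            return {"h": 3.0}

        out, specs = attach_helper_tasks(recs, flaky)
        assert "h" in out[0].values
        assert "h" not in out[1].values

    def test_synthetic_helper_correlates_with_primary(self):
        from lipotask.synthetic import SyntheticSpec, generate, helper_provider

        frame = generate(SyntheticSpec(n_molecules=150, helper_noise_sd=0.2, seed=9))
        recs = make_records(frame["smiles"], {"logp_observed": frame["logp_observed"]})
        out, specs = attach_helper_tasks(recs, helper_provider(frame))
        h = np.array([r.values["helper_logp"] for r in out])
        p = np.array([r.values["logp_observed"] for r in out])
        assert np.corrcoef(h, p)[0, 1] > 0.9


class TestMaskedLoss:
    def _tm(self, values):
        values = np.asarray(values, dtype=float)
        return TargetMatrix(values=values, mask=np.isfinite(values))

    def test_perfect_prediction_zero(self):
        tm = self._tm([[1.0, 2.0], [3.0, 4.0]])
        assert masked_loss(tm.values.copy(), tm) == 0.0

    def test_single_observed_cell(self):
        tm = self._tm([[1.0, np.nan]])
        pred = np.array([[3.0, 100.0]])
        assert masked_loss(pred, tm) == pytest.approx(4.0)

    def test_masked_cells_do_not_affect_loss(self):
        tm = self._tm([[1.0, np.nan], [np.nan, 2.0]])
        pred = np.array([[1.5, 0.0], [0.0, 2.5]])
        base = masked_loss(pred, tm)
        pred2 = pred.copy()
        pred2[0, 1] = 1e9
        pred2[1, 0] = -1e9
        assert masked_loss(pred2, tm) == base

    def test_no_observed_entries_error(self):
        tm = TargetMatrix(values=np.zeros((0, 2)), mask=np.zeros((0, 2), dtype=bool))
        with pytest.raises(ValueError, match="no observed"):
            masked_loss(np.zeros((0, 2)), tm)

    def test_gradient_zero_on_masked_cells_finite_difference(self):
        # end-to-end: perturbing a masked target cell changes neither the
        # loss nor any weight gradient of a tiny model
        rng = np.random.default_rng(0)
        smiles = ["CCO", "CCC", "CCN", "c1ccccc1"]
        params = ModelParams(depth=2, hidden_size=4, n_tasks=2)
        from lipotask.dmpnn import backward, init_weights
        from lipotask import build_directed_graph

        w = init_weights(params, 0)
        batch = batch_graphs([build_directed_graph(s) for s in smiles])
        values = np.array([[1.0, np.nan], [np.nan, 2.0], [0.5, np.nan], [np.nan, 1.5]])
        tm = TargetMatrix(values=values, mask=np.isfinite(values))
        preds, cache = forward(batch, w, params, want_cache=True)
        loss, g = masked_loss_grad(preds, tm)
        assert np.all(g[~tm.mask] == 0.0)
        grads = backward(g, batch, w, params, cache)
        # flip a masked target; loss and gradients must be bit-identical
        values2 = values.copy()
        values2[0, 1] = 123.0
        values2[np.isnan(values2)] = np.nan
        tm2 = TargetMatrix(values=np.where(np.isfinite(values), values2, np.nan),
                           mask=tm.mask)
        loss2, g2 = masked_loss_grad(preds, tm2)
        grads2 = backward(g2, batch, w, params, cache)
        assert loss == loss2
        for k in grads:
            assert np.array_equal(grads[k], grads2[k]), k


class TestTraining:
    def test_loss_decreases(self, linear_logp_records):
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=16, n_tasks=1)
        model = train(records, specs, params=params, seed=0, epochs=5, batch_size=16)
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_same_seed_reproducible(self, linear_logp_records):
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=8, n_tasks=1)
        m1 = train(records, specs, params=params, seed=3, epochs=2)
        m2 = train(records, specs, params=params, seed=3, epochs=2)
        assert m1.history["val_loss"] == m2.history["val_loss"]
        for k in m1.weights:
            assert np.array_equal(m1.weights[k], m2.weights[k])

    def test_zero_epochs_returns_initialized_model(self, linear_logp_records):
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=8, n_tasks=1)
        from lipotask.dmpnn import init_weights

        model = train(records, specs, params=params, seed=5, epochs=0)
        w0 = init_weights(params, 5)
        for k in w0:
            assert np.array_equal(model.weights[k], w0[k])

    def test_too_few_observations_per_task_rejected(self):
        recs = [MoleculeRecord("CCO", values={"a": 1.0, "b": 1.0}),
                MoleculeRecord("CCC", values={"a": 2.0}),
                MoleculeRecord("CCN", values={"a": 3.0})]
        specs = [TaskSpec("a"), TaskSpec("b")]
        with pytest.raises(ValueError, match="fewer than 2"):
            train(recs, specs, params=ModelParams(n_tasks=2), seed=0, epochs=1,
                  split=(np.arange(3), np.array([], dtype=int)))

    def test_normalization_round_trip(self, linear_logp_records):
        # a no-op scaler (shift 0 / scale 1) must reproduce raw-target training
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=8, n_tasks=1)
        m = train(records, specs, params=params, seed=2, epochs=2)
        y = np.array([r.values["logp"] for r in records])
        normed = [
            type(r)(smiles=r.smiles, id=r.id, values={"logp": (v - y.mean()) / y.std(ddof=0)})
            for r, v in zip(records, y)
        ]
        m2 = train(normed, specs, params=params, seed=2, epochs=2)
        p1, _ = predict_primary(m, [r.smiles for r in records[:5]])
        p2, _ = predict_primary(m2, [r.smiles for r in records[:5]])
        # de-normalized predictions agree: p1 ≈ p2 * std + mean
        assert np.allclose(p1, p2 * y.std(ddof=0) + y.mean(), atol=1e-4)


@pytest.fixture(scope="module")
def helper_model(linear_logp_records):
    records, specs = linear_logp_records
    recs, hspecs = attach_helper_tasks(
        records, lambda s: {"h1": float(len(s)), "h2": 0.0}
    )
    params = ModelParams(depth=2, hidden_size=8, n_tasks=3)
    return train(recs, list(specs) + hspecs, params=params, seed=1, epochs=2)


class TestPredictPrimary:

    def test_output_width_is_primary_only(self, helper_model):
        preds, fails = predict_primary(helper_model, ["CCO", "c1ccccc1"])
        assert preds.shape == (2, 1)
        assert not fails

    def test_no_helper_provider_needed_at_predict_time(self, helper_model):
        # prediction succeeds with structure only, no helper columns
        preds, fails = predict_primary(helper_model, ["CCOCC"])
        assert np.isfinite(preds).all()

    def test_helper_free_model_output_matches_full_forward(self, linear_logp_records):
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=8, n_tasks=1)
        m = train(records, specs, params=params, seed=0, epochs=1)
        from lipotask import build_directed_graph
        from lipotask.dmpnn import forward_graphs

        smiles = ["CCO", "CCC"]
        preds, _ = predict_primary(m, smiles)
        full = forward_graphs(
            [build_directed_graph(s) for s in smiles], m.weights, m.params,
            scaler=(m.scaler_mean, m.scaler_sd),
        )
        assert np.allclose(preds, full)

    def test_bad_row_isolated(self, helper_model):
        preds, fails = predict_primary(helper_model, ["CCO", "C1CC", "CCC"])
        assert list(fails) == [1]
        assert np.isnan(preds[1, 0])
        assert np.isfinite(preds[[0, 2], 0]).all()


class TestCheckpoint:
    def test_round_trip(self, tmp_path, linear_logp_records):
        records, specs = linear_logp_records
        params = ModelParams(depth=2, hidden_size=8, n_tasks=1)
        m = train(records, specs, params=params, seed=4, epochs=1)
        path = str(tmp_path / "model.npz")
        m.save(path)
        m2 = TrainedModel.load(path)
        assert m2.params == m.params
        assert m2.tasks == m.tasks
        assert m2.featurization_version == m.featurization_version
        p1, _ = predict_primary(m, ["CCO"])
        p2, _ = predict_primary(m2, ["CCO"])
        assert np.array_equal(p1, p2)
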