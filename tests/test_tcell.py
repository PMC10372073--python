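import numpy as np
import pytest
import scipy.sparse as sp

import immunocall as ic
from immunocall.matrix_io import CellMatrix
from immunocall.tcell import (
    TCellTrainConfig,
    assemble_training_set,
    cross_validate,
    select_features,
    train,
)


@pytest.fixture(scope="module")
def trained(small_tcell_sources, small_tcell_cfg):
    pooled, labels = assemble_training_set(small_tcell_sources, 200, seed=5)
    model = train(pooled, labels, small_tcell_cfg)
    return pooled, labels, model


class TestAssemble:
    def test_pool_size_and_label_split(self, small_tcell_sources):
        pooled, labels = assemble_training_set(small_tcell_sources, 100, seed=1)
        assert pooled.n_cells == 500
        assert (labels == "CD4").sum() == 300 and (labels == "CD8").sum() == 200
        assert pooled.layer == "lognormalized"

    def test_same_seed_identical_selection(self, small_tcell_sources):
        a, _ = assemble_training_set(small_tcell_sources, 50, seed=9)
        b, _ = assemble_training_set(small_tcell_sources, 50, seed=9)
        assert a.barcodes == b.barcodes
        assert (a.counts != b.counts).nnz == 0

    def test_full_size_sample_is_exhaustive_and_ordered(self, small_tcell_sources):
        m, label = small_tcell_sources[0]
        pooled, _ = assemble_training_set([(m, label)], m.n_cells, seed=3)
        assert pooled.barcodes == [f"src0:{b}" for b in m.barcodes]

    def test_undersized_source_named_in_error(self, small_tcell_sources):
        with pytest.raises(ValueError, match="source 0"):
            assemble_training_set(small_tcell_sources, 10_000, seed=0)


class TestFeatureSelection:
    def test_threshold_is_strict(self):
        imp = np.array([0.0, 1e-7, 1.0000001e-7, 2e-7])
        assert select_features(imp, 1e-7).tolist() == [2, 3]

    def test_stage1_soundness(self, trained):
        _, _, model = trained
        thr = model.config.importance_threshold
        imp = model.stage1_importance
        selected = set(model.selected_genes)
        for gene, value in imp.items():
            assert (gene in selected) == (value > thr)


class TestTrain:
    def test_separable_markers_are_selected_and_resubstitution_perfect(
        self, trained
    ):
        pooled, labels, model = trained
        # the class-defining marker panels must dominate the selection
        panels = set(ic.simulate.DEFAULT_CD4_MARKERS) | set(
            ic.simulate.DEFAULT_CD8_MARKERS
        )
        assert len(panels & set(model.selected_genes)) >= 5
        pred, _ = model.predict(pooled)
        assert (pred == labels).mean() >= 0.99

    def test_same_seed_reproduces_selected_genes(
        self, small_tcell_sources, small_tcell_cfg
    ):
        pooled, labels = assemble_training_set(small_tcell_sources, 150, seed=2)
        m1 = train(pooled, labels, small_tcell_cfg)
        m2 = train(pooled, labels, small_tcell_cfg)
        assert m1.selected_genes == m2.selected_genes

    def test_single_class_rejected(self, small_tcell_sources, small_tcell_cfg):
        cd4_only = [s for s in small_tcell_sources if s[1] == "CD4"]
        pooled, labels = assemble_training_set(cd4_only, 100, seed=0)
        with pytest.raises(ValueError, match="both"):
            train(pooled, labels, small_tcell_cfg)


class TestPredict:
    def test_all_zero_cell_gets_a_label_without_crashing(self, trained):
        _, _, model = trained
        m = CellMatrix(
            genes=model.selected_genes[:3], barcodes=["z"],
            counts=sp.csc_matrix((3, 1)), layer="lognormalized",
        )
        labels, margins = model.predict(m)
        assert labels[0] in ("CD4", "CD8") and 0 <= margins[0] <= 1

    def test_duplicated_cell_identical_outputs(self, trained):
        pooled, _, model = trained
        two = pooled.subset_cells(
            np.arange(pooled.n_cells) == 0
        )
        col = two.counts
        dup = CellMatrix(genes=list(two.genes), barcodes=["a", "b"],
                         counts=sp.hstack([col, col]), layer="lognormalized")
        labels, margins = model.predict(dup)
        assert labels[0] == labels[1] and margins[0] == margins[1]

    def test_absent_genes_zero_filled(self, trained):
        pooled, _, model = trained
        sub = pooled.subset_cells(np.arange(pooled.n_cells) < 5)
        # drop half the model genes from the query matrix
        keep = [g for i, g in enumerate(sub.genes) if i % 2 == 0]
        idx = [i for i, g in enumerate(sub.genes) if i % 2 == 0]
        dropped = CellMatrix(genes=keep, barcodes=list(sub.barcodes),
                             counts=sub.counts.tocsr()[idx], layer="lognormalized")
        labels, _ = model.predict(dropped)
        assert len(labels) == 5

    def test_rejects_raw_layer(self, trained):
        _, _, model = trained
        m = CellMatrix(genes=model.selected_genes[:2], barcodes=["x"],
                       counts=sp.csc_matrix(np.ones((2, 1))))
        with pytest.raises(ValueError, match="lognormalized"):
            model.predict(m)


class TestPersistence:
    def test_save_load_round_trip_predicts_identically(self, trained, tmp_path):
        pooled, _, model = trained
        model.save(tmp_path / "model")
        back = ic.TCellModel.load(tmp_path / "model")
        assert back.selected_genes == model.selected_genes
        l1, m1 = model.predict(pooled)
        l2, m2 = back.predict(pooled)
        assert (l1 == l2).all()
        np.testing.assert_allclose(m1, m2, atol=1e-6)


class TestCrossValidate:
    def test_separable_sources_near_perfect(
        self, small_tcell_sources, small_tcell_cfg
    ):
        accs = cross_validate(small_tcell_sources, 200, small_tcell_cfg, folds=2)
        assert all(a >= 0.99 for a in accs)

    def test_shuffled_labels_near_chance(self, small_tcell_cfg):
        # destroy the class signal by giving both classes the same marker law
        rng = np.random.default_rng(12)
        sources = []
        for k in range(4):
            counts = rng.poisson(1.0, size=(60, 150))
            sources.append(
                (
                    CellMatrix(
                        genes=[f"N{i}" for i in range(60)],
                        barcodes=[f"s{k}c{j}" for j in range(150)],
                        counts=sp.csc_matrix(counts.astype(float)),
                    ),
                    "CD4" if k % 2 == 0 else "CD8",
                )
            )
        accs = cross_validate(sources, 100, small_tcell_cfg, folds=2)
        assert all(0.3 < a < 0.7 for a in accs)

    def test_same_seed_identical_accuracy_vector(
        self, small_tcell_sources, small_tcell_cfg
    ):
        a = cross_validate(small_tcell_sources, 200, small_tcell_cfg, folds=2)
        b = cross_validate(small_tcell_sources, 200, small_tcell_cfg, folds=2)
        assert a == b

    def test_empty_remainder_rejected(self, small_tcell_sources):
        m, _ = small_tcell_sources[0]
        with pytest.raises(ValueError, match="remainder"):
            cross_validate(small_tcell_sources, m.n_cells, folds=2)
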