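import numpy as np
import pytest

import immunocall as ic
from immunocall.signature import SignatureMatrix
from immunocall.tcell import TCellTrainConfig


# ---------------------------------------------------------------- oracles

def pearson_brute(x, y):
    """Textbook Pearson correlation, written independently of the package."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / (vx * vy) ** 0.5


def auc_brute(scores, labels):
    """Pairwise-concordance AUC with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture
def oracles():
    return pearson_brute, auc_brute


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def toy_sig():
    """Minimal 4-gene, 2-type binary signature."""
    return SignatureMatrix(
        genes=["G1", "G2", "G3", "G4"],
        types=["TypeA", "TypeB"],
        values=np.array([[1, 0], [1, 0], [0, 1], [0, 0]]),
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition synthetic benchmark, computed once per session:
    10,000 immune + 3,000 non-immune cells, gated and scored."""
    cfg = ic.SimConfig(seed=11)
    matrix, truth = ic.simulate_cells(cfg)
    filtered = ic.filter_cells(matrix)
    normalized = ic.normalize_cells(filtered)
    scores = ic.score_cells(normalized, cfg.resolved_signature())
    truth_aligned = truth.set_index("barcode").loc[scores["barcode"]]
    return {
        "cfg": cfg,
        "matrix": matrix,
        "truth": truth,
        "normalized": normalized,
        "scores": scores,
        "is_immune_true": truth_aligned["is_immune"].to_numpy(),
        "true_type": truth_aligned["true_type"].to_numpy(),
    }


@pytest.fixture(scope="session")
def small_tcell_sources():
    """Light CD4/CD8 sources for unit tests of the discriminator."""
    return ic.simulate_tcell_sources(
        n_sources_cd4=3, n_sources_cd8=2, cells_per_source=300, n_genes=120,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_tcell_cfg():
    return TCellTrainConfig(n_rounds=150, early_stopping_rounds=30, seed=5)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact simulated dataset laid out on disk for CLI runs."""
    from immunocall.matrix_io import write_counts_mtx
    from immunocall.signature import write_signature
    from immunocall.simulate import generate_signature

    root = tmp_path_factory.mktemp("cli_data")
    sig = generate_signature(60, 4, 10, type_names=["B cells naive",
                                                    "T cells CD8",
                                                    "NK cells resting",
                                                    "Monocytes"])
    # means scaled up so per-cell totals clear the 500-count QC filter
    # despite the small gene universe
    cfg = ic.SimConfig(signature=sig, n_genes_background=80, cells_per_type=60,
                       n_nonimmune=40, n_samples=2, mu_marker=60.0,
                       mu_offsignature=1.0, mu_background=5.0, seed=21)
    matrix, truth = ic.simulate_cells(cfg)
    write_counts_mtx(matrix, root)
    write_signature(sig, root / "signature.tsv")
    truth.to_csv(root / "truth.tsv", sep="\t", index=False)
    truth[["barcode", "sample"]].to_csv(root / "samples.tsv", sep="\t",
                                        index=False)
    return root, matrix, truth


@pytest.fixture(scope="session")
def default_cv_accuracies():
    """Five-round repeated-resampling accuracies at the reference design:
    10 CD4 + 5 CD8 sources, 1,000 training cells each per round."""
    sources = ic.simulate_tcell_sources(seed=11)
    return ic.cross_validate(sources, 1000, TCellTrainConfig(seed=11), folds=5)
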