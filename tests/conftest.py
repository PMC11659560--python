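import numpy as np
import pandas as pd
import pytest

import hdcyto as h


def make_table(n_per_sample=(3, 2), n_markers=3, seed=0, with_expr=True):
    """Tiny hand-checkable CytoTable with sequential ids f1_1.. f2_2."""
    rng = np.random.default_rng(seed)
    frames, annos = [], []
    for si, n in enumerate(n_per_sample, start=1):
        ids = [f"f{si}_{j + 1}" for j in range(n)]
        vals = rng.uniform(0, 100, size=(n, n_markers))
        frames.append(
            pd.DataFrame(vals, index=ids, columns=[f"m{k + 1}" for k in range(n_markers)])
        )
        annos.append(pd.DataFrame({"sample_id": f"s{si}"}, index=ids))
    expr_raw = pd.concat(frames)
    anno = pd.concat(annos)
    meta = pd.DataFrame(
        {"group": [["a", "b"][i % 2] for i in range(len(n_per_sample))]},
        index=pd.Index([f"s{i + 1}" for i in range(len(n_per_sample))], name="sample_id"),
    )
    t = h.CytoTable(expr_raw=expr_raw, anno=anno, sample_meta=meta)
    if with_expr:
        t.expr = expr_raw.astype(float).copy()
    return t


@pytest.fixture
def tiny_table():
    return make_table()


@pytest.fixture(scope="session")
def pbmc_table():
    """Shared small PBMC-like dataset with PCA computed."""
    design = h.make_fixture("pbmc_like", seed=11)
    design.cells_per_sample = 300
    table = h.simulate(design)
    return h.run_pca(table, n_pc=8)


@pytest.fixture(scope="session")
def gauss3_table():
    """Three well-separated Gaussian populations (for embeddings/clustering)."""
    design = h.separated_mixture_design(
        3, n_markers=8, level=6.0, min_separation=10.0,
        n_samples=2, cells_per_sample=300, seed=5,
    )
    return h.simulate(design)
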