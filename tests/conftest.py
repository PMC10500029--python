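import numpy as np
import pandas as pd
import pytest

import nichecnn as nc


def make_raw_table(n_cells=30, n_images=2, markers=("m1", "m2"), seed=0):
    """Small hand-rolled raw table: one sample per image pair, 2 conditions."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        img = i % n_images
        rows.append(
            {
                "cell_id": i,
                "sample_id": f"s{img // 1}",
                "image_id": f"img{img}",
                "x": rng.random(),
                "y": rng.random(),
                "cell_type": "A" if i % 3 else "B",
                "condition": "c0",
            }
        )
    df = pd.DataFrame(rows)
    for m in markers:
        df[m] = rng.gamma(2.0, 1.0, size=n_cells)
    return nc.CellTable(df, list(markers))


@pytest.fixture(scope="session")
def small_cohort_raw():
    cfg = nc.SyntheticConfig(
        samples_per_condition=3, images_per_sample=2, cells_per_image=300, seed=5
    )
    return cfg, nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_raw):
    _, table = small_cohort_raw
    return nc.preprocess_intensities(table)


@pytest.fixture(scope="session")
def local_inputs(small_cohort):
    return nc.build_local_inputs(small_cohort, "granulocyte", k=8, seed=3)


def one_hot_model(markers, marker, task="classification", n_classes=2):
    """A fixed single-filter model whose response is exactly one marker."""
    M = len(markers)
    w = np.zeros((1, M))
    w[0, markers.index(marker)] = 1.0
    head = np.ones((1, n_classes)) if task == "classification" else np.ones(1)
    return nc.TrainedModel(
        filter_weights=w,
        filter_biases=np.zeros(1),
        pooling="mean",
        head_weights=head,
        head_bias=np.zeros(n_classes) if task == "classification" else np.zeros(()),
        task=task,
        classes=list(range(n_classes)) if task == "classification" else None,
        feature_names=list(markers),
    )
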