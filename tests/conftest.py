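import numpy as np
import pandas as pd
import pytest

from xnorm_bench import (
    ExpressionMatrix,
    SampleAnnotation,
    SyntheticSpec,
    generate_paired,
    prepare_effects,
)

SMALL_BATCH_PLAN = (
    ("t1", "b1", 8),
    ("t1", "b2", 8),
    ("t2", "b3", 8),
)


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """24-sample, 40-marker spec for fast pipeline tests."""
    params = dict(
        n_samples=24,
        n_markers=40,
        replicate_range=(2, 4),
        batch_plan=SMALL_BATCH_PLAN,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture(scope="session")
def small_paired():
    return generate_paired(small_spec(seed=5))


@pytest.fixture(scope="session")
def small_effects(small_paired):
    eff, report = prepare_effects(small_paired, alpha=0.05)
    return eff


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_matrix():
    """6 probes x 3 samples, 2 markers x 3 replicates, linear scale."""
    values = pd.DataFrame(
        np.array(
            [
                [8.0, 4.0, 2.0],
                [8.0, 4.0, 2.0],
                [16.0, 2.0, 4.0],
                [1.0, 1.0, 1.0],
                [2.0, 8.0, 2.0],
                [4.0, 2.0, 8.0],
            ]
        ),
        index=[f"p{i}" for i in range(1, 7)],
        columns=["s1", "s2", "s3"],
    )
    marker_map = pd.Series(
        ["m1", "m1", "m1", "m2", "m2", "m2"], index=values.index
    )
    return ExpressionMatrix(values, marker_map, "linear")


def make_annotation(n: int, groups=None, batch_sizes=(8, 8, 8)) -> SampleAnnotation:
    if groups is None:
        groups = ["endometrial", "ovarian"] * (n // 2)
    batch, tech = [], []
    for i, size in enumerate(batch_sizes):
        batch.extend([f"b{i + 1}"] * size)
        tech.extend(["t1" if i < len(batch_sizes) // 2 else "t2"] * size)
    pos = np.arange(n)
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": [f"s{i + 1}" for i in range(n)],
                "tumor_group": groups,
                "array_index": pos + 1,
                "technician": tech[:n],
                "batch": batch[:n],
                "slide": [f"sl{p // 8}" for p in pos],
                "slide_row": (pos % 8) // 4 + 1,
                "slide_col": pos % 4 + 1,
            }
        )
    )
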