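"""Preprocessing and the six test-data normalization schemes.

Preprocessing order is fixed: log2 transform -> across-sample normalization at
probe level -> marker-replicate summarization by the median.  Training data
are normalized with quantile normalization (QN, primary) or median
normalization (MN, alternative).  Test data are normalized by one of six
methods:

``NN``   no normalization (identity);
``MN``   median normalization of the test matrix alone;
``QN``   quantile normalization of the test matrix alone;
``fMN``  frozen MN: each test column shifted so its median equals the
         reference median frozen from the normalized training data;
``fQN``  frozen QN: each test column's empirical distribution mapped onto the
         frozen reference quantiles of the normalized training data,
         independently per sample;
``pQN``  pooled QN: QN of the column-concatenation of training and test data,
         returning the test columns.

The frozen methods learn their parameters from training data only and can be
applied to a single prospective sample; they are the leakage-free contract
this package exists to benchmark.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import LOG2, ExpressionMatrix

TEST_METHODS = ("NN", "MN", "QN", "fMN", "fQN", "pQN")
TRAIN_METHODS = ("QN", "MN")
FROZEN_METHODS = ("fMN", "fQN")


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary preprocessing steps
# ---------------------------------------------------------------------------


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a linear-scale matrix; errors on nonpositive cells."""
    if matrix.scale == LOG2:
        raise NormalizationError("matrix is already log2 scale")
    vals = matrix.values.to_numpy()
    bad = np.argwhere(vals <= 0)
    if len(bad):
        r, c = bad[0]
        raise NormalizationError(
            f"{len(bad)} nonpositive values; first at probe "
            f"{matrix.probe_ids[r]!r}, sample {matrix.sample_ids[c]!r}"
        )
    out = pd.DataFrame(np.log2(vals), index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.with_values(out, scale=LOG2)


def ensure_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix if matrix.scale == LOG2 else log2_transform(matrix)


def summarize_replicates(values: pd.DataFrame, marker_map: pd.Series) -> pd.DataFrame:
    """Collapse replicate probes to one row per marker via the median.

    Vectorized by replicate-count class: probes are grouped by marker, markers
    with the same replicate count are stacked into a 3-D block and reduced
    with a single median call.
    """
    mm = marker_map.loc[values.index]
    if mm.isna().any():
        raise NormalizationError("probes without marker assignment")
    arr = values.to_numpy()
    codes, markers = pd.factorize(mm.to_numpy(), sort=True)
    counts = np.bincount(codes, minlength=len(markers))
    if (counts == 0).any():
        raise NormalizationError("marker with zero probes")
    order = np.argsort(codes, kind="stable")
    arr_sorted = arr[order]
    starts = np.concatenate([[0], np.cumsum(counts)])
    out = np.empty((len(markers), arr.shape[1]))
    for c in np.unique(counts):
        which = np.flatnonzero(counts == c)
        rows = np.concatenate([np.arange(starts[m], starts[m] + c) for m in which])
        block = arr_sorted[rows].reshape(len(which), c, arr.shape[1])
        out[which] = np.median(block, axis=1)
    return pd.DataFrame(out, index=pd.Index(markers, name="marker_id"), columns=values.columns)


# ---------------------------------------------------------------------------
# normalization primitives
# ---------------------------------------------------------------------------


def median_normalize(
    values: pd.DataFrame, target: float | str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Shift each column so its median equals a common target.

    Default target is the median of the per-column medians of this matrix.
    Returns the normalized matrix and the per-sample additive shifts.
    """
    medians = values.median(axis=0)
    if target is None or target == "median_of_medians":
        target_val = float(medians.median())
    else:
        target_val = float(target)
    shifts = target_val - medians
    return values.add(shifts, axis=1), shifts


def _map_columns_to_reference(arr: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace each column's values by reference quantiles at its ranks.

    ``reference`` must be sorted and the same length as the columns.  Tied
    values receive the mean of the reference values at the tied rank
    positions (the "average ties" dialect), so equal inputs map to equal
    outputs.
    """
    n, _ = arr.shape
    # sort stability is irrelevant here: within a tie group the assigned
    # reference values are averaged, so any order gives the same output
    order = np.argsort(arr, axis=0)
    out = np.empty_like(arr, dtype=float)
    np.put_along_axis(out, order, np.asarray(reference, dtype=float)[:, None], axis=0)
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    tie_cols = np.flatnonzero((sorted_vals[1:] == sorted_vals[:-1]).any(axis=0))
    for j in tie_cols:  # average reference values over tie groups
        col = arr[:, j]
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=out[:, j], minlength=len(uniq))
        cnt = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / cnt)[inverse]
    return out


def quantile_normalize(values: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classic across-sample quantile normalization.

    The reference is the mean across columns of the within-column sorted
    values; every column is then mapped onto that reference at its own ranks.
    Returns the normalized matrix and the reference quantile vector.
    """
    if values.shape[1] < 2:
        raise NormalizationError("quantile normalization needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = _map_columns_to_reference(arr, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns), reference


# ---------------------------------------------------------------------------
# frozen models
# ---------------------------------------------------------------------------


@dataclass
class NormalizationModel:
    """Frozen test-data normalization parameters learned from training data.

    ``fMN`` stores a reference median (the grand median of the normalized
    training matrix); ``fQN`` stores the reference quantile vector (sorted,
    length = probe count).  ``fitted_on`` is a fingerprint of the training
    matrix for provenance.
    """

    method: str
    reference_median: float | None = None
    reference_quantiles: np.ndarray | None = None
    n_probes: int | None = None
    fitted_on: str | None = None

    def __post_init__(self) -> None:
        if self.method not in FROZEN_METHODS:
            raise NormalizationError(f"not a frozen method: {self.method!r}")
        if self.reference_quantiles is not None:
            rq = np.asarray(self.reference_quantiles, dtype=float)
            if np.any(np.diff(rq) < 0):
                raise NormalizationError("reference quantiles must be nondecreasing")
            self.reference_quantiles = rq

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "reference_median": self.reference_median,
            "reference_quantiles": (
                None
                if self.reference_quantiles is None
                else self.reference_quantiles.tolist()
            ),
            "n_probes": self.n_probes,
            "fitted_on": self.fitted_on,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormalizationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        rq = d.get("reference_quantiles")
        return cls(
            method=d["method"],
            reference_median=d.get("reference_median"),
            reference_quantiles=None if rq is None else np.asarray(rq, dtype=float),
            n_probes=d.get("n_probes"),
            fitted_on=d.get("fitted_on"),
        )


def _fingerprint(values: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(values.to_numpy()).tobytes())
    h.update(",".join(map(str, values.columns)).encode())
    return h.hexdigest()[:16]


def normalize_train(values: pd.DataFrame, method: str) -> pd.DataFrame:
    """Normalize a log2 training matrix by its training method (QN or MN)."""
    if method == "QN":
        out, _ = quantile_normalize(values)
    elif method == "MN":
        out, _ = median_normalize(values)
    else:
        raise NormalizationError(f"training normalization must be QN or MN, got {method!r}")
    return out


def freeze_reference(normalized_train: pd.DataFrame, method: str) -> NormalizationModel:
    """Freeze reference parameters from an already-normalized training matrix.

    ``fQN`` freezes the empirical reference distribution (for QN-trained data
    this equals the QN reference vector, i.e. any column's sorted values,
    averaged across columns for robustness to ties); ``fMN`` freezes the
    grand median of the normalized training matrix.
    """
    if method not in FROZEN_METHODS:
        raise NormalizationError(f"nothing to freeze for method {method!r}")
    fp = _fingerprint(normalized_train)
    if method == "fQN":
        arr = normalized_train.to_numpy(dtype=float)
        reference = np.sort(arr, axis=0).mean(axis=1)
        return NormalizationModel(
            "fQN", reference_quantiles=reference, n_probes=arr.shape[0], fitted_on=fp
        )
    grand_median = float(np.median(normalized_train.to_numpy()))
    return NormalizationModel(
        "fMN",
        reference_median=grand_median,
        n_probes=normalized_train.shape[0],
        fitted_on=fp,
    )


def _frozen_qn_apply(
    values: pd.DataFrame, reference: np.ndarray, interpolate: bool = True
) -> pd.DataFrame:
    """Map each column independently onto the frozen reference distribution."""
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    if n == len(reference):
        out = _map_columns_to_reference(arr, reference)
    else:
        if not interpolate:
            raise NormalizationError(
                f"probe count {n} does not match reference length {len(reference)}"
            )
        # linear interpolation of the reference empirical quantile function
        ref_q = (np.arange(len(reference)) + 0.5) / len(reference)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            ranks = rankdata(arr[:, j], method="average")
            out[:, j] = np.interp((ranks - 0.5) / n, ref_q, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_test(
    values: pd.DataFrame,
    method: str,
    model: NormalizationModel | None = None,
    train_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply one of the six test-data normalization methods to a log2 matrix.

    ``fMN``/``fQN`` require a frozen ``model``; ``pQN`` requires the
    (unnormalized, log2) training matrix ``train_values``.  NN/MN/QN need no
    external context.  MN, fMN and fQN act independently per sample, so a
    single-column test matrix is supported for those methods.
    """
    if method == "NN":
        return values.copy()
    if method == "MN":
        out, _ = median_normalize(values)
        return out
    if method == "QN":
        out, _ = quantile_normalize(values)
        return out
    if method == "fMN":
        if model is None or model.method != "fMN" or model.reference_median is None:
            raise NormalizationError("fMN requires a frozen fMN model")
        shifts = model.reference_median - values.median(axis=0)
        return values.add(shifts, axis=1)
    if method == "fQN":
        if model is None or model.method != "fQN" or model.reference_quantiles is None:
            raise NormalizationError("fQN requires a frozen fQN model")
        return _frozen_qn_apply(values, model.reference_quantiles)
    if method == "pQN":
        if train_values is None:
            raise NormalizationError("pQN requires the log2 training matrix")
        if not values.index.equals(train_values.index):
            raise NormalizationError("pQN: training and test probe sets differ")
        pooled = pd.concat([train_values, values], axis=1)
        normed, _ = quantile_normalize(pooled)
        return normed.iloc[:, train_values.shape[1]:]
    raise NormalizationError(f"unknown test normalization method {method!r}")
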