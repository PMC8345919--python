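"""Decompose paired datasets into biologic and handling effects.

The uniformly handled dataset approximates the biologic effects of each
sample ("virtual samples").  The per-array handling effects ("virtual
arrays") are the difference nonuniform - uniform for the same sample, taken
on the log2 scale and ordered by array collection order.  Both live on the
probe axis of the paired data.

The biologic signal is then attenuated to the typical strength of a molecular
classification study: markers differentially expressed between the two tumor
groups at P < alpha are flagged, and a fraction (default one half) of the
marker-level group-mean difference is subtracted from the flagged markers'
replicate probes in the samples of the target group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, PairedDatasets
from .normalize import ensure_log2, summarize_replicates


@dataclass
class EffectsPair:
    """Virtual samples and virtual arrays extracted from a paired dataset.

    ``biologic``: probes x samples, log2, one column per virtual sample.
    ``handling``: probes x arrays, log2, columns in collection order.
    ``array_meta``: one row per handling column (array_index, technician,
    batch, slide, slide_row, slide_col), aligned with ``handling.columns``.
    """

    biologic: pd.DataFrame
    handling: pd.DataFrame
    marker_map: pd.Series
    group_labels: pd.Series
    array_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.biologic.index.equals(self.handling.index):
            raise DataError("biologic and handling matrices must share the probe axis")
        if len(self.array_meta) != self.handling.shape[1]:
            raise DataError("array_meta must describe every handling column")


def estimate_biologic_effects(paired: PairedDatasets) -> pd.DataFrame:
    """Biologic effects = the log2 uniformly handled data, one column per sample."""
    uni = ensure_log2(paired.uniform)
    return uni.values.copy()


def estimate_handling_effects(paired: PairedDatasets) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Handling effect of each array: log2(nonuniform) - log2(uniform), per sample.

    Returns the handling matrix with columns ordered by array collection
    order, plus the per-array metadata table in the same order.
    """
    uni = ensure_log2(paired.uniform)
    non = ensure_log2(paired.nonuniform)
    if list(uni.sample_ids) != list(non.sample_ids):
        raise DataError("paired matrices have misaligned sample columns")
    diff = non.values - uni.values
    ann = paired.annotation.by_collection_order()
    handling = diff.loc[:, ann["sample_id"]]
    handling.columns = [f"array{int(i):03d}" for i in ann["array_index"]]
    meta = ann[["array_index", "technician", "batch", "slide", "slide_row", "slide_col"]].copy()
    meta.index = handling.columns
    return handling, meta


def decompose(paired: PairedDatasets) -> EffectsPair:
    """Convenience wrapper building an :class:`EffectsPair` from paired data."""
    biologic = estimate_biologic_effects(paired)
    handling, meta = estimate_handling_effects(paired)
    groups = paired.annotation.groups.loc[biologic.columns]
    return EffectsPair(biologic, handling, paired.uniform.marker_map, groups, meta)


def flag_de_markers(
    biologic: pd.DataFrame,
    marker_map: pd.Series,
    group_labels: pd.Series,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Flag differentially expressed markers between the two tumor groups.

    Probe-level values are first summarized to marker level (median over
    replicate probes); each marker is then tested with a two-sided two-sample
    t-test (Welch by default) and flagged when P < ``alpha``.  Returns a
    report with one row per marker: p_value, group_diff (second group minus
    first, in sorted label order) and the flag.
    """
    labels = group_labels.loc[biologic.columns]
    levels = sorted(labels.unique().tolist())
    if len(levels) != 2:
        raise DataError(f"need exactly 2 groups, got {levels}")
    a_mask = (labels == levels[0]).to_numpy()
    b_mask = (labels == levels[1]).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise DataError("each group needs at least 2 samples for the t-test")
    marker = summarize_replicates(biologic, marker_map)
    a = marker.to_numpy()[:, a_mask]
    b = marker.to_numpy()[:, b_mask]
    res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue)
    diffs = b.mean(axis=1) - a.mean(axis=1)
    report = pd.DataFrame(
        {
            "p_value": pvals,
            "group_diff": diffs,
            "flagged": pvals < alpha,
        },
        index=marker.index,
    )
    return report


def attenuate_signal(
    biologic: pd.DataFrame,
    marker_map: pd.Series,
    group_labels: pd.Series,
    flagged_markers,
    fraction: float = 0.5,
    target_group: str | None = None,
) -> pd.DataFrame:
    """Shrink the between-group differences of the flagged markers.

    For each flagged marker, ``fraction`` x (mean_target - mean_other) of the
    marker-level group means is subtracted from every replicate probe of that
    marker in every sample of the target group (default: the second group in
    sorted label order, the ovarian samples in the motivating study).  Other
    samples and unflagged markers are untouched, so after attenuation a
    flagged marker's group-mean difference equals (1 - fraction) times its
    original value.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DataError("fraction must be in [0, 1]")
    flagged = pd.Index(flagged_markers)
    mm = marker_map.loc[biologic.index]
    unknown = flagged.difference(pd.Index(mm.unique()))
    if len(unknown):
        raise DataError(f"flagged markers not in the marker map: {list(unknown)[:5]}")
    if fraction == 0.0 or len(flagged) == 0:
        return biologic.copy()

    labels = group_labels.loc[biologic.columns]
    levels = sorted(labels.unique().tolist())
    if target_group is None:
        target_group = levels[1]
    if target_group not in levels:
        raise DataError(f"target group {target_group!r} not among {levels}")
    other = [g for g in levels if g != target_group][0]

    marker = summarize_replicates(biologic, marker_map)
    t_mask = (labels == target_group).to_numpy()
    o_mask = (labels == other).to_numpy()
    mean_diff = (
        marker.to_numpy()[:, t_mask].mean(axis=1) - marker.to_numpy()[:, o_mask].mean(axis=1)
    )
    shift = pd.Series(fraction * mean_diff, index=marker.index)

    out = biologic.copy()
    probe_shift = shift.reindex(mm.to_numpy()).to_numpy()
    probe_shift = np.where(pd.Index(mm.to_numpy()).isin(flagged), probe_shift, 0.0)
    out.loc[:, t_mask] = out.loc[:, t_mask].sub(
        pd.Series(probe_shift, index=out.index), axis=0
    )
    return out


def attenuation_report(
    before: pd.DataFrame,
    after: pd.DataFrame,
    marker_map: pd.Series,
    group_labels: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Marker-level report of the attenuation step (p-values before/after)."""
    rep_before = flag_de_markers(before, marker_map, group_labels, alpha)
    rep_after = flag_de_markers(after, marker_map, group_labels, alpha)
    return pd.DataFrame(
        {
            "p_value": rep_before["p_value"],
            "group_diff": rep_before["group_diff"],
            "flagged": rep_before["flagged"],
            "attenuated_diff": rep_after["group_diff"],
            "p_value_after": rep_after["p_value"],
            "flagged_after": rep_after["flagged"],
        }
    )
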