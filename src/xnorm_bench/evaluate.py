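"""Scenario execution and the Error_HE vs Error_noHE evaluation protocol.

For each simulated run the training data are normalized once (QN or MN),
frozen reference parameters are learned from the normalized training data,
replicates are summarized to marker level and a classifier is fit with
cross-validated tuning.  Each requested test-data normalization method is
then applied to two versions of the test data — with handling effects
(Error_HE) and the biologic-only reference (Error_noHE) — and the
misclassification error of the frozen classifier is recorded for both.  A
normalization method performs well when its Error_HE both approximates its
Error_noHE (small handling-induced bias) and is small in absolute terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .classify import (
    fit_nsc,
    fit_penalized_logistic,
    misclassification_error,
    predict_nsc,
    predict_penalized_logistic,
)
from .data_model import DataError, PairedDatasets
from .effects import EffectsPair, attenuate_signal, decompose, flag_de_markers
from .normalize import (
    freeze_reference,
    normalize_test,
    normalize_train,
    summarize_replicates,
)
from .rehyb import ScenarioConfig, SimulatedRun, scale_handling, simulate_run, split_virtual_arrays
from .synthetic import SyntheticSpec, generate_paired

logger = logging.getLogger("xnorm_bench")

RUN_COLUMNS = [
    "run_index",
    "run_seed",
    "he_setting",
    "c",
    "f",
    "train_design",
    "test_design",
    "train_norm",
    "classifier",
    "method",
    "error_he",
    "error_nohe",
    "n_active",
    "tuning_value",
]


@dataclass
class EvaluationResult:
    """Per-run records plus scenario-level summaries."""

    runs: pd.DataFrame  # one row per run x test normalization method
    summary: pd.DataFrame  # one row per method
    config: ScenarioConfig

    def write(self, runs_path, summary_path) -> None:
        self.runs.to_csv(runs_path, sep="\t", index=False)
        self.summary.to_csv(summary_path, sep="\t", index=False)


def _fit_classifier(kind: str, X, y, seed: int):
    if kind == "NSC":
        model = fit_nsc(X, y, seed=seed)
        return model, predict_nsc, float(model.delta), model.n_active
    if kind == "penalized_logistic":
        model = fit_penalized_logistic(X, y, seed=seed)
        return model, predict_penalized_logistic, float(model.lam), model.n_active
    raise DataError(f"unknown classifier {kind!r}")


def run_single(run: SimulatedRun, config: ScenarioConfig) -> list[dict]:
    """Evaluate one simulated run under every requested test normalization.

    The classifier and the frozen normalization models are fit once on the
    training data; Error_noHE for the frozen methods reuses the same frozen
    model, so training never sees either version of the test data.
    """
    c, f = config.cf
    train_norm = normalize_train(run.train_values, config.train_norm)
    frozen = {m: freeze_reference(train_norm, m) for m in ("fMN", "fQN")}
    train_marker = summarize_replicates(train_norm, run.marker_map)
    model, predict, tuning_value, n_active = _fit_classifier(
        config.classifier, train_marker, run.train_labels, seed=run.run_seed
    )

    records = []
    for method in config.test_norms:
        kwargs = {
            "model": frozen.get(method),
            "train_values": run.train_values if method == "pQN" else None,
        }
        errs = {}
        for tag, test_values in (
            ("error_he", run.test_values_he),
            ("error_nohe", run.test_values_nohe),
        ):
            normed = normalize_test(test_values, method, **kwargs)
            marker = summarize_replicates(normed, run.marker_map)
            pred = predict(model, marker)
            errs[tag] = misclassification_error(pred, run.test_labels)
        records.append(
            {
                "run_index": run.run_seed - config.seed,
                "run_seed": run.run_seed,
                "he_setting": config.he_setting,
                "c": c,
                "f": f,
                "train_design": config.train_design,
                "test_design": config.test_design,
                "train_norm": config.train_norm,
                "classifier": config.classifier,
                "method": method,
                "error_he": errs["error_he"],
                "error_nohe": errs["error_nohe"],
                "n_active": n_active,
                "tuning_value": tuning_value,
            }
        )
    return records


def prepare_effects(
    paired: PairedDatasets,
    alpha: float = 0.01,
    attenuation: float = 0.5,
    target_group: str | None = None,
) -> tuple[EffectsPair, pd.DataFrame]:
    """Decompose paired data and attenuate the biologic signal.

    Flags differentially expressed markers at P < ``alpha``, subtracts
    ``attenuation`` of the flagged markers' group-mean differences from the
    target group, and returns the resulting effect pair plus the marker
    report.
    """
    eff = decompose(paired)
    report = flag_de_markers(eff.biologic, eff.marker_map, eff.group_labels, alpha)
    flagged = report.index[report["flagged"]]
    logger.info("flagged %d of %d markers at P < %g", len(flagged), len(report), alpha)
    attenuated = attenuate_signal(
        eff.biologic,
        eff.marker_map,
        eff.group_labels,
        flagged,
        fraction=attenuation,
        target_group=target_group,
    )
    eff = EffectsPair(
        attenuated, eff.handling, eff.marker_map, eff.group_labels, eff.array_meta
    )
    return eff, report


def run_scenario(
    source: EffectsPair | PairedDatasets | SyntheticSpec,
    config: ScenarioConfig,
    alpha: float = 0.01,
    attenuation: float = 0.5,
) -> EvaluationResult:
    """Execute a full scenario: ``config.n_runs`` independent runs, summarized.

    ``source`` may be an already-prepared :class:`EffectsPair`, a
    :class:`PairedDatasets` (decomposed and attenuated here), or a
    :class:`SyntheticSpec` (generated, then decomposed and attenuated).
    The nonrandom array split and handling scaling are computed once; the
    sample split and allocations are re-drawn per run.
    """
    if isinstance(source, SyntheticSpec):
        source = generate_paired(source)
    if isinstance(source, PairedDatasets):
        effects, _ = prepare_effects(source, alpha=alpha, attenuation=attenuation)
    else:
        effects = source

    c, f = config.cf
    train_pos, test_pos = split_virtual_arrays(effects.handling.shape[1])
    scaled = scale_handling(effects.handling, train_pos, test_pos, c, f)

    records: list[dict] = []
    for i in range(config.n_runs):
        try:
            run = simulate_run(effects, config, run_index=i, scaled=scaled)
            recs = run_single(run, config)
        except Exception:
            logger.error("scenario aborted at run_seed=%d", config.seed + i)
            raise
        records.extend(recs)
        logger.debug("run %d/%d done", i + 1, config.n_runs)

    runs = pd.DataFrame(records, columns=RUN_COLUMNS)
    summary = summarize_runs(runs)
    return EvaluationResult(runs, summary, config)


def summarize_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run records to one row per scenario x method."""
    keys = ["he_setting", "c", "f", "train_design", "test_design", "train_norm", "classifier", "method"]
    grouped = runs.groupby(keys, sort=False)
    summary = grouped.agg(
        n_runs=("error_he", "size"),
        mean_error_he=("error_he", "mean"),
        mean_error_nohe=("error_nohe", "mean"),
        sd_error_he=("error_he", "std"),
        sd_error_nohe=("error_nohe", "std"),
    ).reset_index()
    summary["mean_bias"] = summary["mean_error_he"] - summary["mean_error_nohe"]
    abs_bias = (runs["error_he"] - runs["error_nohe"]).abs()
    summary["mean_abs_bias"] = (
        abs_bias.groupby([runs[k] for k in keys], sort=False).mean().to_numpy()
    )
    return summary


def summarize_grid(results) -> pd.DataFrame:
    """Long-format grid table across scenarios (one row per scenario x method).

    Accepts an iterable of :class:`EvaluationResult` or per-run DataFrames;
    the output matches the scatter layout of mean Error_noHE (x) against mean
    Error_HE (y) with the bias column their difference.
    """
    frames = []
    for r in results:
        frames.append(r.runs if isinstance(r, EvaluationResult) else pd.DataFrame(r))
    if not frames:
        raise DataError("no results to summarize")
    allruns = pd.concat(frames, ignore_index=True)
    return summarize_runs(allruns)


def fixed_split_evaluation(
    paired: PairedDatasets,
    methods=("QN", "fQN"),
    train_norm: str = "QN",
    classifier: str = "NSC",
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Prospective fixed-split evaluation of the paired data themselves.

    The samples are ordered by array collection order; the first 2/3 (128 of
    192) of the nonuniformly handled data train the classifier and the last
    1/3 are the external test set.  Error_HE uses their nonuniformly handled
    profiles, Error_noHE the uniformly handled profiles of the same test
    samples.  Returns one row per test-normalization method.
    """
    from .normalize import ensure_log2

    uni = ensure_log2(paired.uniform)
    non = ensure_log2(paired.nonuniform)
    ann = paired.annotation.by_collection_order()
    ordered = ann["sample_id"].tolist()
    n = len(ordered)
    n_train = int(round(n * train_fraction))
    train_ids, test_ids = ordered[:n_train], ordered[n_train:]
    labels = paired.annotation.groups

    train_values = non.values[train_ids]
    train_normed = normalize_train(train_values, train_norm)
    frozen = {m: freeze_reference(train_normed, m) for m in ("fMN", "fQN")}
    train_marker = summarize_replicates(train_normed, non.marker_map)
    model, predict, tuning_value, n_active = _fit_classifier(
        classifier, train_marker, labels.loc[train_ids], seed=seed
    )

    rows = []
    for method in methods:
        kwargs = {
            "model": frozen.get(method),
            "train_values": train_values if method == "pQN" else None,
        }
        errs = {}
        for tag, source in (("error_he", non), ("error_nohe", uni)):
            normed = normalize_test(source.values[test_ids], method, **kwargs)
            marker = summarize_replicates(normed, non.marker_map)
            pred = predict(model, marker)
            errs[tag] = misclassification_error(pred, labels.loc[test_ids])
        rows.append({"method": method, **errs, "n_active": n_active, "tuning_value": tuning_value})
    return pd.DataFrame(rows)
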