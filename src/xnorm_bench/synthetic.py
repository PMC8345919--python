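"""Synthetic paired datasets with the structure the benchmark assumes.

The generator emulates the paired miRNA microarray study the framework was
built around: 192 tumor samples in two balanced groups, ~3,523 markers each
represented by 10-40 replicate probes, profiled twice — once uniformly
handled (biologic signal plus small measurement noise) and once nonuniformly
handled (signal plus batch/technician handling effects, arrays processed in
collection order over 5 batches split 80/112 between two technicians, slides
of 8 arrays in a 2 x 4 layout).

Biologic effects are parametric: marker-level value for sample j and marker
m is Normal(mu_m + group_j * delta_m, sigma_m^2) on the log2 scale, with
delta_m != 0 for the differentially expressed subset; replicate probes add
independent Normal(0, sigma_rep^2) noise.  Handling effects are additive on
the log2 scale: for an array in batch b,

    h_pa = tech_offset(b) + alpha_b + beta_b * t_p + Normal(0, (gamma_b tau)^2)

per probe p, where alpha_b is a batch location shift, t_p a probe-specific
trend shared across batches, beta_b the batch's coefficient on it and
gamma_b a per-batch scale factor on the probe-level noise.  This
parametric form is a deliberate stand-in for empirically estimated handling
effects, which it matches in scale and batch structure but not in
probe-probe correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import LOG2, ExpressionMatrix, PairedDatasets, SampleAnnotation

#: technician/batch plan of the nonuniformly handled collection:
#: technician A ran the first 80 arrays in two batches, technician B the
#: last 112 in three batches.
DEFAULT_BATCH_PLAN = (
    ("techA", "batch1", 40),
    ("techA", "batch2", 40),
    ("techB", "batch3", 38),
    ("techB", "batch4", 37),
    ("techB", "batch5", 37),
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic paired-dataset generator (log2 scale).

    Defaults reproduce the motivating study's dimensions.  Handling-effect
    magnitudes default to values giving clearly batch-structured effects of
    about one log2 unit, comparable to real inter-batch array differences.
    """

    n_samples: int = 192
    n_markers: int = 3523
    groups: tuple = ("endometrial", "ovarian")
    replicate_range: tuple = (10, 40)  # inclusive bounds on probes per marker
    de_fraction: float = 0.10  # markers with a planted group effect
    effect_size_range: tuple = (0.3, 0.9)  # |delta_m| / sigma_m, uniform
    marker_mean_range: tuple = (4.0, 12.0)  # mu_m, uniform (log2 intensity)
    marker_sd_range: tuple = (0.3, 1.0)  # sigma_m, uniform
    replicate_sd: float = 0.25  # sigma_rep, probe-level replicate noise
    uniform_noise_sd: float = 0.05  # measurement noise of the uniform dataset
    batch_shift_sd: float = 0.9  # SD of the batch location shifts alpha_b
    batch_trend_sd: float = 0.04  # SD of the batch trend coefficients beta_b
    batch_scale_range: tuple = (0.5, 1.5)  # per-batch scale factors on the noise
    tech_offsets: tuple = (0.0, 1.5)  # per-technician location offsets
    handling_noise_sd: float = 0.06  # tau, probe-level handling noise
    batch_plan: tuple = DEFAULT_BATCH_PLAN
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [int(b[2]) for b in self.batch_plan]
        if sum(sizes) != self.n_samples:
            raise ValueError(
                f"batch plan sums to {sum(sizes)}, expected n_samples={self.n_samples}"
            )
        lo, hi = self.replicate_range
        if not (1 <= lo <= hi <= 64):
            raise ValueError("replicate counts must lie within [1, 64]")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups required")

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "n_markers": self.n_markers,
            "groups": list(self.groups),
            "replicate_range": list(self.replicate_range),
            "de_fraction": self.de_fraction,
            "effect_size_range": list(self.effect_size_range),
            "marker_mean_range": list(self.marker_mean_range),
            "marker_sd_range": list(self.marker_sd_range),
            "replicate_sd": self.replicate_sd,
            "uniform_noise_sd": self.uniform_noise_sd,
            "batch_shift_sd": self.batch_shift_sd,
            "batch_trend_sd": self.batch_trend_sd,
            "batch_scale_range": list(self.batch_scale_range),
            "tech_offsets": list(self.tech_offsets),
            "handling_noise_sd": self.handling_noise_sd,
            "batch_plan": [list(b) for b in self.batch_plan],
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "groups",
            "replicate_range",
            "effect_size_range",
            "marker_mean_range",
            "marker_sd_range",
            "batch_scale_range",
            "tech_offsets",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "batch_plan" in raw:
            raw["batch_plan"] = tuple(tuple(b) for b in raw["batch_plan"])
        return cls(**raw)


def benchmark_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Down-scaled benchmark panel: full study design on fewer markers.

    Keeps the sample size, group balance, batch/technician plan and
    handling-effect magnitudes of the default spec but restricts the panel to
    2,000 markers with 8-16 replicate probes, so a 100-run scenario completes
    in minutes rather than hours.  Used by the acceptance benchmark and the
    heavier tests.
    """
    params = dict(n_markers=2000, replicate_range=(8, 16), seed=seed)
    params.update(overrides)
    return SyntheticSpec(**params)


def _marker_probe_layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Marker ids, per-marker replicate counts and the probe -> marker map."""
    lo, hi = spec.replicate_range
    markers = [f"m{i + 1:05d}" for i in range(spec.n_markers)]
    counts = rng.integers(lo, hi + 1, size=spec.n_markers)
    probe_ids = []
    marker_of = []
    for m, c in zip(markers, counts):
        for r in range(c):
            probe_ids.append(f"{m}_p{r + 1:02d}")
            marker_of.append(m)
    marker_map = pd.Series(marker_of, index=pd.Index(probe_ids, name="probe_id"))
    return markers, counts, marker_map


def build_annotation(spec: SyntheticSpec, rng: np.random.Generator) -> SampleAnnotation:
    """Sample annotation: balanced groups interleaved at random along the
    collection order, batches per the plan, slides of 8 arrays (2 x 4)."""
    n = spec.n_samples
    half = n // 2
    groups = np.array([spec.groups[0]] * half + [spec.groups[1]] * (n - half), dtype=object)
    groups = groups[rng.permutation(n)]
    tech, batch = [], []
    for t, b, size in spec.batch_plan:
        tech.extend([t] * size)
        batch.extend([b] * size)
    pos = np.arange(n)
    tab = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "tumor_group": groups,
            "array_index": pos + 1,
            "technician": tech,
            "batch": batch,
            "slide": [f"slide{p // 8 + 1:02d}" for p in pos],
            "slide_row": (pos % 8) // 4 + 1,
            "slide_col": pos % 4 + 1,
        }
    )
    return SampleAnnotation(tab)


def generate_biologic(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Probe-level biologic effects (log2), plus marker map, labels, truth table.

    Returns ``(values, marker_map, group_labels, marker_truth)`` where
    ``marker_truth`` records each marker's mu, sigma and planted delta.
    """
    rng = rng or np.random.default_rng(spec.seed)
    markers, counts, marker_map = _marker_probe_layout(spec, rng)
    ann = build_annotation(spec, rng)
    groups = ann.groups
    is_second = (groups == spec.groups[1]).to_numpy()

    M, n = spec.n_markers, spec.n_samples
    mu = rng.uniform(*spec.marker_mean_range, size=M)
    sigma = rng.uniform(*spec.marker_sd_range, size=M)
    n_de = int(round(spec.de_fraction * M))
    de_idx = rng.choice(M, size=n_de, replace=False)
    delta = np.zeros(M)
    sizes = rng.uniform(*spec.effect_size_range, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    delta[de_idx] = signs * sizes * sigma[de_idx]

    marker_values = (
        mu[:, None]
        + delta[:, None] * is_second[None, :]
        + rng.normal(0.0, 1.0, size=(M, n)) * sigma[:, None]
    )
    probe_rows = np.repeat(np.arange(M), counts)
    values = marker_values[probe_rows] + rng.normal(
        0.0, spec.replicate_sd, size=(len(probe_rows), n)
    )
    df = pd.DataFrame(values, index=marker_map.index, columns=ann.sample_ids)
    truth = pd.DataFrame(
        {"mu": mu, "sigma": sigma, "delta": delta, "is_de": delta != 0.0},
        index=pd.Index(markers, name="marker_id"),
    )
    # annotation is re-derived in generate_paired; stash it for reuse
    df.attrs["annotation"] = ann
    return df, marker_map, groups, truth


def generate_handling(
    spec: SyntheticSpec,
    annotation: SampleAnnotation,
    probe_index: pd.Index,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-array handling effects (probes x arrays, collection order)."""
    rng = rng or np.random.default_rng(spec.seed)
    ann = annotation.by_collection_order()
    n_probes = len(probe_index)
    batches = [b for (_, b, _) in spec.batch_plan]
    techs = {b: t for (t, b, _) in spec.batch_plan}
    tech_levels = list(dict.fromkeys(t for (t, _, _) in spec.batch_plan))
    tech_offset = dict(zip(tech_levels, spec.tech_offsets))

    alpha = {b: rng.normal(0.0, spec.batch_shift_sd) for b in batches}
    beta = {b: rng.normal(0.0, spec.batch_trend_sd) for b in batches}
    gamma = {b: rng.uniform(*spec.batch_scale_range) for b in batches}
    trend = rng.normal(0.0, 1.0, size=n_probes)

    cols = {}
    for _, row in ann.iterrows():
        b = row["batch"]
        base = tech_offset[techs[b]] + alpha[b] + beta[b] * trend
        noise = rng.normal(0.0, gamma[b] * spec.handling_noise_sd, size=n_probes)
        cols[row["sample_id"]] = base + noise
    out = pd.DataFrame(cols, index=probe_index)
    return out[ann["sample_id"]]


def generate_paired(spec: SyntheticSpec) -> PairedDatasets:
    """Full synthetic paired dataset: uniform and nonuniform profiles.

    uniform = biologic + small i.i.d. measurement noise;
    nonuniform = biologic + handling effects.  Shared probes, samples and
    annotation, so the pair is a drop-in replacement for the real data.
    """
    rng = np.random.default_rng(spec.seed)
    biologic, marker_map, groups, truth = generate_biologic(spec, rng)
    ann: SampleAnnotation = biologic.attrs["annotation"]

    uniform_vals = biologic + rng.normal(0.0, spec.uniform_noise_sd, size=biologic.shape)
    handling = generate_handling(spec, ann, biologic.index, rng)
    nonuniform_vals = biologic + handling[biologic.columns].to_numpy()

    uniform = ExpressionMatrix(uniform_vals, marker_map, LOG2)
    nonuniform = ExpressionMatrix(nonuniform_vals, marker_map, LOG2)
    paired = PairedDatasets(uniform, nonuniform, ann)
    # ground truth kept for tests and reports
    uniform.values.attrs["marker_truth"] = truth
    return paired
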