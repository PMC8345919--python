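"""Virtual rehybridization: compose simulated datasets from effect pairs.

A simulation run pairs "virtual samples" (per-sample biologic-effect columns)
with "virtual arrays" (per-array handling-effect columns) and sums them:

1. virtual samples are split randomly 2:1 into training and test sets,
   stratified by tumor group;
2. virtual arrays are split nonrandomly by collection order — first third and
   last third to training, middle third to test — so training and test
   handling effects are systematically different, as real handling effects
   are; their magnitudes are then adjusted by adding a constant ``c`` to
   training columns and multiplying test columns by a factor ``f``;
3. arrays are allocated to samples under a partial-confounding design (90% of
   the early-collection arrays of the set go to one outcome group) or a
   stratification design (each batch's arrays split evenly between groups);
4. each simulated value is biologic effect + allocated handling effect; the
   reference ("noHE") test data are the biologic columns alone.

The array split and handling scaling are fixed across runs of a scenario;
the sample split and allocations are re-randomized per run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import DataError
from .effects import EffectsPair
from .normalize import TEST_METHODS

#: printed handling-effect settings: name -> (c, f) = (additive constant for
#: training handling effects, multiplicative factor for test handling effects)
HE_SETTINGS = {
    "high": (2.0, 2.0),
    "moderate": (1.0, 1.5),
    "slight": (0.5, 1.25),
}

DESIGNS = ("partial_confounding", "stratification")


@dataclass
class ScenarioConfig:
    """One benchmarking scenario: handling-effect level, designs, methods, runs."""

    he_setting: str = "high"
    c: float | None = None  # override the setting's additive constant
    f: float | None = None  # override the setting's multiplicative factor
    train_design: str = "partial_confounding"
    test_design: str = "partial_confounding"
    n_runs: int = 100
    seed: int = 0
    train_norm: str = "QN"
    test_norms: tuple = tuple(TEST_METHODS)
    classifier: str = "NSC"
    pc_train_group: str | None = None  # favored group for train confounding
    pc_test_group: str | None = None  # favored group for test confounding

    def __post_init__(self) -> None:
        if self.he_setting not in HE_SETTINGS and (self.c is None or self.f is None):
            raise DataError(
                f"unknown he_setting {self.he_setting!r}; give explicit c and f"
            )
        if self.train_design not in DESIGNS or self.test_design not in DESIGNS:
            raise DataError(f"designs must be one of {DESIGNS}")
        if self.n_runs < 1:
            raise DataError("n_runs must be >= 1")
        for m in self.test_norms:
            if m not in TEST_METHODS:
                raise DataError(f"unknown test normalization {m!r}")
        self.test_norms = tuple(self.test_norms)

    @property
    def cf(self) -> tuple[float, float]:
        if self.c is not None and self.f is not None:
            return float(self.c), float(self.f)
        return HE_SETTINGS[self.he_setting]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["test_norms"] = list(self.test_norms)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class Allocation:
    """Array -> sample assignment for one set (training or test)."""

    table: pd.DataFrame  # columns: array (handling column id), sample_id, group
    design: str
    role: str

    def array_for(self) -> pd.Series:
        """sample_id -> handling column id."""
        return self.table.set_index("sample_id")["array"]


@dataclass
class SimulatedRun:
    """One virtual-rehybridization run: probe-level log2 data plus labels."""

    train_values: pd.DataFrame
    test_values_he: pd.DataFrame
    test_values_nohe: pd.DataFrame
    train_labels: pd.Series
    test_labels: pd.Series
    marker_map: pd.Series
    run_seed: int
    train_allocation: Allocation | None = None
    test_allocation: Allocation | None = None
    scaled_handling_test: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def split_virtual_samples(
    group_labels: pd.Series,
    seed: int | np.random.Generator,
    train_fraction: float = 2 / 3,
) -> tuple[list, list]:
    """Random split of virtual samples, stratified by tumor group.

    Default ratio 2:1 (train:test); with 96/96 groups this yields 64 train +
    32 test per group.  Reproducible from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train: list = []
    test: list = []
    for level in sorted(group_labels.unique().tolist()):
        ids = group_labels.index[group_labels == level].to_numpy()
        n_train = int(np.floor(len(ids) * train_fraction + 0.5))
        if n_train < 1 or len(ids) - n_train < 1:
            raise DataError(
                f"group {level!r} too small ({len(ids)}) for a {train_fraction:.2f} split"
            )
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:n_train]].tolist())
        test.extend(ids[perm[n_train:]].tolist())
    return train, test


def split_virtual_arrays(n_arrays: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic split of arrays by collection order (1-based positions).

    The first third and last third form the training arrays, the middle the
    test arrays; for 192 arrays: train = 1..64 and 129..192, test = 65..128.
    Handling effects are not reproducible across datasets, so this split is
    nonrandom by design.
    """
    if n_arrays < 6:
        raise DataError("need at least 6 arrays to split")
    k = n_arrays // 3
    pos = np.arange(1, n_arrays + 1)
    train = np.concatenate([pos[:k], pos[n_arrays - k:]])
    test = pos[k: n_arrays - k]
    return train, test


def scale_handling(
    handling: pd.DataFrame,
    train_pos: np.ndarray,
    test_pos: np.ndarray,
    c: float,
    f: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust handling-effect magnitudes: + ``c`` on training, x ``f`` on test.

    Positions are 1-based collection-order indices into the handling columns.
    """
    train_cols = handling.columns[np.asarray(train_pos) - 1]
    test_cols = handling.columns[np.asarray(test_pos) - 1]
    return handling[train_cols] + c, handling[test_cols] * f


# ---------------------------------------------------------------------------
# allocation designs
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def allocate_arrays(
    array_ids,
    array_meta: pd.DataFrame,
    sample_groups: pd.Series,
    design: str,
    rng: np.random.Generator,
    role: str = "train",
    favored_group: str | None = None,
) -> Allocation:
    """Assign the set's virtual arrays to its virtual samples.

    ``array_ids`` are handling-column ids in collection order; ``array_meta``
    carries batch labels for stratification.  ``sample_groups`` maps the
    set's sample ids to their tumor group.

    partial_confounding
        90% (rounded) of the first half of the arrays plus the complement
        from the last half go to the favored group (by default the second
        group in sorted order for training — ovarian in the motivating study
        — and the first group for test), the remaining arrays to the other
        group.  Which specific arrays fill each quota, and the array-sample
        pairing, are uniform-random.
    stratification
        Within each batch, arrays are split as evenly as possible between the
        groups; leftover arrays from odd batches are distributed at random
        subject to each group receiving exactly as many arrays as it has
        samples.
    """
    array_ids = list(array_ids)
    if len(array_ids) != len(sample_groups):
        raise DataError("need exactly one array per sample")
    levels = sorted(sample_groups.unique().tolist())
    if len(levels) != 2:
        raise DataError(f"need exactly 2 groups, got {levels}")
    group_sizes = sample_groups.value_counts().to_dict()

    if design == "partial_confounding":
        if favored_group is None:
            favored_group = levels[1] if role == "train" else levels[0]
        other = [g for g in levels if g != favored_group][0]
        n = len(array_ids)
        first, last = array_ids[: n // 2], array_ids[n // 2:]
        q_first = _round_half_up(0.9 * len(first))
        q_last = group_sizes[favored_group] - q_first
        if q_first > len(first) or q_last < 0 or q_last > len(last):
            raise DataError(
                f"partial confounding infeasible: quota {q_first}+{q_last} for group "
                f"{favored_group!r} with {group_sizes[favored_group]} samples"
            )
        pick_first = rng.permutation(len(first))[:q_first]
        pick_last = rng.permutation(len(last))[:q_last]
        favored_arrays = [first[i] for i in sorted(pick_first)] + [
            last[i] for i in sorted(pick_last)
        ]
        other_arrays = [a for a in array_ids if a not in set(favored_arrays)]
        assignment = {favored_group: favored_arrays, other: other_arrays}
    elif design == "stratification":
        batches = array_meta.loc[array_ids, "batch"]
        assignment = {g: [] for g in levels}
        leftovers: list = []
        for batch in pd.unique(batches):
            members = [a for a in array_ids if batches[a] == batch]
            members = list(rng.permutation(members))
            base = len(members) // 2
            assignment[levels[0]].extend(members[:base])
            assignment[levels[1]].extend(members[base: 2 * base])
            leftovers.extend(members[2 * base:])
        caps = {g: group_sizes[g] - len(assignment[g]) for g in levels}
        if any(v < 0 for v in caps.values()) or sum(caps.values()) != len(leftovers):
            raise DataError("stratification infeasible: batch plan exceeds group capacity")
        leftovers = list(rng.permutation(leftovers))
        assignment[levels[0]].extend(leftovers[: caps[levels[0]]])
        assignment[levels[1]].extend(leftovers[caps[levels[0]]:])
    else:
        raise DataError(f"unknown design {design!r}")

    rows = []
    for g in levels:
        samples = sample_groups.index[sample_groups == g].to_numpy()
        arrays = np.asarray(assignment[g], dtype=object)
        if len(samples) != len(arrays):
            raise DataError(
                f"group {g!r}: {len(arrays)} arrays for {len(samples)} samples"
            )
        samples = samples[rng.permutation(len(samples))]
        for a, s in zip(arrays, samples):
            rows.append({"array": a, "sample_id": s, "group": g})
    table = pd.DataFrame(rows)
    table["batch"] = array_meta.loc[table["array"], "batch"].to_numpy()
    order = {a: i for i, a in enumerate(array_ids)}
    table = table.sort_values("array", key=lambda s: s.map(order)).reset_index(drop=True)
    return Allocation(table, design, role)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def compose_set(
    biologic: pd.DataFrame,
    sample_ids: list,
    scaled_handling: pd.DataFrame,
    allocation: Allocation,
) -> pd.DataFrame:
    """Sum each sample's biologic column with its allocated handling column."""
    array_for = allocation.array_for()
    missing = [s for s in sample_ids if s not in array_for.index]
    if missing:
        raise DataError(f"samples without an allocated array: {missing[:5]}")
    bio = biologic[sample_ids]
    hdl = scaled_handling[array_for.loc[sample_ids]]
    out = bio.to_numpy() + hdl.to_numpy()
    return pd.DataFrame(out, index=biologic.index, columns=sample_ids)


def simulate_run(
    effects: EffectsPair,
    config: ScenarioConfig,
    run_index: int = 0,
    scaled: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SimulatedRun:
    """Build one simulated run (training data, test data with/without HE).

    The array split and handling scaling are deterministic per scenario and
    may be precomputed and passed via ``scaled``; the sample split and
    allocations are drawn from the run seed ``config.seed + run_index``.
    """
    run_seed = config.seed + run_index
    rng = np.random.default_rng(run_seed)
    c, f = config.cf

    n_arrays = effects.handling.shape[1]
    train_pos, test_pos = split_virtual_arrays(n_arrays)
    if scaled is None:
        train_h, test_h = scale_handling(effects.handling, train_pos, test_pos, c, f)
    else:
        train_h, test_h = scaled

    train_ids, test_ids = split_virtual_samples(effects.group_labels, rng)

    train_alloc = allocate_arrays(
        list(train_h.columns),
        effects.array_meta,
        effects.group_labels.loc[train_ids],
        config.train_design,
        rng,
        role="train",
        favored_group=config.pc_train_group,
    )
    test_alloc = allocate_arrays(
        list(test_h.columns),
        effects.array_meta,
        effects.group_labels.loc[test_ids],
        config.test_design,
        rng,
        role="test",
        favored_group=config.pc_test_group,
    )

    train_values = compose_set(effects.biologic, train_ids, train_h, train_alloc)
    test_values_he = compose_set(effects.biologic, test_ids, test_h, test_alloc)
    test_values_nohe = effects.biologic[test_ids].copy()

    return SimulatedRun(
        train_values=train_values,
        test_values_he=test_values_he,
        test_values_nohe=test_values_nohe,
        train_labels=effects.group_labels.loc[train_ids],
        test_labels=effects.group_labels.loc[test_ids],
        marker_map=effects.marker_map,
        run_seed=run_seed,
        train_allocation=train_alloc,
        test_allocation=test_alloc,
        scaled_handling_test=test_h,
    )
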