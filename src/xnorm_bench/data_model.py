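"""Core data structures and I/O for probe-level expression data.

The central container is :class:`ExpressionMatrix`: a probes x samples table of
expression values together with a probe -> marker map (each miRNA marker is
represented by several replicate probes on the array) and a flag recording
whether values are on the linear or log2 scale.  Sample handling metadata
(tumor group, collection order, technician, batch, slide, slide position)
lives in :class:`SampleAnnotation`, and a :class:`PairedDatasets` bundles the
uniformly and nonuniformly handled profiles of the same specimens.

Everything downstream treats a sample as one column, matching the
series-matrix convention.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("xnorm_bench")

LINEAR = "linear"
LOG2 = "log2"

ANNOTATION_COLUMNS = [
    "sample_id",
    "tumor_group",
    "array_index",
    "technician",
    "batch",
    "slide",
    "slide_row",
    "slide_col",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe-level expression values (probes x samples) with a marker map.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    marker_map
        Series mapping each probe id to its marker id.  Every probe must map
        to exactly one marker; a marker may own any number (>= 1) of
        replicate probes.
    scale
        Either ``"linear"`` or ``"log2"``.
    """

    values: pd.DataFrame
    marker_map: pd.Series
    scale: str = LINEAR

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.marker_map = pd.Series(self.marker_map)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise DataError(f"unknown scale flag {self.scale!r}")
        cols = pd.Index(self.values.columns)
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise DataError(f"duplicate sample ids: {dups}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise DataError(f"duplicate probe ids: {dups}")
        if idx.isna().any() or cols.isna().any():
            raise DataError("missing probe or sample identifiers")
        n_na = int(self.values.isna().to_numpy().sum())
        if n_na:
            raise DataError(f"matrix contains {n_na} missing values; complete matrices required")
        missing = idx.difference(self.marker_map.index)
        if len(missing):
            raise DataError(
                f"{len(missing)} probes lack a marker assignment: "
                f"{sorted(map(str, missing[:10]))}{'...' if len(missing) > 10 else ''}"
            )
        # restrict and order the map to the probes present
        self.marker_map = self.marker_map.loc[idx]
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        self.marker_map.index.name = "probe_id"

    # -- conveniences -------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def marker_sizes(self) -> pd.Series:
        """Replicate-probe count per marker."""
        return self.marker_map.value_counts()

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.marker_map, scale or self.scale)

    # -- I/O ----------------------------------------------------------------

    def write_tsv(self, path: str | Path, marker_map_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (first column probe id, header of sample ids).

        If ``marker_map_path`` is given the probe->marker map is written as a
        two-column sidecar TSV; otherwise it is embedded as a ``marker_id``
        column right after the probe ids.
        """
        path = Path(path)
        if marker_map_path is None:
            out = self.values.copy()
            out.insert(0, "marker_id", self.marker_map.loc[out.index].to_numpy())
            out.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")
        else:
            self.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")
            mm = self.marker_map.rename("marker_id")
            mm.to_csv(Path(marker_map_path), sep="\t", index_label="probe_id")


def read_expression_table(
    path: str | Path,
    fmt: str | None = None,
    marker_map: str | Path | pd.Series | None = None,
    scale: str = LINEAR,
) -> ExpressionMatrix:
    """Read a probe-level expression table from TSV or GEO series-matrix text.

    Parameters
    ----------
    path
        Input file.  Format is auto-detected when ``fmt`` is None: files whose
        first non-blank line starts with ``!`` are treated as series-matrix.
    fmt
        ``"tsv"`` or ``"geo_series_matrix"``.
    marker_map
        Probe -> marker assignment, as a Series or a path to a two-column
        sidecar TSV (probe_id, marker_id).  For plain TSV input a
        ``marker_id`` column embedded in the table is used when present.
    scale
        Scale flag to record on the result (the deposited files do not state
        their scale, so the caller decides; default linear).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt is None:
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    fmt = "geo_series_matrix" if line.startswith("!") else "tsv"
                    break
            else:
                raise DataError(f"empty file: {path}")

    if fmt == "tsv":
        _check_duplicate_header(path)
        table = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "geo_series_matrix":
        table = _read_series_matrix(path)
    else:
        raise DataError(f"unknown format {fmt!r}")

    embedded = None
    if "marker_id" in table.columns:
        embedded = table["marker_id"].astype(str)
        table = table.drop(columns=["marker_id"])

    if marker_map is None:
        if embedded is None:
            raise DataError(
                "no marker assignment: provide a marker_map sidecar or embed a marker_id column"
            )
        mm = embedded
    elif isinstance(marker_map, (str, Path)):
        mm_tab = pd.read_csv(marker_map, sep="\t", index_col=0)
        mm = mm_tab.iloc[:, 0].astype(str)
    else:
        mm = pd.Series(marker_map).astype(str)

    return ExpressionMatrix(table.astype(float), mm, scale)


def _check_duplicate_header(path: Path, header_line: str | None = None) -> None:
    # pandas silently renames duplicate columns, so inspect the raw header
    if header_line is None:
        with open(path) as fh:
            header_line = fh.readline()
    fields = [f.strip().strip('"') for f in header_line.rstrip("\n").split("\t")]
    seen: set = set()
    dups = sorted({f for f in fields[1:] if f in seen or seen.add(f)})
    if dups:
        raise DataError(f"duplicate sample ids in {path.name}: {dups}")


def _read_series_matrix(path: Path) -> pd.DataFrame:
    """Parse the table block of a GEO series-matrix text file.

    Series-matrix files carry ``!`` metadata lines and a tab-delimited value
    table bracketed by ``!series_matrix_table_begin`` / ``_table_end``, with
    quoted ``ID_REF`` probe ids and GSM sample accessions in the header.
    """
    lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            marker = line.strip().lower()
            if marker.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if marker.startswith("!series_matrix_table_end"):
                break
            if in_table:
                lines.append(line)
    if not lines:
        raise DataError(f"{path.name}: no series_matrix_table_begin/_end block found")
    _check_duplicate_header(path, header_line=lines[0])
    table = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [str(c).strip('"') for c in table.columns]
    table.index.name = "probe_id"
    return table


# ---------------------------------------------------------------------------
# SampleAnnotation
# ---------------------------------------------------------------------------


@dataclass
class SampleAnnotation:
    """Per-sample handling metadata, one row per sample.

    Columns: sample_id, tumor_group (two-level outcome), array_index (1-based
    collection order of the nonuniformly handled array), technician, batch,
    slide, slide_row (1-2), slide_col (1-4).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = pd.DataFrame(self.table).copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in tab.columns]
        if missing:
            raise DataError(f"annotation missing columns: {missing}")
        tab["array_index"] = tab["array_index"].astype(int)
        if tab["sample_id"].duplicated().any():
            raise DataError("duplicate sample_id in annotation")
        n = len(tab)
        order = np.sort(tab["array_index"].to_numpy())
        if not np.array_equal(order, np.arange(1, n + 1)):
            raise DataError("array_index must be a permutation of 1..n_samples")
        groups = tab["tumor_group"].unique()
        if len(groups) != 2:
            raise DataError(f"tumor_group must have exactly 2 levels, got {list(groups)}")
        slide_load = tab.groupby("slide").size()
        if (slide_load > 8).any():
            over = slide_load[slide_load > 8].index.tolist()
            raise DataError(f"slides holding more than 8 arrays: {over}")
        self.table = tab.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        return self.table["tumor_group"]

    def group_levels(self) -> list:
        return sorted(self.table["tumor_group"].unique().tolist())

    def by_collection_order(self) -> pd.DataFrame:
        return self.table.sort_values("array_index")

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), sep="\t", index=False)


def read_annotation(path: str | Path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# PairedDatasets
# ---------------------------------------------------------------------------


@dataclass
class PairedDatasets:
    """The same specimens profiled twice: uniformly and nonuniformly handled."""

    uniform: ExpressionMatrix
    nonuniform: ExpressionMatrix
    annotation: SampleAnnotation
    dropped_probes: list = field(default_factory=list)


def pair_datasets(
    uniform: ExpressionMatrix,
    nonuniform: ExpressionMatrix,
    annotation: SampleAnnotation,
) -> PairedDatasets:
    """Align the two profiles of the same samples into a :class:`PairedDatasets`.

    Columns are aligned by sample id (order taken from the annotation); probe
    sets are intersected when unequal, with dropped probes logged.  Fails when
    fewer than half the samples overlap, which indicates mispaired inputs.
    """
    u_samples = set(uniform.sample_ids)
    n_samples_ = set(nonuniform.sample_ids)
    shared = u_samples & n_samples_
    denom = max(len(u_samples), len(n_samples_))
    if denom == 0 or len(shared) < 0.5 * denom:
        raise DataError(
            f"only {len(shared)} of {denom} samples overlap between the two datasets; "
            "inputs look mispaired"
        )
    if shared != u_samples or shared != n_samples_:
        missing = sorted((u_samples | n_samples_) - shared)
        raise DataError(f"datasets do not cover the same samples; unmatched: {missing}")

    ann_ids = [s for s in annotation.sample_ids if s in shared]
    if set(ann_ids) != shared:
        raise DataError("annotation does not cover the paired samples")

    shared_probes = uniform.probe_ids.intersection(nonuniform.probe_ids)
    dropped = sorted(
        set(uniform.probe_ids).symmetric_difference(set(nonuniform.probe_ids))
    )
    if dropped:
        logger.info("pair_datasets: dropping %d probes absent from one dataset", len(dropped))
    if len(shared_probes) == 0:
        raise DataError("datasets share no probes")

    u = ExpressionMatrix(
        uniform.values.loc[shared_probes, ann_ids],
        uniform.marker_map.loc[shared_probes],
        uniform.scale,
    )
    n = ExpressionMatrix(
        nonuniform.values.loc[shared_probes, ann_ids],
        nonuniform.marker_map.loc[shared_probes],
        nonuniform.scale,
    )
    ann = SampleAnnotation(annotation.table.loc[ann_ids].reset_index(drop=True))
    return PairedDatasets(u, n, ann, dropped)
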