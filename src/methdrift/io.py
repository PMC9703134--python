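"""Readers and writers for the pipeline's on-disk formats.

All tables are tab-separated UTF-8 with a header row and no quoting; BED
tracks are 3- or 4-column, 0-based half-open.  Readers validate on load and
raise with row context, so downstream code can assume well-formed objects:

``BetaMatrix``
    :class:`pandas.DataFrame`, probes (rows) x samples (columns), values in
    [0, 1], missing encoded as NA.
``SampleSheet``
    :class:`pandas.DataFrame` with columns ``sample_id``, ``donor_id``,
    ``passage`` (int >= 1), ``segment`` and optionally ``age``, ``sex``,
    ``cohort``.
``ProbeAnnotation``
    :class:`pandas.DataFrame` with columns ``probe_id``, ``chromosome``,
    ``position`` (0-based bp) and optional ``polymorphic`` /
    ``cross_hybridizing`` 0/1 flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "IntervalTrack",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_bed",
    "check_sample_agreement",
]

SAMPLE_SHEET_REQUIRED = ("sample_id", "donor_id", "passage", "segment")
ANNOTATION_REQUIRED = ("probe_id", "chromosome", "position")

_TSV = dict(sep="\t", index=False, na_rep="NA")


@dataclass
class IntervalTrack:
    """A named set of labelled genomic intervals (0-based, half-open).

    ``intervals`` has columns ``chromosome``, ``start``, ``end``, ``label``.
    A position ``p`` overlaps ``[start, end)`` iff ``start <= p < end``.
    """

    name: str
    intervals: pd.DataFrame
    _trees: dict[str, IntervalTree] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chromosome", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"track {self.name!r} missing columns {required - set(df.columns)}")
        if "label" not in df.columns:
            df = df.assign(label=self.name)
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"track {self.name!r}: start >= end at row {bad[0]} "
                f"({row['chromosome']}:{row['start']}-{row['end']})"
            )
        if (df["start"] < 0).any():
            raise ValueError(f"track {self.name!r}: negative start coordinate")
        self.intervals = df.reset_index(drop=True)
        self._trees = None

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].astype(str).unique())

    @property
    def chromosomes(self) -> set[str]:
        return set(self.intervals["chromosome"].astype(str).unique())

    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for c, sub in self.intervals.groupby("chromosome", sort=False):
                trees[str(c)] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub.index)
                )
            self._trees = trees
        return self._trees.get(str(chrom))

    def query(self, chrom: str, position: int) -> pd.DataFrame:
        """All intervals containing ``position`` (may be empty)."""
        tree = self._tree(chrom)
        if tree is None:
            return self.intervals.iloc[[]]
        hits = sorted(iv.data for iv in tree.at(int(position)))
        return self.intervals.loc[hits]

    def boundaries(self, chrom: str) -> np.ndarray:
        """Sorted start/end coordinates of intervals on ``chrom``."""
        sub = self.intervals[self.intervals["chromosome"].astype(str) == str(chrom)]
        return np.sort(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "IntervalTrack":
        return read_bed(path, name=name)

    def to_bed(self, path) -> None:
        cols = ["chromosome", "start", "end", "label"]
        self.intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, name: str | None = None) -> IntervalTrack:
    """Read a 3/4-column BED file into an :class:`IntervalTrack`."""
    name = name or str(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({line!r})")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = fields[3] if len(fields) > 3 else name
            rows.append((chrom, start, end, label))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "label"])
    return IntervalTrack(name=name, intervals=df)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe x sample beta matrix; validates ids and [0, 1] range."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{path}: beta value {values[i, j]} out of [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(float)


def write_beta_matrix(beta: pd.DataFrame, path, decimals: int = 6) -> None:
    beta.to_csv(path, sep="\t", na_rep="NA", float_format=f"%.{decimals}g", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the per-sample covariate sheet; validates required columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"sample_id": str, "donor_id": str})
    missing = set(SAMPLE_SHEET_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df["passage"] = df["passage"].astype(int)
    if (df["passage"] < 1).any():
        row = df.index[df["passage"] < 1][0]
        raise ValueError(f"{path}: passage < 1 at row {row} (sample {df.loc[row, 'sample_id']!r})")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, **_TSV)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation (id, chromosome, position, QC flags)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"probe_id": str, "chromosome": str})
    missing = set(ANNOTATION_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: probe annotation missing columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    df["position"] = df["position"].astype(int)
    if (df["position"] < 0).any():
        raise ValueError(f"{path}: negative probe position")
    for flag in ("polymorphic", "cross_hybridizing"):
        if flag in df.columns:
            df[flag] = df[flag].fillna(0).astype(int)
    return df


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, **_TSV)


def check_sample_agreement(beta: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Raise unless beta-matrix columns and sample-sheet ids coincide."""
    beta_ids, sheet_ids = set(beta.columns), set(sheet["sample_id"])
    if beta_ids != sheet_ids:
        only_beta = sorted(beta_ids - sheet_ids)[:3]
        only_sheet = sorted(sheet_ids - beta_ids)[:3]
        raise ValueError(
            "beta matrix and sample sheet disagree on sample ids "
            f"(only in matrix: {only_beta}, only in sheet: {only_sheet})"
        )
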