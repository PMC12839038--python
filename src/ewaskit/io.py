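"""Core data containers and delimited-text readers/writers.

The pipeline's universal substrate is a beta-value matrix (probes x
samples, methylation fractions in [0, 1]) with a companion detection
p-value matrix, a sample sheet carrying group / age / sex, a CpG
annotation table (chromosome, position, gene symbols, blacklist flags)
and gene sets in GMT format.  All tabular formats are plain delimited
text; the delimiter is inferred from the file extension (``.csv`` means
comma, anything else tab).  Missing values are written as ``NA`` and
represented internally as NaN.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

__all__ = [
    "BetaMatrix",
    "DetectionPMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "GeneSetCollection",
    "ValidationError",
    "read_beta_matrix",
    "read_detection_p_matrix",
    "read_sample_sheet",
    "read_annotation",
    "read_gene_sets",
    "write_matrix",
    "write_sample_sheet",
    "write_annotation",
    "write_gene_sets",
    "write_bed",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _delimiter_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} ids: {dupes}")


@dataclass
class _ProbeSampleMatrix:
    """Probes x samples numeric matrix backed by a pandas DataFrame."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids

    _lo: float = field(default=0.0, repr=False)
    _hi: float = field(default=1.0, repr=False)
    _name: str = field(default="value", repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < self._lo) | (vals > self._hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self._name} out of [{self._lo}, {self._hi}] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}: "
                f"{vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_probes(self, probe_ids: Sequence[str]):
        return type(self)(self.data.loc[list(probe_ids)])

    def select_samples(self, sample_ids: Sequence[str]):
        return type(self)(self.data.loc[:, list(sample_ids)])


class BetaMatrix(_ProbeSampleMatrix):
    """Methylation beta fractions, probes x samples, values in [0, 1]."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data, _lo=0.0, _hi=1.0, _name="beta")


class DetectionPMatrix(_ProbeSampleMatrix):
    """Per-call detection p-values on the same axes as a BetaMatrix."""

    def __init__(self, data: pd.DataFrame):
        super().__init__(data, _lo=0.0, _hi=1.0, _name="detection p")


@dataclass
class SampleSheet:
    """One row per sample: group label, age in years, sex in {M, F}."""

    data: pd.DataFrame  # index = sample_id; columns group, age, sex

    REQUIRED = ("group", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data.index, "sample")
        groups = self.data["group"].unique()
        if len(groups) < 2:
            raise ValidationError(
                f"sample sheet must contain two group levels, found {list(groups)}"
            )
        if len(groups) > 2:
            raise ValidationError(f"more than two group levels: {list(groups)}")
        if (self.data["age"].astype(float) <= 0).any():
            raise ValidationError("ages must be positive")
        bad_sex = set(self.data["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"sex labels must be M/F, found {bad_sex}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def groups(self) -> tuple[str, str]:
        """(control-like, case-like): 'control' first when present,
        otherwise lexical order."""
        levels = sorted(self.data["group"].unique())
        if "control" in levels:
            levels = ["control"] + [g for g in levels if g != "control"]
        return tuple(levels)  # type: ignore[return-value]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.data["group"] == group).to_numpy()

    def case_mask(self) -> np.ndarray:
        return self.group_mask(self.groups[1])

    def select(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)])


@dataclass
class CpGAnnotation:
    """Probe genomic annotation with blacklist flags.

    Coordinates are 1-based inclusive (manifest convention); the BED
    writer converts to 0-based half-open.
    """

    data: pd.DataFrame  # index probe_id; chrom, pos, genes (list),
    # snp_overlap, cross_hybridizing, sex_chromosome

    FLAGS = ("snp_overlap", "cross_hybridizing", "sex_chromosome")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        for col in ("chrom", "pos", "genes", *self.FLAGS):
            if col not in self.data.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if (self.data["pos"].astype(int) < 1).any():
            bad = self.data.index[self.data["pos"].astype(int) < 1][0]
            raise ValidationError(f"non-positive position for probe {bad!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def blacklisted(self) -> pd.Index:
        flagged = self.data[list(self.FLAGS)].any(axis=1)
        return self.data.index[flagged]

    def sorted_by_position(self, probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
        sub = self.data if probe_ids is None else self.data.loc[list(probe_ids)]
        return sub.sort_values(["chrom", "pos"], kind="mergesort")

    def genes_for(self, probe_id: str) -> list[str]:
        return list(self.data.at[probe_id, "genes"])


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> (description, member symbols)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


# ---------------------------------------------------------------------------
# readers


def _read_matrix_frame(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        index_col=0,
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
    )
    frame.index = frame.index.astype(str)
    frame.index.name = "probe_id"
    frame.columns = frame.columns.astype(str)
    return frame.astype(float)


def read_beta_matrix(path: str | os.PathLike) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    First column holds probe ids, the header row sample ids; ``NA``
    cells become missing values.  Values outside [0, 1] or duplicated
    ids raise :class:`ValidationError`.
    """
    return BetaMatrix(_read_matrix_frame(path))


def read_detection_p_matrix(path: str | os.PathLike) -> DetectionPMatrix:
    """Read a detection p-value matrix (same layout as the beta matrix)."""
    return DetectionPMatrix(_read_matrix_frame(path))


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read the sample sheet (sample_id, group, age, sex)."""
    frame = pd.read_csv(path, sep=_delimiter_for(path), dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValidationError("sample sheet missing column 'sample_id'")
    frame = frame.set_index("sample_id")
    return SampleSheet(frame)


def read_annotation(path: str | os.PathLike) -> CpGAnnotation:
    """Read probe annotation; the ``genes`` column is semicolon-joined."""
    frame = pd.read_csv(
        path, sep=_delimiter_for(path), dtype={"probe_id": str, "chrom": str}
    )
    if "probe_id" not in frame.columns:
        raise ValidationError("annotation missing column 'probe_id'")
    frame = frame.set_index("probe_id")
    genes = frame["genes"].fillna("")
    frame["genes"] = [
        tuple(g for g in str(cell).split(";") if g) for cell in genes
    ]
    for flag in CpGAnnotation.FLAGS:
        if flag in frame.columns:
            frame[flag] = frame[flag].astype(bool)
        else:
            frame[flag] = False
    frame["pos"] = frame["pos"].astype(int)
    return CpGAnnotation(frame)


def read_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Read gene sets in GMT dialect: set_id TAB description TAB gene..."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            sid, desc, *genes = parts
            if sid in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set id {sid!r}")
            genes = [g for g in genes if g]
            sets[sid] = (desc, tuple(genes))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers


def write_matrix(matrix: _ProbeSampleMatrix, path: str | os.PathLike) -> None:
    matrix.data.to_csv(
        path, sep=_delimiter_for(path), na_rep=MISSING_TOKEN, index_label="probe_id"
    )


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.data.to_csv(path, sep=_delimiter_for(path), index_label="sample_id")


def write_annotation(annotation: CpGAnnotation, path: str | os.PathLike) -> None:
    frame = annotation.data.copy()
    frame["genes"] = [";".join(g) for g in frame["genes"]]
    frame.to_csv(path, sep=_delimiter_for(path), index_label="probe_id")


def write_gene_sets(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in collection:
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def write_bed(
    intervals: Iterable[Mapping],
    path: str | os.PathLike,
) -> None:
    """Write intervals as BED6.

    Each interval mapping needs ``chrom``, ``start``, ``end`` (1-based
    inclusive, as stored in :class:`CpGAnnotation`), and optionally
    ``name``, ``score``, ``strand``.  Output is 0-based half-open.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        str(iv["chrom"]),
                        str(int(iv["start"]) - 1),
                        str(int(iv["end"])),
                        str(iv.get("name", ".")),
                        str(iv.get("score", 0)),
                        str(iv.get("strand", ".")),
                    ]
                )
                + "\n"
            )


def align_to_sheet(
    matrix: _ProbeSampleMatrix, sheet: SampleSheet
) -> _ProbeSampleMatrix:
    """Reindex matrix columns to the sample sheet's canonical order."""
    missing = [s for s in sheet.sample_ids if s not in matrix.sample_ids]
    if missing:
        raise ValidationError(f"samples in sheet absent from matrix: {missing[:5]}")
    return matrix.select_samples(list(sheet.sample_ids))


def intersect_probes(
    matrix: _ProbeSampleMatrix, annotation: CpGAnnotation
) -> _ProbeSampleMatrix:
    """Restrict a matrix to probes present in the annotation.

    Probe order follows the matrix; sample order is never touched.
    """
    keep = [p for p in matrix.probe_ids if p in annotation.probe_ids]
    return matrix.select_probes(keep)
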