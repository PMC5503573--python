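"""Data model and tab-delimited I/O for LC-MS feature matrices and sample tables.

The pipeline operates on post-alignment feature tables: rows are samples,
columns are spectral ions denoted ``(<rt> min: <mz> m/z)``, entries are
nonnegative intensities with 0 meaning "not detected".  Tables are stored as
plain tab-delimited UTF-8 text; intensities are written as positional decimals
with up to 12 significant digits so a write/read round trip is stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IonID",
    "FeatureMatrix",
    "SampleTable",
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "split_train_test",
]

CASE = "case"
CONTROL = "control"
TRAIN = "train"
TEST = "test"

_ION_RE = re.compile(r"^\((\d+(?:\.\d+)?) min: (\d+(?:\.\d+)?) m/z\)$")


class FormatError(ValueError):
    """A malformed feature-table or sample-table file.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class IonID:
    """A spectral ion, identified by retention time (minutes) and m/z (Th).

    The canonical label ``(R min: M m/z)`` formats retention time to 2
    decimals and m/z to 3 decimals; parsing and formatting are mutually
    inverse at that precision.
    """

    rt: float
    mz: float

    def __post_init__(self) -> None:
        if not self.rt > 0:
            raise ValueError(f"retention time must be positive, got {self.rt}")
        if not self.mz > 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")

    @property
    def label(self) -> str:
        return f"({self.rt:.2f} min: {self.mz:.3f} m/z)"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str) -> "IonID":
        m = _ION_RE.match(label.strip())
        if m is None:
            raise ValueError(f"not a canonical ion label: {label!r}")
        return cls(rt=float(m.group(1)), mz=float(m.group(2)))


def _format_intensity(v: float) -> str:
    # positional (non-scientific) decimal, <= 12 significant digits
    if v == 0:
        return "0"
    return np.format_float_positional(
        v, precision=12, unique=False, fractional=False, trim="-"
    )


@dataclass
class FeatureMatrix:
    """Samples x ions intensity table; 0 encodes non-detection."""

    ions: list[IonID]
    samples: list[str]
    intensity: np.ndarray  # shape (n_samples, n_ions)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.samples), len(self.ions)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.samples)} samples x {len(self.ions)} ions"
            )
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities are not allowed")
        labels = [ion.label for ion in self.ions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ion labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_ions(self) -> int:
        return len(self.ions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensity,
            index=pd.Index(self.samples, name="sample_id"),
            columns=[ion.label for ion in self.ions],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return FeatureMatrix(
            ions=list(self.ions),
            samples=list(sample_ids),
            intensity=self.intensity[idx, :],
        )

    def subset_ions(self, ion_indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(ion_indices)
        return FeatureMatrix(
            ions=[self.ions[i] for i in idx],
            samples=list(self.samples),
            intensity=self.intensity[:, idx],
        )


@dataclass
class SampleTable:
    """Per-sample metadata: group (case/control) and split (train/test)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "split"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        bad_group = set(self.df["group"]) - {CASE, CONTROL}
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_split = set(self.df["split"]) - {TRAIN, TEST}
        if bad_split:
            raise ValueError(f"unknown split labels: {sorted(bad_split)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "SampleTable":
        df = pd.DataFrame(records, columns=["sample_id", "group", "split"])
        return cls(df)

    def ids(self, split: str | None = None, group: str | None = None) -> list[str]:
        sel = self.df
        if split is not None:
            sel = sel[sel["split"] == split]
        if group is not None:
            sel = sel[sel["group"] == group]
        return sel["sample_id"].tolist()

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["group"]))

    def counts(self) -> pd.Series:
        return self.df.groupby(["split", "group"]).size()

    def __len__(self) -> int:
        return len(self.df)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV: sample_id column + canonical ion labels."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(ion.label for ion in matrix.ions) + "\n")
        for sid, row in zip(matrix.samples, matrix.intensity):
            fh.write(sid + "\t" + "\t".join(_format_intensity(v) for v in row) + "\n")


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a TSV feature matrix, validating shape and nonnegativity.

    Raises :class:`FormatError` with a line number on ragged rows, negative
    intensities, unparseable values, or duplicate labels.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty file", lineno=1)
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 2 or cols[0] != "sample_id":
            raise FormatError(
                "header must start with 'sample_id' followed by ion labels", lineno=1
            )
        try:
            ions = [IonID.parse(label) for label in cols[1:]]
        except ValueError as exc:
            raise FormatError(str(exc), lineno=1) from exc
        if len({ion.label for ion in ions}) != len(ions):
            raise FormatError("duplicate ion labels in header", lineno=1)

        samples: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"expected {len(cols)} fields, found {len(fields)}", lineno=lineno
                )
            try:
                values = np.array([float(v) for v in fields[1:]], dtype=float)
            except ValueError as exc:
                raise FormatError(f"non-numeric intensity: {exc}", lineno=lineno) from exc
            if np.any(values < 0):
                raise FormatError("negative intensity", lineno=lineno)
            if fields[0] in samples:
                raise FormatError(f"duplicate sample id {fields[0]!r}", lineno=lineno)
            samples.append(fields[0])
            rows.append(values)
    intensity = np.vstack(rows) if rows else np.empty((0, len(ions)))
    return FeatureMatrix(ions=ions, samples=samples, intensity=intensity)


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.df[["sample_id", "group", "split"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def split_train_test(
    groups: pd.DataFrame | SampleTable | dict[str, str],
    n_case_train: int,
    n_control_train: int,
    seed: int,
) -> SampleTable:
    """Stratified random train/test assignment, deterministic under ``seed``.

    ``groups`` supplies (sample_id, group) pairs; existing split labels are
    ignored.  Exactly ``n_case_train`` case and ``n_control_train`` control
    samples are assigned to the train split, the remainder to test.
    """
    if isinstance(groups, SampleTable):
        df = groups.df[["sample_id", "group"]].copy()
    elif isinstance(groups, dict):
        df = pd.DataFrame(
            {"sample_id": list(groups.keys()), "group": list(groups.values())}
        )
    else:
        df = groups[["sample_id", "group"]].copy()

    rng = np.random.default_rng(seed)
    split = pd.Series(TEST, index=df.index)
    for grp, n_train in ((CASE, n_case_train), (CONTROL, n_control_train)):
        idx = df.index[df["group"] == grp].to_numpy()
        if n_train > len(idx):
            raise ValueError(
                f"requested {n_train} {grp} training samples but only "
                f"{len(idx)} available"
            )
        chosen = rng.permutation(idx)[:n_train]
        split.loc[chosen] = TRAIN
    out = df.copy()
    out["split"] = split
    return SampleTable(out)
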