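"""Readers, writers and validated in-memory containers for expression data.

The pipeline's currency is a genes × samples matrix of fluorescence
intensities (linear or log2 scale), a sample sheet mapping each array to a
platform / gravity-condition / replicate triple, and a gene annotation table
carrying cytogenetic band labels. All readers validate eagerly and refuse
silently-coercible corruption (duplicate identifiers, blank cells, NaN)
instead of imputing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_geo_series_matrix",
    "validate_matrix_sheet",
    "align_annotation",
]

LINEAR = "linear"
LOG2 = "log2"

SHEET_COLUMNS = ("sample_id", "platform", "condition", "replicate")
ANNOTATION_COLUMNS = ("gene_id", "symbol", "chromosome", "band", "annotated")

#: float format used by all writers; 12 significant digits round-trips
#: doubles to well below any tolerance used downstream.
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """A genes × samples intensity matrix with an explicit scale tag.

    ``data`` is indexed by gene id with sample ids as columns. ``scale`` is
    ``"linear"`` (raw fluorescence, strictly positive) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "gene_id"
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        self.validate_values()

    def validate_values(self) -> None:
        values = self.data.to_numpy()
        if values.dtype.kind not in "fi":
            bad = self.data.columns[
                [self.data[c].dtype.kind not in "fi" for c in self.data.columns]
            ]
            raise ValidationError(f"non-numeric values in column(s): {list(bad)}")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing/non-finite value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.scale == LINEAR and values.size and values.min() <= 0:
            g, s = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"non-positive linear intensity at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, scale=scale or self.scale)


@dataclass
class SampleSheet:
    """Maps sample ids to platform, gravity condition and replicate number."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {missing}")
        self.table = self.table.loc[:, list(SHEET_COLUMNS)].copy()
        for c in ("sample_id", "platform", "condition"):
            self.table[c] = self.table[c].astype(str)
        _check_unique(self.table["sample_id"], "sample id")
        reps = self.table["replicate"]
        if reps.isna().any() or (pd.to_numeric(reps, errors="coerce") < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        self.table["replicate"] = pd.to_numeric(reps).astype(int)
        self.table = self.table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def platforms(self) -> list[str]:
        return list(dict.fromkeys(self.table["platform"]))

    def conditions(self, platform: str) -> list[str]:
        sub = self.table[self.table["platform"] == platform]
        return list(dict.fromkeys(sub["condition"]))

    def samples_for(self, platform: str, condition: str) -> list[str]:
        sub = self.table[
            (self.table["platform"] == platform)
            & (self.table["condition"] == condition)
        ]
        return list(sub["sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        return SampleSheet(self.table.loc[ids].reset_index(drop=True))


@dataclass
class GeneAnnotation:
    """Per-gene symbol, chromosome, cytogenetic band and annotated flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing column(s): {missing}")
        self.table = self.table.loc[:, list(ANNOTATION_COLUMNS)].copy()
        for c in ("gene_id", "symbol", "chromosome", "band"):
            self.table[c] = self.table[c].fillna("").astype(str)
        _check_unique(self.table["gene_id"], "gene id")
        if self.table["annotated"].dtype != bool:
            self.table["annotated"] = (
                self.table["annotated"]
                .astype(str)
                .str.lower()
                .map({"true": True, "false": False, "1": True, "0": False})
            )
            if self.table["annotated"].isna().any():
                raise ValidationError("annotated column must be boolean")
        bad = self.table[
            (self.table["band"] != "")
            & ~self.table.apply(lambda r: r["band"].startswith(r["chromosome"]), axis=1)
        ]
        if len(bad):
            raise ValidationError(
                f"band does not match chromosome prefix for gene "
                f"{bad['gene_id'].iloc[0]!r}"
            )
        self.table = self.table.set_index("gene_id", drop=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def genes_in_band(self, band: str, annotated_only: bool = True) -> list[str]:
        sub = self.table[self.table["band"] == band]
        if annotated_only:
            sub = sub[sub["annotated"]]
        return list(sub["gene_id"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, scale: str = LOG2) -> ExpressionMatrix:
    """Read a TSV matrix (first column gene_id, remaining columns samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValidationError(f"cannot read matrix {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"{path}: non-numeric cell at gene {df.index[bad.argmax()]!r}, "
                f"column {col!r}"
            )
        df[col] = coerced
    return ExpressionMatrix(data=df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    return path


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot read sample sheet {path}: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sheet.table.to_csv(path, index=False)
    return path


def read_annotation(path: str | Path) -> GeneAnnotation:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot read annotation {path}: {exc}") from exc
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotation.table.to_csv(path, sep="\t", index=False)
    return path


def read_geo_series_matrix(path: str | Path, scale: str = LOG2) -> ExpressionMatrix:
    """Convenience loader for an uncompressed GEO series-matrix text file.

    Parses the ``!series_matrix_table_begin`` .. ``!series_matrix_table_end``
    block. Metadata lines are ignored; no test or pipeline stage depends on
    this reader.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration as exc:
        raise ValidationError(f"{path}: no series-matrix table block found") from exc
    import io

    block = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(io.StringIO(block), sep="\t", index_col=0)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return ExpressionMatrix(data=df, scale=scale)


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------


def validate_matrix_sheet(matrix: ExpressionMatrix, sheet: SampleSheet) -> None:
    """Check that every matrix column has exactly one sample-sheet row."""
    matrix_ids = set(matrix.sample_ids)
    sheet_ids = set(sheet.sample_ids)
    unknown = sorted(matrix_ids - sheet_ids)
    if unknown:
        raise ValidationError(
            f"matrix sample(s) absent from sample sheet: {unknown[:10]}"
        )


def align_annotation(
    matrix: ExpressionMatrix, annotation: GeneAnnotation
) -> GeneAnnotation:
    """Return an annotation covering every matrix gene.

    Matrix genes missing from the annotation are added with empty fields and
    ``annotated=False`` (with a warning); annotation rows for genes not in the
    matrix are dropped.
    """
    ann = annotation.table
    missing = [g for g in matrix.gene_ids if g not in ann.index]
    if missing:
        warnings.warn(
            f"{len(missing)} matrix gene(s) missing from annotation; "
            "treated as annotated=False",
            stacklevel=2,
        )
        extra = pd.DataFrame(
            {
                "gene_id": missing,
                "symbol": "",
                "chromosome": "",
                "band": "",
                "annotated": False,
            }
        )
        ann = pd.concat([ann.reset_index(drop=True), extra], ignore_index=True)
    out = GeneAnnotation(ann.reset_index(drop=True))
    return GeneAnnotation(out.table.loc[matrix.gene_ids].reset_index(drop=True))
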