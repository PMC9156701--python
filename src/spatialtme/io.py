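"""CSV interchange formats for cell tables and cohort tables.

The canonical cell-table schema is one CSV row per cell with columns
``image_id, sample_id, patient_id, x_px, y_px, cd3, cd8, foxp3, cd163,
panck, pdl1`` (markers strictly 0/1, coordinates finite pixel reals) and an
optional ``phenotype`` column.  Pixel coordinates are the on-disk unit;
microns are derived at compute time.  A loader shim maps inForm-style export
column names onto the schema.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotyping import ImageCellTable, MARKER_COLUMNS, PHENOTYPES

logger = logging.getLogger(__name__)

ID_COLUMNS = ("image_id", "sample_id", "patient_id")
COORD_COLUMNS = ("x_px", "y_px")
REQUIRED_COLUMNS = (*ID_COLUMNS, "cell_id", *COORD_COLUMNS, *MARKER_COLUMNS)

#: inForm-style export headers -> canonical schema names.
INFORM_COLUMN_SHIM = {
    "Cell ID": "cell_id",
    "Cell X Position": "x_px",
    "Cell Y Position": "y_px",
    "Sample Name": "sample_id",
    "Annotation ID": "image_id",
    "Phenotype": "phenotype",
}


class SchemaError(ValueError):
    """A cell-table CSV violates the required schema."""


def _validate_cells(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {', '.join(missing)}")
    for col in MARKER_COLUMNS:
        values = df[col]
        bad = ~values.isin([0, 1])
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise SchemaError(
                f"{source}: column {col!r} must be 0/1; bad values at line(s) {lines}"
            )
    for col in COORD_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(values)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(
                f"{source}: column {col!r} must be finite reals; bad line(s) {lines}"
            )
        df[col] = values
    if "phenotype" in df.columns:
        bad = ~df["phenotype"].isin(PHENOTYPES)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(
                f"{source}: unknown phenotype label(s) at line(s) {lines}"
            )
    return df


def read_cell_tables(
    paths: "str | Path | list[str | Path]",
    um_per_px: float = 0.496,
    inform_shim: bool = False,
) -> list[ImageCellTable]:
    """Read and validate one or more cell-table CSVs, returning one
    ImageCellTable per distinct image_id (file order preserved)."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    tables: list[ImageCellTable] = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path)
        if inform_shim:
            df = df.rename(columns=INFORM_COLUMN_SHIM)
        df = _validate_cells(df, str(path))
        for image_id, grp in df.groupby("image_id", sort=False):
            sample_ids = grp["sample_id"].unique()
            patient_ids = grp["patient_id"].unique()
            if len(sample_ids) > 1 or len(patient_ids) > 1:
                raise SchemaError(
                    f"{path}: image {image_id!r} maps to multiple samples/patients"
                )
            cells = grp.drop(columns=list(ID_COLUMNS)).reset_index(drop=True)
            tables.append(
                ImageCellTable(
                    image_id=str(image_id),
                    sample_id=str(sample_ids[0]),
                    patient_id=str(patient_ids[0]),
                    cells=cells,
                    um_per_px=um_per_px,
                )
            )
    logger.info("loaded %d images from %d file(s)", len(tables), len(paths))
    return tables


def cell_tables_to_frame(tables: "list[ImageCellTable]") -> pd.DataFrame:
    frames = []
    for t in tables:
        df = t.cells.copy()
        df.insert(0, "patient_id", t.patient_id)
        df.insert(0, "sample_id", t.sample_id)
        df.insert(0, "image_id", t.image_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_cell_tables(tables: "list[ImageCellTable]", path: "str | Path") -> None:
    cell_tables_to_frame(tables).to_csv(path, index=False)


def read_cohort_table(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "response") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df
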