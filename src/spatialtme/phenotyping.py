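"""Marker-rule cell phenotyping and PD-L1 positivity summaries.

Cells arrive as tables of binary marker calls (CD3, CD8, FoxP3, CD163,
pancytokeratin, PD-L1) with pixel coordinates.  Phenotypes are assigned by a
fixed precedence rule: the CD3 lineage wins over CD163, which wins over
pancytokeratin; everything negative is OTHER.  PD-L1 status is analytically
meaningful only on epithelial tumor cells (EC) and antigen-presenting cells
(APC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHENOTYPES = ("CTL", "HTL", "Treg", "APC", "EC", "OTHER")

#: Pseudo-phenotype meaning "any T cell" when selecting cells.
T_CELL = "T"
T_CELL_TYPES = ("CTL", "HTL", "Treg")

MARKER_COLUMNS = ("cd3", "cd8", "foxp3", "cd163", "panck", "pdl1")


@dataclass
class ImageCellTable:
    """All segmented cells of one 20x field.

    ``cells`` is a DataFrame with one row per cell and columns
    ``cell_id, x_px, y_px, cd3, cd8, foxp3, cd163, panck, pdl1`` (markers as
    0/1) plus, after phenotyping, a ``phenotype`` string column.
    """

    image_id: str
    sample_id: str
    patient_id: str
    cells: pd.DataFrame
    um_per_px: float = 0.496

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")
        if "cell_id" in self.cells.columns and self.cells["cell_id"].duplicated().any():
            dup = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(
                f"duplicate cell_id {dup!r} in image {self.image_id!r}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords_px(self, phenotype: str | None = None) -> np.ndarray:
        """(n, 2) array of x/y pixel coordinates, optionally for one phenotype
        (``"T"`` selects all T-cell types)."""
        df = self.cells if phenotype is None else self.select(phenotype)
        return df[["x_px", "y_px"]].to_numpy(dtype=float)

    def select(self, phenotype: str) -> pd.DataFrame:
        if phenotype == T_CELL:
            mask = self.cells["phenotype"].isin(T_CELL_TYPES)
        else:
            mask = self.cells["phenotype"] == phenotype
        return self.cells.loc[mask]

    # -- cached numpy views (hot path for the spatial kernels) --------------

    def _arrays(self) -> dict:
        cache = getattr(self, "_np_cache", None)
        if cache is None or cache["obj"] is not self.cells:
            cache = {
                "obj": self.cells,
                "xy": self.cells[["x_px", "y_px"]].to_numpy(dtype=float),
                "ph": self.cells["phenotype"].to_numpy()
                if "phenotype" in self.cells.columns
                else None,
                "rows": {},
            }
            self._np_cache = cache
        return cache

    def xy_px(self) -> np.ndarray:
        return self._arrays()["xy"]

    def phenotype_rows(self, phenotype: str) -> np.ndarray:
        """Row positions of one phenotype (``"T"`` = all T-cell types)."""
        cache = self._arrays()
        if cache["ph"] is None:
            raise ValueError(
                f"image {self.image_id!r} has no phenotype column; "
                "run phenotyping first"
            )
        rows = cache["rows"].get(phenotype)
        if rows is None:
            if phenotype == T_CELL:
                mask = np.isin(cache["ph"], T_CELL_TYPES)
            else:
                mask = cache["ph"] == phenotype
            rows = np.nonzero(mask)[0]
            cache["rows"][phenotype] = rows
        return rows

    def phenotype_counts(self) -> dict[str, int]:
        vc = self.cells["phenotype"].value_counts()
        return {ph: int(vc.get(ph, 0)) for ph in PHENOTYPES}


def assign_phenotype(
    cd3: bool, cd8: bool, foxp3: bool, cd163: bool, panck: bool, pdl1: bool
) -> tuple[str, bool]:
    """Map six binary marker calls to (phenotype, pdl1_status).

    Precedence: CD3 lineage > CD163 > pancytokeratin > OTHER.  Within CD3+:
    CD8+ is CTL (regardless of FoxP3, which only splits the CD8- branch),
    CD8-/FoxP3+ is Treg, CD8-/FoxP3- is HTL.  ``pdl1_status`` echoes the
    PD-L1 call for EC and APC and is False otherwise.

    Total function: every combination of markers maps to exactly one label.
    """
    if cd3:
        if cd8:
            return "CTL", False
        return ("Treg" if foxp3 else "HTL"), False
    if cd163:
        return "APC", bool(pdl1)
    if panck:
        return "EC", bool(pdl1)
    return "OTHER", False


def assign_phenotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Vectorised phenotype assignment; returns a copy with a ``phenotype``
    column added (overwritten if present).

    Cells positive for both CD3 and CD163 resolve to the T lineage; the number
    of such conflicts is logged, as is the count of CD3+CD8+FoxP3+ cells kept
    as CTL.
    """
    m = {c: cells[c].astype(bool).to_numpy() for c in MARKER_COLUMNS}
    phenotype = np.select(
        [
            m["cd3"] & m["cd8"],
            m["cd3"] & ~m["cd8"] & m["foxp3"],
            m["cd3"],
            m["cd163"],
            m["panck"],
        ],
        ["CTL", "Treg", "HTL", "APC", "EC"],
        default="OTHER",
    )
    n_conflict = int((m["cd3"] & m["cd163"]).sum())
    if n_conflict:
        logger.info("%d CD3+CD163+ cells resolved to the T lineage", n_conflict)
    n_triple = int((m["cd3"] & m["cd8"] & m["foxp3"]).sum())
    if n_triple:
        logger.info("%d CD3+CD8+FoxP3+ cells kept as CTL", n_triple)
    out = cells.copy()
    out["phenotype"] = phenotype
    return out


def compute_tps(table: ImageCellTable) -> float:
    """Tumor proportion score of one image: 100 x (PD-L1+ EC) / (all EC).

    Returns NaN (with a warning) when the image contains no EC; callers must
    exclude such images from aggregation.
    """
    ec = table.select("EC")
    if len(ec) == 0:
        warnings.warn(
            f"image {table.image_id!r} has no EC; TPS undefined", stacklevel=2
        )
        return float("nan")
    return 100.0 * float(ec["pdl1"].astype(bool).mean())


@dataclass
class PearsonCorrelation:
    """Pearson correlation between per-sample EC and APC PD-L1 fractions."""

    r: float
    r_squared: float
    p_value: float
    n: int
    defined: bool = True


def pdl1_correlation(
    ec_fractions: "pd.Series | np.ndarray", apc_fractions: "pd.Series | np.ndarray"
) -> PearsonCorrelation:
    """Pearson r / r^2 (two-sided p) across samples with both fractions defined.

    Pairs with a missing value on either side are dropped.  A constant vector
    makes the correlation undefined; the result is flagged rather than raised.
    """
    x = np.asarray(ec_fractions, dtype=float)
    y = np.asarray(apc_fractions, dtype=float)
    if x.shape != y.shape:
        raise ValueError("EC and APC fraction vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >=3 complete sample pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonCorrelation(
            r=float("nan"), r_squared=float("nan"), p_value=float("nan"),
            n=len(x), defined=False,
        )
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonCorrelation(
        r=r, r_squared=r * r, p_value=float(res.pvalue), n=len(x)
    )
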