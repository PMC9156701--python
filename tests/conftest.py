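import numpy as np
import pandas as pd
import pytest

from spatialtme.phenotyping import ImageCellTable, MARKER_COLUMNS


def make_table(
    coords_by_phenotype: dict,
    image_id: str = "img-0",
    sample_id: str = "s-0",
    patient_id: str = "p-0",
    um_per_px: float = 1.0,
    pdl1_flags: dict | None = None,
) -> ImageCellTable:
    """Build an ImageCellTable from {phenotype: [(x, y), ...]} in pixels.

    ``pdl1_flags`` optionally maps phenotype -> list of 0/1 flags.
    """
    marker_map = {
        "CTL": dict(cd3=1, cd8=1),
        "HTL": dict(cd3=1),
        "Treg": dict(cd3=1, foxp3=1),
        "APC": dict(cd163=1),
        "EC": dict(panck=1),
        "OTHER": {},
    }
    rows = []
    i = 0
    for ph, coords in coords_by_phenotype.items():
        flags = (pdl1_flags or {}).get(ph)
        for j, (x, y) in enumerate(coords):
            row = {c: 0 for c in MARKER_COLUMNS}
            row.update(marker_map[ph])
            row.update(
                cell_id=f"c{i:04d}", x_px=float(x), y_px=float(y), phenotype=ph
            )
            if flags is not None:
                row["pdl1"] = int(flags[j])
            rows.append(row)
            i += 1
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "x_px", "y_px", *MARKER_COLUMNS, "phenotype"],
    )
    return ImageCellTable(
        image_id=image_id,
        sample_id=sample_id,
        patient_id=patient_id,
        cells=cells,
        um_per_px=um_per_px,
    )


def random_table(rng, n_by_phenotype: dict, width=200.0, height=200.0, um_per_px=1.0):
    coords = {
        ph: [tuple(rng.uniform([0, 0], [width, height])) for _ in range(n)]
        for ph, n in n_by_phenotype.items()
    }
    return make_table(coords, um_per_px=um_per_px)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
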