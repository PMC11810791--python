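import numpy as np
import pandas as pd
import pytest

from igcpipe.synth.slides import CellClassSpec, SlideSpec, render_slide


def small_slide_spec(seed: int = 5, igc: int = 1, wbc: int = 40, ctc: int = 6,
                     width: int = 320, height: int = 320) -> SlideSpec:
    """A compact slide with the same class morphologies as the cohort preset."""
    classes = [
        CellClassSpec("WBC", wbc, 8.0, 0.4, 10.0, 0.5,
                      {"DAPI": 3000.0, "EPI": 0.0, "CD45": 3000.0, "VAR": 0.0}),
        CellClassSpec("CTC", ctc, 12.0, 0.4, 20.0, 0.8,
                      {"DAPI": 3000.0, "EPI": 3000.0, "CD45": 0.0, "VAR": 0.0}),
    ]
    if igc:
        classes.append(
            CellClassSpec("CTC_IGC", igc, 30.0, 1.0, 38.0, 1.0,
                          {"DAPI": 3000.0, "EPI": 3000.0, "CD45": 0.0, "VAR": 0.0})
        )
    return SlideSpec(width=width, height=height, cell_classes=classes,
                     background_level=200.0, noise_sd=5.0, seed=seed)


@pytest.fixture(scope="session")
def rendered_small_slide():
    spec = small_slide_spec(seed=5)
    image, truth = render_slide(spec)
    return spec, image, truth


@pytest.fixture()
def toy_records():
    """Hand-built cell records covering every class rule."""
    def rec(cell_id, dapi, epi, cd45, var, d_nuc=10.0):
        row = {"cell_id": cell_id, "d_nuc_um": d_nuc, "d_cell_um": d_nuc * 1.5,
               "DAPI_nuc_mean": dapi}
        for ch, v in [("DAPI", dapi), ("EPI", epi), ("CD45", cd45), ("VAR", var)]:
            row[f"{ch}_cell_mean"] = v
        return row

    return pd.DataFrame([
        rec(0, dapi=1000, epi=1000, cd45=0, var=0),        # CTC
        rec(1, dapi=1000, epi=1000, cd45=1000, var=0),     # WBC (CD45 dominates)
        rec(2, dapi=1000, epi=0, cd45=0, var=1000),        # MARKER_ONLY
        rec(3, dapi=0, epi=1000, cd45=0, var=0),           # OTHER (DAPI-)
        rec(4, dapi=1000, epi=0, cd45=0, var=0),           # OTHER
        rec(5, dapi=1000, epi=0, cd45=1000, var=0),        # WBC
    ])


def match_to_truth(records: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Index into `records` of the nearest detected cell per planted cell."""
    from scipy.spatial import cKDTree

    tree = cKDTree(records[["centroid_row", "centroid_col"]].to_numpy())
    _, idx = tree.query(truth[["centroid_row", "centroid_col"]].to_numpy())
    return idx
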