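"""Synthetic patient cohort: slides per compartment plus PFS outcomes.

A cohort has matched patients (one blood and one marrow slide each) and
additional marrow-only patients.  A chosen number of patients carry planted
CTC-IGC cells in each compartment (blood positives are a subset of marrow
positives, matching the clinical observation that marrow is the more
sensitive compartment).  Progression-free survival is exponential with a
higher hazard for IGC-positive patients, censored independently.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from igcpipe.synth.slides import CellClassSpec, SlideSpec

__all__ = ["CohortPreset", "simulate_cohort", "DEFAULT_CELL_CLASSES"]

#: Morphology (µm) and channel intensities for each planted class.  WBC
#: nuclei ~8 µm; typical CTC nuclei ~12 µm; IGC nuclei 30 µm — comfortably
#: above the 2x doubling threshold so the planted/detected sets coincide.
DEFAULT_CELL_CLASSES: dict[str, dict] = {
    "WBC": dict(
        nuclear_diameter_mean=8.0, nuclear_diameter_sd=0.4,
        cell_diameter_mean=10.0, cell_diameter_sd=0.5,
        channel_intensity={"DAPI": 3000.0, "EPI": 0.0, "CD45": 3000.0, "VAR": 0.0},
    ),
    "CTC": dict(
        nuclear_diameter_mean=12.0, nuclear_diameter_sd=0.4,
        cell_diameter_mean=20.0, cell_diameter_sd=0.8,
        channel_intensity={"DAPI": 3000.0, "EPI": 3000.0, "CD45": 0.0, "VAR": 0.0},
    ),
    "CTC_IGC": dict(
        nuclear_diameter_mean=30.0, nuclear_diameter_sd=1.0,
        cell_diameter_mean=38.0, cell_diameter_sd=1.0,
        channel_intensity={"DAPI": 3000.0, "EPI": 3000.0, "CD45": 0.0, "VAR": 0.0},
    ),
    "EPI_NEG_IGC": dict(
        nuclear_diameter_mean=30.0, nuclear_diameter_sd=1.0,
        cell_diameter_mean=38.0, cell_diameter_sd=1.0,
        channel_intensity={"DAPI": 3000.0, "EPI": 0.0, "CD45": 0.0, "VAR": 3000.0},
    ),
}


@dataclasses.dataclass
class CohortPreset:
    """Cohort composition, slide content, and survival parameters."""

    n_matched: int
    n_marrow_only: int
    blood_igc_positive: int
    marrow_igc_positive: int
    marrow_only_igc_positive: int = 0
    hazard_pos: float = 0.12  # progressions / month for IGC-positive patients
    hazard_neg: float = 0.04
    censor_rate: float = 0.2
    # slide content
    slide_width: int = 800
    slide_height: int = 800
    pixel_size: float = 1.0
    background_level: float = 200.0
    noise_sd: float = 5.0
    wbc_per_slide: int = 500
    ctc_per_slide: int = 12
    igc_per_positive_slide: int = 2
    cell_classes: Mapping[str, dict] = dataclasses.field(
        default_factory=lambda: DEFAULT_CELL_CLASSES
    )

    def __post_init__(self) -> None:
        if self.blood_igc_positive > self.n_matched or self.marrow_igc_positive > self.n_matched:
            raise ValueError("positives cannot exceed the matched patient count")
        if self.marrow_only_igc_positive > self.n_marrow_only:
            raise ValueError("marrow-only positives cannot exceed marrow-only patient count")
        if self.blood_igc_positive > self.marrow_igc_positive:
            raise ValueError("blood positives are drawn from marrow positives")
        if self.hazard_pos <= self.hazard_neg:
            raise ValueError("IGC-positive patients must progress faster (hazard_pos > hazard_neg)")

    def slide_spec(self, igc_positive: bool, seed: int) -> SlideSpec:
        classes = []
        counts = {
            "WBC": self.wbc_per_slide,
            "CTC": self.ctc_per_slide,
            "CTC_IGC": self.igc_per_positive_slide if igc_positive else 0,
        }
        for label, count in counts.items():
            if count > 0:
                classes.append(CellClassSpec(label=label, count=count, **self.cell_classes[label]))
        return SlideSpec(
            width=self.slide_width,
            height=self.slide_height,
            cell_classes=classes,
            pixel_size=self.pixel_size,
            background_level=self.background_level,
            noise_sd=self.noise_sd,
            seed=seed,
        )


def simulate_cohort(
    preset: CohortPreset, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, dict[str, SlideSpec | None]]]:
    """Simulate a cohort table and per-patient slide specifications.

    Returns ``(cohort, slides)``.  ``cohort`` has one row per patient with
    the planted positivity flags, the PFS time (months) and event indicator.
    ``slides`` maps patient id to ``{"blood": SlideSpec | None,
    "marrow": SlideSpec}``; marrow-only patients have no blood slide.
    """
    rng = np.random.default_rng(seed)
    n_m, n_o = preset.n_matched, preset.n_marrow_only
    matched_ids = [f"P{i + 1:03d}" for i in range(n_m)]
    marrow_only_ids = [f"P{i + 1:03d}" for i in range(n_m, n_m + n_o)]

    marrow_pos = set(rng.choice(n_m, size=preset.marrow_igc_positive, replace=False).tolist())
    blood_pos = set(
        rng.choice(sorted(marrow_pos), size=preset.blood_igc_positive, replace=False).tolist()
    )
    only_pos = set(
        rng.choice(n_o, size=preset.marrow_only_igc_positive, replace=False).tolist()
    )

    rows = []
    slides: dict[str, dict[str, SlideSpec | None]] = {}
    for i, pid in enumerate(matched_ids + marrow_only_ids):
        matched = i < n_m
        if matched:
            m_pos, b_pos = i in marrow_pos, i in blood_pos
        else:
            m_pos, b_pos = (i - n_m) in only_pos, False
        hazard = preset.hazard_pos if m_pos else preset.hazard_neg
        t = rng.exponential(1.0 / hazard)
        if rng.uniform() < preset.censor_rate:
            time, event = rng.uniform(0.0, t), False
        else:
            time, event = t, True
        rows.append(
            {
                "patient_id": pid,
                "matched": matched,
                "blood_igc_truth": b_pos,
                "marrow_igc_truth": m_pos,
                "pfs_months": time,
                "event": event,
            }
        )
        slides[pid] = {
            "blood": preset.slide_spec(b_pos, int(rng.integers(2**31))) if matched else None,
            "marrow": preset.slide_spec(m_pos, int(rng.integers(2**31))),
        }
    return pd.DataFrame(rows), slides
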