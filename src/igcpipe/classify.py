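"""Rare-cell classification and the increased-genomic-content (IGC) call.

Cells detected on a slide are called into four classes from their channel
positivity: WBC (CD45-positive leukocytes), CTC (epithelial-positive,
CD45-negative circulating tumor cells), MARKER_ONLY (epithelial-negative,
CD45-negative cells positive only for the variable marker channel — likely
tumor-derived but not conclusively so), and OTHER.

A CTC is flagged *IGC* ("increased genomic content") when its nuclear
equivalent diameter is at least double the typical nuclear diameter of the
sample's CTC population.  The population reference is the median nuclear
diameter over all CTC-class cells of the sample: unlike the mean, the median
is not dragged upward by the very large cells the rule is trying to detect,
which makes the doubling rule well-posed without iteration.  A trimmed-mean
dialect is available.  A sample (one patient compartment) is *IGC-positive*
when it contains at least one flagged CTC; MARKER_ONLY cells passing the
size rule are reported separately but never count toward positivity.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PositivityThresholds",
    "call_cells",
    "flag_igc",
    "sample_positivity",
    "positivity_breakdown",
    "compare_morphometry",
    "select_largest_fraction",
    "CLASSES",
]

CLASSES = ("WBC", "CTC", "MARKER_ONLY", "OTHER")


@dataclasses.dataclass
class PositivityThresholds:
    """Per-channel mean-intensity cutoffs for calling a cell positive.

    Cutoffs are background-relative: ``background mean + k * background SD``
    with ``k = 5`` by default, because absolute intensity units are arbitrary
    on any given scanner.
    """

    thresholds: Mapping[str, float]
    k: float = 5.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        self.thresholds = dict(self.thresholds)

    @classmethod
    def from_background(cls, background: Mapping[str, tuple[float, float]], k: float = 5.0):
        """Build cutoffs from per-channel background ``(mean, sd)`` pairs."""
        return cls({ch: m + k * s for ch, (m, s) in background.items()}, k=k)

    def __getitem__(self, channel: str) -> float:
        if channel not in self.thresholds:
            raise KeyError(f"no threshold for channel {channel!r}")
        return self.thresholds[channel]


def _positive(records: pd.DataFrame, channel: str, cutoff: float) -> pd.Series:
    """Mean-intensity positivity; DAPI is judged on the nuclear region."""
    col = f"{channel}_nuc_mean" if channel == "DAPI" else f"{channel}_cell_mean"
    if col not in records.columns:
        raise KeyError(f"records are missing channel column {col!r} for channel {channel!r}")
    return records[col] > cutoff


def call_cells(
    records: pd.DataFrame,
    thresholds: PositivityThresholds,
    channels: Iterable[str] = ("DAPI", "EPI", "CD45", "VAR"),
) -> pd.DataFrame:
    """Call a class for every cell record.

    Rules, applied in order (exhaustive and mutually exclusive):

    - DAPI-negative            -> OTHER (no nucleus, not a cell call)
    - CD45-positive            -> WBC   (exclusion marker dominates)
    - EPI-positive             -> CTC
    - VAR-positive             -> MARKER_ONLY
    - otherwise                -> OTHER

    Returns a table with ``cell_id``, ``cell_class``, ``igc`` (initialised
    False; see :func:`flag_igc`), ``d_nuc_um`` and one ``{ch}_positive``
    column per channel.
    """
    channels = list(channels)
    pos = {ch: _positive(records, ch, thresholds[ch]) for ch in channels}
    cls = np.full(len(records), "OTHER", dtype=object)
    dapi = pos["DAPI"].to_numpy()
    cd45 = pos["CD45"].to_numpy()
    epi = pos["EPI"].to_numpy()
    var = pos["VAR"].to_numpy() if "VAR" in pos else np.zeros(len(records), bool)
    cls[dapi & cd45] = "WBC"
    cls[dapi & ~cd45 & epi] = "CTC"
    cls[dapi & ~cd45 & ~epi & var] = "MARKER_ONLY"
    out = pd.DataFrame(
        {
            "cell_id": records["cell_id"].to_numpy(),
            "cell_class": cls,
            "igc": False,
            "d_nuc_um": records["d_nuc_um"].to_numpy(),
        }
    )
    for ch in channels:
        out[f"{ch}_positive"] = pos[ch].to_numpy()
    return out


def flag_igc(
    calls: pd.DataFrame,
    factor: float = 2.0,
    reference: str = "median",
) -> pd.DataFrame:
    """Flag IGC cells within one sample by the nuclear-diameter doubling rule.

    The reference diameter ``d_ref`` is computed over all CTC-class cells of
    the sample (``reference`` = ``"median"`` or ``"trimmed_mean"``, a 20%
    trimmed mean).  CTC and MARKER_ONLY cells with
    ``d_nuc >= factor * d_ref`` get ``igc = True``; MARKER_ONLY flags are
    informational only (see :func:`sample_positivity`).  With no CTC in the
    sample a warning is emitted and nothing is flagged.
    """
    out = calls.copy()
    out["igc"] = False
    ctc_d = out.loc[out["cell_class"] == "CTC", "d_nuc_um"].to_numpy(float)
    if ctc_d.size == 0:
        warnings.warn("no CTC-class cells in sample; IGC flags not set", stacklevel=2)
        return out
    if reference == "median":
        d_ref = float(np.median(ctc_d))
    elif reference == "trimmed_mean":
        d_ref = float(stats.trim_mean(ctc_d, 0.2))
    else:
        raise ValueError(f"unknown reference dialect {reference!r}")
    eligible = out["cell_class"].isin(["CTC", "MARKER_ONLY"])
    out.loc[eligible & (out["d_nuc_um"] >= factor * d_ref), "igc"] = True
    return out


def sample_positivity(calls: pd.DataFrame) -> bool:
    """True iff the sample contains at least one IGC-flagged CTC-class cell.

    MARKER_ONLY cells are excluded: they cannot be conclusively labelled
    tumor-derived, so they never make a sample positive on their own.
    """
    if len(calls) == 0:
        return False
    return bool(((calls["cell_class"] == "CTC") & calls["igc"]).any())


def positivity_breakdown(
    calls: pd.DataFrame,
    marker_channel: str = "VAR",
    restrict_epi: bool = False,
) -> pd.DataFrame:
    """Percentages of rare cells by EPI/marker channel combination.

    Rare cells are the non-WBC, DAPI-positive calls (CTC and MARKER_ONLY
    classes).  Reported combinations: ``EPI+marker+``, ``marker_only``
    (EPI-negative marker-positive) and ``EPI+marker-``.  With
    ``restrict_epi=True`` only EPI-positive cells enter the denominator
    (the dialect used for markers incompatible with the epithelial cocktail,
    where only EPI-positive cells are interpretable).
    """
    mcol = f"{marker_channel}_positive"
    if mcol not in calls.columns:
        raise KeyError(f"marker channel column {mcol!r} missing")
    rare = calls[calls["cell_class"].isin(["CTC", "MARKER_ONLY"])]
    if restrict_epi:
        rare = rare[rare["EPI_positive"]]
    n = len(rare)
    epi = rare["EPI_positive"].to_numpy() if n else np.zeros(0, bool)
    mk = rare[mcol].to_numpy() if n else np.zeros(0, bool)
    combos = {
        "EPI+marker+": int(np.sum(epi & mk)),
        "marker_only": int(np.sum(~epi & mk)),
        "EPI+marker-": int(np.sum(epi & ~mk)),
    }
    if restrict_epi:
        combos.pop("marker_only")
    rows = [
        {
            "combination": name,
            "count": c,
            "percent": (100.0 * c / n) if n else 0.0,
        }
        for name, c in combos.items()
    ]
    out = pd.DataFrame(rows)
    out.attrs["n_rare_cells"] = n
    return out


def compare_morphometry(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two diameter samples.

    Exact enumeration of the rank-sum null for small groups (both n <= 20),
    normal approximation with tie correction otherwise.  Returns
    ``(U statistic of group_a, p)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def select_largest_fraction(records: pd.DataFrame, fraction: float, column: str = "d_cell_um") -> pd.DataFrame:
    """Select the largest ``fraction`` of cells by equivalent diameter.

    Mirrors size-gated sorting (e.g. keeping the largest 15% of cells for
    single-cell expansion): records at or above the ``1 - fraction`` quantile
    of ``column`` are kept, with ties broken by including all tied records.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(records) == 0:
        return records.copy()
    d = records[column].to_numpy(float)
    cutoff = np.quantile(d, 1.0 - fraction, method="higher")
    return records[records[column] >= cutoff].copy()
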