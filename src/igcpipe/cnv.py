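"""Single-cell copy-number ratio profiles, segmentation, and concordance.

Low-pass whole-genome sequencing of a single cell yields read counts over a
fixed genomic bin grid.  Counts are converted to *copy-number ratios*: read
density per bin scaled so the genome-wide median equals 1, so ratio 1 means
copy-number neutral relative to the cell's own genome.  Ratios are therefore
invariant to sequencing depth and — crucially — to whole-genome doubling
(WGD): a cell and its uniformly doubled copy have identical ratio profiles.

Profiles are segmented per chromosome by recursive binary splitting on log2
ratios (a CBS-style procedure): the candidate breakpoint maximises the
two-sample t statistic and is accepted when a within-chromosome permutation
test rejects at level ``alpha``.  Pairwise *concordance* between cells is
the Pearson correlation of their per-bin log2 segmented ratios; group-level
differences in concordance are tested with Wilcoxon rank-sum comparisons of
the within- and cross-group pairwise values.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinGrid",
    "CNProfile",
    "ConcordanceMatrix",
    "normalize_ratios",
    "segment_profile",
    "concordance",
    "concordance_matrix",
    "group_concordance_test",
]

#: pseudo-ratio added before log2 so zero-coverage bins stay finite
LOG_PSEUDO = 0.01


@dataclasses.dataclass
class BinGrid:
    """Ordered genomic bins (0-based, half-open) with GC content."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=float)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.gc) == n):
            raise ValueError("bin grid columns must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("bins must have end > start")
        for c in pd.unique(self.chrom):
            sel = self.chrom == c
            s, e = self.start[sel], self.end[sel]
            if np.any(np.diff(s) < 0) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins on {c} are unsorted or overlapping")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def lengths(self) -> np.ndarray:
        return (self.end - self.start).astype(float)

    def chromosomes(self) -> list:
        return list(pd.unique(self.chrom))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "gc": self.gc}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "BinGrid":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
        return cls(df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy(), df["gc"].to_numpy())


@dataclasses.dataclass
class CNProfile:
    """One cell's per-bin copy-number ratio profile.

    ``segment_id`` and ``segment_ratio`` are per-bin arrays filled by
    :func:`segment_profile`; before segmentation every bin belongs to one
    segment per chromosome whose ratio is the chromosome mean.
    """

    cell_id: str
    grid: BinGrid
    raw_counts: np.ndarray
    ratio: np.ndarray
    segment_id: np.ndarray | None = None
    segment_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.ratio) != len(self.grid):
            raise ValueError("ratio length must match grid")
        if np.any(self.ratio < 0):
            raise ValueError("ratios must be non-negative")

    @property
    def log2_segmented(self) -> np.ndarray:
        seg = self.segment_ratio if self.segment_ratio is not None else self.ratio
        return np.log2(seg + LOG_PSEUDO)


def normalize_ratios(
    raw_counts: np.ndarray,
    grid: BinGrid,
    cell_id: str = "cell",
    gc_correct: bool = False,
    n_gc_bins: int = 10,
) -> CNProfile:
    """Convert raw bin counts to median-1 copy-number ratios.

    Counts are divided by bin length to a read density; optionally the
    density is divided by a GC-decile median curve (a coarse, monotonicity-
    free correction); the result is scaled so the genome-wide median is 1.
    """
    counts = np.asarray(raw_counts, dtype=float)
    if len(counts) != len(grid):
        raise ValueError("counts length must match grid")
    if not np.any(counts > 0):
        raise ValueError("all bin counts are zero; cannot normalize")
    density = counts / grid.lengths
    if gc_correct:
        deciles = np.quantile(grid.gc, np.linspace(0, 1, n_gc_bins + 1))
        idx = np.clip(np.searchsorted(deciles, grid.gc, side="right") - 1, 0, n_gc_bins - 1)
        expected = np.ones_like(density)
        overall = np.median(density[density > 0]) if np.any(density > 0) else 1.0
        for d in range(n_gc_bins):
            sel = idx == d
            if sel.any():
                med = np.median(density[sel])
                if med > 0:
                    expected[sel] = med / overall
        density = density / expected
    med = np.median(density)
    if med <= 0:
        # more than half the bins empty: fall back to the positive median
        med = np.median(density[density > 0])
    ratio = density / med
    return CNProfile(cell_id=cell_id, grid=grid, raw_counts=counts, ratio=ratio)


def _max_t_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best split index k (left = x[:k]) and its |t|; (-1, 0) if none valid."""
    n = len(x)
    if n < 2 * min_bins:
        return -1, 0.0
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(min_bins, n - min_bins + 1)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = c1[k - 1]
    s2 = c1[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = c2[k - 1] - n1 * m1**2
    ss2 = (c2[-1] - c2[k - 1]) - n2 * m2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        # clamp at 0: cancellation can leave a tiny negative SS on a perfect
        # split, which must rank as t = inf, not NaN
        sp2 = np.maximum((ss1 + ss2) / (n - 2), 0.0)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.where(np.isnan(t), 0.0, t)
    best = int(np.argmax(t))
    return int(k[best]), float(t[best])


def _max_t_rows(mat: np.ndarray, min_bins: int) -> np.ndarray:
    """Row-wise max |t| over splits for a (n_perm, n) matrix."""
    n = mat.shape[1]
    c1 = np.cumsum(mat, axis=1)
    c2 = np.cumsum(mat * mat, axis=1)
    k = np.arange(min_bins, n - min_bins + 1)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = c1[:, k - 1]
    s2 = c1[:, -1:] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = c2[:, k - 1] - n1 * m1**2
    ss2 = (c2[:, -1:] - c2[:, k - 1]) - n2 * m2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = np.maximum((ss1 + ss2) / (n - 2), 0.0)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.where(np.isnan(t), 0.0, t)
    return t.max(axis=1)


def _segment_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    min_bins: int,
    n_perm: int,
    rng: np.random.Generator,
    breaks: list[int],
) -> None:
    seg = x[lo:hi]
    k, t_obs = _max_t_split(seg, min_bins)
    if k < 0:
        return
    if np.ptp(seg) == 0:
        return  # perfectly flat: nothing to split
    if np.isinf(t_obs):
        p = 0.0  # noise-free step: no permutation can match an infinite t
    else:
        perms = rng.permuted(np.tile(seg, (n_perm, 1)), axis=1)
        t_perm = _max_t_rows(perms, min_bins)
        p = (1.0 + np.sum(t_perm >= t_obs)) / (n_perm + 1.0)
    if p >= alpha:
        return
    breaks.append(lo + k)
    _segment_recursive(x, lo, lo + k, alpha, min_bins, n_perm, rng, breaks)
    _segment_recursive(x, lo + k, hi, alpha, min_bins, n_perm, rng, breaks)


def segment_profile(
    profile: CNProfile,
    alpha: float = 0.01,
    min_bins: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> CNProfile:
    """Segment a ratio profile per chromosome by recursive binary splitting.

    Splits maximise the pooled two-sample t statistic on log2 ratios and are
    accepted when the within-chromosome permutation p-value is below
    ``alpha`` and both sides keep at least ``min_bins`` bins.  Segment
    ratios are segment means of the (linear) ratio.
    """
    if len(profile.grid) < 2 * min_bins:
        raise ValueError("profile too short to segment")
    rng = np.random.default_rng(seed)
    log2r = np.log2(profile.ratio + LOG_PSEUDO)
    seg_id = np.zeros(len(profile.grid), dtype=int)
    seg_ratio = np.empty(len(profile.grid), dtype=float)
    next_id = 0
    for chrom in profile.grid.chromosomes():
        sel = np.flatnonzero(profile.grid.chrom == chrom)
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        breaks: list[int] = []
        if hi - lo >= 2 * min_bins:
            _segment_recursive(log2r, lo, hi, alpha, min_bins, n_perm, rng, breaks)
        bounds = [lo] + sorted(breaks) + [hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_id[a:b] = next_id
            seg_ratio[a:b] = profile.ratio[a:b].mean()
            next_id += 1
    return dataclasses.replace(profile, segment_id=seg_id, segment_ratio=seg_ratio)


def concordance(profile_a: CNProfile, profile_b: CNProfile) -> float:
    """Pearson correlation of two cells' per-bin log2 segmented ratios.

    Returns NaN when either profile has zero variance (a flat genome), where
    correlation is undefined.
    """
    if len(profile_a.grid) != len(profile_b.grid):
        raise ValueError("profiles must share one bin grid")
    xa = profile_a.log2_segmented
    xb = profile_b.log2_segmented
    # a flat genome has no profile to correlate (tolerance absorbs log2 jitter)
    if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
        return float("nan")
    return float(np.corrcoef(xa, xb)[0, 1])


def spearman_concordance(profile_a: CNProfile, profile_b: CNProfile) -> float:
    """Spearman dialect of :func:`concordance`."""
    xa, xb = profile_a.log2_segmented, profile_b.log2_segmented
    if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
        return float("nan")
    return float(stats.spearmanr(xa, xb).statistic)


@dataclasses.dataclass
class ConcordanceMatrix:
    """Symmetric cell-by-cell concordance matrix with group labels."""

    values: np.ndarray
    cell_ids: list
    labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("matrix must be square")
        if len(self.cell_ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels must match matrix size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)


def concordance_matrix(
    profiles: Sequence[CNProfile], labels: Sequence, method: str = "pearson"
) -> ConcordanceMatrix:
    """Pairwise concordance over a list of segmented profiles."""
    fn = concordance if method == "pearson" else spearman_concordance
    n = len(profiles)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = fn(profiles[i], profiles[j])
    return ConcordanceMatrix(vals, [p.cell_id for p in profiles], list(labels))


def _offdiag_pairs(matrix: ConcordanceMatrix, idx_a, idx_b) -> np.ndarray:
    vals = []
    for i in idx_a:
        for j in idx_b:
            if i < j:
                vals.append(matrix.values[i, j])
            elif j < i and not np.array_equal(idx_a, idx_b):
                vals.append(matrix.values[i, j])
    return np.asarray(vals)


def group_concordance_test(matrix: ConcordanceMatrix, group_a, group_b) -> dict:
    """Compare within-A, within-B, and cross-group pairwise concordance.

    Returns the three medians and Holm-corrected two-sided Wilcoxon rank-sum
    p-values for each pairwise comparison of the three distributions.  When
    all values are tied the comparison is degenerate and reported with
    p = 1.  Groups of size < 2 have no within-group pairs; their comparisons
    are omitted with a warning.
    """
    labels = np.asarray(matrix.labels, dtype=object)
    idx_a = np.flatnonzero(labels == group_a)
    idx_b = np.flatnonzero(labels == group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be present in the matrix")
    pools: dict[str, np.ndarray] = {}
    if len(idx_a) >= 2:
        pools[f"within_{group_a}"] = _offdiag_pairs(matrix, idx_a, idx_a)
    else:
        warnings.warn(f"group {group_a!r} has < 2 cells; within-group comparison omitted")
    if len(idx_b) >= 2:
        pools[f"within_{group_b}"] = _offdiag_pairs(matrix, idx_b, idx_b)
    else:
        warnings.warn(f"group {group_b!r} has < 2 cells; within-group comparison omitted")
    cross = np.asarray(
        [matrix.values[i, j] for i in idx_a for j in idx_b], dtype=float
    )
    pools["cross"] = cross

    medians = {name: float(np.nanmedian(v)) for name, v in pools.items()}
    names = list(pools)
    comparisons, pvals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = pools[names[i]], pools[names[j]]
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            both = np.concatenate([x, y])
            if x.size == 0 or y.size == 0 or np.ptp(both) == 0:
                p = 1.0  # degenerate / all-tied comparison
            else:
                p = float(
                    stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
                )
            comparisons.append((names[i], names[j]))
            pvals.append(p)
    if pvals:
        adj = multipletests(pvals, method="holm")[1]
    else:
        adj = []
    return {
        "medians": medians,
        "comparisons": [
            {"pair": c, "p": p, "p_holm": float(q)}
            for c, p, q in zip(comparisons, pvals, adj)
        ],
    }
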