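"""Differential expression, survivor-signature intersection, and scoring.

The survivor-signature analysis asks which genes are upregulated in *every*
treated condition of a multi-line, multi-drug experiment: per comparison
(treated vs its own control) a per-gene test yields log2 fold change and a
Benjamini-Hochberg FDR; up-gene sets at (LFC > 1.5, FDR < 0.01) are
intersected within each cell line across its drugs, then across lines to a
shared *survivor set*, which is then characterised by gene biotype,
over-representation against user-supplied gene-set libraries, and a
rank-based per-cell signature score.

The per-gene test is a stratified two-sided Wilcoxon rank-sum on log2 CPM —
strata are sequencing batches, combined by Stouffer weighting sqrt(n) — with
a 10% detection filter.  This is a deliberate, self-contained stand-in for
quasi-likelihood count-model pipelines: with the clearly separated effect
sizes the analysis is designed around, threshold recovery does not depend
on the choice of test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_cpm",
    "de_test",
    "shared_upregulated",
    "SharedUpResult",
    "biotype_breakdown",
    "overrepresentation",
    "signature_score",
    "read_gmt",
    "write_gmt",
]


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + CPM) normalization of a genes x cells count matrix."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"cells with zero library size: {list(zero.index)}")
    cpm = counts * (1e6 / libsize)
    return np.log2(1.0 + cpm)


def _ranksum_z(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Vectorised two-sample rank-sum z per gene (rows), tie-corrected.

    Positive z means group B (treated) ranks higher.
    """
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    n = n_a + n_b
    x = np.concatenate([x_a, x_b], axis=1)
    ranks = stats.rankdata(x, axis=1)
    rb = ranks[:, n_a:].sum(axis=1)
    mu = n_b * (n + 1) / 2.0
    # tie correction: sum(t^3 - t) over tied groups, per gene
    xs = np.sort(x, axis=1)
    new_run = np.ones_like(xs, dtype=bool)
    new_run[:, 1:] = xs[:, 1:] != xs[:, :-1]
    tie_term = np.empty(x.shape[0])
    for g in range(x.shape[0]):
        runs = np.diff(np.append(np.flatnonzero(new_run[g]), n))
        tie_term[g] = np.sum(runs.astype(float) ** 3 - runs)
    var = (n_a * n_b / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (rb - mu) / np.sqrt(var)
    return np.where(var <= 0, 0.0, z)


def de_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    batch: pd.Series | None = None,
    min_detect: float = 0.10,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Differential expression of ``group_b`` (treated) vs ``group_a`` (control).

    Per gene: LFC is the difference of group means of log2(CPM + 1); the
    p-value comes from a two-sided Wilcoxon rank-sum computed within batch
    strata and combined by Stouffer weighting sqrt(n); q is
    Benjamini-Hochberg over tested genes.  Genes expressed in fewer than
    ``min_detect`` of cells in *both* groups are excluded before testing
    (``tested = False``, NaN p/q).
    """
    groups = groups.reindex(counts.columns)
    idx_a = counts.columns[groups == group_a]
    idx_b = counts.columns[groups == group_b]
    if len(idx_a) < min_cells or len(idx_b) < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group; got {len(idx_a)} vs {len(idx_b)}"
        )
    logcpm = normalize_cpm(counts[list(idx_a) + list(idx_b)])
    la, lb = logcpm[idx_a], logcpm[idx_b]
    detect_a = (counts[idx_a] > 0).mean(axis=1)
    detect_b = (counts[idx_b] > 0).mean(axis=1)
    tested = (detect_a >= min_detect) | (detect_b >= min_detect)

    mean_a = la.mean(axis=1)
    mean_b = lb.mean(axis=1)
    lfc = mean_b - mean_a

    if batch is None:
        strata = pd.Series(0, index=logcpm.columns)
    else:
        strata = batch.reindex(logcpm.columns)

    zs, ws = [], []
    for s in pd.unique(strata):
        sa = [c for c in idx_a if strata[c] == s]
        sb = [c for c in idx_b if strata[c] == s]
        if len(sa) < 2 or len(sb) < 2:
            warnings.warn(f"batch stratum {s!r} too small on one side; skipped")
            continue
        zs.append(_ranksum_z(la[sa].to_numpy(), lb[sb].to_numpy()))
        ws.append(np.sqrt(len(sa) + len(sb)))
    if not zs:
        raise ValueError("no usable batch stratum with >= 2 cells per group")
    w = np.asarray(ws)
    z = np.tensordot(w, np.vstack(zs), axes=(0, 0)) / np.sqrt((w**2).sum())
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "q": np.nan,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "detect_a": detect_a,
            "detect_b": detect_b,
            "tested": tested,
        },
        index=counts.index,
    )
    out.loc[~tested, ["p"]] = np.nan
    mask = tested.to_numpy()
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def up_genes(de: pd.DataFrame, lfc_thresh: float = 1.5, fdr_thresh: float = 0.01) -> set:
    """Upregulated genes at the stated thresholds (LFC > thresh and q < FDR)."""
    sel = (de["lfc"] > max(lfc_thresh, 0.0)) & (de["q"] < fdr_thresh)
    return set(de.index[sel.fillna(False)])


@dataclasses.dataclass
class SharedUpResult:
    """Per-comparison up-sets, per-line drug intersections, survivor set."""

    up_sets: dict
    line_sets: dict
    survivor_set: set

    @property
    def sizes(self) -> dict:
        return {
            "comparisons": {k: len(v) for k, v in self.up_sets.items()},
            "lines": {k: len(v) for k, v in self.line_sets.items()},
            "survivor": len(self.survivor_set),
        }


def shared_upregulated(
    de_results: Mapping[str, pd.DataFrame],
    lines: Mapping[str, Sequence[str]],
    lfc_thresh: float = 1.5,
    fdr_thresh: float = 0.01,
) -> SharedUpResult:
    """Nested intersection of up-gene sets: drugs within line, then lines.

    ``lines`` maps a line name to the comparison keys (one per drug) that
    belong to it; every named comparison must be present in ``de_results``.
    """
    for line, comps in lines.items():
        missing = [c for c in comps if c not in de_results]
        if missing:
            raise KeyError(f"line {line!r} is missing comparisons {missing}")
    ups = {k: up_genes(v, lfc_thresh, fdr_thresh) for k, v in de_results.items()}
    line_sets = {}
    for line, comps in lines.items():
        s = set(ups[comps[0]])
        for c in comps[1:]:
            s &= ups[c]
        line_sets[line] = s
    survivor = None
    for s in line_sets.values():
        survivor = set(s) if survivor is None else survivor & s
    return SharedUpResult(up_sets=ups, line_sets=line_sets, survivor_set=survivor or set())


def biotype_breakdown(genes: Iterable, biotypes: pd.Series) -> pd.DataFrame:
    """Percentage of a gene set per biotype (unannotated genes count as TEC).

    Returns a table with ``biotype``, ``count``, ``percent`` (exact) and
    ``percent_int`` (rounded to integers for reporting).
    """
    genes = list(genes)
    if not genes:
        out = pd.DataFrame(columns=["biotype", "count", "percent", "percent_int"])
        out.attrs["n_genes"] = 0
        return out
    bt = biotypes.reindex(genes).fillna("TEC")
    counts = bt.value_counts()
    out = pd.DataFrame(
        {
            "biotype": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(genes),
        }
    )
    out["percent_int"] = np.round(out["percent"]).astype(int)
    out.attrs["n_genes"] = len(genes)
    return out


def overrepresentation(
    query: Iterable, universe: Iterable, library: Mapping[str, Iterable]
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``query`` in each library set.

    Library sets are intersected with the universe; the 2x2 table per set is
    (in query & in set, in set only, in query only, in neither), tested with
    ``alternative="greater"``; q is Benjamini-Hochberg across library sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name, genes in library.items():
        s = set(genes) & universe
        a = len(query & s)
        b = len(s) - a
        c = len(query) - a
        d = len(universe) - a - b - c
        odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a > 0 else 0.0)
        if a == 0:
            odds = 0.0
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append({"set": name, "set_size": len(s), "overlap": a, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def signature_score(logcpm: pd.DataFrame, gene_set: Iterable) -> pd.Series:
    """Rank-based per-cell signature score in [0, 1] (JASMINE-style).

    Per cell, among its expressed genes (log2 CPM > 0): the mean rank of
    expressed signature genes divided by the number of expressed genes
    (rank component), and the odds ratio of being expressed for signature
    vs non-signature genes (Haldane-corrected; enrichment component).  Each
    component is min-max scaled across cells and the two are averaged.
    Degenerate scaling (all cells equal, or a single cell) fixes the
    component at 0.5 with a warning.
    """
    sig = [g for g in gene_set if g in logcpm.index]
    if not sig:
        raise ValueError("no signature gene present in the matrix")
    sig_mask = logcpm.index.isin(sig)
    x = logcpm.to_numpy()
    expressed = x > 0
    if not expressed[sig_mask].any():
        raise ValueError("no signature gene is expressed in any cell")

    n_cells = x.shape[1]
    rank_comp = np.zeros(n_cells)
    or_comp = np.zeros(n_cells)
    for j in range(n_cells):
        expr = expressed[:, j]
        n_expr = int(expr.sum())
        if n_expr == 0:
            continue
        ranks = stats.rankdata(x[expr, j])
        sig_expr = sig_mask[expr]
        rank_comp[j] = ranks[sig_expr].mean() / n_expr if sig_expr.any() else 0.0
        a = np.sum(expr & sig_mask)
        b = np.sum(~expr & sig_mask)
        c = np.sum(expr & ~sig_mask)
        d = np.sum(~expr & ~sig_mask)
        or_comp[j] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))

    def _minmax(v: np.ndarray, name: str) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi - lo <= 0:
            warnings.warn(f"{name} component degenerate (constant across cells); set to 0.5")
            return np.full_like(v, 0.5)
        return (v - lo) / (hi - lo)

    score = 0.5 * (_minmax(rank_comp, "rank") + _minmax(or_comp, "odds-ratio"))
    return pd.Series(score, index=logcpm.columns, name="signature_score")


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set library (name, description, genes...)."""
    library: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            library[parts[0]] = {g for g in parts[2:] if g}
    return library


def write_gmt(library: Mapping[str, Iterable], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in library.items():
            fh.write("\t".join([name, description, *sorted(map(str, genes))]) + "\n")
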