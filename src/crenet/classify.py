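"""Activating/repressing CRE classification and TF-vs-null CRE-count tests.

A DOCR (differentially open chromatin region) associated with a DEG is
labelled by the quadrant of the (peak log2FC, gene log2FC) plane, both on
the NR-over-RPE orientation:

* domain NR  iff peak log2FC > 0 (more accessible in NR), RPE otherwise;
* mode activating iff the two fold changes share a sign (open where the
  gene is up), repressing iff they oppose.

Pairs where either fold change is exactly zero are excluded rather than
tie-broken into a quadrant.  A peak associated with several DEGs yields one
row per gene, so a single region can act as an activating CRE for one gene
and a repressing CRE for another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HISTOGRAM_BINS = ["0", "1", "2", "3", "4", ">=5"]
QUADRANTS = [("NR", "activating"), ("NR", "repressing"),
             ("RPE", "activating"), ("RPE", "repressing")]


def select_degs(expression: pd.DataFrame, contrast: str,
                alpha: float = 0.05) -> pd.DataFrame:
    """Genes with corrected p < alpha and nonzero log2FC for the contrast."""
    lcol, qcol = f"lfc_{contrast}", f"q_{contrast}"
    if lcol not in expression.columns or qcol not in expression.columns:
        raise KeyError(f"contrast {contrast!r} not in expression table")
    sel = expression[(expression[qcol] < alpha) & (expression[lcol] != 0)]
    out = sel.copy()
    out["gene_log2fc"] = out[lcol]
    return out.reset_index(drop=True)


def select_docrs(peaks: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Peaks with adjusted p < alpha; per-domain counts attached as attrs."""
    sel = peaks[peaks["adjusted_p"] < alpha].reset_index(drop=True)
    sel.attrs["n_nr"] = int((sel["log2fc"] > 0).sum())
    sel.attrs["n_rpe"] = int((sel["log2fc"] < 0).sum())
    return sel


def classify_cres(docrs: pd.DataFrame, degs: pd.DataFrame,
                  associations: pd.DataFrame) -> pd.DataFrame:
    """One labelled CRE row per associated (DOCR, DEG) pair.

    Rows where either partner is non-differential, or either log2FC is
    exactly zero, are excluded, not labelled.
    """
    merged = (associations[["peak_id", "gene_id"]]
              .merge(docrs[["peak_id", "log2fc"]], on="peak_id")
              .merge(degs[["gene_id", "gene_log2fc"]], on="gene_id"))
    merged = merged.rename(columns={"log2fc": "peak_log2fc"})
    merged = merged[(merged["peak_log2fc"] != 0)
                    & (merged["gene_log2fc"] != 0)].copy()
    merged["domain"] = np.where(merged["peak_log2fc"] > 0, "NR", "RPE")
    merged["mode"] = np.where(
        np.sign(merged["peak_log2fc"]) == np.sign(merged["gene_log2fc"]),
        "activating", "repressing")
    cols = ["peak_id", "gene_id", "domain", "mode", "peak_log2fc", "gene_log2fc"]
    return merged[cols].sort_values(["peak_id", "gene_id"]).reset_index(drop=True)


def deg_docr_overlap_fraction(degs: pd.DataFrame,
                              associations: pd.DataFrame,
                              docrs: pd.DataFrame) -> float:
    """Fraction of DEGs associated with at least one DOCR."""
    deg_ids = set(degs["gene_id"])
    if not deg_ids:
        raise ValueError("empty DEG set: overlap fraction undefined")
    docr_ids = set(docrs["peak_id"])
    hit = associations[associations["peak_id"].isin(docr_ids)
                       & associations["gene_id"].isin(deg_ids)]
    return len(set(hit["gene_id"])) / len(deg_ids)


def _bin_counts(counts: np.ndarray) -> np.ndarray:
    """Histogram over bins 0,1,2,3,4,>=5."""
    out = np.zeros(len(HISTOGRAM_BINS), dtype=int)
    for c in counts:
        out[min(int(c), 5)] += 1
    return out


@dataclass
class CRECountSummary:
    per_gene: pd.DataFrame        # genes x (domain, mode) CRE counts
    histograms: pd.DataFrame      # bins x (domain, mode)


def cre_counts_per_gene(cres: pd.DataFrame, gene_set: list | pd.Index
                        ) -> CRECountSummary:
    """Per-gene CRE counts for each (domain, mode), with binned histograms."""
    genes = list(gene_set)
    cols = pd.MultiIndex.from_tuples(QUADRANTS, names=["domain", "mode"])
    per_gene = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                            columns=cols)
    sub = cres[cres["gene_id"].isin(set(genes))]
    tally = sub.groupby(["gene_id", "domain", "mode"]).size()
    for (gid, dom, mode), n in tally.items():
        per_gene.loc[gid, (dom, mode)] = n
    hist = pd.DataFrame(
        {q: _bin_counts(per_gene[q].to_numpy()) for q in cols},
        index=pd.Index(HISTOGRAM_BINS, name="bin"))
    hist.columns = cols
    return CRECountSummary(per_gene=per_gene, histograms=hist)


@dataclass
class NullComparisonResult:
    statistic: float
    p_value: float
    dof: int
    bins: list[str]
    observed: np.ndarray          # TF-gene counts per (merged) bin
    expected: np.ndarray          # expected counts under the resampled null
    null_proportions: np.ndarray  # pooled resample bin proportions
    n_resamples: int
    merged_bins: bool


def _total_cre_counts(cres: pd.DataFrame, genes: list) -> np.ndarray:
    counts = cres.groupby("gene_id").size()
    return np.array([counts.get(g, 0) for g in genes], dtype=int)


def randomized_null_comparison(cres: pd.DataFrame,
                               tf_genes: list,
                               all_degs: list,
                               n_resamples: int = 1000,
                               seed: int | None = None,
                               exclude_tfs: bool = True
                               ) -> NullComparisonResult:
    """Chi-square comparison of TF CRE-count histogram against resampled DEGs.

    Draws ``n_resamples`` gene sets of the TF-set size from the DEG pool
    (without replacement within each draw), pools their binned CRE counts
    into null bin proportions, and Pearson-tests the observed TF histogram
    against the implied expected counts.  Bins with expected count < 5 are
    merged downward from the top (the >=5 bin absorbs) before testing.
    """
    if n_resamples <= 0:
        raise ValueError("n_resamples must be positive")
    tf_genes = list(tf_genes)
    pool = list(all_degs)
    if exclude_tfs:
        tf_set = set(tf_genes)
        pool = [g for g in pool if g not in tf_set]
    k = len(tf_genes)
    if k == 0:
        raise ValueError("empty TF gene set")
    if k > len(pool):
        raise ValueError("TF set larger than the null sampling pool")

    rng = np.random.default_rng(seed)
    pool_counts = _total_cre_counts(cres, pool)
    # vectorised without-replacement draws: argsort of uniform keys
    keys = rng.random((n_resamples, len(pool)))
    idx = np.argsort(keys, axis=1)[:, :k]
    drawn = pool_counts[idx]                       # (n_resamples, k)
    drawn_binned = np.minimum(drawn, 5)
    null_hist = np.zeros(len(HISTOGRAM_BINS), dtype=float)
    for b in range(len(HISTOGRAM_BINS)):
        null_hist[b] = np.sum(drawn_binned == b)
    null_prop = null_hist / null_hist.sum()

    observed = _bin_counts(_total_cre_counts(cres, tf_genes)).astype(float)
    expected = null_prop * k

    bins = list(HISTOGRAM_BINS)
    merged = False
    # merge from the top until expected counts are acceptable or only 2 bins
    while len(bins) > 2 and expected.min() < 5:
        merged = True
        observed = np.concatenate([observed[:-2], [observed[-2] + observed[-1]]])
        expected = np.concatenate([expected[:-2], [expected[-2] + expected[-1]]])
        bins = bins[:-2] + [f">={len(bins) - 2}" if len(bins) > 2 else bins[-1]]
    if merged:
        warnings.warn("chi-square bins merged from the top to satisfy the "
                      "expected-count guidance", stacklevel=2)
    if expected.min() < 5:
        raise ValueError(
            "expected counts below 5 even after merging bins; "
            "larger data needed for the chi-square comparison")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(bins) - 1
    p = float(stats.chi2.sf(stat, dof))
    return NullComparisonResult(statistic=stat, p_value=p, dof=dof, bins=bins,
                                observed=observed, expected=expected,
                                null_proportions=null_prop,
                                n_resamples=n_resamples, merged_bins=merged)


def pearson_chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square of independence on an R x C contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected == 0):
        raise ValueError("contingency table has a zero-margin cell")
    stat = float(np.sum((table - expected) ** 2 / expected))
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, dof)), dof
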