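"""TF co-occupancy / co-regulation rates and motif-density enrichment.

Co-occupancy asks how often predicted binding sites for two TFs fall in the
same peak; co-regulation asks how often the two TFs have sites in (possibly
different) peaks associated with the same gene.  Both use presence/absence
semantics (>= 1 retained hit) and, by default, a Jaccard rate
``|A and B| / |A or B|`` which is symmetric and bounded in [0, 1]; a
conditional variant ``|A and B| / |A|`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OccupancyResult:
    """Pairwise rates plus per-TF sharing tallies over peaks or genes."""

    tfs: list[str]
    rate_matrix: pd.DataFrame     # tfs x tfs, diagonal 1
    presence: pd.DataFrame        # units (peaks or genes) x tfs, boolean
    average_rate: float           # mean over off-diagonal pairs w/ support
    unit: str                     # "peak" or "gene"


def _presence_result(presence: pd.DataFrame, unit: str,
                     rate: str) -> OccupancyResult:
    tfs = list(presence.columns)
    if sum(presence[t].any() for t in tfs) < 2:
        raise ValueError(f"need >= 2 TFs with at least one occupied {unit}")
    M = presence.to_numpy(dtype=bool)
    both = (M[:, :, None] & M[:, None, :]).sum(axis=0).astype(float)
    counts = M.sum(axis=0).astype(float)
    if rate == "jaccard":
        union = counts[:, None] + counts[None, :] - both
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(union > 0, both / np.where(union > 0, union, 1), np.nan)
        support = union > 0
    elif rate == "conditional":
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(counts[:, None] > 0,
                         both / np.where(counts[:, None] > 0, counts[:, None], 1),
                         np.nan)
        support = (counts[:, None] > 0) & (counts[None, :] > 0)
    else:
        raise ValueError(f"unknown rate definition {rate!r}")
    np.fill_diagonal(R, 1.0)
    iu = np.triu_indices(len(tfs), k=1)
    vals = R[iu][support[iu]]
    avg = float(vals.mean()) if len(vals) else float("nan")
    return OccupancyResult(
        tfs=tfs,
        rate_matrix=pd.DataFrame(R, index=tfs, columns=tfs),
        presence=presence,
        average_rate=avg,
        unit=unit)


def cooccupancy(hits: pd.DataFrame, peak_set: list | set,
                rate: str = "jaccard") -> OccupancyResult:
    """Pairwise co-occurrence of TF binding sites within the same peak.

    ``hits`` should already have passed overlap resolution.  Every peak in
    ``peak_set`` counts, including peaks with no hit at all.
    """
    peaks = sorted(set(peak_set))
    sub = hits[hits["peak_id"].isin(set(peaks))]
    tfs = sorted(sub["pwm_id"].unique())
    presence = pd.DataFrame(False, index=pd.Index(peaks, name="peak_id"),
                            columns=tfs)
    for pwm_id, grp in sub.groupby("pwm_id"):
        presence.loc[sorted(set(grp["peak_id"])), pwm_id] = True
    return _presence_result(presence, "peak", rate)


def coregulation(hits: pd.DataFrame, associations: pd.DataFrame,
                 gene_set: list | set, rate: str = "jaccard"
                 ) -> OccupancyResult:
    """Pairwise co-occurrence of TF sites among peaks of the same gene.

    A gene's TF set is the union of PWMs hitting any of its associated
    peaks, so two TFs can co-regulate a gene without sharing a single peak.
    """
    genes = sorted(set(gene_set))
    assoc = associations[associations["gene_id"].isin(set(genes))]
    merged = assoc[["peak_id", "gene_id"]].merge(
        hits[["peak_id", "pwm_id"]], on="peak_id")
    tfs = sorted(merged["pwm_id"].unique())
    presence = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"),
                            columns=tfs)
    for (gid, pwm_id), _ in merged.groupby(["gene_id", "pwm_id"]):
        presence.loc[gid, pwm_id] = True
    return _presence_result(presence, "gene", rate)


def sharing_histograms(result: OccupancyResult) -> dict[str, pd.Series]:
    """Per-TF histogram of its units by number of co-occurring other TFs.

    For each TF, counts its occupied peaks (genes) having 0, 1, 2, ... other
    TFs also present; totals equal the TF's occupied-unit count.
    """
    M = result.presence.to_numpy(dtype=bool)
    per_unit_total = M.sum(axis=1)
    out = {}
    for j, tf in enumerate(result.tfs):
        others = per_unit_total[M[:, j]] - 1
        counts = np.bincount(others) if len(others) else np.array([], dtype=int)
        out[tf] = pd.Series(counts,
                            index=pd.RangeIndex(len(counts), name="n_cooccupants"))
    return out


def motif_density_fold(hits: pd.DataFrame,
                       target_peaks: list | set,
                       background_peaks: list | set,
                       pwm_subset: list | set | None = None
                       ) -> tuple[float, float, float]:
    """Average retained motifs per peak in a target vs a background set.

    Returns (target density, background density, fold).  A zero background
    density leaves the fold undefined and raises instead of returning
    infinity.
    """
    target = set(target_peaks)
    background = set(background_peaks)
    if not target or not background:
        raise ValueError("peak sets must be non-empty")
    sub = hits
    if pwm_subset is not None:
        sub = hits[hits["pwm_id"].isin(set(pwm_subset))]
    t_density = len(sub[sub["peak_id"].isin(target)]) / len(target)
    b_density = len(sub[sub["peak_id"].isin(background)]) / len(background)
    if b_density == 0:
        raise ValueError("background motif density is zero; fold undefined")
    return t_density, b_density, t_density / b_density
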