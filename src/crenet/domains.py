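"""Basal-plus-extension regulatory domains and peak-to-gene association.

Each gene receives a strand-aware *basal* window around its TSS (default
5 kb upstream, 1 kb downstream) and an *extended* domain growing from the
TSS up to ``max_extension`` (default 1 Mb) in each direction, truncated at
the nearest flanking basal domain of another gene and at chromosome ends.
A peak is associated with every gene whose extended domain contains the
peak midpoint (default) or overlaps the peak (``mode="overlap"``).

Curated special-case domains of the association tool this emulates are not
implemented; the rule above is applied uniformly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DOMAIN_COLUMNS = ["gene_id", "chrom", "tss", "strand",
                  "basal_start", "basal_end", "ext_start", "ext_end"]


def build_domains(genes: pd.DataFrame,
                  chromosome_lengths: dict[str, int],
                  basal_up: int = 5000,
                  basal_down: int = 1000,
                  max_extension: int = 1_000_000) -> pd.DataFrame:
    """One regulatory domain per gene.

    ``genes`` needs columns gene_id, chrom, tss, strand.  The extension in a
    given direction stops at the first basal edge of another gene beyond the
    gene's own basal window; a neighbouring basal domain overlapping the
    gene's own basal window suppresses extension on that side entirely
    (the extended domain still always contains the basal window).
    """
    out = []
    for chrom, grp in genes.groupby("chrom", sort=True):
        if chrom not in chromosome_lengths:
            raise ValueError(f"gene on unknown chromosome {chrom!r}")
        clen = int(chromosome_lengths[chrom])
        tss = grp["tss"].to_numpy(dtype=np.int64)
        if np.any(tss < 0) or np.any(tss >= clen):
            bad = grp["gene_id"].iloc[int(np.argmax((tss < 0) | (tss >= clen)))]
            raise ValueError(f"TSS of {bad!r} outside chromosome {chrom!r}")
        plus = (grp["strand"] == "+").to_numpy()
        bs = np.where(plus, tss - basal_up, tss - basal_down)
        be = np.where(plus, tss + basal_down, tss + basal_up)
        bs = np.clip(bs, 0, clen)
        be = np.clip(be, 0, clen)

        n = len(grp)
        ext_start = np.maximum(tss - max_extension, 0)
        ext_end = np.minimum(tss + max_extension, clen)
        for i in range(n):
            # rightward: nearest constraining basal edge among genes whose
            # basal window reaches beyond this gene's basal end
            right = [max(bs[j], be[i]) for j in range(n)
                     if j != i and be[j] > be[i]]
            if right:
                ext_end[i] = min(ext_end[i], min(right))
            left = [min(be[j], bs[i]) for j in range(n)
                    if j != i and bs[j] < bs[i]]
            if left:
                ext_start[i] = max(ext_start[i], max(left))
            # extension always contains the basal window
            ext_start[i] = min(ext_start[i], bs[i])
            ext_end[i] = max(ext_end[i], be[i])

        part = pd.DataFrame({
            "gene_id": grp["gene_id"].to_numpy(),
            "chrom": chrom,
            "tss": tss,
            "strand": grp["strand"].to_numpy(),
            "basal_start": bs, "basal_end": be,
            "ext_start": ext_start, "ext_end": ext_end,
        })
        out.append(part)
    if not out:
        return pd.DataFrame(columns=DOMAIN_COLUMNS)
    return (pd.concat(out, ignore_index=True)
            .sort_values(["chrom", "tss", "gene_id"])
            .reset_index(drop=True)[DOMAIN_COLUMNS])


def associate_peaks(peaks: pd.DataFrame, domains: pd.DataFrame,
                    mode: str = "midpoint") -> pd.DataFrame:
    """Associate each peak with the genes whose extended domain covers it.

    Returns one row per (peak, gene) pair with the peak midpoint carried
    along, sorted by (peak_id, gene_id).  Peaks in gene-free regions yield
    no rows.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"unknown association mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in domains.groupby("chrom"):
        tree = IntervalTree()
        for gid, s, e in zip(grp["gene_id"], grp["ext_start"], grp["ext_end"]):
            if e > s:
                tree.addi(int(s), int(e), gid)
        trees[chrom] = tree

    rows = []
    for chrom, start, end, pid in zip(peaks["chrom"], peaks["start"],
                                      peaks["end"], peaks["peak_id"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        mid = (int(start) + int(end)) // 2
        if mode == "midpoint":
            found = tree.at(mid)
        else:
            found = tree.overlap(int(start), int(end))
        for iv in found:
            rows.append((pid, iv.data, mid))
    df = pd.DataFrame(rows, columns=["peak_id", "gene_id", "midpoint"])
    return df.sort_values(["peak_id", "gene_id"]).reset_index(drop=True)


def distance_and_location(associations: pd.DataFrame, genes: pd.DataFrame,
                          promoter_up: int = 1000,
                          promoter_down: int = 100) -> pd.DataFrame:
    """Annotate associations with signed TSS distance and location class.

    The signed distance is measured in gene orientation: negative values lie
    upstream of the TSS.  ``promoter_proximal`` means the midpoint falls in
    the strand-aware window [-promoter_up, +promoter_down] around the TSS.
    """
    ann = associations.merge(genes[["gene_id", "tss", "strand"]], on="gene_id",
                             how="left", validate="many_to_one")
    if ann["tss"].isna().any():
        missing = ann.loc[ann["tss"].isna(), "gene_id"].iloc[0]
        raise ValueError(f"association references unknown gene {missing!r}")
    raw = ann["midpoint"].to_numpy() - ann["tss"].to_numpy()
    sign = np.where(ann["strand"].to_numpy() == "+", 1, -1)
    d = raw * sign
    ann["signed_distance_bp"] = d.astype(np.int64)
    ann["location_class"] = np.where(
        (d >= -promoter_up) & (d <= promoter_down),
        "promoter_proximal", "distal")
    return ann.drop(columns=["tss", "strand"])


def location_summary(annotated: pd.DataFrame,
                     peak_ids: pd.Index | list | None = None,
                     quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)) -> dict:
    """Location-class proportions and |distance| quantiles for a peak subset."""
    sub = annotated
    if peak_ids is not None:
        sub = annotated[annotated["peak_id"].isin(set(peak_ids))]
    n = len(sub)
    if n == 0:
        return {"n": 0, "proportions": {}, "distance_quantiles": {}}
    props = (sub["location_class"].value_counts(normalize=True)
             .sort_index().to_dict())
    absd = sub["signed_distance_bp"].abs()
    qs = {f"q{int(q * 100)}": float(absd.quantile(q)) for q in quantiles}
    return {"n": n, "proportions": props, "distance_quantiles": qs}
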