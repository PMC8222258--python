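# crenet

Integrative analysis of a bifurcating gene-regulatory network from paired
chromatin-accessibility (ATAC-seq) and expression (RNA-seq) data.  The
package is written for the setting where a common progenitor population
splits into two domains — here called NR (neural retina) and RPE (retinal
pigmented epithelium), the two branches of the vertebrate optic-cup
bifurcation — and you have, per gene, expression across five conditions
(progenitors plus two stages per branch) and, per chromatin peak, a
differential-accessibility log2 fold change between the branches.

It is aimed at computational biologists who already have post-quantification
tables (differential peaks, differential expression, gene models, peak
sequences, a PWM library) and want a tested, reusable implementation of the
downstream integration, plus a synthetic-data generator with known ground
truth to validate every stage.

## What it computes

**Activating / repressing CRE classification.** A peak is a DOCR
(differentially open chromatin region) when its adjusted p-value is below
α = 0.05; a gene is a DEG when its corrected p-value is below 0.05 for the
chosen contrast.  With both log2 fold changes on the NR-over-RPE
orientation, each associated (DOCR, DEG) pair is labelled by its quadrant in
the (peak log2FC, gene log2FC) plane: *domain* NR iff the peak log2FC > 0,
and *mode* activating iff sign(peak log2FC) = sign(gene log2FC) (open where
the gene is up), repressing otherwise.  Per-gene CRE counts for TFs are
compared against resampled random DEG sets with a Pearson chi-square test.

**Peak→gene association.** The "basal plus extension" regulatory-domain
model: each gene gets a strand-aware basal window (5 kb upstream / 1 kb
downstream of the TSS) extended up to 1 Mb in each direction, truncated at
neighbouring basal domains and chromosome ends; a peak associates with every
gene whose extended domain contains the peak midpoint.

**Motif scanning.** JASPAR PFMs are converted to log2-odds matrices against
a 0-order background, p(b,j) = (count + 0.1·bg_b)/(total + 0.1).  Scores are
snapped to a 1000-step grid over the achievable range and the null score
distribution is computed exactly by column-wise convolution, so the p-value
of a hit — P(background window of motif length scores ≥ s) — is exact for
the published matrix.  Both strands are scanned; predicted sites overlapping
a better (lowest p-value) site by more than 3 bp are eliminated.

**Network statistics.** Co-occupancy: the rate at which binding sites for
two TFs occur in the same peak, measured as the Jaccard index
|A∩B| / |A∪B| over peaks (a conditional |A∩B|/|A| variant is available).
Co-regulation: the same rate over genes, where a gene's TF set is the union
over all its associated peaks.  Motif-density fold enrichment compares the
average number of retained sites per peak between peak sets.

**Trajectory clustering.** Genes with raw-expression variance ≥ 3 across
the five conditions are z-scored per row and soft-clustered by fuzzy
c-means (fuzziness m = 1.5, c = 25 by default), minimising
J = Σᵢ Σₖ uᵢₖᵐ ‖xᵢ − vₖ‖²; the soft clusters are aggregated into a small
number of main clusters by complete-linkage hierarchical clustering.

**Synthetic data.** `SyntheticConfig`/`generate_dataset` produce a
miniature genome, five-condition expression with planted trajectory
clusters, peaks with planted quadrant labels and log-normal TSS-distance
structure, and peak sequences with motif instances planted under a
controlled pairwise co-occurrence design, together with a full ground-truth
record (including closed-form expected co-occupancy probabilities).

## Worked example

```python
import crenet as cn

cfg = cn.SyntheticConfig(seed=7, n_peaks=400, n_genes=60,
                         motif_marginals={"M01": 0.3, "M02": 0.3},
                         pair_coupling={("M01", "M02"): 0.2})
ds = cn.generate_dataset(cfg)

lengths = dict(zip(ds.chromosomes["chrom"], ds.chromosomes["length"]))
domains = cn.build_domains(ds.genes, lengths)
assoc = cn.distance_and_location(cn.associate_peaks(ds.peaks, domains),
                                 ds.genes)

degs = cn.select_degs(ds.expression, cfg.contrast)
docrs = cn.select_docrs(ds.peaks)
cres = cn.classify_cres(docrs, degs, assoc)
print(f"{len(docrs)} DOCRs, {len(degs)} DEGs, {len(cres)} classified CREs")
print(cres.groupby(["domain", "mode"]).size())

bg = cn.estimate_background(ds.sequences)
mats = [cn.pfm_to_scoring_matrix(p, bg) for p in ds.pwms]
hits = cn.resolve_overlaps(cn.scan_peaks(ds.sequences, mats, 1e-4))
cooc = cn.cooccupancy(hits, ds.peaks["peak_id"])
print(f"co-occupancy (Jaccard) M01-M02: "
      f"{cooc.rate_matrix.loc['M01', 'M02']:.3f}  (planted expectation "
      f"{ds.truth.expected_cooccupancy.loc[0, 'jaccard']:.3f})")
```

Output:

```
240 DOCRs, 30 DEGs, 297 classified CREs
domain  mode
NR      activating    82
        repressing    68
RPE     activating    61
        repressing    86
dtype: int64
co-occupancy (Jaccard) M01-M02: 0.436  (planted expectation 0.447)
```

240 of the 400 peaks pass the DOCR threshold (the configured differential
fraction is 0.6), and the 297 (DOCR, DEG) pairs split across the four
quadrants roughly as the configured quadrant mix (0.18/0.12/0.12/0.18)
prescribes — a peak associated with several DEGs contributes several rows.
The measured M01–M02 co-occupancy, obtained by actually scanning the
generated sequences and resolving overlaps, sits next to the closed-form
expectation implied by the planting design (marginals 0.3, pairwise
coupling 0.2).

The same stages are available from the shell via the `crenet` entry point
(`simulate`, `associate`, `classify-cre`, `scan`, `network-stats`,
`cluster`, `run-all`, `report`), with all thresholds in a YAML config.

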