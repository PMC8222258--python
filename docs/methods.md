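# Methods

This note documents the models, parameter choices and numerical decisions
behind `crenet`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Data model and orientation conventions

All genomic coordinates are 0-based half-open in memory and on disk (BED
convention).  All fold changes are log2 and oriented NR-over-RPE: a
positive peak log2FC means more accessible in the NR branch, a positive
gene log2FC means higher expression in NR for the chosen contrast.  The
five conditions are a progenitor stage (PG16) and two stages per branch
(NR18, RPE18, NR23, RPE23).  The default contrast for the
accessibility/expression intersection is NR23-vs-RPE23, the stage at which
accessibility is measured; it is a config field, not hard-coded, because
the matched-stage choice is an analysis decision rather than a property of
the data.

## Differential calls and CRE classification

DOCRs are peaks with BH-adjusted p < `docr_alpha` (default 0.05); DEGs are
genes with corrected p < `deg_alpha` (default 0.05) and nonzero log2FC for
the named contrast.  Classification labels each associated (DOCR, DEG)
pair by quadrant: domain = NR iff peak log2FC > 0; mode = activating iff
the two log2FCs share a sign.  Two deliberate edge rules:

* pairs with a log2FC of exactly 0 are excluded rather than tie-broken —
  the quadrant scheme has no zero class, and a zero fold change carries no
  directional information;
* a peak associated with several DEGs contributes one row per gene, so the
  same region can act as an activating CRE for one gene and a repressing
  CRE for another.  Counting is therefore per-association; per-peak and
  per-gene tallies can be derived from the same table.

The TF-vs-null comparison bins per-gene CRE counts into
{0, 1, 2, 3, 4, ≥5}, estimates null bin proportions by resampling
`n_resamples` (default 1000) DEG sets of the TF-set size, and applies a
Pearson goodness-of-fit chi-square with bins − 1 degrees of freedom.  Bins
with expected count < 5 are merged downward from the top (the ≥5 bin
absorbs); if the guidance still cannot be met the function refuses rather
than report an unreliable p-value.  TF genes are excluded from the
sampling pool by default (config switch `exclude_tfs_from_null`) so the
null is a contrast rather than a mixture; the calibration tests draw the
"TF" set from the same pool and include it, which is the exchangeable null
under which the nominal 5% level is checked.

## Regulatory domains and peak→gene association

The basal-plus-extension model assigns each gene a strand-aware basal
window of `basal_up` = 5000 bp upstream to `basal_down` = 1000 bp
downstream of the TSS, then extends it up to `max_extension` = 1 Mb in
each direction.  The extension in a direction stops at the first basal
edge of another gene lying beyond the gene's own basal window; a
neighbouring basal domain that overlaps the gene's own basal window
suppresses extension on that side entirely.  Basal windows themselves are
never truncated, so basal ⊆ extended always holds.  The three sizes are
the published defaults of the association tool this emulates and are
config-exposed; the tool's manually curated special-case domains are not
implemented.

A peak associates with every gene whose extended domain contains the peak
midpoint, floor((start+end)/2).  Midpoint containment was chosen over
any-overlap as the default because it is unambiguous (each peak has one
well-defined location) and makes the association independent of peak
width; any-overlap is available via `association_mode: overlap`.  Signed
TSS distances are measured midpoint-to-TSS in gene orientation (negative =
upstream); `promoter_proximal` means the strand-aware window
[−`promoter_up`, +`promoter_down`] = [−1000, +100] bp, the convention of
common peak annotators, exposed in config because "near the promoter" is
not otherwise defined.

## Motif scanning and exact p-values

PFM counts are converted to column probabilities with a
background-proportioned pseudocount, p(b,j) = (n(b,j) + 0.1·bg_b) /
(N_j + 0.1), and to log2-odds against a 0-order background.  The
background is, by default, estimated from the scanned sequence set and
strand-symmetrised (A/T and C/G averaged); a symmetric background makes
hit scores and p-values exactly invariant under reverse complement.
Uniform and explicit backgrounds are config options.

Zero-probability cells (possible only at pseudocount 0) are capped at −30
bits instead of −∞, and an N base contributes the column minimum, so
N-containing windows score finitely low and simply fail the threshold.

Each matrix's column scores are snapped to a shared discretization grid of
`n_score_bins` = 1000 steps spanning the achievable score range.  The null
distribution of the total (an integer grid index) is obtained exactly by
convolving the per-column index distributions under the background, and
scanning accumulates the same integer indices, so the reported p-value —
the probability that a background window of the motif length scores at
least as high — is *exact* for the published (snapped) matrix rather than
an approximation with an unquantified discretization error.  Snapping
perturbs each column score by at most half a grid step (≤ L·range/2000 in
total), far below any biologically meaningful score difference.

The reverse strand is scanned by scoring the reverse complement of each
window with the same matrix; reverse-strand hits are reported at the
forward coordinate of their leftmost base.  The default hit threshold is
p ≤ 1e-4 (the emulated scanner's default), config-exposed.

Overlap resolution ranks hits per peak by ascending p-value (ties: higher
score, then leftmost offset, then pwm_id, then strand — a total order, so
the output is independent of input order) and greedily accepts a hit iff
it overlaps every already accepted hit by at most `max_overlap_bp` = 3 bp,
measured on forward coordinates regardless of strand.  The rule is applied
jointly across all PWMs within a peak, since its purpose is to
de-duplicate sites before co-occupancy estimation across TFs; whether
same-PWM hits should also compete is not externally specified, and joint
application is the stricter, default choice.

Known-motif over-representation between peak sets uses a one-sided Fisher
exact test on peaks-with-hit counts, with a Haldane 0.5 correction for the
odds ratio when a cell is zero.  De novo motif discovery is out of scope.

## Co-occupancy, co-regulation, motif density

Both statistics use presence/absence of ≥1 retained hit, not hit counts.
The pairwise rate is the Jaccard index by default: it is symmetric,
bounded in [0, 1], and has no hidden denominator choice; the conditional
rate |A∩B|/|A| is kept as a config option for sensitivity analysis because
the quantity "co-occurrence rate" admits both readings.  Averages are
taken over unordered pairs with a non-empty union; empty pairs are
excluded rather than counted as zero.  Co-regulation reduces each gene to
the union of PWMs over all its associated peaks, so two TFs co-regulate a
gene even when no single peak contains both.  Motif-density fold is the
ratio of mean retained hits per peak between a target and a background
set; a zero background density raises rather than returning infinity.

## Trajectory clustering

The variance filter uses sample variance (n−1 denominator; unspecified in
the emulated workflow, and the difference is immaterial at the ≥3
threshold) computed on raw FPKM-like values *before* standardization,
matching the stated order of operations.  Rows are then z-scored
(sample sd).  Fuzzy c-means uses the standard alternating updates with
fuzziness m = 1.5 and runs until the largest membership change falls below
`convergence_tol` = 1e-6 or `max_iterations` = 300.  Initialisation is
seeded farthest-point sampling (first point random under the seed, then
repeated farthest-from-chosen), which is deterministic and
well-spread; the reference implementation's random initialisation is not
reproduced, so cluster *identities* differ between implementations even
though the fixed points agree.  A point coinciding with a centroid gets
membership 1 there (split over coinciding centroids).  The objective
J = Σ u^m d² is asserted non-increasing on every iteration.

Main clusters come from complete-linkage agglomeration (scipy) on
Euclidean distances — the linkage is externally specified, the metric is
not, and Euclidean on z-scored rows is the natural companion.  Whether to
agglomerate genes directly or the soft-cluster centroids is ambiguous in
the emulated workflow ("aggregate the small sub-groups"); both modes are
provided and centroid mode is the default, with genes inheriting the main
cluster of their hard label.

## The synthetic-data generator

The generator emulates the statistical structure the downstream stages
assume, not the sequencing process.  Defaults: 2 chromosomes × 5 Mb, 60
genes (TSS near-uniform with ±20% jitter; exactly round(0.3·n) TF-flagged
and a disjoint round(0.15·n) cytoskeletal-flagged, exact counts so tests
are deterministic), 400 peaks with mean length 450 bp (between the two
reported mean differential-peak sizes of ~423 and ~500 nt; sd 15% of the
mean), GC content 0.40, effect size 2.0 log2 units, noise sd 0.3.

* **Expression**: each gene follows one of k template trajectories (a
  fixed bank of eight biologically styled patterns — branch-specific late
  activation, progenitor decay, transients, two-wave — standardized to
  mean 0/sd 1), as log2 expression = baseline + effect·template + noise.
  A gene is planted differential for a contrast when its noiseless
  template log2FC magnitude reaches 0.5.  Corrected p-values are drawn
  U(0, α) for planted differentials and U(α, 1) otherwise: this sidesteps
  simulating a test statistic while preserving exact thresholding
  behaviour, which is all the downstream stages consume.
* **Peaks**: the four quadrant proportions of `quadrant_mix` (default
  0.18/0.12/0.12/0.18, null 0.40) are realised as exact largest-remainder
  counts.  Each non-null peak picks an intended gene differential in the
  required direction and is placed at a signed log-normal distance from
  its TSS — median 2 kb (activating) or 20 kb (repressing), log-sd 0.8,
  random side — reflecting heavy-tailed enhancer distances and the
  planted activating-closer trend.  Truth records the intended gene
  separately from whatever the association step later recovers.
* **Sequences**: i.i.d. background at the configured GC; the PWM set
  planted per peak mixes independent Bernoulli(marginal) events with
  pairwise joint-planting events Bernoulli(coupling), all independent, so
  pairwise presence probabilities have an exact closed form which is
  recorded in the truth record.  Instances are *sampled from the PWM
  columns* (not consensus) on a random strand at non-overlapping offsets,
  so scanner sensitivity is genuinely exercised.

What the generator does **not** emulate: read-level noise, fragment-size
and transposase-insertion structure, peak-calling artefacts, correlated
backgrounds (repeats, CpG islands), overlapping/nested genes, and any
coupling between accessibility magnitude and motif content.  Passing the
recovery tests therefore shows the *inference machinery* is correct under
its own model assumptions; it does not certify performance on real
libraries, where the thresholded inputs arrive from upstream tools.

## Problem sizes and test conditions

Recovery checks run on 5,000-peak datasets (120 genes over 4 × 10 Mb
chromosomes, so regulatory domains comfortably contain the planted
distance distributions).  Quadrant recovery is evaluated on the pairs
whose recovered gene is the planted intended gene; at noise sd 0.1 the
recovered quadrant proportions match the configured mix to well within 2%
absolute.  Co-occupancy recovery uses marginals 0.3/0.3 with coupling 0.2
(strong pair) and 0.02 (weak pair), sharply informative planted PWMs
(dominant base probability 0.99, length 12) and a scan threshold of 1e-5,
at which per-peak false-positive presence (~1%) and missed degraded
instances (<1%) are both small relative to the 3-SE comparison band.
Null calibration runs 200 simulations of 300 resamples over a 600-gene
pool with Poisson(1.2) CRE counts.  The clustering recovery uses two
well-separated templates at noise sd 0.2 and is scored by Rand index.

## Known limitations

* The DP p-value is exact for the snapped matrix, not for the
  infinite-precision log-odds; the two differ by less than half a grid
  step per column.
* `build_domains` is O(G²) per chromosome; fine for the tens to hundreds
  of genes per chromosome it is used with, but a sorted sweep would be
  needed for full mammalian annotations.
* The chi-square null comparison treats the resampled bin proportions as
  known; with the default 1000 resamples the extra variance is negligible,
  but very small resample counts would inflate the statistic.
* Co-occupancy rates depend on the scan threshold through false-positive
  presence; at the default 1e-4 threshold, presence probabilities for
  weakly planted motifs are biased upward by roughly the per-peak
  false-positive rate (~2·peak length·threshold per strand pair).
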