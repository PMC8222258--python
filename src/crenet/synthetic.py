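"""Ground-truth synthetic data for the whole pipeline.

Generates an internally consistent miniature dataset — genome with gene
models, five-condition expression trajectories with planted cluster
structure, accessibility peaks with planted activating/repressing quadrant
membership and distance-to-TSS structure, peak sequences with motif
instances planted under a controlled pairwise co-occurrence design, and a
small PWM library — together with a :class:`SyntheticTruth` record of every
planted parameter, so that downstream stages can be tested against known
answers.

The five conditions model a bifurcating system sampled at a common
progenitor stage and two stages per branch (PG16, NR18, RPE18, NR23,
RPE23); all fold changes follow the NR-over-RPE orientation (positive =
higher/more open in NR).  Quadrant labels combine the domain in which the
peak is open with the activating/repressing mode: an NR-activating peak is
more accessible in NR and its intended gene is upregulated in NR, an
NR-repressing peak is more accessible in NR while its gene is up in RPE,
and so on.

Peak-to-TSS distances are drawn as log-normal magnitudes with a random
side, reflecting the heavy-tailed distribution of enhancer distances;
activating and repressing peaks have separately configurable location-scale
parameters.  Motif planting mixes independent per-PWM Bernoulli events with
extra pairwise joint-planting events, and the exact implied pairwise
co-occupancy probabilities are recorded in closed form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError
from .io import (
    PositionFrequencyMatrix,
    read_bed_peaks, read_expression_table, read_fasta, read_gene_table,
    read_jaspar_pfm,
    write_bed_peaks, write_expression_table, write_fasta, write_gene_table,
    write_jaspar_pfm,
)

CONDITIONS = ("PG16", "NR18", "RPE18", "NR23", "RPE23")
CONTRASTS = {
    "NR23_vs_RPE23": ("NR23", "RPE23"),
    "NR18_vs_RPE18": ("NR18", "RPE18"),
}
QUADRANT_LABELS = ("NR_activating", "NR_repressing",
                   "RPE_activating", "RPE_repressing")

# minimum noiseless |log2FC| for a gene to be planted as differential
DEG_LFC_MIN = 0.5

# canonical trajectory templates over (PG16, NR18, RPE18, NR23, RPE23),
# standardized to mean 0 / sd 1 at module load; ordered so that the first
# two have opposite NR23-vs-RPE23 signs (any cluster count >= 2 provides
# genes of both differential signs)
_TEMPLATE_BANK_RAW = np.array([
    [-1.0, 0.3, -0.7, 1.6, -1.2],   # NR-specific late up
    [-1.0, -0.7, 0.3, -1.2, 1.6],   # RPE-specific late up
    [1.7, 0.1, 0.1, -0.9, -1.0],    # progenitor-high, decays in both
    [-1.6, -0.2, -0.2, 1.0, 1.0],   # late up in both branches
    [-0.8, 1.7, -0.5, 0.2, -0.6],   # NR transient at 18
    [-0.8, -0.5, 1.7, -0.6, 0.2],   # RPE transient at 18
    [1.2, 0.5, 0.8, -1.5, -1.0],    # monotone down, NR-biased end
    [-1.4, -0.6, 0.6, -0.3, 1.7],   # RPE two-wave
])


def _standardize(rows: np.ndarray) -> np.ndarray:
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    return (rows - mu) / sd


TEMPLATE_BANK = _standardize(_TEMPLATE_BANK_RAW)


def _rng(config: "SyntheticConfig", stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_genes: int = 60
    tf_fraction: float = 0.3
    cytoskeletal_fraction: float = 0.15
    n_peaks: int = 400
    # (NR-activating, NR-repressing, RPE-activating, RPE-repressing, null)
    quadrant_mix: tuple = (0.18, 0.12, 0.12, 0.18, 0.40)
    docr_fraction: float | None = None   # default: 1 - null proportion
    effect_size_log2fc: float = 2.0
    noise_sd: float = 0.3
    activating_tss_distance_bp: tuple = (2000.0, 0.8)   # (scale bp, sigma)
    repressing_tss_distance_bp: tuple = (20000.0, 0.8)
    motif_marginals: dict = field(default_factory=dict)  # pwm_id -> prob
    pair_coupling: dict = field(default_factory=dict)    # (id_a, id_b) -> prob
    peak_length_mean: int = 450
    gc_content: float = 0.40
    n_conditions: int = 5
    n_trajectory_clusters: int = 4
    contrast: str = "NR23_vs_RPE23"
    deg_alpha: float = 0.05
    docr_alpha: float = 0.05

    def validate(self) -> "SyntheticConfig":
        if self.n_conditions != 5:
            raise ConfigError("n_conditions is fixed at 5")
        mix = np.asarray(self.quadrant_mix, dtype=float)
        if mix.shape != (5,):
            raise ConfigError("quadrant_mix needs 5 entries "
                              "(4 quadrants + null)")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigError("quadrant_mix must be nonnegative and sum to 1")
        for name in ("tf_fraction", "cytoskeletal_fraction", "gc_content",
                     "deg_alpha", "docr_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.docr_fraction is not None and not 0 <= self.docr_fraction <= 1:
            raise ConfigError("docr_fraction must lie in [0, 1]")
        if self.chromosome_length <= 2 * self.peak_length_mean:
            raise ConfigError(
                "chromosome_length must exceed twice peak_length_mean")
        for name in ("activating_tss_distance_bp", "repressing_tss_distance_bp"):
            scale, sigma = getattr(self, name)
            if scale <= 0 or sigma < 0:
                raise ConfigError(f"{name} needs positive scale and "
                                  "nonnegative sigma")
        for pid, p in self.motif_marginals.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"motif marginal for {pid!r} outside [0, 1]")
        seen = set()
        for pair, c in self.pair_coupling.items():
            a, b = pair
            if a == b:
                raise ConfigError("pair_coupling diagonal must be zero "
                                  f"(got pair {pair!r})")
            if not 0 <= c <= 1:
                raise ConfigError(f"pair_coupling for {pair!r} outside [0, 1]")
            key = frozenset(pair)
            if key in seen:
                raise ConfigError(f"pair {pair!r} given twice")
            seen.add(key)
        if self.n_trajectory_clusters < 1:
            raise ConfigError("n_trajectory_clusters must be >= 1")
        if self.noise_sd < 0 or self.effect_size_log2fc < 0:
            raise ConfigError("noise_sd and effect_size_log2fc must be >= 0")
        return self

    @property
    def resolved_docr_fraction(self) -> float:
        if self.docr_fraction is None:
            return float(np.sum(self.quadrant_mix[:4]))
        return float(self.docr_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quadrant_mix"] = [float(x) for x in self.quadrant_mix]
        d["activating_tss_distance_bp"] = [
            float(x) for x in self.activating_tss_distance_bp]
        d["repressing_tss_distance_bp"] = [
            float(x) for x in self.repressing_tss_distance_bp]
        d["pair_coupling"] = sorted(
            [[a, b, float(c)] for (a, b), c in self.pair_coupling.items()])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["quadrant_mix"] = tuple(d["quadrant_mix"])
        d["activating_tss_distance_bp"] = tuple(d["activating_tss_distance_bp"])
        d["repressing_tss_distance_bp"] = tuple(d["repressing_tss_distance_bp"])
        d["pair_coupling"] = {(a, b): c for a, b, c in d["pair_coupling"]}
        return cls(**d).validate()


@dataclass
class SyntheticTruth:
    """Every planted parameter, for recovery tests.

    ``peaks`` is indexed by peak_id with the quadrant label (or ``null``),
    the intended associated gene and the planted signed TSS distance (gene
    orientation).  ``motifs`` lists every planted PWM instance with its
    exact offset and strand.  ``expected_cooccupancy`` holds the
    closed-form pairwise presence probabilities implied by the planting
    mixture.
    """

    peaks: pd.DataFrame
    motifs: pd.DataFrame
    clusters: pd.Series
    expected_cooccupancy: pd.DataFrame


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    peaks: pd.DataFrame
    sequences: dict
    pwms: list
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-model and chromosome tables.

    TSS positions are laid out near-uniformly with seeded jitter; exactly
    ``round(tf_fraction * n_genes)`` genes are flagged as TFs and a disjoint
    ``round(cytoskeletal_fraction * n_genes)`` as cytoskeletal.
    """
    config.validate()
    rng = _rng(config, 0)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chromosomes = pd.DataFrame({
        "chrom": chrom_names,
        "length": [config.chromosome_length] * config.n_chromosomes,
    })
    n = config.n_genes
    if n == 0:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand",
                                      "is_tf", "is_cytoskeletal"])
        genes = genes.astype({"tss": int, "is_tf": bool,
                              "is_cytoskeletal": bool})
        return genes, chromosomes

    per_chrom = np.bincount(np.arange(n) % config.n_chromosomes,
                            minlength=config.n_chromosomes)
    clen = config.chromosome_length
    if clen / per_chrom.max() < 2000:
        raise ConfigError(
            "n_genes too large: minimum inter-TSS spacing below 2 kb "
            "would make basal domains fully degenerate")
    records = []
    for chrom, count in zip(chrom_names, per_chrom):
        if count == 0:
            continue
        spacing = clen / count
        base = (np.arange(count) + 0.5) * spacing
        jitter = rng.uniform(-0.2, 0.2, count) * spacing
        tss = np.clip(np.round(base + jitter).astype(np.int64), 0, clen - 1)
        strands = rng.choice(["+", "-"], size=count)
        for t, s in zip(tss, strands):
            records.append((chrom, int(t), s))
    genes = pd.DataFrame(records, columns=["chrom", "tss", "strand"])
    genes.insert(0, "gene_id", [f"g{i + 1:04d}" for i in range(n)])

    n_tf = round(config.tf_fraction * n)
    n_cyto = round(config.cytoskeletal_fraction * n)
    if n_tf + n_cyto > n:
        raise ConfigError("tf_fraction + cytoskeletal_fraction exceed 1 "
                          "for this gene count (flags are disjoint)")
    flagged = rng.choice(n, size=n_tf + n_cyto, replace=False)
    genes["is_tf"] = False
    genes["is_cytoskeletal"] = False
    genes.loc[flagged[:n_tf], "is_tf"] = True
    genes.loc[flagged[n_tf:], "is_cytoskeletal"] = True
    return genes, chromosomes


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: SyntheticConfig, genes: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with per-contrast differential calls, plus the
    planted trajectory-cluster ids.

    Each gene follows one of ``n_trajectory_clusters`` template
    trajectories: log2 expression = baseline + effect_size * template +
    N(0, noise_sd) per condition.  A gene is planted as differential for a
    contrast when its noiseless template log2FC magnitude reaches 0.5;
    planted differentials get corrected p ~ U(0, alpha), all others
    U(alpha, 1).
    """
    config.validate()
    rng = _rng(config, 1)
    n = len(genes)
    k = config.n_trajectory_clusters
    templates = TEMPLATE_BANK[:k].copy()
    if k > len(TEMPLATE_BANK):
        extra = _standardize(rng.normal(size=(k - len(TEMPLATE_BANK), 5)))
        templates = np.vstack([TEMPLATE_BANK, extra])

    if n == 0:
        cols = (["gene_id", *CONDITIONS]
                + [c for ct in CONTRASTS for c in (f"lfc_{ct}", f"q_{ct}")]
                + ["is_tf", "is_cytoskeletal"])
        empty = pd.DataFrame(columns=cols)
        return empty, pd.Series(dtype=int, name="cluster",
                                index=pd.Index([], name="gene_id"))

    clusters = rng.permutation(n) % k
    z = templates[clusters]
    baseline = rng.uniform(3.0, 8.0, size=n)
    log2e = (baseline[:, None] + config.effect_size_log2fc * z
             + rng.normal(0.0, config.noise_sd, size=(n, 5)))
    fpkm = 2.0 ** log2e

    expr = pd.DataFrame(fpkm, columns=list(CONDITIONS))
    expr.insert(0, "gene_id", genes["gene_id"].to_numpy())
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}
    for ct, (c1, c2) in CONTRASTS.items():
        i1, i2 = cond_index[c1], cond_index[c2]
        lfc = log2e[:, i1] - log2e[:, i2]
        planted = (np.abs(config.effect_size_log2fc * (z[:, i1] - z[:, i2]))
                   >= DEG_LFC_MIN)
        q = np.where(planted,
                     rng.uniform(0.0, config.deg_alpha, size=n),
                     rng.uniform(config.deg_alpha, 1.0, size=n))
        expr[f"lfc_{ct}"] = lfc
        expr[f"q_{ct}"] = q
    expr["is_tf"] = genes["is_tf"].to_numpy()
    expr["is_cytoskeletal"] = genes["is_cytoskeletal"].to_numpy()
    truth = pd.Series(clusters, index=pd.Index(genes["gene_id"], name="gene_id"),
                      name="cluster")
    return expr, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_peaks(config: SyntheticConfig, genes: pd.DataFrame,
                   expression: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak table plus per-peak truth (quadrant, intended gene, distance).

    Non-null peaks are placed at a signed log-normal distance from the TSS
    of a gene differential in the required direction; the accessibility
    log2FC sign follows the label's domain (positive = NR-open) and the
    intended gene's expression log2FC sign follows the label's mode.  Null
    peaks are placed uniformly with noise-only log2FC.  Output is sorted by
    coordinate; peak ids are assigned in coordinate order.
    """
    config.validate()
    rng = _rng(config, 2)
    clen = config.chromosome_length
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]

    merged = genes.merge(
        expression[["gene_id", f"lfc_{config.contrast}",
                    f"q_{config.contrast}"]],
        on="gene_id", how="inner")
    lfc = merged[f"lfc_{config.contrast}"].to_numpy()
    deg = merged[f"q_{config.contrast}"].to_numpy() < config.deg_alpha
    pos_pool = merged.index[deg & (lfc > 0)].to_numpy()
    neg_pool = merged.index[deg & (lfc < 0)].to_numpy()

    frac = config.resolved_docr_fraction
    n_docr = round(frac * config.n_peaks)
    n_null = config.n_peaks - n_docr
    qm = np.asarray(config.quadrant_mix[:4], dtype=float)
    qm = qm / qm.sum() if qm.sum() > 0 else np.full(4, 0.25)
    quadrant_counts = (_largest_remainder(n_docr, qm) if n_docr
                       else np.zeros(4, dtype=int))

    length_sd = 0.15 * config.peak_length_mean
    records = []  # chrom, start, end, log2fc, p, meanacc, quadrant, gene, dist

    def draw_length() -> int:
        return max(60, int(round(rng.normal(config.peak_length_mean,
                                            length_sd))))

    for (domain, mode), count in zip(
            [("NR", "activating"), ("NR", "repressing"),
             ("RPE", "activating"), ("RPE", "repressing")], quadrant_counts):
        if count == 0:
            continue
        domain_sign = 1 if domain == "NR" else -1
        gene_sign = domain_sign * (1 if mode == "activating" else -1)
        pool = pos_pool if gene_sign > 0 else neg_pool
        if len(pool) == 0:
            raise ConfigError(
                f"no differential gene with log2FC sign {gene_sign:+d} "
                f"available for quadrant {domain}_{mode}")
        scale, sigma = (config.activating_tss_distance_bp
                        if mode == "activating"
                        else config.repressing_tss_distance_bp)
        for _ in range(count):
            gi = int(rng.choice(pool))
            tss = int(merged.loc[gi, "tss"])
            strand = merged.loc[gi, "strand"]
            chrom = merged.loc[gi, "chrom"]
            placed = False
            for _attempt in range(100):
                signed = ((1 if rng.random() < 0.5 else -1)
                          * rng.lognormal(np.log(scale), sigma))
                offset = signed if strand == "+" else -signed
                mid = int(round(tss + offset))
                length = draw_length()
                start = mid - length // 2
                end = start + length
                if start >= 0 and end <= clen:
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place a {domain}_{mode} peak near gene "
                    f"{merged.loc[gi, 'gene_id']!r} inside the chromosome")
            peak_lfc = domain_sign * (config.effect_size_log2fc
                                      + rng.normal(0.0, config.noise_sd))
            records.append((
                chrom, start, end, peak_lfc,
                rng.uniform(0.0, config.docr_alpha),
                rng.lognormal(3.0, 0.5),
                f"{domain}_{mode}", merged.loc[gi, "gene_id"],
                int(round(signed))))

    for _ in range(n_null):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = draw_length()
        start = int(rng.integers(0, clen - length + 1))
        records.append((
            chrom, start, start + length,
            rng.normal(0.0, config.noise_sd),
            rng.uniform(config.docr_alpha, 1.0),
            rng.lognormal(3.0, 0.5),
            "null", None, 0))

    df = pd.DataFrame(records, columns=[
        "chrom", "start", "end", "log2fc", "adjusted_p",
        "mean_accessibility", "quadrant", "intended_gene",
        "signed_distance_bp"])
    df = df.sort_values(["chrom", "start", "end"],
                        kind="mergesort").reset_index(drop=True)
    df.insert(3, "peak_id", [f"pk{i + 1:06d}" for i in range(len(df))])
    df.insert(4, "score", 0.0)
    df.insert(5, "strand", ".")

    peak_cols = ["chrom", "start", "end", "peak_id", "score", "strand",
                 "log2fc", "adjusted_p", "mean_accessibility"]
    peaks = df[peak_cols].copy()
    truth = df.set_index("peak_id")[
        ["quadrant", "intended_gene", "signed_distance_bp"]].copy()
    truth["domain"] = truth["quadrant"].str.split("_").str[0].where(
        truth["quadrant"] != "null")
    truth["mode"] = truth["quadrant"].str.split("_").str[1].where(
        truth["quadrant"] != "null")
    return peaks, truth


# ---------------------------------------------------------------------------
# sequences and motif planting
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def expected_cooccupancy(marginals: np.ndarray, coupling: np.ndarray,
                         ids: list[str]) -> pd.DataFrame:
    """Closed-form pairwise presence probabilities of the planting mixture.

    PWM i is planted when its own Bernoulli(marginal_i) fires or any pair
    event Bernoulli(coupling_ij) touching it fires; all events are
    independent, so miss probabilities factorise exactly.
    """
    p = np.asarray(marginals, dtype=float)
    C = np.asarray(coupling, dtype=float)
    m = len(p)
    if C.shape != (m, m) or not np.allclose(C, C.T) or np.any(np.diag(C) != 0):
        raise ValueError("coupling must be symmetric with zero diagonal")
    miss = (1 - p) * np.prod(1 - C, axis=1)  # P(PWM i absent)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            others_i = np.prod([1 - C[i, k] for k in range(m)
                                if k not in (i, j)])
            others_j = np.prod([1 - C[j, k] for k in range(m)
                                if k not in (i, j)])
            miss_both = ((1 - p[i]) * (1 - p[j]) * (1 - C[i, j])
                         * others_i * others_j)
            p_both = 1 - miss[i] - miss[j] + miss_both
            p_either = 1 - miss_both
            rows.append((ids[i], ids[j], p_both, p_either,
                         p_both / p_either if p_either > 0 else np.nan))
    return pd.DataFrame(rows, columns=[
        "pwm_a", "pwm_b", "p_both", "p_either", "jaccard"])


def generate_peak_sequences(config: SyntheticConfig, peaks: pd.DataFrame,
                            pwm_library: list[PositionFrequencyMatrix]
                            ) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Peak sequences with planted motif instances.

    Background bases are i.i.d. at the configured GC content.  The set of
    PWMs planted in a peak is drawn from the mixture of independent
    Bernoulli(marginal) events and pairwise joint-planting events; each
    planted instance is sampled from the PWM's column distributions (not
    its consensus), placed on a random strand at a non-overlapping offset.
    Returns (sequences, planted-motif table, expected pairwise
    co-occupancy table).
    """
    config.validate()
    rng = _rng(config, 3)
    ids = [m.pwm_id for m in pwm_library]
    id_index = {pid: i for i, pid in enumerate(ids)}
    for pid in config.motif_marginals:
        if pid not in id_index:
            raise ConfigError(f"motif marginal for unknown PWM {pid!r}")
    p = np.array([config.motif_marginals.get(pid, 0.0) for pid in ids])
    C = np.zeros((len(ids), len(ids)))
    for (a, b), c in config.pair_coupling.items():
        if a not in id_index or b not in id_index:
            raise ConfigError(f"pair_coupling references unknown PWM in "
                              f"({a!r}, {b!r})")
        C[id_index[a], id_index[b]] = c
        C[id_index[b], id_index[a]] = c

    bases = np.array(list("ACGT"))
    bg = np.array([(1 - config.gc_content) / 2, config.gc_content / 2,
                   config.gc_content / 2, (1 - config.gc_content) / 2])
    col_probs = [m.column_probabilities() for m in pwm_library]
    pair_idx = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))
                if C[i, j] > 0]

    sequences: dict[str, str] = {}
    planted_rows = []
    for row in peaks.itertuples():
        plen = row.end - row.start
        seq = rng.choice(bases, size=plen, p=bg)
        plant = rng.random(len(ids)) < p
        for i, j in pair_idx:
            if rng.random() < C[i, j]:
                plant[i] = plant[j] = True
        occupied: list[tuple[int, int]] = []
        for i in np.flatnonzero(plant):
            L = pwm_library[i].length
            if plen < L:
                raise ValueError(
                    f"peak {row.peak_id!r} shorter than motif {ids[i]!r}")
            inst = "".join(
                bases[rng.choice(4, p=col_probs[i][:, j2])]
                for j2 in range(L))
            strand = "+" if rng.random() < 0.5 else "-"
            placed_at = None
            for _attempt in range(200):
                off = int(rng.integers(0, plen - L + 1))
                if all(off + L <= s or off >= e for s, e in occupied):
                    placed_at = off
                    break
            if placed_at is None:
                raise ValueError(
                    f"cannot fit planted motifs non-overlapping in peak "
                    f"{row.peak_id!r}")
            occupied.append((placed_at, placed_at + L))
            oriented = inst if strand == "+" else reverse_complement(inst)
            seq[placed_at:placed_at + L] = list(oriented)
            planted_rows.append((row.peak_id, ids[i], placed_at, strand, inst))
        sequences[row.peak_id] = "".join(seq)

    planted = pd.DataFrame(planted_rows, columns=[
        "peak_id", "pwm_id", "offset", "strand", "instance"])
    expected = expected_cooccupancy(p, C, ids)
    return sequences, planted, expected


def generate_pwm_library(n_pwms: int = 4, length: int = 12,
                         seed: int = 0, dominant: float = 0.95,
                         total: int = 400) -> list[PositionFrequencyMatrix]:
    """Random sharply informative PFMs (one dominant base per column)."""
    rng = np.random.default_rng([seed, 4])
    lib = []
    minor = (1 - dominant) / 3
    for i in range(n_pwms):
        counts = np.full((4, length), minor * total)
        dom = rng.integers(0, 4, size=length)
        counts[dom, np.arange(length)] = dominant * total
        lib.append(PositionFrequencyMatrix(f"M{i + 1:02d}",
                                           np.round(counts, 6),
                                           name=f"synthetic_motif_{i + 1}"))
    return lib


# ---------------------------------------------------------------------------
# orchestration and serialization
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig,
                     pwm_library: list[PositionFrequencyMatrix] | None = None
                     ) -> SyntheticDataset:
    config.validate()
    if pwm_library is None:
        pwm_library = generate_pwm_library(seed=config.seed)
    genes, chromosomes = generate_genome(config)
    expression, clusters = generate_expression(config, genes)
    peaks, peak_truth = generate_peaks(config, genes, expression)
    sequences, planted, expected = generate_peak_sequences(
        config, peaks, pwm_library)
    truth = SyntheticTruth(peaks=peak_truth, motifs=planted,
                           clusters=clusters,
                           expected_cooccupancy=expected)
    return SyntheticDataset(config=config, chromosomes=chromosomes,
                            genes=genes, expression=expression, peaks=peaks,
                            sequences=sequences, pwms=pwm_library,
                            truth=truth)


_FILES = {
    "manifest": "manifest.yaml",
    "chromosomes": "chromosomes.tsv",
    "genes": "genes.tsv",
    "expression": "expression.tsv",
    "peaks": "peaks.bed",
    "sequences": "sequences.fasta",
    "pwms": "motifs.jaspar",
    "truth_peaks": "truth_peaks.tsv",
    "truth_motifs": "truth_motifs.tsv",
    "truth_clusters": "truth_clusters.tsv",
    "truth_cooccupancy": "truth_cooccupancy.tsv",
}


def write_dataset(dataset: SyntheticDataset, directory: str | Path,
                  overwrite: bool = False) -> dict[str, Path]:
    """Write every table in the exact formats the readers consume.

    Refuses to overwrite existing files unless ``overwrite`` is set.  Two
    writes of the same dataset are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    if not overwrite:
        existing = [p for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"{existing[0]} exists; pass overwrite=True to replace")

    manifest = {"format": "crenet-synthetic-v1",
                "seed": int(dataset.config.seed),
                "config": dataset.config.to_dict()}
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    dataset.chromosomes.to_csv(paths["chromosomes"], sep="\t", index=False)
    write_gene_table(dataset.genes, paths["genes"])
    write_expression_table(dataset.expression, paths["expression"])
    write_bed_peaks(dataset.peaks, paths["peaks"])
    write_fasta(dataset.sequences, paths["sequences"])
    write_jaspar_pfm(dataset.pwms, paths["pwms"])
    dataset.truth.peaks.to_csv(paths["truth_peaks"], sep="\t")
    dataset.truth.motifs.to_csv(paths["truth_motifs"], sep="\t", index=False)
    dataset.truth.clusters.to_frame().to_csv(paths["truth_clusters"], sep="\t")
    dataset.truth.expected_cooccupancy.to_csv(paths["truth_cooccupancy"],
                                              sep="\t", index=False)
    return paths


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Load a written dataset back through the standard readers."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in _FILES.items()}
    with open(paths["manifest"]) as fh:
        manifest = yaml.safe_load(fh)
    config = SyntheticConfig.from_dict(manifest["config"])
    chromosomes = pd.read_csv(paths["chromosomes"], sep="\t",
                              dtype={"chrom": str})
    genes = read_gene_table(paths["genes"])
    expression = read_expression_table(paths["expression"])
    peaks = read_bed_peaks(paths["peaks"])
    sequences = read_fasta(paths["sequences"])
    pwms = read_jaspar_pfm(paths["pwms"])
    truth_peaks = pd.read_csv(paths["truth_peaks"], sep="\t",
                              index_col="peak_id")
    truth_motifs = pd.read_csv(paths["truth_motifs"], sep="\t")
    truth_clusters = pd.read_csv(paths["truth_clusters"], sep="\t",
                                 index_col="gene_id")["cluster"]
    truth_cooc = pd.read_csv(paths["truth_cooccupancy"], sep="\t")
    truth = SyntheticTruth(peaks=truth_peaks, motifs=truth_motifs,
                           clusters=truth_clusters,
                           expected_cooccupancy=truth_cooc)
    return SyntheticDataset(config=config, chromosomes=chromosomes,
                            genes=genes, expression=expression, peaks=peaks,
                            sequences=sequences, pwms=pwms, truth=truth)
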