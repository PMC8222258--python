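"""PWM scanning with exact p-values and the >3 bp overlap-resolution rule.

A position frequency matrix is converted to a log2-odds scoring matrix
against a 0-order background.  Column scores are snapped to a fixed
discretization grid (``n_bins`` steps spanning the achievable score range),
and the null score distribution is obtained exactly for the snapped matrix
by column-wise convolution over that grid.  Because scanning uses the same
snapped scores, the p-value of a hit — the probability that a random
background window of the motif length scores at least as high — is exact
for the published scoring matrix, not an approximation of it.

The reverse strand is scanned by scoring the reverse complement of each
window with the same matrix, so a sequence and its reverse complement give
mirror hit sets with identical scores and p-values.

Overlap resolution implements the rule that binding-site predictions
overlapping an already accepted, better-ranked prediction by more than 3 bp
are eliminated, keeping the hit with the lowest p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PositionFrequencyMatrix

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SEP = 5
_SEP_PENALTY = -(2 ** 40)  # any window touching a separator goes negative

HIT_COLUMNS = ["peak_id", "pwm_id", "offset", "strand", "width",
               "score", "p_value"]


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def estimate_background(sequences: dict[str, str] | list[str]) -> np.ndarray:
    """Strand-symmetric 0-order base composition of a sequence set.

    A/T and C/G frequencies are averaged so the background is invariant
    under reverse complement; N bases are ignored.
    """
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    counts = np.zeros(4)
    for seq in seqs:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2
    cg = (counts[1] + counts[2]) / 2
    bg = np.array([at, cg, cg, at])
    return bg / bg.sum()


@dataclass
class ScoringMatrix:
    """Grid-snapped log2-odds matrix with its exact null score distribution."""

    pwm_id: str
    log_odds: np.ndarray          # (4, L), snapped to the grid
    background: np.ndarray        # (4,)
    pseudocount: float
    score_range: tuple[float, float]
    step: float
    col_min: np.ndarray           # (L,) per-column score minimum
    index: np.ndarray             # (4, L) integer grid offsets per column
    tail: np.ndarray              # tail[t] = P(total grid index >= t)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_index(self) -> int:
        return len(self.tail) - 1

    def score(self, seq: str) -> float:
        """Score a sequence of exactly the motif length (N scores the
        column minimum)."""
        codes = encode(seq)
        if len(codes) != self.length:
            raise ValueError(
                f"sequence length {len(codes)} != motif length {self.length}")
        lo = np.vstack([self.log_odds, self.col_min])
        return float(lo[codes, np.arange(self.length)].sum())


def pfm_to_scoring_matrix(pfm: PositionFrequencyMatrix,
                          background: np.ndarray | None = None,
                          pseudocount: float = 0.1,
                          n_bins: int = 1000,
                          min_log_odds: float = -30.0) -> ScoringMatrix:
    """Convert counts to a snapped log2-odds matrix with its exact null
    distribution.

    Column probabilities are ``(count + pseudocount * bg) / (total +
    pseudocount)``; zero-probability cells (possible only with
    ``pseudocount=0``) are capped at ``min_log_odds`` instead of minus
    infinity so that N-containing windows score finitely low.
    """
    if background is None:
        background = np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0:
        warnings.warn(f"{pfm.pwm_id}: pseudocount 0 gives capped -inf scores "
                      "for zero-count cells", stacklevel=2)

    counts = pfm.counts
    totals = counts.sum(axis=0, keepdims=True)
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    with np.errstate(divide="ignore"):
        lo = np.log2(probs / bg[:, None])
    lo = np.maximum(lo, min_log_odds)

    col_min = lo.min(axis=0)
    span = float((lo.max(axis=0) - col_min).sum())
    step = span / n_bins if span > 0 else 1.0
    index = np.rint((lo - col_min[None, :]) / step).astype(np.int64)
    lo_q = col_min[None, :] + index * step

    # exact null distribution of the total grid index under the background
    dist = np.array([1.0])
    for j in range(index.shape[1]):
        col_pmf = np.zeros(index[:, j].max() + 1)
        for a in range(4):
            col_pmf[index[a, j]] += bg[a]
        dist = np.convolve(dist, col_pmf)
    tail = np.cumsum(dist[::-1])[::-1]

    smin = float(col_min.sum())
    smax = smin + step * int(index.max(axis=0).sum())
    return ScoringMatrix(pwm_id=pfm.pwm_id, log_odds=lo_q, background=bg,
                         pseudocount=pseudocount, score_range=(smin, smax),
                         step=step, col_min=col_min, index=index, tail=tail)


def score_pvalue(matrix: ScoringMatrix, score: float) -> float:
    """P(background window of the motif length scores >= ``score``).

    Exact for the snapped matrix.  The minimum score returns 1.0; the
    maximum returns the (positive) probability of the top grid cell; scores
    above the achievable maximum are a caller error.
    """
    smin, smax = matrix.score_range
    tol = 1e-6 * max(1.0, abs(smax))
    if score > smax + tol:
        raise ValueError(f"score {score} above achievable maximum {smax}")
    t = math.ceil((score - smin) / matrix.step - 1e-9)
    t = min(max(t, 0), matrix.max_index)
    return float(matrix.tail[t])


def _scan_one_strand(concat: np.ndarray, matrix: ScoringMatrix,
                     reverse: bool) -> tuple[np.ndarray, np.ndarray]:
    """Total grid index for every window start; separator windows < 0."""
    L = matrix.length
    idx = matrix.index
    if reverse:
        idx = idx[::-1, ::-1]  # complement bases, reverse columns
    rows = np.vstack([
        idx,
        np.zeros((1, L), dtype=np.int64),             # N -> column minimum
        np.full((1, L), _SEP_PENALTY, dtype=np.int64),  # separator
    ])
    n_windows = len(concat) - L + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    total = np.zeros(n_windows, dtype=np.int64)
    for j in range(L):
        total += rows[:, j][concat[j:j + n_windows]]
    starts = np.arange(n_windows, dtype=np.int64)
    return starts, total


def scan_peaks(sequences: dict[str, str], matrices: list[ScoringMatrix],
               p_threshold: float = 1e-4) -> pd.DataFrame:
    """Scan every sequence with every matrix on both strands.

    Returns hits with p-value <= ``p_threshold``; reverse-strand hits are
    reported at the forward-strand coordinate of their leftmost base.
    Output order is (peak_id, offset, strand, pwm_id).
    """
    names = list(sequences)
    encoded = [encode(sequences[n]) for n in names]
    sep = np.array([_SEP], dtype=np.int8)
    concat = (np.concatenate([x for e in encoded for x in (e, sep)])
              if encoded else np.empty(0, dtype=np.int8))
    seq_starts = np.zeros(len(names), dtype=np.int64)
    pos = 0
    for i, e in enumerate(encoded):
        seq_starts[i] = pos
        pos += len(e) + 1

    rows = []
    for matrix in matrices:
        smin = matrix.score_range[0]
        for strand, reverse in (("+", False), ("-", True)):
            starts, total = _scan_one_strand(concat, matrix, reverse)
            valid = total >= 0
            if not valid.any():
                continue
            t = total[valid]
            pvals = matrix.tail[np.minimum(t, matrix.max_index)]
            keep = pvals <= p_threshold
            if not keep.any():
                continue
            gpos = starts[valid][keep]
            t = t[keep]
            pvals = pvals[keep]
            which = np.searchsorted(seq_starts, gpos, side="right") - 1
            offsets = gpos - seq_starts[which]
            scores = smin + matrix.step * t
            for w, off, s, p in zip(which, offsets, scores, pvals):
                rows.append((names[w], matrix.pwm_id, int(off), strand,
                             matrix.length, float(s), float(p)))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["peak_id", "offset", "strand", "pwm_id"]
                          ).reset_index(drop=True)


def resolve_overlaps(hits: pd.DataFrame, max_overlap: int = 3) -> pd.DataFrame:
    """Greedy per-peak elimination of hits overlapping a better hit > 3 bp.

    Hits are ranked by ascending p-value (ties: higher score, leftmost
    offset, lexicographic pwm_id, strand); a hit is retained iff it overlaps
    every already retained hit by at most ``max_overlap`` bp, measured on
    forward coordinates regardless of strand.  The result is independent of
    the input row order.
    """
    if hits.empty:
        return hits.copy()
    kept_index = []
    ranked = hits.sort_values(
        ["peak_id", "p_value", "score", "offset", "pwm_id", "strand"],
        ascending=[True, True, False, True, True, True], kind="mergesort")
    for _, grp in ranked.groupby("peak_id", sort=False):
        accepted: list[tuple[int, int]] = []
        for row in grp.itertuples():
            s, e = row.offset, row.offset + row.width
            ok = all(min(e, ae) - max(s, as_) <= max_overlap
                     for as_, ae in accepted)
            if ok:
                accepted.append((s, e))
                kept_index.append(row.Index)
    out = hits.loc[sorted(kept_index)]
    return out.sort_values(["peak_id", "offset", "strand", "pwm_id"]
                           ).reset_index(drop=True)


def motif_enrichment(target_peaks: list | set, background_peaks: list | set,
                     hits: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per PWM.

    For each PWM, a 2x2 table of peaks with >= 1 hit vs without, target set
    vs background set.  The odds ratio uses a Haldane correction of 0.5 per
    cell when any cell is zero.
    """
    target = set(target_peaks)
    background = set(background_peaks)
    if not target or not background:
        raise ValueError("target and background peak sets must be non-empty")
    rows = []
    for pwm_id, grp in hits.groupby("pwm_id", sort=True):
        with_hit = set(grp["peak_id"])
        a = len(target & with_hit)
        b = len(target) - a
        c = len(background & with_hit)
        d = len(background) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            oddsr = (a * d) / (b * c)
        rows.append((pwm_id, a, len(target), c, len(background),
                     float(oddsr), float(p)))
    return pd.DataFrame(rows, columns=[
        "pwm_id", "n_target_hit", "n_target", "n_background_hit",
        "n_background", "odds_ratio", "p_value"])
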