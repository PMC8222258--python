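"""PWM scoring, exact p-values, scanning, overlap resolution, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crenet as cn
from crenet.io import PositionFrequencyMatrix
from crenet.synthetic import reverse_complement
from conftest import random_hits


def pfm(counts, pwm_id="m"):
    return PositionFrequencyMatrix(pwm_id, np.asarray(counts, dtype=float))


AC_DIMER = pfm([[8, 1], [1, 8], [1, 1], [1, 1]], "ac")  # unique max word AC


class TestScoringMatrix:
    def test_uniform_column_uniform_background_scores_zero(self):
        m = cn.pfm_to_scoring_matrix(pfm([[5, 5], [5, 5], [5, 5], [5, 5]]),
                                     pseudocount=0.1)
        np.testing.assert_allclose(m.log_odds, 0.0, atol=1e-12)

    def test_pseudocount_zero_warns_and_caps(self):
        with pytest.warns(UserWarning, match="pseudocount 0"):
            m = cn.pfm_to_scoring_matrix(pfm([[10], [0], [0], [0]]),
                                         pseudocount=0.0)
        assert m.log_odds[0, 0] == pytest.approx(2.0)   # log2(1/0.25)
        assert m.log_odds[1, 0] == pytest.approx(-30.0, abs=0.05)

    @pytest.mark.parametrize("trial", range(6))
    def test_score_range_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        L = int(rng.integers(1, 6))
        m = cn.pfm_to_scoring_matrix(
            pfm(rng.integers(1, 40, size=(4, L))),
            background=rng.dirichlet(np.ones(4) * 8))
        scores = [m.score("".join(w))
                  for w in itertools.product("ACGT", repeat=L)]
        assert m.score_range[0] == pytest.approx(min(scores), abs=1e-9)
        assert m.score_range[1] == pytest.approx(max(scores), abs=1e-9)


class TestScorePvalue:
    def test_unique_max_dimer_p_is_one_sixteenth(self):
        m = cn.pfm_to_scoring_matrix(AC_DIMER)
        assert cn.score_pvalue(m, m.score_range[1]) == pytest.approx(1 / 16)

    def test_min_score_p_is_one(self):
        m = cn.pfm_to_scoring_matrix(AC_DIMER)
        assert cn.score_pvalue(m, m.score_range[0]) == 1.0

    def test_score_above_max_rejected(self):
        m = cn.pfm_to_scoring_matrix(AC_DIMER)
        with pytest.raises(ValueError, match="above achievable"):
            cn.score_pvalue(m, m.score_range[1] + 1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_dp_matches_exhaustive_enumeration(self, trial):
        """DP tail probabilities equal the brute-force word enumeration for
        random 4 x 4 matrices and arbitrary backgrounds, within 1e-9."""
        rng = np.random.default_rng(100 + trial)
        bg = rng.dirichlet(np.ones(4) * 5)
        m = cn.pfm_to_scoring_matrix(pfm(rng.integers(0, 60, (4, 4)) + 1),
                                     background=bg)
        words = ["".join(w) for w in itertools.product("ACGT", repeat=4)]
        scores = np.array([m.score(w) for w in words])
        probs = np.array([np.prod([bg["ACGT".index(c)] for c in w])
                          for w in words])
        for s in np.unique(scores):
            enum = probs[scores >= s - 1e-12].sum()
            assert cn.score_pvalue(m, s) == pytest.approx(enum, abs=1e-9)

    def test_pvalue_monotone_in_score(self):
        rng = np.random.default_rng(7)
        m = cn.pfm_to_scoring_matrix(pfm(rng.integers(1, 50, (4, 8))))
        grid = np.linspace(*m.score_range, 200)
        ps = [cn.score_pvalue(m, s) for s in grid]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)


CONSENSUS = "TTACGTGA"


def consensus_pfm(word, pwm_id="cons", weight=20):
    counts = np.ones((4, len(word)))
    for j, b in enumerate(word):
        counts["ACGT".index(b), j] = weight
    return pfm(counts, pwm_id)


class TestScanPeaks:
    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(0)
        bgseq = "".join(rng.choice(list("ACGT"), 40))
        seq = bgseq[:7] + CONSENSUS + bgseq[7 + len(CONSENSUS):]
        m = cn.pfm_to_scoring_matrix(consensus_pfm(CONSENSUS))
        hits = cn.scan_peaks({"p1": seq}, [m], p_threshold=1e-3)
        fwd = hits[hits["strand"] == "+"]
        assert 7 in set(fwd["offset"])

    def test_reverse_complement_hit_on_minus_strand(self):
        rng = np.random.default_rng(0)
        bgseq = "".join(rng.choice(list("ACGT"), 40))
        seq = bgseq[:7] + CONSENSUS + bgseq[7 + len(CONSENSUS):]
        m = cn.pfm_to_scoring_matrix(consensus_pfm(CONSENSUS))
        rc_hits = cn.scan_peaks({"p1": reverse_complement(seq)}, [m], 1e-3)
        minus = rc_hits[rc_hits["strand"] == "-"]
        expect_offset = len(seq) - 7 - len(CONSENSUS)
        assert expect_offset in set(minus["offset"])

    def test_strand_symmetry_full_mirror(self):
        """Scanning a sequence set and its reverse complement yields mirror
        hit tables with identical scores and p-values."""
        rng = np.random.default_rng(5)
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), 300))
                for i in range(5)}
        rc = {k: reverse_complement(v) for k, v in seqs.items()}
        mats = [cn.pfm_to_scoring_matrix(
            pfm(rng.integers(1, 30, (4, 9)), f"m{i}"),
            background=cn.estimate_background(seqs)) for i in range(2)]
        fwd = cn.scan_peaks(seqs, mats, p_threshold=1e-2)
        rev = cn.scan_peaks(rc, mats, p_threshold=1e-2)
        fwd = fwd.assign(
            mirror=[len(seqs[r.peak_id]) - r.offset - r.width
                    for r in fwd.itertuples()],
            flipped=fwd["strand"].map({"+": "-", "-": "+"}))
        key = ["peak_id", "pwm_id", "offset", "strand"]
        lhs = (fwd[["peak_id", "pwm_id", "mirror", "flipped",
                    "score", "p_value"]]
               .rename(columns={"mirror": "offset", "flipped": "strand"})
               .sort_values(key).reset_index(drop=True))
        rhs = (rev[key + ["score", "p_value"]]
               .sort_values(key).reset_index(drop=True))
        pd.testing.assert_frame_equal(lhs[key + ["score", "p_value"]], rhs)

    def test_threshold_monotonicity(self, small_dataset):
        bg = cn.estimate_background(small_dataset.sequences)
        mats = [cn.pfm_to_scoring_matrix(p, bg)
                for p in small_dataset.pwms[:2]]
        strict = cn.scan_peaks(small_dataset.sequences, mats, 1e-5)
        loose = cn.scan_peaks(small_dataset.sequences, mats, 1e-4)
        key = ["peak_id", "pwm_id", "offset", "strand"]
        sset = set(map(tuple, strict[key].to_numpy()))
        lset = set(map(tuple, loose[key].to_numpy()))
        assert sset <= lset

    def test_sequence_shorter_than_motif_gives_no_hits(self):
        m = cn.pfm_to_scoring_matrix(consensus_pfm(CONSENSUS))
        hits = cn.scan_peaks({"p1": "ACG"}, [m], p_threshold=1.0)
        assert len(hits) == 0

    def test_n_bases_score_column_minimum_not_crash(self):
        m = cn.pfm_to_scoring_matrix(consensus_pfm("ACGT"))
        hits = cn.scan_peaks({"p1": "NNACGTNN"}, [m], p_threshold=1e-2)
        assert (hits["offset"] == 2).all()

    def test_planted_instances_recovered(self):
        """Sequences planted at marginal 1.0 are recovered at p <= 1e-3 for
        at least 99% of instances."""
        cfg = cn.SyntheticConfig(seed=30, n_peaks=300, n_genes=40,
                                 motif_marginals={"M01": 1.0})
        ds = cn.generate_dataset(cfg)
        bg = cn.estimate_background(ds.sequences)
        mats = [cn.pfm_to_scoring_matrix(p, bg) for p in ds.pwms]
        hits = cn.scan_peaks(ds.sequences, mats, p_threshold=1e-3)
        key = ["peak_id", "pwm_id", "offset", "strand"]
        found = ds.truth.motifs.merge(hits, on=key)
        assert len(found) / len(ds.truth.motifs) >= 0.99


class TestResolveOverlaps:
    @staticmethod
    def hit(pid, pwm, off, width, p, score=10.0, strand="+"):
        return {"peak_id": pid, "pwm_id": pwm, "offset": off, "width": width,
                "strand": strand, "score": score, "p_value": p}

    def test_five_bp_overlap_keeps_best_only(self):
        hits = pd.DataFrame([self.hit("p1", "A", 10, 10, 1e-6),
                             self.hit("p1", "B", 15, 10, 1e-5)])
        kept = cn.resolve_overlaps(hits)
        assert list(kept["pwm_id"]) == ["A"]

    def test_three_bp_overlap_keeps_both(self):
        hits = pd.DataFrame([self.hit("p1", "A", 10, 10, 1e-6),
                             self.hit("p1", "B", 17, 10, 1e-5)])
        assert len(cn.resolve_overlaps(hits)) == 2

    def test_empty_table_passthrough(self):
        hits = pd.DataFrame(columns=["peak_id", "pwm_id", "offset", "width",
                                     "strand", "score", "p_value"])
        assert len(cn.resolve_overlaps(hits)) == 0

    @pytest.mark.parametrize("trial", range(25))
    def test_random_sets_satisfy_posthoc_conditions(self, trial):
        """On random hit sets: (a) no retained pair overlaps > 3 bp,
        (b) every removed hit overlaps a retained better-ranked hit, and
        (c) the output is invariant to input row order."""
        rng = np.random.default_rng(trial)
        hits = random_hits(rng, int(rng.integers(5, 40)))
        kept = cn.resolve_overlaps(hits)
        spans = list(zip(kept["offset"], kept["offset"] + kept["width"],
                         kept["p_value"]))
        for i, (s1, e1, _) in enumerate(spans):
            for s2, e2, _ in spans[i + 1:]:
                assert min(e1, e2) - max(s1, s2) <= 3
        kept_keys = set(map(tuple, kept[["pwm_id", "offset", "strand",
                                         "p_value"]].to_numpy()))
        for row in hits.itertuples():
            if (row.pwm_id, row.offset, row.strand, row.p_value) in kept_keys:
                continue
            s, e = row.offset, row.offset + row.width
            assert any(min(e, e2) - max(s, s2) > 3 and p2 <= row.p_value
                       for s2, e2, p2 in spans)
        shuffled = hits.sample(frac=1, random_state=1).reset_index(drop=True)
        kept2 = cn.resolve_overlaps(shuffled)
        pd.testing.assert_frame_equal(
            kept.reset_index(drop=True), kept2.reset_index(drop=True))


class TestMotifEnrichment:
    def test_hand_computed_odds_ratio(self):
        hits = pd.DataFrame({
            "peak_id": [f"t{i}" for i in range(8)]
                       + [f"b{i}" for i in range(10)],
            "pwm_id": "M"})
        res = cn.motif_enrichment([f"t{i}" for i in range(10)],
                                  [f"b{i}" for i in range(100)], hits)
        assert res.loc[0, "odds_ratio"] == pytest.approx(36.0)

    def test_identical_rates_null(self):
        hits = pd.DataFrame({"peak_id": ["t0", "b0"], "pwm_id": "M"})
        res = cn.motif_enrichment(["t0", "t1"], ["b0", "b1"], hits)
        assert res.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] >= 0.5

    @pytest.mark.parametrize("trial", range(10))
    def test_fisher_matches_hypergeometric_tail_sum(self, trial):
        """scipy's one-sided Fisher p equals the direct hypergeometric tail
        summation on small tables."""
        rng = np.random.default_rng(trial)
        a, b, c, d = rng.integers(0, 13, 4)
        n_t, n_b = a + b, c + d
        if n_t == 0 or n_b == 0:
            pytest.skip("degenerate table")
        hits = pd.DataFrame({
            "peak_id": [f"t{i}" for i in range(a)]
                       + [f"b{i}" for i in range(c)], "pwm_id": "M"})
        res = cn.motif_enrichment([f"t{i}" for i in range(n_t)],
                                  [f"b{i}" for i in range(n_b)], hits)
        K, N = a + c, n_t + n_b
        tail = sum(stats.hypergeom.pmf(x, N, K, n_t)
                   for x in range(a, min(K, n_t) + 1))
        assert res.loc[0, "p_value"] == pytest.approx(tail, abs=1e-9)
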