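"""CRE classification, DEG/DOCR selection, and the randomized-DEG null."""

import numpy as np
import pandas as pd
import pytest

import crenet as cn
from crenet.classify import HISTOGRAM_BINS, pearson_chi_square


def expr_table(rows):
    """rows: (gene_id, lfc, q)."""
    df = pd.DataFrame(rows, columns=["gene_id", "lfc_c", "q_c"])
    for cond in ("PG16", "NR18", "RPE18", "NR23", "RPE23"):
        df[cond] = 1.0
    df["is_tf"] = False
    df["is_cytoskeletal"] = False
    return df


class TestSelection:
    def test_all_p_one_gives_empty_deg_set(self):
        expr = expr_table([("g1", 2.0, 1.0), ("g2", -1.0, 1.0)])
        assert len(cn.select_degs(expr, "c")) == 0

    def test_single_significant_gene(self):
        expr = expr_table([("g1", 2.0, 0.01), ("g2", 1.0, 0.5)])
        degs = cn.select_degs(expr, "c")
        assert list(degs["gene_id"]) == ["g1"]
        assert degs.loc[0, "gene_log2fc"] == 2.0

    def test_zero_lfc_excluded_even_if_significant(self):
        expr = expr_table([("g1", 0.0, 0.001)])
        assert len(cn.select_degs(expr, "c")) == 0

    def test_deg_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        expr = expr_table([(f"g{i}", rng.normal(), rng.random())
                           for i in range(200)])
        strict = set(cn.select_degs(expr, "c", alpha=0.01)["gene_id"])
        loose = set(cn.select_degs(expr, "c", alpha=0.05)["gene_id"])
        assert strict <= loose

    def test_docr_threshold_monotonicity(self, small_dataset):
        peaks = small_dataset.peaks
        strict = set(cn.select_docrs(peaks, 0.01)["peak_id"])
        loose = set(cn.select_docrs(peaks, 0.05)["peak_id"])
        assert strict <= loose
        counts = cn.select_docrs(peaks, 0.05)
        assert counts.attrs["n_nr"] + counts.attrs["n_rpe"] == len(counts)


def make_cre_inputs(pairs):
    """pairs: (peak_id, peak_lfc, gene_id, gene_lfc); everything significant."""
    docrs = pd.DataFrame(
        {"peak_id": [p[0] for p in pairs], "log2fc": [p[1] for p in pairs],
         "adjusted_p": 0.01}).drop_duplicates("peak_id")
    degs = pd.DataFrame(
        {"gene_id": [p[2] for p in pairs],
         "gene_log2fc": [p[3] for p in pairs]}).drop_duplicates("gene_id")
    assoc = pd.DataFrame({"peak_id": [p[0] for p in pairs],
                          "gene_id": [p[2] for p in pairs]})
    return docrs, degs, assoc


class TestClassifyCres:
    @pytest.mark.parametrize("peak_lfc,gene_lfc,domain,mode", [
        (2.0, 1.5, "NR", "activating"),
        (2.0, -1.5, "NR", "repressing"),
        (-2.0, -1.5, "RPE", "activating"),
        (-2.0, 1.5, "RPE", "repressing"),
    ])
    def test_quadrant_rule(self, peak_lfc, gene_lfc, domain, mode):
        docrs, degs, assoc = make_cre_inputs([("p1", peak_lfc, "g1", gene_lfc)])
        cres = cn.classify_cres(docrs, degs, assoc)
        assert len(cres) == 1
        assert cres.loc[0, "domain"] == domain
        assert cres.loc[0, "mode"] == mode

    def test_non_deg_gene_yields_no_row(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 2.0, "g1", 1.0)])
        degs = degs[degs["gene_id"] != "g1"]
        assert len(cn.classify_cres(docrs, degs, assoc)) == 0

    def test_zero_lfc_excluded_not_tiebroken(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 0.0, "g1", 1.0),
                                              ("p2", 1.0, "g2", 0.0)])
        assert len(cn.classify_cres(docrs, degs, assoc)) == 0

    def test_multi_gene_peak_yields_multiple_rows(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 2.0, "g1", 1.0),
                                              ("p1", 2.0, "g2", -1.0)])
        cres = cn.classify_cres(docrs, degs, assoc)
        assert len(cres) == 2
        assert set(cres["mode"]) == {"activating", "repressing"}

    def test_sign_flip_with_domain_relabel_is_invariant(self):
        """Flipping both log2FC columns while swapping the NR/RPE labels
        leaves every (domain, mode) label unchanged."""
        rng = np.random.default_rng(1)
        pairs = [(f"p{i}", float(rng.choice([-1, 1]) * rng.uniform(0.5, 3)),
                  f"g{i}", float(rng.choice([-1, 1]) * rng.uniform(0.5, 3)))
                 for i in range(50)]
        docrs, degs, assoc = make_cre_inputs(pairs)
        base = cn.classify_cres(docrs, degs, assoc)
        docrs2 = docrs.assign(log2fc=-docrs["log2fc"])
        degs2 = degs.assign(gene_log2fc=-degs["gene_log2fc"])
        flipped = cn.classify_cres(docrs2, degs2, assoc)
        relabel = flipped["domain"].map({"NR": "RPE", "RPE": "NR"})
        assert (relabel.to_numpy() == base["domain"].to_numpy()).all()
        assert (flipped["mode"].to_numpy() == base["mode"].to_numpy()).all()

    def test_noise_free_synthetic_labels_recover_truth(self):
        """With noise_sd = 0 every CRE whose recovered gene is the planted
        intended gene carries exactly the planted quadrant label."""
        cfg = cn.SyntheticConfig(seed=21, noise_sd=0.0, n_peaks=300,
                                 n_genes=60)
        ds = cn.generate_dataset(cfg)
        lengths = dict(zip(ds.chromosomes["chrom"], ds.chromosomes["length"]))
        ann = cn.distance_and_location(
            cn.associate_peaks(ds.peaks, cn.build_domains(ds.genes, lengths)),
            ds.genes)
        cres = cn.classify_cres(cn.select_docrs(ds.peaks),
                                cn.select_degs(ds.expression, cfg.contrast),
                                ann)
        m = cres.merge(ds.truth.peaks, left_on="peak_id", right_index=True,
                       suffixes=("", "_truth"))
        m = m[m["gene_id"] == m["intended_gene"]]
        assert len(m) > 100
        assert (m["domain"] == m["domain_truth"]).all()
        assert (m["mode"] == m["mode_truth"]).all()


class TestOverlapFraction:
    def test_full_and_zero_overlap(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 1.0, "g1", 1.0)])
        assert cn.deg_docr_overlap_fraction(degs, assoc, docrs) == 1.0
        empty_assoc = assoc.iloc[0:0]
        assert cn.deg_docr_overlap_fraction(degs, empty_assoc, docrs) == 0.0

    def test_three_of_eight(self):
        degs = pd.DataFrame({"gene_id": [f"g{i}" for i in range(8)],
                             "gene_log2fc": 1.0})
        docrs = pd.DataFrame({"peak_id": ["p1", "p2"], "log2fc": 1.0,
                              "adjusted_p": 0.01})
        assoc = pd.DataFrame({"peak_id": ["p1", "p1", "p2", "p2"],
                              "gene_id": ["g0", "g1", "g2", "g9"]})
        assert cn.deg_docr_overlap_fraction(degs, assoc, docrs) == 0.375

    def test_empty_deg_set_is_an_error(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 1.0, "g1", 1.0)])
        with pytest.raises(ValueError, match="empty DEG set"):
            cn.deg_docr_overlap_fraction(degs.iloc[0:0], assoc, docrs)


class TestCreCounts:
    def test_two_activating_nr_cres_land_in_bin_two(self):
        docrs, degs, assoc = make_cre_inputs([("p1", 2.0, "g1", 1.0),
                                              ("p2", 1.0, "g1", 1.0)])
        cres = cn.classify_cres(docrs, degs, assoc)
        summary = cn.cre_counts_per_gene(cres, ["g1"])
        assert summary.per_gene.loc["g1", ("NR", "activating")] == 2
        assert summary.histograms.loc["2", ("NR", "activating")] == 1

    def test_empty_gene_set(self):
        cres = pd.DataFrame(columns=["peak_id", "gene_id", "domain", "mode"])
        summary = cn.cre_counts_per_gene(cres, [])
        assert summary.per_gene.empty
        assert (summary.histograms.sum() == 0).all()

    def test_histogram_totals_match_brute_force(self, small_pipeline,
                                                small_dataset):
        cres = small_pipeline["cres"]
        genes = list(small_dataset.genes["gene_id"])
        summary = cn.cre_counts_per_gene(cres, genes)
        assert (summary.histograms.sum() == len(genes)).all()
        for (dom, mode) in summary.per_gene.columns:
            sub = cres[(cres["domain"] == dom) & (cres["mode"] == mode)]
            for g in genes:
                assert summary.per_gene.loc[g, (dom, mode)] == \
                    (sub["gene_id"] == g).sum()


class TestNullComparison:
    def test_chi_square_kernel_hand_computed(self):
        stat, p, dof = pearson_chi_square(np.array([[10, 20], [20, 10]]))
        assert stat == pytest.approx(20 / 3, abs=1e-9)
        assert dof == 1

    def test_zero_resamples_rejected(self, small_pipeline):
        with pytest.raises(ValueError, match="n_resamples"):
            cn.randomized_null_comparison(small_pipeline["cres"], ["g1"],
                                          ["g1", "g2"], n_resamples=0)

    def test_tf_set_larger_than_pool_rejected(self, small_pipeline):
        with pytest.raises(ValueError, match="pool"):
            cn.randomized_null_comparison(
                small_pipeline["cres"], ["g1", "g2", "g3"], ["g4"],
                n_resamples=10)

    @pytest.mark.filterwarnings("ignore:chi-square bins merged")
    def test_null_matched_tf_set_gives_large_p(self):
        """A TF set with exactly the pool's CRE-count composition produces
        a near-zero statistic and p > 0.5 on 20 seeded replicates."""
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.2, size=600)
        genes = [f"g{i}" for i in range(600)]
        cres = pd.DataFrame({
            "gene_id": np.repeat(genes, counts),
            "peak_id": [f"p{i}" for i in range(counts.sum())],
            "domain": "NR", "mode": "activating"})
        # TF set: every third gene after sorting by count -> same composition
        order = np.argsort(counts, kind="stable")
        tf = [genes[i] for i in order[::3]]
        for seed in range(20):
            res = cn.randomized_null_comparison(
                cres, tf, genes, n_resamples=400, seed=seed,
                exclude_tfs=False)
            assert res.p_value > 0.5, seed
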