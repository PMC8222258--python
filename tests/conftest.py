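import numpy as np
import pandas as pd
import pytest

import crenet as cn


@pytest.fixture(scope="session")
def small_config():
    return cn.SyntheticConfig(
        seed=11, n_peaks=200, n_genes=40,
        motif_marginals={"M01": 0.3, "M02": 0.3},
        pair_coupling={("M01", "M02"): 0.2})


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return cn.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Associations, DEGs, DOCRs and CREs for the small dataset."""
    ds = small_dataset
    lengths = dict(zip(ds.chromosomes["chrom"], ds.chromosomes["length"]))
    dom = cn.build_domains(ds.genes, lengths)
    assoc = cn.associate_peaks(ds.peaks, dom)
    ann = cn.distance_and_location(assoc, ds.genes)
    degs = cn.select_degs(ds.expression, ds.config.contrast)
    docrs = cn.select_docrs(ds.peaks)
    cres = cn.classify_cres(docrs, degs, ann)
    return {"domains": dom, "associations": ann, "degs": degs,
            "docrs": docrs, "cres": cres}


def naive_associate(peaks: pd.DataFrame, domains: pd.DataFrame
                    ) -> pd.DataFrame:
    """O(P x G) midpoint-containment scan, the association oracle."""
    rows = []
    for p in peaks.itertuples():
        mid = (p.start + p.end) // 2
        for g in domains.itertuples():
            if g.chrom == p.chrom and g.ext_start <= mid < g.ext_end:
                rows.append((p.peak_id, g.gene_id, mid))
    return (pd.DataFrame(rows, columns=["peak_id", "gene_id", "midpoint"])
            .sort_values(["peak_id", "gene_id"]).reset_index(drop=True))


def random_hits(rng: np.random.Generator, n: int, peak: str = "p1",
                seq_len: int = 200) -> pd.DataFrame:
    """Random motif-hit table for overlap-resolution stress tests."""
    width = rng.integers(6, 15, size=n)
    offset = np.array([rng.integers(0, seq_len - w + 1) for w in width])
    return pd.DataFrame({
        "peak_id": peak,
        "pwm_id": [f"M{int(i):02d}" for i in rng.integers(1, 6, size=n)],
        "offset": offset,
        "strand": rng.choice(["+", "-"], size=n),
        "width": width,
        "score": rng.normal(10, 3, size=n).round(4),
        "p_value": 10.0 ** rng.uniform(-8, -2, size=n),
    })
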