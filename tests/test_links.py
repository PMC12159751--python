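from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from regdyn.io import MotifSet
from regdyn.links import (candidate_pairs, cluster_links,
                          cluster_motif_enrichment, is_high_confidence,
                          link_peaks_to_genes, pearson_with_p)
from regdyn.pseudobulk import make_pseudobulks

from conftest import make_dataset


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand",
                                     "biotype"])
    df["is_mito"] = False
    return df.set_index("gene_id", drop=False)


def _peaks(rows):
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    df["gc"] = 0.5
    return df.set_index("peak_id", drop=False)


def test_candidate_window_inclusive_bounds():
    """Peaks at 1 kb and 250 kb are candidates; 500 bp and 300 kb are not."""
    genes = _genes([("gA", "chr1", 1_000_000, "+", "protein_coding"),
                    ("gB", "chr1", 1_000_000, "-", "other")])
    peaks = _peaks([
        ("p_50k", "chr1", 1_049_750, 1_050_250),    # mid 1,050,000: +50 kb
        ("p_500", "chr1", 1_000_250, 1_000_750),    # mid 500 bp: too close
        ("p_1k", "chr1", 1_000_750, 1_001_250),     # mid exactly +1 kb
        ("p_250k", "chr1", 1_249_750, 1_250_250),   # mid exactly +250 kb
        ("p_300k", "chr1", 1_299_750, 1_300_250),   # beyond window
        ("p_chr2", "chr2", 1_049_750, 1_050_250),   # wrong chromosome
    ])
    out = candidate_pairs(genes, peaks, marker_genes={"gA", "gB"})
    got = set(zip(out["peak_id"], out["gene_id"]))
    assert got == {("p_50k", "gA"), ("p_1k", "gA"), ("p_250k", "gA")}
    # gB excluded by biotype even though coordinates match


def test_candidate_distance_sign_is_strand_aware():
    genes = _genes([("gP", "chr1", 1_000_000, "+", "protein_coding"),
                    ("gM", "chr1", 1_000_000, "-", "lincRNA")])
    peaks = _peaks([("pk", "chr1", 1_049_750, 1_050_250)])
    out = candidate_pairs(genes, peaks, marker_genes={"gP", "gM"})
    d = out.set_index("gene_id")["distance_bp"]
    assert d["gP"] == 50_000      # downstream of + gene
    assert d["gM"] == -50_000     # upstream of - gene


def test_pearson_affine_and_oracle():
    x = np.arange(5, dtype=float)
    assert pearson_with_p(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def oracle(x, y):
        n = len(x)
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        df = n - 2
        # two-sided p via the regularized incomplete beta
        p = betainc(df / 2.0, 0.5, df / (df + df * r * r / (1 - r * r)))
        return r, p

    x = np.array([1, 2, 3, 4, 5.0])
    y = np.array([2, 1, 4, 3, 6.0])
    r, p = pearson_with_p(x, y)
    ro, po = oracle(x, y)
    assert r == pytest.approx(ro, abs=1e-12)
    assert p == pytest.approx(po, abs=1e-12)

    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.normal(size=rng.integers(5, 30))
        y = rng.normal(size=x.size)
        r, p = pearson_with_p(x, y)
        ro, po = oracle(x, y)
        assert abs(r - ro) < 1e-12 and abs(p - po) < 1e-12

    with pytest.raises(ValueError, match="constant"):
        pearson_with_p(np.ones(5), np.arange(5.0))


def _series_for(profiles_atac, profiles_rna):
    """Pseudobulk series built from per-sample feature profiles."""
    n_s = profiles_atac.shape[0]
    rna = np.repeat(profiles_rna, 50, axis=0)
    atac = np.repeat(profiles_atac, 50, axis=0)
    ds = make_dataset(rna, atac, pseudotime=np.linspace(0, 1, n_s * 50))
    return make_pseudobulks(ds, group_size=50)


def test_link_threshold_boundaries():
    """|PCC| >= 0.3 is inclusive and p < 0.05 strict; both required."""
    assert bool(is_high_confidence(0.30, 0.049))
    assert bool(is_high_confidence(-0.30, 0.049))    # sign-symmetric
    assert not is_high_confidence(0.29, 0.01)
    assert not is_high_confidence(0.60, 0.20)
    assert not is_high_confidence(0.0, 0.9)
    assert not is_high_confidence(0.30, 0.05)        # p bound is strict


def test_link_flags_on_constructed_series():
    """A pair engineered to r ~= 1 is flagged; an uncorrelated one is not."""
    n_s = 6
    tshape = np.linspace(1, 2, n_s)[:, None]
    atac = np.round(200 * np.hstack([tshape, np.ones((n_s, 1))])).astype(int)
    rna = np.round(200 * np.hstack([tshape, 1 + 0.5 * np.random.default_rng(0)
                                    .uniform(size=(n_s, 1))])).astype(int)
    series = _series_for(atac, rna)
    pairs = pd.DataFrame({"peak_id": ["p000", "p001"],
                          "gene_id": ["g000", "g000"],
                          "distance_bp": [0, 0]})
    out = link_peaks_to_genes(series, pairs)
    assert bool(out.loc[0, "high_confidence"])
    assert out.loc[1, "pcc"] == pytest.approx(
        np.corrcoef(series.atac_cpm[:, 1], series.rna_cpm[:, 0])[0, 1],
        abs=1e-12)
    with pytest.raises(ValueError, match="absent"):
        link_peaks_to_genes(series, pd.DataFrame(
            {"peak_id": ["nope"], "gene_id": ["g000"], "distance_bp": [0]}))


def test_cluster_links_recovers_separated_shapes_and_is_deterministic():
    """Two well-separated profile shapes with k=2 are exactly recovered;
    fixed seed gives identical assignments across runs."""
    n_s, n_genes = 10, 12
    t = np.linspace(0, 1, n_s)
    rising = np.outer(t, np.ones(n_genes // 2)) * 400 + 50
    falling = np.outer(1 - t, np.ones(n_genes // 2)) * 400 + 50
    rna = np.round(np.hstack([rising, falling])).astype(int)
    atac = np.tile(np.round(rising).astype(int), (1, 2))
    series = _series_for(atac, rna)
    links = pd.DataFrame({
        "peak_id": [f"p{i:03d}" for i in range(n_genes)],
        "gene_id": [f"g{i:03d}" for i in range(n_genes)],
        "distance_bp": 0, "pcc": 0.9, "p_value": 1e-4,
        "high_confidence": True})
    res1 = cluster_links(links, series, k=2, seed=9)
    res2 = cluster_links(links, series, k=2, seed=9)
    lab = res1.links["kmeans_cluster"].to_numpy()
    assert (lab == lab[0]).sum() == 6 and len(set(lab)) == 2
    assert set(lab[:6]) != set(lab[6:]) or (lab[:6] == lab[0]).all()
    assert (lab[:6] == lab[0]).all() and (lab[6:] == lab[6]).all()
    assert (res2.links["kmeans_cluster"].to_numpy() == lab).all()
    # clusters are numbered by ascending profile-peak position:
    # rising profiles peak last -> cluster 2, falling peak first -> cluster 1
    assert lab[0] == 2 and lab[6] == 1
    # z-profiles have per-link mean ~0 and sd ~1
    assert np.allclose(res1.profiles.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(res1.profiles.std(axis=1), 1, atol=1e-9)
    with pytest.raises(ValueError, match="smaller k"):
        cluster_links(links.head(3), series, k=6, seed=0)


def test_regulator_motifs_enriched_in_link_clusters(default_run):
    """Regulator motifs sit in enhancers of co-regulated genes, so at least
    one (cluster, planted motif) pair is BH-significantly enriched."""
    res, truth = default_run
    enr = res.enrichment
    planted = enr[enr["motif_id"].isin(truth.planted_regulators)]
    assert (planted["p_adjusted"] < 0.05).any()
    sig = planted[planted["p_adjusted"] < 0.05]
    assert (sig["fold_enrichment"] > 1).all()


def _hypergeom_tail_oracle(N, K, n, x):
    """P(X >= x) by exhaustive enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(x, min(K, n) + 1)) / total


def test_cluster_motif_enrichment_against_enumeration():
    """Motif exclusive to one cluster: p equals the enumerated tail on a
    20-peak toy; a ubiquitous motif has fold 1 and p = 1."""
    n_links = 20
    peak_ids = [f"p{i:03d}" for i in range(n_links)]
    links = pd.DataFrame({
        "peak_id": peak_ids, "gene_id": [f"g{i:03d}" for i in range(n_links)],
        "distance_bp": 0, "pcc": 0.9, "p_value": 1e-4,
        "high_confidence": True,
        "kmeans_cluster": [1] * 8 + [2] * 12})
    match = np.zeros((n_links, 2), dtype=bool)
    match[:8, 0] = True          # motif exclusive to cluster 1 peaks
    match[:, 1] = True           # ubiquitous motif
    motifs = MotifSet(["M1", "M2"], ["tf1", "tf2"],
                      [np.ones((4, 4))] * 2, peak_match=match)

    class Res:  # minimal LinkClusterResult stand-in
        k = 2
    res = Res()
    res.links = links
    out = cluster_motif_enrichment(res, motifs, peak_ids)
    m1c1 = out[(out["cluster"] == 1) & (out["motif_id"] == "M1")].iloc[0]
    assert m1c1["p_value"] == pytest.approx(
        _hypergeom_tail_oracle(20, 8, 8, 8), rel=1e-9)
    m2 = out[out["motif_id"] == "M2"]
    assert np.allclose(m2["fold_enrichment"], 1.0)
    assert np.allclose(m2["p_value"], 1.0)
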