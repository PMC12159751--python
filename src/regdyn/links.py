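"""Peak-to-gene linking along pseudotime and dynamic-element clustering.

Candidate pairs are peaks whose midpoint lies 1-250 kb (inclusive) from the
TSS of a protein-coding or lincRNA marker gene on the same chromosome. Each
pair is scored by the Pearson correlation between the peak's CPM
accessibility and the gene's CPM expression across the pseudobulk series;
pairs with |PCC| >= 0.3 and P < 0.05 are high-confidence links. Links are
clustered with k-means (k = 6) on the z-scored expression profiles of their
genes, and each cluster's peaks are tested for motif enrichment against all
linked peaks with a one-sided hypergeometric test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import MotifSet
from .pseudobulk import PseudobulkSeries

LINK_BIOTYPES = ("protein_coding", "lincRNA")


def candidate_pairs(genes: pd.DataFrame, peaks: pd.DataFrame, marker_genes,
                    min_dist: int = 1_000, max_dist: int = 250_000
                    ) -> pd.DataFrame:
    """Enumerate (peak, gene, signed distance) candidates within the window.

    Distance is TSS to peak midpoint, strand-aware: positive means the peak
    lies downstream of the gene. Both window bounds are inclusive.
    """
    marker_genes = set(marker_genes)
    g = genes[genes["biotype"].isin(LINK_BIOTYPES)
              & genes["gene_id"].isin(marker_genes)]
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    rows = []
    for chrom, gsub in g.groupby("chrom", sort=False):
        pmask = (peaks["chrom"] == chrom).to_numpy()
        pmid = mid[pmask]
        pids = peaks["peak_id"].to_numpy()[pmask]
        order = np.argsort(pmid)
        pmid, pids = pmid[order], pids[order]
        for gene_id, tss, strand in zip(gsub["gene_id"], gsub["tss"],
                                        gsub["strand"]):
            for lo, hi in ((tss - max_dist, tss - min_dist),
                           (tss + min_dist, tss + max_dist)):
                i0 = np.searchsorted(pmid, lo, side="left")
                i1 = np.searchsorted(pmid, hi, side="right")
                for j in range(i0, i1):
                    d = int(pmid[j] - tss)
                    if strand == "-":
                        d = -d
                    rows.append((pids[j], gene_id, d))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance_bp"])


def pearson_with_p(x, y):
    """Pearson r with the two-sided p-value from the t(n-2) reference.

    Raises for constant input; callers drop such pairs with a reason code.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return r, float(p)


def link_peaks_to_genes(series: PseudobulkSeries, pairs: pd.DataFrame,
                        pcc_min: float = 0.3, p_max: float = 0.05
                        ) -> pd.DataFrame:
    """Correlate each candidate pair across pseudobulks and flag links."""
    if series.n_samples < 3:
        raise ValueError("need >= 3 pseudobulk samples")
    gene_pos = {g: i for i, g in enumerate(series.gene_ids)}
    peak_pos = {p: i for i, p in enumerate(series.peak_ids)}
    missing = [p for p in pairs["peak_id"].unique() if p not in peak_pos]
    missing += [g for g in pairs["gene_id"].unique() if g not in gene_pos]
    if missing:
        raise ValueError(f"pair references absent features: {missing[:5]}")

    n = series.n_samples
    pk = pairs["peak_id"].map(peak_pos).to_numpy()
    gn = pairs["gene_id"].map(gene_pos).to_numpy()
    X = series.atac_cpm[:, pk]
    Y = series.rna_cpm[:, gn]
    xs = X - X.mean(axis=0)
    ys = Y - Y.mean(axis=0)
    sx = np.sqrt((xs * xs).sum(axis=0))
    sy = np.sqrt((ys * ys).sum(axis=0))
    ok = (sx > 0) & (sy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs * ys).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    out = pairs.copy()
    out["pcc"] = np.where(ok, r, np.nan)
    out["p_value"] = np.where(ok, p, np.nan)
    out["dropped_constant"] = ~ok
    out["high_confidence"] = ok & is_high_confidence(
        out["pcc"].fillna(0.0), out["p_value"].fillna(1.0), pcc_min, p_max)
    return out


def is_high_confidence(pcc, p_value, pcc_min: float = 0.3,
                       p_max: float = 0.05):
    """The published link rule: |PCC| >= pcc_min (inclusive) AND p < p_max."""
    return (np.abs(pcc) >= pcc_min) & (np.asarray(p_value) < p_max)


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (mat - mu) / sd


@dataclasses.dataclass
class LinkClusterResult:
    links: pd.DataFrame            # high-confidence links + kmeans_cluster
    profiles: np.ndarray           # links x samples, z-scored gene expression
    cluster_means: np.ndarray      # k x samples mean z-profiles
    k: int


def cluster_links(links: pd.DataFrame, series: PseudobulkSeries, k: int = 6,
                  seed: int = 0) -> LinkClusterResult:
    """k-means on z-scored gene expression profiles of high-confidence links.

    Clusters are renumbered 1..k by ascending position of their mean
    profile's maximum along the pseudobulk series.
    """
    hc = links[links["high_confidence"]].reset_index(drop=True)
    if len(hc) < k:
        raise ValueError(f"{len(hc)} high-confidence links < k={k}; use a "
                         "smaller k")
    gene_pos = {g: i for i, g in enumerate(series.gene_ids)}
    prof = series.rna_cpm[:, hc["gene_id"].map(gene_pos).to_numpy()].T
    prof = _zscore_rows(prof)
    km = KMeans(n_clusters=k, n_init=10, init="k-means++",
                random_state=seed).fit(prof)
    raw = km.labels_
    centers = np.stack([prof[raw == c].mean(axis=0) for c in range(k)])
    order = np.argsort(np.argmax(centers, axis=1), kind="stable")
    renum = np.empty(k, dtype=int)
    renum[order] = np.arange(1, k + 1)
    hc = hc.copy()
    hc["kmeans_cluster"] = renum[raw]
    return LinkClusterResult(links=hc, profiles=prof,
                             cluster_means=centers[order], k=k)


def cluster_motif_enrichment(result: LinkClusterResult, motifs: MotifSet,
                             peak_ids) -> pd.DataFrame:
    """Hypergeometric motif enrichment of each cluster's peaks vs all linked
    peaks (one-sided, BH across motifs within each cluster)."""
    if motifs.peak_match is None:
        raise ValueError("MotifSet.peak_match required for enrichment")
    match = np.asarray(motifs.peak_match)
    pos = {p: i for i, p in enumerate(peak_ids)}
    linked = result.links.drop_duplicates("peak_id")
    bg_idx = linked["peak_id"].map(pos).to_numpy()
    N = len(bg_idx)
    rows = []
    for c in range(1, result.k + 1):
        cl = linked[linked["kmeans_cluster"] == c]
        idx = cl["peak_id"].map(pos).to_numpy()
        n = len(idx)
        if n == 0:
            continue
        recs = []
        for m, mid in enumerate(motifs.motif_ids):
            K = int(match[bg_idx, m].sum())
            if K == 0:
                continue
            x = int(match[idx, m].sum())
            # P(X >= x) under hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(x - 1, N, K, n))
            fold = (x / n) / (K / N)
            recs.append({"cluster": c, "motif_id": mid,
                         "tf_name": motifs.tf_names[m], "n_cluster_peaks": n,
                         "n_with_motif": x, "fold_enrichment": fold,
                         "p_value": p})
        if recs:
            padj = multipletests([r["p_value"] for r in recs],
                                 method="fdr_bh")[1]
            for r_, a in zip(recs, padj):
                r_["p_adjusted"] = a
            rows.extend(recs)
    return pd.DataFrame(rows, columns=["cluster", "motif_id", "tf_name",
                                       "n_cluster_peaks", "n_with_motif",
                                       "fold_enrichment", "p_value",
                                       "p_adjusted"])
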