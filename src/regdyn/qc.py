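"""Joint QC filtering, CPM normalization, and cluster marker genes.

QC keeps cells passing the RNA rules (detected genes >= 200, mitochondrial
fraction <= 25%) and the ATAC rule (total counts within [1 000, 50 000]);
the strict inequalities match the published thresholds exactly, so a cell
sitting on a boundary is retained. Markers are called one-vs-rest with a
two-sided Wilcoxon rank-sum on log1p(CPM/100) expression, filtered on
natural-log fold change and expressing fraction, BH-adjusted per cluster.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import MultiomeDataset


@dataclasses.dataclass
class QCReport:
    n_input_cells: int
    n_pass_rna: int
    n_pass_atac: int
    n_pass_joint: int
    flags: pd.DataFrame  # per-cell pass booleans and reason codes

    def __post_init__(self):
        assert self.n_pass_joint <= min(self.n_pass_rna, self.n_pass_atac) \
            <= self.n_input_cells


def qc_filter(ds: MultiomeDataset, min_features: int = 200,
              max_mito_frac: float = 0.25, min_fragments: int = 1_000,
              max_fragments: int = 50_000):
    """Filter cells jointly on RNA and ATAC quality.

    Returns (filtered dataset, QCReport). Raises if no cell survives.
    """
    rna, atac = ds.rna_counts, ds.atac_counts
    detected = np.asarray((rna > 0).sum(axis=1)).ravel()
    rna_total = np.asarray(rna.sum(axis=1)).ravel()
    mito_mask = ds.genes["is_mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(rna[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(rna_total > 0, mito_counts / rna_total, 1.0)
    frags = np.asarray(atac.sum(axis=1)).ravel()

    low_feat = detected < min_features
    high_mito = mito_frac > max_mito_frac
    low_frag = frags < min_fragments
    high_frag = frags > max_fragments

    pass_rna = ~(low_feat | high_mito)
    pass_atac = ~(low_frag | high_frag)
    keep = pass_rna & pass_atac

    reasons = []
    for i in range(ds.n_cells):
        r = [name for name, bad in (
            ("low_features", low_feat[i]), ("high_mito", high_mito[i]),
            ("low_fragments", low_frag[i]), ("high_fragments", high_frag[i]))
            if bad]
        reasons.append(";".join(r) if r else "pass")
    flags = pd.DataFrame({
        "cell_id": ds.cell_ids, "detected_genes": detected,
        "mito_frac": mito_frac, "fragments": frags,
        "pass_rna": pass_rna, "pass_atac": pass_atac, "keep": keep,
        "reason": reasons,
    })
    report = QCReport(ds.n_cells, int(pass_rna.sum()), int(pass_atac.sum()),
                      int(keep.sum()), flags)
    if not keep.any():
        raise ValueError("QC removed every cell; review thresholds")
    return ds.subset_cells(keep), report


def cpm_normalize(counts) -> np.ndarray:
    """Counts-per-million per row: row_i / total_i * 1e6 (dense output)."""
    if sp.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"sample {bad} has zero total count")
    return counts / totals[:, None] * 1e6


def find_markers(ds: MultiomeDataset, logfc_min: float = 0.25,
                 min_pct: float = 0.25) -> pd.DataFrame:
    """One-vs-rest cluster markers on log-normalized RNA.

    Genes are reported for a cluster when the natural-log ratio of mean
    expression (pseudocount 1) exceeds ``logfc_min`` and the expressing
    fraction exceeds ``min_pct`` in either the cluster or the rest.
    p-values are Wilcoxon rank-sum, BH-adjusted across genes per cluster.
    """
    clusters = ds.cells["cluster"].to_numpy()
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters to call markers")
    cpm = cpm_normalize(ds.rna_counts)
    logexp = np.log1p(cpm / 100.0)
    expressed = np.asarray((ds.rna_counts > 0).toarray()
                           if sp.issparse(ds.rna_counts) else ds.rna_counts > 0)

    rows = []
    for lab in labels:
        inside = clusters == lab
        if inside.sum() < 3:
            continue
        outside = ~inside
        mean_in = np.expm1(logexp[inside]).mean(axis=0)
        mean_out = np.expm1(logexp[outside]).mean(axis=0)
        log_fc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        pct_in = expressed[inside].mean(axis=0)
        pct_out = expressed[outside].mean(axis=0)
        sel = (log_fc > logfc_min) & (np.maximum(pct_in, pct_out) > min_pct)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        pvals = mannwhitneyu(logexp[inside][:, idx], logexp[outside][:, idx],
                             alternative="two-sided", axis=0).pvalue
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, g in enumerate(idx):
            rows.append({
                "gene_id": ds.gene_ids[g], "cluster": lab,
                "log_fc": log_fc[g], "pct_in": pct_in[g], "pct_out": pct_out[g],
                "p_value": pvals[j], "p_adjusted": padj[j],
            })
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "log_fc",
                                       "pct_in", "pct_out", "p_value",
                                       "p_adjusted"])
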