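"""Pseudotime-ordered pseudobulk aggregation and lineage-fate bin stacks.

Cells on the trajectory are sorted by pseudotime (ties broken by cell id)
and summed in consecutive blocks of 50 into pseudobulk samples for both
assays; a trailing block of fewer than half the group size is merged into
the previous sample. Fate composition divides the pooled pseudotime range
into 50 equal-width bins and reports, per group and bin, the proportion of
each cluster label among the cells of a fate-state subset.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import MultiomeDataset
from .qc import cpm_normalize


@dataclasses.dataclass
class PseudobulkSeries:
    sample_index: list
    member_cells: list            # list of cell-id lists, pseudotime order
    mean_pseudotime: np.ndarray   # non-decreasing
    groups: pd.DataFrame          # per-sample group composition (counts)
    rna_agg: np.ndarray           # samples x genes, integer
    atac_agg: np.ndarray          # samples x peaks, integer
    rna_cpm: np.ndarray
    atac_cpm: np.ndarray
    gene_ids: list
    peak_ids: list

    @property
    def n_samples(self) -> int:
        return len(self.sample_index)


@dataclasses.dataclass
class FateComposition:
    bin_edges: np.ndarray         # n_bins + 1 edges over pooled pseudotime
    celltypes: list
    proportions: dict             # group -> (n_bins x n_celltypes) matrix
    counts: dict                  # group -> per-bin cell counts
    empty: dict                   # group -> boolean per-bin empty flags


def make_pseudobulks(ds: MultiomeDataset, trajectory_cells=None,
                     group_size: int = 50) -> PseudobulkSeries:
    """Aggregate trajectory cells into pseudotime-ordered pseudobulks."""
    cells = ds.cells
    if trajectory_cells is None:
        mask = cells["pseudotime"].notna().to_numpy()
    else:
        wanted = set(trajectory_cells)
        mask = np.array([c in wanted for c in ds.cell_ids])
    if cells["pseudotime"].to_numpy()[mask].size and \
            np.isnan(cells["pseudotime"].to_numpy()[mask]).any():
        raise ValueError("trajectory cell without a pseudotime score")
    sub = ds.subset_cells(mask)
    n = sub.n_cells
    if n < 2 * group_size:
        raise ValueError(
            f"{n} trajectory cells < 2 x group_size={group_size}: series too "
            "short to correlate")

    order = sorted(range(n), key=lambda i: (sub.cells["pseudotime"].iloc[i],
                                            sub.cell_ids[i]))
    blocks = [order[i:i + group_size] for i in range(0, n, group_size)]
    if len(blocks) > 1 and len(blocks[-1]) < group_size // 2:
        blocks[-2].extend(blocks.pop())

    rna = sub.rna_counts.toarray() if sp.issparse(sub.rna_counts) else sub.rna_counts
    atac = sub.atac_counts.toarray() if sp.issparse(sub.atac_counts) else sub.atac_counts
    pt = sub.cells["pseudotime"].to_numpy()
    grp = sub.cells["group"].to_numpy()

    rna_agg = np.stack([rna[b].sum(axis=0) for b in blocks])
    atac_agg = np.stack([atac[b].sum(axis=0) for b in blocks])
    mean_pt = np.array([pt[b].mean() for b in blocks])
    groups = pd.DataFrame(
        [pd.Series(grp[b]).value_counts().to_dict() for b in blocks]
    ).fillna(0).astype(int)

    return PseudobulkSeries(
        sample_index=[f"pb{i:03d}" for i in range(len(blocks))],
        member_cells=[[sub.cell_ids[i] for i in b] for b in blocks],
        mean_pseudotime=mean_pt,
        groups=groups,
        rna_agg=rna_agg, atac_agg=atac_agg,
        rna_cpm=cpm_normalize(rna_agg), atac_cpm=cpm_normalize(atac_agg),
        gene_ids=sub.gene_ids, peak_ids=sub.peak_ids)


def fate_composition(ds: MultiomeDataset, fate_states, n_bins: int = 50
                     ) -> FateComposition:
    """Per-group stacked cluster proportions over pooled-pseudotime bins."""
    cells = ds.cells
    states = cells["state"]
    sel = states.isin(set(fate_states)) & cells["pseudotime"].notna()
    if not sel.any():
        raise ValueError(f"no cells in fate states {sorted(set(fate_states))}")
    sub = cells[sel]
    pt = sub["pseudotime"].to_numpy(dtype=float)
    lo, hi = pt.min(), pt.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-inclusive top bin so the max-pseudotime cell lands in bin n-1
    bins = np.clip(np.searchsorted(edges, pt, side="right") - 1, 0, n_bins - 1)

    celltypes = sorted(pd.unique(sub["cluster"]))
    ct_index = {c: j for j, c in enumerate(celltypes)}
    proportions, counts, empty = {}, {}, {}
    for g in pd.unique(sub["group"]):
        gm = (sub["group"] == g).to_numpy()
        mat = np.zeros((n_bins, len(celltypes)))
        for b, c in zip(bins[gm], sub["cluster"].to_numpy()[gm]):
            mat[b, ct_index[c]] += 1
        tot = mat.sum(axis=1)
        is_empty = tot == 0
        with np.errstate(invalid="ignore"):
            prop = np.where(is_empty[:, None], 0.0,
                            mat / np.where(tot == 0, 1, tot)[:, None])
        proportions[g] = prop
        counts[g] = tot.astype(int)
        empty[g] = is_empty
    return FateComposition(edges, celltypes, proportions, counts, empty)


def fate_composition_table(fc: FateComposition) -> pd.DataFrame:
    """Long-format (group, bin, celltype, proportion) table for plotting."""
    rows = []
    for g, prop in fc.proportions.items():
        for b in range(prop.shape[0]):
            for j, ct in enumerate(fc.celltypes):
                rows.append({"group": g, "bin": b, "celltype": ct,
                             "proportion": prop[b, j],
                             "n_cells": fc.counts[g][b]})
    return pd.DataFrame(rows)
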