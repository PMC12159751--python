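"""End-to-end orchestration of the regulatory-dynamics stages.

`run_pipeline` chains QC -> markers -> pseudobulks -> peak-gene links ->
link clusters -> motif deviations -> regulator matching -> differential
deviation on one dataset, and `evaluate_against_truth` scores the outputs
against a synthetic generator's planted ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import Config
from .deviations import (background_peaks, bias_corrected_z,
                         differential_deviation)
from .io import MotifSet, MultiomeDataset
from .links import (candidate_pairs, cluster_links, cluster_motif_enrichment,
                    link_peaks_to_genes)
from .network import gene_scores, match_regulators
from .pseudobulk import fate_composition, make_pseudobulks
from .qc import find_markers, qc_filter
from .simulate import MYELOID_CLUSTERS


@dataclasses.dataclass
class PipelineResult:
    dataset: MultiomeDataset
    qc_report: object
    markers: pd.DataFrame
    series: object
    links: pd.DataFrame
    link_clusters: object
    enrichment: pd.DataFrame
    deviations: object
    gene_score: object
    regulators: pd.DataFrame
    differential: pd.DataFrame


def run_pipeline(ds: MultiomeDataset, motifs: MotifSet, tf_gene_map: dict,
                 config: Config = Config(), seed: int = 0,
                 diff_per_cell: bool = True) -> PipelineResult:
    """Run every stage with the given configuration and seed."""
    ds_qc, report = qc_filter(ds, config.min_features, config.max_mito_frac,
                              config.min_fragments, config.max_fragments)
    markers = find_markers(ds_qc, config.logfc_min, config.min_pct)
    series = make_pseudobulks(ds_qc, group_size=config.group_size)

    pairs = candidate_pairs(ds_qc.genes, ds_qc.peaks,
                            markers["gene_id"].unique(),
                            config.min_dist, config.max_dist)
    links = link_peaks_to_genes(series, pairs, config.pcc_min, config.p_max)
    n_hc = int(links["high_confidence"].sum())
    k = min(config.k_clusters, max(n_hc, 1))
    clusters = cluster_links(links, series, k=k, seed=seed) if n_hc >= k \
        else None
    enrich = (cluster_motif_enrichment(clusters, motifs, ds_qc.peak_ids)
              if clusters is not None and motifs.peak_match is not None
              else pd.DataFrame())

    bg = background_peaks(ds_qc.peaks, series.atac_agg,
                          n_bg=config.n_background, seed=seed)
    dev = bias_corrected_z(series.atac_agg, motifs, bg,
                           sample_index=series.sample_index)
    gs = gene_scores(series, ds_qc.genes, ds_qc.peaks,
                     config.gene_score_window, config.gene_score_decay)
    regulators = match_regulators(gs, dev, tf_gene_map,
                                  config.r_min, config.fdr_max)

    if diff_per_cell:
        dev_cells = bias_corrected_z(ds_qc.atac_counts, motifs, bg,
                                     sample_index=ds_qc.cell_ids)
        diff = differential_deviation(dev_cells,
                                      ds_qc.cells["group"].to_numpy())
    else:
        grp = series.groups.idxmax(axis=1).to_numpy()
        diff = differential_deviation(dev, grp)

    return PipelineResult(ds_qc, report, markers, series, links, clusters,
                          enrich, dev, gs, regulators, diff)


def link_recovery(links: pd.DataFrame, planted_links) -> dict:
    """Recall and precision of high-confidence links vs planted truth."""
    truth = {(p, g) for p, g in planted_links}
    called = {(p, g) for p, g in
              links.loc[links["high_confidence"], ["peak_id", "gene_id"]]
              .itertuples(index=False)}
    tp = len(called & truth)
    return {
        "n_called": len(called), "n_planted": len(truth), "n_true": tp,
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }


def myeloid_fraction_by_bin(ds: MultiomeDataset, fate_states=None,
                            n_bins: int = 50) -> pd.DataFrame:
    """Per (group, bin): summed proportion of myeloid-branch cell types.

    Pools both fates by default (all states), so terminal bins compare the
    myeloid-vs-lymphoid split rather than within-fate composition.
    """
    if fate_states is None:
        fate_states = set(pd.unique(ds.cells["state"].dropna()))
    fc = fate_composition(ds, fate_states, n_bins)
    my = [i for i, c in enumerate(fc.celltypes) if c in MYELOID_CLUSTERS]
    rows = []
    for g, prop in fc.proportions.items():
        frac = prop[:, my].sum(axis=1)
        for b in range(n_bins):
            rows.append({"group": g, "bin": b, "myeloid_fraction": frac[b],
                         "empty": bool(fc.empty[g][b])})
    return pd.DataFrame(rows)
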