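"""Gene activity scores, positive-TF-regulator matching, and the
promoter-scanning TF-to-target network.

Gene scores summarize local chromatin accessibility: every peak within a
window of the TSS contributes its CPM accessibility weighted by
exp(-distance/decay); the sum is log1p-transformed. A TF is a positive
regulator when its motif deviation z-scores and its own gene score rise
and fall together along the pseudobulk series (Pearson r >= 0.5 at
BH-FDR < 0.05 by default). The network step converts each PFM to a
log-odds PWM (pseudocount 0.8, uniform background) and scans target-gene
promoter windows (2 kb upstream to 500 bp downstream of the TSS) on both
strands, keeping matches with relative score > 0.85 and log-odds > 8.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import BASES, MotifSet
from .links import pearson_with_p
from .pseudobulk import PseudobulkSeries

log = logging.getLogger("regdyn")

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G in ACGT encoding


@dataclasses.dataclass
class GeneScoreMatrix:
    sample_index: list
    gene_ids: list
    scores: np.ndarray        # samples x genes, log1p of decayed CPM sums
    window: int
    decay: int


def gene_scores(series: PseudobulkSeries, genes: pd.DataFrame,
                peaks: pd.DataFrame, window: int = 100_000,
                decay: int = 5_000) -> GeneScoreMatrix:
    """Accessibility-derived activity scores per pseudobulk sample and gene."""
    mid = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2)
    peak_pos = {p: i for i, p in enumerate(series.peak_ids)}
    pidx = peaks["peak_id"].map(peak_pos).to_numpy()
    out = np.zeros((series.n_samples, len(genes)))
    by_chrom = {}
    for chrom in peaks["chrom"].unique():
        m = (peaks["chrom"] == chrom).to_numpy()
        order = np.argsort(mid[m])
        by_chrom[chrom] = (mid[m][order], pidx[m][order])
    for j, (tss, chrom) in enumerate(zip(genes["tss"], genes["chrom"])):
        if chrom not in by_chrom:
            continue
        mids, cols = by_chrom[chrom]
        i0 = np.searchsorted(mids, tss - window, side="left")
        i1 = np.searchsorted(mids, tss + window, side="right")
        if i0 == i1:
            continue
        d = np.abs(mids[i0:i1] - tss)
        w = np.exp(-d / decay)
        out[:, j] = series.atac_cpm[:, cols[i0:i1]] @ w
    return GeneScoreMatrix(list(series.sample_index), list(genes["gene_id"]),
                           np.log1p(out), window, decay)


def match_regulators(gene_score: GeneScoreMatrix, dev, tf_gene_map: dict,
                     r_min: float = 0.5, fdr_max: float = 0.05
                     ) -> pd.DataFrame:
    """Correlate each motif's deviation with its TF's gene score.

    Returns one row per motif with Pearson r, p, BH-adjusted p and the
    positive-regulator call (r >= r_min and adjusted p < fdr_max).
    """
    if gene_score.scores.shape[0] < 5:
        raise ValueError("need >= 5 pseudobulk samples")
    gpos = {g: i for i, g in enumerate(gene_score.gene_ids)}
    rows = []
    for m, mid in enumerate(dev.motif_ids):
        gene = tf_gene_map.get(mid)
        if gene is None or gene not in gpos:
            log.warning("match_regulators: no TF gene for motif %s", mid)
            continue
        z = dev.z_dev[m]
        gs = gene_score.scores[:, gpos[gene]]
        ok = np.isfinite(z) & np.isfinite(gs)
        if ok.sum() < 5 or np.ptp(z[ok]) == 0 or np.ptp(gs[ok]) == 0:
            continue
        r, p = pearson_with_p(z[ok], gs[ok])
        rows.append({"motif_id": mid, "tf_gene_id": gene, "correlation": r,
                     "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["is_positive_regulator"] = (df["correlation"] >= r_min) \
            & (df["p_adjusted"] < fdr_max)
    else:
        df["p_adjusted"] = []
        df["is_positive_regulator"] = []
    return df


def promoter_windows(genes: pd.DataFrame, up: int = 2_000, down: int = 500
                     ) -> pd.DataFrame:
    """Strand-aware promoter intervals, 0-based half-open, clipped at 0.

    A + strand gene with TSS t gets [t-up, t+down); a - strand gene the
    mirrored [t-down+1, t+up+1). Both spans are up+down long when unclipped.
    """
    tss = genes["tss"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - up, tss - down + 1)
    end = np.where(plus, tss + down, tss + up + 1)
    start = np.maximum(start, 0)
    out = {"gene_id": genes["gene_id"].to_numpy()}
    if "chrom" in genes:
        out["chrom"] = genes["chrom"].to_numpy()
    out.update({"start": start, "end": end,
                "strand": genes["strand"].to_numpy()})
    return pd.DataFrame(out)


def pfm_to_pwm(pfm: np.ndarray, pseudocount: float = 0.8,
               background: float = 0.25) -> np.ndarray:
    """Log2-odds PWM: log2((count + pc*bg) / (colsum + pc) / bg)."""
    pfm = np.asarray(pfm, dtype=float)
    colsum = pfm.sum(axis=0)
    return np.log2((pfm + pseudocount * background)
                   / (colsum + pseudocount) / background)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    enc = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return enc  # -1 marks N / unknown


def scan_pwm(sequence: str, pfm: np.ndarray, rel_min: float = 0.85,
             score_min: float = 8.0) -> pd.DataFrame:
    """Scan both strands of a sequence with a PFM-derived log-odds PWM.

    Returns matches with relative score (min-max rescaled, "homology")
    strictly above ``rel_min`` and raw log-odds strictly above
    ``score_min``. Windows containing N are skipped.
    """
    pwm = pfm_to_pwm(pfm)
    w = pwm.shape[1]
    if w == 0:
        raise ValueError("zero-width PFM")
    enc = _encode(sequence)
    L = enc.size
    if w > L:
        return pd.DataFrame(columns=["match_start", "strand", "score",
                                     "relative_score"])
    smin = pwm.min(axis=0).sum()
    smax = pwm.max(axis=0).sum()
    rc_pwm = pwm[::-1, ::-1]  # complement bases, reversed positions
    rows = []
    valid = enc >= 0
    for strand, mat in (("+", pwm), ("-", rc_pwm)):
        for off in range(L - w + 1):
            win = enc[off: off + w]
            if not valid[off: off + w].all():
                continue
            score = float(mat[win, np.arange(w)].sum())
            rel = (score - smin) / (smax - smin) if smax > smin else 1.0
            if rel > rel_min and score > score_min:
                rows.append({"match_start": off, "strand": strand,
                             "score": score, "relative_score": rel})
    return pd.DataFrame(rows, columns=["match_start", "strand", "score",
                                       "relative_score"])


def build_network(motifs: MotifSet, promoter_seqs: dict, target_gene_set,
                  rel_min: float = 0.85, score_min: float = 8.0,
                  tf_names=None) -> pd.DataFrame:
    """TF-to-target edges from promoter scans of a target gene set.

    ``promoter_seqs`` maps gene_id to its promoter-window sequence; one
    edge is emitted per passing PWM match.
    """
    rows = []
    for m, (mid, tf) in enumerate(zip(motifs.motif_ids, motifs.tf_names)):
        if tf_names is not None and tf not in tf_names:
            continue
        for gene in target_gene_set:
            seq = promoter_seqs.get(gene)
            if seq is None:
                log.warning("build_network: no promoter sequence for %s", gene)
                continue
            hits = scan_pwm(seq, motifs.pfms[m], rel_min, score_min)
            for _, h in hits.iterrows():
                rows.append({"tf_name": tf, "motif_id": mid,
                             "target_gene_id": gene,
                             "match_start": int(h["match_start"]),
                             "strand": h["strand"],
                             "relative_score": h["relative_score"],
                             "log_odds": h["score"]})
    return pd.DataFrame(rows, columns=["tf_name", "motif_id",
                                       "target_gene_id", "match_start",
                                       "strand", "relative_score",
                                       "log_odds"])
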