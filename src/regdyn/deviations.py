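"""Bias-corrected TF motif accessibility deviations and derived scores.

For a motif's peak set, the raw deviation of a sample is the relative
excess of observed counts in those peaks over the depth-scaled expectation
from the peak's overall share of counts. Technical bias (GC content, mean
accessibility) is corrected by z-scoring each sample's raw deviation
against deviations of matched background peak sets: every member peak is
repeatedly replaced by a peak drawn from its nearest neighbors in
standardized (GC, log1p mean accessibility) space. Motif variability is
the standard deviation of the z-scores across samples. Pairwise synergy
compares the variability of two motifs' shared peaks against random
same-size subsets of their union; pairwise correlation is the Pearson r of
the two z-score profiles. Differential deviation contrasts group means of
the z-scores with a Wilcoxon rank-sum test, BH-adjusted across motifs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import MotifSet

log = logging.getLogger("regdyn")


def _dense(a):
    return a.toarray() if sp.issparse(a) else np.asarray(a, dtype=float)


def expected_fraction(atac) -> np.ndarray:
    """Per-peak share of all counts: e_p = total_p / grand_total (sums to 1)."""
    atac = _dense(atac)
    grand = atac.sum()
    if grand <= 0:
        raise ValueError("all-zero accessibility matrix")
    return atac.sum(axis=0) / grand


def raw_deviation(atac, motif_peaks) -> np.ndarray:
    """Raw accessibility deviation of one peak set, per sample.

    dev_i = (observed_i - expected_i) / expected_i with expected_i =
    depth_i * sum of member peaks' expected fractions. Samples with zero
    expectation get NaN.
    """
    atac = _dense(atac)
    idx = np.asarray(list(motif_peaks), dtype=int)
    if idx.size == 0:
        raise ValueError("motif with no peaks")
    e = expected_fraction(atac)
    depth = atac.sum(axis=1)
    o = atac[:, idx].sum(axis=1)
    x = depth * e[idx].sum()
    out = np.full(atac.shape[0], np.nan)
    ok = x > 0
    if not ok.all():
        log.warning("raw_deviation: %d samples with zero expectation",
                    int((~ok).sum()))
    out[ok] = (o[ok] - x[ok]) / x[ok]
    return out


def background_peaks(peaks: pd.DataFrame, atac, n_bg: int = 50, seed: int = 0
                     ) -> np.ndarray:
    """Sample matched background peaks: (n_peaks, n_bg) index matrix.

    Matching is k-nearest-neighbors in standardized (gc, log1p mean
    accessibility); draws are weighted by a Gaussian kernel on neighbor
    distance, with replacement, never including the peak itself.
    """
    atac = _dense(atac)
    n = len(peaks)
    if n < n_bg + 1:
        raise ValueError(f"need >= n_bg+1={n_bg + 1} peaks, have {n}")
    rng = np.random.default_rng(seed)
    feats = np.column_stack([peaks["gc"].to_numpy(dtype=float),
                             np.log1p(atac.mean(axis=0))])
    sd = feats.std(axis=0)
    if (sd == 0).all():
        log.warning("background_peaks: degenerate features, uniform sampling")
        draws = rng.integers(0, n - 1, size=(n, n_bg))
        draws += draws >= np.arange(n)[:, None]  # skip self
        return draws
    feats = (feats - feats.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    k = min(n, max(int(np.ceil(0.05 * n)), n_bg, 10) + 1)
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    dist, idx = nn.kneighbors(feats)
    out = np.empty((n, n_bg), dtype=int)
    for p in range(n):
        keep = idx[p] != p
        cand, d = idx[p][keep], dist[p][keep]
        sigma = np.median(d)
        w = np.exp(-(d / sigma) ** 2) if sigma > 0 else np.ones_like(d)
        w /= w.sum()
        out[p] = rng.choice(cand, size=n_bg, replace=True, p=w)
    return out


@dataclasses.dataclass
class DeviationResult:
    motif_ids: list
    sample_index: list
    raw_dev: np.ndarray          # motifs x samples
    z_dev: np.ndarray            # motifs x samples, bias-corrected
    variability: np.ndarray      # per motif, sd of z across samples
    background_sets: np.ndarray  # peaks x n_bg
    n_background: int
    # retained inputs so synergy can score arbitrary peak sets
    atac: np.ndarray = dataclasses.field(repr=False, default=None)
    motif_members: list = dataclasses.field(repr=False, default=None)


def _devs_for_indicators(atac, ind, e, depth):
    """Raw deviations for many weighted peak sets at once.

    ``ind`` is a (peaks x sets) column-sparse weight matrix; returns a
    (samples x sets) array with NaN where the expectation is zero.
    """
    O = atac @ ind
    if sp.issparse(O):
        O = O.toarray()
    O = np.asarray(O)
    exp_frac = np.asarray(e @ ind).ravel()
    X = depth[:, None] * exp_frac[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (O - X) / X
    dev[X == 0] = np.nan
    return dev


def _member_indicator(members_list, n_peaks):
    cols, rows, data = [], [], []
    for j, members in enumerate(members_list):
        for p in members:
            rows.append(p)
            cols.append(j)
            data.append(1.0)
    return sp.csc_matrix((data, (rows, cols)),
                         shape=(n_peaks, len(members_list)))


def _bias_corrected(atac, members_list, backgrounds):
    """(raw, z, variability) for a list of peak-index sets."""
    atac = _dense(atac)
    n_samples, n_peaks = atac.shape
    e = expected_fraction(atac)
    depth = atac.sum(axis=1)
    ind = _member_indicator(members_list, n_peaks)
    raw = _devs_for_indicators(atac, ind, e, depth)   # samples x sets
    n_bg = backgrounds.shape[1]
    mean = np.zeros_like(raw)
    m2 = np.zeros_like(raw)
    for b in range(n_bg):
        # scatter: member peak p is replaced by backgrounds[p, b]
        S = sp.csc_matrix((np.ones(n_peaks), (backgrounds[:, b],
                                              np.arange(n_peaks))),
                          shape=(n_peaks, n_peaks))
        bg_dev = _devs_for_indicators(atac, S @ ind, e, depth)
        delta = bg_dev - mean
        mean += delta / (b + 1)
        m2 += delta * (bg_dev - mean)
    sd = np.sqrt(m2 / (n_bg - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean) / sd
    z[sd == 0] = np.nan
    variability = np.array([np.nanstd(z[:, j], ddof=1)
                            for j in range(z.shape[1])])
    return raw.T, z.T, variability


def bias_corrected_z(atac, motifs: MotifSet, backgrounds: np.ndarray,
                     sample_index=None) -> DeviationResult:
    """Bias-corrected deviation z-scores for every motif."""
    if motifs.peak_match is None:
        raise ValueError("MotifSet.peak_match required")
    match = np.asarray(motifs.peak_match)
    members = [list(np.flatnonzero(match[:, m])) for m in range(len(motifs))]
    if any(len(m) == 0 for m in members):
        raise ValueError("motif with zero peaks")
    raw, z, var = _bias_corrected(atac, members, backgrounds)
    atac_d = _dense(atac)
    if sample_index is None:
        sample_index = [f"s{i}" for i in range(atac_d.shape[0])]
    return DeviationResult(
        motif_ids=list(motifs.motif_ids), sample_index=list(sample_index),
        raw_dev=raw, z_dev=z, variability=var,
        background_sets=backgrounds, n_background=backgrounds.shape[1],
        atac=atac_d, motif_members=members)


@dataclasses.dataclass
class SynergyMatrix:
    motif_ids: list
    correlation: np.ndarray   # motifs x motifs Pearson r of z profiles
    synergy: np.ndarray       # motifs x motifs z-scores, NaN where undefined


def synergy_and_correlation(dev: DeviationResult, motifs: MotifSet,
                            n_sub: int = 100, min_shared: int = 5,
                            seed: int = 0) -> SynergyMatrix:
    """Pairwise motif correlation and shared-peak synergy z-scores.

    synergy(A, B) scores the variability of the A-and-B peak set against
    ``n_sub`` random same-size subsets of the A-or-B set; pairs sharing
    fewer than ``min_shared`` peaks are NaN.
    """
    n_m = len(dev.motif_ids)
    if n_m < 2:
        raise ValueError("need >= 2 motifs")
    z = dev.z_dev
    zc = np.ma.masked_invalid(z)
    corr = np.ma.corrcoef(zc).filled(np.nan)
    np.fill_diagonal(corr, 1.0)

    rng = np.random.default_rng(seed)
    synergy = np.full((n_m, n_m), np.nan)
    members = [np.asarray(m) for m in dev.motif_members]
    e = expected_fraction(dev.atac)
    depth = dev.atac.sum(axis=1)
    for a in range(n_m):
        for b in range(a + 1, n_m):
            inter = np.intersect1d(members[a], members[b])
            if inter.size < min_shared:
                continue
            union = np.union1d(members[a], members[b])
            sets = [list(inter)] + [
                list(rng.choice(union, size=inter.size, replace=False))
                for _ in range(n_sub)]
            _, _, var = _bias_corrected(dev.atac, sets, dev.background_sets)
            null = var[1:]
            sd = null.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                continue
            synergy[a, b] = synergy[b, a] = (var[0] - null.mean()) / sd
    return SynergyMatrix(list(dev.motif_ids), corr, synergy)


def differential_deviation(dev: DeviationResult, groups,
                           group_ctrl=None, group_case=None) -> pd.DataFrame:
    """Group-wise differential motif accessibility on deviation z-scores.

    Per motif: group means, delta = case - ctrl, two-sided Wilcoxon
    rank-sum across samples, BH across motifs.
    """
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if group_ctrl is None or group_case is None:
        if len(labels) != 2:
            raise ValueError("specify group_ctrl/group_case for >2 groups")
        group_ctrl, group_case = labels[0], labels[1]
    in_ctrl = groups == group_ctrl
    in_case = groups == group_case
    if in_ctrl.sum() < 3 or in_case.sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    rows = []
    for m, mid in enumerate(dev.motif_ids):
        zc = dev.z_dev[m][in_ctrl]
        zl = dev.z_dev[m][in_case]
        zc, zl = zc[np.isfinite(zc)], zl[np.isfinite(zl)]
        if zc.size < 3 or zl.size < 3:
            continue
        p = stats.mannwhitneyu(zl, zc, alternative="two-sided").pvalue
        rows.append({"motif_id": mid, "mean_dev_ctrl": zc.mean(),
                     "mean_dev_case": zl.mean(),
                     "delta": zl.mean() - zc.mean(), "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df
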