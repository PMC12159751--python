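import numpy as np
import pandas as pd
import pytest

from regdyn.deviations import (DeviationResult, background_peaks,
                               bias_corrected_z, differential_deviation,
                               expected_fraction, raw_deviation,
                               synergy_and_correlation)
from regdyn.io import MotifSet


def test_expected_fraction():
    atac = np.array([[5, 15], [5, 15]])
    assert np.allclose(expected_fraction(atac), [0.25, 0.75])
    assert np.allclose(expected_fraction(np.full((3, 4), 7)), 0.25)
    rng = np.random.default_rng(0)
    e = expected_fraction(rng.integers(0, 9, (4, 6)))
    assert e.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        expected_fraction(np.zeros((2, 2)))


def test_raw_deviation_hand_example_and_invariances():
    """Counts ((1,2,3),(3,2,1)), motif {peak0}: e=(1/3,...), sample devs
    (1-2)/2 = -0.5 and (3-2)/2 = +0.5."""
    atac = np.array([[1, 2, 3], [3, 2, 1]])
    dev = raw_deviation(atac, [0])
    assert np.allclose(dev, [-0.5, 0.5])
    # motif covering all peaks: observed equals expected exactly
    assert np.allclose(raw_deviation(atac, [0, 1, 2]), 0.0)
    # doubling all counts changes nothing
    assert np.allclose(raw_deviation(2 * atac, [0]), dev)
    # rescaling one sample of many barely moves the deviations: the pooled
    # expectation absorbs a vanishing share of the change
    rng = np.random.default_rng(0)
    big = rng.integers(1, 30, (100, 6))
    big2 = big.copy()
    big2[0] *= 3
    assert np.abs(raw_deviation(big2, [1, 4])[1:]
                  - raw_deviation(big, [1, 4])[1:]).max() < 0.05


def test_background_peaks_properties(default_sim):
    """Backgrounds exclude the peak itself, match GC, and are seed-stable."""
    ds, _, _ = default_sim
    atac = ds.atac_counts.toarray()[:200]
    bg1 = background_peaks(ds.peaks, atac, n_bg=50, seed=5)
    bg2 = background_peaks(ds.peaks, atac, n_bg=50, seed=5)
    assert (bg1 == bg2).all()
    n = len(ds.peaks)
    assert (bg1 != np.arange(n)[:, None]).all()
    gc = ds.peaks["gc"].to_numpy()
    mean_bg_gc = gc[bg1].mean(axis=1)
    assert np.abs(mean_bg_gc - gc).mean() < 0.05
    assert np.quantile(np.abs(mean_bg_gc - gc), 0.9) < 0.05


def _brute_force_bias_z(atac, members_list, backgrounds):
    """Nested-loop oracle for the bias-corrected deviation z-scores."""
    atac = np.asarray(atac, dtype=float)
    n_s = atac.shape[0]
    e = atac.sum(axis=0) / atac.sum()
    depth = atac.sum(axis=1)

    def dev_of(idx):
        out = np.empty(n_s)
        for i in range(n_s):
            o = sum(atac[i, p] for p in idx)
            x = depth[i] * sum(e[p] for p in idx)
            out[i] = (o - x) / x if x > 0 else np.nan
        return out

    raw, z = [], []
    for members in members_list:
        r = dev_of(members)
        bg = np.array([dev_of([backgrounds[p, b] for p in members])
                       for b in range(backgrounds.shape[1])])
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0, ddof=1)
        raw.append(r)
        z.append((r - mu) / sd)
    return np.array(raw), np.array(z)


def test_bias_corrected_z_matches_enumeration_oracle():
    """5-peak / 4-sample / 2-motif toy with fixed background draws matches a
    nested-loop recomputation to 1e-9."""
    rng = np.random.default_rng(3)
    atac = rng.integers(1, 30, (4, 5))
    backgrounds = np.array([[1, 2, 3], [0, 2, 4], [4, 0, 1],
                            [2, 4, 0], [3, 1, 2]])
    match = np.zeros((5, 2), dtype=bool)
    match[[0, 2], 0] = True
    match[[1, 3, 4], 1] = True
    motifs = MotifSet(["M1", "M2"], ["t1", "t2"], [np.ones((4, 3))] * 2,
                      peak_match=match)
    res = bias_corrected_z(atac, motifs, backgrounds)
    raw_o, z_o = _brute_force_bias_z(atac, [[0, 2], [1, 3, 4]], backgrounds)
    assert np.allclose(res.raw_dev, raw_o, atol=1e-9)
    assert np.allclose(res.z_dev, z_o, atol=1e-9)
    var_o = np.nanstd(z_o, axis=1, ddof=1)
    assert np.allclose(res.variability, var_o, atol=1e-9)


def test_null_motif_z_near_zero(default_sim):
    """A motif whose peaks are draws from the background pool has |mean z|
    < 0.2; planted regulators rank in the top variability decile."""
    ds, motifs, truth = default_sim
    order = np.argsort(ds.cells["pseudotime"].to_numpy())[::4][:500]
    atac = ds.atac_counts.toarray()[order]
    # 10 pseudotime-ordered pseudobulks spanning the trajectory
    agg = atac.reshape(10, 50, -1).sum(axis=1)
    bg = background_peaks(ds.peaks, agg, n_bg=50, seed=2)
    rng = np.random.default_rng(0)
    match = np.asarray(motifs.peak_match).copy()
    # a truly null motif: time-constant decoy peaks (no planted link, no
    # motif membership), which are statistically identical to backgrounds
    pos = {p: i for i, p in enumerate(ds.peak_ids)}
    linked = {pos[p] for p, _ in truth.planted_links}
    constant = np.array([i for i in range(match.shape[0])
                         if not match[i].any() and i not in linked])
    null_col = np.zeros((match.shape[0], 1), dtype=bool)
    null_col[rng.choice(constant, 60, replace=False)] = True
    motifs2 = MotifSet(motifs.motif_ids + ["NULL"],
                       motifs.tf_names + ["null"],
                       motifs.pfms + [np.ones((4, 4))],
                       peak_match=np.hstack([match, null_col]))
    res = bias_corrected_z(agg, motifs2, bg)
    znull = res.z_dev[-1]
    assert abs(np.nanmean(znull)) < 0.2
    # the three planted regulators carry the most variable deviations
    order = np.argsort(res.variability)[::-1]
    top3 = {res.motif_ids[i] for i in order[:3]}
    assert top3 == set(truth.planted_regulators)


def test_synergy_and_correlation_structure():
    """Identical peak sets: correlation 1 and synergy centered near 0;
    disjoint motifs: synergy NA; correlation matrix symmetric, unit diag."""
    rng = np.random.default_rng(8)
    atac = rng.integers(5, 60, (12, 30))
    match = np.zeros((30, 3), dtype=bool)
    match[:10, 0] = True
    match[:10, 1] = True          # identical to motif 0
    match[20:, 2] = True          # disjoint from both
    motifs = MotifSet(["A", "B", "C"], ["a", "b", "c"],
                      [np.ones((4, 3))] * 3, peak_match=match)
    bg = background_peaks(
        pd.DataFrame({"peak_id": [f"p{i}" for i in range(30)],
                      "gc": rng.uniform(0.3, 0.7, 30)}),
        atac, n_bg=20, seed=0)
    dev = bias_corrected_z(atac, motifs, bg)
    syn = synergy_and_correlation(dev, motifs, n_sub=60, seed=1)
    assert np.allclose(np.diag(syn.correlation), 1.0)
    assert np.allclose(syn.correlation, syn.correlation.T, equal_nan=True)
    assert syn.correlation[0, 1] == pytest.approx(1.0, abs=1e-9)
    assert np.isnan(syn.synergy[0, 2]) and np.isnan(syn.synergy[1, 2])
    assert abs(syn.synergy[0, 1]) < 3.0   # same-set synergy is a null draw
    # PSD up to numerical tolerance
    w = np.linalg.eigvalsh(np.nan_to_num(syn.correlation))
    assert w.min() > -1e-8


def test_anti_programmed_regulators_anticorrelate(default_run):
    """Generator plants regulators with opposite ramps: at least one pair of
    planted motifs has negative deviation correlation."""
    res, truth = default_run
    dev = res.deviations
    idx = [dev.motif_ids.index(m) for m in truth.planted_regulators]
    z = dev.z_dev[idx]
    cors = np.corrcoef(z)
    off = cors[np.triu_indices_from(cors, 1)]
    assert off.min() < -0.5


def _toy_dev(z, motif_ids=None):
    n_m, n_s = z.shape
    return DeviationResult(
        motif_ids=motif_ids or [f"m{i}" for i in range(n_m)],
        sample_index=[f"s{i}" for i in range(n_s)],
        raw_dev=z.copy(), z_dev=z, variability=z.std(axis=1, ddof=1),
        background_sets=np.zeros((1, 2), dtype=int), n_background=2)


def test_differential_deviation_antisymmetry_and_null():
    rng = np.random.default_rng(4)
    z = rng.normal(size=(6, 40))
    groups = np.array(["Ctrl"] * 20 + ["LIP"] * 20)
    out = differential_deviation(_toy_dev(z), groups)
    flipped = differential_deviation(_toy_dev(z),
                                     np.where(groups == "Ctrl", "LIP", "Ctrl"))
    merged = out.merge(flipped, on="motif_id", suffixes=("", "_f"))
    assert np.allclose(merged["delta"], -merged["delta_f"], atol=1e-12)
    assert np.allclose(merged["p_value"], merged["p_value_f"], atol=1e-12)
    # pure-noise groups: deltas small and nothing BH-significant here
    assert (out["p_adjusted"] > 0.05).all()
    assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()


def test_differential_deviation_detects_planted_shift(default_run):
    """The group-shifted motif is the top differential hit at FDR < 0.05 with
    the expected sign (more accessible in the case group)."""
    res, truth = default_run
    diff = res.differential.sort_values("p_adjusted")
    shifted = truth.group_shifted_motifs[0]
    top = diff.iloc[0]
    assert top["motif_id"] == shifted
    assert top["p_adjusted"] < 0.05
    assert top["delta"] > 0
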