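"""Synthetic bifurcating-trajectory multiome generator with planted truth.

Emulates a hematopoietic stem/progenitor compartment profiled with paired
scRNA + scATAC: cells carry a latent differentiation time t in [0, 1] and
commit to a myeloid or lymphoid branch with a group-dependent bias (the
inflammatory group is skewed toward the myeloid branch). Gene expression
follows smooth programs along (t, branch) sampled as negative-binomial
counts; peak accessibility is Poisson around per-peak rate programs. Ground
truth is planted at three levels so every downstream stage is checkable:

* peak-gene links — one enhancer-like peak per planted gene whose
  accessibility rate tracks the partner gene's expression program, placed
  1-250 kb from the gene's TSS;
* positive TF regulators — motifs whose member peaks track the TF's own
  gene program, with a few of those peaks at the TF's promoter so the
  accessibility-derived gene score moves with the motif deviation;
* a group-shifted motif — member peaks uniformly more accessible in the
  case group, giving the differential-deviation stage a known hit.

Geometry: one synthetic chromosome with one gene per fixed-width territory,
so a planted peak can only fall in the linking window of its own partner.
Decoy peaks with time-constant rates are placed inside linking windows,
just outside them, under 1 kb from a TSS, and in a gene-free region, so the
distance filter and the correlation test are both exercised in each
direction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (MotifSet, MultiomeDataset, write_jaspar, write_manifest,
                 write_multiome)

TERRITORY = 600_000          # bp per gene territory; > 2 * max link distance
PEAK_WIDTH = 500
MYELOID_CLUSTERS = ("CMP", "GMP", "NeuP")
LYMPHOID_CLUSTERS = ("CLP", "pro_B")


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_cells: int = 2_000
    n_genes: int = 500
    n_peaks: int = 5_000
    n_motifs: int = 20
    n_planted_links: int = 200
    n_planted_regulators: int = 3
    branch_bias: tuple = (("Ctrl", 0.4), ("LIP", 0.8))  # P(myeloid) per group
    rna_depth_mean: float = 2_000.0
    atac_depth_mean: float = 10_000.0
    nb_dispersion: float = 0.3
    link_effect: float = 0.9
    group_shift: float = 0.6   # case-group accessibility boost of the shifted motif
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_links > min(self.n_peaks, self.n_genes):
            raise ValueError("more planted links than peaks or genes")
        if self.n_planted_regulators > self.n_motifs:
            raise ValueError("more planted regulators than motifs")
        if self.n_planted_links + self.n_motifs > self.n_genes:
            raise ValueError("need n_genes >= n_planted_links + n_motifs")
        for _, p in self.branch_bias:
            if not 0.0 <= p <= 1.0:
                raise ValueError("branch bias outside [0, 1]")
        if not 0.0 <= self.link_effect <= 1.0:
            raise ValueError("link_effect outside [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    planted_links: list          # of (peak_id, gene_id)
    planted_regulators: list     # motif ids
    true_pseudotime: np.ndarray
    true_branch: np.ndarray      # "myeloid" / "lymphoid" per cell
    group_shifted_motifs: list   # motif ids boosted in the case group
    tf_gene_map: dict            # motif id -> TF gene id

    def to_json(self) -> str:
        return json.dumps({
            "planted_links": [list(x) for x in self.planted_links],
            "planted_regulators": list(self.planted_regulators),
            "true_pseudotime": [round(float(t), 10) for t in self.true_pseudotime],
            "true_branch": list(map(str, self.true_branch)),
            "group_shifted_motifs": list(self.group_shifted_motifs),
            "tf_gene_map": dict(self.tf_gene_map),
        }, indent=1)


# ---------------------------------------------------------------------------
# smooth expression / accessibility programs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _program(t, kind, center, width, lo, hi, rising=True):
    """Smooth rate program on t in [0, 1], bounded in [lo, hi]."""
    if kind == "ramp":
        f = _sigmoid((t - center) / width)
        if not rising:
            f = 1.0 - f
    else:  # bump
        f = np.exp(-0.5 * ((t - center) / width) ** 2)
    return lo + (hi - lo) * f


def _assign_states(t, myeloid):
    """Trajectory states: shared trunk 1 -> 3 -> 4, terminal 5 (myeloid) or
    6 (lymphoid), so fate sets {1,3,4,5} and {1,3,4,6} are both realizable."""
    state = np.full(t.shape, 1, dtype=int)
    state[t >= 0.3] = 3
    state[t >= 0.6] = 4
    late = t >= 0.8
    state[late & myeloid] = 5
    state[late & ~myeloid] = 6
    return state


def _assign_clusters(t, myeloid):
    lab = np.where(t < 0.25, "LSK",
                   np.where(t < 0.5, np.where(myeloid, "CMP", "CLP"),
                            np.where(t < 0.75, np.where(myeloid, "GMP", "CLP"),
                                     np.where(myeloid, "NeuP", "pro_B"))))
    return lab


def _random_pfm(rng, width):
    """Informative PFM: one dominant base per column (counts sum to 100)."""
    consensus = rng.integers(0, 4, size=width)
    pfm = np.full((4, width), 5.0)
    pfm[consensus, np.arange(width)] = 85.0
    return pfm, consensus


def generate(spec: SyntheticSpec):
    """Build one dataset; returns (MultiomeDataset, MotifSet, GroundTruth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_c, n_g, n_p = spec.n_cells, spec.n_genes, spec.n_peaks
    groups = [g for g, _ in spec.branch_bias]
    bias = dict(spec.branch_bias)

    # --- cells -------------------------------------------------------------
    group = np.array([groups[i % len(groups)] for i in range(n_c)])
    t = rng.uniform(0.0, 1.0, n_c)
    myeloid = rng.uniform(size=n_c) < np.array([bias[g] for g in group])
    branch = np.where(myeloid, "myeloid", "lymphoid")
    # observed pseudotime: jitter then re-rank onto [0, 1]
    noisy = t + rng.normal(0.0, 0.02, n_c)
    pseudotime = np.argsort(np.argsort(noisy)) / max(n_c - 1, 1)
    state = _assign_states(t, myeloid)
    cluster = _assign_clusters(t, myeloid)

    # --- gene roles and programs -------------------------------------------
    gene_ids = [f"gene{g:04d}" for g in range(n_g)]
    perm = rng.permutation(n_g)
    linked_genes = perm[: spec.n_planted_links]
    tf_genes = perm[spec.n_planted_links: spec.n_planted_links + spec.n_motifs]
    other = perm[spec.n_planted_links + spec.n_motifs:]

    mu = np.ones((n_c, n_g))
    gene_kind = np.full(n_g, "flat", dtype=object)

    def strong_program(i, rising):
        kind = "ramp" if rng.uniform() < 0.7 else "bump"
        center = rng.uniform(0.25, 0.75)
        width = rng.uniform(0.08, 0.2)
        gene_kind[i] = kind
        return _program(t, kind, center, width, 0.3, 3.0, rising)

    for j, i in enumerate(linked_genes):
        mu[:, i] = strong_program(i, rising=bool(rng.integers(0, 2)))
    # planted-regulator TF genes alternate rising/falling so at least one
    # pair of regulators is anti-programmed (negative deviation correlation)
    for j, i in enumerate(tf_genes[: spec.n_planted_regulators]):
        mu[:, i] = strong_program(i, rising=(j % 2 == 0))
    # half of the remaining genes are branch-biased or time-dynamic markers
    n_dyn = len(other) // 2
    for i in other[:n_dyn]:
        prog = _program(t, "ramp", rng.uniform(0.2, 0.8),
                        rng.uniform(0.1, 0.25), 0.5, 2.0,
                        rising=bool(rng.integers(0, 2)))
        if rng.uniform() < 0.5:  # branch-specific
            on = myeloid if rng.uniform() < 0.5 else ~myeloid
            prog = np.where(on, prog, 0.5)
        mu[:, i] = prog

    # --- genome layout ------------------------------------------------------
    tss = 300_000 + np.arange(n_g, dtype=np.int64) * TERRITORY
    strand = np.where(rng.uniform(size=n_g) < 0.5, "+", "-")
    biotype = np.full(n_g, "protein_coding", dtype=object)
    biotype[rng.uniform(size=n_g) < 0.05] = "lincRNA"
    is_mito = np.zeros(n_g, dtype=bool)
    is_mito[rng.choice(n_g, size=max(1, n_g // 50), replace=False)] = True
    desert_start = int(tss[-1] + TERRITORY)

    # --- peak budget --------------------------------------------------------
    motif_size = int(np.clip(n_p // 33, 8, 150))
    n_track = max(4, int(round(0.87 * motif_size)))      # >= 80% of members
    n_prox = min(8, max(2, n_track // 12))               # promoter-proximal
    n_rand_member = motif_size - n_track
    n_null = spec.n_motifs - spec.n_planted_regulators
    shifted_idx = spec.n_planted_regulators  # first non-regulator motif

    n_special = (spec.n_planted_links
                 + spec.n_planted_regulators * n_track
                 + n_null * n_prox
                 + (motif_size if n_null > 0 else 0))    # shifted motif members
    budget = n_p - n_special
    if budget < 4:
        raise ValueError("infeasible spec: peak budget exhausted by planted sets")
    n_inwin = min(n_g, budget // 4)
    n_sub1k = min(n_g, budget // 20)
    n_outwin = min(n_g, budget // 8)
    n_desert = budget - n_inwin - n_sub1k - n_outwin

    chrom_list, mid_list, rate_cols, col_meta = [], [], [], []

    def add_peak(mid, rate_col):
        mid_list.append(int(mid))
        rate_cols.append(rate_col)

    const_rate = lambda: np.full(n_c, float(np.exp(rng.normal(0.0, 0.25))))

    planted_links = []
    # 1. planted-link peaks: rate tracks the partner gene, 1-250 kb away
    for i in linked_genes:
        d = int(rng.integers(1_000, 250_001)) * int(rng.choice([-1, 1]))
        add_peak(tss[i] + d,
                 spec.link_effect * mu[:, i] + (1.0 - spec.link_effect))
        planted_links.append((len(mid_list) - 1, int(i)))

    # 2. regulator motifs: tracking peaks in the desert + at the TF promoter
    motif_members: list[list[int]] = [[] for _ in range(spec.n_motifs)]
    desert_cursor = desert_start
    for m in range(spec.n_planted_regulators):
        g = tf_genes[m]
        # affine-rescaled copy of the TF's own program: each member peak
        # tracks it, but at reduced amplitude so that a motif's ~100 shared
        # peaks do not dominate the genome-wide accessibility composition
        prog = 0.8 + (mu[:, g] - 0.3) * (1.3 - 0.8) / 2.7
        for _ in range(n_prox):          # drive the TF's own gene score
            add_peak(tss[g] + int(rng.integers(-900, 901)), prog)
            motif_members[m].append(len(mid_list) - 1)
        for _ in range(n_track - n_prox):
            add_peak(desert_cursor, prog)
            desert_cursor += 2_000
            motif_members[m].append(len(mid_list) - 1)

    # 3. constant promoter-proximal peaks for the null TFs (gene scores exist)
    for m in range(spec.n_planted_regulators, spec.n_motifs):
        g = tf_genes[m]
        for _ in range(n_prox):
            add_peak(tss[g] + int(rng.integers(-900, 901)), const_rate())

    # 4. dedicated members of the group-shifted motif (constant in Ctrl)
    case = groups[-1]
    shifted_members = []
    if n_null > 0:
        boost = np.where(group == case, 1.0 + spec.group_shift, 1.0)
        for _ in range(motif_size):
            add_peak(desert_cursor, const_rate() * boost)
            desert_cursor += 2_000
            shifted_members.append(len(mid_list) - 1)
        motif_members[shifted_idx] = shifted_members

    # 5. decoys: inside the linking window, under 1 kb, and just outside it
    for j in range(n_inwin):
        g = j % n_g
        d = int(rng.integers(1_000, 250_001)) * int(rng.choice([-1, 1]))
        add_peak(tss[g] + d, const_rate())
    for j in range(n_sub1k):
        add_peak(tss[j % n_g] + int(rng.integers(-800, 801)), const_rate())
    for j in range(n_outwin):
        g = j % (n_g - 1)
        add_peak(tss[g] + 255_000 + int(rng.integers(0, 85_000)), const_rate())

    # 6. desert constants; the first chunk is the shared null-motif pool
    desert_pool = []
    for _ in range(n_desert):
        add_peak(desert_cursor, const_rate())
        desert_cursor += 2_000
        desert_pool.append(len(mid_list) - 1)
    pool = desert_pool[: max(len(desert_pool) // 3, motif_size)]
    for m in range(spec.n_planted_regulators, spec.n_motifs):
        if m == shifted_idx:
            continue
        k = min(motif_size, len(pool))
        motif_members[m] = list(rng.choice(pool, size=k, replace=False))
    # top up regulator motifs (< 20% of members) with planted-link peaks of
    # genes co-regulated with the TF: the TF's motif appears in enhancers of
    # targets sharing its program, so link clusters carry motif enrichment
    if planted_links:
        link_peak_idx = np.array([p for p, _ in planted_links])
        link_gene_idx = np.array([g for _, g in planted_links])
        prog_mat = mu[:, link_gene_idx]
        for m in range(spec.n_planted_regulators):
            g = tf_genes[m]
            cors = np.array([np.corrcoef(prog_mat[:, j], mu[:, g])[0, 1]
                             for j in range(prog_mat.shape[1])])
            take = np.argsort(cors)[::-1][:n_rand_member]
            motif_members[m].extend(link_peak_idx[take])

    # --- assemble matrices --------------------------------------------------
    rates = np.column_stack(rate_cols)           # cells x peaks
    assert rates.shape[1] == n_p, (rates.shape, n_p)
    adepth = np.exp(rng.normal(np.log(spec.atac_depth_mean), 0.3, n_c))
    lam = rates / rates.sum(axis=1, keepdims=True) * adepth[:, None]
    atac = rng.poisson(lam).astype(np.int64)

    rdepth = np.exp(rng.normal(np.log(spec.rna_depth_mean), 0.3, n_c))
    m_rna = mu / mu.sum(axis=1, keepdims=True) * rdepth[:, None]
    r = 1.0 / spec.nb_dispersion
    rna = rng.negative_binomial(r, r / (r + m_rna)).astype(np.int64)

    peak_ids = [f"peak{j:05d}" for j in range(n_p)]
    mids = np.asarray(mid_list, dtype=np.int64)
    peaks = pd.DataFrame({
        "peak_id": peak_ids, "chrom": "chrS",
        "start": mids - PEAK_WIDTH // 2, "end": mids + PEAK_WIDTH // 2,
        "gc": rng.beta(5.0, 5.0, n_p),
    }).set_index("peak_id", drop=False)

    genes = pd.DataFrame({
        "gene_id": gene_ids, "chrom": "chrS", "tss": tss, "strand": strand,
        "biotype": biotype, "is_mito": is_mito,
    }).set_index("gene_id", drop=False)

    cell_ids = [f"cell{i:05d}" for i in range(n_c)]
    cells = pd.DataFrame({
        "cell_id": cell_ids, "group": group, "cluster": cluster,
        "pseudotime": pseudotime, "state": state,
    }).set_index("cell_id", drop=False)

    ds = MultiomeDataset(
        cell_ids=cell_ids, gene_ids=gene_ids, peak_ids=peak_ids,
        rna_counts=sp.csr_matrix(rna), atac_counts=sp.csr_matrix(atac),
        cells=cells, genes=genes, peaks=peaks)

    motif_ids, tf_names, pfms = [], [], []
    match = np.zeros((n_p, spec.n_motifs), dtype=bool)
    for m in range(spec.n_motifs):
        g = tf_genes[m]
        motif_ids.append(f"MA{m:04d}.1")
        tf_names.append(gene_ids[g])
        pfm, _ = _random_pfm(rng, int(rng.integers(8, 13)))
        pfms.append(pfm)
        match[motif_members[m], m] = True
    motifs = MotifSet(motif_ids, tf_names, pfms, peak_match=match)

    truth = GroundTruth(
        planted_links=[(peak_ids[p], gene_ids[g]) for p, g in planted_links],
        planted_regulators=motif_ids[: spec.n_planted_regulators],
        true_pseudotime=t,
        true_branch=branch,
        group_shifted_motifs=[motif_ids[shifted_idx]] if n_null > 0 else [],
        tf_gene_map={motif_ids[m]: gene_ids[tf_genes[m]]
                     for m in range(spec.n_motifs)},
    )
    return ds, motifs, truth


def make_promoters(motifs: MotifSet, tf_names, target_genes, length=2_500,
                   n_sites=3, seed=0):
    """Random promoter sequences with planted motif consensus sites.

    For each TF named in ``tf_names``, its consensus is planted in
    ``n_sites`` of the target promoters at recorded offsets. Returns
    (dict gene_id -> sequence, list of (tf_name, gene_id, offset)).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = {g: rng.integers(0, 4, size=length) for g in target_genes}
    plants = []
    for tf in tf_names:
        m = motifs.tf_names.index(tf)
        consensus = np.argmax(motifs.pfms[m], axis=0)
        w = len(consensus)
        for g in rng.choice(list(target_genes), size=min(n_sites, len(target_genes)),
                            replace=False):
            off = int(rng.integers(0, length - w + 1))
            seqs[g][off: off + w] = consensus
            plants.append((tf, g, off))
    return {g: "".join(bases[s]) for g, s in seqs.items()}, plants


def write_fixture(ds: MultiomeDataset, motifs: MotifSet, truth: GroundTruth,
                  out_dir) -> dict:
    """Write all on-disk formats plus ground truth; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = write_multiome(ds, out)
    write_jaspar(motifs, out / "motifs.jaspar")
    payload = json.loads(truth.to_json())
    if motifs.peak_match is not None:
        match = np.asarray(motifs.peak_match)
        payload["motif_peaks"] = {
            mid: [ds.peak_ids[p] for p in np.flatnonzero(match[:, m])]
            for m, mid in enumerate(motifs.motif_ids)}
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
    manifest["files"] += ["motifs.jaspar", "truth.json"]
    write_manifest(manifest, out / "manifest.json")
    return manifest
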