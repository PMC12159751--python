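import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regdyn.config import Config
from regdyn.io import MultiomeDataset
from regdyn.pipeline import link_recovery, run_pipeline
from regdyn.simulate import SyntheticSpec, generate

SMALL_SPEC = SyntheticSpec(n_cells=300, n_genes=250, n_peaks=400, n_motifs=6,
                           n_planted_links=20, n_planted_regulators=2,
                           seed=11)


def make_dataset(rna, atac, *, group=None, cluster=None, pseudotime=None,
                 state=None, gene_meta=None, peak_meta=None):
    """Hand-built MultiomeDataset from dense count arrays."""
    rna = np.asarray(rna)
    atac = np.asarray(atac)
    n_c, n_g = rna.shape
    n_p = atac.shape[1]
    cell_ids = [f"c{i:03d}" for i in range(n_c)]
    gene_ids = [f"g{i:03d}" for i in range(n_g)]
    peak_ids = [f"p{i:03d}" for i in range(n_p)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "group": group if group is not None else ["Ctrl"] * n_c,
        "cluster": cluster if cluster is not None else ["A"] * n_c,
        "pseudotime": pseudotime if pseudotime is not None
        else np.linspace(0, 1, n_c),
        "state": state if state is not None else [1] * n_c,
    }).set_index("cell_id", drop=False)
    if gene_meta is None:
        gene_meta = {}
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": gene_meta.get("chrom", ["chr1"] * n_g),
        "tss": gene_meta.get("tss", np.arange(n_g) * 1_000_000 + 500_000),
        "strand": gene_meta.get("strand", ["+"] * n_g),
        "biotype": gene_meta.get("biotype", ["protein_coding"] * n_g),
        "is_mito": gene_meta.get("is_mito", [False] * n_g),
    }).set_index("gene_id", drop=False)
    if peak_meta is None:
        peak_meta = {}
    start = np.asarray(peak_meta.get(
        "start", np.arange(n_p) * 1_000_000 + 600_000))
    peaks = pd.DataFrame({
        "peak_id": peak_ids,
        "chrom": peak_meta.get("chrom", ["chr1"] * n_p),
        "start": start,
        "end": peak_meta.get("end", start + 500),
        "gc": peak_meta.get("gc", [0.5] * n_p),
    }).set_index("peak_id", drop=False)
    return MultiomeDataset(cell_ids, gene_ids, peak_ids,
                           sp.csr_matrix(rna.astype(np.int64)),
                           sp.csr_matrix(atac.astype(np.int64)),
                           cells, genes, peaks)


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared by read-only tests."""
    return generate(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions, seed 1."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    ds, motifs, truth = default_sim
    res = run_pipeline(ds, motifs, truth.tf_gene_map, Config(), seed=1)
    return res, truth


@pytest.fixture(scope="session")
def multiseed_metrics():
    """Planted-truth recovery metrics of the full pipeline, seeds 1-5.

    Datasets are discarded after each run to bound memory; only the link
    table metrics, regulator table, differential table and truth survive.
    """
    out = []
    for seed in range(1, 6):
        ds, motifs, truth = generate(SyntheticSpec(seed=seed))
        res = run_pipeline(ds, motifs, truth.tf_gene_map, Config(), seed=seed)
        hc = res.links[res.links["high_confidence"]]
        out.append({
            "seed": seed,
            "recovery": link_recovery(res.links, truth.planted_links),
            "hc_abs_pcc": hc["pcc"].abs().to_numpy(),
            "planted_pcc": res.links.merge(
                pd.DataFrame(truth.planted_links,
                             columns=["peak_id", "gene_id"]),
                on=["peak_id", "gene_id"])["pcc"].to_numpy(),
            "regulators": res.regulators,
            "differential": res.differential,
            "truth": truth,
        })
    return out
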