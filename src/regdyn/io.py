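"""On-disk formats and core in-memory containers.

Matrices travel as Matrix Market (cells x features, transposing the 10x
features-x-cells convention on read when needed), tables as TSV with a
header row, peaks as BED (0-based half-open throughout), motifs as JASPAR
PFM text parsed by Biopython.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import motifs as bio_motifs

log = logging.getLogger("regdyn")

BASES = "ACGT"


class FormatError(ValueError):
    """A file's contents contradict its declared structure."""


@dataclasses.dataclass
class MultiomeDataset:
    """Paired RNA/ATAC count matrices with cell, gene and peak metadata.

    ``rna_counts`` is cells x genes, ``atac_counts`` cells x peaks, both
    non-negative integer CSR. ``cells`` carries group / cluster / pseudotime
    / state columns (pseudotime and state may be NaN for cells off the
    trajectory); ``genes`` carries chrom / tss / strand / biotype / is_mito;
    ``peaks`` carries chrom / start / end / gc.
    """

    cell_ids: list
    gene_ids: list
    peak_ids: list
    rna_counts: sp.csr_matrix
    atac_counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n_c, n_g, n_p = len(self.cell_ids), len(self.gene_ids), len(self.peak_ids)
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids),
                          ("peak", self.peak_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids")
        if self.rna_counts.shape != (n_c, n_g):
            raise FormatError(
                f"rna_counts shape {self.rna_counts.shape} != ({n_c}, {n_g})")
        if self.atac_counts.shape != (n_c, n_p):
            raise FormatError(
                f"atac_counts shape {self.atac_counts.shape} != ({n_c}, {n_p})")
        for name, mat in (("rna", self.rna_counts), ("atac", self.atac_counts)):
            if mat.size and mat.data.min() < 0:
                raise FormatError(f"{name} counts contain negative values")
        if len(self.cells) != n_c or len(self.genes) != n_g or len(self.peaks) != n_p:
            raise FormatError("metadata table lengths do not match id lists")
        pk = self.peaks
        if len(pk) and not (pk["start"] < pk["end"]).all():
            raise FormatError("peak with start >= end")
        if len(pk) and not pk["gc"].between(0, 1).all():
            raise FormatError("peak gc outside [0, 1]")
        gn = self.genes
        if len(gn) and not gn["strand"].isin(["+", "-"]).all():
            raise FormatError("gene strand must be + or -")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask_or_ids) -> "MultiomeDataset":
        """Row-subset both assays and the cell table, preserving order."""
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = [self.cell_ids.index(c) for c in mask_or_ids]
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return MultiomeDataset(
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=self.gene_ids,
            peak_ids=self.peak_ids,
            rna_counts=self.rna_counts[idx],
            atac_counts=self.atac_counts[idx],
            cells=self.cells.iloc[idx].copy(),
            genes=self.genes,
            peaks=self.peaks,
        )


@dataclasses.dataclass
class MotifSet:
    """TF motifs: position frequency matrices plus optional peak membership.

    Each PFM is a 4 x width array in A,C,G,T row order; ``peak_match`` is a
    peaks x motifs boolean matrix when motif-in-peak annotation is known.
    """

    motif_ids: list
    tf_names: list
    pfms: list  # of (4, width) float arrays
    peak_match: np.ndarray | sp.spmatrix | None = None

    def __post_init__(self):
        for mid, pfm in zip(self.motif_ids, self.pfms):
            pfm = np.asarray(pfm, dtype=float)
            if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] == 0:
                raise FormatError(f"motif {mid}: PFM must be 4 x width>=1")
            if (pfm.sum(axis=0) <= 0).any():
                raise FormatError(f"motif {mid}: PFM column with zero total")
        if self.peak_match is not None:
            pm = self.peak_match
            if pm.shape[1] != len(self.motif_ids):
                raise FormatError("peak_match column count != number of motifs")

    def __len__(self) -> int:
        return len(self.motif_ids)


# ---------------------------------------------------------------------------
# readers / writers


def _read_ids(path: Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != f"{what}_id":
        raise FormatError(f"{path}: first column must be '{what}_id'")
    return df


def read_multiome(rna_mtx, atac_mtx, cells_tsv, genes_tsv, peaks_bed) -> MultiomeDataset:
    """Read a paired dataset; cell order is shared by both matrices.

    Matrices are stored cells-as-rows. Dimension mismatches raise a
    FormatError naming the offending file.
    """
    rna = sp.csr_matrix(scipy.io.mmread(rna_mtx))
    atac = sp.csr_matrix(scipy.io.mmread(atac_mtx))
    cells = _read_ids(Path(cells_tsv), "cell")
    genes = _read_ids(Path(genes_tsv), "gene")
    peaks = read_peaks_bed(peaks_bed)

    if rna.shape[0] != len(cells):
        raise FormatError(
            f"{rna_mtx}: {rna.shape[0]} cell rows but {cells_tsv} lists {len(cells)}")
    if rna.shape[1] != len(genes):
        raise FormatError(
            f"{rna_mtx}: {rna.shape[1]} gene cols but {genes_tsv} lists {len(genes)}")
    if atac.shape[0] != len(cells):
        raise FormatError(
            f"{atac_mtx}: {atac.shape[0]} cell rows but {cells_tsv} lists {len(cells)}")
    if atac.shape[1] != len(peaks):
        raise FormatError(
            f"{atac_mtx}: {atac.shape[1]} peak cols but {peaks_bed} lists {len(peaks)}")

    cell_table = cells.set_index("cell_id", drop=False)[
        ["cell_id"] + [c for c in ("group", "cluster", "pseudotime", "state")
                       if c in cells]]
    gene_table = genes.set_index("gene_id", drop=False)[
        ["gene_id"] + [c for c in ("chrom", "tss", "strand", "biotype",
                                   "is_mito") if c in genes]]
    if "is_mito" in gene_table:
        gene_table["is_mito"] = gene_table["is_mito"].astype(bool)
    return MultiomeDataset(
        cell_ids=list(cells["cell_id"]),
        gene_ids=list(genes["gene_id"]),
        peak_ids=list(peaks["peak_id"]),
        rna_counts=rna.astype(np.int64),
        atac_counts=atac.astype(np.int64),
        cells=cell_table,
        genes=gene_table,
        peaks=peaks.set_index("peak_id", drop=False),
    )


def read_peaks_bed(path) -> pd.DataFrame:
    """BED with 0-based half-open intervals; score column carries GC fraction."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise FormatError(f"{path}: need >= 4 BED columns (chrom start end name)")
    out = pd.DataFrame({
        "peak_id": df[3].astype(str),
        "chrom": df[0].astype(str),
        "start": df[1].astype(int),
        "end": df[2].astype(int),
        "gc": df[4].astype(float) if df.shape[1] > 4 else 0.5,
    })
    return out


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    cols = peaks[["chrom", "start", "end", "peak_id", "gc"]].copy()
    cols["strand"] = "."
    cols.to_csv(path, sep="\t", header=False, index=False, float_format="%.12g")


def write_multiome(ds: MultiomeDataset, out_dir) -> dict:
    """Write all components; returns a manifest of file names and totals."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "rna.mtx", sp.coo_matrix(ds.rna_counts), field="integer")
    scipy.io.mmwrite(out / "atac.mtx", sp.coo_matrix(ds.atac_counts), field="integer")
    cells = ds.cells.reset_index(drop=True)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False, float_format="%.12g")
    ds.genes.reset_index(drop=True).to_csv(
        out / "genes.tsv", sep="\t", index=False, float_format="%.12g")
    write_peaks_bed(ds.peaks, out / "peaks.bed")
    manifest = {
        "files": ["rna.mtx", "atac.mtx", "cells.tsv", "genes.tsv", "peaks.bed"],
        "n_cells": ds.n_cells,
        "n_genes": len(ds.gene_ids),
        "n_peaks": len(ds.peak_ids),
        "rna_total": int(ds.rna_counts.sum()),
        "atac_total": int(ds.atac_counts.sum()),
    }
    return manifest


def read_jaspar(pfm_path) -> MotifSet:
    """Parse JASPAR-format PFMs (``>ID NAME`` headers, four base rows)."""
    text = Path(pfm_path).read_text()
    if not text.strip():
        log.warning("empty JASPAR file %s", pfm_path)
        return MotifSet([], [], [])
    try:
        records = bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # Biopython raises bare Exceptions on bad rows
        raise FormatError(f"{pfm_path}: cannot parse JASPAR records: {exc}") from exc
    ids, names, pfms = [], [], []
    for m in records:
        ids.append(m.matrix_id)
        names.append(m.name)
        pfms.append(np.array([m.counts[b] for b in BASES], dtype=float))
    return MotifSet(ids, names, pfms)


def write_jaspar(motifs: MotifSet, path) -> None:
    lines = []
    for mid, name, pfm in zip(motifs.motif_ids, motifs.tf_names, motifs.pfms):
        lines.append(f">{mid} {name}")
        for b, row in zip(BASES, pfm):
            lines.append(f"{b} [ " + " ".join(f"{v:.6g}" for v in row) + " ]")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
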