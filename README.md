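# regdyn

Regulatory-dynamics analysis for paired single-cell multiome (scRNA +
scATAC) data along differentiation trajectories, built for studying how
inflammatory conditions skew hematopoietic stem/progenitor (HSPC) fate —
e.g. a neutrophil-lineage bias in a ligature-induced periodontitis (LIP)
model versus control. Trajectory inference, dimensionality reduction and
clustering happen upstream; `regdyn` consumes count matrices plus per-cell
pseudotime/state labels and carries out the downstream regulatory analyses:

1. **QC and markers** — joint cell filtering (detected genes ≥ 200,
   mitochondrial fraction ≤ 25%, ATAC counts in [1 000, 50 000]) and
   one-vs-rest Wilcoxon cluster markers (ln FC > 0.25, min.pct > 0.25).
2. **Pseudobulk series** — cells sorted by pseudotime and summed in blocks
   of 50 for both assays, CPM-normalized; 50-bin stacked lineage-fate
   composition per group (myeloid fate = trajectory states {1,3,4,5},
   lymphoid = {1,3,4,6}).
3. **Peak-to-gene links** — for peaks 1–250 kb from a marker gene's TSS,
   Pearson r between CPM accessibility and CPM expression across the
   pseudobulk series; pairs with |r| ≥ 0.3 and P < 0.05 (two-sided t on
   n−2 df) are high-confidence links, k-means-clustered (k = 6) on
   z-scored gene profiles, with hypergeometric motif enrichment per
   cluster.
4. **Motif deviations** — chromVAR-style bias-corrected accessibility
   deviations: for motif peak set *M* and sample *i*, the raw deviation is
   (o_i − x_i)/x_i with x_i the depth-scaled expected count, z-scored
   against deviations of GC/mean-accessibility-matched background peak
   sets; plus per-motif variability, pairwise synergy/correlation, and
   group-wise differential deviation (Wilcoxon + BH).
5. **Positive TF regulators** — accessibility-derived gene scores
   (exponentially distance-decayed CPM within 100 kb of the TSS) correlated
   with the TF's own motif deviation along pseudotime; r ≥ 0.5 at
   BH-FDR < 0.05 calls a positive regulator.
6. **TF–target network** — PFM → log-odds PWM promoter scanning (TSS
   −2000/+500, both strands), keeping matches with relative score > 0.85
   and log-odds > 8.

Because no public accession accompanies the motivating dataset, the package
ships a first-class synthetic generator (`regdyn.simulate`) that emulates a
bifurcating HSPC trajectory with group-dependent branch bias, NB expression
programs, Poisson peak accessibility, and planted ground truth (links,
regulators, a group-shifted motif), so every stage is validated against
recoverable truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic conditions (2 000 cells, 500 genes, 5 000 peaks, 200 planted
links, 20 motifs with 3 planted regulators, branch bias Ctrl 0.4 / LIP
0.8, seed 1) and write their tables under `results/`:

```text
$ python analysis/01_simulate.py
wrote fixture to scratch/fixture; {'n_cells': 2000, ..., 'planted_regulators': ['MA0000.1', 'MA0001.1', 'MA0002.1'], ...}
$ python analysis/02_qc_markers.py
QC kept 2000/2000 cells; 343 marker genes across 6 clusters
$ python analysis/03_pseudobulk_fates.py
40 pseudobulk samples; LIP myeloid fraction exceeds Ctrl in 25/25 terminal bins
$ python analysis/04_link_peaks.py
543 candidate pairs -> 209 high-confidence links; recall 1.00, precision 0.96 vs 200 planted links; ...
$ python analysis/05_motif_deviations.py
most variable motifs: ['MA0002.1', 'MA0001.1', 'MA0000.1'] (planted: ['MA0000.1', 'MA0001.1', 'MA0002.1']); top differential motif MA0003.1 (delta 8.04, planted shifted: ['MA0003.1'])
$ python analysis/06_regulators_network.py
4 positive regulators ['MA0000.1', 'MA0001.1', 'MA0002.1', 'MA0005.1'] (planted: ['MA0000.1', 'MA0001.1', 'MA0002.1']); network: 7 edges for gene0264, 3 planted sites
```

Reading the output: all 200 planted enhancer–gene pairs are recovered as
high-confidence links with 96% precision; the three planted positive
regulators are exactly the three most variable motifs and head the
positive-regulator calls (the fourth call, MA0005.1, is a borderline null
— one false call among 17 nulls is what an FDR-controlled procedure is
allowed); the motif planted with a case-group accessibility boost is the
top differential hit; and the case group's myeloid-branch proportion
dominates every terminal pseudotime bin, reproducing the fate-bias readout
the stacked plots are designed to show.

The same stages are scriptable via the thin CLI
(`regdyn simulate|qc|markers|pseudobulk|fates|run`), which reads/writes the
on-disk formats (Matrix Market + TSV + BED + JASPAR).

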