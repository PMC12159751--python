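# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Data model and conventions

A `MultiomeDataset` holds a cells×genes RNA count matrix and a cells×peaks
ATAC count matrix over one shared cell order, with per-cell metadata
(group, cluster, pseudotime, trajectory state), gene annotation (chrom,
TSS, strand, biotype, mitochondrial flag) and peak intervals (BED 0-based
half-open) carrying a GC fraction. Pseudotime and state labels are inputs:
trajectory inference is out of scope. All randomized stages take an
explicit integer seed; with a fixed seed the whole pipeline is
byte-reproducible (asserted in tests).

Coordinates: peak anchors are interval midpoints; gene anchors are a
single TSS coordinate; distances are signed by strand (positive =
downstream). The on-disk peak convention (0-based half-open) is an
assumption — upstream tools rarely state theirs — and is applied
uniformly, so no off-by-one can accumulate across stages.

## QC and markers

Cells are kept when detected genes ≥ 200 AND mitochondrial fraction ≤ 0.25
AND total ATAC counts within [1 000, 50 000]. The strict inequalities
mirror the thresholds as printed ("< 200", "> 25%", "< 1 000",
"> 50 000"): a cell sitting exactly on a boundary is retained. ATAC
column sums stand in for fragment counts, since fragment files are not an
input. Filtering is idempotent.

Markers are one-vs-rest per cluster: two-sided Wilcoxon rank-sum on
log1p(CPM/100) expression, reported when ln((mean_in+1)/(mean_out+1)) >
0.25 and the expressing fraction exceeds 0.25 in either population
(the documented "min.pct in either" semantics), BH-adjusted across genes
within each cluster. Per-cluster (not global) BH is a choice; it matches
how per-cluster marker tables are consumed downstream.

## Pseudobulk series and fate stacks

Trajectory cells are sorted by pseudotime (ties broken by cell id for
determinism) and summed in consecutive blocks of 50 for both assays; a
trailing block of < 25 cells is merged into the previous one, bounding
sample-size heterogeneity at 2×. Each sample is CPM-normalized (row total
10^6). Pseudobulks are built on cells pooled across groups so both groups
share one pseudotime axis; a per-group mode is a one-line subset upstream.

Fate composition restricts to cells whose state lies in a fate set
(myeloid {1,3,4,5}, lymphoid {1,3,4,6}), divides the pooled pseudotime
range into 50 equal-width bins, and reports per (group, bin) the cluster
proportions; empty bins are flagged rather than interpolated. For the
"myeloid fraction" readout the states are pooled (both fates), since
within a single fate subset terminal bins are trivially single-branch.

## Peak-to-gene linking

Candidates are (peak, gene) pairs on one chromosome with the peak midpoint
1–250 kb (inclusive both ends) from the TSS of a protein-coding or lincRNA
marker gene. Each pair gets the Pearson r between the peak's CPM
accessibility and the gene's CPM expression across the pseudobulk series,
with the two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. High confidence
⇔ |r| ≥ 0.3 AND p < 0.05; link p-values are deliberately not
multiplicity-corrected (the analysis style this reimplements uses a raw
threshold). Constant profiles are dropped with a reason code.

High-confidence links are clustered by k-means (k = 6, k-means++, 10
restarts, seeded) on the z-scored (per link: mean 0, sd 1 across samples)
expression profile of the linked gene; expression-only clustering is used
because the element clusters are read through their genes' dynamics.
Clusters are renumbered 1..k by the pseudotime position of the mean
profile's maximum, so cluster order follows differentiation. Motif
enrichment per cluster is a one-sided hypergeometric test of motif-bearing
peaks among the cluster's peaks versus all linked peaks, BH within
cluster.

## Motif deviations

For motif peak set M and sample i: raw deviation = (o_i − x_i)/x_i, where
o_i is the summed count in M and x_i = depth_i · Σ_{p∈M} e_p with e_p the
peak's share of all counts. This is exactly zero for the all-peaks set and
invariant to global count rescaling; rescaling a single sample perturbs e
and hence the deviations only marginally (the stated formula takes
precedence over exact single-sample invariance).

Bias correction: each peak receives 50 background draws sampled (with
replacement, never itself) from its k nearest neighbors in standardized
(GC, log1p mean accessibility) space — k = 5% of peaks, at least
n_bg — weighted by a Gaussian kernel on neighbor distance (σ = the
neighbor-distance median). For background iteration b, every member peak
is replaced by its b-th draw; z_i = (raw_i − mean_b)/sd_b. Variability is
the sd (ddof 1) of z across samples. Degenerate features fall back to
uniform sampling with a warning.

Synergy(A,B) z-scores the variability of the A∩B peak set against 100
random same-size subsets of A∪B (NA when |A∩B| < 5); correlation(A,B) is
the Pearson r of the two z profiles. This follows the published concept
(excess variability of shared peaks) but is specified self-containedly;
numerical parity with any particular implementation is a non-goal.

Differential deviation contrasts group means of z per motif with a
two-sided Wilcoxon rank-sum across samples, BH across motifs. It defaults
to per-cell deviations (case/control volcano over cells); the
pseudotime analyses use pseudobulk deviations.

## Gene scores and regulator matching

The accessibility gene score of gene g in sample i is
log1p(Σ_p exp(−d_p/5000)·CPM_ip) over peaks within 100 kb of the TSS
(d_p = TSS-to-midpoint distance). Window 100 kb, decay 5 kb and the log1p
are this package's own parameterization of "gene scores from peak
accessibility" and are exposed in config. A TF is a positive regulator
when the Pearson r between its motif's deviation z profile and its own
gene-score profile is ≥ 0.5 with BH-FDR < 0.05 across motifs; the
thresholds mirror common practice for this analysis style and are
configurable.

## Promoter network

Promoter windows span 2 000 bp upstream to 500 bp downstream of the TSS,
strand-aware and clipped at zero, always 2 500 bp when unclipped. PFMs
become log2-odds PWMs via (count + 0.8·0.25)/(colsum + 0.8)/0.25 —
pseudocount 0.8 with uniform background, the common JASPAR-processing
convention. Both strands are scanned; windows containing N are skipped.
"Homology" is the min–max relative score, "binding score" the raw
log-odds sum; an edge requires relative score > 0.85 AND log-odds > 8,
both strict. The target gene set (a pathway list in the motivating
analysis) is supplied as a plain gene list; synthetic fixtures ship their
own list, so no ontology access is needed.

## Synthetic data: what it emulates, what it does not

Each cell draws latent time t ~ U(0,1) and a branch (myeloid/lymphoid)
with group-dependent probability (Ctrl 0.4, LIP 0.8 by default). Genes
follow smooth logistic-ramp or Gaussian-bump programs in (t, branch);
RNA counts are negative binomial with shared dispersion 0.3 around
depth·μ, per-cell depth LogNormal around 2 000. Observed pseudotime is t
plus N(0, 0.02) noise, re-ranked onto [0,1]. States follow a trunk
1→3→4 with terminal 5 (myeloid) or 6 (lymphoid); clusters are
LSK → CMP/CLP → GMP → NeuP / pro_B by (t, branch).

Peaks live on one synthetic chromosome with one gene per 600 kb territory
(so a planted enhancer can only be a candidate of its own gene), and ATAC
counts are Poisson at per-cell normalized rates with depth LogNormal
around 10 000. Planted-link peaks track their partner gene's program at
`link_effect` (0.9 default) plus a constant floor; decoy peaks are
time-constant and placed inside the 1–250 kb window, under 1 kb, just
outside 250 kb, and in a gene-free desert, exercising the distance filter
in both directions. Peak GC is Beta(5,5), independent of dynamics.

Motif peak sets: planted regulators get ≥ 80% member peaks that track the
TF's own gene program (a few at the TF's promoter, so the gene score moves
with the deviation) and the remainder drawn from planted-link peaks of
co-regulated genes (so link clusters show motif enrichment); planted
regulator programs alternate rising/falling, guaranteeing an
anti-correlated pair. Tracking peaks follow the program at reduced
per-peak amplitude: since a motif's deviation aggregates ~100 peaks the
motif-level signal is unaffected, while the genome-wide accessibility
composition stays balanced — otherwise every time-constant peak would
inherit a spurious pseudotime trend through CPM/expectation normalization,
violating the design requirement that non-planted peaks are independent of
any gene. One non-regulator motif's member peaks are uniformly boosted
(+60%) in the case group, planting a differential-deviation hit.

Not emulated: real genome sequence and motif occurrences in peaks (peak
membership is assigned, not scanned), doublets, ambient contamination,
batch effects, fragment-level ATAC structure, and branch-dependent linking
(planted programs are branch-shared so pooled pseudobulks see them
cleanly). Passing tests therefore demonstrate correctness and statistical
calibration of the stages under a controlled generative model — not
robustness to every artifact of real multiome data.

## Problem sizes and runtime

Default conditions (2 000 cells / 500 genes / 5 000 peaks / 20 motifs /
50 backgrounds) run the full pipeline in ~10–15 s; the test suite runs
five such seeds plus toys in about a minute. Tolerances: oracle
equivalence at ≤ 1e-9, CPM sums at float tolerance, correlation PSD at
−1e-8. Ties in pseudotime and k-means initialization are seeded/broken
deterministically, so identical seeds give identical outputs.

## Known limitations

- Wilcoxon p-values are asymptotic for groups larger than scipy's exact
  regime; at per-cell sample sizes minute effects become significant, so
  differential results should be read jointly with the effect size
  (delta).
- The synergy resampling null is conditional on the realized peak sets
  and backgrounds; scores are comparable within a run, not across runs
  with different background seeds.
- Gene scores use a single decay form; alternatives (flat windows,
  model-based weights) would need only a new weight function but are not
  implemented.
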