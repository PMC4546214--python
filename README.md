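# xcidyn

Allele-specific RNA-seq analysis of X-chromosome inactivation (XCI)
dynamics, for transcriptomics groups working with hybrid female mouse ESC
systems (e.g. 129 × Cast crosses with forced inactivation of one X).

During differentiation of female embryonic stem cells one X chromosome is
transcriptionally silenced. When the two X chromosomes are distinguishable
at ~1 SNP / 300 bp, RNA-seq reads can be assigned to the future inactive X
(Xi) and active X (Xa), turning silencing into a measurable per-gene
quantity. This package implements that analysis end to end:

* **Allelic quantification** — per-site 129/Cast counts are pooled over
  exons; a gene is quantified when (i) both alleles accumulate >80 counts
  over the differentiation course, (ii) its per-site allelic ratios are
  consistent (standard error of the mean ≤ 0.1), and (iii) its mean
  expression exceeds 0.5 RPKM. The relative contribution
  `rel₁₂₉ = c₁₂₉ / (c₁₂₉ + c_Cast)` times the total RPKM gives absolute
  allelic expression.
* **Silencing kinetics** — per-gene trajectories
  `Δ(t) = log₂(Xi/Xa)(t) − log₂(Xi/Xa)(0)` are clustered (K-means, k = 4)
  into early / intermediate / late / not-silenced groups; each group is
  tested for proximity to the X-inactivation center (XIC) with an
  unweighted GSEA running-sum rank statistic against a label-permutation
  null (mid-p, BH-corrected), plus a cubic positional trend of the day-2
  deltas and notched-boxplot (McGill, 1.58·IQR/√n) comparisons of
  expression strata and Xa upregulation.
* **Escape calling** — in lines with completed XCI a gene escapes when ≥2
  polymorphic sites show Xi signal, >2 counts come from the Xi, and the Xi
  is expressed at >10 % of the Xa level (log₂ Xi/Xa > −3.32). Runs of ≥3
  consecutive escaping genes with no informative silenced gene in between
  form escape regions. Allelic-bias (imprinting-style) calls in
  undifferentiated cells use per-site exact binomial tests.
* **Hi-C / TADs** — 40-kb contact matrices, iterative proportional fitting,
  the directionality index DI = sign(B−A)·((A−E)² + (B−E)²)/E over a 2-Mb
  window, 3-state HMM segmentation into topologically associating domains,
  allele-specific matrices, replicate correlations, and per-TAD homogeneity
  of escape status.
* **Synthetic data** — a seeded generator plants known silencing kinetics
  (exponential Xi-fraction decay with distance-to-XIC and expression-level
  dependence, calibrated to 46 % mean day-2 silencing), escape regions
  occupying whole TADs, NPC-like lines in which ~70 % of silenced genes
  show zero Xi tags, and block-structured Hi-C matrices — so every stage is
  verifiable against ground truth without any external download.

## Worked example

A complete seeded run — simulate, quantify, cluster, call escape, call TADs
and summarize — from the command line:

```console
$ xci run-all --seed 1 --outdir run/
run complete: 30 outputs in run/ (seed 1)
$ xci report --rundir run/
== report_clusters.tsv
#cluster      n_genes  mean_dist_xic  gsea_p     gsea_q
late          86       5709675.1      0.00025    0.00025
early         84       2192402.1      0.00025    0.00025
intermediate  84       3509745.0      0.00025    0.00025
not_silenced  45       7333854.4      0.00025    0.00025
== report_escape.tsv
#line        n_informative  n_escape  n_regions  zero_xi_fraction_subject
*NPC_129-Xi  299            46        3          0.696
NPC_Cast-Xi  299            34        2          0.645
NPC_129-Xi   299            7         0          0.736
== report_concordance.tsv
#n_scored_tads  n_homogeneous  boundary_overlap_full_vs_allelic
20              14             1.0
```

Reading the output: the four kinetic clusters sit at increasing mean
distance from the XIC (2.2 → 7.3 Mb from early to not-silenced) and every
cluster's positional enrichment is significant (q < 0.05) — silencing
propagates outward from the XIC. In the NPC-like lines, 46/34/7 genes
escape XCI, forming 3/2/0 contiguous escape regions, and ~70 % of silenced
genes show zero Xi tags. All 20 scored TADs against the allele-specific
matrix share boundaries within one 40-kb bin.

The same stages are available as library functions
(`xcidyn.simulate`, `.quantify`, `.dynamics`, `.escape`, `.tads`) and as
standalone subcommands (`xci simulate|quantify|dynamics|escape|tads`) that
operate on the TSV/BED/WIG files of any earlier stage.

The package also ships the published table of escape genes in three
NPC lines (`xcidyn.io.load_table1_fixture()`): per gene the printed
log₂ Xi/Xa ratio per line, escape status, distal-region membership and
Sanger-validation flag, used to audit the ratio classifier.

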