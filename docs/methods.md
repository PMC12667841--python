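# Methods

## The problem

Loss of nuclear TDP-43 — the hallmark of ALS and most FTLD — de-represses
*cryptic exons* (CEs): unannotated splicing outcomes that are near-absent in
healthy tissue and appear when TDP-43 is depleted. `crypticburden`
re-implements, as a reusable library, the analysis chain that turns splice
junction counts into (i) CE calls, (ii) NMD-sensitivity, localisation and
dose-responsiveness classes per CE, (iii) per-junction biomarker statistics,
and (iv) a per-sample composite *cryptic burden* score, plus the sequence
features (UG repeats, TDP-43 binding-motif classes, CLIP-peak profiles) that
separate early- from late-responsive events.

## Core definitions and rules

**PSI.** For junction *j* in cluster *c* and sample *s*,
`PSI(j, s) = count(j, s) / total_c(s)`; PSI is missing when the cluster has
fewer than `min_cluster_reads` (default 15) reads in that sample. Fifteen
reads keep the binomial standard error of a PSI of 0.5 below ~0.13. Junction
clusters follow the LeafCutter relaxed filter: a junction is dropped when it
carries less than a 1e-4 fraction of its cluster's reads (summed over
samples).

**CE call.** A junction is a cryptic splicing event when its category is not
`annotated`, its control group-mean PSI is `< 0.05`, and condition-minus-
control mean PSI is `> 0.10` (both strict). Group means are unweighted over
samples with defined PSI. Categories against a GTF follow the DASPER-style
vocabulary (`annotated`, `novel_acceptor`, `novel_donor`, `novel_exon_skip`,
`novel_combo`, `ambig_gene`, `none`), resolved strand-aware against each
gene's annotated donor/acceptor sites. Adjacent `novel_acceptor` +
`novel_donor` events flanking a common unannotated exonic interval of
1–10,000 bp are fused into one cassette event; others carry a
single-junction flag.

**NMD.** Rescue is thresholded on group-mean PSI:
`rescued iff PSI(KD+NMDi) − PSI(KD) > 0.05` (absolute PSI points, strict).
A *dark* cryptic meets CE criteria only under NMD inhibition; it is *true
dark* when its exact coordinates match no CE in any reference knockdown
dataset lacking NMD inhibition. Localisation is
`log2((nuclear + 0.5) / (cytoplasmic + 0.5))` after independent
median-of-ratios normalisation of each fraction.

**Dose staging.** With knockdown levels 1..K beyond the untreated control:
*early* iff mean PSI ≥ 0.20 at level 1 or 2; *late* iff PSI < 0.10 at every
level except the strongest and ≥ 0.10 there; otherwise *intermediate*.
Events need ≥ 5 junction-spanning reads at some level on every defining
junction (both sides for cassettes). "Reached" is read inclusively.

**Biomarkers and burden.** Per dataset, PSI is z-scored per junction across
all samples (missing PSI imputed to 0 first — an uncovered cluster carries
zero supporting reads; sample sd, n−1). Threshold zero — the cohort mean —
turns each junction into a classifier: positive iff z > 0 (z = 0 counts
negative). AUC is the rank statistic `P(case > control) + ½ P(tie)`.
A junction is *predictive* iff FPR ≤ 0.10, TPR ≥ 0.10 and it is detected
(≥ 2 reads) in ≥ 5 distinct proteinopathy samples; the burden of a sample is
the sum of its z-scores over the dataset's predictive junctions.

**Sequence features.** UG density counts overlapping TGTGTG windows within
one mismatch, divided by sequence length (on a perfect (TG)^k repeat this is
exactly (k−2)/2k). Hexamer classes YG / YA / AA are counted as overlapping
exact matches per kilobase. Class enrichment between groups uses a
two-sided Fisher exact test on present/absent per sequence with BH
correction; fold change is the ratio of mean per-kb frequencies. Binding
profiles report the fraction of junctions covered by a (merged; touching
intervals fuse) CLIP peak at each offset within ±500 bp of a splice site in
transcript orientation, the bound fraction within 250 bp, and the
nucleotide probability matrix of the first 50 intronic bases past the donor.

## Synthetic data: what it emulates, and what it does not

All generators share one integer seed; each stage draws from an independent
substream keyed by a hash of its name, so adding a stage never perturbs
earlier draws. Counts follow a hierarchical model: per-sample cluster depth
~ NegBin(mean 100, dispersion 10), inclusion reads ~ Binomial(depth, PSI),
baseline inclusion ~ Beta(1, 99) (mean 1% — repressed CEs). Each cluster is
minimal: one inclusion and one exclusion junction sharing a donor.

* **Cohort** (40 cases / 40 controls, 200 clusters, 15% carrying CEs):
  penetrant case samples (Bernoulli 0.5 per case) gain +0.2 PSI. The planted
  per-CE true-positive rate at the cohort-mean threshold is therefore the
  penetrance.
* **Dose series**: latent PSI follows a Hill curve
  `psi(dose) = psi_max / (1 + (ec50/dose)^h)` with `psi_max = 0.5`, `h = 6`,
  dose value = level index (1..5), and ec50 cycling through (0.8, 2.5, 6.0)
  — one value per staging class, with latent margins of several binomial
  standard errors at depth 200. Truth labels come from applying the
  package's own staging rule to the noiseless curve, so zero-noise recovery
  is exact by construction and noisy recovery measures counting error only.
* **NMD experiment**: degradation acts on isoform abundance before PSI is
  formed, giving the competition renormalisation
  `psi' = psi(1−d) / (psi(1−d) + 1−psi)` — the source of the nonlinear
  masking of cryptic inclusion. Events are NMD-sensitive with probability
  0.5 (d = 0.8) or insensitive (d = 0, e.g. frame-preserving events);
  knockdown inclusion is U(0.15, 0.5). This keeps latent rescue deltas away
  from the 5% decision boundary, so recovery failures indicate bugs rather
  than boundary noise.
* **Fractionation**: each gene draws log2 N/C ~ Normal(0, 1) shared by its
  annotated and CE isoforms; active NMD multiplies cytoplasmic CE abundance
  by (1 − d_g) with per-event efficacy d_g ~ Beta(d·c, (1−d)·c), c = 2.
  Per-event variability is essential: a constant d is a monotone shift of
  the log-ratio and would leave the CE-vs-annotated rank correlation at 1.
  With d = 0.9 the Beta(1.8, 0.2) efficacy spread (sd of log2 survival ≈ 7)
  swamps the 1-unit localisation signal, collapsing the correlation; NMD
  inhibition (or d = 0) restores it. Poisson counts at expected depth 10⁴.
* **Sequences**: i.i.d. background at 40% GC; "early" junctions receive an
  uninterrupted (TG)₂₀ run 5 bp into the intron, "late" junctions the same
  run with dinucleotides replaced by AA at rate 1/3 (interruptions generate
  AA-class hexamers such as GTGTGA/TGAATG at the splice of each break);
  CLIP peaks cover the runs with ≤ 10 bp jitter.

Not modelled: read-level artifacts, alignment bias, batch effects beyond
per-sample depth, full splice graphs, gene-expression confounding. A green
recovery test therefore establishes that the decision rules are implemented
correctly and are robust to counting noise at the stated depths — not that
they would survive postmortem-tissue artifacts.

## Numerical choices

* Missing PSI → 0 before z-scoring (configurable); a constant junction
  (sample sd ≤ 1e-12, the floating-point floor for a [0,1] variable) is
  flagged degenerate and contributes 0 to every burden.
* All interval arithmetic is 0-based half-open; GTF is converted on ingest.
  Touching intervals merge (collapsed binding regions keep no zero-gap
  seams).
* Fisher p-values use the point-probability two-sided rule (sum of
  hypergeometric outcomes no more probable than observed); a zero margin
  yields p = 1 with undefined odds ratio. BH is the step-up procedure.
* Spearman p: exhaustive permutation for n ≤ 10, t-approximation above.
  Mann-Whitney: exact when min(n) ≤ 8 without ties, else normal
  approximation with tie correction.
* Ties at the z = 0 threshold classify negative (conservative; the rule's
  tie handling is otherwise unspecified).
* Strand "." junctions are classified against gene strand; conflicts or
  multi-gene ambiguity yield `ambig_gene`, and strand-dependent profile
  operations exclude such junctions with a logged count.

## Known limitations

Cluster-ratio PSI stands in for splice-graph PSI (MAJIQ-style local splice
variations are out of scope), so complex events sharing partial reads are
approximated. Cassette pairing uses a coordinate heuristic (1–10,000 bp
putative exon), not transcript reconstruction. True-dark matching is exact
on coordinates; alignment-shifted junctions would need external
normalisation. The burden score is per-dataset by construction and is not
comparable across datasets without harmonisation.
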