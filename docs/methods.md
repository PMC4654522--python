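# Methods

## Quantitation model

Each labelling group is an 8-plex isobaric run in which reporter channels
114/115/116 carry the three developmental stages of one tissue and channel 113
carries a common control sample.  For protein *p* and sample *s* (with group
*g(s)* and reporter channel *c(s)*),

    r(p, s) = I_{c(s)}(p) / I_113(p)        within group g(s),

where *I* are reporter peak-area integrals.  Cells are masked (never imputed)
when the protein has no record in the sample's group, the control intensity is
zero, or the reporter intensity is zero.  No normalisation (median-centering,
channel-bias or isotope-impurity correction) is applied by default because the
quantitation model defines none; the ratio matrix's metadata records the
assumption that channel 113 carries the same reference sample in both groups —
the only reading under which cross-tissue ratios such as N4/N1 (quotients of
control-channel ratios across groups) are well defined.

**Identification criterion.** A protein is "identified" at a (tissue, stage)
when its record passes both FDR filters (protein and peptide FDR ≤ 0.05,
boundary inclusive) and has a strictly positive reporter intensity in that
stage's channel together with a positive control intensity.  The presence
criterion is a package decision: the upstream search engine's own presence
semantics are not recoverable from a flat quantitation table.

**Differential expression.** Fold ratios between two samples are compared to
fixed thresholds: up iff fold ≥ 1.5, down iff fold ≤ 0.67, on the stored
floating value.  0.67 is used literally rather than 1/1.5, so reversing a
contrast swaps up and down only outside the narrow band (1/1.505, 1/1.49);
the tests document this asymmetry.  There is no replicate-based variance
model — calls are threshold-only by design.

## Set analytics

Venn decomposition over the three stages of a tissue is exact 7-cell set
algebra on accession strings (case-sensitive, no gene-model collapsing).
Tissue specificity operates on the per-tissue stage unions; the three output
sets partition the overall nonredundant union by construction.  The
cross-method overlap percentage is `100 * |shared| / |query list|` rounded to
two decimals (used to compare an orthogonal 2DE spot list against the
isobaric identifications).

## Clustering

Profiles are log2 ratios over the six samples.  Proteins with any masked cell
or zero profile variance (Pearson correlation undefined) are excluded and
reported.  Distance is 1 − Pearson r; linkage is average (UPGMA).  These are
configurable because the classic Cluster 3.0 lineage of tools exposes several
metrics and none is canonical.  Leaves are ordered lexicographically before
linkage and Newick children are ordered by smallest leaf label, so the tree
is a pure function of the profile set, independent of input order.

## Regulation patterns

Each tissue has two chained stage contrasts (pericarp: N2/N1, N3/N2;
endosperm: N5/N4, N6/N5).  *Intersection* mode requires the same DE direction
in all of a tissue's contrasts; *union* mode requires it in at least one (a
protein DE in both directions within a tissue in union mode is "mixed").
Cross-tissue classes are the cartesian product of per-tissue statuses;
(none, none) proteins are unclassified.  This is one concrete formalisation
of intersection/union pattern analysis; the mode is a flag.

## Annotation tallies

Category percentages are shares of **assignments**, not of proteins: a
protein annotated to two categories of an aspect contributes to both
numerators and twice to the denominator.  This is the reading under which
per-aspect shares sum to 100%, and it is flag-independent of the tally code.
KO assignment takes the best BLAST hit per query (highest bit score, ties to
the lexicographically smallest subject) under e-value ≤ 1e-05.

## Network integration

Candidates are proteins with `|log2 r_a − log2 r_b| ≥ log2(fold_min)`
(default fold_min = 5) in any configured contrast.  Differencing is done in
log space: subtracting linear-scale ratios would make a "5-fold" criterion
dimensionally incoherent (a `fold_space="linear"` escape hatch exists).  The
default contrast set is the 5 single contrasts against the control sample
plus the 15 unordered sample pairs (20 contrasts, configurable).  A contrast
carries a tissue label only when its samples lie within one tissue (single
contrasts take the sample's own tissue, the control acting as a neutral
reference); candidates triggered only by cross-tissue pairs belong to the
whole network but to neither tissue subnetwork, which is why the whole
network can carry more proteins than the two tissue subnetworks combined.

A study protein and its KO are one merged node (the protein stands in the
KO's graph position); explicit protein–KO relation edges appear only between
distinct proteins mapping to the same KO.  The graph includes the two-hop KO
interaction neighbourhood of every candidate KO plus the compounds attached
to any represented KO.  First-degree neighbours traverse KO–KO interaction
edges only; second-degree neighbours are neighbours-of-neighbours excluding
the focal node and the first ring.  Node and edge insertion is sorted, so
GraphML/edge-list serialisation is byte-stable.  KEGG data is consumed
exclusively as offline two-column link-style flat files; no live API is
called anywhere.

## qRT-PCR validation

Replicate triples whose max−min spread strictly exceeds 0.5 Ct are discarded
(a spread of exactly 0.5 passes — "exceeds" is read as strict).  Then

    ΔCt  = Ct(gene, sample) − Ct(reference gene, sample)
    ΔΔCt = ΔCt(sample) − ΔCt(calibrator sample)
    REV  = 2^(−ΔΔCt)

with β-actin as the default reference gene and the pericarp 10 DAP sample as
the default calibrator.  A gene whose calibrator cell fails QC has all its
REVs marked discarded rather than aborting the table (fail-soft, surfaced in
the QC status column).  No amplification-efficiency correction is applied —
the model is plain 2^(−ΔΔCt).

Concordance between an mRNA REV profile and a protein ratio profile is scored
per consecutive stage interval within each tissue as agreement of direction
categories, with a flat band of |log2 change| < log2(1.5) so "unchanged"
means the same thing on both sides.  A gene is completely concordant iff all
its evaluable intervals agree.  This interval-direction metric is a
formalisation of an otherwise qualitative comparison and is labelled as such
in outputs.

## Synthetic data: what it emulates and what it does not

Reporter intensities are `2^(baseline + effect + noise)` with baseline ~
U(14, 20) log2 units and noise i.i.d. N(0, noise_sd²) in log2 space —
log-normal multiplicative noise, the natural model when every decision is a
ratio threshold.  Default noise_sd is 0.1 log2 units; planted effects are
separated from every decision threshold by a margin (default `4 × noise_sd`),
which makes the true call under the exact pipeline thresholds decidable
without simulation calibration.  Planted features: per-comparison DE counts
(effect on the numerator sample only), per-tissue ≥5-fold candidates (with a
fold tail beyond the cutoff), cross-tissue-only candidates (the effect split
between tissues so only cross pairs trigger), stage- and tissue-specific
identification dropout, and planted FDR failures (confined to the null block
so planted truth survives filtering).  Truth calls are derived from the
planted effects, so cross-talk between blocks (an effect planted for one
contrast necessarily shifts the chained one) is part of the truth, not an
error source.

Simplifications: the control channel is modelled as a reference pool carrying
every protein at baseline abundance, so ratios are defined wherever a
reporter fires; noise is independent per channel (no channel bias, isotope
impurity bleed, or abundance-dependent variance); identifications never
depend on peptide sampling.  Passing tests therefore demonstrate the
correctness of the downstream arithmetic and set algebra under the declared
noise model — not robustness to the systematic effects a real instrument
adds.

Ct tables are inverted from planted REV profiles with symmetric replicate
triples (m−d, m, m+d), so the replicate mean is exact and downstream REV
recovery is limited only by float arithmetic; planted discards use a spread
of 0.62 Ct.  Exact-count identification fixtures solve the pairwise Venn
cells from printed marginal counts (stage totals, the all-three cell, the
three singles) and fail before generation when the implied cells are negative
or non-integral.

## Problem sizes and numerical choices

The test suite and acceptance script run studies of 150–2,000 proteins, which
is ample to separate the planted effects from the thresholds at the default
margins; call-recovery acceptance uses n = 2,000, noise_sd = 0.1 on the four
within-tissue stage contrasts (the contrasts whose calls the study reports as
DE counts).  Within-group folds cancel the control channel (noise sd √2 ×
noise_sd); cross-group folds involve two controls (2 × noise_sd), so
recovered counts on cross-tissue contrasts may deviate by ±1 from planted
values at the published count magnitudes.  Correlation distances are clipped
at 0 to guard tiny negative rounding; merge heights are compared at 1e-10
when canonicalising trees.  All randomness flows from a single integer seed
through `numpy.random.default_rng`; every generator is a pure function of
(parameters, seed).

## Known limitations

* No statistical significance model for ratios — calls are fixed-threshold,
  faithful to the quantitation scheme but blunt at low abundance.
* GO tallies are flat label counts; no ontology-graph propagation or
  enrichment testing.
* The network uses KO identity as the interaction proxy; two proteins on the
  same KO are topologically interchangeable apart from their relation edge.
* Cross-group ratios assume the 113 channel is biochemically identical in
  both runs; any labelling bias between runs propagates into cross-tissue
  calls undetected.
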